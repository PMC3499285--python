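"""Synthetic genomes, reference panels and diploid populations with known truth.

The generator emulates the study system end to end: multi-exon defensin
genes (2-exon by default, optionally 3-exon) whose exon-2 translation
carries exactly one six-cysteine motif, GT..AG introns, motif-free uniform
background sequence, a reference cDNA panel at controlled divergence, and
diploid animals carrying exon-2 SNPs at specified minor-allele
frequencies.  Default scales follow the study conditions: 14 animals for
SNP discovery, 35 for genotyping, a 57-entry reference panel.

Everything is driven by a single integer seed through one
``numpy.random.Generator``; identical configuration and seed give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .motif import (
    DEFAULT_SPACING,
    reverse_complement,
    scan_six_cys_motif,
    six_frame_translate,
    translate,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CYS = ("TGT", "TGC")
#: codons that encode neither a stop nor a cysteine (exon-2 filler)
_FILLER = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c not in _CYS
]
_NONSTOP = [c for c in _FILLER] + list(_CYS)

#: IUPAC codes for unordered base pairs (heterozygote in Sanger traces)
IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
}


@dataclass(frozen=True)
class SnpSpec:
    """One planted exon-2 SNP: 1-based coding position, alleles, frequency."""

    position: int
    major: str
    minor: str
    minor_freq: float

    def __post_init__(self):
        if not 0.0 <= self.minor_freq <= 0.5:
            raise ValueError("minor_freq must lie in [0, 0.5]")
        if self.major == self.minor:
            raise ValueError("alleles must differ")


@dataclass
class SimulationConfig:
    seed: int = 42
    n_contigs: int = 5
    contig_length: int = 200_000
    n_planted_genes: int = 10
    intron_length_range: Tuple[int, int] = (80, 800)
    panel_divergence_range: Tuple[float, float] = (0.0, 0.30)
    n_animals: int = 14
    allele_freqs: Dict[str, Sequence[SnpSpec]] = field(default_factory=dict)
    three_exon_fraction: float = 0.2
    exon2_codons: int = 45

    def __post_init__(self):
        if self.intron_length_range[0] < 4:
            raise ValueError("intron_length_range min must be >= 4 (room for GT..AG)")
        lo, hi = self.panel_divergence_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("panel_divergence_range must lie in [0, 1]")


@dataclass
class PlantedGene:
    """Ground-truth record for one simulated locus."""

    name: str
    contig_id: str
    strand: str
    exons: List[Tuple[int, int]]  # 1-based inclusive, forward strand
    cdna: str  # coding mRNA (exons spliced, coding orientation)
    peptide: str
    exon2_cds: str  # mature-peptide coding sequence incl. stop codon
    three_exon: bool


@dataclass
class PanelEntry:
    name: str
    sequence: str
    source_gene: str
    realized_divergence: float


@dataclass
class TruthSet:
    genes: List[PlantedGene] = field(default_factory=list)
    genotypes: Dict[str, Dict[int, List[Tuple[str, str]]]] = field(default_factory=dict)
    panel: List[PanelEntry] = field(default_factory=list)


def _random_codons(rng, n: int, pool: Sequence[str]) -> List[str]:
    return [pool[int(i)] for i in rng.integers(0, len(pool), size=n)]


def _mature_codons(rng, n_codons: int, spacing=DEFAULT_SPACING) -> Tuple[List[str], int, int]:
    """Exon-2 codons with exactly one six-cysteine motif embedded.

    Returns (codons, motif start codon, motif span in codons).
    """
    gaps = [lo for lo, _ in spacing]
    span = 6 + sum(gaps)
    if n_codons < span + 2:
        raise ValueError("exon2 too short for the motif")
    lead = int(rng.integers(1, n_codons - span - 1))
    codons = _random_codons(rng, n_codons, _FILLER)
    offs = [0]
    for g in gaps:
        offs.append(offs[-1] + g + 1)
    for o in offs:
        codons[lead + o] = _CYS[int(rng.integers(0, 2))]
    return codons, lead, span


def _make_intron(rng, length: int, next_exon_prefix: str) -> str:
    """GT..AG intron whose interior cannot mimic the downstream acceptor."""
    while True:
        mid = "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=length - 4))
        intron = "GT" + mid + "AG"
        if "AG" + next_exon_prefix[:6] not in intron[:-2]:
            return intron


def _make_gene(rng, cfg: SimulationConfig, name: str, three_exon: bool):
    """Build one gene cassette; returns (cassette, local exon coords, parts)."""
    exon1 = "ATG" + "".join(_random_codons(rng, 19, _NONSTOP))
    mature, motif_lead, motif_span = _mature_codons(rng, cfg.exon2_codons)
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    exon2_cds = "".join(mature) + stop
    # avoid a G at an exon start: keeps cDNA-guided donor placement unambiguous
    while exon2_cds[0] == "G":
        mature[0] = _FILLER[int(rng.integers(0, len(_FILLER)))]
        exon2_cds = "".join(mature) + stop
    lo, hi = cfg.intron_length_range
    parts: List[Tuple[str, str]] = [("exon", exon1)]
    if three_exon:
        # the extra junction falls outside the motif codons, so the motif
        # stays discoverable within a single genomic reading frame
        valid_cuts = [
            c for c in range(5, cfg.exon2_codons - 4)
            if (c <= motif_lead or c >= motif_lead + motif_span)
            and exon2_cds[3 * c] != "G"
        ]
        if not valid_cuts:
            # first motif cysteine codon starts with T, always a safe cut
            valid_cuts = [max(motif_lead, 5)]
        cut = 3 * valid_cuts[int(rng.integers(0, len(valid_cuts)))]
        left, right = exon2_cds[:cut], exon2_cds[cut:]
        i1 = _make_intron(rng, int(rng.integers(lo, hi + 1)), left)
        i2 = _make_intron(rng, int(rng.integers(lo, hi + 1)), right)
        parts += [("intron", i1), ("exon", left), ("intron", i2), ("exon", right)]
    else:
        i1 = _make_intron(rng, int(rng.integers(lo, hi + 1)), exon2_cds)
        parts += [("intron", i1), ("exon", exon2_cds)]
    cassette = "".join(s for _, s in parts)
    exons_local: List[Tuple[int, int]] = []
    pos = 0
    for kind, s in parts:
        if kind == "exon":
            exons_local.append((pos + 1, pos + len(s)))
        pos += len(s)
    cdna = exon1 + exon2_cds
    return cassette, exons_local, cdna, exon2_cds


def _spurious_motif(contig: str, gene_spans: List[Tuple[int, int]], spacing) -> bool:
    """True if a motif window falls outside every planted gene span."""
    L = len(contig)
    for frame, pep in six_frame_translate(contig).items():
        off = abs(frame) - 1
        for m in scan_six_cys_motif(pep, spacing):
            if frame > 0:
                s = off + 3 * m.start + 1
                e = off + 3 * (m.start + m.span)
            else:
                e = L - (off + 3 * m.start)
                s = L - (off + 3 * (m.start + m.span)) + 1
            if not any(gs <= s and e <= ge for gs, ge in gene_spans):
                return True
    return False


def simulate_genome(
    config: SimulationConfig, spacing=DEFAULT_SPACING
) -> Tuple[Dict[str, str], TruthSet]:
    """Generate contigs with planted defensin genes and the matching truth.

    Background is uniform ACGT, rejection-sampled so that no six-cysteine
    motif window survives outside a planted gene in any of the six frames
    (a clean negative control).  Genes are placed on random strands at
    non-overlapping positions with >= 200 bp flanks.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthSet()
    contigs: Dict[str, str] = {}
    per_contig = [config.n_planted_genes // config.n_contigs] * config.n_contigs
    for i in range(config.n_planted_genes % config.n_contigs):
        per_contig[i] += 1
    g_idx = 0
    for ci in range(config.n_contigs):
        cid = f"contig{ci + 1:02d}"
        n_genes = per_contig[ci]
        cassettes = []
        for _ in range(n_genes):
            name = f"gene{g_idx + 1:02d}"
            three = bool(rng.random() < config.three_exon_fraction)
            cassettes.append((name, three, _make_gene(rng, config, name, three)))
            g_idx += 1
        total_genes = sum(len(c[2][0]) for c in cassettes)
        margin = 200
        if total_genes + margin * (n_genes + 1) > config.contig_length:
            raise ValueError(
                f"contig_length {config.contig_length} too short for "
                f"{n_genes} genes on {cid}"
            )
        for _attempt in range(50):
            free = config.contig_length - total_genes
            cuts = np.sort(rng.integers(margin, free - margin, size=n_genes)) if n_genes else []
            pieces, spans, pos, prev = [], [], 0, 0
            genes_here = []
            ok = True
            for k, (name, three, (cassette, exons_local, cdna, exon2)) in enumerate(cassettes):
                gap = int(cuts[k]) - prev
                if gap < margin // 2:
                    ok = False
                    break
                prev = int(cuts[k])
                bg = "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=gap))
                strand = "+" if rng.random() < 0.5 else "-"
                placed = cassette if strand == "+" else reverse_complement(cassette)
                pieces += [bg, placed]
                start0 = pos + gap  # 0-based start of cassette
                clen = len(cassette)
                if strand == "+":
                    exons = [(start0 + a, start0 + b) for a, b in exons_local]
                else:
                    # transcription order kept; coordinates descend on '+' axis
                    exons = [(start0 + clen - b + 1, start0 + clen - a + 1) for a, b in exons_local]
                spans.append((start0 + 1, start0 + clen))
                pos = start0 + clen
                genes_here.append(
                    PlantedGene(name, cid, strand, exons, cdna, translate(cdna).rstrip("*"),
                                exon2, three)
                )
            if not ok:
                continue
            tail = config.contig_length - pos
            pieces.append("".join(_BASES[int(i)] for i in rng.integers(0, 4, size=tail)))
            contig = "".join(pieces)
            if not _spurious_motif(contig, spans, spacing):
                contigs[cid] = contig
                truth.genes.extend(genes_here)
                break
        else:
            raise RuntimeError("could not generate a motif-free background")
    return contigs, truth


def simulate_population(
    exon2_ref: str,
    snps: Sequence[SnpSpec],
    n_animals: int,
    seed: int,
    ensure_minor: bool = False,
) -> Tuple[List[Tuple[str, str]], Dict[int, List[Tuple[str, str]]]]:
    """Draw a diploid sample carrying the planted exon-2 SNPs.

    Each animal contributes two haplotypes (sequencing of an amplicon sees
    both alleles; a heterozygote shows two bases at the column).  Alleles
    are drawn binomially at each SNP's minor frequency.  With
    ``ensure_minor`` the sample is forced to carry at least one copy of
    each allele at every site (the discovery-panel setting: a variant table
    only lists sites actually observed to vary).

    Returns (per-animal haplotype pairs, truth genotypes keyed by
    position).
    """
    rng = np.random.default_rng(seed)
    for s in snps:
        if not 1 <= s.position <= len(exon2_ref):
            raise ValueError(f"SNP position {s.position} outside exon-2 coding span")
        if exon2_ref[s.position - 1] != s.major:
            raise ValueError(
                f"reference base at {s.position} is {exon2_ref[s.position - 1]}, "
                f"not major allele {s.major}"
            )
    haplos = [[list(exon2_ref), list(exon2_ref)] for _ in range(n_animals)]
    genotypes: Dict[int, List[Tuple[str, str]]] = {}
    for s in snps:
        draws = rng.random((n_animals, 2)) < s.minor_freq
        if ensure_minor and not draws.any():
            draws[0, 0] = True
        if ensure_minor and draws.all():
            draws[0, 0] = False
        per_animal = []
        for a in range(n_animals):
            pair = []
            for h in range(2):
                base = s.minor if draws[a, h] else s.major
                haplos[a][h][s.position - 1] = base
                pair.append(base)
            per_animal.append(tuple(pair))
        genotypes[s.position] = per_animal
    seqs = [("".join(h1), "".join(h2)) for h1, h2 in haplos]
    return seqs, genotypes


def iupac_consensus(pair: Tuple[str, str]) -> str:
    """Collapse a haplotype pair into one IUPAC-coded trace sequence."""
    return "".join(
        IUPAC_PAIR[frozenset((a, b))] for a, b in zip(pair[0], pair[1])
    )


def make_reference_panel(
    truth: TruthSet,
    divergence_range: Tuple[float, float],
    seed: int,
    names: Optional[Sequence[str]] = None,
    size: Optional[int] = None,
) -> List[PanelEntry]:
    """Derive a divergent cDNA reference panel from the truth genes.

    Each entry is a truth cDNA mutated site-wise at a divergence drawn
    uniformly from ``divergence_range`` (Jukes-Cantor-style: a mutated
    site takes one of the three other bases uniformly).  ``size`` entries
    are produced by cycling over the truth genes (default: one per gene);
    pass ``names`` to label entries, e.g. with a published reference list.
    """
    lo, hi = divergence_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("divergence_range must lie in [0, 1]")
    if not truth.genes:
        raise ValueError("empty truth set")
    rng = np.random.default_rng(seed)
    n = size if size is not None else len(truth.genes)
    entries: List[PanelEntry] = []
    for i in range(n):
        gene = truth.genes[i % len(truth.genes)]
        d = float(rng.uniform(lo, hi))
        seq = list(gene.cdna)
        mutated = 0
        for j in range(len(seq)):
            if rng.random() < d:
                alts = [b for b in _BASES if b != seq[j]]
                seq[j] = alts[int(rng.integers(0, 3))]
                mutated += 1
        name = names[i] if names else f"REF{i + 1:03d}_{gene.name}"
        entries.append(PanelEntry(name, "".join(seq), gene.name, mutated / len(seq)))
    truth.panel = entries
    return entries
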