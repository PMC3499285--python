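"""Exon-2 coding SNPs: calling, consequences, allele frequencies, assays.

The variant workflow mirrors amplicon resequencing of a diploid panel:
per-animal exon-2 sequences (haplotype pairs, or single traces with IUPAC
ambiguity codes at heterozygous columns) are compared column-wise to a
reference; biallelic polymorphic columns become SNP records; consequences
are annotated under frame offset 0 (position 1 is the first base of a
codon); minor allele frequencies are folded counts over non-missing
chromosomes.  PCR-RFLP assays are designed by scanning both allele
contexts with IUPAC-aware restriction sites, and in-silico PCR predicts
amplicon sizes (the genomic-vs-cDNA size difference is what makes an
assay splice-aware).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from .motif import reverse_complement, translate

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class SnpRecord:
    """One biallelic coding SNP in the exon-2 frame (offset 0)."""

    gene: str
    position: int  # 1-based bp within the exon-2 coding sequence
    major: str
    minor: str
    consequence: Optional[str] = None  # synonymous | nonsynonymous
    amino_acids: Optional[Tuple[str, str]] = None
    maf: Optional[float] = None
    n_chromosomes: Optional[int] = None

    @property
    def codon_index(self) -> int:
        """1-based codon number containing the SNP."""
        return (self.position - 1) // 3 + 1

    @property
    def codon_position(self) -> int:
        """Position of the SNP within its codon (1, 2 or 3)."""
        return (self.position - 1) % 3 + 1


@dataclass(frozen=True)
class RflpAssay:
    gene: str
    position: int
    enzyme: str
    site: str  # IUPAC recognition sequence
    cutting_allele: str
    site_start: int  # 1-based position of the site in the supplied context


@dataclass(frozen=True)
class Amplicon:
    forward: str
    reverse: str
    start: int  # 1-based position of the forward primer 5' end
    end: int  # 1-based position of the reverse primer 5' end on the template
    length: int


SequenceInput = Union[str, Tuple[str, str]]


def _expand_animal(seq: SequenceInput) -> Tuple[str, str]:
    """Turn one animal's input into an (h1, h2) haplotype pair.

    A plain string is a Sanger-style trace: IUPAC two-base codes mark
    heterozygous columns and expand into the two alleles.
    """
    if isinstance(seq, tuple):
        return seq
    h1, h2 = [], []
    for ch in seq.upper():
        bases = IUPAC_EXPAND.get(ch)
        if bases is None:
            raise ValueError(f"unknown base code {ch!r}")
        if len(bases) == 1:
            h1.append(bases)
            h2.append(bases)
        elif len(bases) == 2:
            h1.append(bases[0])
            h2.append(bases[1])
        else:
            h1.append("N")
            h2.append("N")
    return "".join(h1), "".join(h2)


def call_snps(
    animals: Sequence[SequenceInput],
    reference: str,
    gene: str = "",
) -> Tuple[List[SnpRecord], List[int]]:
    """Column-wise SNP calling against an exon-2 reference.

    All sequences must match the reference length (amplicons are assumed
    pre-trimmed/aligned).  Returns (biallelic records, flagged
    multi-allelic column positions).  The major allele is the more
    frequent one; ties resolve to the reference base.
    """
    ref = reference.upper()
    pairs = [_expand_animal(a) for a in animals]
    for h1, h2 in pairs:
        if len(h1) != len(ref) or len(h2) != len(ref):
            raise ValueError("sequence length differs from reference")
    records: List[SnpRecord] = []
    multi: List[int] = []
    for i, ref_base in enumerate(ref):
        counts: Dict[str, int] = {}
        for h1, h2 in pairs:
            for base in (h1[i], h2[i]):
                if base in "ACGT":
                    counts[base] = counts.get(base, 0) + 1
        alleles = sorted(counts)
        if len(alleles) <= 1:
            continue
        if len(alleles) > 2:
            multi.append(i + 1)
            continue
        a, b = alleles
        if counts[a] == counts[b]:
            major, minor = (a, b) if a == ref_base else (b, a)
        else:
            major, minor = (a, b) if counts[a] > counts[b] else (b, a)
        records.append(SnpRecord(gene, i + 1, major, minor))
    return records, multi


def annotate_consequence(record: SnpRecord, coding_sequence: str) -> SnpRecord:
    """Fill in the codon consequence of a SNP on its exon-2 CDS.

    The CDS is read in frame offset 0.  The reference codon is taken from
    the coding sequence (which must carry the major allele at the SNP
    position); the alternate codon substitutes the minor allele.
    """
    cds = coding_sequence.upper()
    if record.position > len(cds):
        raise ValueError(
            f"position {record.position} beyond coding length {len(cds)}"
        )
    ref_base = cds[record.position - 1]
    if ref_base == record.major:
        alt_base = record.minor
    elif ref_base == record.minor:
        # the sample-major allele can be the non-reference one
        alt_base = record.major
    else:
        raise ValueError(
            f"coding sequence has {ref_base} at position {record.position}, "
            f"matching neither allele {record.major}/{record.minor}"
        )
    c0 = (record.codon_index - 1) * 3
    ref_codon = cds[c0 : c0 + 3]
    if len(ref_codon) < 3:
        raise ValueError("SNP codon truncated by end of coding sequence")
    alt_codon = list(ref_codon)
    alt_codon[record.codon_position - 1] = alt_base
    alt_codon = "".join(alt_codon)
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    if ref_aa == alt_aa:
        return replace(record, consequence="synonymous", amino_acids=None)
    return replace(
        record, consequence="nonsynonymous", amino_acids=(ref_aa, alt_aa)
    )


def estimate_maf(genotypes: Sequence[Optional[str]]) -> Tuple[float, int]:
    """Folded minor allele frequency from per-animal diploid calls.

    Genotypes are two-letter strings ("AA", "AG", ...); None or "NN"
    marks a missing animal.  Returns (maf, number of non-missing
    chromosomes); the frequency is folded so maf <= 0.5.
    """
    counts: Dict[str, int] = {}
    n_chrom = 0
    for gt in genotypes:
        if gt is None or set(gt.upper()) <= {"N", ".", "-"}:
            continue
        for allele in gt.upper():
            counts[allele] = counts.get(allele, 0) + 1
            n_chrom += 1
    if n_chrom == 0:
        raise ValueError("all genotypes missing: allele frequency undefined")
    if len(counts) == 1:
        return 0.0, n_chrom
    minor_count = min(counts.values())
    return minor_count / n_chrom, n_chrom


def _iupac_match(site: str, seq: str) -> bool:
    return len(site) == len(seq) and all(
        b in IUPAC_EXPAND[s] for s, b in zip(site, seq)
    )


def find_sites(enzyme_site: str, seq: str) -> List[int]:
    """0-based start positions where an IUPAC recognition site matches."""
    k = len(enzyme_site)
    return [
        i for i in range(len(seq) - k + 1) if _iupac_match(enzyme_site, seq[i : i + k])
    ]


def design_rflp_assay(
    record: SnpRecord,
    context: str,
    snp_index: int,
    enzyme_table: Dict[str, str],
) -> List[RflpAssay]:
    """Find enzymes whose recognition site overlaps the SNP in exactly one allele.

    ``context`` is reference-allele flanking sequence with the SNP at
    0-based ``snp_index``; it must cover the SNP by at least the longest
    recognition site minus one on both sides.  For each enzyme both
    allele contexts are scanned over every window overlapping the SNP
    (IUPAC-expanded); an assay is reported when the overlapping site
    positions differ between the alleles — usually exactly one allele is
    cut, but a SNP that shifts a site also changes the fragment pattern.
    Either way the digest genotypes the SNP: the fragment patterns of the
    two alleles differ iff an assay is reported.
    """
    ctx = context.upper()
    if ctx[snp_index] not in (record.major, record.minor):
        raise ValueError("context carries neither allele at snp_index")
    longest = max(len(s) for s in enzyme_table.values())
    if snp_index < longest - 1 or len(ctx) - snp_index < longest:
        raise ValueError("flanking context too short for the enzyme table")
    with_major = ctx[:snp_index] + record.major + ctx[snp_index + 1 :]
    with_minor = ctx[:snp_index] + record.minor + ctx[snp_index + 1 :]
    assays: List[RflpAssay] = []
    for enzyme, site in sorted(enzyme_table.items()):
        k = len(site)
        hits = {}
        for allele, seq in ((record.major, with_major), (record.minor, with_minor)):
            overlapping = [
                i
                for i in find_sites(site, seq)
                if i <= snp_index <= i + k - 1
            ]
            hits[allele] = overlapping
        maj_sites, min_sites = set(hits[record.major]), set(hits[record.minor])
        if maj_sites == min_sites:
            continue
        extra_major = sorted(maj_sites - min_sites)
        extra_minor = sorted(min_sites - maj_sites)
        if extra_major and (not extra_minor or extra_major[0] <= extra_minor[0]):
            allele, pos = record.major, extra_major[0]
        else:
            allele, pos = record.minor, extra_minor[0]
        assays.append(
            RflpAssay(record.gene, record.position, enzyme, site, allele, pos + 1)
        )
    return assays


def digest_fragments(seq: str, site: str, cut_offset: int = 0) -> List[int]:
    """Fragment lengths of a complete digest (brute-force site scan)."""
    cuts = [i + cut_offset for i in find_sites(site, seq)]
    bounds = [0] + sorted(cuts) + [len(seq)]
    return [b - a for a, b in zip(bounds, bounds[1:]) if b > a]


def _matches_with_mismatch(primer: str, seq: str, start: int, max_mismatch: int) -> bool:
    window = seq[start : start + len(primer)]
    if len(window) < len(primer):
        return False
    return sum(1 for a, b in zip(primer, window) if a != b) <= max_mismatch


def insilico_pcr(
    template: str,
    forward: str,
    reverse: str,
    max_mismatch: int = 0,
    max_product: int = 20_000,
) -> List[Amplicon]:
    """Predict PCR products on the forward strand of a template.

    The forward primer must match the template, the reverse-complement of
    the reverse primer must match downstream; product length is the
    distance between primer 5' ends plus the reverse primer length.  All
    products are reported, sorted by start.
    """
    if len(forward) < 15 or len(reverse) < 15:
        raise ValueError("primers must be at least 15 nt")
    tpl = template.upper()
    fwd = forward.upper()
    rev_rc = reverse_complement(reverse.upper())
    fwd_hits = [
        i for i in range(len(tpl) - len(fwd) + 1)
        if _matches_with_mismatch(fwd, tpl, i, max_mismatch)
    ]
    rev_hits = [
        i for i in range(len(tpl) - len(rev_rc) + 1)
        if _matches_with_mismatch(rev_rc, tpl, i, max_mismatch)
    ]
    products: List[Amplicon] = []
    for f in fwd_hits:
        for r in rev_hits:
            rev_5p = r + len(rev_rc) - 1  # 5' end of the reverse primer
            if rev_5p <= f:
                continue
            length = (rev_5p - f) + 1
            if length > max_product:
                continue
            products.append(Amplicon(forward, reverse, f + 1, rev_5p + 1, length))
    products.sort(key=lambda p: (p.start, p.length))
    return products


# --------------------------------------------------------------------------
# VCF output (minimal, version 4.2)


def write_vcf(
    records: Iterable[SnpRecord],
    path,
    reference_name: str = "exon2",
) -> None:
    """Write SNP records as a minimal VCF 4.2 against per-gene exon-2 refs.

    Positions are 1-based within each gene's local exon-2 coding
    sequence; the gene is carried as the contig and in INFO.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##reference={reference_name}",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Codon consequence">',
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ref/alt amino acid">',
        '##INFO=<ID=MAF,Number=1,Type=Float,Description="Folded minor allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for r in records:
        info = [f"GENE={r.gene}"]
        if r.consequence:
            info.append(f"CSQ={r.consequence}")
        if r.amino_acids:
            info.append(f"AA={r.amino_acids[0]}/{r.amino_acids[1]}")
        if r.maf is not None:
            info.append(f"MAF={r.maf:.4g}")
        lines.append(
            f"{r.gene}\t{r.position}\t.\t{r.major}\t{r.minor}\t.\tPASS\t"
            + ";".join(info)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> List[SnpRecord]:
    """Read back the minimal VCF written by :func:`write_vcf`."""
    out: List[SnpRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            aa = fields.get("AA")
            out.append(
                SnpRecord(
                    gene=fields.get("GENE", chrom),
                    position=int(pos),
                    major=ref,
                    minor=alt,
                    consequence=fields.get("CSQ"),
                    amino_acids=tuple(aa.split("/")) if aa else None,
                    maf=float(fields["MAF"]) if "MAF" in fields else None,
                )
            )
    return out
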