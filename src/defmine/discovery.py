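"""Candidate beta-defensin discovery in genomic sequence.

The screen mirrors manual genome mining of a small gene family: translate
contigs in six frames, keep open reading frames containing the
six-cysteine motif, confirm homology to a reference cDNA panel by local
alignment with identity/coverage thresholds (plus a high-identity rescue
rule for short hits), and build exon-intron gene models under the GT-AG
splice rule, either guided by a cDNA or by junction enumeration.

Conventions (declared once, used throughout the package): genomic
coordinates are 1-based inclusive on the forward strand; peptide offsets
are 0-based; percent identity is matches over aligned columns with
internal gaps counted as columns and terminal gaps excluded; coverage is
the aligned fraction of the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .motif import (
    DEFAULT_SPACING,
    MotifMatch,
    reverse_complement,
    scan_six_cys_motif,
    six_frame_translate,
    translate,
)

# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class OrfCandidate:
    """A motif-containing open reading frame found by the six-frame scan."""

    contig_id: str
    strand: str  # '+' or '-'
    frame: int  # +1..+3 / -1..-3
    start: int  # 1-based inclusive, forward-strand coordinates
    end: int
    peptide: str
    motifs: Tuple[MotifMatch, ...]


@dataclass(frozen=True)
class HomologyHit:
    """Local-alignment hit of a candidate against one panel reference."""

    query_id: str
    reference_id: str
    percent_identity: float
    query_coverage: float
    status: str  # pass | rescued | fail


@dataclass
class GeneModel:
    """Exon-intron model of one defensin locus.

    ``exons`` are 1-based inclusive (start, end) pairs ordered 5'->3' in
    the coding direction; for strand '-' the coordinates still refer to
    the forward strand, with exon order following transcription.
    ``phases`` gives the CDS phase offset of each exon.
    """

    contig_id: str
    strand: str
    exons: List[Tuple[int, int]]
    phases: List[int]
    prepropeptide: str
    classification: str  # intact | three_exon | partial_psi | rejected
    reason: Optional[str] = None

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]


# --------------------------------------------------------------------------
# ORF scan


def _orf_bounds(peptide: str, pos: int) -> Tuple[int, int]:
    """Stop-free stretch [lo, hi) of ``peptide`` around residue ``pos``."""
    lo = peptide.rfind("*", 0, pos) + 1
    hi = peptide.find("*", pos)
    if hi == -1:
        hi = len(peptide)
    return lo, hi


def _frame_residue_to_genomic(frame: int, aa_index: int, length: int) -> Tuple[int, int]:
    """1-based inclusive genomic span of one residue in a six-frame peptide."""
    off = abs(frame) - 1
    if frame > 0:
        start0 = off + 3 * aa_index
        return start0 + 1, start0 + 3
    start0 = off + 3 * aa_index  # offset on the reverse complement
    return length - (start0 + 2), length - start0


def find_candidate_orfs(
    contigs: Dict[str, str],
    min_orf_aa: int = 31,
    spacing: Sequence[Tuple[int, int]] = DEFAULT_SPACING,
) -> List[OrfCandidate]:
    """Scan contigs for motif-containing ORFs in all six frames.

    An ORF here is a maximal stop-free stretch of one reading frame that
    contains at least one six-cysteine motif and is at least ``min_orf_aa``
    residues long.  Reported coordinates map exactly onto the genomic
    substring encoding the ORF.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    out: List[OrfCandidate] = []
    for cid, seq in contigs.items():
        length = len(seq)
        frames = six_frame_translate(seq)
        for frame, pep in frames.items():
            hits = scan_six_cys_motif(pep, spacing, peptide_id=cid)
            seen: set = set()
            for hit in hits:
                lo, hi = _orf_bounds(pep, hit.start)
                if (lo, hi) in seen:
                    continue
                seen.add((lo, hi))
                if hi - lo < min_orf_aa:
                    continue
                motifs = tuple(
                    m for m in hits if lo <= m.start and m.start + m.span <= hi
                )
                s1, _ = _frame_residue_to_genomic(frame, lo, length)
                _, e1 = _frame_residue_to_genomic(frame, hi - 1, length)
                if frame < 0:
                    s1, e1 = (
                        _frame_residue_to_genomic(frame, hi - 1, length)[0],
                        _frame_residue_to_genomic(frame, lo, length)[1],
                    )
                out.append(
                    OrfCandidate(
                        contig_id=cid,
                        strand="+" if frame > 0 else "-",
                        frame=frame,
                        start=s1,
                        end=e1,
                        peptide=pep[lo:hi],
                        motifs=motifs,
                    )
                )
    out.sort(key=lambda c: (c.contig_id, c.start, c.strand))
    return out


# --------------------------------------------------------------------------
# homology screen


def _nucleotide_aligner(local: bool = True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if local else "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def alignment_identity_coverage(alignment, query_len: int) -> Tuple[float, float]:
    """Percent identity over aligned columns and percent coverage of the query.

    Identity counts matches over all printed alignment columns (internal
    gaps included; a local alignment has no terminal gap columns).
    Coverage is the aligned query span as a fraction of the query length.
    """
    a, b = alignment[0], alignment[1]
    cols = len(a)
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    q0, q1 = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    identity = 100.0 * matches / cols if cols else 0.0
    coverage = 100.0 * (q1 - q0) / query_len if query_len else 0.0
    return identity, coverage


def classify_hit(
    percent_identity: float,
    query_coverage: float,
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
    rescue_identity: float = 80.0,
) -> str:
    """Apply the strict identity/coverage thresholds plus the rescue rule.

    A hit passes with identity > ``min_identity`` and coverage >
    ``min_coverage`` (strict inequalities); a short but highly similar hit
    (coverage <= ``min_coverage``, identity >= ``rescue_identity``) is
    rescued rather than discarded.
    """
    if percent_identity > min_identity and query_coverage > min_coverage:
        return "pass"
    if query_coverage <= min_coverage and percent_identity >= rescue_identity:
        return "rescued"
    return "fail"


def homology_screen(
    query_id: str,
    query_seq: str,
    panel: Dict[str, str],
    min_identity: float = 70.0,
    min_coverage: float = 50.0,
    rescue_identity: float = 80.0,
) -> List[HomologyHit]:
    """Screen one candidate nucleotide sequence against a reference panel.

    Pairwise local alignment with affine gaps against every panel entry;
    hits are returned sorted by percent identity (descending).
    """
    if not panel:
        raise ValueError("empty reference panel")
    if not query_seq:
        raise ValueError("empty query sequence")
    aligner = _nucleotide_aligner(local=True)
    hits: List[HomologyHit] = []
    for ref_id, ref_seq in panel.items():
        best = None
        for qseq in (query_seq, reverse_complement(query_seq)):
            alns = aligner.align(qseq, ref_seq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            ident, cov = alignment_identity_coverage(aln, len(query_seq))
            if best is None or (ident, cov) > best:
                best = (ident, cov)
        if best is None:
            best = (0.0, 0.0)
        status = classify_hit(best[0], best[1], min_identity, min_coverage, rescue_identity)
        hits.append(HomologyHit(query_id, ref_id, best[0], best[1], status))
    hits.sort(key=lambda h: -h.percent_identity)
    return hits


# --------------------------------------------------------------------------
# gene-model building


def _spliced_exact_alignment(
    region: str,
    cdna: str,
    intron_bounds: Tuple[int, int],
    max_exons: int = 4,
    donor_slack: int = 6,
) -> Optional[List[Tuple[int, int]]]:
    """Chain co-linear exact-match blocks of ``cdna`` in ``region``.

    Gaps between blocks must be GT..AG introns with lengths inside
    ``intron_bounds``.  Returns 0-based half-open exon intervals on
    ``region`` or None.  Depth-first search with backtracking over donor
    placement (a maximal exact match can overrun the true donor when the
    intron happens to begin with the same bases as the next exon).
    """
    lo_i, hi_i = intron_bounds
    n, m = len(region), len(cdna)

    def match_len(g: int, c: int) -> int:
        k = 0
        while g + k < n and c + k < m and region[g + k] == cdna[c + k]:
            k += 1
        return k

    def solve(g: int, c: int, exons: List[Tuple[int, int]]) -> Optional[List[Tuple[int, int]]]:
        k = match_len(g, c)
        if c + k == m:
            return exons + [(g, g + k)]
        if len(exons) + 1 >= max_exons:
            return None
        for e in range(k, max(k - donor_slack, 0), -1):
            if e == 0:
                continue
            donor = g + e
            if region[donor : donor + 2] != "GT":
                continue
            cc = c + e
            lo = donor + lo_i
            hi = min(donor + hi_i, n - 1)
            want = cdna[cc : cc + 8]
            j = lo
            while j <= hi:
                # intron is region[donor:j], acceptor "AG" at its 3' end
                if region[j - 2 : j] == "AG" and region[j : j + len(want)] == want:
                    res = solve(j, cc, exons + [(g, donor)])
                    if res is not None:
                        return res
                j += 1
        return None

    seed = cdna[: min(18, m)]
    start = region.find(seed)
    while start != -1:
        res = solve(start, 0, [])
        if res is not None:
            return res
        start = region.find(seed, start + 1)
    return None


def _guideless_model(
    region: str,
    intron_bounds: Tuple[int, int],
    spacing: Sequence[Tuple[int, int]],
) -> Optional[List[Tuple[int, int]]]:
    """Choose 2-exon junctions by GT..AG enumeration, maximizing the ORF.

    Exon 2 begins at an acceptor (AG immediately upstream, in frame with
    the motif), exon 1 is the longest in-frame ATG-led stop-free stretch
    ending at a GT donor within the intron bounds.  Returns 0-based
    half-open exon intervals or None.
    """
    lo_i, hi_i = intron_bounds
    n = len(region)
    best: Optional[Tuple[int, List[Tuple[int, int]]]] = None
    for off in range(3):
        pep = translate(region[off:])
        for hit in scan_six_cys_motif(pep, spacing):
            mlo, mhi = _orf_bounds(pep, hit.start)
            motif_nt = off + 3 * hit.start
            orf_end_nt = off + 3 * mhi  # exclusive; stop excluded
            stop_nt = orf_end_nt + 3 if mhi < len(pep) else orf_end_nt
            # acceptor candidates: in-frame positions upstream of the motif
            # with AG immediately before and no stop before the motif
            for acc in range(motif_nt, off + 3 * mlo - 1, -3):
                if acc < 2 or region[acc - 2 : acc] != "AG":
                    continue
                for donor in range(acc - lo_i, max(acc - hi_i, 0) - 1, -1):
                    if region[donor : donor + 2] != "GT":
                        continue
                    # exon 1: in-frame, ends at donor, starts at ATG, stop-free
                    s = donor - 3
                    start1 = None
                    while s >= 0:
                        codon = region[s : s + 3]
                        if codon in ("TAA", "TAG", "TGA"):
                            break
                        if codon == "ATG":
                            start1 = s
                        s -= 3
                    if start1 is None:
                        continue
                    total = (donor - start1) + (stop_nt - acc)
                    cand = [(start1, donor), (acc, stop_nt)]
                    key = (total, -start1)
                    if best is None or key > (best[0], -best[1][0][0]):
                        best = (total, cand)
    return best[1] if best else None


def build_gene_model(
    region: str,
    contig_id: str = "region",
    guide_cdna: Optional[str] = None,
    intron_bounds: Tuple[int, int] = (60, 10_000),
    spacing: Sequence[Tuple[int, int]] = DEFAULT_SPACING,
    strand: str = "+",
    region_offset: int = 0,
) -> GeneModel:
    """Build an exon-intron model for a candidate region.

    With ``guide_cdna``, exons are the co-linear exact-match blocks whose
    gaps are GT..AG introns within ``intron_bounds`` (cDNA-guided splice
    determination); without a guide, junctions are enumerated under the
    GT-AG rule to maximize the motif-containing ORF.  ``region`` must be
    given in the coding orientation; for ``strand == '-'`` pass the
    reverse complement of the forward-strand region and the model's
    coordinates are mapped back to forward-strand 1-based positions.
    ``region_offset`` is the 0-based forward-strand offset of the region's
    first base.
    """
    exons0: Optional[List[Tuple[int, int]]] = None
    reason = None
    if guide_cdna:
        exons0 = _spliced_exact_alignment(region, guide_cdna, intron_bounds)
        if exons0 is None:
            reason = "non-canonical splice"
    else:
        exons0 = _guideless_model(region, intron_bounds, spacing)
        if exons0 is None:
            reason = "no GT-AG consistent model"

    if exons0 is None:
        return GeneModel(contig_id, strand, [], [], "", "rejected", reason)

    cds = "".join(region[a:b] for a, b in exons0)
    pep = translate(cds)
    phases, acc = [], 0
    for a, b in exons0:
        phases.append(acc % 3)
        acc += b - a

    if strand == "+":
        exons = [(region_offset + a + 1, region_offset + b) for a, b in exons0]
    else:
        L = len(region)
        exons = [
            (region_offset + (L - b) + 1, region_offset + (L - a))
            for a, b in exons0
        ]
    model = GeneModel(contig_id, strand, exons, phases, pep.rstrip("*"), "unclassified")
    model.classification = classify_candidate(model, spacing)
    return model


def classify_candidate(
    model: GeneModel, spacing: Sequence[Tuple[int, int]] = DEFAULT_SPACING
) -> str:
    """Classify a built model: intact, three_exon, partial_psi or rejected.

    Intact: full exon set (>=2 exons), no internal stop, motif present in
    the translation.  Three-exon models otherwise intact keep their own
    label.  A model lacking exon 1 (single exon-2-like exon whose
    translation starts mid-peptide, i.e. no initiator methionine) is a
    partial pseudogene; anything else is rejected.
    """
    if not model.exons:
        return "rejected"
    pep = model.prepropeptide
    has_motif = bool(scan_six_cys_motif(pep, spacing))
    internal_stop = "*" in pep
    if len(model.exons) == 1:
        return "partial_psi" if has_motif and not internal_stop else "rejected"
    if internal_stop or not has_motif or not pep.startswith("M"):
        return "rejected"
    return "three_exon" if len(model.exons) == 3 else "intact"
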