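"""Six-frame translation and the six-cysteine motif scanner.

Beta-defensin mature peptides carry a diagnostic disulfide scaffold of six
cysteines with fixed spacing, C-X6-C-X4-C-X9-C-X6-C-C.  The scanner reports
every window of a peptide matching that spacing (configurable as per-spacer
intervals); translation is codon-table based with ambiguous codons rendered
as X so that an N in the genome can never fake a cysteine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

from Bio.Data.CodonTable import standard_dna_table

#: Default spacer intervals (min, max) between consecutive cysteines:
#: C-X6-C-X4-C-X9-C-X6-C-C.
DEFAULT_SPACING: Tuple[Tuple[int, int], ...] = ((6, 6), (4, 4), (9, 9), (6, 6), (0, 0))

#: Residue span of a motif match under the default (fixed) spacing.
DEFAULT_MOTIF_SPAN = 6 + 6 + 4 + 9 + 6 + 0  # 6 cysteines + 25 spacer residues = 31

_CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate(dna: str) -> str:
    """Translate a coding sequence; codons with non-ACGT letters become X."""
    seq = dna.upper()
    out = []
    for i in range(0, len(seq) - 2, 3):
        out.append(_CODON_TABLE.get(seq[i : i + 3], "X"))
    return "".join(out)


def six_frame_translate(dna: str) -> Dict[int, str]:
    """Translate ``dna`` in all six frames.

    Returns a mapping from frame key to peptide.  Frames +1/+2/+3 start at
    offsets 0/1/2 of the forward strand; -1/-2/-3 at offsets 0/1/2 of the
    reverse complement.  Frame f has ``(L - offset) // 3`` codons.
    """
    if len(dna) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(dna)
    frames: Dict[int, str] = {}
    for off in range(3):
        frames[off + 1] = translate(dna[off:])
        frames[-(off + 1)] = translate(rc[off:])
    return frames


@dataclass(frozen=True)
class MotifMatch:
    """One six-cysteine motif hit within a peptide.

    ``start`` and ``cysteine_offsets`` are 0-based residue offsets;
    ``span`` is the number of residues from the first to the last cysteine
    inclusive.
    """

    peptide_id: str
    start: int
    cysteine_offsets: Tuple[int, int, int, int, int, int]
    span: int


def scan_six_cys_motif(
    peptide: str,
    spacing: Sequence[Tuple[int, int]] = DEFAULT_SPACING,
    peptide_id: str = "",
) -> List[MotifMatch]:
    """Report all (possibly overlapping) six-cysteine motif matches.

    ``spacing`` gives, for each of the five gaps between consecutive
    cysteines, the (min, max) number of intervening residues.  X never
    matches C.  Matches are sorted by start offset.
    """
    if len(spacing) != 5:
        raise ValueError("spacing must give 5 inter-cysteine intervals")
    pep = peptide.upper()
    n = len(pep)
    matches: List[MotifMatch] = []

    fixed = all(lo == hi for lo, hi in spacing)
    if fixed:
        gaps = [lo for lo, _ in spacing]
        span = 6 + sum(gaps)
        offs = [0]
        for g in gaps:
            offs.append(offs[-1] + g + 1)
        for i in range(n - span + 1):
            if all(pep[i + o] == "C" for o in offs):
                cys = tuple(i + o for o in offs)
                matches.append(MotifMatch(peptide_id, i, cys, span))
        return matches

    def extend(offsets: List[int], gap_idx: int) -> None:
        if gap_idx == 5:
            cys = tuple(offsets)
            matches.append(
                MotifMatch(peptide_id, cys[0], cys, cys[-1] - cys[0] + 1)
            )
            return
        lo, hi = spacing[gap_idx]
        last = offsets[-1]
        for g in range(lo, hi + 1):
            j = last + g + 1
            if j < n and pep[j] == "C":
                extend(offsets + [j], gap_idx + 1)

    for i in range(n):
        if pep[i] == "C":
            extend([i], 0)
    matches.sort(key=lambda m: m.start)
    return matches
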