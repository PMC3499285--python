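"""Prepropeptide phylogenetics: alignment, JTT distances, NJ, bootstrap, naming.

The annotation strategy names each newly found gene after its nearest
human reference: pairwise identity nominates the ortholog, clade
membership in a bootstrap consensus tree confirms it, and a legacy table
preserves historical names (with the evidence recorded rather than
silently overridden).  Distances are maximum-likelihood estimates under
the JTT empirical model; trees come from neighbor joining with
majority-rule bootstrap consensus.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import minimize_scalar

from .jtt_model import AMINO_ACIDS, JTT_FREQUENCIES, transition_matrix

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

MAX_JTT_DISTANCE = 5.0


# --------------------------------------------------------------------------
# pairwise alignment and identity


def _protein_aligner(gap_open: float = 7.0, gap_extend: float = 0.2) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("GONNET1992")
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def align_pair(
    a: str,
    b: str,
    gap_open: float = 7.0,
    gap_extend: float = 0.2,
) -> Tuple[str, str, float]:
    """Optimal global alignment of two peptides (GONNET scores).

    Gap open/extension penalties default to 7 and 0.2 (the first gap
    position costs the opening penalty).  Returns (aligned_a, aligned_b,
    score); ties are broken deterministically by taking the aligner's
    first (high-road) traceback.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _protein_aligner(gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def identity_from_aligned(row_a: str, row_b: str) -> float:
    """Percent identity over aligned columns, terminal gaps excluded."""
    n = len(row_a)
    start = 0
    while start < n and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    end = n
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    cols = end - start
    if cols <= 0:
        return 0.0
    matches = sum(
        1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-"
    )
    return 100.0 * matches / cols


def percent_identity(a: str, b: str, **align_kwargs) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``."""
    ra, rb, _ = align_pair(a, b, **align_kwargs)
    return identity_from_aligned(ra, rb)


# --------------------------------------------------------------------------
# JTT maximum-likelihood distance


def _pair_counts(row_a: str, row_b: str) -> np.ndarray:
    counts = np.zeros((20, 20))
    for x, y in zip(row_a, row_b):
        i = _AA_INDEX.get(x)
        j = _AA_INDEX.get(y)
        if i is not None and j is not None:
            counts[i, j] += 1
    return counts


def jtt_log_likelihood(t: float, counts: np.ndarray) -> float:
    """Log-likelihood of a pairwise divergence time given site-pair counts."""
    P = transition_matrix(t)
    return float(np.sum(counts * np.log(JTT_FREQUENCIES[:, None] * P)))


def jtt_distance(
    a: str,
    b: str,
    aligned: bool = False,
    cap: float = MAX_JTT_DISTANCE,
) -> float:
    """ML evolutionary distance (substitutions/site) under the JTT model.

    Sequences are globally aligned first unless ``aligned`` (then equal
    length is required and gap/X columns are skipped).  The likelihood is
    maximized over t in [1e-6, cap] by bounded Brent search; estimates at
    the cap are truncated there.
    """
    if aligned:
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        ra, rb = a, b
    else:
        ra, rb, _ = align_pair(a, b)
    counts = _pair_counts(ra, rb)
    total = counts.sum()
    if total == 0:
        raise ValueError("no shared ungapped columns: distance undefined")
    if counts.trace() == total:
        return 0.0
    res = minimize_scalar(
        lambda t: -jtt_log_likelihood(t, counts),
        bounds=(1e-6, cap),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(min(res.x, cap))


def simulate_jtt_pair(
    t: float, n_sites: int, seed: int
) -> Tuple[str, str]:
    """Draw a sequence pair at true divergence ``t`` under the JTT model."""
    rng = np.random.default_rng(seed)
    anc = rng.choice(20, size=n_sites, p=JTT_FREQUENCIES)
    P = transition_matrix(t)
    der = np.array([rng.choice(20, p=P[i]) for i in anc])
    return (
        "".join(AMINO_ACIDS[i] for i in anc),
        "".join(AMINO_ACIDS[i] for i in der),
    )


# --------------------------------------------------------------------------
# distance matrices and neighbor joining


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a fixed taxon order."""

    taxa: List[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


@dataclass
class PhyloTree:
    """Unrooted tree with branch lengths and optional bootstrap supports."""

    newick: str
    taxa: List[str] = field(default_factory=list)

    def as_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.newick, schema="newick")

    def clades(self) -> set:
        """Nontrivial bipartitions, each as the side excluding the first taxon."""
        tree = self.as_dendropy()
        all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        ref = sorted(all_taxa)[0]
        out = set()
        for node in tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            side = leaves if ref not in leaves else all_taxa - leaves
            if 1 < len(side) < len(all_taxa) - 1:
                out.add(side)
        return out

    def supports(self) -> Dict[frozenset, int]:
        """Bootstrap support (percent) per internal-branch bipartition."""
        tree = self.as_dendropy()
        all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        ref = sorted(all_taxa)[0]
        out: Dict[frozenset, int] = {}
        for node in tree.preorder_internal_node_iter():
            if node.parent_node is None or node.label is None:
                continue
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            side = leaves if ref not in leaves else all_taxa - leaves
            out[side] = int(round(float(node.label)))
        return out


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is chosen; ties break on the
    lowest (row, column) index pair.  Negative branch lengths are clamped
    to zero with the deficit transferred to the sibling branch.
    """
    n = len(d.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = d.matrix[0, 1] / 2.0
        nwk = f"({_quote(d.taxa[0])}:{half:.10g},{_quote(d.taxa[1])}:{half:.10g});"
        return PhyloTree(nwk, list(d.taxa))
    D = d.matrix.copy()
    labels = [_quote(t) for t in d.taxa]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or Q[i, j] < best[0] - 1e-12:
                    best = (Q[i, j], i, j)
        _, bi, bj = best
        i_id, j_id = active[bi], active[bj]
        dij = sub[bi, bj]
        li = dij / 2.0 + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = dij, 0.0
        if lj < 0:
            li, lj = dij, 0.0
        new_label = f"({labels[i_id]}:{li:.10g},{labels[j_id]}:{lj:.10g})"
        new_row = np.zeros(D.shape[0] + 1)
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        for k in active:
            if k in (i_id, j_id):
                continue
            D[u, k] = D[k, u] = (D[i_id, k] + D[j_id, k] - dij) / 2.0
        labels.append(new_label)
        active = [k for k in active if k not in (i_id, j_id)] + [u]
    # final 3-way (or smaller) join
    a, b, c = active
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = D[a, b] - la
    lc = D[a, c] - la
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    nwk = (
        f"({labels[a]}:{la:.10g},{labels[b]}:{lb:.10g},{labels[c]}:{lc:.10g});"
    )
    return PhyloTree(nwk, list(d.taxa))


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def distance_matrix(
    records: Sequence[Tuple[str, str]],
    metric: str = "jtt",
    aligned: bool = True,
) -> DistanceMatrix:
    """All-pairs distances from (possibly aligned) peptide records."""
    names = [n for n, _ in records]
    seqs = [s for _, s in records]
    n = len(names)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "jtt":
                M[i, j] = M[j, i] = jtt_distance(seqs[i], seqs[j], aligned=aligned)
            elif metric == "p":
                pairs = [
                    (x, y)
                    for x, y in zip(seqs[i], seqs[j])
                    if x in _AA_INDEX and y in _AA_INDEX
                ]
                if not pairs:
                    raise ValueError("no shared ungapped columns")
                M[i, j] = M[j, i] = sum(1 for x, y in pairs if x != y) / len(pairs)
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(names, M)


# --------------------------------------------------------------------------
# bootstrap consensus


def _tree_bipartitions(tree: PhyloTree, taxa: Sequence[str]) -> set:
    full = frozenset(taxa)
    ref = sorted(taxa)[0]
    out = set()
    dtree = tree.as_dendropy()
    for node in dtree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label.replace(" ", "_") for l in node.leaf_iter())
        side = leaves if ref not in leaves else full - leaves
        if 1 < len(side) < len(full) - 1:
            out.add(side)
    return out


def _compatible(s: frozenset, kept: Sequence[frozenset]) -> bool:
    return all(s <= t or t <= s or not (s & t) for t in kept)


def bootstrap_consensus(
    alignment: Sequence[Tuple[str, str]],
    n_reps: int = 1000,
    collapse: float = 50.0,
    seed: int = 42,
    metric: str = "jtt",
) -> PhyloTree:
    """Majority-rule bootstrap consensus of NJ trees.

    Alignment columns are resampled with replacement per replicate (the
    random stream is indexed by the column draw only, so supports do not
    depend on taxon input order); branches below the ``collapse`` percent
    threshold are collapsed into polytomies.  Supports are attached as
    internal node labels.
    """
    names = [_quote(n) for n, _ in alignment]
    seqs = [s for _, s in alignment]
    if len(names) < 3:
        raise ValueError("need at least 3 taxa")
    L = len(seqs[0])
    if L < 2 or any(len(s) != L for s in seqs):
        raise ValueError("need an alignment with >= 2 columns of equal length")
    rng = np.random.default_rng(seed)
    counts: Dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep = [(n, "".join(s[c] for c in cols)) for n, s in zip(names, seqs)]
        tree = nj_tree(distance_matrix(rep, metric=metric, aligned=True))
        for side in _tree_bipartitions(tree, names):
            counts[side] = counts.get(side, 0) + 1
    kept: List[Tuple[frozenset, float]] = []
    for side, c in sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))):
        pct = 100.0 * c / n_reps
        if pct < collapse:
            continue
        if _compatible(side, [s for s, _ in kept]):
            kept.append((side, pct))
    # build the consensus tree by nesting retained clades
    full = frozenset(names)

    def render(members: frozenset, children_sets: List[Tuple[frozenset, float]]) -> str:
        direct = []
        used = set()
        for s, pct in sorted(children_sets, key=lambda kv: -len(kv[0])):
            if s <= members and not any(s < t for t, _ in direct):
                direct.append((s, pct))
        parts = []
        for s, pct in direct:
            inner = [(t, p) for t, p in children_sets if t < s]
            parts.append(f"{render(s, inner)}{int(round(pct))}")
            used |= s
        for leaf in sorted(members - used):
            parts.append(leaf)
        return "(" + ",".join(parts) + ")"

    top = [(s, p) for s, p in kept]
    nwk = render(full, top) + ";"
    return PhyloTree(nwk, names)


# --------------------------------------------------------------------------
# ortholog naming


@dataclass
class NameAssignment:
    candidate_id: str
    name: Optional[str]
    nearest_reference: str
    identity: float
    ambiguous: bool = False
    legacy_applied: bool = False
    tree_confirmed: Optional[bool] = None
    evidence: str = ""


_NUM_RE = re.compile(r"(\d+[A-Za-z]?)$")


def reference_number(ref_name: str) -> str:
    m = _NUM_RE.search(ref_name)
    if not m:
        raise ValueError(f"cannot extract gene number from {ref_name!r}")
    return m.group(1)


def assign_ortholog_name(
    candidate_id: str,
    candidate_seq: str,
    panel: Dict[str, str],
    legacy_table: Optional[Dict[str, str]] = None,
    tree: Optional[PhyloTree] = None,
    tie_tolerance: float = 0.5,
    prefix: str = "pBD",
) -> NameAssignment:
    """Name a candidate after its nearest human reference.

    The reference with the highest percent identity nominates the number;
    two references within ``tie_tolerance`` identity points trigger an
    ambiguity flag instead of a silent choice.  A legacy table (historic
    names kept to avoid confusion) overrides the nomination, with the
    nearest reference still recorded as evidence.  When a bootstrap tree
    is supplied, clade membership confirms (or flags) the nomination.
    """
    if not panel:
        raise ValueError("empty reference panel")
    scored = sorted(
        ((percent_identity(candidate_seq, seq), ref) for ref, seq in panel.items()),
        key=lambda t: (-t[0], t[1]),
    )
    best_ident, best_ref = scored[0]
    evidence = f"nearest={best_ref} ({best_ident:.2f}% identity)"
    tree_confirmed = None
    if tree is not None:
        tree_confirmed = _clade_confirms(tree, candidate_id, best_ref, set(panel))
        evidence += f"; clade_confirms={tree_confirmed}"
    legacy_table = legacy_table or {}
    if candidate_id in legacy_table:
        return NameAssignment(
            candidate_id, legacy_table[candidate_id], best_ref, best_ident,
            legacy_applied=True, tree_confirmed=tree_confirmed,
            evidence=evidence + "; legacy name retained",
        )
    if len(scored) > 1 and best_ident - scored[1][0] < tie_tolerance:
        return NameAssignment(
            candidate_id, None, best_ref, best_ident, ambiguous=True,
            tree_confirmed=tree_confirmed,
            evidence=evidence + f"; tie with {scored[1][1]} ({scored[1][0]:.2f}%)",
        )
    name = f"{prefix}{reference_number(best_ref)}"
    return NameAssignment(
        candidate_id, name, best_ref, best_ident,
        tree_confirmed=tree_confirmed, evidence=evidence,
    )


def _clade_confirms(
    tree: PhyloTree, candidate: str, chosen_ref: str, panel_ids: set
) -> bool:
    """Does the smallest clade joining the candidate to any reference
    contain the chosen one?"""
    dtree = tree.as_dendropy()
    cand = _quote(candidate)
    node = None
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon.label.replace(" ", "_") == cand:
            node = leaf
            break
    if node is None:
        return False
    panel_q = {_quote(p) for p in panel_ids}
    while node.parent_node is not None:
        node = node.parent_node
        leaves = {l.taxon.label.replace(" ", "_") for l in node.leaf_iter()}
        refs_here = leaves & panel_q
        if refs_here:
            return _quote(chosen_ref) in refs_here
    return False
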