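"""Alignment, JTT distances, neighbor joining, bootstrap and naming."""

import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from defmine import (
    DistanceMatrix,
    align_pair,
    assign_ortholog_name,
    bootstrap_consensus,
    distance_matrix,
    jtt_distance,
    nj_tree,
    percent_identity,
    simulate_jtt_pair,
)
from defmine.jtt_model import transition_matrix
from defmine.phylo import jtt_log_likelihood, _pair_counts

GONNET = substitution_matrices.load("GONNET1992")


# --------------------------------------------------------------------------
# pairwise alignment


def brute_force_best_score(a, b, gap_open=7.0, gap_extend=0.2):
    """Enumerate all global alignments of two short peptides.

    Gap runs cost open + (k-1)*extend, matching the aligner's convention.
    """
    best = -np.inf

    def gap_cost(k):
        return gap_open + (k - 1) * gap_extend if k else 0.0

    def rec(i, j, score, in_gap):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + GONNET[a[i], b[j]], None)
        if i < len(a):
            pen = gap_extend if in_gap == "a" else gap_open
            rec(i + 1, j, score - pen, "a")
        if j < len(b):
            pen = gap_extend if in_gap == "b" else gap_open
            rec(i, j + 1, score - pen, "b")

    rec(0, 0, 0.0, None)
    return best


def test_identical_alignment_scores_diagonal():
    seq = "ACDEFGHIKL"
    ra, rb, score = align_pair(seq, seq)
    assert ra == rb == seq
    assert score == pytest.approx(sum(GONNET[x, x] for x in seq))


def test_single_gap_alignment_matches_enumeration():
    ra, rb, score = align_pair("ACDE", "ACE")
    assert score == pytest.approx(brute_force_best_score("ACDE", "ACE"))
    assert sum(1 for x, y in zip(ra, rb) if "-" in (x, y)) == 1


@pytest.mark.parametrize("seed", [0, 1])
def test_alignment_score_matches_enumeration_on_short_peptides(seed):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(15):
        a = "".join(rng.choice(aas, size=rng.integers(2, 5)))
        b = "".join(rng.choice(aas, size=rng.integers(2, 5)))
        _, _, score = align_pair(a, b)
        assert score == pytest.approx(brute_force_best_score(a, b))


def test_alignment_is_symmetric():
    ra, rb, s1 = align_pair("MKWVTFISLL", "MKWVTISLL")
    rb2, ra2, s2 = align_pair("MKWVTISLL", "MKWVTFISLL")
    assert s1 == pytest.approx(s2)
    assert (ra, rb) == (ra2, rb2)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        align_pair("", "ACD")


def test_percent_identity_examples():
    assert percent_identity("ACDEFG", "ACDEFG") == pytest.approx(100.0)
    assert percent_identity("ACGT", "ACGA") == pytest.approx(75.0)
    assert percent_identity("MKWVTF", "MKWVT") == pytest.approx(
        percent_identity("MKWVT", "MKWVTF")
    )


# --------------------------------------------------------------------------
# JTT distance


def test_jtt_identical_sequences_zero():
    assert jtt_distance("ACDEFGHIKL" * 5, "ACDEFGHIKL" * 5) == 0.0


def test_jtt_estimate_agrees_with_grid_search():
    """Brent optimum matches a coarse-to-fine likelihood grid to 1e-4."""
    a, b = simulate_jtt_pair(0.5, 400, seed=9)
    counts = _pair_counts(a, b)
    est = jtt_distance(a, b, aligned=True)
    coarse = np.arange(0.001, 5.0, 0.001)
    ll = [jtt_log_likelihood(t, counts) for t in coarse]
    t0 = coarse[int(np.argmax(ll))]
    fine = np.arange(max(t0 - 0.002, 1e-6), t0 + 0.002, 1e-5)
    llf = [jtt_log_likelihood(t, counts) for t in fine]
    t_grid = fine[int(np.argmax(llf))]
    assert abs(est - t_grid) <= 1e-4


def test_jtt_monotone_in_substitution_load():
    base = "ACDEFGHIKLMNPQRSTVWY" * 10
    prev = 0.0
    swapped = list(base)
    rng = np.random.default_rng(2)
    for k in range(0, 60, 10):
        for idx in rng.choice(len(base), size=10, replace=False):
            cur = swapped[idx]
            swapped[idx] = "W" if cur != "W" else "Y"
        d = jtt_distance(base, "".join(swapped), aligned=True)
        assert d >= prev - 1e-9
        prev = d


def test_jtt_no_shared_columns_rejected():
    with pytest.raises(ValueError):
        jtt_distance("XX", "XX", aligned=True)


def test_jtt_distance_agrees_with_phangorn(tmp_path):
    """Independent oracle: phangorn's ML JTT distance on a small alignment."""
    a, b = simulate_jtt_pair(0.4, 300, seed=3)
    fasta = tmp_path / "pair.fasta"
    fasta.write_text(f">a\n{a}\n>b\n{b}\n")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(phangorn))
        aln <- read.phyDat("{fasta}", format = "fasta", type = "AA")
        d <- as.matrix(dist.ml(aln, model = "JTT"))
        cat(d[1, 2])
        """
    )
    res = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    oracle = float(res.stdout.strip().split()[-1])
    ours = jtt_distance(a, b, aligned=True)
    assert ours == pytest.approx(oracle, rel=0.02)


# --------------------------------------------------------------------------
# neighbor joining


def test_two_taxon_tree_splits_distance():
    t = nj_tree(DistanceMatrix(["A", "B"], np.array([[0.0, 2.0], [2.0, 0.0]])))
    assert t.newick == "(A:1,B:1);"


def test_additive_four_taxon_matrix_recovered_exactly():
    taxa = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]], dtype=float
    )
    tree = nj_tree(DistanceMatrix(taxa, D))
    assert tree.clades() == {frozenset({"C", "D"})}  # AB|CD split
    # additivity: path lengths reproduce the input matrix
    pdm = tree.as_dendropy().phylogenetic_distance_matrix()
    tax = {t.label: t for t in pdm.taxon_iter()}
    for i, j in itertools.combinations(range(4), 2):
        assert pdm.distance(tax[taxa[i]], tax[taxa[j]]) == pytest.approx(D[i, j])


def test_asymmetric_matrix_rejected():
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def random_additive_case(rng, n_taxa):
    """Random topology + positive branch lengths -> (taxa, D, clades).

    Built by random sequential joins; each subtree is a map
    leaf -> distance to the subtree root, so path lengths are exact.
    """
    taxa = [f"T{i}" for i in range(n_taxa)]
    idx = {t: i for i, t in enumerate(taxa)}
    D = np.zeros((n_taxa, n_taxa))
    subtrees = [{t: 0.0} for t in taxa]
    merged_sets = []
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b_i, b_j = rng.uniform(0.2, 1.0, size=2)
        a, b = subtrees[i], subtrees[j]
        for la, da in a.items():
            for lb, db in b.items():
                d = da + b_i + db + b_j
                D[idx[la], idx[lb]] = D[idx[lb], idx[la]] = d
        merged = {la: da + b_i for la, da in a.items()}
        merged.update({lb: db + b_j for lb, db in b.items()})
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(merged)
        merged_sets.append(frozenset(merged))
    full = frozenset(taxa)
    ref = sorted(taxa)[0]
    clades = set()
    for s in merged_sets:
        side = s if ref not in s else full - s
        if 1 < len(side) < n_taxa - 1:
            clades.add(side)
    return taxa, D, clades


def test_nj_recovers_random_additive_topologies():
    rng = np.random.default_rng(7)
    for _ in range(25):
        n = int(rng.integers(4, 9))
        taxa, D, want = random_additive_case(rng, n)
        got = nj_tree(DistanceMatrix(taxa, D)).clades()
        assert got == want


def test_nj_agrees_with_scikit_bio_on_additive_matrix():
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(13)
    taxa, D, _ = random_additive_case(rng, 7)
    ours = nj_tree(DistanceMatrix(taxa, D)).clades()
    sk_tree = skbio_nj(SkbioDM(D, ids=taxa))
    full = frozenset(taxa)
    theirs = set()
    for node in sk_tree.non_tips(include_self=False):
        leaves = frozenset(t.name for t in node.tips())
        side = leaves if taxa[0] not in leaves else full - leaves
        if 1 < len(side) < len(taxa) - 1:
            theirs.add(side)
    assert ours == theirs


# --------------------------------------------------------------------------
# bootstrap consensus


STRUCTURED = [
    ("A", "AAAAAAAAAAAAAAA"),
    ("B", "AAAAAAAAAAAAAAC"),
    ("C", "CCCCCCCCCCCCCCA"),
    ("D", "CCCCCCCCCCCCCCC"),
]


def test_repeated_column_alignment_full_support():
    tree = bootstrap_consensus(STRUCTURED, n_reps=100, seed=1, metric="p")
    assert set(tree.supports().values()) == {100}
    assert frozenset({"C", "D"}) in tree.supports()


def test_bootstrap_deterministic_under_seed():
    t1 = bootstrap_consensus(STRUCTURED, n_reps=50, seed=5, metric="p")
    t2 = bootstrap_consensus(STRUCTURED, n_reps=50, seed=5, metric="p")
    assert t1.newick == t2.newick


def test_star_signal_collapses_to_polytomy():
    """Equal support for conflicting splits never clears the 50% bar."""
    # the three conflicting quartet splits appear in exactly equal numbers
    cols = {"A": "AAA", "B": "ACC", "C": "CAC", "D": "CCA"}
    aln = [(k, v * 8) for k, v in cols.items()]
    tree = bootstrap_consensus(aln, n_reps=50, seed=3, metric="p")
    assert tree.supports() == {}
    assert tree.clades() == set()


def test_supports_invariant_to_taxon_order():
    t1 = bootstrap_consensus(STRUCTURED, n_reps=80, seed=9, metric="p")
    t2 = bootstrap_consensus(STRUCTURED[::-1], n_reps=80, seed=9, metric="p")
    assert t1.supports() == t2.supports()


def test_too_few_columns_rejected():
    with pytest.raises(ValueError):
        bootstrap_consensus([("A", "A"), ("B", "C"), ("C", "G")], n_reps=10)


# --------------------------------------------------------------------------
# ortholog naming


def _mutate(seq, n, rng, alphabet="ARNDEQGHILKFPSTWYV"):
    out = list(seq)
    for idx in rng.choice(len(seq), size=n, replace=False):
        choices = [a for a in alphabet if a != out[idx]]
        out[idx] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def test_candidate_named_after_nearest_reference():
    rng = np.random.default_rng(4)
    base = "MRVLYLLFSFLFLALQVSPGLS" + "ARNDEQGHILKF" * 4
    ref121 = _mutate(base, 4, rng)
    ref123 = _mutate(base, 20, rng)
    cand = _mutate(ref121, 2, rng)
    asn = assign_ortholog_name(
        "candX", cand, {"DEFB121": ref121, "DEFB123": ref123}
    )
    assert asn.name == "pBD121"
    assert asn.nearest_reference == "DEFB121"
    assert not asn.ambiguous


def test_legacy_name_retained_with_evidence():
    rng = np.random.default_rng(5)
    base = "MKLLVVLGLAVLSAQA" + "HILKFPSTWY" * 5
    ref4 = _mutate(base, 3, rng)
    ref1 = _mutate(base, 25, rng)
    cand = _mutate(ref4, 2, rng)
    asn = assign_ortholog_name(
        "pBD1", cand, {"DEFB4": ref4, "DEFB1": ref1}, legacy_table={"pBD1": "pBD1"}
    )
    assert asn.name == "pBD1"
    assert asn.legacy_applied
    assert "nearest=DEFB4" in asn.evidence


def test_equidistant_references_flag_ambiguity():
    base = "MKLLVVLGLAVLSAQA" + "HILKFPSTWY" * 5
    asn = assign_ortholog_name("c", base, {"DEFB115": base, "DEFB116": base})
    assert asn.ambiguous
    assert asn.name is None


def test_naming_deterministic():
    rng = np.random.default_rng(6)
    base = "MKLLVVLGLAVLSAQA" + "HILKFPSTWY" * 5
    panel = {f"DEFB{100 + i}": _mutate(base, 5 + i, rng) for i in range(5)}
    cand = _mutate(panel["DEFB102"], 1, rng)
    runs = {assign_ortholog_name("c", cand, panel).name for _ in range(3)}
    assert runs == {"pBD102"}
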