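"""SNP calling, consequence annotation, MAF, RFLP design, in-silico PCR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from defmine import (
    SnpRecord,
    SnpSpec,
    annotate_consequence,
    call_snps,
    design_rflp_assay,
    digest_fragments,
    estimate_maf,
    insilico_pcr,
    iupac_consensus,
    read_vcf,
    reverse_complement,
    simulate_population,
    translate,
    write_vcf,
)
from defmine import fixtures as fx


# --------------------------------------------------------------------------
# SNP calling


def test_monomorphic_panel_gives_no_snps():
    ref = "ATGGCTAAAGGGTTT" * 4
    records, multi = call_snps([ref] * 14, ref)
    assert records == [] and multi == []


def test_snp_fixture_population_reproduces_all_rows():
    refs = fx.exon2_reference_cds()
    specs = fx.exon2_snp_specs()
    want = {
        (row["gene"], int(row["position"]), row["major"], row["minor"])
        for _, row in fx.snp_table().iterrows()
    }
    got = set()
    for gene, spec_list in specs.items():
        ref = refs[gene]
        seqs, _ = simulate_population(ref, spec_list, 14, seed=101, ensure_minor=True)
        records, _ = call_snps([iupac_consensus(p) for p in seqs], ref, gene=gene)
        for r in records:
            alleles = tuple(sorted((r.major, r.minor)))
            for g, p, ma, mi in want:
                if g == gene and p == r.position and alleles == tuple(sorted((ma, mi))):
                    got.add((g, p, ma, mi))
    assert got == want


def test_caller_equals_columnwise_oracle():
    """Planted variants (incl. a 1/28-chromosome singleton) match a direct
    per-column comparison of all haplotypes."""
    rng = np.random.default_rng(8)
    ref = "".join(rng.choice(list("ACGT"), size=90))
    specs = [
        SnpSpec(10, ref[9], "A" if ref[9] != "A" else "G", 0.3),
        SnpSpec(50, ref[49], "C" if ref[49] != "C" else "T", 0.0),
    ]
    seqs, _ = simulate_population(ref, specs, 14, seed=9, ensure_minor=True)
    # singleton at position 50: exactly one carrier chromosome
    records, _ = call_snps(seqs, ref)
    haplos = [h for pair in seqs for h in pair]
    oracle = []
    for i in range(len(ref)):
        col = {h[i] for h in haplos}
        if len(col) == 2:
            oracle.append(i + 1)
    assert [r.position for r in records] == oracle
    assert 50 in oracle  # the singleton is detected


def test_multiallelic_column_flagged_not_emitted():
    ref = "ATGGCTAAAGGGTTT"
    animals = [ref, ref[:5] + "A" + ref[6:], ref[:5] + "G" + ref[6:]]
    records, multi = call_snps(animals, ref)  # column 6 has T/A/G
    assert multi == [6]
    assert all(r.position != 6 for r in records)


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        call_snps(["ACGT"], "ACGTA")


def test_het_iupac_trace_expands_to_two_alleles():
    ref = "ATGGCTAAAGGGTTT"
    trace = ref[:5] + "W" + ref[6:]  # T/A heterozygote at column 6
    records, _ = call_snps([trace, ref], ref)
    (r,) = records
    assert r.position == 6 and {r.major, r.minor} == {"T", "A"}


# --------------------------------------------------------------------------
# consequence annotation


def test_printed_codon_contexts():
    # position 65, G/A at codon position 2 of an arginine codon -> R/K
    cds = "GCT" * 21 + "AGG" + "GCT" * 10
    r = annotate_consequence(SnpRecord("g", 65, "G", "A"), cds)
    assert r.consequence == "nonsynonymous" and r.amino_acids == ("R", "K")
    # position 144, A/T third-position change CAA -> CAT is Q/H
    cds = "GCT" * 47 + "CAA" + "GCT" * 10
    r = annotate_consequence(SnpRecord("g", 144, "A", "T"), cds)
    assert r.consequence == "nonsynonymous" and r.amino_acids == ("Q", "H")
    # position 171, A/G at a 4-fold-degenerate third position: CTA -> CTG
    cds = "GCT" * 56 + "CTA" + "GCT" * 10
    r = annotate_consequence(SnpRecord("g", 171, "A", "G"), cds)
    assert r.consequence == "synonymous" and r.amino_acids is None


def test_snp_fixture_synonymous_positions_are_third_codon_positions():
    df = fx.snp_table()
    syn = df[df["amino_acids"] == "."]
    assert (syn["position"] % 3 == 0).all()
    refs = fx.exon2_reference_cds()
    nonsyn = 0
    for _, row in df.iterrows():
        r = annotate_consequence(
            SnpRecord(row["gene"], int(row["position"]), row["major"], row["minor"]),
            refs[row["gene"]],
        )
        if r.consequence == "nonsynonymous":
            nonsyn += 1
            assert "/".join(r.amino_acids) == row["amino_acids"]
        else:
            assert row["amino_acids"] == "."
    assert nonsyn == 3


def test_position_beyond_cds_rejected():
    with pytest.raises(ValueError):
        annotate_consequence(SnpRecord("g", 100, "A", "G"), "ATGGCT")


@pytest.mark.parametrize("seed", [0, 1])
def test_annotator_agrees_with_full_translation_diff(seed):
    """Codon-level annotation equals diffing full ref/alt peptide translations."""
    rng = np.random.default_rng(seed)
    bases = list("ACGT")
    for _ in range(500):
        n_codons = int(rng.integers(5, 30))
        cds = "".join(rng.choice(bases, size=3 * n_codons))
        pos = int(rng.integers(1, 3 * n_codons + 1))
        ref_base = cds[pos - 1]
        alt = bases[int(rng.integers(4))]
        if alt == ref_base:
            continue
        rec = annotate_consequence(SnpRecord("g", pos, ref_base, alt), cds)
        alt_cds = cds[: pos - 1] + alt + cds[pos:]
        same = translate(cds) == translate(alt_cds)
        assert (rec.consequence == "synonymous") == same


# --------------------------------------------------------------------------
# minor allele frequency


def test_maf_hand_counted_example():
    # 35 animals, 14 minor alleles among 70 chromosomes -> 0.2
    gts = ["AG"] * 14 + ["AA"] * 21
    maf, n = estimate_maf(gts)
    assert (maf, n) == (0.2, 70)


def test_maf_monomorphic_zero():
    assert estimate_maf(["AA", "AA", "AA"]) == (0.0, 6)


def test_maf_fold_boundary():
    assert estimate_maf(["AA", "AG", "GG"]) == (0.5, 6)


def test_maf_missing_handling_and_error():
    maf, n = estimate_maf(["AG", None, "NN", "AA"])
    assert n == 4 and maf == 0.25
    with pytest.raises(ValueError):
        estimate_maf([None, "NN"])


@given(st.lists(st.sampled_from(["AA", "AG", "GG"]), min_size=1, max_size=40))
@settings(max_examples=100, derandomize=True)
def test_maf_invariant_under_allele_relabeling(gts):
    swapped = [g.replace("A", "x").replace("G", "A").replace("x", "G") for g in gts]
    assert estimate_maf(gts) == estimate_maf(swapped)


# --------------------------------------------------------------------------
# RFLP design


def _enzymes():
    return fx.enzyme_table()


def test_ecorv_differential_site():
    # context GAT[A/G]TC: allele A completes GATATC
    ctx = "TTTTTCTTTGATGTCTTTTTCTTT"
    rec = SnpRecord("g", 13, "G", "A")
    assays = design_rflp_assay(rec, ctx, 12, {"EcoRV": "GATATC"})
    (a,) = assays
    assert a.enzyme == "EcoRV" and a.cutting_allele == "A"


def test_iupac_site_cut_by_both_alleles_not_reported():
    # CC[A/T]GG completes BstNI's CCWGG for both alleles -> no assay
    ctx = "TTTTTTTTCCAGGTTTTTTTT"
    rec = SnpRecord("g", 11, "A", "T")
    assert design_rflp_assay(rec, ctx, 10, {"BstNI": "CCWGG"}) == []
    # but CC[A/C]GG is completed only by the A allele
    rec2 = SnpRecord("g", 11, "C", "A")
    ctx2 = "TTTTTTTTCCCGGTTTTTTTT"
    (a,) = design_rflp_assay(rec2, ctx2, 10, {"BstNI": "CCWGG"})
    assert a.cutting_allele == "A"


def test_no_differential_context_empty():
    ctx = "TTTTTTTTTTATTTTTTTTTT"
    rec = SnpRecord("g", 11, "A", "G")
    assert design_rflp_assay(rec, ctx, 10, _enzymes()) == []


def test_flank_too_short_rejected():
    with pytest.raises(ValueError):
        design_rflp_assay(SnpRecord("g", 2, "A", "G"), "TAT", 1, _enzymes())


@pytest.mark.parametrize("seed", [0, 1])
def test_designer_agrees_with_double_digest_oracle(seed):
    """Assay reported iff complete digests of the two allele sequences differ."""
    rng = np.random.default_rng(seed)
    enzymes = _enzymes()
    for _ in range(100):
        ctx = "".join(rng.choice(list("ACGT"), size=40))
        idx = 20
        major = ctx[idx]
        minor = rng.choice([b for b in "ACGT" if b != major])
        rec = SnpRecord("g", idx + 1, major, str(minor))
        assays = {a.enzyme for a in design_rflp_assay(rec, ctx, idx, enzymes)}
        alt = ctx[:idx] + str(minor) + ctx[idx + 1 :]
        oracle = {
            name
            for name, site in enzymes.items()
            if digest_fragments(ctx, site) != digest_fragments(alt, site)
        }
        assert assays == oracle


# --------------------------------------------------------------------------
# in-silico PCR


FWD = "ATGCGTACGGATCCTTA"
REV = "TTGCCAGTAGGCAATCC"


def test_constructed_template_single_product():
    insert = "ACGT" * 12 + "AC"  # 50 bp
    template = FWD + insert + reverse_complement(REV)
    (amp,) = insilico_pcr(template, FWD, REV)
    assert amp.length == len(FWD) + 50 + len(REV)
    assert amp.start == 1 and amp.end == len(template)


def test_genomic_vs_spliced_template_size_difference():
    exon_gap = "GCTA" * 5
    intron = "GT" + "A" * 96 + "AG"  # 100 bp, GT..AG
    cdna = FWD + exon_gap + reverse_complement(REV)
    genomic = FWD + exon_gap[:10] + intron + exon_gap[10:] + reverse_complement(REV)
    (amp_c,) = insilico_pcr(cdna, FWD, REV)
    (amp_g,) = insilico_pcr(genomic, FWD, REV)
    assert amp_g.length - amp_c.length == 100


def test_repeated_primer_site_reports_all_products_sorted():
    spacer = "GGGCCCAAATTT"
    template = FWD + spacer + FWD + spacer + reverse_complement(REV)
    amps = insilico_pcr(template, FWD, REV)
    assert len(amps) == 2
    assert amps[0].start < amps[1].start
    assert amps[0].end == amps[1].end


def test_pcr_matches_naive_scan_oracle():
    rng = np.random.default_rng(5)
    template = "".join(rng.choice(list("ACGT"), size=400))
    template = template[:50] + FWD + template[50:300] + reverse_complement(REV) + template[300:]
    amps = insilico_pcr(template, FWD, REV)
    starts = [i for i in range(len(template)) if template.startswith(FWD, i)]
    rc = reverse_complement(REV)
    ends = [i + len(rc) for i in range(len(template)) if template.startswith(rc, i)]
    oracle = sorted(
        (s + 1, e) for s in starts for e in ends if e - s >= len(FWD) + len(REV)
    )
    assert [(a.start, a.end) for a in amps] == oracle


def test_short_primer_rejected():
    with pytest.raises(ValueError):
        insilico_pcr("ACGT" * 20, "ACGTACGT", REV)


def test_no_site_empty_result():
    assert insilico_pcr("ACGT" * 30, FWD, REV) == []


# --------------------------------------------------------------------------
# VCF round trip


def test_vcf_round_trip(tmp_path):
    recs = [
        SnpRecord("pBD4", 65, "G", "A", "nonsynonymous", ("R", "K"), 0.451, 70),
        SnpRecord("pBD1", 171, "A", "G", "synonymous", None, 0.177, 70),
    ]
    path = tmp_path / "out.vcf"
    write_vcf(recs, path)
    back = read_vcf(path)
    assert [(r.gene, r.position, r.major, r.minor, r.consequence) for r in back] == [
        (r.gene, r.position, r.major, r.minor, r.consequence) for r in recs
    ]
    assert back[0].amino_acids == ("R", "K")
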