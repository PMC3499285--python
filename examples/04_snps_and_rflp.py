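"""Call exon-2 SNPs in a diploid panel, annotate codons, design RFLPs.

Rebuilds the packaged SNP-table population fixture: 14 animals carrying
every tabulated variant, Sanger-style traces with IUPAC heterozygote
codes, column-wise calling, codon consequences under frame offset 0,
folded minor allele frequencies, and restriction-enzyme assay design.
"""

from defmine import (
    annotate_consequence,
    call_snps,
    design_rflp_assay,
    estimate_maf,
    insilico_pcr,
    iupac_consensus,
    reverse_complement,
    simulate_population,
)
from defmine import fixtures as fx

refs = fx.exon2_reference_cds()
enzymes = fx.enzyme_table()
total = []
for gene, specs in sorted(fx.exon2_snp_specs().items()):
    ref = refs[gene]
    seqs, genotypes = simulate_population(ref, specs, 14, seed=9, ensure_minor=True)
    traces = [iupac_consensus(pair) for pair in seqs]
    records, _ = call_snps(traces, ref, gene=gene)
    for rec in records:
        rec = annotate_consequence(rec, ref)
        maf, n = estimate_maf(["".join(p) for p in genotypes[rec.position]])
        assays = design_rflp_assay(rec, ref, rec.position - 1, enzymes)
        aa = "/".join(rec.amino_acids) if rec.amino_acids else "-"
        enz = ",".join(a.enzyme for a in assays) or "-"
        print(f"{gene:8s} pos {rec.position:3d} {rec.major}/{rec.minor} "
              f"{rec.consequence:14s} aa {aa:4s} MAF {maf:.3f} (2n={n}) RFLP: {enz}")
        total.append(rec)

n_nonsyn = sum(r.consequence == "nonsynonymous" for r in total)
print(f"\n{len(total)} coding SNPs in {len({r.gene for r in total})} genes; "
      f"{n_nonsyn} nonsynonymous")
print("(MAF is the folded minor-allele count over non-missing chromosomes;")
print(" an RFLP enzyme is listed when its digest distinguishes the alleles)")

# in-silico PCR: a genomic template with an intron vs its spliced cDNA
fwd, rev = "ATGCGTACGGATCCTTA", "TTGCCAGTAGGCAATCC"
exonic = "GCTA" * 6
intron = "GT" + "C" * 120 + "AG"
cdna = fwd + exonic + reverse_complement(rev)
genomic = fwd + exonic[:12] + intron + exonic[12:] + reverse_complement(rev)
(pc,) = insilico_pcr(cdna, fwd, rev)
(pg,) = insilico_pcr(genomic, fwd, rev)
print(f"\nin-silico PCR: cDNA product {pc.length} bp vs genomic {pg.length} bp "
      f"(difference = {pg.length - pc.length} bp intron, distinguishing the templates)")
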