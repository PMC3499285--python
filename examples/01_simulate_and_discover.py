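"""Simulate a genome with planted defensin genes and rediscover them.

Builds a 2-contig synthetic genome carrying 4 two/three-exon defensin
loci on random strands, scans all six reading frames for the
six-cysteine motif, screens candidates against a divergent cDNA panel,
and rebuilds exon-intron models with cDNA guidance under the GT-AG rule.
"""

from defmine import (
    SimulationConfig,
    build_gene_model,
    find_candidate_orfs,
    homology_screen,
    make_reference_panel,
    reverse_complement,
    simulate_genome,
)

cfg = SimulationConfig(seed=42, n_contigs=2, contig_length=60_000, n_planted_genes=4)
contigs, truth = simulate_genome(cfg)
panel = {e.name: e.sequence for e in make_reference_panel(truth, (0.05, 0.25), seed=43)}

candidates = find_candidate_orfs(contigs)
print(f"planted {len(truth.genes)} genes; six-frame motif scan found "
      f"{len(candidates)} candidate ORFs")

exact = 0
for gene in truth.genes:
    region = contigs[gene.contig_id]
    oriented = region if gene.strand == "+" else reverse_complement(region)
    hits = homology_screen(gene.name, gene.cdna, panel)
    best = hits[0]
    model = build_gene_model(
        oriented, gene.contig_id, guide_cdna=gene.cdna, strand=gene.strand
    )
    ok = model.exons == gene.exons
    exact += ok
    print(f"  {gene.name} ({gene.strand}, {len(gene.exons)} exons): "
          f"best panel hit {best.reference_id} at {best.percent_identity:.0f}% "
          f"identity -> model {model.classification}, exact coordinates: {ok}")

print(f"{exact}/{len(truth.genes)} loci recovered with exact exon coordinates")
print("(a candidate passes the screen at >70% identity and >50% coverage;")
print(" exact recovery means every exon boundary matches the planted truth)")
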