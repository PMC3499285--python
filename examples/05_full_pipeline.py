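"""Run the full pipeline end to end from one seed.

One config drives simulation, discovery, phylogeny/naming, synteny and
variant calling; every stage writes standard formats (FASTA, GFF3,
Newick, VCF, TSV) into the output directory and the run report records
counts and warnings.
"""

import json

from defmine import PipelineConfig, run_pipeline

config = PipelineConfig(seed=7, outdir="pipeline_demo")
report = run_pipeline(config)

print("per-stage record counts:")
print(json.dumps(report.counts, indent=2))
print("\nwarnings (rescues, ties, unplaced genes):")
for w in report.warnings:
    print(" -", w)
print(f"\noutputs in {config.outdir}/: genome.fasta, models.gff3, tree.nwk,")
print("identity_matrix.tsv, synteny_events.tsv, variants.vcf, rflp_assays.tsv ...")
print("rerunning with the same seed reproduces every file byte for byte")
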