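"""Compare defensin cluster architecture between the pig and human maps.

Builds anchor-bounded clusters from the packaged coordinate fixtures and
classifies cross-species events: conserved order, clusters split across
chromosomes, and order changes.
"""

from defmine import build_clusters, compare_cluster_architecture
from defmine import fixtures as fx
from defmine.synteny import render_comparative_map

_, legacy_numbers = fx.legacy_tables()
pig, unplaced = build_clusters(fx.pig_positions(), fx.anchor_table())
human, _ = build_clusters(fx.human_positions())

print(f"pig: {len(pig)} anchored clusters "
      f"({', '.join(f'{c.chromosome}={len(c.members)}' for c in pig)})")
for gene in unplaced:
    print(f"  {gene.gene} is unplaced in the assembly "
          f"(most likely position: {gene.inferred_position})")

print("\ncross-species events (gene names number-normalized, legacy mapped):")
for ev in compare_cluster_architecture(pig, human, legacy_numbers):
    if ev.kind in ("conserved", "split", "order_change"):
        print(f"  {ev.kind:12s} {' + '.join(ev.source_clusters)}")
        print(f"  {'':12s} -> {' + '.join(ev.target_clusters)}")

print("\ncomparative map (anchors flank each ordered cluster):")
print(render_comparative_map({"pig": pig, "human": human}, legacy_numbers))
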