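"""End-to-end orchestration: simulate -> discover -> annotate -> synteny -> SNPs.

One config, one seed, one output directory.  The single seed fans out to
per-stage seeds through a fixed derivation so a run is reproducible from
one number; every output file is written in a format the package can read
back.  Stage warnings surface the cases the screen adjudicates by rule
rather than by thresholds alone (rescued homology hits, naming ties,
anchor discrepancies).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import fixtures
from .discovery import (
    GeneModel,
    build_gene_model,
    find_candidate_orfs,
    homology_screen,
)
from .io import read_fasta, write_fasta, write_gff3
from .motif import reverse_complement, translate
from .phylo import (
    assign_ortholog_name,
    distance_matrix,
    nj_tree,
    percent_identity,
)
from .simulate import (
    SimulationConfig,
    iupac_consensus,
    make_reference_panel,
    simulate_genome,
    simulate_population,
)
from .synteny import build_clusters, compare_cluster_architecture, render_comparative_map
from .variants import annotate_consequence, call_snps, design_rflp_assay, estimate_maf, write_vcf


@dataclass
class PipelineConfig:
    seed: int = 42
    outdir: str = "defmine_out"
    # simulation scale (the demo study system)
    n_contigs: int = 2
    contig_length: int = 60_000
    n_planted_genes: int = 4
    intron_length_range: Tuple[int, int] = (80, 600)
    panel_divergence_range: Tuple[float, float] = (0.0, 0.25)
    n_animals: int = 14
    # discovery thresholds
    min_identity: float = 70.0
    min_coverage: float = 50.0
    rescue_identity: float = 80.0
    min_orf_aa: int = 31
    intron_bounds: Tuple[int, int] = (60, 10_000)
    # phylogeny / naming
    bootstrap_reps: int = 1000
    collapse_percent: float = 50.0
    name_tie_tolerance: float = 0.5
    # synteny
    max_gap: int = 2_000_000
    # optional external inputs (skip simulation when given)
    genome_fasta: Optional[str] = None
    panel_fasta: Optional[str] = None
    guides_fasta: Optional[str] = None

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("intron_length_range", "panel_divergence_range", "intron_bounds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    parameters: dict
    counts: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    wall_time_s: float = 0.0

    def to_file(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                dict(
                    parameters=self.parameters,
                    counts=self.counts,
                    warnings=self.warnings,
                    wall_time_s=round(self.wall_time_s, 2),
                ),
                indent=2,
            )
            + "\n"
        )


def _stage_seeds(seed: int, n: int = 8) -> List[int]:
    """Fan one seed out to per-stage seeds (fixed derivation)."""
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def discover_genes(
    contigs: Dict[str, str],
    panel: Dict[str, str],
    guides: Dict[str, str],
    config: PipelineConfig,
) -> Tuple[List[Tuple[str, GeneModel]], pd.DataFrame, List[str]]:
    """Motif scan + homology screen + cDNA-guided model building."""
    warnings: List[str] = []
    candidates = find_candidate_orfs(contigs, min_orf_aa=config.min_orf_aa)
    rows = []
    models: List[Tuple[str, GeneModel]] = []
    for idx, cand in enumerate(candidates):
        cand_id = f"cand{idx + 1:03d}"
        genomic = contigs[cand.contig_id][cand.start - 1 : cand.end]
        if cand.strand == "-":
            genomic = reverse_complement(genomic)
        hits = homology_screen(
            cand_id, genomic, panel,
            config.min_identity, config.min_coverage, config.rescue_identity,
        )
        passing = [h for h in hits if h.status == "pass"]
        rescued = [h for h in hits if h.status == "rescued"]
        best = (passing or rescued or hits or [None])[0]
        if not passing and rescued:
            h = rescued[0]
            warnings.append(
                f"{cand_id}: retained by rescue vs {h.reference_id} "
                f"(coverage {h.query_coverage:.0f}%, identity {h.percent_identity:.0f}%)"
            )
        kept = best is not None and best.status in ("pass", "rescued")
        model = None
        if kept:
            region = contigs[cand.contig_id]
            oriented = region if cand.strand == "+" else reverse_complement(region)
            for guide_seq in guides.values():
                m = build_gene_model(
                    oriented, cand.contig_id, guide_cdna=guide_seq,
                    intron_bounds=config.intron_bounds, strand=cand.strand,
                )
                if m.classification != "rejected" and any(
                    s <= cand.end and e >= cand.start
                    for s, e in (tuple(sorted(x)) for x in m.exons)
                ):
                    model = m
                    break
            if model is None:
                model = build_gene_model(
                    oriented, cand.contig_id, guide_cdna=None,
                    intron_bounds=config.intron_bounds, strand=cand.strand,
                )
            models.append((cand_id, model))
        rows.append(
            dict(
                candidate=cand_id, contig=cand.contig_id, strand=cand.strand,
                start=cand.start, end=cand.end,
                best_reference=best.reference_id if best else ".",
                identity=round(best.percent_identity, 2) if best else np.nan,
                coverage=round(best.query_coverage, 2) if best else np.nan,
                status=best.status if best else "no_hit",
                classification=model.classification if model else ".",
            )
        )
    return models, pd.DataFrame(rows), warnings


def run_pipeline(config: PipelineConfig) -> RunReport:
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    report = RunReport(parameters=asdict(config))

    # stage 1: inputs (simulated study system or user files)
    if config.genome_fasta:
        contigs = read_fasta(config.genome_fasta)
        panel = read_fasta(config.panel_fasta) if config.panel_fasta else {}
        guides = read_fasta(config.guides_fasta) if config.guides_fasta else {}
        truth = None
    else:
        sim = SimulationConfig(
            seed=seeds[0],
            n_contigs=config.n_contigs,
            contig_length=config.contig_length,
            n_planted_genes=config.n_planted_genes,
            intron_length_range=config.intron_length_range,
            panel_divergence_range=config.panel_divergence_range,
            n_animals=config.n_animals,
        )
        contigs, truth = simulate_genome(sim)
        if truth.genes:
            entries = make_reference_panel(
                truth, config.panel_divergence_range, seeds[1]
            )
            panel = {e.name: e.sequence for e in entries}
        else:
            panel = {}
        guides = {g.name: g.cdna for g in truth.genes}
        write_fasta(contigs.items(), out / "genome.fasta")
        write_fasta(panel.items(), out / "panel.fasta")
        write_fasta(guides.items(), out / "guides.fasta")
        write_gff3(
            [
                (g.name, GeneModel(g.contig_id, g.strand, g.exons,
                                   [0] * len(g.exons), g.peptide, "truth"))
                for g in truth.genes
            ],
            out / "truth.gff3",
        )
    report.counts["contigs"] = len(contigs)
    report.counts["planted_genes"] = len(truth.genes) if truth else 0

    # stage 2: discovery
    models, cand_df, warn = discover_genes(contigs, panel, guides, config)
    report.warnings += warn
    cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)
    write_gff3(models, out / "models.gff3")
    report.counts["candidates"] = len(cand_df)
    report.counts["models_intact"] = sum(
        1 for _, m in models if m.classification in ("intact", "three_exon")
    )

    # stage 3: phylogeny + naming
    peptides = [
        (name, m.prepropeptide) for name, m in models if m.prepropeptide
    ]
    panel_peptides = [
        (ref, translate(seq).split("*")[0]) for ref, seq in panel.items()
    ]
    taxa = peptides + [(n, p) for n, p in panel_peptides if p]
    names_rows = []
    if len(taxa) >= 3:
        dm = distance_matrix(taxa, metric="jtt", aligned=False)
        tree = nj_tree(dm)
        (out / "tree.nwk").write_text(tree.newick + "\n")
        ident = pd.DataFrame(
            [
                [round(percent_identity(a_seq, b_seq), 2) for _, b_seq in taxa]
                for _, a_seq in taxa
            ],
            index=[n for n, _ in taxa],
            columns=[n for n, _ in taxa],
        )
        ident.to_csv(out / "identity_matrix.tsv", sep="\t")
        legacy, _ = fixtures.legacy_tables()
        panel_map = dict(panel_peptides)
        for cand_id, pep in peptides:
            asn = assign_ortholog_name(
                cand_id, pep, panel_map, legacy_table=legacy,
                tie_tolerance=config.name_tie_tolerance,
            )
            if asn.ambiguous:
                report.warnings.append(f"{cand_id}: ambiguous name ({asn.evidence})")
            names_rows.append(
                dict(candidate=cand_id, name=asn.name or ".",
                     nearest=asn.nearest_reference,
                     identity=round(asn.identity, 2), evidence=asn.evidence)
            )
    pd.DataFrame(names_rows).to_csv(out / "names.tsv", sep="\t", index=False)
    report.counts["taxa_in_tree"] = len(taxa)

    # stage 4: synteny on the packaged comparative fixtures
    _, legacy_numbers = fixtures.legacy_tables()
    anchors = fixtures.anchor_table()
    pig_cl, pig_unplaced = build_clusters(
        fixtures.pig_positions(), anchors, config.max_gap
    )
    human_cl, _ = build_clusters(fixtures.human_positions(), None, config.max_gap)
    events = compare_cluster_architecture(pig_cl, human_cl, legacy_numbers)
    for g in pig_unplaced:
        report.warnings.append(
            f"{g.gene}: unplaced (inferred position {g.inferred_position})"
        )
    pd.DataFrame(
        [
            dict(kind=e.kind, direction=e.direction,
                 sources=";".join(e.source_clusters),
                 targets=";".join(e.target_clusters), genes=";".join(e.genes))
            for e in events
        ]
    ).to_csv(out / "synteny_events.tsv", sep="\t", index=False)
    (out / "comparative_map.txt").write_text(
        render_comparative_map({"pig": pig_cl, "human": human_cl}, legacy_numbers)
    )
    report.counts["pig_clusters"] = len(pig_cl)
    report.counts["synteny_events"] = len(events)

    # stage 5: exon-2 variants on the packaged SNP fixture
    refs = fixtures.exon2_reference_cds()
    specs_by_gene = fixtures.exon2_snp_specs()
    enzymes = fixtures.enzyme_table()
    all_records = []
    assay_rows = []
    pop_seed_rng = np.random.default_rng(seeds[4])
    for gene in sorted(specs_by_gene):
        specs = specs_by_gene[gene]
        ref = refs[gene]
        seqs, genotypes = simulate_population(
            ref, specs, config.n_animals,
            int(pop_seed_rng.integers(0, 2**31 - 1)), ensure_minor=True,
        )
        traces = [iupac_consensus(pair) for pair in seqs]
        records, _multi = call_snps(traces, ref, gene=gene)
        for rec in records:
            rec = annotate_consequence(rec, ref)
            gts = ["".join(pair) for pair in genotypes.get(rec.position, [])]
            if gts:
                maf, n_chrom = estimate_maf(gts)
                rec = dc_replace(rec, maf=maf, n_chromosomes=n_chrom)
            for assay in design_rflp_assay(rec, ref, rec.position - 1, enzymes):
                assay_rows.append(asdict(assay))
            all_records.append(rec)
    write_vcf(all_records, out / "variants.vcf")
    pd.DataFrame(assay_rows).to_csv(out / "rflp_assays.tsv", sep="\t", index=False)
    report.counts["snps"] = len(all_records)
    report.counts["snp_genes"] = len({r.gene for r in all_records})
    report.counts["nonsynonymous"] = sum(
        1 for r in all_records if r.consequence == "nonsynonymous"
    )

    report.wall_time_s = time.time() - t0
    report.to_file(out / "run_report.json")
    return report


# --------------------------------------------------------------------------
# fixture table parsing (schema-checked)

_SCHEMAS = {
    "snps": ["gene", "position", "major", "minor", "amino_acids", "rflp", "maf"],
    "primers": ["gene", "accession", "nt_position", "forward", "reverse",
                "annealing_c", "product_bp"],
    "positions": ["gene", "species", "chromosome", "start", "end", "strand",
                  "pseudo", "inferred_position"],
    "catalog": ["gene", "status", "accession", "chromosome"],
}


def parse_table(path, kind: str) -> pd.DataFrame:
    """Read a delimited fixture table, validating its schema header."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty table") from None
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return df
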