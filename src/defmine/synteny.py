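"""Anchor-bounded defensin cluster building and cross-species comparison.

Defensin genes sit in compact chromosomal clusters flanked by
evolutionarily conserved anchor genes.  This module groups per-species
gene positions into clusters (runs split by large gaps or anchor
boundaries), matches orthologs across species by the number in the gene
name (with a legacy-name mapping for historically named genes), and
classifies architecture differences: conserved clusters, clusters split
across chromosomes, duplications, and order changes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

_PREFIX_RE = re.compile(r"^(DEFB|BBD|pBD|defb|bbd)[-_ ]?", re.IGNORECASE)


class AnchorTableError(ValueError):
    pass


def normalize_gene_name(
    name: str, species: str = "", legacy: Optional[Dict[str, str]] = None
) -> str:
    """Strip the species prefix and map legacy names to ortholog numbers.

    ``legacy`` maps raw species-specific names (e.g. historical pig names
    kept for continuity) to the ortholog number used for cross-species
    matching.
    """
    raw = name.strip()
    if legacy:
        key = f"{species}:{raw}" if f"{species}:{raw}" in legacy else raw
        if key in legacy:
            return legacy[key]
    stripped = _PREFIX_RE.sub("", raw)
    return stripped.rstrip("ψ").strip("-_ ")


@dataclass(frozen=True)
class GenePosition:
    gene: str  # raw name as annotated (species prefix intact)
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    inferred_position: Optional[str] = None  # e.g. unplaced gene with a likely home

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if not self.chromosome:
            raise ValueError(f"{self.gene}: empty chromosome")


@dataclass
class AnchorTable:
    """Anchor coordinates plus per-chromosome flanking pairs.

    ``pairs`` rows may list alternative upstream candidates separated by
    '|' (discrepant sources are recorded, not resolved).
    """

    positions: Dict[Tuple[str, str], Tuple[str, int, int]] = field(default_factory=dict)
    # (species, chromosome) -> (upstream names, downstream names)
    pairs: Dict[Tuple[str, str], Tuple[List[str], List[str]]] = field(default_factory=dict)

    @classmethod
    def from_rows(cls, position_rows, pair_rows) -> "AnchorTable":
        """position_rows: (species, chromosome, name, start, end);
        pair_rows: (species, chromosome, upstream, downstream)."""
        t = cls()
        chrom_of: Dict[Tuple[str, str], str] = {}
        for sp, chrom, name, start, end in position_rows:
            t.positions[(sp, name)] = (chrom, int(start), int(end))
            chrom_of[(sp, name)] = chrom
        for sp, chrom, up, down in pair_rows:
            ups = [u.strip() for u in str(up).split("|") if u.strip()]
            downs = [d.strip() for d in str(down).split("|") if d.strip()]
            for name in ups + downs:
                known = chrom_of.get((sp, name))
                if known is not None and known != chrom:
                    raise AnchorTableError(
                        f"anchor pair on {chrom} references {name} located on {known}"
                    )
            t.pairs[(sp, chrom)] = (ups, downs)
        return t


@dataclass
class SyntenyCluster:
    species: str
    chromosome: str
    upstream_anchor: Optional[str]
    downstream_anchor: Optional[str]
    members: List[GenePosition]

    @property
    def member_names(self) -> List[str]:
        return [g.gene for g in self.members]

    def label(self) -> str:
        up = self.upstream_anchor or self.members[0].gene
        down = self.downstream_anchor or self.members[-1].gene
        return f"{self.species}:{self.chromosome}[{up}..{down}]"


@dataclass
class ArchitectureEvent:
    kind: str  # conserved | split | duplication | order_change | unplaced
    source_clusters: List[str]
    target_clusters: List[str]
    genes: List[str]
    direction: str = "forward"  # forward | reverse (a split seen from the merged side)


def build_clusters(
    positions: Sequence[GenePosition],
    anchors: Optional[AnchorTable] = None,
    max_gap: int = 2_000_000,
) -> Tuple[List[SyntenyCluster], List[GenePosition]]:
    """Group gene positions into anchor-bounded clusters per chromosome.

    Genes on one chromosome are sorted by start and split into runs
    wherever the gap to the previous gene exceeds ``max_gap`` or an anchor
    lies between them.  Clusters are labeled with the anchor pair declared
    for their chromosome when available, otherwise by their first/last
    member genes.  Genes with chromosome ``"unplaced"`` are never placed;
    they are returned separately (with any inferred position preserved).
    """
    if not positions:
        raise ValueError("no gene positions supplied")
    placed = [p for p in positions if p.chromosome.lower() != "unplaced"]
    unplaced = [p for p in positions if p.chromosome.lower() == "unplaced"]
    by_chrom: Dict[Tuple[str, str], List[GenePosition]] = {}
    for p in placed:
        by_chrom.setdefault((p.species, p.chromosome), []).append(p)
    clusters: List[SyntenyCluster] = []
    for (sp, chrom), genes in sorted(by_chrom.items()):
        genes = sorted(genes, key=lambda g: g.start)
        anchor_pts = []
        if anchors:
            for (a_sp, name), (a_chrom, a_start, a_end) in anchors.positions.items():
                if a_sp == sp and a_chrom == chrom:
                    anchor_pts.append((a_start + a_end) // 2)
        runs: List[List[GenePosition]] = [[genes[0]]]
        for prev, cur in zip(genes, genes[1:]):
            gap = cur.start - prev.end
            anchor_between = any(prev.end < a < cur.start for a in anchor_pts)
            if gap > max_gap or anchor_between:
                runs.append([cur])
            else:
                runs[-1].append(cur)
        up_names, down_names = (None, None)
        if anchors and (sp, chrom) in anchors.pairs:
            ups, downs = anchors.pairs[(sp, chrom)]
            up_names = "|".join(ups)
            down_names = "|".join(downs)
        for run in runs:
            clusters.append(SyntenyCluster(sp, chrom, up_names, down_names, run))
    return clusters, unplaced


def match_orthologs_across_species(
    clusters_by_species: Dict[str, List[SyntenyCluster]],
    legacy: Optional[Dict[str, str]] = None,
) -> Tuple[Dict[str, Dict[str, List[str]]], List[ArchitectureEvent]]:
    """Match genes across species by normalized ortholog number.

    Returns (correspondence, events): correspondence maps each number to
    {species: [cluster labels containing it]}; duplicated numbers within
    one species are emitted as duplication events (both copies recorded),
    numbers present in only one species are flagged unplaced.
    """
    corr: Dict[str, Dict[str, List[str]]] = {}
    events: List[ArchitectureEvent] = []
    for sp, clusters in clusters_by_species.items():
        for cl in clusters:
            for g in cl.members:
                num = normalize_gene_name(g.gene, sp, legacy)
                corr.setdefault(num, {}).setdefault(sp, []).append(cl.label())
    species = list(clusters_by_species)
    for num, present in sorted(corr.items()):
        for sp, labels in present.items():
            if len(labels) > 1 or _copies(clusters_by_species[sp], num, sp, legacy) > 1:
                events.append(
                    ArchitectureEvent(
                        "duplication", labels, labels,
                        genes=[num] * _copies(clusters_by_species[sp], num, sp, legacy),
                    )
                )
        if len(present) < len(species):
            missing_from = [s for s in species if s not in present]
            events.append(
                ArchitectureEvent(
                    "unplaced",
                    [lbl for labels in present.values() for lbl in labels],
                    missing_from,
                    genes=[num],
                )
            )
    return corr, events


def _copies(clusters, num, sp, legacy) -> int:
    return sum(
        1
        for cl in clusters
        for g in cl.members
        if normalize_gene_name(g.gene, sp, legacy) == num
    )


def compare_cluster_architecture(
    a_clusters: List[SyntenyCluster],
    b_clusters: List[SyntenyCluster],
    legacy: Optional[Dict[str, str]] = None,
) -> List[ArchitectureEvent]:
    """Classify architecture differences between two species' clusters.

    conserved: one A-cluster maps to one B-cluster with identical shared
    gene order (whole-cluster reversal allowed); order_change: same
    membership, different order; split: one cluster's genes land on >= 2
    clusters of the other species (annotated with direction when the
    merged side is A); duplication/unplaced per ortholog matching.
    """
    a_sp = a_clusters[0].species if a_clusters else "A"
    b_sp = b_clusters[0].species if b_clusters else "B"
    _, match_events = match_orthologs_across_species(
        {a_sp: a_clusters, b_sp: b_clusters}, legacy
    )
    events: List[ArchitectureEvent] = list(match_events)

    def numbers(cl: SyntenyCluster, sp: str) -> List[str]:
        return [normalize_gene_name(g.gene, sp, legacy) for g in cl.members]

    b_index: Dict[str, List[SyntenyCluster]] = {}
    for bc in b_clusters:
        for num in numbers(bc, b_sp):
            b_index.setdefault(num, []).append(bc)
    a_index: Dict[str, List[SyntenyCluster]] = {}
    for ac in a_clusters:
        for num in numbers(ac, a_sp):
            a_index.setdefault(num, []).append(ac)

    handled_b: Dict[int, List[SyntenyCluster]] = {}
    for ac in a_clusters:
        nums_a = numbers(ac, a_sp)
        targets: List[SyntenyCluster] = []
        for num in nums_a:
            for bc in b_index.get(num, []):
                if bc not in targets:
                    targets.append(bc)
        shared = [n for n in nums_a if n in b_index]
        if not targets:
            continue  # covered by unplaced events
        if len(targets) >= 2:
            events.append(
                ArchitectureEvent(
                    "split", [ac.label()], [t.label() for t in targets], shared
                )
            )
            continue
        bc = targets[0]
        # does bc also map back only to ac?
        sources = []
        for num in numbers(bc, b_sp):
            for cand in a_index.get(num, []):
                if cand not in sources:
                    sources.append(cand)
        if len(sources) >= 2:
            events.append(
                ArchitectureEvent(
                    "split",
                    [bc.label()],
                    [s.label() for s in sources],
                    [n for n in numbers(bc, b_sp) if n in a_index],
                    direction="reverse",
                )
            )
            continue
        order_a = [n for n in nums_a if n in b_index]
        order_b = [n for n in numbers(bc, b_sp) if n in a_index]
        if order_a == order_b or order_a == order_b[::-1]:
            events.append(
                ArchitectureEvent("conserved", [ac.label()], [bc.label()], order_a)
            )
        else:
            events.append(
                ArchitectureEvent("order_change", [ac.label()], [bc.label()], order_a)
            )
    # dedupe reverse splits reported once per participating A cluster
    seen = set()
    unique: List[ArchitectureEvent] = []
    for ev in events:
        key = (ev.kind, tuple(ev.source_clusters), tuple(sorted(ev.target_clusters)))
        if key in seen:
            continue
        seen.add(key)
        unique.append(ev)
    return unique


def render_comparative_map(
    clusters_by_species: Dict[str, List[SyntenyCluster]],
    legacy: Optional[Dict[str, str]] = None,
) -> str:
    """Plain-text comparative map: one line per cluster, ordered members."""
    lines = []
    for sp, clusters in clusters_by_species.items():
        lines.append(f"== {sp} ==")
        for cl in clusters:
            nums = [normalize_gene_name(g.gene, sp, legacy) for g in cl.members]
            up = cl.upstream_anchor or "(" + cl.members[0].gene + ")"
            down = cl.downstream_anchor or "(" + cl.members[-1].gene + ")"
            lines.append(f"{cl.chromosome}: {up} - " + " - ".join(nums) + f" - {down}")
    return "\n".join(lines) + "\n"
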