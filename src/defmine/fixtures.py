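"""Packaged fixtures: study tables and synthetic sequence stand-ins.

The delimited tables under ``defmine/data`` encode the printed record of
the study system: the 29-entry gene catalog, the 8-row exon-2 SNP table,
the 17-row RT-PCR primer table, per-chromosome gene orders with flanking
anchors, the 57-entry reference panel name list (verbatim, including its
duplicated DEFB132), the legacy-name table, and a restriction enzyme
table.  Sequence-level stand-ins that the printed record does not contain
(exon-2 reference coding sequences, the 113-taxon prepropeptide panel)
are generated deterministically and labeled synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .motif import scan_six_cys_motif, translate
from .simulate import SnpSpec, _CYS, _FILLER
from .synteny import AnchorTable, GenePosition


def _data_path(name: str):
    return resources.files("defmine.data").joinpath(name)


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t", comment="#", dtype=str)


def gene_catalog() -> pd.DataFrame:
    """The 29-entry gene catalog (17 new, 10 reported, 2 partial psi)."""
    return _read_tsv("gene_catalog.tsv")


def snp_table() -> pd.DataFrame:
    """The 8-row exon-2 coding SNP table."""
    df = _read_tsv("exon2_snps.tsv")
    df["position"] = df["position"].astype(int)
    df["maf"] = df["maf"].astype(float)
    return df


def primer_table() -> pd.DataFrame:
    """The 17-row RT-PCR primer table."""
    df = _read_tsv("rtpcr_primers.tsv")
    df["annealing_c"] = df["annealing_c"].astype(int)
    df["product_bp"] = df["product_bp"].astype(int)
    return df


def enzyme_table() -> Dict[str, str]:
    df = _read_tsv("enzymes.tsv")
    return dict(zip(df["enzyme"], df["site"]))


def reference_panel_names() -> List[str]:
    """The verbatim 57-entry reference name list (DEFB132 listed twice)."""
    with resources.as_file(_data_path("reference_panel_names.txt")) as p:
        return [
            line.strip()
            for line in p.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]


def legacy_tables() -> Tuple[Dict[str, str], Dict[str, str]]:
    """(retained-name table, ortholog-number normalization map).

    The first maps a legacy gene id to the name it keeps; the second maps
    species-qualified legacy names to the ortholog number used for
    cross-species synteny matching (e.g. ``pig:pBD1 -> 4``).
    """
    df = _read_tsv("legacy_names.tsv")
    retained = dict(zip(df["gene"], df["retained_name"]))
    numbers = {
        f"{sp}:{g}": num
        for sp, g, num in zip(df["species"], df["gene"], df["ortholog_number"])
    }
    return retained, numbers


def _positions_from(df: pd.DataFrame) -> List[GenePosition]:
    out = []
    for _, row in df.iterrows():
        out.append(
            GenePosition(
                gene=row["gene"],
                species=row["species"],
                chromosome=row["chromosome"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                inferred_position=None if row["inferred_position"] == "." else row["inferred_position"],
            )
        )
    return out


def pig_positions() -> List[GenePosition]:
    """Pig gene placements (printed order; synthetic bp coordinates)."""
    return _positions_from(_read_tsv("pig_positions_synthetic.tsv"))


def human_positions() -> List[GenePosition]:
    """Human comparative-map placements (synthetic bp coordinates)."""
    return _positions_from(_read_tsv("human_positions_synthetic.tsv"))


def anchor_table() -> AnchorTable:
    pos = _read_tsv("anchors.tsv")
    pairs = _read_tsv("anchor_pairs.tsv")
    return AnchorTable.from_rows(
        [
            (r["species"], r["chromosome"], r["name"], int(r["start"]), int(r["end"]))
            for _, r in pos.iterrows()
        ],
        [
            (r["species"], r["chromosome"], r["upstream"], r["downstream"])
            for _, r in pairs.iterrows()
        ],
    )


def fixture_from_tables():
    """All four study table fixtures as (catalog, snps, primers, positions)."""
    return gene_catalog(), snp_table(), primer_table(), pd.concat(
        [_read_tsv("pig_positions_synthetic.tsv"), _read_tsv("human_positions_synthetic.tsv")],
        ignore_index=True,
    )


# --------------------------------------------------------------------------
# synthetic exon-2 reference coding sequences for the SNP table


@dataclass(frozen=True)
class _GeneDesign:
    n_codons: int
    motif_start_codon: int  # 1-based
    fixed_codons: Tuple[Tuple[int, str], ...]  # (1-based codon index, codon)


# Codon contexts realize every printed constraint: SNP position, alleles,
# amino-acid change under frame offset 0, and differential BstNI / EcoRV /
# PciI sites for pBD1 / pBD4 / pBD121.
_DESIGNS: Dict[str, _GeneDesign] = {
    # BstNI CCWGG completed by the minor G at 171: ..TCC AGA|AGG TTT..
    "pBD1": _GeneDesign(60, 10, ((56, "TCC"), (57, "AGA"), (58, "TTT"))),
    # EcoRV GATATC spans 65-70 on the major allele: AGA|AAA TAT C.. (R/K)
    "pBD4": _GeneDesign(72, 30, ((21, "GGA"), (22, "AGA"), (23, "TAT"), (24, "CAT"))),
    # synonymous third-position change GCA/GCG
    "pBD113": _GeneDesign(45, 2, ((38, "GCA"),)),
    # synonymous third-position change ACG/ACA
    "pBD114": _GeneDesign(64, 10, ((62, "ACG"),)),
    # CAA/CAT (Q/H) at 144 and synonymous CCG/CCA at 291
    "pBD115": _GeneDesign(100, 50, ((48, "CAA"), (97, "CCG"))),
    # PciI ACATGT completed by the minor A at 96; codon 33 is the motif's
    # fifth cysteine (TGT), so the site reads AC[G/A]TGT
    "pBD121": _GeneDesign(45, 4, ((31, "TTT"), (32, "ACG"), (33, "TGT"))),
    # AAA/CAA (K/Q) at first codon position 196
    "pBD133": _GeneDesign(70, 10, ((66, "AAA"),)),
}

_MOTIF_C_OFFSETS = (0, 7, 12, 22, 29, 30)


def exon2_reference_cds() -> Dict[str, str]:
    """Synthetic exon-2 reference CDS per SNP-table gene.

    These are deterministic stand-ins for sequences the printed record
    does not contain.  Each carries the major allele at every SNP
    position, translates without internal stops, and contains exactly one
    six-cysteine motif.
    """
    refs: Dict[str, str] = {}
    for gi, (gene, design) in enumerate(sorted(_DESIGNS.items())):
        rng = np.random.default_rng(20120 + gi)
        codons = [_FILLER[int(i)] for i in rng.integers(0, len(_FILLER), design.n_codons)]
        m0 = design.motif_start_codon - 1
        for off in _MOTIF_C_OFFSETS:
            codons[m0 + off] = _CYS[int(rng.integers(0, 2))]
        for idx, codon in design.fixed_codons:
            codons[idx - 1] = codon
        cds = "".join(codons)
        pep = translate(cds)
        assert "*" not in pep and len(scan_six_cys_motif(pep)) == 1, gene
        refs[gene] = cds + "TAA"
    return refs


def exon2_snp_specs() -> Dict[str, List[SnpSpec]]:
    """SNP table rows as planting specs, grouped by gene."""
    specs: Dict[str, List[SnpSpec]] = {}
    for _, row in snp_table().iterrows():
        specs.setdefault(row["gene"], []).append(
            SnpSpec(int(row["position"]), row["major"], row["minor"], float(row["maf"]))
        )
    return specs


# --------------------------------------------------------------------------
# synthetic 113-taxon prepropeptide panel (36 human, 48 cattle, 29 pig)


def synthetic_prepropeptide_panel(seed: int = 0) -> List[Tuple[str, str]]:
    """113 labeled prepropeptide stand-ins with the study's species counts.

    29 pig entries use the catalog names; 36 human and 48 cattle entries
    carry DEFB/BBD labels.  Sequences are synthetic: a common motif
    scaffold with random signal and spacer residues.
    """
    rng = np.random.default_rng(seed)
    aa_pool = "ARNDEQGHILKFPSTWYV"  # no C, no M: cysteines placed explicitly
    names: List[str] = []
    names += [f"pig_{g}" for g in gene_catalog()["gene"]]
    human = [n for n in reference_panel_names() if n.startswith("DEFB")]
    seen = set()
    for n in human:
        if n not in seen:
            seen.add(n)
            names.append(f"human_{n}")
    extra = 36 - len(seen)
    for k in range(extra):
        names.append(f"human_DEFB{140 + k}")
    for k in range(48):
        names.append(f"cattle_BBD{k + 1}")
    panel: List[Tuple[str, str]] = []
    for name in names:
        signal = "M" + "".join(rng.choice(list(aa_pool), size=19))
        spacer = lambda n: "".join(rng.choice(list(aa_pool), size=n))
        mature = (
            spacer(4) + "C" + spacer(6) + "C" + spacer(4) + "C" + spacer(9)
            + "C" + spacer(6) + "CC" + spacer(4)
        )
        panel.append((name, signal + mature))
    assert len(panel) == 113
    return panel
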