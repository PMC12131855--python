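"""Glycogene pathway profiling of differential-expression tables.

Cell-type-resolved differential-expression (DE) tables from published
single-nucleus RNA-seq studies are filtered against a reference list of
glycosylation-related genes (glycogenes) organised into 19 pathway
categories, and each pathway's percentage contribution to the significant
glycogene signal is computed per cell type and ventricular region.

The bundled reference (``data/glycogene_reference_synthetic.csv``) is a
synthetic stand-in that mirrors the shape of a GlycoMaple-style export —
950 genes across 19 categories, anchored by well-known glycogene symbols
(MGAT/FUT/ST6GAL families etc.) and padded with synthetic symbols; supply
your own export via ``load_reference(path)`` for real analyses.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Optional

import pandas as pd

__all__ = [
    "load_reference",
    "filter_significant",
    "pathway_contribution",
    "radial_heatmap_table",
    "PATHWAYS",
    "DE_COLUMNS",
]

#: The 19 glycosylation-pathway categories used to group glycogenes.
PATHWAYS = (
    "N-glycan biosynthesis",
    "N-glycan degradation",
    "Mucin-type O-glycans",
    "O-Fucose glycans",
    "O-Glucose glycans",
    "O-Mannose glycans",
    "O-GlcNAc",
    "C-Mannosylation",
    "GPI-anchor biosynthesis",
    "GAG chondroitin/dermatan sulfate",
    "GAG heparan sulfate",
    "GAG keratan sulfate",
    "Hyaluronan",
    "Glycosphingolipids",
    "Nucleotide sugar biosynthesis",
    "Nucleotide sugar transporters",
    "Sulfation-related",
    "Lectins",
    "Golgi homeostasis",
)

DE_COLUMNS = ["gene", "cell_type", "region", "log2FC", "adj_p"]
REGIONS = ("LV", "RV")


def load_reference(path=None) -> pd.DataFrame:
    """Load a glycogene reference CSV (columns: gene, pathway).

    Without ``path`` the bundled synthetic 950-gene / 19-pathway stand-in
    is used.  Every gene must map to exactly one pathway.
    """
    if path is None:
        ref_file = resources.files("glycardio").joinpath(
            "data/glycogene_reference_synthetic.csv"
        )
        with resources.as_file(ref_file) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in ("gene", "pathway") if c not in df.columns]
    if missing:
        raise ValueError(f"reference missing columns: {missing}")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"genes mapped to more than one pathway: {dups}")
    return df


def _check_de_schema(table: pd.DataFrame) -> None:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    if ((table["adj_p"] < 0) | (table["adj_p"] > 1)).any():
        raise ValueError("adjusted p-values must lie in [0, 1]")


def filter_significant(
    table: pd.DataFrame, lfc_threshold: float = 1.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Keep rows with |log2FC| strictly greater than ``lfc_threshold`` and
    adjusted p strictly below ``fdr_threshold``.

    Defaults (1 and 0.05) match the usual DE convention for calling a
    glycogene significantly changed; boundary values are excluded.
    Idempotent."""
    if lfc_threshold <= 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    _check_de_schema(table)
    keep = (table["log2FC"].abs() > lfc_threshold) & (table["adj_p"] < fdr_threshold)
    return table.loc[keep].reset_index(drop=True)


def _map_pathways(
    table: pd.DataFrame, ref: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    lookup = dict(zip(ref["gene"], ref["pathway"]))
    mapped = table.copy()
    mapped["pathway"] = mapped["gene"].map(lookup)
    unmapped = sorted(set(mapped.loc[mapped["pathway"].isna(), "gene"]))
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} gene(s) not in glycogene reference, dropped: "
            f"{unmapped[:10]}{'...' if len(unmapped) > 10 else ''}"
        )
    return mapped.dropna(subset=["pathway"]), unmapped


def pathway_contribution(
    filtered: pd.DataFrame,
    ref: pd.DataFrame,
    cell_type: Optional[str] = None,
    region: Optional[str] = None,
    weighting: str = "gene-count",
) -> pd.Series:
    """Percentage contribution of each pathway to the significant
    glycogene signal in one stratum.

    ``weighting`` is ``gene-count`` (each significant glycogene counts 1)
    or ``abs-log2FC`` (genes weighted by |log2FC|).  Percentages sum to
    100 for a non-empty stratum; an empty stratum returns an empty series
    with a warning.
    """
    if weighting not in ("gene-count", "abs-log2FC"):
        raise ValueError(f"unknown weighting {weighting!r}")
    _check_de_schema(filtered)
    sub = filtered
    if cell_type is not None:
        sub = sub[sub["cell_type"] == cell_type]
    if region is not None:
        sub = sub[sub["region"] == region]
    sub, _ = _map_pathways(sub, ref)
    if sub.empty:
        warnings.warn(
            f"no significant glycogenes in stratum (cell_type={cell_type}, "
            f"region={region})"
        )
        return pd.Series(dtype=float, name="percent")
    weights = (
        pd.Series(1.0, index=sub.index) if weighting == "gene-count"
        else sub["log2FC"].abs()
    )
    totals = weights.groupby(sub["pathway"]).sum()
    out = totals / totals.sum() * 100.0
    out.name = "percent"
    return out.sort_index()


def radial_heatmap_table(
    filtered: pd.DataFrame, ref: pd.DataFrame, weighting: str = "gene-count"
) -> pd.DataFrame:
    """Long-format export for radial-heatmap plotting: one row per
    significant glycogene with its pathway and the pathway's percentage
    contribution within the gene's (cell type, region) stratum."""
    _check_de_schema(filtered)
    if filtered.empty:
        raise ValueError("filtered DE table is empty")
    mapped, _ = _map_pathways(filtered, ref)
    rows = []
    for (ct, rg), sub in mapped.groupby(["cell_type", "region"], sort=True):
        pct = pathway_contribution(sub, ref, weighting=weighting)
        for _, r in sub.sort_values(["pathway", "gene"]).iterrows():
            rows.append({
                "cell_type": ct, "region": rg, "pathway": r["pathway"],
                "gene": r["gene"], "log2FC": r["log2FC"],
                "pathway_percent": pct[r["pathway"]],
            })
    return pd.DataFrame(rows)
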