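"""Human-miRNA filtering, validated target lookup, and DEM-target/DEG intersection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)


def filter_human(mirna_ids: Iterable[str]) -> list[str]:
    """Keep ids whose lower-cased form starts with the species prefix 'hsa'."""
    return [m for m in mirna_ids if str(m).strip().lower().startswith("hsa")]


def lookup_targets(
    dems: Iterable[str],
    table: pd.DataFrame,
    validated_only: bool = True,
) -> dict[str, set[str]]:
    """Map each significant miRNA to its (validated) target gene set.

    Duplicate rows across source databases collapse to one gene per miRNA;
    miRNAs absent from the table map to an empty set (counted in the log).
    Ids are matched case-insensitively after trimming, consistent with the
    meta-analysis feature harmonisation.
    """
    if table.empty:
        raise ValueError("empty interaction table")
    t = table
    if validated_only:
        t = t[t["validated"] == 1]
    key = t["mirna_id"].astype(str).str.strip().str.lower()
    grouped = t.groupby(key)["gene_symbol"].agg(set)
    out: dict[str, set[str]] = {}
    n_empty = 0
    for m in dems:
        genes = set(grouped.get(str(m).strip().lower(), set()))
        if not genes:
            n_empty += 1
        out[m] = genes
    if n_empty:
        logger.info("%d of %d miRNAs have no recorded targets", n_empty, len(out))
    return out


@dataclass
class IntersectionReport:
    """Overlap of DEM target genes with the union of per-study DEGs."""

    dem_targets: set = field(default_factory=set)
    deg_union: set = field(default_factory=set)
    overlap: set = field(default_factory=set)
    per_study_overlap: dict = field(default_factory=dict)
    back_map: dict = field(default_factory=dict)   # gene -> sorted targeting miRNAs

    @property
    def venn_counts(self) -> dict[str, int]:
        return {
            "targets_only": len(self.dem_targets - self.deg_union),
            "degs_only": len(self.deg_union - self.dem_targets),
            "overlap": len(self.overlap),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_symbol": g, "mirnas": ";".join(self.back_map.get(g, []))}
            for g in sorted(self.overlap)
        ]
        return pd.DataFrame(rows, columns=["gene_symbol", "mirnas"])


def intersect_targets_with_degs(
    target_map: Mapping[str, set],
    deg_lists: Mapping[str, Iterable[str]],
    mode: str = "union",
) -> IntersectionReport:
    """Intersect the DEM target-gene union with the aggregated DEG sets.

    ``mode`` controls DEG aggregation across the mRNA studies: ``"union"``
    (default), ``"intersection"`` or ``"majority"`` (gene DE in more than half
    of the studies).
    """
    sets = {sid: set(genes) for sid, genes in deg_lists.items()}
    if mode == "union":
        deg_agg = set().union(*sets.values()) if sets else set()
    elif mode == "intersection":
        deg_agg = set.intersection(*sets.values()) if sets else set()
    elif mode == "majority":
        counts: dict[str, int] = {}
        for genes in sets.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        deg_agg = {g for g, c in counts.items() if c > len(sets) / 2}
    else:
        raise ValueError(f"unknown aggregation mode '{mode}'")

    dem_targets = set().union(*target_map.values()) if target_map else set()
    overlap = dem_targets & deg_agg
    back_map = {
        g: sorted(m for m, genes in target_map.items() if g in genes)
        for g in overlap
    }
    per_study = {sid: len(overlap & genes) for sid, genes in sets.items()}
    return IntersectionReport(
        dem_targets=dem_targets,
        deg_union=deg_agg,
        overlap=overlap,
        per_study_overlap=per_study,
        back_map=back_map,
    )
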