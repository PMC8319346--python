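"""Hit calling on gene-fitness tables.

A gene disruption counts as a positive (resistance-conferring) hit when
its replicate-averaged fitness and combined t-statistic clear stringent
fixed thresholds and its summed, depth-normalized barcode reads rise
from Time0 to the treated sample; negative (sensitizing) hits mirror
this with reads falling. Comparisons are inclusive at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import TailoseqError

__all__ = ["HitThresholds", "call_hits", "summarize_hits"]


@dataclass(frozen=True)
class HitThresholds:
    """Fixed hit-calling thresholds (log2 fitness units; t dimensionless)."""

    f_pos: float = 7.0
    t_pos: float = 5.0
    f_neg: float = -2.0
    t_neg: float = -5.0
    require_count_direction: bool = True

    def __post_init__(self) -> None:
        if not (self.f_pos > 0 > self.f_neg and self.t_pos > 0 > self.t_neg):
            raise ValueError("positive thresholds must be > 0 > negative thresholds")


def call_hits(genes: pd.DataFrame, thresholds: HitThresholds = HitThresholds()) -> pd.DataFrame:
    """Apply thresholds to a replicate-averaged gene-fitness table.

    ``genes`` must carry columns ``locus_tag``, ``condition``, ``f``,
    ``t`` and, when the read-direction check is on, ``reads_before`` /
    ``reads_after`` (depth-normalized sums over used strains, pooled
    across replicates). Returns the hit rows with a ``direction`` column
    (``positive``/``negative``), sorted by condition then |f| descending.
    """
    th = thresholds
    required = {"locus_tag", "f", "t"}
    missing = required - set(genes.columns)
    if missing:
        raise TailoseqError(f"gene table lacks columns: {sorted(missing)}")
    if th.require_count_direction and not {"reads_before", "reads_after"} <= set(genes.columns):
        raise TailoseqError("read summaries required for the count-direction check")

    pos = (genes["f"] >= th.f_pos) & (genes["t"] >= th.t_pos)
    neg = (genes["f"] <= th.f_neg) & (genes["t"] <= th.t_neg)
    if th.require_count_direction:
        pos &= genes["reads_after"] > genes["reads_before"]
        neg &= genes["reads_after"] < genes["reads_before"]

    out = genes[pos | neg].copy()
    out["direction"] = pd.Series("negative", index=out.index).where(neg[pos | neg], "positive")
    if "condition" not in out.columns:
        out["condition"] = ""
    out = out.sort_values(
        ["condition", "f"], key=lambda s: s.abs() if s.name == "f" else s, ascending=[True, False]
    )
    return out.reset_index(drop=True)


def summarize_hits(hits: pd.DataFrame, group_cols: tuple[str, ...] = ("tailocin_source", "condition")) -> dict:
    """Count unique hit genes per assay group and overall.

    Returns a dict with ``per_group`` (unique genes per group x
    direction), ``unique_genes`` (de-duplicated across everything) and
    ``unique_genes_by_direction``.
    """
    if hits.empty:
        return {"per_group": {}, "unique_genes": 0, "unique_genes_by_direction": {}}
    cols = [c for c in group_cols if c in hits.columns]
    per_group = {}
    grouped = hits.groupby(cols + ["direction"]) if cols else hits.groupby("direction")
    for key, d in grouped:
        key = key if isinstance(key, tuple) else (key,)
        per_group["/".join(str(k) for k in key)] = int(d["locus_tag"].nunique())
    by_dir = {
        direction: int(d["locus_tag"].nunique()) for direction, d in hits.groupby("direction")
    }
    return {
        "per_group": per_group,
        "unique_genes": int(hits["locus_tag"].nunique()),
        "unique_genes_by_direction": by_dir,
    }
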