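"""Differential-expression set comparison and qPCR fold changes.

Consumes already-fitted DEG tables (gene_id, log2fc, pvalue, padj,
mean_count) — no expression model is fitted here.  Provides threshold
filtering with the named significance presets, two-condition intersection
partitioned by fold-change sign concordance, keyword counting over
enrichment-term names (radar-plot input), and delta-delta-Ct log2 fold
changes for qPCR validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "PRESETS",
    "DEGFilterResult",
    "SharedGeneSet",
    "filter_degs",
    "intersect_degs",
    "keyword_term_counts",
    "qpcr_log2fc",
]

#: named significance presets (mutually inconsistent by design; pick one)
PRESETS: dict[str, dict] = {
    "pboo_inclusion": {"p_thresh": 0.1},
    "sci_inclusion": {"padj_thresh": 0.1},
    "volcano_strict": {"padj_thresh": 0.05, "min_abs_log2fc": 0.5},
}

_REQUIRED_COLUMNS = ("gene_id", "log2fc", "pvalue", "padj", "mean_count")


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DEG table missing columns: {missing}")
    return table


@dataclass
class DEGFilterResult:
    """Outcome of DEG threshold filtering."""

    up: list[str]
    down: list[str]
    n_total_nonzero: int
    fraction_up_pct: float
    fraction_down_pct: float

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)

    @property
    def n_significant(self) -> int:
        return self.n_up + self.n_down


def filter_degs(
    table: pd.DataFrame,
    p_thresh: float | None = None,
    padj_thresh: float | None = None,
    min_abs_log2fc: float = 0.0,
    min_mean_count: float = 0.0,
    decimals: int = 2,
) -> DEGFilterResult:
    """Threshold-filter a DEG table into up/down gene lists.

    Exactly one of ``p_thresh`` / ``padj_thresh`` must be given (one
    criterion per preset).  A gene passes iff its chosen p-statistic is
    below the threshold, ``|log2fc| > min_abs_log2fc`` and ``mean_count >=
    min_mean_count``.  Fractions are percentages of the genes with nonzero
    mean counts, rounded to ``decimals`` decimals.
    """
    table = _validate_table(table)
    if (p_thresh is None) == (padj_thresh is None):
        raise ConfigurationError("supply exactly one of p_thresh / padj_thresh")
    thresh = p_thresh if p_thresh is not None else padj_thresh
    if not 0.0 < thresh <= 1.0:
        raise ConfigurationError("threshold must lie in (0, 1]")
    if len(table) == 0:
        raise ValidationError("empty DEG table")

    stat = table["pvalue"] if p_thresh is not None else table["padj"]
    passing = (
        (stat < thresh)
        & (table["log2fc"].abs() > min_abs_log2fc)
        & (table["mean_count"] >= min_mean_count)
    )
    up = table.loc[passing & (table["log2fc"] > 0), "gene_id"].tolist()
    down = table.loc[passing & (table["log2fc"] < 0), "gene_id"].tolist()
    n_nonzero = int((table["mean_count"] > 0).sum())
    frac = lambda k: round(100.0 * k / n_nonzero, decimals) if n_nonzero else 0.0
    return DEGFilterResult(
        up=up,
        down=down,
        n_total_nonzero=n_nonzero,
        fraction_up_pct=frac(len(up)),
        fraction_down_pct=frac(len(down)),
    )


@dataclass
class SharedGeneSet:
    """Intersection of two DEG sets partitioned by sign concordance."""

    shared: list[str]
    concordant: list[str]
    discordant: list[str]
    unique_a: list[str]
    unique_b: list[str]

    def __post_init__(self) -> None:
        if len(self.concordant) + len(self.discordant) != len(self.shared):
            raise ValidationError("concordant + discordant must partition shared")
        s, a, b = set(self.shared), set(self.unique_a), set(self.unique_b)
        if s & a or s & b or a & b:
            raise ValidationError("shared/unique sets must be pairwise disjoint")


def intersect_degs(degs_a: pd.DataFrame, degs_b: pd.DataFrame) -> SharedGeneSet:
    """Intersect two DEG tables on gene_id and split by fold-change sign.

    Concordant genes have the same log2FC sign in both conditions; a zero
    fold change is classed discordant (with a warning).  Tables must not
    contain duplicate gene ids.
    """
    for name, tab in (("A", degs_a), ("B", degs_b)):
        _validate_table(tab)
        if tab["gene_id"].duplicated().any():
            raise ValidationError(f"duplicate gene_id in table {name}")
    merged = degs_a.merge(degs_b, on="gene_id", suffixes=("_a", "_b"))
    sign_product = np.sign(merged["log2fc_a"]) * np.sign(merged["log2fc_b"])
    if (sign_product == 0).any():
        warnings.warn("zero log2fc in shared genes classed discordant", stacklevel=2)
    shared = merged["gene_id"].tolist()
    concordant = merged.loc[sign_product > 0, "gene_id"].tolist()
    discordant = merged.loc[sign_product <= 0, "gene_id"].tolist()
    set_b = set(degs_b["gene_id"])
    set_a = set(degs_a["gene_id"])
    unique_a = [g for g in degs_a["gene_id"] if g not in set_b]
    unique_b = [g for g in degs_b["gene_id"] if g not in set_a]
    return SharedGeneSet(shared, concordant, discordant, unique_a, unique_b)


def keyword_term_counts(term_names: list[str], keywords: list[str]) -> dict[str, int]:
    """Count enriched-term names containing each keyword (case-insensitive).

    A term may count toward several keywords; the result preserves the
    keyword order.
    """
    lowered = [t.lower() for t in term_names]
    return {
        kw: sum(kw.lower() in term for term in lowered) for kw in keywords
    }


def qpcr_log2fc(ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl) -> float:
    """Delta-delta-Ct log2 fold change (amplification efficiency 2).

    Ct values are normalised to the reference gene per replicate and
    averaged per group: ``log2FC = -(mean(dCt_case) - mean(dCt_ctrl))`` with
    ``dCt = Ct_target - Ct_ref``.
    """
    d_case = np.asarray(ct_target_case, float) - np.asarray(ct_ref_case, float)
    d_ctrl = np.asarray(ct_target_ctrl, float) - np.asarray(ct_ref_ctrl, float)
    if not (np.all(np.isfinite(d_case)) and np.all(np.isfinite(d_ctrl))):
        raise ValidationError("Ct values must be finite")
    return float(-(d_case.mean() - d_ctrl.mean()))
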