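"""Differential stoichiometry and abundance testing between two groups.

For each ribosomal protein, a two-tailed two-sample t-test compares its
ratio (stoichiometry mode) or raw intensity (level mode) between two sample
groups; raw p-values are Benjamini-Hochberg adjusted across all RPs tested
within the comparison, and an RP is called up- or downregulated when its
adjusted p is strictly below alpha.  The fold change is the log2 ratio of
the group arithmetic means of the linear-space values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import QuantTable
from .ratios import RatioMatrix

__all__ = [
    "DiffTable",
    "two_sample_t",
    "bh_adjust",
    "differential_ratio",
    "volcano_table",
]

logger = logging.getLogger(__name__)


@dataclass
class DiffTable:
    """Per-RP differential results for one two-group comparison.

    ``table`` columns: mean_a, mean_b, log2fc, t_stat, p_raw, p_adj, n_a,
    n_b, tested, direction (up/down/ns; empty for untested RPs).
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    alpha: float
    variant: str
    mode: str

    @property
    def n_tested(self) -> int:
        return int(self.table["tested"].sum())

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    def summary(self) -> dict:
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "mode": self.mode,
            "variant": self.variant,
            "alpha": self.alpha,
            "n_tested": self.n_tested,
            "n_up": self.n_up,
            "n_down": self.n_down,
        }

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def two_sample_t(
    a: np.ndarray, b: np.ndarray, variant: str = "student"
) -> tuple[float, float]:
    """Two-tailed two-sample t-test.

    ``variant="student"`` pools the variance (df = n_a + n_b - 2);
    ``variant="welch"`` uses the Welch-Satterthwaite approximation.

    Returns
    -------
    (t_stat, p_raw)
        ``(0.0, 1.0)`` when both groups are constant and equal;
        ``(nan, nan)`` when variance is zero but means differ — the test is
        undefined there and no p-value is fabricated.

    Raises
    ------
    ValueError
        With fewer than two non-missing observations in either group, or an
        unknown variant.
    """
    if variant not in {"student", "welch"}:
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >= 2 observations per group (got {a.size} and {b.size})"
        )
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("nan"), float("nan")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, adj_(i) = min_{j >= i} m * p_(j) / j, capped at 1,
    returned in the original order.  Missing entries stay missing and do
    not count toward the family size m.

    Raises
    ------
    ValueError
        If any non-missing p lies outside (0, 1].
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    valid = ~np.isnan(arr)
    vals = arr[valid]
    if vals.size == 0:
        return out
    if (vals <= 0).any() or (vals > 1).any():
        bad = vals[(vals <= 0) | (vals > 1)][0]
        raise ValueError(f"p-values must lie in (0, 1]; got {bad}")
    out[valid] = multipletests(vals, method="fdr_bh")[1]
    return out


def differential_ratio(
    ratios: RatioMatrix | QuantTable,
    group_a: str,
    group_b: str,
    mode: str = "ratio",
    alpha: float = 0.05,
    variant: str = "student",
) -> DiffTable:
    """Per-RP differential test of group A versus group B.

    In ``mode="ratio"`` the input is a :class:`RatioMatrix` of stoichiometry
    proportions; in ``mode="level"`` it is the RP-filtered
    :class:`QuantTable` of raw intensities (detecting overall abundance
    shifts rather than stoichiometry remodeling).  An RP is tested only when
    both groups contribute >= 2 non-missing values; BH adjustment runs over
    the tested RPs of this comparison.  ``log2fc > 0`` means higher in
    group A.

    Raises
    ------
    ValueError
        Unknown group label, invalid alpha/mode, or zero testable RPs.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if mode not in {"ratio", "level"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ratio" and isinstance(ratios, QuantTable):
        raise ValueError("ratio mode expects a RatioMatrix")
    if mode == "level" and isinstance(ratios, RatioMatrix):
        raise ValueError("level mode expects the RP-filtered QuantTable")
    frame = ratios.ratios if isinstance(ratios, RatioMatrix) else ratios.values
    labels = ratios.group_labels()
    for g in (group_a, group_b):
        if g not in set(labels):
            raise ValueError(f"group label {g!r} not present in metadata")

    cols_a = labels.index[labels == group_a]
    cols_b = labels.index[labels == group_b]
    xa = frame[cols_a].to_numpy(dtype=float)
    xb = frame[cols_b].to_numpy(dtype=float)

    records = []
    for i, rp in enumerate(frame.index):
        a = xa[i][~np.isnan(xa[i])]
        b = xb[i][~np.isnan(xb[i])]
        rec = {
            "mean_a": a.mean() if a.size else np.nan,
            "mean_b": b.mean() if b.size else np.nan,
            "n_a": a.size,
            "n_b": b.size,
        }
        if a.size >= 2 and b.size >= 2:
            t, praw = two_sample_t(a, b, variant)
            rec["tested"] = not np.isnan(praw)
            rec["t_stat"], rec["p_raw"] = t, praw
        else:
            rec["tested"] = False
            rec["t_stat"] = rec["p_raw"] = np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            rec["log2fc"] = (
                np.log2(rec["mean_a"] / rec["mean_b"])
                if rec["n_a"] and rec["n_b"] else np.nan
            )
        records.append(rec)

    table = pd.DataFrame(records, index=frame.index)
    if not table["tested"].any():
        raise ValueError("no RP has enough data to test in either group")
    p_for_adjust = table["p_raw"].where(table["tested"]).to_numpy()
    table["p_adj"] = bh_adjust(p_for_adjust)

    direction = np.where(
        table["tested"] & (table["p_adj"] < alpha) & (table["log2fc"] > 0),
        "up",
        np.where(
            table["tested"] & (table["p_adj"] < alpha) & (table["log2fc"] < 0),
            "down",
            "ns",
        ),
    )
    table["direction"] = np.where(table["tested"], direction, "")
    table = table[
        ["mean_a", "mean_b", "log2fc", "t_stat", "p_raw", "p_adj",
         "n_a", "n_b", "tested", "direction"]
    ]
    diff = DiffTable(
        table=table, group_a=group_a, group_b=group_b,
        alpha=alpha, variant=variant, mode=mode,
    )
    logger.info(
        "differential %s vs %s (%s mode): %d tested, %d up, %d down",
        group_a, group_b, mode, diff.n_tested, diff.n_up, diff.n_down,
    )
    return diff


def volcano_table(diff: DiffTable) -> pd.DataFrame:
    """Plot-ready table of (gene, log2fc, -log10 adjusted p, direction).

    No thresholding beyond the direction already present in the DiffTable.
    """
    if diff.table.empty:
        raise ValueError("empty differential table")
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(diff.table["p_adj"].to_numpy(dtype=float))
    out = pd.DataFrame(
        {
            "log2fc": diff.table["log2fc"],
            "neg_log10_p_adj": neg_log10,
            "direction": diff.table["direction"],
        },
        index=diff.table.index,
    )
    out.index.name = "gene"
    return out
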