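"""Per-sample ribosomal-protein stoichiometry ratios.

The stoichiometry barcode of a sample is the vector of each detected RP's
share of the total detected-RP intensity in that sample:

    ratio[i, s] = intensity[i, s] / sum_j intensity[j, s]

with the sum running over the RPs detected in sample *s* only.  Because
iBAQ intensities are proportional to molar amounts, these ratios are molar
proportions: each sample's non-missing ratios form a point on the simplex
(they sum to one), and the vector is invariant to any per-sample scale
factor such as input amount or instrument response.

No imputation or pseudocounts are applied here; missing stays missing, and
the denominator of each sample uses only that sample's detected panel.  The
subcompositional consequence — removing an RP rescales the remaining ratios
of that sample by a common factor — is inherent to the definition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import QuantTable

__all__ = ["RatioMatrix", "compute_ratios", "detected_rp_counts"]

logger = logging.getLogger(__name__)


@dataclass
class RatioMatrix:
    """RPs x samples matrix of stoichiometry proportions.

    Non-missing entries are in (0, 1] and each sample's non-missing entries
    sum to 1; the missingness pattern equals that of the source
    quantification table.
    """

    ratios: pd.DataFrame
    sample_groups: dict[str, str] | None = None

    @property
    def protein_ids(self) -> list[str]:
        return list(self.ratios.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.columns)

    def group_labels(self) -> pd.Series:
        if self.sample_groups is None:
            raise ValueError("no sample metadata attached to this matrix")
        missing = [s for s in self.sample_ids if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        return pd.Series(
            [self.sample_groups[s] for s in self.sample_ids],
            index=self.sample_ids,
            name="group",
        )

    def to_tsv(self, path: str | Path, id_column: str = "gene") -> None:
        out = self.ratios.copy()
        out.index.name = id_column
        out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def compute_ratios(rp_quant: QuantTable) -> RatioMatrix:
    """Compute the per-sample RP stoichiometry barcode.

    Parameters
    ----------
    rp_quant
        Quantification table already restricted to ribosomal proteins
        (see :func:`riboratio.io.filter_rp`).

    Returns
    -------
    RatioMatrix
        Each sample's detected intensities divided by their sum.

    Raises
    ------
    ValueError
        If any sample has no detected RP (an empty denominator).
    """
    values = rp_quant.values
    totals = values.sum(axis=0, skipna=True)
    dead = totals.index[values.notna().sum(axis=0) == 0]
    if len(dead):
        raise ValueError(
            f"samples with zero detected RPs: {list(map(str, dead))}"
        )
    ratios = values.div(totals, axis=1)
    return RatioMatrix(
        ratios,
        dict(rp_quant.sample_groups) if rp_quant.sample_groups else None,
    )


def detected_rp_counts(
    rp_quant: QuantTable | RatioMatrix,
    threshold: int | None = None,
    *,
    drop: bool = False,
) -> pd.DataFrame:
    """Per-sample detected-RP counts with an optional QC gate.

    Single-cell proteomes are expected to cover >50 RPs per cell; passing
    ``threshold=50`` flags (not drops) cells below that depth unless
    ``drop=True``.

    Returns
    -------
    DataFrame
        Indexed by sample with column ``detected`` and, when a threshold is
        given, boolean ``passed``.  With ``drop=True`` failing samples are
        omitted from the returned report (callers subset their data by the
        surviving index).
    """
    values = rp_quant.values if isinstance(rp_quant, QuantTable) \
        else rp_quant.ratios
    if values.shape[0] == 0:
        raise ValueError("empty table")
    counts = values.notna().sum(axis=0).astype(int)
    report = pd.DataFrame({"detected": counts})
    report.index.name = "sample"
    if threshold is not None:
        report["passed"] = counts >= threshold
        n_fail = int((~report["passed"]).sum())
        if n_fail:
            logger.warning(
                "%d sample(s) below detection threshold %d", n_fail, threshold
            )
        if drop:
            report = report[report["passed"]]
    return report
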