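"""Reading and writing protein quantification tables.

Two input dialects are supported:

* **generic** delimited text (TSV/CSV, auto-detected by extension): first
  column (or ``id_column``) holds gene symbols, every remaining column is a
  per-sample intensity.
* **MaxQuant proteinGroups.txt**: gene symbols from ``Gene names`` (first
  symbol of a semicolon-separated group), intensities from the per-sample
  ``iBAQ <sample>`` columns; rows flagged ``Reverse`` or
  ``Potential contaminant`` (``+``) are dropped.

Intensities are iBAQ-style: non-negative, proportional to molar amount,
with missing values for undetected proteins.  By default an exact zero is
recorded as *not detected* (missing) rather than as a measured abundance of
zero, since downstream stoichiometry ratios are defined over detected
proteins only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import RPCatalog

__all__ = [
    "QuantTable",
    "read_quant_table",
    "read_sample_groups",
    "write_sample_groups",
    "filter_rp",
]

logger = logging.getLogger(__name__)

_NA_STRINGS = {"", "NA", "NaN", "nan", "N/A", "na", "NAN", "null", "None"}


@dataclass
class QuantTable:
    """Proteins x samples intensity matrix with optional group labels.

    ``values`` holds non-negative finite intensities with ``NaN`` marking
    missing (not-detected) entries; the index are unique upper-cased gene
    symbols, the columns unique sample names.  ``sample_groups`` maps sample
    name to group label and is required by group-aware operations.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate protein ids: {sorted(map(str, dups))}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(map(str, dups))}")
        arr = self.values.to_numpy(dtype=float)
        bad = np.isinf(arr) | (arr < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "intensities must be finite and >= 0; offending entry "
                f"({self.values.index[i]}, {self.values.columns[j]}) = "
                f"{arr[i, j]}"
            )
        self.values = self.values.astype(float)
        if self.sample_groups is not None:
            extra = set(self.sample_groups) - set(self.sample_ids)
            for s in extra:
                del self.sample_groups[s]

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_labels(self) -> pd.Series:
        """Group label per sample; raises if any sample is unlabeled."""
        if self.sample_groups is None:
            raise ValueError("no sample metadata attached to this table")
        missing = [s for s in self.sample_ids if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        return pd.Series(
            [self.sample_groups[s] for s in self.sample_ids],
            index=self.sample_ids,
            name="group",
        )

    def with_groups(self, sample_groups: dict[str, str]) -> "QuantTable":
        return QuantTable(self.values.copy(), dict(sample_groups))

    def to_tsv(self, path: str | Path, id_column: str = "gene") -> None:
        """Write as generic TSV; missing entries become empty cells.

        Full float precision (17 significant digits) is used so a
        write/read round trip is bit-identical.
        """
        out = self.values.copy()
        out.index.name = id_column
        out.to_csv(path, sep="\t", float_format="%.17g", na_rep="")


def _detect_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(
    path: str | Path,
    format: str = "generic_tsv",
    id_column: str | None = None,
    intensity_prefix: str = "iBAQ ",
    *,
    zeros_as_missing: bool = True,
    sum_duplicates: bool = False,
) -> QuantTable:
    """Read a quantification matrix from delimited text.

    Parameters
    ----------
    path
        Input file; ``.csv`` is comma-separated, anything else tab-separated.
    format
        ``"generic_tsv"`` or ``"maxquant_proteingroups"``.
    id_column
        Gene-symbol column.  Defaults to the first column (generic) or
        ``"Gene names"`` (MaxQuant).
    intensity_prefix
        MaxQuant only: per-sample intensity columns are those starting with
        this prefix (sample name = the remainder).
    zeros_as_missing
        Record exact zeros as not-detected (default).
    sum_duplicates
        Aggregate rows sharing a gene symbol by summing instead of raising.

    Raises
    ------
    ValueError
        Unknown format, missing id column, no intensity columns, duplicate
        symbols (without ``sum_duplicates``), or a negative intensity.
    """
    path = Path(path)
    if format not in {"generic_tsv", "maxquant_proteingroups"}:
        raise ValueError(f"unknown format {format!r}")
    raw = pd.read_csv(
        path, sep=_detect_sep(path), dtype=str, keep_default_na=False
    )
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus >=1 intensity column")

    if format == "maxquant_proteingroups":
        id_column = id_column or "Gene names"
        if id_column not in raw.columns:
            raise ValueError(f"{path}: id column {id_column!r} not found")
        for flag in ("Reverse", "Potential contaminant", "Contaminant"):
            if flag in raw.columns:
                raw = raw[raw[flag].str.strip() != "+"]
        intensity_cols = [
            c for c in raw.columns
            if c.startswith(intensity_prefix) and c != intensity_prefix.strip()
        ]
        if not intensity_cols:
            raise ValueError(
                f"{path}: no intensity columns matching prefix "
                f"{intensity_prefix!r}"
            )
        sample_names = [c[len(intensity_prefix):] for c in intensity_cols]
        ids = raw[id_column].str.split(";").str[0].str.strip().str.upper()
        data = raw[intensity_cols].copy()
        data.columns = sample_names
        keep = ids != ""
        if (~keep).any():
            logger.warning(
                "%s: dropped %d rows without a gene symbol", path, (~keep).sum()
            )
        ids, data = ids[keep], data[keep]
    else:
        id_column = id_column or raw.columns[0]
        if id_column not in raw.columns:
            raise ValueError(f"{path}: id column {id_column!r} not found")
        ids = raw[id_column].str.strip().str.upper()
        data = raw.drop(columns=[id_column])

    values = pd.DataFrame(index=ids.to_numpy(), columns=data.columns,
                          dtype=float)
    for col in data.columns:
        cell = data[col].str.strip()
        is_na = cell.isin(_NA_STRINGS)
        parsed = pd.to_numeric(cell.where(~is_na), errors="coerce")
        unparsable = parsed.isna() & ~is_na
        if unparsable.any():
            row = data.index[unparsable][0]
            raise ValueError(
                f"{path}: non-numeric intensity {cell[unparsable].iloc[0]!r} "
                f"at row {row}, column {col!r}"
            )
        neg = parsed < 0
        if neg.any():
            row = data.index[neg][0]
            raise ValueError(
                f"{path}: negative intensity {parsed[neg].iloc[0]} at row "
                f"{row}, column {col!r}"
            )
        values[col] = parsed.to_numpy()

    if zeros_as_missing:
        values = values.mask(values == 0.0)

    if values.index.has_duplicates:
        if sum_duplicates:
            dups = sorted(values.index[values.index.duplicated()].unique())
            logger.warning("summing duplicate gene symbols: %s", dups)
            values = values.groupby(level=0, sort=False).sum(min_count=1)
        else:
            dups = sorted(values.index[values.index.duplicated()].unique())
            raise ValueError(
                f"duplicate gene symbols (pass sum_duplicates=True to "
                f"aggregate): {dups}"
            )

    empty = values.columns[values.isna().all(axis=0)]
    for s in empty:
        logger.warning("%s: sample %r has no measured intensities", path, s)

    return QuantTable(values)


def read_sample_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) delimited metadata table."""
    path = Path(path)
    meta = pd.read_csv(path, sep=_detect_sep(path), dtype=str)
    if meta.shape[1] < 2:
        raise ValueError(f"{path}: expected columns (sample_id, group)")
    sample_col, group_col = meta.columns[:2]
    if meta[sample_col].duplicated().any():
        dups = sorted(meta[sample_col][meta[sample_col].duplicated()])
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    return dict(zip(meta[sample_col].str.strip(), meta[group_col].str.strip()))


def write_sample_groups(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values())}
    ).to_csv(path, sep="\t", index=False)


def filter_rp(quant: QuantTable, catalog: RPCatalog) -> QuantTable:
    """Restrict a table to catalog ribosomal proteins detected in >=1 sample.

    Returns a new :class:`QuantTable` whose proteins are the catalog members
    with at least one non-missing intensity; the sample set (and any group
    labels) is unchanged.  The resulting RP count is the dataset's detected
    panel size and is logged.

    Raises
    ------
    ValueError
        If no catalog protein is present in the table.
    """
    if quant.n_proteins == 0:
        raise ValueError("empty quantification table")
    in_catalog = [p for p in quant.protein_ids if p.upper() in catalog.symbols]
    if not in_catalog:
        raise ValueError("no ribosomal proteins found in the table")
    sub = quant.values.loc[in_catalog]
    detected = sub.index[sub.notna().any(axis=1)]
    out = QuantTable(
        sub.loc[detected].copy(),
        dict(quant.sample_groups) if quant.sample_groups else None,
    )
    logger.info(
        "RP filter: %d/%d proteins are detected catalog RPs across %d samples",
        out.n_proteins, quant.n_proteins, out.n_samples,
    )
    return out
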