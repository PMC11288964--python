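"""Catalog of cytosolic ribosomal-protein (RP) gene symbols.

The eukaryotic ribosome carries ~80 conserved core RPs (60S large subunit:
RPL family plus the P-stalk proteins; 40S small subunit: RPS family) and a
handful of tissue-restricted paralogs such as RPL10L and RPL39L (testis) or
RPS4Y1/RPS4Y2 (Y-linked).  The catalog defines which gene symbols count as
ribosomal proteins when a quantification table is filtered; mitochondrial
ribosomal proteins (MRPL*/MRPS*) are excluded by default because they belong
to a separate ribosome.  Symbols are matched case-insensitively so mouse
(``Rpl10l``) and human (``RPL10L``) tables hit the same catalog.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "RPCatalog",
    "load_catalog",
    "default_rp_names",
    "CORE_LARGE",
    "CORE_SMALL",
    "PARALOGS_LARGE",
    "PARALOGS_SMALL",
]

# Core 60S symbols (human nomenclature; RPL40/RPL41 kept alongside the HGNC
# fusion-gene symbols UBA52/FAU so either naming convention matches).
CORE_LARGE: tuple[str, ...] = (
    "RPL3", "RPL4", "RPL5", "RPL6", "RPL7", "RPL7A", "RPL8", "RPL9",
    "RPL10", "RPL10A", "RPL11", "RPL12", "RPL13", "RPL13A", "RPL14",
    "RPL15", "RPL17", "RPL18", "RPL18A", "RPL19", "RPL21", "RPL22",
    "RPL23", "RPL23A", "RPL24", "RPL26", "RPL27", "RPL27A", "RPL28",
    "RPL29", "RPL30", "RPL31", "RPL32", "RPL34", "RPL35", "RPL35A",
    "RPL36", "RPL36A", "RPL37", "RPL37A", "RPL38", "RPL39", "RPL40",
    "RPL41", "RPLP0", "RPLP1", "RPLP2",
)

# Core 40S symbols.
CORE_SMALL: tuple[str, ...] = (
    "RPSA", "RPS2", "RPS3", "RPS3A", "RPS4X", "RPS5", "RPS6", "RPS7",
    "RPS8", "RPS9", "RPS10", "RPS11", "RPS12", "RPS13", "RPS14", "RPS15",
    "RPS15A", "RPS16", "RPS17", "RPS18", "RPS19", "RPS20", "RPS21",
    "RPS23", "RPS24", "RPS25", "RPS26", "RPS27", "RPS27A", "RPS28",
    "RPS29", "RPS30",
)

PARALOGS_LARGE: tuple[str, ...] = (
    "RPL3L", "RPL7L1", "RPL10L", "RPL22L1", "RPL26L1", "RPL36AL", "RPL39L",
)

PARALOGS_SMALL: tuple[str, ...] = ("RPS4Y1", "RPS4Y2", "RPS27L")

# HGNC aliases for the ubiquitin-fusion RPs.
_ALIASES_LARGE: tuple[str, ...] = ("UBA52",)   # == RPL40
_ALIASES_SMALL: tuple[str, ...] = ("FAU",)     # == RPS30


@dataclass(frozen=True)
class RPCatalog:
    """Recognized ribosomal-protein gene symbols, split by subunit.

    Attributes
    ----------
    large_subunit, small_subunit
        Upper-cased gene symbols for the 60S and 40S subunits.
    include_rack1
        Whether RACK1, a constitutive 40S-associated protein that is not a
        core RP, is counted as small-subunit.
    exclude_mitochondrial
        Whether MRPL*/MRPS* symbols are rejected (default).
    """

    large_subunit: frozenset[str]
    small_subunit: frozenset[str]
    include_rack1: bool = False
    exclude_mitochondrial: bool = True

    def __post_init__(self) -> None:
        overlap = self.large_subunit & self.small_subunit
        if overlap:
            raise ValueError(
                f"symbols assigned to both subunits: {sorted(overlap)}"
            )
        if self.exclude_mitochondrial:
            mito = {
                s for s in self.large_subunit | self.small_subunit
                if s.startswith(("MRPL", "MRPS"))
            }
            if mito:
                raise ValueError(
                    f"mitochondrial RP symbols not allowed: {sorted(mito)}"
                )

    @property
    def symbols(self) -> frozenset[str]:
        return self.large_subunit | self.small_subunit

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def subunit_of(self, symbol: str) -> str | None:
        """Return 'large', 'small', or None for an unrecognized symbol."""
        s = symbol.upper()
        if s in self.large_subunit:
            return "large"
        if s in self.small_subunit:
            return "small"
        return None

    def to_dict(self) -> dict:
        return {
            "large_subunit": sorted(self.large_subunit),
            "small_subunit": sorted(self.small_subunit),
            "include_rack1": self.include_rack1,
            "exclude_mitochondrial": self.exclude_mitochondrial,
        }

    def write(self, path: str | Path) -> None:
        """Serialize as YAML (``.yaml``/``.yml``) or JSON."""
        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


def load_catalog(
    config: str | Path | None = None,
    *,
    include_rack1: bool = False,
    exclude_mitochondrial: bool = True,
) -> RPCatalog:
    """Build the RP catalog, optionally extended/overridden from a config file.

    The default catalog holds the ~80 core cytosolic RPs plus known paralogs
    (RPL10L, RPL39L, RPL22L1, RPS27L, RPS4Y1, ...).  A YAML/JSON config with
    ``large_subunit`` / ``small_subunit`` symbol lists extends the defaults;
    ``replace: true`` substitutes them entirely.

    Raises
    ------
    ValueError
        If a configured symbol ends up in both subunits.
    """
    large = set(CORE_LARGE) | set(PARALOGS_LARGE) | set(_ALIASES_LARGE)
    small = set(CORE_SMALL) | set(PARALOGS_SMALL) | set(_ALIASES_SMALL)
    if include_rack1:
        small.add("RACK1")

    if config is not None:
        path = Path(config)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in {".yaml", ".yml"}
            else json.loads(text)
        )
        if not isinstance(data, dict):
            raise ValueError(f"catalog config {path} must be a mapping")
        extra_large = {str(s).upper() for s in data.get("large_subunit", [])}
        extra_small = {str(s).upper() for s in data.get("small_subunit", [])}
        both = extra_large & extra_small
        if both:
            raise ValueError(
                f"config assigns symbols to both subunits: {sorted(both)}"
            )
        if data.get("replace", False):
            large, small = extra_large, extra_small
        else:
            large |= extra_large
            small |= extra_small
        if "include_rack1" in data:
            include_rack1 = bool(data["include_rack1"])
            if include_rack1:
                small.add("RACK1")
        if "exclude_mitochondrial" in data:
            exclude_mitochondrial = bool(data["exclude_mitochondrial"])

    return RPCatalog(
        large_subunit=frozenset(large),
        small_subunit=frozenset(small),
        include_rack1=include_rack1,
        exclude_mitochondrial=exclude_mitochondrial,
    )


def default_rp_names(n: int, include: tuple[str, ...] = ()) -> list[str]:
    """Deterministic list of ``n`` distinct RP symbols for simulated datasets.

    Core RPs come first (large then small subunit), then paralogs; symbols in
    ``include`` are guaranteed to appear.  Used by the synthetic presets so a
    71-RP single-cell panel and an 86-RP cohort panel are reproducible.
    """
    order = list(CORE_LARGE) + list(CORE_SMALL) + \
        list(PARALOGS_LARGE) + list(PARALOGS_SMALL)
    must = [s.upper() for s in include]
    rest = [s for s in order if s not in must]
    names = must + rest
    if n > len(names):
        raise ValueError(
            f"requested {n} RP names but only {len(names)} are available"
        )
    return sorted(names[:n])
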