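"""Synthetic iBAQ-like RP quantification datasets with known ground truth.

The generator models a proteomic measurement of ribosome composition as a
compositional x scale decomposition:

1. each group has a target stoichiometry simplex (a baseline barcode times
   the group's planted fold effects, renormalized);
2. per-sample biological variability is an optional Dirichlet draw around
   that target (concentration parameter = precision);
3. the sample's proportions are multiplied by a lognormal total-abundance
   factor (cell size / loading) and by multiplicative lognormal measurement
   noise of a given coefficient of variation;
4. detection dropout is an abundance-dependent logistic on log10 intensity
   (low-abundance RPs are more likely to go missing), plus an optional
   small missing-at-random rate for bulk designs.

Presets mirror the structure of five published study designs: six mouse
tissues x 3 monosome samples (82 RPs), four testis ages x 3 (81 RPs, with
stagewise RPL10L/RPL39L increases), a two-group neuron culture (81 RPs,
3 vs 3), a normal-vs-tumor gastric cohort (82 vs 58 whole-cell proteomes,
86 RPs), and a single-cell macrophage design (10 control vs 38 treated
cells, 71 RPs, dropout calibrated to >50 detected RPs per cell).  Group
sizes and RP counts are fixed study conditions; effect sizes are didactic
defaults (2-fold unless noted), not estimates of the real data.

All randomness flows from ``SyntheticSpec.seed`` through one
``numpy.random.Generator``; the same spec and seed reproduce the dataset
bit-identically.  Each preset's baseline barcode is frozen (drawn once from
a per-preset constant seed), so the identity of the planted RPs does not
change with the user's seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .catalog import default_rp_names
from .differential import DiffTable
from .io import QuantTable

__all__ = [
    "DropoutSpec",
    "SyntheticSpec",
    "TruthTable",
    "generate_dataset",
    "preset",
    "PRESETS",
    "evaluate_recovery",
    "cluster_purity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DropoutSpec:
    """Abundance-dependent detection: P(detected) = sigmoid(k (log10 x - m)).

    ``midpoint`` is the log10 intensity at 50% detection, ``steepness`` the
    logistic slope per decade.
    """

    midpoint: float
    steepness: float = 3.0


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic RP quantification dataset.

    Attributes
    ----------
    n_rp
        Number of ribosomal proteins in the panel.
    groups
        ``(label, n_samples)`` per group.
    seed
        Seed for all random draws (biology, noise, dropout).
    rp_names
        Panel gene symbols; drawn from the default catalog order if omitted.
    baseline_stoichiometry
        Baseline simplex over the panel.  If omitted it is drawn once from
        the spec seed as normalized lognormal(0, ``baseline_sigma``)
        variates, emulating the orders-of-magnitude spread of real iBAQ
        barcodes.
    planted_effects
        ``{group: {gene: fold}}`` multiplicative stoichiometry shifts
        (applied to the baseline, then renormalized).
    bio_concentration
        Dirichlet precision of per-sample biological variability around the
        group target; ``None`` disables it (samples share the exact target).
    total_abundance_median, total_abundance_sigma
        Lognormal per-sample total intensity (median, sd of ln).
    noise_cv
        Coefficient of variation of multiplicative measurement noise.
    dropout
        Abundance-dependent detection curve, or ``None``.
    mar_missing_rate
        Extra missing-completely-at-random probability per entry.
    """

    n_rp: int
    groups: list[tuple[str, int]]
    seed: int = 0
    rp_names: list[str] | None = None
    baseline_stoichiometry: np.ndarray | None = None
    baseline_sigma: float = 1.2
    planted_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    bio_concentration: float | None = None
    total_abundance_median: float = 1e9
    total_abundance_sigma: float = 0.25
    noise_cv: float = 0.2
    dropout: DropoutSpec | None = None
    mar_missing_rate: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_rp < 2:
            raise ValueError("n_rp must be >= 2")
        if not self.groups:
            raise ValueError("at least one group is required")
        labels = [g for g, _ in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        for g, n in self.groups:
            if n < 1:
                raise ValueError(f"group {g!r} must have n_samples >= 1")
        if self.rp_names is not None:
            if len(self.rp_names) != self.n_rp:
                raise ValueError("rp_names length must equal n_rp")
            if len(set(self.rp_names)) != self.n_rp:
                raise ValueError("rp_names must be unique")
        if self.baseline_stoichiometry is not None:
            base = np.asarray(self.baseline_stoichiometry, dtype=float)
            if base.shape != (self.n_rp,):
                raise ValueError("baseline must have length n_rp")
            if (base <= 0).any():
                raise ValueError("baseline entries must be > 0")
            if abs(base.sum() - 1.0) > 1e-9:
                raise ValueError("baseline must sum to 1")
            self.baseline_stoichiometry = base / base.sum()
        for g, effects in self.planted_effects.items():
            if g not in labels:
                raise ValueError(f"planted effects for unknown group {g!r}")
            for rp, fold in effects.items():
                if not fold > 0:
                    raise ValueError(
                        f"fold change for {rp} in {g!r} must be > 0"
                    )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0.0 <= self.mar_missing_rate < 1.0:
            raise ValueError("mar_missing_rate must be in [0, 1)")
        if self.bio_concentration is not None and self.bio_concentration <= 0:
            raise ValueError("bio_concentration must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.baseline_stoichiometry is not None:
            d["baseline_stoichiometry"] = [
                float(v) for v in self.baseline_stoichiometry
            ]
        if self.dropout is not None:
            d["dropout"] = asdict(self.dropout)
        return d

    def write(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class TruthTable:
    """Ground truth of a generated dataset.

    ``stoichiometry`` holds each group's exact target simplex (RPs x
    groups); ``planted_effects`` the fold map that produced it.  The planted
    direction of a contrast refers to the fold effects, not to the small
    renormalization shifts they induce on the other RPs.
    """

    stoichiometry: pd.DataFrame
    planted_effects: dict[str, dict[str, float]]

    @property
    def groups(self) -> list[str]:
        return list(self.stoichiometry.columns)

    def direction(self, group_a: str, group_b: str) -> pd.Series:
        """Planted direction (up/down/null) of A vs B per RP."""
        for g in (group_a, group_b):
            if g not in self.stoichiometry.columns:
                raise ValueError(f"unknown group {g!r}")
        fa = self.planted_effects.get(group_a, {})
        fb = self.planted_effects.get(group_b, {})
        out = []
        for rp in self.stoichiometry.index:
            ra, rb = fa.get(rp, 1.0), fb.get(rp, 1.0)
            out.append("up" if ra > rb else "down" if ra < rb else "null")
        return pd.Series(out, index=self.stoichiometry.index, name="planted")

    def to_tsv(self, path) -> None:
        out = self.stoichiometry.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.17g")


def _draw_baseline(n_rp: int, sigma: float, rng: np.random.Generator
                   ) -> np.ndarray:
    raw = np.exp(rng.normal(0.0, sigma, size=n_rp))
    return raw / raw.sum()


def _group_target(base: np.ndarray, rp_names: list[str],
                  effects: dict[str, float]) -> np.ndarray:
    folds = np.ones_like(base)
    index = {rp: i for i, rp in enumerate(rp_names)}
    for rp, fold in effects.items():
        if rp not in index:
            raise ValueError(f"planted effect on unknown RP {rp!r}")
        folds[index[rp]] = fold
    target = base * folds
    return target / target.sum()


def generate_dataset(spec: SyntheticSpec) -> tuple[QuantTable, TruthTable]:
    """Generate one dataset and its ground truth from a spec.

    Every sample is guaranteed at least one detected RP (the most intense
    entry is retained if dropout would otherwise empty the sample).

    Returns
    -------
    (QuantTable, TruthTable)
        Intensities with NaN for undetected entries and group labels
        attached; the truth table of group target stoichiometries.
    """
    rng = np.random.default_rng(spec.seed)
    rp_names = spec.rp_names or default_rp_names(spec.n_rp)
    base = (
        spec.baseline_stoichiometry
        if spec.baseline_stoichiometry is not None
        else _draw_baseline(spec.n_rp, spec.baseline_sigma, rng)
    )

    targets = {
        g: _group_target(base, rp_names, spec.planted_effects.get(g, {}))
        for g, _ in spec.groups
    }
    noise_sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    ln_total_median = math.log(spec.total_abundance_median)

    columns: dict[str, np.ndarray] = {}
    groups_map: dict[str, str] = {}
    for g, n in spec.groups:
        for i in range(n):
            name = f"{g}_{i + 1}"
            pi = targets[g]
            if spec.bio_concentration is not None:
                pi = rng.dirichlet(spec.bio_concentration * pi)
                pi = np.clip(pi, np.finfo(float).tiny, None)
                pi = pi / pi.sum()
            total = math.exp(
                rng.normal(ln_total_median, spec.total_abundance_sigma)
            )
            x = pi * total
            if spec.noise_cv > 0:
                x = x * np.exp(rng.normal(0.0, noise_sigma, size=spec.n_rp))
            detected = np.ones(spec.n_rp, dtype=bool)
            if spec.dropout is not None:
                z = spec.dropout.steepness * (
                    np.log10(x) - spec.dropout.midpoint
                )
                p_detect = 1.0 / (1.0 + np.exp(-z))
                detected &= rng.random(spec.n_rp) < p_detect
            if spec.mar_missing_rate > 0:
                detected &= rng.random(spec.n_rp) >= spec.mar_missing_rate
            if not detected.any():
                detected[int(np.argmax(x))] = True
            x = np.where(detected, x, np.nan)
            columns[name] = x
            groups_map[name] = g

    values = pd.DataFrame(columns, index=rp_names)
    quant = QuantTable(values, groups_map)
    truth = TruthTable(
        stoichiometry=pd.DataFrame(
            {g: targets[g] for g, _ in spec.groups}, index=rp_names
        ),
        planted_effects={
            g: dict(eff) for g, eff in spec.planted_effects.items()
        },
    )
    return quant, truth


# ---------------------------------------------------------------------------
# Presets emulating the five study designs.

# Per-preset constant seeds freezing the baseline barcode (and thereby the
# identity of the planted RPs) independently of the user-facing seed.
_BASELINE_SEEDS = {
    "tissues6": 101,
    "testis4": 102,
    "neuron2": 103,
    "gastric_cohort": 104,
    "macrophage_sc": 105,
}

# Detection midpoint of the single-cell preset, calibrated so the median
# detected-RP count per cell sits near 55 of 71 (see docs/methods.md).
_SC_DROPOUT_MIDPOINT = 5.00
_SC_DROPOUT_STEEPNESS = 2.0


def _ranked_rps(base: np.ndarray, rp_names: list[str]) -> list[str]:
    """Panel symbols sorted by decreasing baseline abundance."""
    order = np.argsort(base)[::-1]
    return [rp_names[i] for i in order]


def _balanced_up_block(
    base: np.ndarray,
    rp_names: list[str],
    down_block: list[str],
    n_up: int,
    fold_up: float,
    fold_down: float,
    start_rank: int,
) -> list[str]:
    """Choose ``n_up`` consecutive-rank RPs whose planted mass gain best
    cancels the mass lost by ``down_block``.

    Keeping the total planted mass balanced (sum of baseline x fold stays
    ~1) confines the stoichiometry shift to the planted RPs; otherwise
    renormalization would drag every unplanted ratio along with it.
    """
    mass = dict(zip(rp_names, base))
    target = (1.0 - fold_down) * sum(mass[r] for r in down_block)
    ranked = [r for r in _ranked_rps(base, rp_names) if r not in down_block]
    best, best_err = None, float("inf")
    for r in range(start_rank, len(ranked) - n_up + 1):
        block = ranked[r: r + n_up]
        gain = (fold_up - 1.0) * sum(mass[b] for b in block)
        err = abs(gain - target)
        if err < best_err:
            best, best_err = block, err
    assert best is not None
    return best


def _preset_tissues6() -> SyntheticSpec:
    n_rp = 82
    rp_names = default_rp_names(n_rp)
    rng = np.random.default_rng(_BASELINE_SEEDS["tissues6"])
    base = _draw_baseline(n_rp, 1.2, rng)
    ranked = _ranked_rps(base, rp_names)
    tissues = ["fat", "spleen", "liver", "kidney", "heart", "muscle"]
    effects: dict[str, dict[str, float]] = {}
    # each tissue up-shifts its own block of mid/high-abundance RPs; fat
    # and spleen additionally suppress each other's blocks, making them
    # the most divergent pair
    for t_i, tissue in enumerate(tissues):
        block = ranked[4 + 8 * t_i: 12 + 8 * t_i]
        effects[tissue] = {rp: 2.2 for rp in block}
    for rp in list(effects["spleen"]):
        effects["fat"][rp] = 0.45
    for rp in [r for r in effects["fat"] if r not in effects["spleen"]]:
        effects["spleen"][rp] = 0.45
    return SyntheticSpec(
        n_rp=n_rp, groups=[(t, 3) for t in tissues], rp_names=rp_names,
        baseline_stoichiometry=base, planted_effects=effects,
        bio_concentration=20000.0, noise_cv=0.05, mar_missing_rate=0.01,
        name="tissues6",
    )


def _preset_testis4() -> SyntheticSpec:
    n_rp = 81
    rp_names = default_rp_names(n_rp, include=("RPL10L", "RPL39L"))
    rng = np.random.default_rng(_BASELINE_SEEDS["testis4"])
    base = _draw_baseline(n_rp, 1.2, rng)
    ranked = [r for r in _ranked_rps(base, rp_names)
              if r not in ("RPL10L", "RPL39L")]
    stages = ["day7", "day14", "day28", "adult"]
    # stagewise paralog switching: RPL39L rises at day14 and stays; RPL10L
    # rises at day14 and again at day28
    effects: dict[str, dict[str, float]] = {
        "day7": {},
        "day14": {"RPL39L": 2.5, "RPL10L": 2.0},
        "day28": {"RPL39L": 2.5, "RPL10L": 4.0},
        "adult": {"RPL39L": 2.5, "RPL10L": 4.0},
    }
    # additional per-stage remodeling so each age forms its own PCA group
    for s_i, stage in enumerate(stages):
        for rp in ranked[6 + 5 * s_i: 11 + 5 * s_i]:
            effects[stage][rp] = 1.6
    return SyntheticSpec(
        n_rp=n_rp, groups=[(s, 3) for s in stages], rp_names=rp_names,
        baseline_stoichiometry=base, planted_effects=effects,
        bio_concentration=20000.0, noise_cv=0.05, mar_missing_rate=0.01,
        name="testis4",
    )


def _preset_neuron2() -> SyntheticSpec:
    n_rp = 81
    rp_names = default_rp_names(n_rp)
    rng = np.random.default_rng(_BASELINE_SEEDS["neuron2"])
    base = _draw_baseline(n_rp, 1.2, rng)
    ranked = _ranked_rps(base, rp_names)
    # maturation remodels seven RPs: four up, three down (mass-balanced)
    down = ranked[4:7]
    up = _balanced_up_block(base, rp_names, down, n_up=4,
                            fold_up=2.0, fold_down=0.5, start_rank=4)
    effects = {
        "DIV15": {**{rp: 2.0 for rp in up}, **{rp: 0.5 for rp in down}}
    }
    return SyntheticSpec(
        n_rp=n_rp, groups=[("DIV5", 3), ("DIV15", 3)], rp_names=rp_names,
        baseline_stoichiometry=base, planted_effects=effects,
        bio_concentration=20000.0, noise_cv=0.05, mar_missing_rate=0.01,
        name="neuron2",
    )


def _preset_gastric_cohort() -> SyntheticSpec:
    n_rp = 86
    rp_names = default_rp_names(n_rp)
    rng = np.random.default_rng(_BASELINE_SEEDS["gastric_cohort"])
    base = _draw_baseline(n_rp, 1.2, rng)
    ranked = _ranked_rps(base, rp_names)
    # tumor remodeling: 34 RPs up, 23 down (modest effects, large cohort;
    # the up block is mass-balanced against the down block)
    down = ranked[4:27]
    up = _balanced_up_block(base, rp_names, down, n_up=34,
                            fold_up=1.35, fold_down=0.75, start_rank=4)
    effects = {
        "tumor": {**{rp: 1.35 for rp in up}, **{rp: 0.75 for rp in down}}
    }
    return SyntheticSpec(
        n_rp=n_rp, groups=[("normal", 82), ("tumor", 58)], rp_names=rp_names,
        baseline_stoichiometry=base, planted_effects=effects,
        bio_concentration=3000.0, noise_cv=0.15, mar_missing_rate=0.02,
        name="gastric_cohort",
    )


def _preset_macrophage_sc() -> SyntheticSpec:
    n_rp = 71
    rp_names = default_rp_names(n_rp)
    rng = np.random.default_rng(_BASELINE_SEEDS["macrophage_sc"])
    base = _draw_baseline(n_rp, 1.2, rng)
    ranked = _ranked_rps(base, rp_names)
    # LPS activation: nine RPs double their share, nine others halve it;
    # the up block is chosen so the planted mass gain cancels the loss
    down = ranked[4:13]
    up = _balanced_up_block(base, rp_names, down, n_up=9,
                            fold_up=2.0, fold_down=0.5, start_rank=4)
    effects = {
        "LPS": {**{rp: 2.0 for rp in up}, **{rp: 0.5 for rp in down}}
    }
    return SyntheticSpec(
        n_rp=n_rp, groups=[("control", 10), ("LPS", 38)], rp_names=rp_names,
        baseline_stoichiometry=base, planted_effects=effects,
        bio_concentration=None, noise_cv=0.20,
        total_abundance_median=1e8, total_abundance_sigma=0.3,
        dropout=DropoutSpec(
            midpoint=_SC_DROPOUT_MIDPOINT, steepness=_SC_DROPOUT_STEEPNESS
        ),
        name="macrophage_sc",
    )


PRESETS = {
    "tissues6": _preset_tissues6,
    "testis4": _preset_testis4,
    "neuron2": _preset_neuron2,
    "gastric_cohort": _preset_gastric_cohort,
    "macrophage_sc": _preset_macrophage_sc,
}


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Spec for one of the named study designs.

    Raises
    ------
    ValueError
        Unknown name (the message lists the available presets).
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    spec = PRESETS[name]()
    spec.seed = seed
    return spec


def evaluate_recovery(diff: DiffTable, truth: TruthTable) -> dict:
    """Compare differential calls against the planted ground truth.

    Returns sensitivity per direction (recovered / planted), the count of
    false positives (calls on RPs with no planted effect in this contrast),
    and the false discovery proportion (NaN when nothing was called).

    Raises
    ------
    ValueError
        If the RP panels of the two tables differ.
    """
    if set(diff.table.index) != set(truth.stoichiometry.index):
        raise ValueError("differential table and truth cover different RPs")
    planted = truth.direction(diff.group_a, diff.group_b)
    called = diff.table["direction"].reindex(planted.index)

    n_up_true = int((planted == "up").sum())
    n_down_true = int((planted == "down").sum())
    up_hit = int(((planted == "up") & (called == "up")).sum())
    down_hit = int(((planted == "down") & (called == "down")).sum())
    is_call = called.isin(["up", "down"])
    false_pos = int((is_call & (planted == "null")).sum())
    n_calls = int(is_call.sum())
    return {
        "n_planted_up": n_up_true,
        "n_planted_down": n_down_true,
        "recovered_up": up_hit,
        "recovered_down": down_hit,
        "sensitivity_up": up_hit / n_up_true if n_up_true else float("nan"),
        "sensitivity_down": (
            down_hit / n_down_true if n_down_true else float("nan")
        ),
        "false_positives": false_pos,
        "n_calls": n_calls,
        "fdp": false_pos / n_calls if n_calls else float("nan"),
    }


def cluster_purity(
    clusters: pd.Series, groups: pd.Series | dict[str, str]
) -> float:
    """Fraction of samples whose cluster's majority group matches theirs."""
    g = pd.Series(groups) if not isinstance(groups, pd.Series) else groups
    g = g.reindex(clusters.index)
    if g.isna().any():
        raise ValueError("group labels missing for some clustered samples")
    total = len(clusters)
    hit = sum(
        g[clusters == c].value_counts().iloc[0]
        for c in clusters.unique()
    )
    return float(hit) / total
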