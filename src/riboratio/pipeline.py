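"""End-to-end orchestration of the stoichiometry analysis.

One call runs the full per-dataset analysis sequence — RP filtering,
stoichiometry ratios, detection QC, row scaling, SVD-imputation PCA with
group prediction ellipses, sample correlation, correlation-distance/average-
linkage clustering of rows and columns (with an optional k-cut), two-group
differential ratio testing and the volcano table — and writes every
artifact plus a JSON run report to an output directory.  Each stage is also
available standalone through the library modules, and staged runs on the
written TSVs reproduce the end-to-end artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalog import load_catalog
from .clustering import (
    average_linkage,
    cluster_composition,
    correlation_distance,
    cut_tree,
    pearson_correlation,
)
from .differential import differential_ratio, volcano_table
from .io import QuantTable, filter_rp, read_quant_table, read_sample_groups
from .multivariate import pca_svd_impute, prediction_ellipse, scale_rows
from .ratios import compute_ratios, detected_rp_counts

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (the zero-configuration path uses
    the standard defaults: alpha 0.05, 95% ellipses, correlation distance
    with average linkage, Student t-tests)."""

    input: str | Path
    out_dir: str | Path
    metadata: str | Path | None = None
    format: str = "generic_tsv"
    id_column: str | None = None
    intensity_prefix: str = "iBAQ "
    catalog_config: str | Path | None = None
    include_rack1: bool = False
    mode: str = "ratio"
    group_a: str | None = None
    group_b: str | None = None
    alpha: float = 0.05
    test_variant: str = "student"
    n_components: int = 2
    pca_tol: float = 1e-9
    pca_max_iter: int = 500
    ellipse_prob: float = 0.95
    ellipse_method: str = "f"
    cluster_k: int | None = None
    detection_threshold: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.ellipse_prob < 1.0:
            raise ValueError("ellipse probability must be in (0, 1)")
        if self.mode not in {"ratio", "level"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.test_variant not in {"student", "welch"}:
            raise ValueError(f"unknown test variant {self.test_variant!r}")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input"] = str(self.input)
        d["out_dir"] = str(self.out_dir)
        for key in ("metadata", "catalog_config"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


def _pick_groups(labels: pd.Series, cfg: RunConfig) -> tuple[str, str] | None:
    if cfg.group_a and cfg.group_b:
        return cfg.group_a, cfg.group_b
    uniq = list(pd.unique(labels))
    if len(uniq) == 2:
        return str(uniq[0]), str(uniq[1])
    logger.warning(
        "differential stage skipped: %d groups present and no pair given",
        len(uniq),
    )
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write artifacts under ``out_dir``.

    Returns the run report (also written as ``report.json``).  On a stage
    failure the report names the failed stage, partial outputs are kept and
    the exception propagates.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "riboratio",
        "version": __version__,
        "python": platform.python_version(),
        "config": config.to_dict(),
        "stages": {},
    }
    stage = "setup"
    try:
        # --- ingestion ----------------------------------------------------
        stage = "read_input"
        quant = read_quant_table(
            config.input, format=config.format, id_column=config.id_column,
            intensity_prefix=config.intensity_prefix,
        )
        if config.metadata is not None:
            quant = quant.with_groups(read_sample_groups(config.metadata))
        report["stages"]["read_input"] = {
            "n_proteins": quant.n_proteins, "n_samples": quant.n_samples,
        }

        stage = "filter_rp"
        catalog = load_catalog(
            config.catalog_config, include_rack1=config.include_rack1
        )
        rp_quant = filter_rp(quant, catalog)
        rp_quant.to_tsv(out / "rp_quant.tsv")
        report["stages"]["filter_rp"] = {"n_rp_detected": rp_quant.n_proteins}

        stage = "ratios"
        ratios = compute_ratios(rp_quant)
        ratios.to_tsv(out / "ratios.tsv")
        qc = detected_rp_counts(rp_quant, threshold=config.detection_threshold)
        qc.to_csv(out / "qc_detected.tsv", sep="\t")
        report["stages"]["ratios"] = {
            "median_detected_per_sample": float(qc["detected"].median()),
        }

        # --- multivariate -------------------------------------------------
        stage = "scale_rows"
        scaled = scale_rows(ratios, center=True, unit_variance=True)
        frame = scaled.values.copy()
        frame.index.name = "gene"
        frame.to_csv(out / "scaled.tsv", sep="\t",
                     float_format="%.17g", na_rep="")
        report["stages"]["scale_rows"] = {
            "n_rows": len(scaled.protein_ids),
            "dropped": scaled.scaling_record["dropped"],
        }

        stage = "pca"
        pca = pca_svd_impute(
            scaled, n_components=config.n_components,
            tol=config.pca_tol, max_iter=config.pca_max_iter,
        )
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t",
                          float_format="%.17g")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t",
                            float_format="%.17g")
        pd.Series(
            pca.explained_var,
            index=[f"PC{i+1}" for i in range(len(pca.explained_var))],
            name="explained_var",
        ).to_csv(out / "pca_explained.tsv", sep="\t", float_format="%.17g")
        report["stages"]["pca"] = {
            "explained_var": [float(v) for v in pca.explained_var],
            "converged": pca.converged,
            "n_iter": pca.n_iter,
        }

        stage = "ellipses"
        labels = None
        if ratios.sample_groups:
            labels = ratios.group_labels()
            try:
                ellipses = prediction_ellipse(
                    pca.scores, labels, prob=config.ellipse_prob,
                    method=config.ellipse_method,
                )
                (out / "ellipses.json").write_text(
                    json.dumps([e.to_dict() for e in ellipses], indent=2)
                )
                report["stages"]["ellipses"] = {
                    "groups": [e.group for e in ellipses]
                }
            except ValueError as exc:
                logger.warning("prediction ellipses skipped: %s", exc)
                report["stages"]["ellipses"] = {"skipped": str(exc)}

        stage = "correlation"
        corr = pearson_correlation(ratios)
        corr.to_tsv(out / "correlation.tsv")
        report["stages"]["correlation"] = {
            "min_r": float(np.nanmin(corr.r.to_numpy())),
        }

        stage = "clustering"
        d_samples = correlation_distance(scaled, axis="columns")
        dend_samples = average_linkage(d_samples)
        (out / "samples.newick").write_text(dend_samples.to_newick() + "\n")
        d_rows = correlation_distance(scaled, axis="rows")
        dend_rows = average_linkage(d_rows)
        (out / "rp_rows.newick").write_text(dend_rows.to_newick() + "\n")
        pd.DataFrame({
            "sample_order": dend_samples.leaf_order,
        }).to_csv(out / "sample_order.tsv", sep="\t", index=False)
        pd.DataFrame({
            "gene_order": dend_rows.leaf_order,
        }).to_csv(out / "gene_order.tsv", sep="\t", index=False)
        report["stages"]["clustering"] = {
            "n_samples": dend_samples.n_leaves, "n_rows": dend_rows.n_leaves,
        }
        if config.cluster_k is not None:
            clusters = cut_tree(dend_samples, config.cluster_k)
            clusters.to_csv(out / "clusters.tsv", sep="\t")
            if labels is not None:
                comp = cluster_composition(clusters, labels)
                comp.to_csv(out / "cluster_composition.tsv", sep="\t")
                report["stages"]["clustering"]["composition"] = {
                    str(c): comp.loc[c].to_dict() for c in comp.index
                }

        # --- differential -------------------------------------------------
        if labels is not None:
            pair = _pick_groups(labels, config)
            if pair is not None:
                stage = "differential"
                source = ratios if config.mode == "ratio" else rp_quant
                diff = differential_ratio(
                    source, pair[0], pair[1], mode=config.mode,
                    alpha=config.alpha, variant=config.test_variant,
                )
                diff.to_tsv(out / "differential.tsv")
                volcano = volcano_table(diff)
                volcano.to_csv(out / "volcano.tsv", sep="\t",
                               float_format="%.10g", na_rep="NA")
                report["stages"]["differential"] = diff.summary()
    except Exception as exc:
        report["failed_stage"] = stage
        report["error"] = str(exc)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        raise

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
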