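"""Readers, writers and the end-to-end pipeline driver.

All tables are plain TSV with a header row.  Expression matrices have the
sample identifier in the first column and one column per gene; clinical
tables carry the controlled-vocabulary covariates plus the relapse-free
survival time/event pair; mutation tables are MAF-like (sample_id,
gene_symbol, extra columns ignored).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, cohort_stats, survival
from .signature import ExpressionMatrix, GeneSignature, load_signature, score_cohort

__all__ = [
    "RunConfig",
    "read_expression",
    "write_expression",
    "read_signature_config",
    "read_clinical",
    "read_scores",
    "read_labels",
    "read_mutations",
    "write_table",
    "run_pipeline",
]

logger = logging.getLogger("tp53sig")

FLOAT_FORMAT = "%.6g"

#: controlled vocabulary for categorical clinical columns
CLINICAL_VOCAB = {
    "er_positive": {0, 1},
    "pgr_positive": {0, 1},
    "her2_positive": {0, 1},
    "node_positive": {0, 1},
    "chemo": {0, 1},
    "endocrine": {0, 1},
    "stage": {"I", "IIA", "IIB"},
    "grade": {1, 2, 3},
}


@dataclass
class RunConfig:
    """Paths and parameters for one end-to-end pipeline run."""

    expression_path: Path
    clinical_path: Path
    signature_path: Path
    labels_path: Path | None  # TP53 structural-mutation labels; enables calibration
    out_dir: Path
    platform: str = "ncounter"
    cutoff: float | None = None  # fixed cutoff; default: calibrate from labels
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("expression_path", "clinical_path", "signature_path"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if self.labels_path is not None:
            self.labels_path = Path(self.labels_path)
            if not self.labels_path.exists():
                raise FileNotFoundError(f"labels_path does not exist: {self.labels_path}")
        if self.labels_path is None and self.cutoff is None:
            raise ValueError("either a labels table (for calibration) or a fixed cutoff is required")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        self.out_dir = Path(self.out_dir)


def read_expression(path, platform: str = "ncounter") -> ExpressionMatrix:
    """Load a sample x gene count TSV (first column sample_id)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    genes = header[1:]
    if len(set(genes)) != len(genes):
        dups = sorted({g for g in genes if genes.count(g) > 1})
        raise ValueError(f"duplicate gene columns in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"duplicate sample identifiers in {path}")
    non_numeric = df.columns[[not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
        raise ValueError(f"non-numeric count in column {col!r}, sample {bad[0]!r}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(f"missing count at sample {row!r}, gene {col!r}")
    return ExpressionMatrix(df.astype(float), platform=platform)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.counts.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="sample_id")


def read_signature_config(path) -> GeneSignature:
    """Load a YAML mapping of up/down/control to gene identifier lists."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"signature config {path} must be a mapping of roles to gene lists")
    allow = bool(cfg.pop("allow_nonstandard_sizes", False))
    return load_signature(cfg, allow_nonstandard_sizes=allow)


def read_clinical(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load a clinical TSV; returns (covariates, outcomes).

    The table must contain ``time`` and ``event`` columns (RFS months and
    recurrence indicator); categorical columns listed in
    ``CLINICAL_VOCAB`` are validated against their controlled vocabulary.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} lacks required column {col!r}")
    for col, levels in CLINICAL_VOCAB.items():
        if col in df.columns:
            observed = set(df[col].unique())
            bad = observed - levels
            if bad:
                raise ValueError(f"column {col!r} has unknown levels {sorted(map(str, bad))}; allowed {sorted(map(str, levels))}")
    outcomes = df[["time", "event"]].astype(float)
    outcomes["event"] = outcomes["event"].astype(int)
    covariates = df.drop(columns=["time", "event"])
    return covariates, outcomes


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "risk_score" not in df.columns:
        raise ValueError(f"scores table {path} lacks a 'risk_score' column")
    if "status" not in df.columns:
        df["status"] = "unassigned"
    return df


def read_labels(path) -> pd.Series:
    """TP53 structural-mutation labels: columns sample_id, tp53_mutation (0/1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "tp53_mutation" not in df.columns:
        raise ValueError(f"labels table {path} lacks a 'tp53_mutation' column")
    labels = df["tp53_mutation"].astype(int)
    if not labels.isin((0, 1)).all():
        raise ValueError("tp53_mutation labels must be 0/1")
    return labels


def read_mutations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"mutation table {path} lacks required column {col!r}")
    return df[["sample_id", "gene_symbol"]]


def write_table(df: pd.DataFrame, path, *, index_label: str | None = "sample_id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def run_pipeline(config: RunConfig) -> dict:
    """Score -> calibrate/assign -> survival -> associations, writing every table.

    Returns a report dictionary with the calibration summary, survival
    statistics and output paths; everything is also written under
    ``config.out_dir`` along with a provenance log of all decision
    parameters.
    """
    logging.basicConfig(level=config.verbosity)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    signature = read_signature_config(config.signature_path)
    expr = read_expression(config.expression_path, platform=config.platform)
    covariates, outcomes = read_clinical(config.clinical_path)

    scores = score_cohort(expr, signature)
    report: dict = {"n_samples": len(scores)}

    if config.labels_path is not None:
        labels = read_labels(config.labels_path).reindex(scores.index)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()[:5]
            raise ValueError(f"samples lack TP53 labels: {missing}")
        cal = calibration.select_cutoff(scores["risk_score"].to_numpy(), labels.to_numpy())
        cutoff = config.cutoff if config.cutoff is not None else cal.cutoff
        curve = calibration.roc_curve(scores["risk_score"].to_numpy(), labels.to_numpy())
        write_table(
            pd.DataFrame({"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}),
            out / "roc_points.tsv",
            index_label=None,
        )
        report["calibration"] = {
            "cutoff": cal.cutoff,
            "auc": cal.auc,
            "confusion": cal.confusion,
            "sensitivity": cal.sensitivity,
            "specificity": cal.specificity,
            "accuracy": cal.accuracy,
        }
    else:
        cutoff = float(config.cutoff)
    report["cutoff_applied"] = cutoff

    assigned = calibration.assign_status(scores, cutoff)
    write_table(assigned, out / "risk_scores.tsv")

    common = assigned.index.intersection(outcomes.index)
    outc = outcomes.loc[common]
    status = assigned.loc[common, "status"]

    curves = survival.km_estimate(outc, status)
    for label, curve_df in curves.items():
        write_table(curve_df, out / f"km_{label}.tsv", index_label=None)
    stat, p = survival.logrank_test(outc, status)
    report["logrank"] = {"statistic": stat, "p_value": p}

    cov = covariates.loc[common].copy()
    cov["signature_mt"] = (status == "MT").astype(int)
    numeric = cov.select_dtypes("number")
    uni = survival.cox_fit(numeric, outc, "univariate")
    try:
        multi = survival.cox_fit(numeric, outc, "multivariate")
    except (ValueError, RuntimeError) as exc:
        logger.warning("multivariate Cox fit skipped: %s", exc)
        multi = []
    cox_rows = [
        {"mode": mode, "variable": r.variable, "hazard_ratio": r.hazard_ratio,
         "ci_low": r.ci_low, "ci_high": r.ci_high, "p_value": r.p_value}
        for mode, rows in (("univariate", uni), ("multivariate", multi))
        for r in rows
    ]
    cox_df = pd.DataFrame(cox_rows)
    write_table(cox_df, out / "cox.tsv", index_label=None)
    report["cox"] = cox_rows

    assoc_rows = []
    for col in covariates.columns:
        if col not in covariates.loc[common].columns:
            continue
        series = covariates.loc[common, col]
        continuous = col == "age"
        try:
            res = cohort_stats.association_table(series, status, variable=col, continuous=continuous)
        except ValueError as exc:
            logger.warning("association skipped for %s: %s", col, exc)
            continue
        assoc_rows.append({"variable": res.variable, "test": res.test_used, "p_value": res.p_value})
    write_table(pd.DataFrame(assoc_rows), out / "associations.tsv", index_label=None)
    report["associations"] = assoc_rows

    provenance = {
        "cutoff_convention": "midpoint of accuracy-maximising interval; MT iff score > cutoff",
        "seed": config.seed,
        "cutoff_applied": cutoff,
        "platform": config.platform,
        "signature": {"up": len(signature.up_genes), "down": len(signature.down_genes)},
    }
    (out / "run_log.json").write_text(json.dumps({**provenance, "report": _jsonable(report)}, indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
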