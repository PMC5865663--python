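"""Signature-status assignment without a calibrated cutoff, plus variant filtering.

Public expression cohorts (TCGA-style) lack the nCounter learning cohort
needed to calibrate a risk-score cutoff, so status is assigned from the
31 signature genes directly by either of two routes anchored to TP53
somatic-mutation calls:

* unsupervised — split the cohort into two Ward-linkage clusters and label
  the cluster dominated by TP53-mutant samples as signature MT;
* supervised — train a linear max-margin (SVM) classifier on a balanced
  random subset of mutant and wild-type samples and predict status for the
  held-out remainder.

Also implements the somatic-variant filter applied to RNA-seq-derived
calls: population frequency under 1% in both SNP databases and read depth
strictly over 20.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.svm import SVC

from .signature import STATUS_MT, STATUS_WT, ExpressionMatrix, GeneSignature

__all__ = [
    "VariantRecord",
    "ClassifierModel",
    "ClusterTieError",
    "cluster_classify",
    "svm_classify",
    "filter_somatic_variants",
]

MAX_POP_FREQ = 0.01  # "under 1 percent in both SNP databases"
MIN_DEPTH = 20  # strict: DP > 20


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant call: population frequencies may be absent (None)."""

    sample_id: str
    gene: str
    variant_id: str
    popfreq_db1: float | None
    popfreq_db2: float | None
    depth: int

    def __post_init__(self) -> None:
        for f in (self.popfreq_db1, self.popfreq_db2):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"population frequency {f} outside [0, 1]")
        if self.depth < 0:
            raise ValueError("read depth must be non-negative")


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted linear decision rule over the signature genes."""

    weights: pd.Series  # one weight per signature gene
    intercept: float
    training_samples: tuple[str, ...]
    seed: int


class ClusterTieError(RuntimeError):
    """Both clusters carry the same TP53-mutant fraction; labelling is ambiguous."""


def _feature_matrix(expr: ExpressionMatrix, genes: Sequence[str], log_transform: bool) -> pd.DataFrame:
    x = expr.restrict(list(genes)).counts.astype(float)
    if log_transform:
        x = np.log2(x + 1.0)
    return x


def _zscore(x: pd.DataFrame, mean: pd.Series | None = None, sd: pd.Series | None = None):
    if mean is None:
        mean = x.mean(axis=0)
    if sd is None:
        sd = x.std(axis=0, ddof=0)
    sd = sd.mask(_is_constant(sd, mean), 1.0)  # constant genes carry no information; avoid 0/0
    return (x - mean) / sd, mean, sd


def _is_constant(sd: pd.Series, mean: pd.Series) -> pd.Series:
    return sd <= 1e-12 * np.maximum(1.0, mean.abs())


def _check_mut_labels(expr: ExpressionMatrix, tp53_mut: pd.Series) -> pd.Series:
    tp53_mut = pd.Series(tp53_mut).reindex(expr.sample_ids)
    if tp53_mut.isna().any():
        missing = tp53_mut.index[tp53_mut.isna()].tolist()[:5]
        raise ValueError(f"TP53 mutation label missing for samples: {missing}")
    tp53_mut = tp53_mut.astype(int)
    if not tp53_mut.isin((0, 1)).all():
        raise ValueError("TP53 mutation labels must be binary")
    return tp53_mut


def cluster_classify(
    expr31: ExpressionMatrix,
    tp53_mut: pd.Series,
    *,
    signature: GeneSignature | None = None,
    log_transform: bool = True,
) -> pd.Series:
    """Assign MT/WT status by two-way hierarchical clustering.

    Samples are clustered on per-gene standardised log2(x+1) expression of
    the signature genes (Euclidean distance, Ward linkage) and cut into two
    clusters; the cluster with the higher fraction of TP53-mutant samples
    is labelled MT.  An exact tie in mutant fractions raises
    :class:`ClusterTieError` rather than guessing.
    """
    genes = list(signature.signature_genes) if signature is not None else expr31.gene_ids
    if len(expr31.sample_ids) < 4:
        raise ValueError("clustering needs at least 4 samples")
    tp53_mut = _check_mut_labels(expr31, tp53_mut)
    if tp53_mut.nunique() < 2:
        raise ValueError("both TP53 mutation classes must be present")

    x = _feature_matrix(expr31, genes, log_transform)
    z, _, _ = _zscore(x)
    assignment = fcluster(linkage(z.to_numpy(), method="ward"), t=2, criterion="maxclust")

    fracs = {c: tp53_mut[assignment == c].mean() for c in (1, 2)}
    if np.isclose(fracs[1], fracs[2]):
        raise ClusterTieError(
            "both clusters have equal TP53-mutant fraction "
            f"({fracs[1]:.3f}); inspect the dendrogram or change the linkage"
        )
    mt_cluster = max(fracs, key=fracs.get)
    status = np.where(assignment == mt_cluster, STATUS_MT, STATUS_WT)
    return pd.Series(status, index=expr31.sample_ids, name="status")


def svm_classify(
    expr31: ExpressionMatrix,
    tp53_mut: pd.Series,
    *,
    train_per_class: int = 50,
    seed: int = 0,
    c: float = 1.0,
    signature: GeneSignature | None = None,
    log_transform: bool = True,
) -> tuple[pd.Series, ClassifierModel]:
    """Assign MT/WT status with a linear max-margin classifier.

    A balanced training set of ``train_per_class`` TP53-mutant and as many
    wild-type samples is drawn at random with ``seed``; a linear SVM (hinge
    loss, regularisation ``c``) is fitted on per-gene standardised log
    expression and status is predicted for every non-training sample.
    Training samples are excluded from the returned status series so
    downstream group statistics are computed on held-out samples only.
    """
    genes = list(signature.signature_genes) if signature is not None else expr31.gene_ids
    tp53_mut = _check_mut_labels(expr31, tp53_mut)
    mutants = tp53_mut.index[tp53_mut == 1]
    wildtypes = tp53_mut.index[tp53_mut == 0]
    if len(mutants) < train_per_class or len(wildtypes) < train_per_class:
        raise ValueError(
            f"need at least {train_per_class} samples per TP53 class, "
            f"got {len(mutants)} mutant / {len(wildtypes)} wild type"
        )

    rng = np.random.default_rng(seed)
    train = list(rng.choice(mutants, train_per_class, replace=False)) + list(
        rng.choice(wildtypes, train_per_class, replace=False)
    )
    test = [s for s in expr31.sample_ids if s not in set(train)]

    x = _feature_matrix(expr31, genes, log_transform)
    x_train = x.loc[train]
    if _is_constant(x_train.std(axis=0, ddof=0), x_train.mean(axis=0)).all():
        raise ValueError("training expression is constant for every gene; classes are not separable")
    z_train, mean, sd = _zscore(x_train)
    z_test, _, _ = _zscore(x.loc[test], mean, sd)

    clf = SVC(kernel="linear", C=c)
    clf.fit(z_train.to_numpy(), tp53_mut.loc[train].to_numpy())

    pred = clf.predict(z_test.to_numpy())
    status = pd.Series(np.where(pred == 1, STATUS_MT, STATUS_WT), index=test, name="status")
    model = ClassifierModel(
        weights=pd.Series(clf.coef_.ravel(), index=genes, name="weight"),
        intercept=float(clf.intercept_[0]),
        training_samples=tuple(train),
        seed=seed,
    )
    return status, model


def filter_somatic_variants(
    variants: Sequence[VariantRecord],
    *,
    max_pop_freq: float = MAX_POP_FREQ,
    min_depth: int = MIN_DEPTH,
    drop_unannotated: bool = False,
) -> list[VariantRecord]:
    """Keep putative somatic variants: rare in both SNP databases and well covered.

    A record passes when its population frequency is below ``max_pop_freq``
    (1%) in *both* databases and its read depth is strictly greater than
    ``min_depth`` (DP > 20).  A frequency absent from a database is treated
    as 0 so novel variants are kept; ``drop_unannotated=True`` instead
    discards records missing either annotation.
    """
    kept = []
    for v in variants:
        freqs = (v.popfreq_db1, v.popfreq_db2)
        if drop_unannotated and any(f is None for f in freqs):
            continue
        if any((f or 0.0) >= max_pop_freq for f in freqs):
            continue
        if v.depth <= min_depth:
            continue
        kept.append(v)
    return kept
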