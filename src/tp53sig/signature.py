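"""TP53-signature gene sets, risk scores, and FFPE/FF platform concordance.

The TP53 signature summarises p53-pathway functional status from the
expression of 31 genes: 22 genes up-regulated and 9 genes down-regulated in
TP53-mutant tumours (plus internal control genes used only for display
normalisation).  The per-sample risk score is the ratio

    score = (sum of counts over the 22 up-genes)
          / (sum of counts over the 9 down-genes)

which is invariant to any per-sample scaling of the counts, so raw counts
can be scored directly on either the nCounter or an RNA-seq platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneSignature",
    "ExpressionMatrix",
    "load_signature",
    "compute_risk_score",
    "score_cohort",
    "paired_concordance",
    "control_gene_normalise",
    "DEFAULT_UP_SIZE",
    "DEFAULT_DOWN_SIZE",
]

DEFAULT_UP_SIZE = 22
DEFAULT_DOWN_SIZE = 9

#: risk-score table column names / status levels
STATUS_UNASSIGNED = "unassigned"
STATUS_MT = "MT"
STATUS_WT = "WT"


@dataclass(frozen=True)
class GeneSignature:
    """The up-/down-regulated and control gene identifier sets.

    ``up_genes`` and ``down_genes`` are stored as ordered tuples so that
    scoring is deterministic; set semantics (disjointness, membership) are
    enforced at construction.
    """

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    control_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        up, down, ctl = set(self.up_genes), set(self.down_genes), set(self.control_genes)
        if len(up) != len(self.up_genes) or len(down) != len(self.down_genes) or len(ctl) != len(self.control_genes):
            raise ValueError("duplicate gene identifiers within a signature role")
        overlap = (up & down) | (up & ctl) | (down & ctl)
        if overlap:
            raise ValueError(f"genes assigned to more than one signature role: {sorted(overlap)}")

    @property
    def signature_genes(self) -> tuple[str, ...]:
        """Up- and down-regulated genes, in scoring order (controls excluded)."""
        return self.up_genes + self.down_genes

    @property
    def all_genes(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes + self.control_genes


@dataclass
class ExpressionMatrix:
    """Non-negative sample x gene counts with a platform tag.

    ``counts`` is a pandas DataFrame indexed by sample identifier with gene
    identifiers as columns.  Both axes must be unique and every entry must
    be a finite non-negative number.
    """

    counts: pd.DataFrame
    platform: str = "ncounter"

    _PLATFORMS = ("ncounter", "rnaseq")

    def __post_init__(self) -> None:
        if self.platform not in self._PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {self._PLATFORMS}")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        values = self.counts.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite count at sample {self.counts.index[i]!r}, gene {self.counts.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[i]!r}, gene {self.counts.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    def restrict(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Sub-matrix over ``genes`` (hard error on any absent gene)."""
        missing = [g for g in genes if g not in self.counts.columns]
        if missing:
            raise KeyError(f"genes absent from expression matrix: {missing}")
        return ExpressionMatrix(self.counts.loc[:, list(genes)].copy(), platform=self.platform)


def load_signature(
    signature_config: Mapping[str, Iterable[str]],
    *,
    allow_nonstandard_sizes: bool = False,
) -> GeneSignature:
    """Build a validated :class:`GeneSignature` from a role -> gene-list mapping.

    The configuration maps the roles ``up``, ``down`` and (optionally)
    ``control`` to gene identifier lists.  The default signature has exactly
    22 up- and 9 down-regulated genes; synthetic or reduced panels may
    override the size check with ``allow_nonstandard_sizes=True``.
    """
    known = {"up", "down", "control"}
    unknown = set(signature_config) - known
    if unknown:
        raise ValueError(f"unknown signature roles {sorted(unknown)}; expected subset of {sorted(known)}")
    if "up" not in signature_config or "down" not in signature_config:
        raise ValueError("signature configuration must provide 'up' and 'down' gene lists")

    up = tuple(str(g) for g in signature_config["up"])
    down = tuple(str(g) for g in signature_config["down"])
    control = tuple(str(g) for g in signature_config.get("control", ()))
    sig = GeneSignature(up, down, control)

    if not allow_nonstandard_sizes:
        if len(up) != DEFAULT_UP_SIZE or len(down) != DEFAULT_DOWN_SIZE:
            raise ValueError(
                f"expected {DEFAULT_UP_SIZE} up- and {DEFAULT_DOWN_SIZE} down-regulated genes, "
                f"got {len(up)} and {len(down)}; pass allow_nonstandard_sizes=True for synthetic panels"
            )
    return sig


def compute_risk_score(sample_counts: Mapping[str, float], signature: GeneSignature) -> float:
    """Risk score of one sample: sum(up-gene counts) / sum(down-gene counts).

    Raises ``KeyError`` naming the first missing signature gene and
    ``ZeroDivisionError`` when the down-gene sum is zero (the score is
    undefined for such a degenerate sample).
    """
    for gene in signature.signature_genes:
        if gene not in sample_counts:
            raise KeyError(f"signature gene {gene!r} missing from sample counts")
    up_sum = float(sum(sample_counts[g] for g in signature.up_genes))
    down_sum = float(sum(sample_counts[g] for g in signature.down_genes))
    if down_sum == 0.0:
        raise ZeroDivisionError("down-gene count sum is zero; risk score undefined for this sample")
    return up_sum / down_sum


def score_cohort(matrix: ExpressionMatrix, signature: GeneSignature) -> pd.DataFrame:
    """Score every sample of a cohort.

    Returns a DataFrame indexed by sample_id with columns ``risk_score``
    (float) and ``status`` (all ``"unassigned"`` until a cutoff is applied
    via :func:`tp53sig.calibration.assign_status`).
    """
    missing = [g for g in signature.signature_genes if g not in matrix.counts.columns]
    if missing:
        raise KeyError(f"signature genes absent from expression matrix: {missing}")
    up = matrix.counts.loc[:, list(signature.up_genes)].sum(axis=1).astype(float)
    down = matrix.counts.loc[:, list(signature.down_genes)].sum(axis=1).astype(float)
    zero = down == 0.0
    if zero.any():
        bad = down.index[zero][0]
        raise ZeroDivisionError(f"down-gene count sum is zero for sample {bad!r}; risk score undefined")
    table = pd.DataFrame({"risk_score": up / down, "status": STATUS_UNASSIGNED})
    table.index.name = "sample_id"
    return table


def paired_concordance(
    ff: ExpressionMatrix,
    ffpe: ExpressionMatrix,
    genes: Sequence[str],
    *,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-sample Pearson correlation between paired FF and FFPE profiles.

    For each sample present in both matrices, the correlation is computed
    across ``genes`` on log2(count + 1) values by default (count data are
    heavy-tailed; ``log_scale=False`` correlates raw counts).  Requires at
    least 3 genes and identical sample sets.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("paired concordance needs at least 3 genes")
    if set(ff.sample_ids) != set(ffpe.sample_ids):
        raise ValueError("FF and FFPE matrices must contain the same samples")
    a = ff.restrict(genes).counts
    b = ffpe.restrict(genes).counts.loc[a.index]
    if log_scale:
        a, b = np.log2(a + 1.0), np.log2(b + 1.0)
    rows = []
    for sample in a.index:
        x = a.loc[sample].to_numpy(dtype=float)
        y = b.loc[sample].to_numpy(dtype=float)
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            raise ValueError(f"zero variance across genes for sample {sample!r}; correlation undefined")
        rows.append((sample, float(np.corrcoef(x, y)[0, 1])))
    out = pd.DataFrame(rows, columns=["sample_id", "pearson_r"]).set_index("sample_id")
    return out


def control_gene_normalise(matrix: ExpressionMatrix, control_genes: Sequence[str]) -> ExpressionMatrix:
    """Scale each sample by the geometric mean of its control-gene counts.

    Intended only for cross-sample displays; the risk score itself is a
    within-sample ratio and never requires this step.
    """
    ctl = matrix.restrict(list(control_genes)).counts
    if (ctl.to_numpy() <= 0).any():
        raise ValueError("control-gene counts must be strictly positive for geometric-mean scaling")
    geo = np.exp(np.log(ctl).mean(axis=1))
    factor = geo.mean() / geo
    scaled = matrix.counts.mul(factor, axis=0)
    return ExpressionMatrix(scaled, platform=matrix.platform)
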