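"""Clinicopathological association tests and the somatic-mutation screen.

Categorical clinical variables (ER, PgR, HER2, grade, stage, node...) are
tested against signature status with the chi-square test, falling back to
Fisher's exact test for 2x2 tables with a small expected cell; continuous
variables (age) go to Kruskal-Wallis.  Continuous molecular burdens (CNV,
somatic mutation number, PD-L1/CD8B expression) are compared between
status groups with the two-sided Mann-Whitney/Wilcoxon rank-sum test.  The
mutation screen retains genes mutated in at least ``min_mt_samples``
signature-mutant samples and tests each with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .signature import STATUS_MT, STATUS_WT

__all__ = [
    "ContingencyResult",
    "MutationScreenRow",
    "association_table",
    "compare_continuous",
    "mutation_burden",
    "mutated_gene_screen",
]


@dataclass(frozen=True)
class ContingencyResult:
    variable: str
    table: pd.DataFrame  # status (rows MT/WT) x category counts
    test_used: str  # chi_square | fisher_exact | kruskal_wallis
    statistic: float
    p_value: float


@dataclass(frozen=True)
class MutationScreenRow:
    gene: str
    n_mut_in_mt: int
    n_mut_in_wt: int
    n_mt: int
    n_wt: int
    p_value: float
    enriched_in: str  # MT | WT


def _split_statuses(statuses: pd.Series) -> pd.Series:
    statuses = pd.Series(statuses)
    bad = set(statuses.unique()) - {STATUS_MT, STATUS_WT}
    if bad:
        raise ValueError(f"unknown status levels {sorted(bad)}; expected MT/WT")
    if statuses.nunique() < 2:
        raise ValueError("both MT and WT statuses must be present")
    return statuses


def association_table(
    clinical: pd.Series,
    statuses: pd.Series,
    *,
    variable: str | None = None,
    continuous: bool = False,
) -> ContingencyResult:
    """Test the association between one clinical variable and MT/WT status.

    Categorical variables give a 2 x k contingency table tested by
    chi-square (with Fisher's exact test when any expected count of a 2x2
    table falls below 5).  ``continuous=True`` routes the variable (e.g.
    age) to the Kruskal-Wallis rank test across the status groups.
    """
    statuses = _split_statuses(statuses)
    clinical = pd.Series(clinical)
    if len(clinical) != len(statuses):
        raise ValueError("clinical variable and statuses must have equal length")
    name = variable or (clinical.name if clinical.name is not None else "variable")

    if continuous:
        groups = [clinical[np.asarray(statuses) == s].to_numpy(dtype=float) for s in (STATUS_MT, STATUS_WT)]
        stat, p = stats.kruskal(*groups)
        table = pd.DataFrame(
            {"n": [len(g) for g in groups], "median": [float(np.median(g)) for g in groups]},
            index=[STATUS_MT, STATUS_WT],
        )
        return ContingencyResult(name, table, "kruskal_wallis", float(stat), float(p))

    if clinical.nunique() < 2:
        raise ValueError(f"variable {name!r} has a single category; association undefined")
    table = pd.crosstab(pd.Series(np.asarray(statuses), name="status"), clinical.reset_index(drop=True))
    table = table.reindex([STATUS_MT, STATUS_WT])
    counts = table.to_numpy()

    chi2, p, _, expected = stats.chi2_contingency(counts)
    if counts.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(counts, alternative="two-sided")
        return ContingencyResult(name, table, "fisher_exact", float("nan"), float(p))
    return ContingencyResult(name, table, "chi_square", float(chi2), float(p))


def compare_continuous(values: pd.Series, statuses: pd.Series) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum comparison of a burden between MT and WT.

    Returns the U statistic (for the MT group) and the two-sided p-value.
    """
    statuses = _split_statuses(statuses)
    values = pd.Series(values)
    mt = values[np.asarray(statuses) == STATUS_MT].to_numpy(dtype=float)
    wt = values[np.asarray(statuses) == STATUS_WT].to_numpy(dtype=float)
    if len(mt) == 0 or len(wt) == 0:
        raise ValueError("both status groups must be non-empty")
    stat, p = stats.mannwhitneyu(mt, wt, alternative="two-sided")
    return float(stat), float(p)


def mutation_burden(mutations: pd.DataFrame, *, count_records: bool = False) -> pd.Series:
    """Somatic mutation number (SMN) per sample from a MAF-like table.

    By default counts distinct mutated genes per sample; ``count_records=True``
    counts mutation records instead.  Samples absent from the table simply
    do not appear (callers reindex with fill 0 against their cohort).
    """
    for col in ("sample_id", "gene_symbol"):
        if col not in mutations.columns:
            raise ValueError(f"mutation table must contain a {col!r} column")
    if count_records:
        smn = mutations.groupby("sample_id").size()
    else:
        smn = mutations.groupby("sample_id")["gene_symbol"].nunique()
    smn.name = "smn"
    return smn


def mutated_gene_screen(
    mutations: pd.DataFrame,
    statuses: pd.Series,
    *,
    min_mt_samples: int = 6,
    exclude_tp53_mutants: bool = False,
    tp53_gene: str = "TP53",
    alternative: str = "two-sided",
    bh_correct: bool = False,
) -> list[MutationScreenRow]:
    """Screen for genes mutated more often in one signature-status group.

    Genes mutated in at least ``min_mt_samples`` MT samples (default 6 —
    "more than five patients") are tested with Fisher's exact test on the
    2x2 mutated/not x MT/WT table; ``enriched_in`` flags the group with
    the higher mutation rate.  ``exclude_tp53_mutants`` removes samples
    carrying a TP53 mutation from both groups first, isolating the
    signature-mutant-without-TP53-mutation subgroup.  Raw p-values are
    reported to match screening practice; ``bh_correct=True`` replaces them
    with Benjamini-Hochberg adjusted values.
    """
    if min_mt_samples < 1:
        raise ValueError("min_mt_samples must be at least 1")
    statuses = _split_statuses(statuses)
    samples_with_mut = set(mutations["sample_id"])
    missing = samples_with_mut - set(statuses.index)
    if missing:
        raise ValueError(f"mutation table contains samples without a status: {sorted(missing)[:5]}")

    keep = statuses.index
    if exclude_tp53_mutants:
        tp53_mutants = set(mutations.loc[mutations["gene_symbol"] == tp53_gene, "sample_id"])
        keep = statuses.index[~statuses.index.isin(tp53_mutants)]
    statuses = statuses.loc[keep]
    muts = mutations[mutations["sample_id"].isin(keep)]

    mt_samples = set(statuses.index[np.asarray(statuses) == STATUS_MT])
    wt_samples = set(statuses.index[np.asarray(statuses) == STATUS_WT])
    n_mt, n_wt = len(mt_samples), len(wt_samples)

    rows: list[MutationScreenRow] = []
    pvals: list[float] = []
    for gene, sub in muts.groupby("gene_symbol"):
        carriers = set(sub["sample_id"])
        k_mt = len(carriers & mt_samples)
        if k_mt < min_mt_samples:
            continue
        k_wt = len(carriers & wt_samples)
        table = [[k_mt, n_mt - k_mt], [k_wt, n_wt - k_wt]]
        _, p = stats.fisher_exact(table, alternative=alternative)
        enriched = STATUS_MT if (k_mt / n_mt) >= (k_wt / n_wt) else STATUS_WT
        rows.append(MutationScreenRow(str(gene), k_mt, k_wt, n_mt, n_wt, float(p), enriched))
        pvals.append(float(p))

    if bh_correct and rows:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests(pvals, method="fdr_bh")[1]
        rows = [
            MutationScreenRow(r.gene, r.n_mut_in_mt, r.n_mut_in_wt, r.n_mt, r.n_wt, float(q), r.enriched_in)
            for r, q in zip(rows, adj)
        ]
    rows.sort(key=lambda r: (r.p_value, r.gene))
    return rows
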