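"""Association tests, burden comparisons and the mutated-gene screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tp53sig import (
    SyntheticConfig,
    association_table,
    compare_continuous,
    generate_tcga_like,
    mutated_gene_screen,
    mutation_burden,
)


def statuses_from_counts(n_mt, n_wt):
    s = pd.Series(["MT"] * n_mt + ["WT"] * n_wt, index=[f"S{i}" for i in range(n_mt + n_wt)])
    return s


def categorical_from_table(table):
    """Expand a status x category count table into per-sample series."""
    status, values = [], []
    for row_status, row in table.items():
        for cat, n in row.items():
            status += [row_status] * n
            values += [cat] * n
    return pd.Series(values), pd.Series(status)


def fisher_oracle(k_mt, n_mt, k_wt, n_wt):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    total_mut = k_mt + k_wt
    n = n_mt + n_wt
    pmf = [stats.hypergeom.pmf(k, n, total_mut, n_mt) for k in range(total_mut + 1)]
    p_obs = pmf[k_mt]
    return sum(p for p in pmf if p <= p_obs * (1 + 1e-7))


class TestAssociationTable:
    def test_er_imbalance_highly_significant(self):
        """ER-negativity concentrated in the MT group: 36/64 vs 14/110."""
        values, status = categorical_from_table(
            {"MT": {"pos": 28, "neg": 36}, "WT": {"pos": 96, "neg": 14}}
        )
        res = association_table(values, status, variable="ER")
        assert res.test_used == "chi_square"
        assert res.p_value < 0.001

    def test_identical_rows_are_null(self):
        values, status = categorical_from_table(
            {"MT": {"a": 20, "b": 20}, "WT": {"a": 20, "b": 20}}
        )
        res = association_table(values, status)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_proportional_rows_are_null(self):
        values, status = categorical_from_table(
            {"MT": {"a": 10, "b": 30}, "WT": {"a": 20, "b": 60}}
        )
        assert association_table(values, status).statistic == pytest.approx(0.0, abs=1e-12)

    def test_small_expected_cell_routes_to_fisher(self):
        values, status = categorical_from_table(
            {"MT": {"pos": 2, "neg": 18}, "WT": {"pos": 1, "neg": 19}}
        )
        res = association_table(values, status)
        assert res.test_used == "fisher_exact"

    def test_continuous_routes_to_kruskal(self, rng):
        status = statuses_from_counts(30, 30)
        age = pd.Series(rng.normal(58, 10, size=60), index=status.index)
        res = association_table(age, status, variable="age", continuous=True)
        assert res.test_used == "kruskal_wallis"
        stat, p = stats.kruskal(age[status == "MT"], age[status == "WT"])
        assert res.p_value == pytest.approx(p)

    def test_single_category_rejected(self):
        status = statuses_from_counts(5, 5)
        with pytest.raises(ValueError, match="single category"):
            association_table(pd.Series(["x"] * 10), status)

    def test_single_status_rejected(self):
        with pytest.raises(ValueError, match="MT and WT"):
            association_table(pd.Series(["a", "b"]), pd.Series(["MT", "MT"]))


class TestCompareContinuous:
    def test_identical_groups_are_null(self):
        status = statuses_from_counts(3, 3)
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=status.index)
        _, p = compare_continuous(values, status)
        assert p == pytest.approx(1.0)

    def test_complete_separation_significant(self):
        status = statuses_from_counts(20, 20)
        values = pd.Series(list(range(100, 120)) + list(range(20)), index=status.index, dtype=float)
        _, p = compare_continuous(values, status)
        assert p < 0.001

    def test_doubled_mutation_burden_detected(self, rng):
        status = statuses_from_counts(100, 100)
        smn = pd.Series(
            np.concatenate([rng.negative_binomial(10, 0.2, 100), rng.negative_binomial(5, 0.2, 100)]),
            index=status.index,
        )
        _, p = compare_continuous(smn, status)
        assert p < 0.01


class TestMutationBurden:
    def test_distinct_genes_vs_records(self):
        muts = pd.DataFrame(
            {"sample_id": ["A", "A", "A", "B"], "gene_symbol": ["G1", "G1", "G2", "G3"]}
        )
        assert mutation_burden(muts).to_dict() == {"A": 2, "B": 1}
        assert mutation_burden(muts, count_records=True).to_dict() == {"A": 3, "B": 1}


class TestMutatedGeneScreen:
    def build(self, mt_carriers, wt_carriers, n_mt=10, n_wt=10, gene="G1"):
        status = statuses_from_counts(n_mt, n_wt)
        mt_ids = status.index[:mt_carriers]
        wt_ids = status.index[n_mt : n_mt + wt_carriers]
        muts = pd.DataFrame(
            {"sample_id": list(mt_ids) + list(wt_ids), "gene_symbol": gene}
        )
        return muts, status

    def test_enriched_gene_detected(self):
        muts, status = self.build(6, 0)
        (row,) = mutated_gene_screen(muts, status)
        assert row.enriched_in == "MT"
        assert row.p_value == pytest.approx(0.0108, abs=2e-4)
        assert row.p_value == pytest.approx(fisher_oracle(6, 10, 0, 10), rel=1e-9)

    def test_threshold_drops_rare_genes(self):
        muts, status = self.build(5, 0)
        assert mutated_gene_screen(muts, status, min_mt_samples=6) == []
        assert len(mutated_gene_screen(muts, status, min_mt_samples=5)) == 1

    def test_equal_rates_not_significant(self):
        muts, status = self.build(6, 6)
        (row,) = mutated_gene_screen(muts, status)
        assert row.p_value == pytest.approx(1.0)

    def test_exclude_tp53_mutants_subgroup(self):
        muts, status = self.build(6, 2, gene="G1")
        tp53 = pd.DataFrame({"sample_id": [status.index[0], status.index[12]], "gene_symbol": "TP53"})
        muts = pd.concat([muts, tp53], ignore_index=True)
        rows = mutated_gene_screen(muts, status, min_mt_samples=5, exclude_tp53_mutants=True)
        (row,) = [r for r in rows if r.gene == "G1"]
        # one MT and one WT TP53 carrier removed from both the cohort and the counts
        assert (row.n_mt, row.n_wt) == (9, 9)
        assert row.n_mut_in_mt == 5 + 0  # the removed MT sample carried G1
        assert not any(r.gene == "TP53" for r in rows)

    def test_fisher_matches_hypergeometric_enumeration(self, rng):
        """Oracle equivalence on random 2x2 tables with margins up to 30."""
        for _ in range(100):
            n_mt, n_wt = int(rng.integers(6, 16)), int(rng.integers(2, 16))
            k_mt = int(rng.integers(1, n_mt + 1))
            k_wt = int(rng.integers(0, n_wt + 1))
            muts, status = self.build(k_mt, k_wt, n_mt=n_mt, n_wt=n_wt)
            rows = mutated_gene_screen(muts, status, min_mt_samples=1)
            assert rows[0].p_value == pytest.approx(fisher_oracle(k_mt, n_mt, k_wt, n_wt), rel=1e-9)

    def test_null_screen_false_positive_rate(self, rng, sig):
        """Equal mutation rates: ~5% of tested genes reach p < 0.05."""
        pvals = []
        for seed in range(12):
            cfg = SyntheticConfig(
                seed=seed, n_mutant=120, n_wildtype=120,
                mutation_rate_mt=0.1, mutation_rate_wt=0.1,
                tp53_mut_fraction_mt=0.0, tp53_mut_fraction_wt=0.0,
            )
            bundle = generate_tcga_like(cfg, sig)
            rows = mutated_gene_screen(bundle.mutations, bundle.true_status, min_mt_samples=6)
            pvals += [r.p_value for r in rows]
        assert len(pvals) > 500
        frac = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= frac <= 0.08

    def test_status_must_cover_all_samples(self):
        muts = pd.DataFrame({"sample_id": ["ZZ"], "gene_symbol": ["G1"]})
        with pytest.raises(ValueError, match="without a status"):
            mutated_gene_screen(muts, statuses_from_counts(2, 2))

    def test_invalid_threshold_rejected(self):
        muts, status = self.build(6, 0)
        with pytest.raises(ValueError, match="min_mt_samples"):
            mutated_gene_screen(muts, status, min_mt_samples=0)
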