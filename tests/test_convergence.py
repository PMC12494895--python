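"""Poisson-tail oracle, BH behaviour, exclusion and partition logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evorepair import convergence as cv
from evorepair.exceptions import ConfigError, DomainError, ValidationError
from evorepair.genome import GeneModel


def poisson_tail_by_summation(n: int, mu: float) -> float:
    """Independent oracle: direct pmf summation of P(X >= n)."""
    if n == 0:
        return 1.0
    # P(X >= n) = 1 - sum_{k<n} pmf; pmf built by stable recurrence
    log_pmf = -mu
    acc = np.exp(log_pmf)
    for k in range(1, n):
        log_pmf += np.log(mu) - np.log(k)
        acc += np.exp(log_pmf)
    return max(0.0, 1.0 - acc)


class TestPoissonTail:
    def test_zero_count_certain(self):
        assert cv.poisson_tail(0, 0.0) == 1.0
        assert cv.poisson_tail(0, 37.5) == 1.0

    @pytest.mark.parametrize(
        "n, mu, expected",
        [
            (1, 0.1, 1 - np.exp(-0.1)),
            (3, 0.5, 1 - np.exp(-0.5) * (1 + 0.5 + 0.125)),
        ],
    )
    def test_small_case_closed_forms(self, n, mu, expected):
        assert cv.poisson_tail(n, mu) == pytest.approx(expected, abs=1e-12)

    def test_matches_summation_oracle_over_grid(self):
        mus = [1e-6, 1e-3, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 25.0, 50.0]
        ns = [0, 1, 2, 3, 5, 10, 20, 50, 100]
        worst = max(
            abs(cv.poisson_tail(n, mu) - poisson_tail_by_summation(n, mu))
            for mu in mus
            for n in ns
        )
        assert worst <= 1e-10

    def test_gt_variant_differs_by_one_pmf_term(self):
        from scipy.stats import poisson

        for n, mu in [(1, 0.1), (3, 0.5), (7, 2.0), (0, 1.0)]:
            diff = cv.poisson_tail(n, mu, tail="ge") - cv.poisson_tail(n, mu, tail="gt")
            assert diff == pytest.approx(poisson.pmf(n, mu), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        n=st.integers(min_value=1, max_value=60),
        mu=st.floats(min_value=1e-6, max_value=50.0),
    )
    def test_monotonicity(self, n, mu):
        assert cv.poisson_tail(n + 1, mu) <= cv.poisson_tail(n, mu)
        assert cv.poisson_tail(n, mu * 1.5) >= cv.poisson_tail(n, mu)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            cv.poisson_tail(-1, 1.0)
        with pytest.raises(DomainError):
            cv.poisson_tail(1, -1.0)


def _gene(gene_id, length=1500, chrom="chr1", start=1001):
    seq = "ATG" * (length // 3)
    return GeneModel(gene_id, chrom, "+", start, start + length - 1, seq)


def _calls(hit_spec):
    """hit_spec: list of (population, gene_id) mutation events."""
    return pd.DataFrame(
        {
            "population": [p for p, _ in hit_spec],
            "gene_id": [g for _, g in hit_spec],
            "category": "nonsynonymous",
            "chrom": "chr1",
            "pos": np.arange(len(hit_spec)) + 1,
            "ref": "A",
            "alt": "T",
            "fraction": 1.0,
        }
    )


class TestFitNull:
    def test_lambda_is_total_over_coding_bp(self):
        genes = [_gene(f"g{i}") for i in range(4)]  # 4 x 2500 bp targets
        calls = _calls([("p1", "g0")] * 100)
        model = cv.fit_null(calls, genes)
        assert model.coding_bp == 10_000
        assert model.lambda_rate == pytest.approx(0.01)

    def test_empty_calls_give_zero_lambda(self):
        genes = [_gene("g0")]
        model = cv.fit_null(_calls([]), genes)
        assert model.lambda_rate == 0.0
        assert cv.poisson_tail(0, model.lambda_rate * 2500) == 1.0

    def test_no_genes_rejected(self):
        with pytest.raises(ValidationError):
            cv.fit_null(_calls([("p1", "g0")]), [])

    def test_lambda_recovers_generative_rate(self, null_genome, null_config):
        """On null synthetic tables, lambda-hat tracks the generative rate
        (downweighted by the synonymous fraction excluded from mutations)."""
        from evorepair.synthetic_data import gen_mutation_tables
        from evorepair.variant_annotation import classify_variants

        tab = gen_mutation_tables(null_genome, null_config)
        calls = classify_variants(tab, null_genome)
        model = cv.fit_null(calls, null_genome.genes)
        rate = null_config.per_base_rate * 3.5 * 48  # genotype multiplier x pops
        # excluded synonymous calls make lambda-hat < full generative rate
        assert 0.7 * rate < model.lambda_rate <= rate


class TestCallAdaptive:
    def test_no_hits_no_tests(self):
        genes = [_gene("g0"), _gene("g1")]
        out = cv.call_adaptive(_calls([]), genes)
        assert len(out) == 0

    def test_bh_matches_stepup_enumeration(self):
        """BH rejections equal the brute-force step-up rule on a known p-vector."""
        pvals = np.array([0.001, 0.01, 0.03, 0.2])
        alpha = 0.05
        m = len(pvals)
        order = np.argsort(pvals)
        passing = [i for i, idx in enumerate(order, start=1)
                   if pvals[idx] <= alpha * i / m]
        k = max(passing) if passing else 0
        expected_reject = np.zeros(m, dtype=bool)
        expected_reject[order[:k]] = True

        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        assert np.array_equal(reject, expected_reject)
        assert expected_reject.tolist() == [True, True, True, False]

    def test_q_at_least_p_and_adaptive_below_alpha(self):
        genes = [_gene(f"g{i}") for i in range(10)]
        spec = [("p1", "g0")] * 12 + [(f"p{i}", f"g{i % 10}") for i in range(5)]
        out = cv.call_adaptive(_calls(spec), genes, alpha=0.05)
        assert (out["q_value"] >= out["p_value"] - 1e-15).all()
        assert (out.loc[out["adaptive"], "q_value"] < 0.05).all()

    def test_excluded_gene_never_reported(self):
        genes = [_gene(f"g{i}") for i in range(5)]
        spec = [("p1", "g0")] * 50  # overwhelmingly significant
        out = cv.call_adaptive(_calls(spec), genes, exclude={"g0"})
        assert "g0" not in set(out["unit_id"])

    def test_dedup_counts_population_gene_pairs_once(self):
        genes = [_gene("g0"), _gene("g1")]
        spec = [("p1", "g0")] * 5 + [("p2", "g0")] * 2
        pooled = cv.call_adaptive(_calls(spec), genes)
        dedup = cv.call_adaptive(_calls(spec), genes, dedup_per_population=True)
        assert pooled.loc[pooled["unit_id"] == "g0", "n_hits"].iloc[0] == 7
        assert dedup.loc[dedup["unit_id"] == "g0", "n_hits"].iloc[0] == 2

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            cv.call_adaptive(_calls([]), [_gene("g0")], alpha=1.5)


class TestGoTermTest:
    def test_single_gene_term_reduces_to_gene_test(self):
        genes = [_gene(f"g{i}") for i in range(3)]
        spec = [("p1", "g0")] * 6 + [("p2", "g1")]
        gene_res = cv.call_adaptive(_calls(spec), genes)
        go_res = cv.go_term_test(_calls(spec), {"g0": ["T0"]}, genes)
        g = gene_res.set_index("unit_id").loc["g0"]
        t = go_res.set_index("unit_id").loc["T0"]
        assert t["n_hits"] == g["n_hits"]
        assert t["expected"] == pytest.approx(g["expected"])
        assert t["p_value"] == pytest.approx(g["p_value"])

    def test_disjoint_terms_partition_hits(self):
        genes = [_gene(f"g{i}") for i in range(4)]
        spec = [("p1", "g0")] * 3 + [("p1", "g1")] * 2 + [("p2", "g2")]
        mapping = {"g0": ["A"], "g1": ["A"], "g2": ["B"], "g3": ["B"]}
        out = cv.go_term_test(_calls(spec), mapping, genes)
        assert out["n_hits"].sum() == 6

    def test_module_detected_when_no_member_is(self):
        """Three genes each at a modest rate: the 3-gene term reaches
        significance while individual members do not."""
        genes = [_gene(f"g{i}") for i in range(50)]
        # background: one hit in many genes; module genes: 4 hits each
        spec = [(f"p{i}", f"g{i}") for i in range(10, 40)]
        for g in ("g0", "g1", "g2"):
            spec += [(f"p{j}", g) for j in range(4)]
        calls = _calls(spec)
        gene_res = cv.call_adaptive(calls, genes, alpha=0.05)
        module = cv.go_term_test(calls, {g: ["MOD"] for g in ("g0", "g1", "g2")},
                                 genes, alpha=0.05)
        members = gene_res[gene_res["unit_id"].isin(["g0", "g1", "g2"])]
        assert not members["adaptive"].any()
        assert module.set_index("unit_id").loc["MOD", "adaptive"]

    def test_unannotated_term_skipped_with_warning(self):
        genes = [_gene("g0")]
        with pytest.warns(UserWarning):
            out = cv.go_term_test(_calls([("p1", "g0")]), {"gX": ["T"]}, genes)
        assert len(out) == 0


class TestConditionPartition:
    def test_identical_sets_all_shared(self):
        part = cv.condition_partition({"a": {"x", "y"}, "b": {"x", "y"}})
        assert part.counts.to_dict() == {"a+b": 2}

    def test_disjoint_sets_all_unique(self):
        part = cv.condition_partition({"a": {"x"}, "b": {"y"}})
        assert part.counts.to_dict() == {"a": 1, "b": 1}

    def test_mixed_overlap(self):
        part = cv.condition_partition({"c1": {"A", "B"}, "c2": {"B", "C"}})
        assert part.counts.to_dict() == {"c1": 1, "c1+c2": 1, "c2": 1}
        assert part.membership.loc["B"].all()

    def test_single_set_rejected(self):
        with pytest.raises(ValidationError):
            cv.condition_partition({"a": {"x"}})
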