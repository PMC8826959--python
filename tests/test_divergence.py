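"""Folded Skellam pmf, P values, discrete FDR, consistency across pairs.

The independent oracle throughout is a brute-force convolution of two
Poisson laws: Pr[Δn = d] = Σ_m Pois(m + d; λ1)·Pois(m; λ2), folded onto
|Δn|, truncated far into the tail.
"""

import numpy as np
import pytest
from scipy import stats

from paradiv import (
    SkellamNull,
    TreatmentPair,
    ValidationError,
    consistent_enrichment,
    critical_p_value,
    divergence_p_value,
    divergence_test,
    expected_significant,
    skellam_abs_pmf,
)

LAMBDA_GRID = [0.0, 0.1, 1.0, 5.0, 20.0]


def oracle_folded_pmf(k, lam1, lam2, m_max=400):
    """Brute-force folded Poisson-difference pmf."""
    m = np.arange(m_max)
    diff = lambda d: float(np.sum(stats.poisson.pmf(m + d, lam1) * stats.poisson.pmf(m, lam2)))
    return diff(0) if k == 0 else diff(k) + diff(-k)


def pair(n1, n2, labels=("t1", "t2")):
    n1, n2 = np.asarray(n1), np.asarray(n2)
    return TreatmentPair(
        label_1=labels[0], label_2=labels[1],
        gene_ids=[f"g{i}" for i in range(len(n1))], n_1=n1, n_2=n2,
    )


class TestSkellamAbsPmf:
    def test_point_mass_at_zero_when_rates_vanish(self):
        null = SkellamNull(0.0, 0.0, 10)
        assert skellam_abs_pmf(0, null) == 1.0
        assert skellam_abs_pmf(3, null) == 0.0

    def test_equal_unit_rates_k0(self):
        # Σ_m Pois(m;1)² = e⁻² I₀(2)
        null = SkellamNull(1.0, 1.0, 10)
        assert skellam_abs_pmf(0, null) == pytest.approx(
            oracle_folded_pmf(0, 1.0, 1.0), abs=1e-10
        )

    @pytest.mark.parametrize("lam1", LAMBDA_GRID)
    @pytest.mark.parametrize("lam2", LAMBDA_GRID)
    def test_matches_convolution_oracle(self, lam1, lam2):
        null = SkellamNull(lam1, lam2, 100)
        ks = np.arange(0, 61)
        mine = np.array([skellam_abs_pmf(int(k), null) for k in ks])
        ref = np.array([oracle_folded_pmf(int(k), lam1, lam2) for k in ks])
        assert np.max(np.abs(mine - ref)) < 1e-9

    @pytest.mark.parametrize("lam1,lam2", [(0.1, 0.1), (1.0, 5.0), (20.0, 20.0)])
    def test_pmf_normalized(self, lam1, lam2):
        null = SkellamNull(lam1, lam2, 100)
        total = sum(skellam_abs_pmf(k, null) for k in range(400))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_symmetric_in_rates(self):
        a, b = SkellamNull(2.0, 7.0, 10), SkellamNull(7.0, 2.0, 10)
        for k in range(10):
            assert skellam_abs_pmf(k, a) == pytest.approx(skellam_abs_pmf(k, b), rel=1e-12)

    def test_matches_scipy_skellam_fold(self):
        """Independent route: scipy's Skellam law folded onto |Δn|."""
        null = SkellamNull(3.0, 1.5, 10)
        ks = np.arange(0, 30)
        mine = skellam_abs_pmf(ks, null)
        ref = stats.skellam.pmf(ks, 3.0, 1.5) + np.where(
            ks > 0, stats.skellam.pmf(-ks, 3.0, 1.5), 0.0
        )
        assert np.max(np.abs(mine - ref)) < 1e-12

    def test_negative_or_fractional_k_rejected(self):
        null = SkellamNull(1.0, 1.0, 10)
        with pytest.raises(ValidationError):
            skellam_abs_pmf(-1, null)
        with pytest.raises(ValidationError):
            skellam_abs_pmf(1.5, null)


class TestDivergencePValue:
    def test_k0_is_exactly_one(self):
        assert divergence_p_value(0, SkellamNull(4.2, 0.3, 10)) == 1.0

    def test_no_mass_above_zero_when_rates_vanish(self):
        assert divergence_p_value(1, SkellamNull(0.0, 0.0, 10)) == 0.0

    @pytest.mark.parametrize("lam1,lam2,k", [(3.0, 3.0, 5), (0.1, 1.0, 3), (20.0, 5.0, 40)])
    def test_matches_oracle_tail(self, lam1, lam2, k):
        null = SkellamNull(lam1, lam2, 100)
        ref = 1.0 - sum(oracle_folded_pmf(j, lam1, lam2) for j in range(k))
        assert divergence_p_value(k, null) == pytest.approx(ref, abs=1e-9)

    @pytest.mark.parametrize("lam1,lam2", [(0.5, 0.5), (2.0, 8.0)])
    def test_strictly_decreasing_in_k(self, lam1, lam2):
        null = SkellamNull(lam1, lam2, 100)
        p = divergence_p_value(np.arange(0, 40), null)
        assert np.all(np.diff(p) < 0)


class TestExpectedSignificant:
    def test_p_one_counts_every_gene(self):
        null = SkellamNull(1.0, 2.0, 500)
        assert expected_significant(1.0, null, n_min=0) == pytest.approx(500.0)

    def test_unachievably_small_p_gives_zero(self):
        null = SkellamNull(0.5, 0.5, 500)
        assert expected_significant(1e-200, null, n_min=1) == pytest.approx(0.0, abs=1e-9)

    def test_shortcut_equals_literal_summation(self):
        """The k*(P) threshold reduction vs literal Heaviside summation."""
        rng = np.random.default_rng(0)
        null_rngs = rng.uniform(0.05, 8.0, size=(40, 2))
        for lam1, lam2 in null_rngs:
            null = SkellamNull(float(lam1), float(lam2), 300)
            P = float(rng.uniform(1e-6, 1.0))
            for n_min in (1, 3):
                p_of_k = divergence_p_value(np.arange(0, 200), null)
                pmf = np.array([skellam_abs_pmf(k, null) for k in range(200)])
                literal = 300 * float(
                    np.sum((p_of_k[n_min:] <= P) * pmf[n_min:])
                )
                shortcut = expected_significant(P, null, n_min=n_min)
                assert shortcut == pytest.approx(literal, abs=1e-9)

    def test_monotone_in_p(self):
        null = SkellamNull(2.0, 2.0, 100)
        grid = [1e-6, 1e-4, 1e-2, 0.1, 0.5, 1.0]
        vals = [expected_significant(p, null, n_min=1) for p in grid]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestCriticalPValue:
    def test_no_tested_gene_returns_none(self):
        null = SkellamNull(1.0, 1.0, 100)
        p_star, sig, _ = critical_p_value(np.zeros(5, dtype=int), null, alpha=0.05)
        assert p_star is None and not sig.any()

    def test_extreme_single_gene_is_significant(self):
        null = SkellamNull(0.01, 0.01, 1000)
        k = np.zeros(1000, dtype=int)
        k[0] = 20
        p_star, sig, _ = critical_p_value(k, null, alpha=0.05)
        assert p_star is not None and sig[0]
        # direct check of the expected-count bound at that level
        assert expected_significant(p_star, null, n_min=1) <= 0.05 * sig.sum()

    def test_largest_qualifying_level_chosen(self):
        null = SkellamNull(0.1, 0.1, 200)
        k = np.array([8, 6, 1, 0, 0])
        p_star, sig, table = critical_p_value(k, null, alpha=0.05)
        qualifying = table[table.ratio <= 0.05].p_level
        assert p_star == pytest.approx(qualifying.max())


class TestDivergenceTest:
    def test_identical_counts_nothing_significant(self):
        tp = pair([3, 1, 0], [3, 1, 0])
        rep = divergence_test(tp, n_genes=100)
        assert rep.p_star is None and not rep.significant.any()
        assert set(rep.direction) == {"none"}

    def test_label_swap_flips_directions_only(self):
        tp = pair([9, 0, 2], [0, 4, 2])
        fwd = divergence_test(tp, n_genes=50)
        rev = divergence_test(pair([0, 4, 2], [9, 0, 2], labels=("t2", "t1")), n_genes=50)
        assert np.allclose(fwd.p_values, rev.p_values)
        assert np.array_equal(fwd.significant, rev.significant)
        for d1, d2 in zip(fwd.direction, rev.direction):
            assert d1 == d2  # same physical treatment wins either way

    def test_both_treatments_empty_rejected(self):
        with pytest.raises(ValidationError, match="no mutations"):
            divergence_test(pair([0, 0], [0, 0]))

    def test_null_rates_from_totals(self):
        tp = pair([5, 5], [2, 0])
        rep = divergence_test(tp, n_genes=100)
        assert rep.null.lambda_1 == pytest.approx(0.1)
        assert rep.null.lambda_2 == pytest.approx(0.02)


class TestConsistentEnrichment:
    def _report(self, labels, gene_ids, sig, direction):
        import pandas as pd

        from paradiv.divergence import DivergenceReport, SkellamNull

        n = len(gene_ids)
        return DivergenceReport(
            label_1=labels[0], label_2=labels[1], gene_ids=gene_ids,
            n_1=np.zeros(n, dtype=int), n_2=np.zeros(n, dtype=int),
            abs_delta=np.zeros(n, dtype=int),
            direction=np.array(direction), p_values=np.ones(n),
            significant=np.array(sig), p_star=None, alpha=0.05, n_min=1,
            n_genes_null=n, null=SkellamNull(1.0, 1.0, n), n_tested=n,
            expected_table=pd.DataFrame(),
        )

    def test_two_treatments_single_pair(self):
        r = self._report(("A", "B"), ["g0", "g1"], [True, False], ["A", "none"])
        assigned = consistent_enrichment({("A", "B"): r})
        assert assigned == {"A": ["g0"], "B": []}

    def test_partial_support_not_assigned(self):
        # g0 points to A in 2 of 3 pairs involving A → not assigned
        rAB = self._report(("A", "B"), ["g0"], [True], ["A"])
        rAC = self._report(("A", "C"), ["g0"], [True], ["A"])
        rAD = self._report(("A", "D"), ["g0"], [False], ["none"])
        others = {
            (a, b): self._report((a, b), ["g0"], [False], ["none"])
            for a, b in [("B", "C"), ("B", "D"), ("C", "D")]
        }
        assigned = consistent_enrichment(
            {("A", "B"): rAB, ("A", "C"): rAC, ("A", "D"): rAD, **others}
        )
        assert assigned["A"] == []

    def test_missing_pair_listed(self):
        rAB = self._report(("A", "B"), ["g0"], [True], ["A"])
        rAC = self._report(("A", "C"), ["g0"], [True], ["A"])
        with pytest.raises(ValidationError, match="missing"):
            consistent_enrichment({("A", "B"): rAB, ("A", "C"): rAC})
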