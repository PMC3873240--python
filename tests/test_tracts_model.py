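import numpy as np
import pytest
from scipy.stats import poisson

from admixdemo.containers import InvalidHistoryError, MigrationHistory
from admixdemo import synthsim as ss
from admixdemo import tracts_model as tm


class TestDiscretizePulse:
    def test_non_integer_founding_splits_to_neighbours(self):
        rows = tm.discretize_pulse(13.02, np.array([1.0, 0.0, 0.0]))
        assert set(rows) == {13, 14}
        np.testing.assert_allclose(rows[14], [1.0, 0.0, 0.0])
        # near-complete replacement one generation later
        assert rows[13][0] == pytest.approx(0.98)

    def test_integer_time_single_row(self):
        rows = tm.discretize_pulse(13.0, np.array([0.3, 0.5, 0.2]))
        assert set(rows) == {13}

    def test_halfway_weight(self):
        rows = tm.discretize_pulse(13.5, np.array([1.0, 0.0, 0.0]))
        assert rows[13][0] == pytest.approx(0.5)

    def test_ancestry_proportions_preserved(self):
        frac = np.array([0.6, 0.3, 0.1])
        m = np.zeros((15, 3))
        for g, row in tm.discretize_pulse(13.4, frac).items():
            m[g] += row
        hist = MigrationHistory(m)
        np.testing.assert_allclose(hist.ancestry_proportions(), frac)

    def test_partial_pulse_mass_preserved(self):
        rows = tm.discretize_pulse(4.8, np.array([1.0, 0.0, 0.0]), magnitude=0.05)
        assert sum(r[0] for r in rows.values()) == pytest.approx(0.05)

    def test_rejects_too_recent(self):
        with pytest.raises(InvalidHistoryError):
            tm.discretize_pulse(0.9, np.array([1.0, 0.0, 0.0]))


class TestExpectedTractCounts:
    def test_pure_ancestry_gives_whole_chromosomes(self, small_genome):
        m = np.zeros((3, 3))
        m[2] = [1.0, 0.0, 0.0]
        mig = MigrationHistory(m)
        bins = tm.default_bins(small_genome, 12)
        exp = tm.expected_tract_counts(mig, bins, small_genome, n_haplotypes=10)
        assert exp.counts["NAT"].sum() == pytest.approx(30.0, rel=1e-6)
        assert exp.counts["EUR"].sum() == 0.0

    def test_minor_ancestry_rate_matches_closed_form(self, genome):
        # single pulse, small minority fraction p: minority tract lengths are
        # approximately Exp((t-1)(1-p)) per Morgan
        t, p = 11, 0.05
        m = np.zeros((t + 1, 3))
        m[t] = [p, 1 - p, 0.0]
        mig = MigrationHistory(m)
        bins = np.linspace(1.0, 41.0, 21)  # cM, away from chromosome ends
        exp = tm.expected_tract_counts(mig, bins, genome, n_haplotypes=1)
        counts = exp.counts["NAT"]
        mids = 0.5 * (bins[:-1] + bins[1:]) / 100.0
        # remove the finite-chromosome (L - x) start-position factor before
        # reading off the exponential rate
        span = np.array([
            np.maximum(np.array(genome.lengths_cm) / 100.0 - x, 0.0).sum()
            for x in mids
        ])
        slope = np.polyfit(mids, np.log(counts / span), 1)[0]
        assert slope == pytest.approx(-(t - 1) * (1 - p), rel=0.05)

    def test_total_length_conservation(self, genome, three_way_history):
        # sum of expected count x mean bin length recovers ancestry content
        bins = np.geomspace(1e-3, genome.lengths_cm[0] * (1 + 1e-9), 400)
        exp = tm.expected_tract_counts(three_way_history, bins, genome, 10)
        expect_cm = tm.expected_ancestry_cm(three_way_history, genome)
        mids = np.sqrt(bins[:-1] * bins[1:])
        for anc, per_hap in expect_cm.items():
            got = float(exp.counts[anc] @ mids) / 10.0
            assert got == pytest.approx(per_hap, rel=0.01)

    def test_stationarity_of_entry_distribution(self, three_way_history):
        states, pi, Q = tm._state_chain(three_way_history)
        np.testing.assert_allclose(pi @ Q, np.zeros(len(states)), atol=1e-12)


@pytest.mark.parametrize("history_fixture", ["two_way_pulse", "three_way_history"])
def test_expected_counts_match_simulation(history_fixture, genome, request):
    """Analytic per-bin expectations agree with forward painting within
    Poisson error on at least 95% of informative bins."""
    mig = request.getfixturevalue(history_fixture)
    bins = tm.default_bins(genome, 20)
    n_dip = 30
    tracts = ss.simulate_admixed_tracts(mig, genome, n_dip, seed=11)
    obs = tm.tract_histogram(tracts, bins)
    exp = tm.expected_tract_counts(mig, bins, genome, 2 * n_dip)
    z_all = []
    for anc in obs.counts:
        e, o = exp.counts[anc], obs.counts[anc]
        sel = e > 2
        z_all.extend(((o[sel] - e[sel]) / np.sqrt(e[sel])).tolist())
    z_all = np.abs(z_all)
    assert np.mean(z_all <= 3.0) >= 0.95


class TestTractHistogram:
    def test_empty_set_all_zero(self, small_genome):
        import pandas as pd
        from admixdemo.containers import AncestryTractSet

        empty = AncestryTractSet(
            pd.DataFrame(columns=list(AncestryTractSet.REQUIRED)), small_genome
        )
        h = tm.tract_histogram(empty, tm.default_bins(small_genome))
        assert h.total() == 0.0

    def test_single_tract_in_right_bin(self, small_genome):
        import pandas as pd
        from admixdemo.containers import AncestryTractSet

        df = pd.DataFrame(
            {"individual": ["i0"], "hap": [0], "chrom": ["chrA"],
             "start_cm": [0.0], "end_cm": [30.0], "ancestry": ["NAT"]}
        )
        bins = tm.default_bins(small_genome)
        h = tm.tract_histogram(AncestryTractSet(df, small_genome), bins)
        assert h.counts["NAT"].sum() == 1
        b = np.searchsorted(bins, 30.0, side="right") - 1
        assert h.counts["NAT"][b] == 1

    def test_tract_longer_than_chromosome_rejected(self, small_genome):
        import pandas as pd
        from admixdemo.containers import AncestryTractSet

        df = pd.DataFrame(
            {"individual": ["i0"], "hap": [0], "chrom": ["chrC"],
             "start_cm": [0.0], "end_cm": [500.0], "ancestry": ["NAT"]}
        )
        with pytest.raises(ValueError):
            tm.tract_histogram(AncestryTractSet(df, small_genome),
                               tm.default_bins(small_genome))


class TestPoissonLoglik:
    def _hist(self, small_genome, counts):
        bins = np.array([1.0, 10.0, 100.0])
        return tm.TractHistogram(
            bin_edges_cm=bins,
            counts={"NAT": np.array(counts, float),
                    "EUR": np.zeros(2), "AFR": np.zeros(2)},
            n_haplotypes=2,
            genome=small_genome,
        )

    def test_matches_direct_pmf_product(self, small_genome):
        obs = self._hist(small_genome, [3, 7])
        exp = self._hist(small_genome, [2.5, 8.1])
        direct = poisson.logpmf(3, 2.5) + poisson.logpmf(7, 8.1)
        assert tm.poisson_loglik(obs, exp) == pytest.approx(direct)

    def test_observed_equals_expected_is_maximum(self, small_genome):
        obs = self._hist(small_genome, [4, 9])
        best = tm.poisson_loglik(obs, self._hist(small_genome, [4, 9]))
        for other in ([3, 9], [4, 10], [5, 8]):
            assert tm.poisson_loglik(obs, self._hist(small_genome, other)) < best

    def test_zero_expected_with_observation_is_impossible(self, small_genome):
        obs = self._hist(small_genome, [1, 0])
        exp = self._hist(small_genome, [0, 5])
        assert tm.poisson_loglik(obs, exp) == -np.inf

    def test_all_zero_is_zero(self, small_genome):
        obs = self._hist(small_genome, [0, 0])
        exp = self._hist(small_genome, [0, 0])
        assert tm.poisson_loglik(obs, exp) == 0.0


class TestFitting:
    def test_noise_free_self_consistency(self, genome):
        """Fitting the model's own expectation recovers the parameters."""
        family = tm.FAMILIES["three_pulses_simultaneous"]
        true = np.array([10.0, 0.45, 0.10])
        bins = tm.default_bins(genome)
        exp = tm.expected_tract_counts(family.history(true), bins, genome, 120)
        fit = tm.fit_tracts_model(exp, family, n_starts=6, seed=1)
        np.testing.assert_allclose(fit.params, true, rtol=0.05, atol=0.02)

    def test_trace_non_decreasing(self, genome, two_way_pulse):
        tracts = ss.simulate_admixed_tracts(two_way_pulse, genome, 10, seed=3)
        obs = tm.tract_histogram(tracts, tm.default_bins(genome))
        fit = tm.fit_tracts_model(obs, "three_pulses_simultaneous",
                                  n_starts=4, seed=5)
        assert np.all(np.diff(fit.trace) >= -1e-9)

    def test_select_model_prefers_fewer_params_at_equal_loglik(self):
        a = tm.TractsFit("simple", np.zeros(3), ("a", "b", "c"), -100.0, 3, 500)
        b = tm.TractsFit("complex", np.zeros(5), tuple("abcde"), -100.0, 5, 500)
        assert tm.select_model([a, b]).family == "simple"

    def test_select_model_requires_same_data(self):
        a = tm.TractsFit("x", np.zeros(3), ("a", "b", "c"), -100.0, 3, 500)
        b = tm.TractsFit("y", np.zeros(3), ("a", "b", "c"), -90.0, 3, 600)
        with pytest.raises(ValueError):
            tm.select_model([a, b])

    def test_bootstrap_rejects_degenerate(self, genome, two_way_pulse):
        tracts = ss.simulate_admixed_tracts(two_way_pulse, genome, 4, seed=3)
        with pytest.raises(ValueError):
            tm.bootstrap_tracts_ci(tracts, "three_pulses_simultaneous", n_boot=1)

    def test_bootstrap_ci_contains_point_estimate(self, small_genome,
                                                  two_way_pulse):
        tracts = ss.simulate_admixed_tracts(two_way_pulse, small_genome, 12,
                                            seed=7)
        bins = tm.default_bins(small_genome, 15)
        fit = tm.bootstrap_tracts_ci(
            tracts, "three_pulses_simultaneous", n_boot=4, seed=2, bins=bins,
            n_starts=2,
        )
        for name, (lo, hi) in fit.ci.items():
            val = fit.params[fit.param_names.index(name)]
            assert lo - 1e-9 <= val <= hi + 1e-9
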