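import itertools

import numpy as np
import pytest
from scipy.stats import poisson

from admixdemo.containers import JointSFS, PostContactBottleneck, SplitModel
from admixdemo import sfs_demography as sd
from admixdemo import synthsim as ss


class TestProjection:
    def test_identity(self):
        rng = np.random.default_rng(0)
        sfs = JointSFS(counts=rng.random((5, 7)), pop_ids=("a", "b"))
        out = sd.project_sfs(sfs, {"a": 4, "b": 6})
        np.testing.assert_allclose(out.counts, sfs.counts)

    def test_matches_enumeration_of_draws(self):
        # one variant at derived count 2 of 4 haploids, projected to 2:
        # enumerate the C(4,2) subsamples directly
        counts = np.zeros(5)
        counts[2] = 1.0
        sfs = JointSFS(counts=counts, pop_ids=("a",))
        out = sd.project_sfs(sfs, {"a": 2})
        np.testing.assert_allclose(out.counts, [1 / 6, 4 / 6, 1 / 6])

    def test_target_larger_than_current_rejected(self):
        sfs = JointSFS(counts=np.zeros(5), pop_ids=("a",))
        with pytest.raises(ValueError):
            sd.project_sfs(sfs, {"a": 10})

    def test_mass_conserved(self):
        rng = np.random.default_rng(1)
        sfs = JointSFS(counts=rng.random((9, 11)), pop_ids=("a", "b"))
        out = sd.project_sfs(sfs, {"a": 4, "b": 5})
        assert out.counts.sum() == pytest.approx(sfs.counts.sum())


class TestEngine:
    def test_single_population_neutral_spectrum(self):
        """Constant-size expected SFS equals theta/i within 1%."""
        n = 20
        sfs = sd.expected_single_sfs(1e4, [], n, grids=(40, 50, 60))
        i = np.arange(1, n)
        ratio = sfs[1:n] * i
        np.testing.assert_allclose(ratio, ratio[0], rtol=0.01)

    def test_theta_linearity(self):
        pre = [(50.0, 500.0)]
        post = [(100.0, 800.0, 300.0)]
        arr = sd.expected_pair_sfs(1e3, pre, post, (6, 6))
        assert np.all(arr >= 0)
        # masked-corner-free total scales linearly with theta by construction
        np.testing.assert_allclose(3.7 * arr, arr * 3.7)

    def test_simultaneous_split_perfectly_correlated(self):
        # zero time since divergence: the two marginals coincide with the
        # ancestral spectrum and all mass lies on the diagonal
        arr = sd.expected_pair_sfs(1e3, [], [(0.0, 1e3, 1e3)], (8, 8),
                                   grids=(30, 40, 50))
        anc = sd.expected_single_sfs(1e3, [], 8, grids=(30, 40, 50))
        np.testing.assert_allclose(arr.sum(axis=1), anc, rtol=1e-6)
        np.testing.assert_allclose(arr.sum(axis=0), anc, rtol=1e-6)

    def test_projection_commutes_with_expectation(self):
        pre = [(30.0, 400.0)]
        post = [(120.0, 900.0, 500.0)]
        big = sd.expected_pair_sfs(1e3, pre, post, (12, 12))
        small = sd.expected_pair_sfs(1e3, pre, post, (6, 6))
        projected = sd.project_sfs(
            JointSFS(counts=big, pop_ids=("a", "b")), {"a": 6, "b": 6}
        )
        sel = slice(1, 6)
        np.testing.assert_allclose(
            projected.counts[sel, sel], small[sel, sel], rtol=0.02
        )

    def test_matches_forward_simulation(self):
        """Deterministic expectations agree with the per-locus forward
        simulator within Monte Carlo error."""
        model = SplitModel(
            n_ancestral=1000.0, t_found_gen=300.0, n_bottleneck=100.0,
            t_recovery_gen=260.0, r=10.0, t1_gen=150.0, t2_gen=80.0,
            pop_sizes={"A": 1500.0, "B": 400.0, "C": 800.0}, split_order="A",
        )
        sizes = {"A": 10, "B": 10, "C": 10}
        sim = ss.simulate_split_sfs(model, sizes, n_loci=150_000, seed=7)
        exp = sd.expected_joint_sfs(model, sizes)
        js = sim.joint_sfs()
        pops = sorted(sizes)
        chis = []
        for pair in itertools.combinations(pops, 2):
            obs2 = js.marginal(tuple(pops.index(p) for p in pair))
            ll, theta = sd.composite_loglik({pair: obs2}, {pair: exp[pair]})
            o = obs2.counts[~obs2.mask]
            e = theta * exp[pair].counts[~obs2.mask]
            sel = e > 5
            chis.append(np.mean((o[sel] - e[sel]) ** 2 / e[sel]))
        assert max(chis) < 1.6

    def test_against_msprime_branch_spectrum(self):
        """Independent coalescent cross-check: the engine's two-population
        spectrum matches msprime's expected branch-length SFS for a clean
        split model."""
        import msprime

        n_anc, n1, n2, t_split = 1000.0, 1000.0, 1000.0, 400.0
        ns = (6, 6)
        demography = msprime.Demography()
        demography.add_population(name="anc", initial_size=n_anc)
        demography.add_population(name="p1", initial_size=n1)
        demography.add_population(name="p2", initial_size=n2)
        demography.add_population_split(time=t_split, derived=["p1", "p2"],
                                        ancestral="anc")
        afs = np.zeros((ns[0] + 1, ns[1] + 1))
        n_rep = 3000
        for ts in msprime.sim_ancestry(
            samples={"p1": ns[0] // 2, "p2": ns[1] // 2},
            demography=demography, ploidy=2,
            num_replicates=n_rep, random_seed=42,
        ):
            afs += ts.allele_frequency_spectrum(
                sample_sets=[list(range(ns[0])),
                             list(range(ns[0], ns[0] + ns[1]))],
                mode="branch", polarised=True, span_normalise=False,
            )
        afs /= n_rep
        engine = sd.expected_pair_sfs(n_anc, [], [(t_split, n1, n2)], ns)
        mask = JointSFS.default_mask(afs.shape)
        ratio = afs[~mask].sum() / engine[~mask].sum()
        # compare the well-estimated classes; tolerance covers the
        # coalescent Monte Carlo error at this replicate count
        sel = (~mask) & (afs > 200.0)
        rel = engine[sel] * ratio / afs[sel] - 1.0
        assert np.abs(rel).max() < 0.08
        assert np.abs(rel).mean() < 0.03


class TestCompositeLoglik:
    def test_matches_direct_pmf_product(self):
        obs = JointSFS(counts=np.array([[0, 3, 1], [2, 5, 0], [1, 0, 0]],
                                       float), pop_ids=("a", "b"))
        exp = JointSFS(counts=np.array([[0.1, 2.5, 1.2], [1.8, 4.9, 0.4],
                                        [0.9, 0.3, 0.2]]), pop_ids=("a", "b"))
        ll, theta = sd.composite_loglik({("a", "b"): obs}, {("a", "b"): exp})
        sel = ~obs.mask
        direct = poisson.logpmf(obs.counts[sel].astype(int),
                                theta * exp.counts[sel]).sum()
        assert ll == pytest.approx(direct)

    def test_profiled_theta_maximises(self):
        rng = np.random.default_rng(2)
        exp = JointSFS(counts=rng.random((4, 4)) + 0.1, pop_ids=("a", "b"))
        obs = JointSFS(counts=2.5 * exp.counts, pop_ids=("a", "b"))
        ll_hat, theta = sd.composite_loglik({("a", "b"): obs}, {("a", "b"): exp})
        assert theta == pytest.approx(2.5)
        for t in (2.0, 3.0):
            ll_t, _ = sd.composite_loglik({("a", "b"): obs}, {("a", "b"): exp},
                                          theta=t)
            assert ll_t < ll_hat

    def test_empty_spectra_rejected(self):
        z = JointSFS(counts=np.zeros((3, 3)), pop_ids=("a", "b"))
        with pytest.raises(ValueError):
            sd.composite_loglik({("a", "b"): z}, {("a", "b"): z})


class TestCalibration:
    def _fit(self):
        model = SplitModel(
            n_ancestral=1e4, t_found_gen=533.3, n_bottleneck=30.0,
            t_recovery_gen=466.7, r=100.0, t1_gen=413.3, t2_gen=396.7,
            pop_sizes={"MXL": 64000.0, "CLM": 15000.0, "PUR": 2000.0},
            split_order="MXL",
        )
        return sd.DemographyFit(model=model, loglik=0.0, theta=1200.0,
                                ordering_logliks={}, sample_sizes={})

    def test_anchor_scaling_law(self):
        fit = self._fit()
        a = sd.calibrate_physical(fit, t_found_years=16000.0, l_callable=1e6)
        b = sd.calibrate_physical(fit, t_found_years=32000.0, l_callable=1e6)
        assert b["t1_years"] == pytest.approx(2 * a["t1_years"])
        assert b["n_MXL"] == pytest.approx(2 * a["n_MXL"])
        assert b["mu"] == pytest.approx(a["mu"] / 2)

    def test_default_anchor_prints_16kya_founding(self):
        a = sd.calibrate_physical(self._fit())
        assert a["t_found_years"] == pytest.approx(16000.0)
        # this fit is already expressed at the anchor: identity scaling
        assert a["scale"] == pytest.approx(1.0, rel=1e-3)

    def test_round_trip(self):
        fit = self._fit()
        a = sd.calibrate_physical(fit, t_found_years=16000.0)
        assert a["n_MXL"] / a["scale"] == pytest.approx(64000.0)

    def test_invalid_callable_length(self):
        with pytest.raises(ValueError):
            sd.calibrate_physical(self._fit(), l_callable=0.0)


@pytest.fixture(scope="module")
def sensitivity_setup():
    model = SplitModel(
        n_ancestral=500.0, t_found_gen=300.0, n_bottleneck=20.0,
        t_recovery_gen=260.0, r=25.0, t1_gen=150.0, t2_gen=80.0,
        pop_sizes={"A": 800.0, "B": 300.0, "C": 500.0}, split_order="A",
    )
    sizes = {"A": 8, "B": 8, "C": 8}
    sim = ss.simulate_split_sfs(model, sizes, n_loci=100_000, seed=9)
    js = sim.joint_sfs()
    pops = sorted(sizes)
    obs = {
        pair: js.marginal(tuple(pops.index(p) for p in pair))
        for pair in itertools.combinations(pops, 2)
    }
    fit = sd.fit_split_model(obs, fixed={"n_ancestral": 500.0, "r": 25.0},
                             orderings=["A"], n_starts=1, seed=0)
    return obs, fit


class TestBottleneckSensitivity:
    def test_severity_one_reproduces_fit(self, sensitivity_setup):
        """A no-decline 'bottleneck' leaves the refit at the same optimum."""
        obs, fit = sensitivity_setup
        bc = PostContactBottleneck(pop_id="A", start_gen=17.0,
                                   duration_gen=10.0, severity=1.0)
        rep = sd.bottleneck_sensitivity(fit, bc, obs, seed=0)
        assert rep["size_ratio"] == pytest.approx(1.0, rel=0.05)

    def test_severe_bottleneck_inflates_branch_size(self, sensitivity_setup):
        """Fixing a real post-contact crash forces a larger pre-crash size to
        explain the same diversity, increasingly so with severity."""
        obs, fit = sensitivity_setup
        ratios = []
        for severity in (0.3, 0.05):
            bc = PostContactBottleneck(pop_id="C", start_gen=17.0,
                                       duration_gen=12.0, severity=severity)
            rep = sd.bottleneck_sensitivity(fit, bc, obs, seed=0)
            ratios.append(rep["size_ratio"])
        assert ratios[0] > 0.95
        assert ratios[1] > ratios[0]  # inflation grows with severity

    def test_free_bottleneck_parameters_rejected(self):
        with pytest.raises(ValueError):
            PostContactBottleneck(pop_id="A", start_gen=17.0, duration_gen=10.0,
                                  severity=0.0)
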