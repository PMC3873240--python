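"""Parameter-recovery studies at the study conditions.

Each function simulates data under the documented study configuration
(:mod:`admixdemo.presets`), re-runs the corresponding inference, and returns
the recovered quantities.  They are shared by the test suite and the
acceptance script.
"""

from __future__ import annotations

import numpy as np

from . import ascertain, ibd_stats, presets, sfs_demography as sd, synthsim as ss
from . import tracts_model as tm
from .containers import GenomeMap

__all__ = [
    "tract_onset_recovery",
    "ibd_ne_recovery",
    "ascertainment_equivalence",
    "demography_recovery",
    "em_validation",
]

_TRACT_PRESETS = {
    "MXL": (presets.MXL_TRACTS_FAMILY, presets.MXL_TRACTS_PARAMS),
    "CLM": (presets.CLM_TRACTS_FAMILY, presets.CLM_TRACTS_PARAMS),
    "PUR": (presets.PUR_TRACTS_FAMILY, presets.PUR_TRACTS_PARAMS),
}


def tract_onset_recovery(
    population: str,
    n_seeds: int = 20,
    seed: int = 0,
    n_starts: int = 10,
    n_diploid: int | None = None,
) -> dict:
    """Simulate tracts under a population's best-fit history and refit.

    Returns per-seed fitted parameter vectors along with the onset (and,
    for the CLM family, second-pulse) summaries.
    """
    family_name, true_params = _TRACT_PRESETS[population]
    family = tm.FAMILIES[family_name]
    genome = presets.default_genome()
    n_dip = n_diploid or presets.N_DIPLOID[population]
    bins = tm.default_bins(genome)
    fits = []
    for k in range(n_seeds):
        mig = family.history(true_params)
        tracts = ss.simulate_admixed_tracts(mig, genome, n_dip, seed=seed + 1000 * k)
        obs = tm.tract_histogram(tracts, bins)
        fit = tm.fit_tracts_model(obs, family, n_starts=n_starts,
                                  seed=seed + 1000 * k + 1)
        fits.append(fit.params)
    fits = np.array(fits)
    out = {
        "family": family_name,
        "true_params": np.asarray(true_params),
        "fits": fits,
        "mean_onset": float(fits[:, 0].mean()),
    }
    if "t_nat2" in family.param_names:
        out["mean_t_nat2"] = float(
            fits[:, family.param_names.index("t_nat2")].mean()
        )
    return out


def ibd_ne_recovery(
    ne: float = presets.IBD_NE["PUR"],
    n_diploid: int = presets.IBD_N_DIPLOID_PUR,
    min_len_cm: float = presets.IBD_MIN_LEN_CM,
    n_seeds: int = 10,
    seed: int = 0,
) -> dict:
    """Simulate IBD sharing at a known size and invert the count estimator."""
    genome = presets.default_genome()
    n_pairs = 2 * n_diploid * (n_diploid - 1)  # 4 haplotype pairs per duo
    estimates = []
    for k in range(n_seeds):
        seg = ss.simulate_ibd_sharing(ne, n_diploid, genome, min_len_cm,
                                      seed=seed + 97 * k)
        estimates.append(
            ibd_stats.ibd_ne_from_counts(seg, min_len_cm, n_pairs, genome)
        )
    estimates = np.array(estimates)
    return {"true_ne": ne, "estimates": estimates,
            "mean_ne": float(estimates.mean())}


def ascertainment_equivalence(
    n_seeds: int = 4,
    seed: int = 0,
    n_loci: int = presets.ASCERT_N_LOCI,
) -> dict:
    """The negative-ascertainment bottleneck-equivalence study."""
    truth = presets.ascertainment_truth_model()
    reports = []
    for k in range(n_seeds):
        reports.append(
            ascertain.bottleneck_equivalence_report(
                truth,
                in_sample_haploids=presets.ASCERT_SAMPLE_HAPLOIDS,
                outgroup_diploids=presets.ASCERT_OUTGROUP_DIPLOIDS,
                n_loci=n_loci,
                seed=seed + 31 * k,
            )
        )
    t_bot = np.array([r["t_bottleneck_gen"] for r in reports])
    return {
        "reports": reports,
        "t_outgroup_gen": truth.t1_gen,
        "mean_t_bottleneck_gen": float(t_bot.mean()),
        "mean_t_bottleneck_kya": float(t_bot.mean() * 30.0 / 1000.0),
    }


def demography_recovery(
    seed: int = 0,
    n_loci: int = 8_000_000,
    n_starts: int = 2,
    n_boot: int = 0,
    grids: tuple[int, int, int] | None = None,
    polish: str = "full",
) -> dict:
    """Simulate ascertained-style spectra under the split model, project to
    the study sample sizes, refit by pairwise composite likelihood over all
    orderings, and calibrate to the 16,000-year founding anchor."""
    model = presets.split_model()
    sim = ss.simulate_split_sfs(model, presets.SPLIT_SIM_SIZES, n_loci=n_loci,
                                seed=seed)
    proj = sd.project_sfs(sim.joint_sfs(), presets.SPLIT_PROJECTED_SIZES)
    pops = sorted(presets.SPLIT_POP_SIZES)
    obs = {}
    for i, pa in enumerate(pops):
        for pb in pops[i + 1:]:
            obs[(pa, pb)] = proj.marginal((pops.index(pa), pops.index(pb)))
    # the flat branch-size valley amplifies small grid residuals, so the
    # winning ordering is polished on successively finer grids
    stages = {
        "full": [((100, 130, 160), 500), ((150, 200, 250), 150)],
        "light": [((100, 130, 160), 400)],
    }[polish]
    fit = sd.fit_split_model(
        obs,
        fixed={"n_ancestral": presets.SPLIT_N_ANCESTRAL, "r": 100.0},
        n_starts=n_starts,
        seed=seed + 1,
        grids=grids,
        polish_grids=stages,
        maxfev=900,
    )
    out = {"fit": fit, "true_sizes": dict(presets.SPLIT_POP_SIZES)}
    if n_boot >= 2:
        # project the per-locus counts for block resampling
        proj_counts = {}
        rng = np.random.default_rng(seed + 2)
        for pop, n_target in presets.SPLIT_PROJECTED_SIZES.items():
            c = sim.sample_counts[pop]
            n_c = presets.SPLIT_SIM_SIZES[pop]
            proj_counts[pop] = rng.hypergeometric(
                c, n_c - c, n_target
            )
        fit = sd.bootstrap_demography(
            proj_counts,
            presets.SPLIT_PROJECTED_SIZES,
            fit,
            n_boot=n_boot,
            seed=seed + 3,
            grids=grids,
            orderings=[fit.model.split_order],
            maxfev=900,
        )
        keys = sorted(fit.params_dict())
        t_found_b = fit.boot_params[:, keys.index("t_found_gen")]
        scale_b = presets.SPLIT_T_FOUND_GEN / t_found_b
        out["boot_n_MXL_cal"] = (
            fit.boot_params[:, keys.index("n_MXL")] * scale_b
        )
        out["boot_mxl_pur_ratio"] = (
            fit.boot_params[:, keys.index("n_MXL")]
            / fit.boot_params[:, keys.index("n_PUR")]
        )
    cal = sd.calibrate_physical(fit)
    out["calibrated"] = cal
    out["n_MXL"] = cal["n_MXL"]
    out["mxl_pur_ratio"] = cal["n_MXL"] / cal["n_PUR"]
    return out


def em_validation(
    n_sites: int = 100_000,
    n_diploid: int = 84,
    iters: int = 20,
    seed: int = 0,
) -> dict:
    """The two-ancestry 50-50 pseudo-admixed validation panel.

    Builds diploids whose haplotypes are drawn from two source populations
    in equal proportion, runs the EM at the stated iteration count, and
    reports the fraction of polymorphic sites whose true per-ancestry sample
    frequency escapes the 95% interval.
    """
    from . import em_freqs as em

    genome = GenomeMap(names=("chr22",), lengths_cm=(5000.0,))
    m = np.zeros((13, 3))
    m[12] = [0.5, 0.5, 0.0]
    from .containers import MigrationHistory

    mig = MigrationHistory(m)
    tracts = ss.simulate_admixed_tracts(mig, genome, n_diploid, seed=seed)
    freqs = ss.sample_ancestral_frequencies(n_sites, seed=seed + 1, populations=2)
    rng = np.random.default_rng(seed + 2)
    pos = [("chr22", p) for p in np.sort(rng.uniform(0, 5000.0, n_sites))]
    table = ss.assign_genotypes(tracts, freqs, pos, seed=seed + 3)
    res = em.em_estimate(table, iters=iters)

    poly = res.polymorphic
    out = {"result": res, "n_polymorphic": int(poly.sum()), "violations": {}}
    for a, ai in (("NAT", 0), ("EUR", 1)):
        derived = ((table.hap_ancestry == ai) & (table.hap_alleles == 1)).sum(
            axis=(1, 2)
        )[poly]
        total = (table.hap_ancestry == ai).sum(axis=(1, 2))[poly]
        ok = total > 0
        sample_freq = derived[ok] / total[ok]
        lo = res.site_ci[a][ok, 0]
        hi = res.site_ci[a][ok, 1]
        outside = (sample_freq < lo - 1e-9) | (sample_freq > hi + 1e-9)
        out["violations"][a] = {
            "n_outside": int(outside.sum()),
            "n_sites": int(ok.sum()),
            "fraction": float(outside.mean()),
        }
    trace = np.array(res.loglik_trace)
    out["loglik_monotone"] = bool(np.all(np.diff(trace) >= -1e-6))
    return out
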