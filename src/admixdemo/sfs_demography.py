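"""Joint-SFS demographic inference for the three-population split model.

The Native American ancestors of the three admixed panels are modelled as a
single ancestral population (size ``N_anc``) that passes through a severe
founding bottleneck (size ``N_bot`` from ``T_found`` to ``T_recovery``,
then recovered at ``r * N_bot`` with ``r`` fixed at 100), after which one
population splits off at ``T1`` and the remaining pair splits at ``T2``.

Expected spectra are computed by deterministic propagation of the
allele-frequency distribution on a uniform frequency grid: per-generation
Wright-Fisher drift is the tridiagonal diffusion operator
``(1/4N) d2(x(1-x) phi)/dx2``, epochs are advanced with matrix
exponentials (exact in time), splits copy the one-population distribution
onto the diagonal of a two-population array, and new mutations enter at the
lowest segregating frequency at a rate that reproduces the neutral
``theta/i`` spectrum at stationarity.  Sample spectra are obtained by
binomial sampling of the grid and refined by quadratic Richardson
extrapolation over three grid sizes; everything is linear in theta, which
is profiled analytically in the Poisson composite likelihood over the three
pairwise two-population spectra.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammaln
from scipy.stats import binom as binom_dist
from scipy.stats import hypergeom

from .containers import (
    GENERATION_YEARS,
    JointSFS,
    PostContactBottleneck,
    SplitModel,
)

__all__ = [
    "project_sfs",
    "expected_pair_sfs",
    "expected_single_sfs",
    "expected_joint_sfs",
    "composite_loglik",
    "TwoPopBottleneckModel",
    "DemographyFit",
    "fit_split_model",
    "fit_two_pop_bottleneck",
    "bootstrap_demography",
    "calibrate_physical",
    "bottleneck_sensitivity",
]

DEFAULT_SLICE_GENS = 25.0
_R_FIXED = 100.0


# ---------------------------------------------------------------------------
# Projection


def project_sfs(sfs: JointSFS, target_sizes: dict[str, int]) -> JointSFS:
    """Hypergeometric down-sampling of a joint SFS to smaller sample sizes.

    A site with ``i`` derived copies in ``n`` sampled haplotypes contributes
    ``P(j | hypergeom(n, i, m))`` to class ``j`` of an ``m``-haplotype
    sub-sample; the operator is linear and applied per population axis.
    """
    counts = sfs.counts
    for axis, pop in enumerate(sfs.pop_ids):
        n = counts.shape[axis] - 1
        m = target_sizes[pop]
        if m > n:
            raise ValueError(f"target size {m} exceeds current size {n} for {pop}")
        if m == n:
            continue
        proj = hypergeom.pmf(
            np.arange(m + 1)[:, None], n, np.arange(n + 1)[None, :], m
        )
        counts = np.moveaxis(
            np.tensordot(proj, counts, axes=(1, axis)), 0, axis
        )
    return JointSFS(counts=counts, pop_ids=sfs.pop_ids)


# ---------------------------------------------------------------------------
# Frequency-grid engine


def _drift_operator(G: int, N: float) -> np.ndarray:
    """Per-generation WF diffusion generator on grid masses (absorbing ends)."""
    x = np.arange(G + 1) / G
    a = x * (1.0 - x)
    dx = 1.0 / G
    C = np.zeros((G + 1, G + 1))
    coef = 1.0 / (4.0 * N * dx * dx)
    for j in range(G + 1):
        C[j, j] -= 2.0 * coef * a[j]
        if j > 0:
            C[j, j - 1] += coef * a[j - 1]
        if j < G:
            C[j, j + 1] += coef * a[j + 1]
    return C


class _GridEngine:
    """One-grid expected-SFS machinery with per-size operator caching."""

    def __init__(self, G: int, n_root: float, slice_gens: float = DEFAULT_SLICE_GENS):
        self.G = G
        self.n_root = n_root
        self.slice_gens = slice_gens
        self.inject = G / (4.0 * n_root)  # mutations per generation, unit theta
        self._ops: dict[float, np.ndarray] = {}
        self._props: dict[tuple[float, float], np.ndarray] = {}

    def op(self, N: float) -> np.ndarray:
        if N not in self._ops:
            self._ops[N] = _drift_operator(self.G, N)
        return self._ops[N]

    def propagator(self, N: float, dt: float) -> np.ndarray:
        key = (N, round(dt, 9))
        if key not in self._props:
            self._props[key] = expm(self.op(N) * dt)
        return self._props[key]

    def equilibrium(self) -> np.ndarray:
        """Stationary segregating mass under mutation-drift balance at the
        root size; exactly proportional to 1/x on the grid nodes."""
        G = self.G
        C = self.op(self.n_root)
        s = np.zeros(G + 1)
        s[1] = self.inject
        interior = slice(1, G)
        phi_int = np.linalg.solve(C[interior, interior], -s[interior])
        phi = np.zeros(G + 1)
        phi[interior] = phi_int
        return phi

    def propagate_one(self, phi: np.ndarray, N: float, T: float) -> np.ndarray:
        """Advance a one-population distribution T generations with constant
        mutation influx (augmented-matrix exponential: exact in time)."""
        if T <= 0:
            return phi
        G = self.G
        A = np.zeros((G + 2, G + 2))
        A[: G + 1, : G + 1] = self.op(N) * T
        A[1, G + 1] = self.inject * T
        M = expm(A)
        return M[: G + 1, : G + 1] @ phi + M[: G + 1, G + 1]

    def propagate_two(
        self, phi2: np.ndarray, NA: float, NB: float, T: float
    ) -> np.ndarray:
        """Advance a two-population distribution; axis drifts are exact per
        slice, corner mutation injection is trapezoidal across slices."""
        if T <= 0:
            return phi2
        n_slices = max(1, int(math.ceil(T / self.slice_gens)))
        dt = T / n_slices
        PA = self.propagator(NA, dt)
        PBt = self.propagator(NB, dt).T
        half_a = 0.5 * dt * self.inject
        for _ in range(n_slices):
            phi2[1, 0] += half_a
            phi2[0, 1] += half_a
            phi2 = PA @ phi2 @ PBt
            phi2[1, 0] += half_a
            phi2[0, 1] += half_a
        return phi2

    def sample_one(self, phi: np.ndarray, n: int) -> np.ndarray:
        x = np.arange(self.G + 1) / self.G
        B = binom_dist.pmf(np.arange(n + 1)[:, None], n, x[None, :])
        return B @ phi

    def sample_two(self, phi2: np.ndarray, n1: int, n2: int) -> np.ndarray:
        x = np.arange(self.G + 1) / self.G
        B1 = binom_dist.pmf(np.arange(n1 + 1)[:, None], n1, x[None, :])
        B2 = binom_dist.pmf(np.arange(n2 + 1)[:, None], n2, x[None, :])
        return B1 @ phi2 @ B2.T


def _default_grids(n_max: int) -> tuple[int, int, int]:
    base = max(n_max + 10, 30)
    return (base, base + 15, base + 30)


def _richardson(values: list[np.ndarray], grids) -> np.ndarray:
    """Quadratic extrapolation to grid spacing zero (h = 1/G)."""
    h = np.array([1.0 / g for g in grids])
    # Lagrange weights for evaluating the interpolating quadratic at h = 0
    w = []
    for i in range(3):
        num, den = 1.0, 1.0
        for j in range(3):
            if j != i:
                num *= -h[j]
                den *= h[i] - h[j]
        w.append(num / den)
    out = sum(wi * v for wi, v in zip(w, values))
    floor = 1e-12 * max(float(np.max(out)), 1.0)
    return np.maximum(out, floor)


def _epoch_lists(model: SplitModel, pair: tuple[str, str]):
    """(pre-split, post-split) epoch lists for a population pair.

    Pre-split epochs are ``(duration, N)`` from the end of the root epoch to
    the pair's divergence; post-split epochs are ``(duration, N_A, N_B)``
    down to the present.  The intermediate ancestor of the later-splitting
    pair is held at the recovered size.  Splitting off a third population
    leaves the marginal dynamics of the remaining branch unchanged (no
    migration), so pairwise spectra marginalise exactly.
    """
    first = model.split_order
    n_rec = model.n_recovered
    pre = [(model.t_found_gen - model.t_recovery_gen, model.n_bottleneck)]
    if first in pair:
        other = pair[0] if pair[1] == first else pair[1]
        pre.append((model.t_recovery_gen - model.t1_gen, n_rec))
        t_split = model.t1_gen
        traj_a = [(t_split, 0.0, model.pop_sizes[first])]
        traj_b = [
            (t_split, model.t2_gen, n_rec),
            (model.t2_gen, 0.0, model.pop_sizes[other]),
        ]
        axis_pops = (first, other)
    else:
        pre.append((model.t_recovery_gen - model.t2_gen, n_rec))
        t_split = model.t2_gen
        traj_a = [(t_split, 0.0, model.pop_sizes[pair[0]])]
        traj_b = [(t_split, 0.0, model.pop_sizes[pair[1]])]
        axis_pops = pair
    traj_a = _apply_post_contact_traj(traj_a, axis_pops[0], model)
    traj_b = _apply_post_contact_traj(traj_b, axis_pops[1], model)
    post = _merge_trajectories(traj_a, traj_b)
    return pre, post, axis_pops


def _apply_post_contact_traj(traj, pop, model: SplitModel):
    bc = model.post_contact
    if bc is None or bc.pop_id != pop:
        return traj
    t_hi = bc.start_gen
    t_lo = max(bc.start_gen - bc.duration_gen, 0.0)
    out = []
    for t_old, t_young, N in traj:
        cuts = sorted(
            {t_old, t_young} | {t for t in (t_hi, t_lo) if t_young < t < t_old},
            reverse=True,
        )
        for a, b in zip(cuts[:-1], cuts[1:]):
            mid = 0.5 * (a + b)
            out.append((a, b, N * bc.severity if t_lo < mid <= t_hi else N))
    return out


def _merge_trajectories(traj_a, traj_b):
    cuts = sorted({t for seg in traj_a + traj_b for t in (seg[0], seg[1])},
                  reverse=True)

    def size_at(traj, t_mid):
        for t_old, t_young, N in traj:
            if t_young <= t_mid <= t_old + 1e-12:
                return N
        raise RuntimeError("trajectory gap")

    post = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mid = 0.5 * (a + b)
        post.append((a - b, size_at(traj_a, mid), size_at(traj_b, mid)))
    return post


def expected_pair_sfs(
    n_root: float,
    pre_epochs,
    post_epochs,
    sample_sizes: tuple[int, int],
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
) -> np.ndarray:
    """Expected two-population sample SFS per unit theta (extrapolated)."""
    n1, n2 = sample_sizes
    if grids is None:
        grids = _default_grids(max(n1, n2))
    values = []
    for G in grids:
        eng = _GridEngine(G, n_root, slice_gens)
        phi = eng.equilibrium()
        for dur, N in pre_epochs:
            phi = eng.propagate_one(phi, N, dur)
        phi2 = np.diag(phi).copy()
        for dur, NA, NB in post_epochs:
            phi2 = eng.propagate_two(phi2, NA, NB, dur)
        values.append(eng.sample_two(phi2, n1, n2))
    return _richardson(values, grids)


def expected_single_sfs(
    n_root: float,
    epochs,
    n: int,
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
) -> np.ndarray:
    """Expected one-population sample SFS per unit theta (extrapolated)."""
    if grids is None:
        grids = _default_grids(n)
    values = []
    for G in grids:
        eng = _GridEngine(G, n_root, slice_gens)
        phi = eng.equilibrium()
        for dur, N in epochs:
            phi = eng.propagate_one(phi, N, dur)
        values.append(eng.sample_one(phi, n))
    return _richardson(values, grids)


def expected_joint_sfs(
    model: SplitModel,
    sample_sizes: dict[str, int],
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
) -> dict[tuple[str, str], JointSFS]:
    """Expected pairwise spectra (per unit theta) for all three pairs."""
    out = {}
    pops = sorted(model.pop_sizes)
    for pair in itertools.combinations(pops, 2):
        pre, post, axis_pops = _epoch_lists(model, pair)
        arr = expected_pair_sfs(
            model.n_ancestral, pre, post,
            (sample_sizes[axis_pops[0]], sample_sizes[axis_pops[1]]),
            grids=grids, slice_gens=slice_gens,
        )
        if axis_pops != pair:  # reorder axes to the sorted pair
            arr = arr.T
        out[pair] = JointSFS(counts=arr, pop_ids=pair)
    return out


# ---------------------------------------------------------------------------
# Composite likelihood


def composite_loglik(
    obs_pairs: dict[tuple[str, str], JointSFS],
    exp_pairs: dict[tuple[str, str], JointSFS],
    theta: float | None = None,
) -> tuple[float, float]:
    """Poisson composite log-likelihood; theta profiled analytically unless
    fixed.

    Returns ``(loglik, theta)``; the profiled value is the ratio of total
    observed to total expected segregating mass over unmasked entries,
    pooled across the pairs.
    """
    tot_obs = tot_exp = 0.0
    for key, obs in obs_pairs.items():
        exp = exp_pairs[key]
        sel = ~obs.mask
        tot_obs += obs.counts[sel].sum()
        tot_exp += exp.counts[sel].sum()
    if tot_exp <= 0 or tot_obs <= 0:
        raise ValueError("empty (all-masked) spectra")
    if theta is None:
        theta = tot_obs / tot_exp
    ll = 0.0
    for key, obs in obs_pairs.items():
        exp = exp_pairs[key]
        sel = ~obs.mask
        o = obs.counts[sel]
        e = np.maximum(theta * exp.counts[sel], 1e-300)
        ll += float(np.sum(o * np.log(e) - e - gammaln(o + 1)))
    return ll, theta


# ---------------------------------------------------------------------------
# Fitting: 3-population split model


@dataclass
class DemographyFit:
    """Best split model with composite likelihood and bootstrap summaries."""

    model: SplitModel
    loglik: float
    theta: float
    ordering_logliks: dict[str, float]
    sample_sizes: dict[str, int]
    ci: dict[str, tuple[float, float]] | None = None
    order_frequencies: dict[str, int] | None = None
    t2_t1_ratios: np.ndarray | None = None
    boot_params: np.ndarray | None = None

    def params_dict(self) -> dict[str, float]:
        m = self.model
        d = {
            "n_ancestral": m.n_ancestral,
            "n_bottleneck": m.n_bottleneck,
            "t_found_gen": m.t_found_gen,
            "t_recovery_gen": m.t_recovery_gen,
            "t1_gen": m.t1_gen,
            "t2_gen": m.t2_gen,
        }
        for pop, size in m.pop_sizes.items():
            d[f"n_{pop}"] = size
        return d


_FIT_KEYS = ("n_bottleneck", "t2_gen", "d21", "d_r1", "d_fr")


def _model_from_free(free: np.ndarray, pops, ordering, fixed) -> SplitModel:
    n_bot, nA, nB, nC, t2, d21, dr1, dfr = np.exp(free)
    sizes = dict(zip(pops, (nA, nB, nC)))
    t1 = t2 + d21
    return SplitModel(
        n_ancestral=fixed["n_ancestral"],
        t_found_gen=t1 + dr1 + dfr,
        n_bottleneck=n_bot,
        t_recovery_gen=t1 + dr1,
        r=fixed.get("r", _R_FIXED),
        t1_gen=t1,
        t2_gen=t2,
        pop_sizes=sizes,
        split_order=ordering,
        post_contact=fixed.get("post_contact"),
    )


_LOG_BOUNDS = [
    (math.log(5.0), math.log(2e4)),      # n_bottleneck
    (math.log(100.0), math.log(2e6)),    # three branch sizes
    (math.log(100.0), math.log(2e6)),
    (math.log(100.0), math.log(2e6)),
    (math.log(30.0), math.log(2000.0)),  # t2
    (math.log(0.5), math.log(1000.0)),   # t1 - t2
    (math.log(2.0), math.log(1500.0)),   # t_recovery - t1
    (math.log(2.0), math.log(2000.0)),   # t_found - t_recovery
]


def fit_split_model(
    obs_pairs: dict[tuple[str, str], JointSFS],
    fixed: dict | None = None,
    orderings: list[str] | None = None,
    n_starts: int = 3,
    seed: int = 0,
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
    x0: np.ndarray | None = None,
    polish_grids: tuple[int, int, int] | None = None,
    maxfev: int = 1200,
) -> DemographyFit:
    """Composite-likelihood fit of the split model over split orderings.

    ``fixed`` must provide ``n_ancestral`` (the scale anchor: with theta
    profiled, the spectra identify sizes and times only relative to the
    ancestral size) and may fix ``r`` (default 100) and a ``post_contact``
    bottleneck.  When ``polish_grids`` is given, the winning ordering's
    optimum is refined once on those (finer) grids.  Deterministic given
    ``seed``.
    """
    from scipy.optimize import minimize

    fixed = {"n_ancestral": 1e4, "r": _R_FIXED, **(fixed or {})}
    pops = sorted({p for pair in obs_pairs for p in pair})
    if len(pops) != 3:
        raise ValueError("observed pairs must cover exactly three populations")
    sample_sizes = {}
    for pair, sfs in obs_pairs.items():
        for pop, n in zip(pair, sfs.sample_sizes):
            sample_sizes[pop] = n
    if orderings is None:
        orderings = pops
    rng = np.random.default_rng(seed)

    def objective(ordering, use_grids):
        def neg(free):
            if np.any(free < [b[0] for b in _LOG_BOUNDS]) or np.any(
                free > [b[1] for b in _LOG_BOUNDS]
            ):
                return 1e12
            try:
                model = _model_from_free(free, pops, ordering, fixed)
                exp = expected_joint_sfs(model, sample_sizes, grids=use_grids,
                                         slice_gens=slice_gens)
                ll, _ = composite_loglik(obs_pairs, exp,
                                         theta=fixed.get("theta"))
            except (ValueError, np.linalg.LinAlgError):
                return 1e12
            return -ll

        return neg

    lo = np.array([b[0] for b in _LOG_BOUNDS])
    hi = np.array([b[1] for b in _LOG_BOUNDS])
    center = 0.5 * (lo + hi)
    best = {}
    for ordering in orderings:
        neg = objective(ordering, grids)
        best_res = None
        starts = [x0] if x0 is not None else [center]
        while len(starts) < max(n_starts, 1):
            starts.append(lo + (hi - lo) * rng.uniform(0.2, 0.8, size=len(lo)))
        for s in starts:
            if neg(s) >= 1e11:
                continue
            res = minimize(
                neg, s, method="Powell", bounds=list(zip(lo, hi)),
                options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": maxfev},
            )
            if np.isfinite(res.fun) and res.fun < 1e11 and (
                best_res is None or res.fun < best_res.fun
            ):
                best_res = res
        if best_res is None:
            raise RuntimeError(f"optimizer failed for ordering {ordering}")
        best[ordering] = best_res

    ordering = min(best, key=lambda o: best[o].fun)
    res = best[ordering]
    final_grids = grids
    if polish_grids is not None:
        stages = (
            polish_grids
            if isinstance(polish_grids, list)
            else [(tuple(polish_grids), 900)]
        )
        for stage_grids, stage_maxfev in stages:
            neg = objective(ordering, stage_grids)
            polished = minimize(
                neg, res.x, method="Powell", bounds=list(zip(lo, hi)),
                options={"xtol": 1e-3, "ftol": 1e-7, "maxfev": stage_maxfev},
            )
            if np.isfinite(polished.fun) and polished.fun < 1e11:
                res = polished
            final_grids = stage_grids
    model = _model_from_free(res.x, pops, ordering, fixed)
    exp = expected_joint_sfs(model, sample_sizes, grids=final_grids,
                             slice_gens=slice_gens)
    ll, theta = composite_loglik(obs_pairs, exp, theta=fixed.get("theta"))
    return DemographyFit(
        model=model,
        loglik=ll,
        theta=theta,
        ordering_logliks={o: -r.fun for o, r in best.items()},
        sample_sizes=sample_sizes,
    )


# ---------------------------------------------------------------------------
# Fitting: 2-population root-bottleneck model (ascertainment equivalence)


@dataclass
class TwoPopBottleneckModel:
    """Two populations splitting from an ancestor that passed through a
    drastic root bottleneck (the negative-ascertainment approximation).

    The crash is a short epoch of fixed duration and free size ``n_bot``
    starting at ``t_bottleneck_gen``; the ancestor then recovers to a free
    size until the split.
    """

    n_ancestral: float
    t_bottleneck_gen: float
    n_bottleneck: float
    bottleneck_duration_gen: float
    n_recovered: float
    t_split_gen: float
    n1: float
    n2: float
    pop_ids: tuple[str, str] = ("pop1", "pop2")

    @property
    def t_recovery_gen(self) -> float:
        return self.t_bottleneck_gen - self.bottleneck_duration_gen

    def epochs(self):
        pre = [
            (self.bottleneck_duration_gen, self.n_bottleneck),
            (self.t_recovery_gen - self.t_split_gen, self.n_recovered),
        ]
        post = [(self.t_split_gen, self.n1, self.n2)]
        return pre, post


def fit_two_pop_bottleneck(
    obs: JointSFS,
    fixed: dict | None = None,
    n_starts: int = 3,
    seed: int = 0,
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
    bottleneck_duration_gen: float = 10.0,
) -> tuple[TwoPopBottleneckModel, float, float]:
    """Fit the root-bottleneck two-population model to an (ascertained)
    joint SFS; returns ``(model, loglik, theta)``.

    ``fixed`` must carry ``n_ancestral`` (scale anchor) and should carry
    ``theta`` when fitting simulated data with a known mutation supply: a
    bottleneck drastic enough to erase pre-existing variation also erases
    the information that would otherwise anchor the overall scale.
    """
    from scipy.optimize import minimize

    fixed = {"n_ancestral": 1e4, **(fixed or {})}
    n1, n2 = obs.sample_sizes
    bounds = [
        (math.log(1.0), math.log(5e4)),      # n_bottleneck
        (math.log(100.0), math.log(2e6)),    # n_recovered
        (math.log(100.0), math.log(2e6)),    # n1
        (math.log(100.0), math.log(2e6)),    # n2
        (math.log(30.0), math.log(2000.0)),  # t_split
        (math.log(1.0), math.log(1500.0)),   # t_bottleneck - duration - t_split
    ]

    def build(free):
        n_bot, n_rec, na, nb, ts, drs = np.exp(free)
        return TwoPopBottleneckModel(
            n_ancestral=fixed["n_ancestral"],
            t_bottleneck_gen=ts + drs + bottleneck_duration_gen,
            n_bottleneck=n_bot,
            bottleneck_duration_gen=bottleneck_duration_gen,
            n_recovered=n_rec,
            t_split_gen=ts,
            n1=na,
            n2=nb,
            pop_ids=obs.pop_ids,
        )

    def neg(free):
        if np.any(free < [b[0] for b in bounds]) or np.any(
            free > [b[1] for b in bounds]
        ):
            return np.inf
        model = build(free)
        pre, post = model.epochs()
        try:
            arr = expected_pair_sfs(model.n_ancestral, pre, post, (n1, n2),
                                    grids=grids, slice_gens=slice_gens)
            exp = JointSFS(counts=arr, pop_ids=obs.pop_ids)
            ll, _ = composite_loglik({obs.pop_ids: obs}, {obs.pop_ids: exp},
                                     theta=fixed.get("theta"))
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        return -ll

    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [0.5 * (lo + hi)]
    while len(starts) < max(n_starts, 1):
        starts.append(lo + (hi - lo) * rng.uniform(0.2, 0.8, size=len(lo)))
    best = None
    for s in starts:
        if not np.isfinite(neg(s)):
            continue
        res = minimize(neg, s, method="Powell", bounds=list(zip(lo, hi)),
                       options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 1000})
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("two-population bottleneck fit failed on all starts")
    model = build(best.x)
    pre, post = model.epochs()
    arr = expected_pair_sfs(model.n_ancestral, pre, post, (n1, n2),
                            grids=grids, slice_gens=slice_gens)
    exp = JointSFS(counts=arr, pop_ids=obs.pop_ids)
    ll, theta = composite_loglik({obs.pop_ids: obs}, {obs.pop_ids: exp},
                                 theta=fixed.get("theta"))
    return model, ll, theta


# ---------------------------------------------------------------------------
# Bootstrap, calibration, sensitivity


def _pairs_from_counts(
    sample_counts: dict[str, np.ndarray], sample_sizes: dict[str, int],
    loci_idx: np.ndarray | None = None,
) -> dict[tuple[str, str], JointSFS]:
    pops = sorted(sample_sizes)
    out = {}
    for pa, pb in itertools.combinations(pops, 2):
        ca, cb = sample_counts[pa], sample_counts[pb]
        if loci_idx is not None:
            ca, cb = ca[loci_idx], cb[loci_idx]
        arr = np.zeros((sample_sizes[pa] + 1, sample_sizes[pb] + 1))
        np.add.at(arr, (ca, cb), 1.0)
        out[(pa, pb)] = JointSFS(counts=arr, pop_ids=(pa, pb))
    return out


def bootstrap_demography(
    sample_counts: dict[str, np.ndarray],
    sample_sizes: dict[str, int],
    fit: DemographyFit,
    n_boot: int,
    n_blocks: int = 50,
    seed: int = 0,
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
    orderings: list[str] | None = None,
    maxfev: int = 600,
) -> DemographyFit:
    """Block bootstrap over loci: percentile CIs, split-order frequencies
    and the T2/T1 ratio distribution, attached to ``fit``.

    Replicate fits restart from the point estimate (single start), the
    standard shortcut for bootstrap refits.
    """
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    n_loci = len(next(iter(sample_counts.values())))
    blocks = np.array_split(np.arange(n_loci), n_blocks)
    rng = np.random.default_rng(seed)
    m = fit.model
    x0 = np.log([
        m.n_bottleneck,
        *[m.pop_sizes[p] for p in sorted(m.pop_sizes)],
        m.t2_gen,
        m.t1_gen - m.t2_gen,
        m.t_recovery_gen - m.t1_gen,
        m.t_found_gen - m.t_recovery_gen,
    ])
    params, orders, ratios = [], [], []
    for b in range(n_boot):
        chosen = rng.integers(0, n_blocks, size=n_blocks)
        idx = np.concatenate([blocks[c] for c in chosen])
        obs = _pairs_from_counts(sample_counts, sample_sizes, idx)
        try:
            f = fit_split_model(
                obs,
                fixed={"n_ancestral": m.n_ancestral, "r": m.r},
                orderings=orderings,
                n_starts=1,
                seed=seed + 1 + b,
                grids=grids,
                slice_gens=slice_gens,
                x0=x0,
                maxfev=maxfev,
            )
        except RuntimeError:
            continue
        params.append([f.params_dict()[k] for k in sorted(f.params_dict())])
        orders.append(f.model.split_order)
        ratios.append(f.model.t2_gen / f.model.t1_gen)
    keys = sorted(fit.params_dict())
    params = np.array(params)
    ci = {}
    for i, k in enumerate(keys):
        lo_q, hi_q = np.quantile(params[:, i], [0.025, 0.975])
        pt = fit.params_dict()[k]
        ci[k] = (float(min(lo_q, pt)), float(max(hi_q, pt)))
    fit.ci = ci
    fit.order_frequencies = {
        o: int(sum(1 for x in orders if x == o)) for o in sorted(set(orders))
    }
    fit.t2_t1_ratios = np.array(ratios)
    fit.boot_params = params
    return fit


def calibrate_physical(
    fit: DemographyFit,
    t_found_years: float = 16000.0,
    gen_years: float = GENERATION_YEARS,
    l_callable: float = 1.0,
) -> dict:
    """Anchor the founding bottleneck at ``t_found_years`` and convert the
    fit to physical units.

    All times and sizes scale linearly with the anchor (the SFS constrains
    only their ratios once theta is profiled), and the mutation rate follows
    as ``mu = theta / (4 N_ref L)`` with ``N_ref`` the rescaled ancestral
    size; the returned ``scale`` lets users re-anchor without refitting.
    """
    if l_callable <= 0:
        raise ValueError("l_callable must be positive")
    m = fit.model
    t_found_target_gen = t_found_years / gen_years
    scale = t_found_target_gen / m.t_found_gen
    n_ref = m.n_ancestral * scale
    out = {
        "scale": scale,
        "gen_years": gen_years,
        "t_found_years": t_found_years,
        "n_ancestral": n_ref,
        "n_bottleneck": m.n_bottleneck * scale,
        "t_recovery_years": m.t_recovery_gen * scale * gen_years,
        "t1_years": m.t1_gen * scale * gen_years,
        "t2_years": m.t2_gen * scale * gen_years,
        "mu": fit.theta / (4.0 * n_ref * l_callable),
    }
    for pop, size in m.pop_sizes.items():
        out[f"n_{pop}"] = size * scale
    return out


def bottleneck_sensitivity(
    fit: DemographyFit,
    bottleneck: PostContactBottleneck,
    obs_pairs: dict[tuple[str, str], JointSFS],
    n_starts: int = 1,
    seed: int = 0,
    grids: tuple[int, int, int] | None = None,
    slice_gens: float = DEFAULT_SLICE_GENS,
) -> dict:
    """Refit with a fully fixed post-contact bottleneck on one branch and
    report the pre-bottleneck size inflation.

    The no-bottleneck baseline is refit from the same starting point with
    the same protocol, so the reported ratios compare like with like."""
    m = fit.model
    x0 = np.log([
        m.n_bottleneck,
        *[m.pop_sizes[p] for p in sorted(m.pop_sizes)],
        m.t2_gen,
        m.t1_gen - m.t2_gen,
        m.t_recovery_gen - m.t1_gen,
        m.t_found_gen - m.t_recovery_gen,
    ])

    def _refit(post_contact):
        return fit_split_model(
            obs_pairs,
            fixed={
                "n_ancestral": m.n_ancestral,
                "r": m.r,
                "post_contact": post_contact,
            },
            orderings=[m.split_order],
            n_starts=n_starts,
            seed=seed,
            grids=grids,
            slice_gens=slice_gens,
            x0=x0,
            maxfev=600,
        )

    baseline = _refit(None)
    refit = _refit(bottleneck)
    pop = bottleneck.pop_id
    return {
        "fit_with_bottleneck": refit,
        "fit_baseline": baseline,
        "size_ratio": refit.model.pop_sizes[pop] / baseline.model.pop_sizes[pop],
        "split_time_shift": {
            "t1": refit.model.t1_gen / baseline.model.t1_gen,
            "t2": refit.model.t2_gen / baseline.model.t2_gen,
        },
    }
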