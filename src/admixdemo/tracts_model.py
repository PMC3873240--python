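"""Analytic ancestry-tract-length model under time-varying migration.

The length distribution of continuous local-ancestry tracts in an admixed
population carries the signal of when, and at what intensity, each source
population contributed migrants.  Under Wright-Fisher reproduction with
unadmixed migrants, the ancestry process along a present-day haplotype is
well approximated by a Markov jump process whose states are pairs
``(entry generation t, source p)``: a lineage that entered the admixed
population ``t`` generations ago has accumulated ``t - 1`` meioses, so
recombination breakpoints occur at rate ``t - 1`` per Morgan, and at a
breakpoint the flanking lineage is re-drawn from the population standing at
the (uniformly chosen) generation of that crossover.

Aggregating states by source label turns per-ancestry tract lengths into
phase-type distributions; expected per-bin tract counts on finite
chromosomes (with edge and whole-chromosome corrections) follow in closed
form and feed a Poisson maximum-likelihood fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .containers import (
    ANCESTRIES,
    ANCESTRY_INDEX,
    AncestryTractSet,
    GenomeMap,
    InvalidHistoryError,
    MigrationHistory,
)

__all__ = [
    "TractHistogram",
    "TractsFit",
    "ModelFamily",
    "FAMILIES",
    "discretize_pulse",
    "default_bins",
    "expected_tract_counts",
    "expected_ancestry_cm",
    "tract_histogram",
    "poisson_loglik",
    "fit_tracts_model",
    "select_model",
    "bootstrap_tracts_ci",
]

#: Default shortest countable tract, cM (local-ancestry detection limit).
MIN_TRACT_CM = 0.2
DEFAULT_N_BINS = 30


# ---------------------------------------------------------------------------
# Pulse discretization


def discretize_pulse(t: float, fractions, magnitude: float = 1.0) -> dict[int, np.ndarray]:
    """Place a migration pulse at non-integer time ``t`` onto integer generations.

    A founding pulse (``magnitude == 1``) at ``t`` between integers is
    realised as a founding at ``ceil(t)`` followed by a replacement migration
    at ``floor(t)`` of weight ``ceil(t) - t`` with the same source fractions,
    so an inferred onset of 13.02 generations becomes founding 14 generations
    ago with near-complete (0.98) replacement 13 generations ago, and integer
    ``t`` reduces to a single row.  Ancestry fractions are preserved exactly.

    A partial pulse (``magnitude < 1``) is mass-split linearly between the
    neighbouring generations, preserving the total migrant input.

    Returns a mapping ``generation -> migrant-fraction row`` (length 3).
    """
    if t <= 1:
        raise InvalidHistoryError("pulse time must exceed 1 generation")
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (len(ANCESTRIES),):
        raise ValueError("fractions must have one entry per ancestry")
    lo, hi = math.floor(t), math.ceil(t)
    if lo == hi:
        return {lo: magnitude * fractions}
    if magnitude == 1.0:
        w = hi - t  # replacement weight at the lower generation
        return {hi: fractions.copy(), lo: w * fractions}
    return {hi: magnitude * (t - lo) * fractions, lo: magnitude * (hi - t) * fractions}


# ---------------------------------------------------------------------------
# Histograms


@dataclass
class TractHistogram:
    """Per-ancestry tract counts over length bins (edges in cM)."""

    bin_edges_cm: np.ndarray
    counts: dict[str, np.ndarray]
    n_haplotypes: int
    genome: GenomeMap

    def __post_init__(self):
        self.bin_edges_cm = np.asarray(self.bin_edges_cm, dtype=float)
        if np.any(np.diff(self.bin_edges_cm) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        for a, c in self.counts.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (len(self.bin_edges_cm) - 1,):
                raise ValueError(f"count vector for {a} does not match bins")
            if np.any(c < 0):
                raise ValueError("negative counts")
            self.counts[a] = c

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges_cm) - 1

    def total(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))

    def compatible_with(self, other: "TractHistogram") -> bool:
        return (
            np.allclose(self.bin_edges_cm, other.bin_edges_cm)
            and set(self.counts) == set(other.counts)
        )


def default_bins(
    genome: GenomeMap,
    n_bins: int = DEFAULT_N_BINS,
    min_cm: float = MIN_TRACT_CM,
) -> np.ndarray:
    """Log-spaced length bins from the detection limit to the longest chromosome."""
    top = max(genome.lengths_cm) * (1 + 1e-9)
    return np.geomspace(min_cm, top, n_bins + 1)


def tract_histogram(tracts: AncestryTractSet, bins: np.ndarray) -> TractHistogram:
    """Count observed tracts by ancestry and length bin.

    Tracts shorter than the first edge are below the detection limit and are
    not counted; chromosomes are never merged.
    """
    bins = np.asarray(bins, dtype=float)
    lens = (tracts.data["end_cm"] - tracts.data["start_cm"]).to_numpy()
    chrom_len = np.array(
        [tracts.genome.length_of(c) for c in tracts.data["chrom"]]
    )
    if np.any(lens > chrom_len * (1 + 1e-9)):
        raise ValueError("tract longer than its chromosome")
    anc = tracts.data["ancestry"].to_numpy()
    counts = {}
    for a in ANCESTRIES:
        counts[a], _ = np.histogram(lens[anc == a], bins=bins)
        counts[a] = counts[a].astype(float)
    return TractHistogram(
        bin_edges_cm=bins,
        counts=counts,
        n_haplotypes=tracts.n_haplotypes(),
        genome=tracts.genome,
    )


# ---------------------------------------------------------------------------
# Markov chain construction


def _state_chain(mig: MigrationHistory):
    """States ``(t, p)``, stationary weights, and the per-Morgan rate matrix.

    Returns ``(states, pi, Q)`` where ``Q[i, j]`` is the per-Morgan rate of
    switching from state ``i`` to state ``j`` (rows sum to zero).
    """
    m = mig.m
    T0 = mig.founding_generation
    M = mig.total_inflow

    states = [
        (t, p) for t in range(2, T0 + 1) for p in range(len(ANCESTRIES))
        if m[t, p] > 0
    ]
    if not states:
        raise InvalidHistoryError("history has no migrant input after generation 1")
    n = len(states)
    t_of = np.array([t for t, _ in states])

    # E[u, j]: distribution of the entry state of a random lineage standing at
    # generation u (probability it entered at t >= u from source p);
    # survival factors prod_{v=u}^{t-1}(1 - M[v]) via cumulative products.
    m_state = np.array([m[t, p] for t, p in states])
    E = np.zeros((T0 + 1, n))
    cp = np.concatenate([[1.0], np.cumprod(1.0 - M[1:T0])])  # cp[k] to gen k
    if np.any(cp[:-1] <= 0):
        for u in range(1, T0 + 1):
            for j, (t, p) in enumerate(states):
                if t >= u:
                    surv = np.prod(1.0 - M[u:t])
                    E[u, j] = m[t, p] * surv
    else:
        u_arr = np.arange(1, T0 + 1)
        mask = t_of[None, :] >= u_arr[:, None]
        E[1:] = m_state[None, :] * (cp[t_of - 1][None, :] / cp[u_arr - 1][:, None]) * mask
    # A lineage that entered at t has meioses at levels 1..t-1; the crossover
    # at level g swaps to a haplotype standing at generation g+1, so the
    # re-draw flow sums E[v] over v = 2..t.
    F = np.cumsum(E, axis=0)
    Q = F[t_of, :] - E[1][None, :]
    rates = (t_of - 1).astype(float)
    Q[np.arange(n), np.arange(n)] -= rates

    pi = E[1]  # entry distribution of a present-day lineage (stationary)
    if not np.isclose(pi.sum(), 1.0, atol=1e-9):
        raise InvalidHistoryError("entry distribution does not sum to 1")
    return states, pi, Q


def _exp_integrals(lam: np.ndarray, x0: float, x1: float):
    """``(I0, I1) = (int e^{lam x} dx, int x e^{lam x} dx)`` over [x0, x1]."""
    small = np.abs(lam) < 1e-10
    lam_safe = np.where(small, 1.0, lam)
    e0, e1 = np.exp(lam_safe * x0), np.exp(lam_safe * x1)
    I0 = np.where(small, x1 - x0, (e1 - e0) / lam_safe)
    I1 = np.where(
        small,
        0.5 * (x1**2 - x0**2),
        (x1 * e1 - x0 * e0) / lam_safe - (e1 - e0) / lam_safe**2,
    )
    return I0, I1


class _AncestryPhase:
    """Spectral pieces for one ancestry's phase-type tract-length law."""

    def __init__(self, pi, Q, idx):
        self.empty = len(idx) == 0
        if self.empty:
            return
        comp = np.setdiff1d(np.arange(Q.shape[0]), idx)
        T = Q[np.ix_(idx, idx)]
        self.exit = -T.sum(axis=1)                    # exit rate per state
        self.alpha = pi[comp] @ Q[np.ix_(comp, idx)]  # switch-in flux
        self.pi_a = pi[idx]                           # stationary occupancy
        lam, V = np.linalg.eig(T)
        Vinv = np.linalg.inv(V)
        self.lam = lam
        # coefficient vectors: f(x) = sum_m w_m e^{lam_m x}
        aV = self.alpha @ V
        pV = self.pi_a @ V
        ve = Vinv @ self.exit
        v1 = Vinv @ np.ones(len(idx))
        self.w_int = aV * ve    # interior: switch-in ... switch-out
        self.w_left = pV * ve   # left-censored: chromosome start ... switch-out
        self.w_right = aV * v1  # right-censored: switch-in ... chromosome end
        self.w_whole = pV * v1  # whole-chromosome tract

    def stationary_mass(self) -> float:
        return 0.0 if self.empty else float(self.pi_a.sum())

    def bin_counts(self, edges_m: np.ndarray, chrom_lengths_m: np.ndarray):
        """Expected tract counts per length bin per haplotype (summed over
        chromosomes), plus whole-chromosome contributions."""
        nb = len(edges_m) - 1
        out = np.zeros(nb)
        if self.empty:
            return out
        L = np.asarray(chrom_lengths_m)[:, None, None]      # (nc, 1, 1)
        edges = np.minimum(edges_m[None, :, None], L)       # (nc, ne, 1)
        lam = self.lam[None, None, :]                       # (1, 1, nm)
        small = np.abs(lam) < 1e-10
        lam_safe = np.where(small, 1.0, lam)
        E = np.exp(lam_safe * edges)                        # (nc, ne, nm)
        # antiderivatives of e^{lam x} and x e^{lam x} at the edges
        A0 = np.where(small, edges, E / lam_safe)
        A1 = np.where(small, 0.5 * edges**2,
                      edges * E / lam_safe - E / lam_safe**2)
        I0 = np.diff(A0, axis=1)                            # (nc, nb, nm)
        I1 = np.diff(A1, axis=1)
        w_edge = self.w_left + self.w_right
        vals = (L * I0 - I1) @ self.w_int + I0 @ w_edge     # (nc, nb)
        out = vals.real.sum(axis=0)
        # whole-chromosome tract lands in the bin containing L
        Lc = np.asarray(chrom_lengths_m)
        whole = (np.exp(np.outer(Lc, self.lam)) @ self.w_whole).real
        b = np.searchsorted(edges_m, Lc, side="right") - 1
        ok = (b >= 0) & (b < nb)
        np.add.at(out, b[ok], whole[ok])
        return np.maximum(out, 0.0)

    def expected_total_length_m(self, chrom_lengths_m) -> float:
        """Exact expected ancestry content: stationarity gives pi_a * L."""
        return self.stationary_mass() * float(np.sum(chrom_lengths_m))


def expected_tract_counts(
    mig: MigrationHistory,
    bins: np.ndarray,
    genome: GenomeMap,
    n_haplotypes: int,
) -> TractHistogram:
    """Expected (real-valued) per-bin tract counts under a migration history."""
    states, pi, Q = _state_chain(mig)
    edges_m = np.asarray(bins, dtype=float) / 100.0
    chrom_m = np.array(genome.lengths_cm) / 100.0
    counts = {}
    for a in ANCESTRIES:
        idx = np.array(
            [k for k, (t, p) in enumerate(states) if p == ANCESTRY_INDEX[a]],
            dtype=int,
        )
        phase = _AncestryPhase(pi, Q, idx)
        counts[a] = n_haplotypes * phase.bin_counts(edges_m, chrom_m)
    return TractHistogram(
        bin_edges_cm=np.asarray(bins, dtype=float),
        counts=counts,
        n_haplotypes=n_haplotypes,
        genome=genome,
    )


def expected_ancestry_cm(mig: MigrationHistory, genome: GenomeMap) -> dict[str, float]:
    """Expected cM of each ancestry per haplotype (stationary occupancy)."""
    props = mig.ancestry_proportions()
    return {a: float(props[ANCESTRY_INDEX[a]] * genome.total_cm) for a in ANCESTRIES}


# ---------------------------------------------------------------------------
# Likelihood


def poisson_loglik(obs: TractHistogram, exp: TractHistogram) -> float:
    """Poisson log-likelihood of observed per-bin counts given expectations.

    Bins with zero expectation contribute 0 when the observation is also 0
    and ``-inf`` otherwise (an impossible observation under the model).
    """
    if not obs.compatible_with(exp):
        raise ValueError("histograms have mismatched bins or ancestries")
    total = 0.0
    for a in obs.counts:
        o, e = obs.counts[a], exp.counts[a]
        zero = e <= 0
        if np.any(o[zero] > 0):
            return -np.inf
        keep = ~zero
        ok, ek = o[keep], e[keep]
        total += float(np.sum(ok * np.log(ek) - ek - gammaln(ok + 1)))
    return total


# ---------------------------------------------------------------------------
# Model families


@dataclass(frozen=True)
class ModelFamily:
    """A parametric family of migration histories.

    ``builder(params)`` maps the continuous parameter vector to a
    :class:`MigrationHistory` (raising :class:`InvalidHistoryError` outside
    the feasible region); ``bounds`` are per-parameter boxes for the
    optimizer.
    """

    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    builder: callable

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def history(self, params) -> MigrationHistory:
        return self.builder(np.asarray(params, dtype=float))


def _founding_rows(t, f_eur, f_afr):
    f_nat = 1.0 - f_eur - f_afr
    if f_nat < 0:
        raise InvalidHistoryError("founding fractions exceed 1")
    fractions = np.zeros(3)
    fractions[ANCESTRY_INDEX["NAT"]] = f_nat
    fractions[ANCESTRY_INDEX["EUR"]] = f_eur
    fractions[ANCESTRY_INDEX["AFR"]] = f_afr
    return discretize_pulse(t, fractions)


def _blank(t_top):
    return np.zeros((math.ceil(t_top) + 1, 3))


def _build_single_pulse(p):
    t, f_eur, f_afr = p
    m = _blank(t)
    for g, row in _founding_rows(t, f_eur, f_afr).items():
        m[g] += row
    return MigrationHistory(m)


def _build_founding_plus_continuing(p):
    t, f_eur, f_afr, m_eur, m_nat = p
    m = _blank(t)
    for g, row in _founding_rows(t, f_eur, f_afr).items():
        m[g] += row
    for g in range(2, math.floor(t)):
        m[g, ANCESTRY_INDEX["EUR"]] += m_eur
        m[g, ANCESTRY_INDEX["NAT"]] += m_nat
    return MigrationHistory(m)


def _secondary_pulse(m, t2, t1, mags: dict[str, float]):
    if t2 >= t1 - 1:
        raise InvalidHistoryError("second pulse must predate founding by > 1 gen")
    for anc, mag in mags.items():
        row = np.zeros(3)
        row[ANCESTRY_INDEX[anc]] = 1.0
        for g, r in discretize_pulse(t2, row, magnitude=mag).items():
            m[g] += r
    return m


def _build_two_eur_afr_pulses(p):
    t1, f_eur, f_afr, t2, m_e2, m_a2 = p
    m = _blank(t1)
    for g, row in _founding_rows(t1, f_eur, f_afr).items():
        m[g] += row
    m = _secondary_pulse(m, t2, t1, {"EUR": m_e2, "AFR": m_a2})
    return MigrationHistory(m)


def _build_founding_plus_nat_pulse(p):
    t1, f_eur, f_afr, t2, m_n2 = p
    m = _blank(t1)
    for g, row in _founding_rows(t1, f_eur, f_afr).items():
        m[g] += row
    m = _secondary_pulse(m, t2, t1, {"NAT": m_n2})
    return MigrationHistory(m)


FAMILIES: dict[str, ModelFamily] = {
    "three_pulses_simultaneous": ModelFamily(
        name="three_pulses_simultaneous",
        param_names=("t_onset", "f_eur", "f_afr"),
        bounds=((2.05, 30.0), (0.0, 1.0), (0.0, 1.0)),
        builder=_build_single_pulse,
    ),
    "founding_plus_continuing": ModelFamily(
        name="founding_plus_continuing",
        param_names=("t_onset", "f_eur", "f_afr", "m_eur", "m_nat"),
        bounds=((4.05, 30.0), (0.0, 1.0), (0.0, 1.0), (0.0, 0.1), (0.0, 0.1)),
        builder=_build_founding_plus_continuing,
    ),
    "two_EUR_two_AFR_pulses": ModelFamily(
        name="two_EUR_two_AFR_pulses",
        param_names=("t_onset", "f_eur", "f_afr", "t_pulse2", "m_eur2", "m_afr2"),
        bounds=((4.05, 30.0), (0.0, 1.0), (0.0, 1.0), (2.05, 25.0), (0.0, 0.5),
                (0.0, 0.5)),
        builder=_build_two_eur_afr_pulses,
    ),
    "founding_plus_second_NAT_pulse": ModelFamily(
        name="founding_plus_second_NAT_pulse",
        param_names=("t_onset", "f_eur", "f_afr", "t_nat2", "m_nat2"),
        bounds=((4.05, 30.0), (0.0, 1.0), (0.0, 1.0), (2.05, 25.0), (0.0, 0.5)),
        builder=_build_founding_plus_nat_pulse,
    ),
}


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class TractsFit:
    """Result of a maximum-likelihood tract-model fit."""

    family: str
    params: np.ndarray
    param_names: tuple[str, ...]
    loglik: float
    n_params: int
    n_obs: float
    trace: list[float] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] | None = None

    @property
    def bic(self) -> float:
        return -2.0 * self.loglik + self.n_params * math.log(max(self.n_obs, 1.0))

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def as_dict(self) -> dict:
        d = {
            "family": self.family,
            "params": dict(zip(self.param_names, map(float, self.params))),
            "loglik": self.loglik,
            "bic": self.bic,
            "aic": self.aic,
        }
        if self.ci is not None:
            d["ci"] = {k: list(map(float, v)) for k, v in self.ci.items()}
        return d


def _repair(family: ModelFamily, params: np.ndarray) -> tuple[np.ndarray, float]:
    """Project parameters into the feasible region, returning a smooth
    penalty proportional to the distance moved (keeps direction-set
    optimizers from stalling on flat infeasible plateaus)."""
    x = np.array(params, dtype=float)
    penalty = 0.0
    names = family.param_names
    if "f_eur" in names:
        i_e, i_a = names.index("f_eur"), names.index("f_afr")
        s = x[i_e] + x[i_a]
        if s > 0.999:
            x[i_e] *= 0.999 / s
            x[i_a] *= 0.999 / s
            penalty += 1e3 * (s - 0.999)
    for nm in ("t_pulse2", "t_nat2"):
        if nm in names:
            i = names.index(nm)
            limit = x[0] - 1.05
            if x[i] > limit:
                penalty += 1e3 * (x[i] - limit)
                x[i] = max(limit, 1.05)
            if limit < 1.05:
                penalty += 1e3 * (1.05 - limit)
    return x, penalty


def _objective(family: ModelFamily, obs: TractHistogram):
    genome, n_hap, bins = obs.genome, obs.n_haplotypes, obs.bin_edges_cm

    PENALTY = 1e12

    def neg_loglik(params):
        params, pen = _repair(family, params)
        try:
            mig = family.history(params)
        except InvalidHistoryError:
            return PENALTY
        try:
            exp = expected_tract_counts(mig, bins, genome, n_hap)
        except (InvalidHistoryError, np.linalg.LinAlgError):
            return PENALTY
        # keep tiny positive expectations from underflowing to exact zero;
        # ancestries absent from the candidate history stay structurally zero
        for a, c in exp.counts.items():
            if c.sum() > 0:
                exp.counts[a] = np.maximum(c, 1e-12)
        ll = poisson_loglik(obs, exp)
        return PENALTY if not np.isfinite(ll) else -ll + pen

    return neg_loglik


def fit_tracts_model(
    obs: TractHistogram,
    family: ModelFamily | str,
    n_starts: int = 10,
    seed: int = 0,
) -> TractsFit:
    """Multi-start bounded ML fit of a migration-model family to a histogram.

    Deterministic given ``seed``; raises if no start reaches a finite
    likelihood.
    """
    from scipy.optimize import minimize

    if isinstance(family, str):
        family = FAMILIES[family]
    if obs.total() <= 0:
        raise ValueError("observed histogram is empty")
    neg = _objective(family, obs)
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in family.bounds])
    hi = np.array([b[1] for b in family.bounds])

    best, trace = None, []
    for _ in range(n_starts):
        x0 = lo + (hi - lo) * rng.uniform(0.05, 0.95, size=len(lo))
        # keep random fraction starts inside the simplex
        if "f_eur" in family.param_names:
            i_e = family.param_names.index("f_eur")
            i_a = family.param_names.index("f_afr")
            tot = x0[i_e] + x0[i_a]
            if tot >= 1.0:
                x0[i_e] *= 0.9 / tot
                x0[i_a] *= 0.9 / tot
        if "t_pulse2" in family.param_names or "t_nat2" in family.param_names:
            i_t2 = len(family.param_names) - 2
            i_t2 = next(
                i for i, nm in enumerate(family.param_names)
                if nm in ("t_pulse2", "t_nat2")
            )
            x0[i_t2] = min(x0[i_t2], x0[0] - 1.5)
            x0[i_t2] = max(x0[i_t2], lo[i_t2])
        if neg(x0) >= 1e11:
            continue
        res = minimize(
            neg, x0, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"xtol": 1e-2, "ftol": 1e-4, "maxfev": 400},
        )
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            continue
        if best is None or res.fun < best.fun:
            best = res
        trace.append(-(best.fun))
    if best is None:
        raise RuntimeError(
            f"no finite-likelihood optimum found for family {family.name}"
        )
    # polish the best exploration result
    res = minimize(
        neg, best.x, method="Powell", bounds=list(zip(lo, hi)),
        options={"xtol": 1e-4, "ftol": 1e-8, "maxfev": 2000},
    )
    if np.isfinite(res.fun) and res.fun < best.fun:
        best = res
    trace.append(-(best.fun))
    return TractsFit(
        family=family.name,
        params=_repair(family, np.asarray(best.x, dtype=float))[0],
        param_names=family.param_names,
        loglik=float(-best.fun),
        n_params=family.n_params,
        n_obs=obs.total(),
        trace=trace,
    )


def select_model(fits: list[TractsFit], criterion: str = "bic") -> TractsFit:
    """Pick the fit minimizing the information criterion (default BIC)."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    n_obs = {round(f.n_obs) for f in fits}
    if len(n_obs) > 1:
        raise ValueError("fits were not computed on the same data")
    key = (lambda f: f.bic) if criterion == "bic" else (lambda f: f.aic)
    return min(fits, key=key)


def bootstrap_tracts_ci(
    tracts: AncestryTractSet,
    family: ModelFamily | str,
    n_boot: int,
    seed: int = 0,
    bins: np.ndarray | None = None,
    n_starts: int = 3,
    level: float = 0.95,
) -> TractsFit:
    """Percentile CIs from bootstrap over diploid individuals.

    Refits the family to each resample; returns the full-data fit with the
    ``ci`` field populated.
    """
    if isinstance(family, str):
        family = FAMILIES[family]
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    individuals = tracts.individuals
    if len(individuals) < 2:
        raise ValueError("need at least two individuals to bootstrap")
    if bins is None:
        bins = default_bins(tracts.genome)
    obs = tract_histogram(tracts, bins)
    fit = fit_tracts_model(obs, family, n_starts=max(n_starts, 2), seed=seed)
    rng = np.random.default_rng(seed)
    draws = []
    for b in range(n_boot):
        chosen = rng.choice(individuals, size=len(individuals), replace=True)
        sub = tracts.subset_individuals(chosen)
        h = tract_histogram(sub, bins)
        try:
            f = fit_tracts_model(h, family, n_starts=n_starts, seed=seed + 1 + b)
        except RuntimeError:
            continue
        draws.append(f.params)
    draws = np.array(draws)
    alpha = (1.0 - level) / 2.0
    ci = {}
    for i, nm in enumerate(family.param_names):
        lo_q, hi_q = np.quantile(draws[:, i], [alpha, 1 - alpha])
        lo_q = min(lo_q, fit.params[i])
        hi_q = max(hi_q, fit.params[i])
        ci[nm] = (float(lo_q), float(hi_q))
    fit.ci = ci
    return fit
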