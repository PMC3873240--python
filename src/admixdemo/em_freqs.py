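"""EM estimation of ancestry-specific allele frequencies.

Unphased genotypes cannot be attributed to a haplotype, so at
ancestry-heterozygous sites the derived allele's continental background is
ambiguous.  Modelling the two haplotypes of an individual as independent
Bernoulli draws from the allele frequency of their own ancestry makes the
genotype likelihood phasing-free:

    P(G | A=(a,b), f) :  P(0) = (1-f_a)(1-f_b),
                         P(1) = f_a (1-f_b) + f_b (1-f_a),
                         P(2) = f_a f_b,

and Bayes' rule on a discrete frequency grid gives per-site posteriors
P(f_a | D, A) once a prior P(f_a) is available.  Because the prior is itself
unknown, it is estimated self-consistently: the expectation step computes
site posteriors under the current prior, the maximization step replaces the
prior by the average site posterior (optionally corrected for monomorphic,
hence unobserved, sites), and the cycle repeats — the marginal likelihood
is non-decreasing at every iteration.  Point estimates are posterior means;
intervals are highest-posterior-density intervals on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ANCESTRIES, ANCESTRY_INDEX, AncestryGenotypeTable, DIPLOID_PAIRS

__all__ = [
    "FrequencyGrid",
    "SitePosterior",
    "EmResult",
    "genotype_prob",
    "site_posterior",
    "em_estimate",
    "monomorphic_correction",
    "frequency_ci",
    "ancestry_freq_difference_test",
]

DEFAULT_GRID = 201
_EPS = 1e-300


@dataclass
class FrequencyGrid:
    """Candidate frequencies in [0, 1] and a per-ancestry prior over them."""

    f: np.ndarray
    priors: dict[str, np.ndarray]

    @classmethod
    def uniform(cls, ancestries, n_points: int = DEFAULT_GRID) -> "FrequencyGrid":
        f = np.linspace(0.0, 1.0, n_points)
        p = np.full(n_points, 1.0 / n_points)
        return cls(f=f, priors={a: p.copy() for a in ancestries})

    def check(self):
        for a, p in self.priors.items():
            if abs(p.sum() - 1.0) > 1e-8 or np.any(p < 0):
                raise ValueError(f"prior for {a} is not a distribution")


@dataclass
class SitePosterior:
    """Per-ancestry posterior over the grid at one site."""

    f: np.ndarray
    posteriors: dict[str, np.ndarray]     # each sums to 1
    hap_counts: dict[str, int]            # ancestry haplotypes at the site
    log_marginal: float

    def mean(self, ancestry: str) -> float:
        return float(self.posteriors[ancestry] @ self.f)

    def ci(self, ancestry: str, level: float = 0.95) -> tuple[float, float]:
        return frequency_ci((self.f, self.posteriors[ancestry]), level)


def genotype_prob(g: int, pair: tuple[str, str], f_a: float, f_b: float) -> float:
    """P(G = g | diploid ancestry pair, per-ancestry frequencies)."""
    if g not in (0, 1, 2):
        raise ValueError("genotype must be 0, 1 or 2")
    fa = f_a
    fb = f_b if pair[0] != pair[1] else f_a
    if g == 0:
        return (1 - fa) * (1 - fb)
    if g == 1:
        return fa * (1 - fb) + fb * (1 - fa)
    return fa * fb


# ---------------------------------------------------------------------------
# Site-level counts


def _site_class_counts(table: AncestryGenotypeTable) -> np.ndarray:
    """(n_sites, 6 pairs, 3 genotypes) counts of complete calls."""
    n_sites, n_ind = table.genotypes.shape
    counts = np.zeros((n_sites, len(DIPLOID_PAIRS), 3), dtype=np.int32)
    valid = (table.genotypes >= 0) & (table.ancestry >= 0)
    code = table.ancestry.astype(np.int64) * 3 + table.genotypes
    for s in range(n_sites):
        v = valid[s]
        if v.any():
            flat = np.bincount(code[s, v], minlength=18)
            counts[s] = flat.reshape(len(DIPLOID_PAIRS), 3)
    return counts


_PAIR_IDX = {tuple(sorted(p)): c for c, p in enumerate(DIPLOID_PAIRS)}


def _hap_counts(counts_site: np.ndarray) -> dict[str, int]:
    out = {a: 0 for a in ANCESTRIES}
    for c, (a, b) in enumerate(DIPLOID_PAIRS):
        n = int(counts_site[c].sum())
        out[a] += n
        out[b] += n
    return out


# ---------------------------------------------------------------------------
# Posterior machinery (vectorised over sites for <= 2 involved ancestries)


def _separable_logliks(counts: np.ndarray, f: np.ndarray, a: str, b: str):
    """Log-likelihood pieces for sites involving ancestries {a, b}.

    Returns ``(u_a, u_b, n_het1)`` with ``u_x`` of shape (n_sites, n_grid):
    all genotype classes are separable in (f_a, f_b) except the G=1 class of
    the heterozygous-ancestry pair, whose counts are returned separately.
    """
    with np.errstate(divide="ignore"):
        lf = np.log(np.clip(f, _EPS, None))
        l1f = np.log(np.clip(1.0 - f, _EPS, None))
    hom = {
        0: 2.0 * l1f,
        1: np.log(np.clip(2.0 * f * (1.0 - f), _EPS, None)),
        2: 2.0 * lf,
    }
    n_sites = counts.shape[0]
    u = {a: np.zeros((n_sites, len(f))), b: np.zeros((n_sites, len(f)))}
    for x in (a, b):
        c = _PAIR_IDX[tuple(sorted((x, x)))]
        for g in (0, 1, 2):
            u[x] += counts[:, c, g][:, None] * hom[g][None, :]
    if a != b:
        c = _PAIR_IDX[tuple(sorted((a, b)))]
        u[a] += counts[:, c, 0][:, None] * l1f[None, :]
        u[b] += counts[:, c, 0][:, None] * l1f[None, :]
        u[a] += counts[:, c, 2][:, None] * lf[None, :]
        u[b] += counts[:, c, 2][:, None] * lf[None, :]
        n_het1 = counts[:, c, 1].copy()
    else:
        n_het1 = np.zeros(n_sites, dtype=np.int32)
    return u[a], u[b], n_het1


def _het1_log_matrix(f: np.ndarray) -> np.ndarray:
    """log P(G=1 | f_a, f_b) on the product grid."""
    fa = f[:, None]
    fb = f[None, :]
    return np.log(np.clip(fa * (1 - fb) + fb * (1 - fa), _EPS, None))


class _PairKernel:
    """Cache of exp(n1 * L1) coupling matrices, one per heterozygote count."""

    def __init__(self, f: np.ndarray):
        self.L1 = _het1_log_matrix(f)
        self._cache: dict[int, np.ndarray] = {}

    def __call__(self, n1: int) -> np.ndarray:
        if n1 not in self._cache:
            self._cache[n1] = np.exp(n1 * self.L1)
        return self._cache[n1]


def _pair_posteriors(u_a, u_b, n_het1, log_pa, log_pb, kernel: _PairKernel):
    """Normalised marginal posteriors and log-marginals for a site batch."""
    la = u_a + log_pa[None, :]
    lb = u_b + log_pb[None, :]
    ma = la.max(axis=1, keepdims=True)
    mb = lb.max(axis=1, keepdims=True)
    ea = np.exp(la - ma)
    eb = np.exp(lb - mb)
    post_a = np.empty_like(ea)
    post_b = np.empty_like(eb)
    logZ = np.empty(len(ea))
    for n1 in np.unique(n_het1):
        sel = n_het1 == n1
        M = kernel(int(n1))
        pa = ea[sel] * (eb[sel] @ M.T)
        pb = eb[sel] * (ea[sel] @ M)
        Z = pa.sum(axis=1)
        post_a[sel] = pa / np.maximum(Z, _EPS)[:, None]
        post_b[sel] = pb / np.maximum(pb.sum(axis=1), _EPS)[:, None]
        logZ[sel] = np.log(np.maximum(Z, _EPS))
    logZ += ma[:, 0] + mb[:, 0]
    return post_a, post_b, logZ


def site_posterior(
    counts_site: np.ndarray,
    grid: FrequencyGrid,
    kernel: _PairKernel | None = None,
) -> SitePosterior:
    """Joint-then-marginal posterior for one site (any number of involved
    ancestries; the three-ancestry case is contracted on the product grid)."""
    if counts_site.sum() == 0:
        raise ValueError("site has no complete (genotype + ancestry) calls")
    involved = sorted(
        {x for c, p in enumerate(DIPLOID_PAIRS) if counts_site[c].sum() for x in p},
        key=ANCESTRIES.index,
    )
    f = grid.f
    logp = {a: np.log(np.clip(grid.priors[a], _EPS, None)) for a in involved}
    if len(involved) == 1:
        (a,) = involved
        u, _, _ = _separable_logliks(counts_site[None], f, a, a)
        l = u[0] + logp[a]
        m = l.max()
        e = np.exp(l - m)
        Z = e.sum()
        return SitePosterior(
            f=f,
            posteriors={a: e / Z},
            hap_counts=_hap_counts(counts_site),
            log_marginal=float(np.log(Z) + m),
        )
    if len(involved) == 2:
        a, b = involved
        u_a, u_b, n1 = _separable_logliks(counts_site[None], f, a, b)
        kern = kernel or _PairKernel(f)
        pa, pb, logZ = _pair_posteriors(u_a, u_b, n1, logp[a], logp[b], kern)
        return SitePosterior(
            f=f,
            posteriors={a: pa[0], b: pb[0]},
            hap_counts=_hap_counts(counts_site),
            log_marginal=float(logZ[0]),
        )
    # three ancestries: explicit contraction over the product grid
    a, b, c = involved
    L1 = _het1_log_matrix(f)
    terms = {x: np.zeros(len(f)) for x in involved}
    with np.errstate(divide="ignore"):
        lf = np.log(np.clip(f, _EPS, None))
        l1f = np.log(np.clip(1 - f, _EPS, None))
    hom = {0: 2 * l1f, 1: np.log(np.clip(2 * f * (1 - f), _EPS, None)), 2: 2 * lf}
    for x in involved:
        ci = _PAIR_IDX[tuple(sorted((x, x)))]
        for g in (0, 1, 2):
            terms[x] += counts_site[ci, g] * hom[g]
    het = {}
    for x, y in ((a, b), (a, c), (b, c)):
        ci = _PAIR_IDX[tuple(sorted((x, y)))]
        terms[x] += counts_site[ci, 0] * l1f + counts_site[ci, 2] * lf
        terms[y] += counts_site[ci, 0] * l1f + counts_site[ci, 2] * lf
        het[(x, y)] = counts_site[ci, 1]
    la = terms[a] + logp[a]
    lb = terms[b] + logp[b]
    lc = terms[c] + logp[c]
    shift = la.max() + lb.max() + lc.max()
    cube = (
        la[:, None, None] + lb[None, :, None] + lc[None, None, :]
        + het[(a, b)] * L1[:, :, None]
        + het[(a, c)] * L1[:, None, :]
        + het[(b, c)] * L1[None, :, :]
    )
    w = np.exp(cube - shift)
    Z = w.sum()
    return SitePosterior(
        f=f,
        posteriors={
            a: w.sum(axis=(1, 2)) / Z,
            b: w.sum(axis=(0, 2)) / Z,
            c: w.sum(axis=(0, 1)) / Z,
        },
        hap_counts=_hap_counts(counts_site),
        log_marginal=float(np.log(Z) + shift),
    )


# ---------------------------------------------------------------------------
# Monomorphic correction


def monomorphic_correction(
    prior: np.ndarray,
    f: np.ndarray,
    mean_hap_count: float,
    n0: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Undetected-site frequency distribution and detection probability.

    A site at frequency ``f`` on a background sampled with ``H`` haplotypes
    on average escapes detection with probability about ``(1-f)^H``; the
    ``n0`` monomorphic sites are therefore distributed over the grid as
    ``prior(f) (1-f)^H`` (normalised), and the maximisation step averages
    them together with the polymorphic-site posteriors.  Returns
    ``(q, d)``: the undetected-site distribution and the detection
    probability ``d(f) = 1 - (1-f)^H``.
    """
    if n0 < 0:
        raise ValueError("n0 must be >= 0")
    undet = np.power(np.clip(1.0 - f, 0.0, 1.0), mean_hap_count)
    q = prior * undet
    tot = q.sum()
    if n0 > 0 and tot <= 0:
        raise ValueError("no prior mass can remain undetected, but n0 > 0")
    q = q / tot if tot > 0 else q
    return q, 1.0 - undet


# ---------------------------------------------------------------------------
# EM


@dataclass
class EmResult:
    grid: FrequencyGrid
    loglik_trace: list[float]
    site_means: dict[str, np.ndarray]      # NaN where ancestry not involved
    site_ci: dict[str, np.ndarray]         # (n_sites, 2)
    hap_counts: dict[str, np.ndarray]
    polymorphic: np.ndarray                # boolean site filter applied


def em_estimate(
    table: AncestryGenotypeTable,
    n_grid: int = DEFAULT_GRID,
    iters: int = 20,
    n_monomorphic: int = 0,
    ci_level: float = 0.95,
    chunk: int = 4096,
) -> EmResult:
    """Self-consistent estimation of per-ancestry priors and site posteriors.

    Sites with any missing genotype or ancestry call are excluded, as are
    monomorphic sites (their aggregate count may be supplied through
    ``n_monomorphic``).  The marginal log-likelihood is checked to be
    non-decreasing across iterations.  Deterministic.
    """
    counts = _site_class_counts(table)
    complete = counts.sum(axis=(1, 2)) == table.n_individuals
    derived = (counts * np.arange(3)[None, None, :]).sum(axis=(1, 2))
    total_haps = 2 * counts.sum(axis=(1, 2))
    poly = complete & (derived > 0) & (derived < total_haps)
    counts = counts[poly]
    n_sites = len(counts)
    if n_sites == 0:
        raise ValueError("no polymorphic site with complete calls")

    # involved-ancestry signature per site
    pair_present = counts.sum(axis=2) > 0
    inv_mask = np.zeros((n_sites, len(ANCESTRIES)), dtype=bool)
    for c, (a, b) in enumerate(DIPLOID_PAIRS):
        inv_mask[pair_present[:, c], ANCESTRY_INDEX[a]] = True
        inv_mask[pair_present[:, c], ANCESTRY_INDEX[b]] = True

    involved_all = [a for a in ANCESTRIES if inv_mask[:, ANCESTRY_INDEX[a]].any()]
    grid = FrequencyGrid.uniform(involved_all, n_grid)
    f = grid.f
    kernel = _PairKernel(f)

    hap_counts = {a: np.zeros(n_sites, dtype=np.int64) for a in ANCESTRIES}
    for c, (a, b) in enumerate(DIPLOID_PAIRS):
        n = counts[:, c].sum(axis=1)
        hap_counts[a] += n
        hap_counts[b] += n
    mean_haps = {
        a: float(hap_counts[a][inv_mask[:, ANCESTRY_INDEX[a]]].mean())
        if inv_mask[:, ANCESTRY_INDEX[a]].any()
        else 0.0
        for a in involved_all
    }

    sig = [tuple(a for a in ANCESTRIES if inv_mask[s, ANCESTRY_INDEX[a]])
           for s in range(n_sites)]
    groups: dict[tuple, np.ndarray] = {}
    for key in set(sig):
        groups[key] = np.array([s for s in range(n_sites) if sig[s] == key])

    trace: list[float] = []
    site_means = {a: np.full(n_sites, np.nan) for a in involved_all}
    site_ci = {a: np.full((n_sites, 2), np.nan) for a in involved_all}

    for it in range(iters):
        last = it == iters - 1
        post_sum = {a: np.zeros(n_grid) for a in involved_all}
        post_n = {a: 0 for a in involved_all}
        ll = 0.0
        logp = {a: np.log(np.clip(grid.priors[a], _EPS, None)) for a in involved_all}
        for key, idx in groups.items():
            if len(key) <= 2:
                a = key[0]
                b = key[1] if len(key) == 2 else key[0]
                for lo in range(0, len(idx), chunk):
                    sel = idx[lo:lo + chunk]
                    u_a, u_b, n1 = _separable_logliks(counts[sel], f, a, b)
                    if a == b:
                        l = u_a + logp[a][None, :]
                        m = l.max(axis=1, keepdims=True)
                        e = np.exp(l - m)
                        Z = e.sum(axis=1)
                        pa = e / Z[:, None]
                        ll += float(np.sum(np.log(Z) + m[:, 0]))
                        post_sum[a] += pa.sum(axis=0)
                        post_n[a] += len(sel)
                        if last:
                            _store(site_means, site_ci, a, sel, f, pa, ci_level)
                    else:
                        pa, pb, logZ = _pair_posteriors(
                            u_a, u_b, n1, logp[a], logp[b], kernel
                        )
                        ll += float(logZ.sum())
                        post_sum[a] += pa.sum(axis=0)
                        post_sum[b] += pb.sum(axis=0)
                        post_n[a] += len(sel)
                        post_n[b] += len(sel)
                        if last:
                            _store(site_means, site_ci, a, sel, f, pa, ci_level)
                            _store(site_means, site_ci, b, sel, f, pb, ci_level)
            else:
                for s in idx:
                    sp = site_posterior(counts[s], grid, kernel)
                    ll += sp.log_marginal
                    for a, p in sp.posteriors.items():
                        post_sum[a] += p
                        post_n[a] += 1
                        if last:
                            _store(site_means, site_ci, a, np.array([s]), f,
                                   p[None, :], ci_level)
        if not np.isfinite(ll):
            raise ValueError("non-finite EM likelihood")
        # plain EM is monotone in the polymorphic-site likelihood; with the
        # monomorphic correction the M-step targets the corrected objective,
        # so the observed-site likelihood need not increase
        if n_monomorphic == 0 and trace and ll < trace[-1] - 1e-6:
            raise AssertionError(
                f"EM likelihood decreased: {trace[-1]:.6f} -> {ll:.6f}"
            )
        trace.append(ll)
        # maximisation: prior = average site posterior (+ undetected sites)
        for a in involved_all:
            num = post_sum[a].copy()
            den = post_n[a]
            if n_monomorphic > 0 and mean_haps[a] > 0:
                q, _ = monomorphic_correction(
                    grid.priors[a], f, mean_haps[a], n_monomorphic
                )
                num += n_monomorphic * q
                den += n_monomorphic
            if den > 0:
                grid.priors[a] = num / num.sum()

    return EmResult(
        grid=grid,
        loglik_trace=trace,
        site_means=site_means,
        site_ci=site_ci,
        hap_counts={a: hap_counts[a] for a in involved_all},
        polymorphic=poly,
    )


def _store(site_means, site_ci, a, sel, f, post, level):
    site_means[a][sel] = post @ f
    for row, s in enumerate(sel):
        site_ci[a][s] = frequency_ci((f, post[row]), level)


def frequency_ci(posterior: tuple[np.ndarray, np.ndarray], level: float = 0.95):
    """Highest-posterior-density interval on the grid.

    The smallest set of grid points holding mass ``level`` is selected; each
    grid point represents a frequency cell of one grid-step width, so the
    interval spans half a step beyond the extreme selected points (clipped
    to [0, 1])."""
    f, p = posterior
    order = np.argsort(p)[::-1]
    cum = np.cumsum(p[order])
    k = int(np.searchsorted(cum, level)) + 1
    chosen = f[order[:k]]
    half = 0.5 * float(np.median(np.diff(np.sort(f)))) if len(f) > 1 else 0.0
    return (
        float(max(chosen.min() - half, 0.0)),
        float(min(chosen.max() + half, 1.0)),
    )


# ---------------------------------------------------------------------------
# Cross-population differentiation


def ancestry_freq_difference_test(
    table1: AncestryGenotypeTable,
    table2: AncestryGenotypeTable,
    site1: int,
    site2: int,
    ancestry: str,
    priors: FrequencyGrid | None = None,
    n_boot: int = 200,
    seed: int = 0,
    n_tests: int = 1,
) -> dict:
    """Bootstrap test for a per-site frequency difference between the same
    ancestry background of two panels.

    Individuals are resampled within each panel, the single-site posterior
    mean is recomputed under fixed priors, and the raw p-value is the
    two-sided bootstrap p: twice the fraction of replicates in which the
    difference crosses zero (capped at 1, so it is null-uniform); Bonferroni
    adjustment multiplies by ``n_tests``.
    """
    if n_boot < 20:
        raise ValueError("n_boot too small for a meaningful p-value")
    rng = np.random.default_rng(seed)
    if priors is None:
        priors = FrequencyGrid.uniform(ANCESTRIES)

    def site_mean(table, site, cols):
        sub = table.take_individuals(cols)
        c = _site_class_counts(sub.take_sites(np.array([site])))[0]
        if c.sum() == 0:
            return np.nan
        sp = site_posterior(c, priors)
        return sp.mean(ancestry) if ancestry in sp.posteriors else np.nan

    n1, n2 = table1.n_individuals, table2.n_individuals
    point = site_mean(table1, site1, list(range(n1))) - site_mean(
        table2, site2, list(range(n2))
    )
    crosses = 0
    used = 0
    for _ in range(n_boot):
        d = site_mean(
            table1, site1, rng.integers(0, n1, size=n1)
        ) - site_mean(table2, site2, rng.integers(0, n2, size=n2))
        if not np.isfinite(d):
            continue
        used += 1
        if (point >= 0 and d <= 0) or (point < 0 and d >= 0):
            crosses += 1
    p_raw = min(1.0, 2.0 * crosses / max(used, 1))
    return {
        "difference": float(point),
        "p_raw": float(p_raw),
        "p_bonferroni": float(min(1.0, p_raw * n_tests)),
        "n_boot_used": used,
    }
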