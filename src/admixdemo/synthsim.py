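"""Synthetic-data generators emulating the study's inputs.

Every downstream stage (tract fitting, IBD statistics, ascertainment, SFS
demography, EM frequencies) is exercised on data produced here, so the
generators implement the *model assumptions* of the corresponding inference
steps in an independent, sample-path form:

* :func:`simulate_admixed_tracts` — forward Wright-Fisher chromosome
  painting under a time-varying migration history (Poisson crossovers, no
  interference), realised by recursive lineage splitting so only ancestral
  material is tracked.
* :func:`assign_genotypes` — Bernoulli alleles from per-ancestry frequencies
  on the painted backgrounds.
* :func:`inject_phase_switch_errors` — Markov phase-switch errors on the
  phased emission; unphased genotypes and diploid ancestry are untouched.
* :func:`simulate_split_sfs` — per-locus forward binomial propagation of
  allele frequencies through a population tree (infinite sites, mutations
  placed uniformly in time weighted by population size, plus equilibrium
  standing variation at the root), with optional outgroup sampling for
  negative ascertainment.
* :func:`simulate_ibd_sharing` — IBD segments from the sequential Markovian
  approximation to the pairwise coalescent with recombination, realised as
  the thinned point process of recent-coalescence segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    ANCESTRIES,
    ANCESTRY_INDEX,
    AncestralFrequencies,
    AncestryGenotypeTable,
    AncestryTractSet,
    GenomeMap,
    IBDSegmentSet,
    MigrationHistory,
    SplitModel,
    pair_code,
)

__all__ = [
    "simulate_admixed_tracts",
    "assign_genotypes",
    "inject_phase_switch_errors",
    "simulate_split_sfs",
    "simulate_ibd_sharing",
    "SfsSimResult",
]

_CROSSOVER_PER_CM = 0.01  # 1 Morgan^-1


# ---------------------------------------------------------------------------
# Ancestry tract painting


def _paint_chromosome(L_cm: float, mig: MigrationHistory, rng: np.random.Generator):
    """One present-day haplotype of a chromosome, as [(start, end, anc_idx)].

    Recursive lineage splitting: a haplotype standing ``t`` generations ago
    is a fresh migrant chromosome with probability ``M[t]`` (forced at the
    founding), otherwise a crossover mosaic of two independent haplotypes
    standing at ``t + 1``.  Only intervals ancestral to the present-day
    haplotype are propagated; crossovers are Poisson(1/Morgan) within the
    needed intervals with gap parity sampled exactly.
    """
    M = mig.total_inflow
    m = mig.m
    T0 = mig.founding_generation
    out = []

    def recurse(intervals, t):
        if not intervals:
            return
        if t >= T0 or (M[t] > 0 and rng.random() < M[t]):
            w = m[t] / m[t].sum()
            p = int(rng.choice(len(ANCESTRIES), p=w))
            out.extend((a, b, p) for a, b in intervals)
            return
        # meiosis: split needed intervals between the parent's two gametes
        phase = int(rng.integers(2))
        pos = 0.0
        h0, h1 = [], []
        for a, b in intervals:
            gap = a - pos
            if gap > 0 and rng.random() < 0.5 * (1.0 - math.exp(-2.0 * gap * _CROSSOVER_PER_CM)):
                phase ^= 1
            n_x = rng.poisson((b - a) * _CROSSOVER_PER_CM)
            if n_x == 0:
                (h0 if phase == 0 else h1).append((a, b))
            else:
                cuts = np.sort(rng.uniform(a, b, size=n_x))
                edges = np.concatenate([[a], cuts, [b]])
                for k in range(len(edges) - 1):
                    seg = (float(edges[k]), float(edges[k + 1]))
                    if seg[1] > seg[0]:
                        (h0 if phase == 0 else h1).append(seg)
                    phase ^= 1
                phase ^= 1  # undo the trailing flip: phase after b
            pos = b
        recurse(h0, t + 1)
        recurse(h1, t + 1)

    recurse([(0.0, L_cm)], 1)
    out.sort()
    # merge adjacent pieces of equal ancestry
    merged = []
    for a, b, p in out:
        if merged and merged[-1][2] == p and abs(merged[-1][1] - a) < 1e-9:
            merged[-1][1] = b
        else:
            merged.append([a, b, p])
    return merged


def simulate_admixed_tracts(
    mig: MigrationHistory,
    genome: GenomeMap,
    n_diploid: int,
    seed: int,
) -> AncestryTractSet:
    """Forward Wright-Fisher painting of ancestry tracts for a diploid sample."""
    if n_diploid < 1:
        raise ValueError("n_diploid must be >= 1")
    rng = np.random.default_rng(seed)
    rows = {k: [] for k in ("individual", "hap", "chrom", "start_cm", "end_cm",
                            "ancestry")}
    for i in range(n_diploid):
        ind = f"ind{i:03d}"
        for hap in (0, 1):
            for name, L in zip(genome.names, genome.lengths_cm):
                for a, b, p in _paint_chromosome(L, mig, rng):
                    rows["individual"].append(ind)
                    rows["hap"].append(hap)
                    rows["chrom"].append(name)
                    rows["start_cm"].append(a)
                    rows["end_cm"].append(b)
                    rows["ancestry"].append(ANCESTRIES[p])
    return AncestryTractSet(pd.DataFrame(rows), genome)


# ---------------------------------------------------------------------------
# Genotypes on ancestry backgrounds


def ancestry_at_positions(
    tracts: AncestryTractSet, chrom: str, pos_cm: np.ndarray
) -> dict[tuple[str, int], np.ndarray]:
    """Ancestry index of each (individual, hap) at the given positions (-1
    where a position falls outside the haplotype's tracts)."""
    result = {}
    for (ind, hap), grp in tracts.data[tracts.data["chrom"] == chrom].groupby(
        ["individual", "hap"], sort=False
    ):
        grp = grp.sort_values("start_cm")
        ends = grp["end_cm"].to_numpy()
        starts = grp["start_cm"].to_numpy()
        anc = np.array([ANCESTRY_INDEX[a] for a in grp["ancestry"]])
        k = np.searchsorted(ends, pos_cm, side="right")
        ok = (k < len(ends)) & (pos_cm >= starts[np.minimum(k, len(ends) - 1)])
        res = np.where(ok, anc[np.minimum(k, len(anc) - 1)], -1)
        result[(ind, hap)] = res.astype(np.int8)
    return result


def assign_genotypes(
    tracts: AncestryTractSet,
    freqs: AncestralFrequencies,
    site_positions: list[tuple[str, float]] | None,
    seed: int,
) -> AncestryGenotypeTable:
    """Draw diploid genotypes: each haploid allele is Bernoulli(f_p) where p
    is the ancestry of the tract overlapping the site."""
    rng = np.random.default_rng(seed)
    chroms = np.array([c for c, _ in site_positions])
    pos = np.array([p for _, p in site_positions], dtype=float)
    n_sites = len(pos)
    inds = tracts.individuals
    n_ind = len(inds)

    hap_anc = np.full((n_sites, n_ind, 2), -1, dtype=np.int8)
    for chrom in dict.fromkeys(chroms):
        sel = chroms == chrom
        lookup = ancestry_at_positions(tracts, chrom, pos[sel])
        for (ind, hap), anc in lookup.items():
            hap_anc[sel, inds.index(ind), hap] = anc

    f = freqs.freqs  # (n_sites, 3)
    hap_alleles = np.zeros((n_sites, n_ind, 2), dtype=np.int8)
    u = rng.random((n_sites, n_ind, 2))
    for p in range(len(ANCESTRIES)):
        mask = hap_anc == p
        hap_alleles[mask] = (u[mask] < np.broadcast_to(f[:, p, None, None],
                                                       u.shape)[mask]).astype(np.int8)
    missing = np.any(hap_anc < 0, axis=2)
    G = hap_alleles.sum(axis=2).astype(np.int8)
    G[missing] = -1

    A = np.full((n_sites, n_ind), -1, dtype=np.int8)
    valid = ~missing
    lo = np.minimum(hap_anc[..., 0], hap_anc[..., 1])
    hi = np.maximum(hap_anc[..., 0], hap_anc[..., 1])
    for (a, b), code in _PAIR_CODE_BY_IDX.items():
        A[valid & (lo == a) & (hi == b)] = code

    return AncestryGenotypeTable(
        genotypes=G,
        ancestry=A,
        chrom=chroms,
        pos_cm=pos,
        individuals=list(inds),
        hap_alleles=hap_alleles,
        hap_ancestry=hap_anc,
    )


_PAIR_CODE_BY_IDX = {
    tuple(sorted((ANCESTRY_INDEX[a], ANCESTRY_INDEX[b]))): pair_code(a, b)
    for a in ANCESTRIES
    for b in ANCESTRIES
}


def inject_phase_switch_errors(
    table: AncestryGenotypeTable, switch_rate: float, seed: int
) -> AncestryGenotypeTable:
    """Swap haplotype-of-origin labels downstream of Markov switch points.

    Emulates phasing errors: with per-site probability ``switch_rate`` the
    phase flips and stays flipped until the next switch.  Unphased genotypes
    and diploid ancestry are invariant by construction.
    """
    if not (0 <= switch_rate <= 1):
        raise ValueError("switch_rate must be in [0, 1]")
    if table.hap_alleles is None:
        return table
    rng = np.random.default_rng(seed)
    flips = rng.random(table.genotypes.shape) < switch_rate
    state = np.cumsum(flips, axis=0) % 2 == 1
    hap_alleles = table.hap_alleles.copy()
    hap_ancestry = (
        None if table.hap_ancestry is None else table.hap_ancestry.copy()
    )
    hap_alleles[state] = hap_alleles[state][:, ::-1]
    if hap_ancestry is not None:
        hap_ancestry[state] = hap_ancestry[state][:, ::-1]
    return AncestryGenotypeTable(
        genotypes=table.genotypes.copy(),
        ancestry=table.ancestry.copy(),
        chrom=table.chrom,
        pos_cm=table.pos_cm,
        individuals=list(table.individuals),
        pos_bp=table.pos_bp,
        hap_alleles=hap_alleles,
        hap_ancestry=hap_ancestry,
    )


def sample_ancestral_frequencies(
    n_sites: int,
    seed: int,
    fst: float = 0.15,
    f_min: float = 0.005,
    populations: int = len(ANCESTRIES),
) -> AncestralFrequencies:
    """Correlated per-ancestry derived-allele frequencies for variant panels.

    The shared ancestral frequency is drawn from the neutral spectrum
    (density proportional to 1/f on [f_min, 1)); each continental frequency
    is then a Balding-Nichols draw, Beta(g (1-F)/F, (1-g)(1-F)/F), around
    the ancestral value with differentiation ``fst``.
    """
    rng = np.random.default_rng(seed)
    u = rng.random(n_sites)
    g = f_min ** (1.0 - u)  # inverse-CDF of 1/f on [f_min, 1)
    c = (1.0 - fst) / fst
    f = np.empty((n_sites, len(ANCESTRIES)))
    for p in range(len(ANCESTRIES)):
        if p < populations:
            f[:, p] = rng.beta(np.maximum(g * c, 1e-8),
                               np.maximum((1.0 - g) * c, 1e-8))
        else:
            f[:, p] = 0.0
    return AncestralFrequencies(f)


# ---------------------------------------------------------------------------
# Forward SFS simulation


@dataclass
class _Phase:
    """A stretch of generations with a fixed set of populations."""

    t_old: int
    t_young: int
    sizes: dict[str, float]          # diploid sizes
    origins: dict[str, str] = field(default_factory=dict)  # child -> parent


@dataclass
class SfsSimResult:
    """Joint sample SFS plus the per-locus machinery needed for ascertainment."""

    counts: np.ndarray               # joint SFS array over in-model pops
    pop_ids: tuple[str, ...]
    sample_counts: dict[str, np.ndarray]   # per-pop derived counts per locus
    outgroup_counts: np.ndarray | None     # derived counts in outgroup sample
    #: genome-wide mutation rate implied by treating the requested loci as the
    #: full mutation supply of the simulated history (per-generation; anchors
    #: theta when fitting back simulated data)
    mu_l: float = float("nan")

    def joint_sfs(self):
        from .containers import JointSFS

        return JointSFS(counts=self.counts, pop_ids=self.pop_ids)


def _phases_from_split_model(
    model: SplitModel, include_outgroup: bool
) -> list[_Phase]:
    first = model.split_order
    pa, pb = model.later_pair
    og = include_outgroup and model.outgroup_t_gen is not None
    t_out = int(round(model.outgroup_t_gen)) if og else None
    tf = int(round(model.t_found_gen))
    tr = int(round(model.t_recovery_gen))
    t1 = int(round(model.t1_gen))
    t2 = int(round(model.t2_gen))
    N_rec = model.n_recovered

    phases: list[_Phase] = []
    if og and t_out > tf:
        phases.append(
            _Phase(t_out, tf, {"anc": model.n_ancestral,
                               "OUT": model.outgroup_size},
                   origins={"OUT": "anc"})
        )
        phases.append(_Phase(tf, tr, {"anc": model.n_bottleneck,
                                      "OUT": model.outgroup_size}))
    else:
        phases.append(
            _Phase(tf, tr, {"anc": model.n_bottleneck,
                            **({"OUT": model.outgroup_size} if og else {})},
                   origins={"OUT": "anc"} if og else {})
        )
    base = {"OUT": model.outgroup_size} if og else {}
    phases.append(_Phase(tr, t1, {"anc": N_rec, **base}))
    phases.append(
        _Phase(t1, t2,
               {first: model.pop_sizes[first], "anc": N_rec, **base},
               origins={first: "anc"})
    )
    phases.append(
        _Phase(t2, 0,
               {first: model.pop_sizes[first], pa: model.pop_sizes[pa],
                pb: model.pop_sizes[pb], **base},
               origins={pa: "anc", pb: "anc"})
    )
    if model.post_contact is not None:
        phases = _apply_post_contact(phases, model)
    return [ph for ph in phases if ph.t_old > ph.t_young or ph.origins]


def _apply_post_contact(phases: list[_Phase], model: SplitModel) -> list[_Phase]:
    bc = model.post_contact
    t_hi = int(round(bc.start_gen))
    t_lo = int(round(max(bc.start_gen - bc.duration_gen, 0)))
    out = []
    for ph in phases:
        cuts = sorted(
            {ph.t_old, ph.t_young}
            | {t for t in (t_hi, t_lo) if ph.t_young < t < ph.t_old},
            reverse=True,
        )
        for a, b in zip(cuts[:-1], cuts[1:]):
            sizes = dict(ph.sizes)
            if bc.pop_id in sizes and b >= t_lo and a <= t_hi:
                sizes[bc.pop_id] = sizes[bc.pop_id] * bc.severity
            out.append(_Phase(a, b, sizes, ph.origins if a == ph.t_old else {}))
    return out


def _standing_weight(n_root: float) -> float:
    """Expected segregating sites at mutation-drift equilibrium, per unit
    mutation supply: theta * H_{2N-1} with theta = 4N (mu*L == 1)."""
    two_n = max(int(round(2 * n_root)), 2)
    return 4.0 * n_root * (math.log(two_n - 1) + 0.5772156649015329)


def simulate_forward_phases(
    phases: list[_Phase],
    n_root: float,
    n_loci: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-locus final allele frequencies under forward binomial drift.

    Mutation origins are allocated across root standing variation (drawn
    from the 1/k equilibrium) and new single-copy mutations uniform in time,
    weighted by the haploid population sizes (infinite-sites, single origin).
    """
    # mutation-opportunity weights (units: expected sites per unit mu*L)
    weights = [("root", None, _standing_weight(n_root))]
    for k, ph in enumerate(phases):
        for pop, N in ph.sizes.items():
            dur = ph.t_old - ph.t_young
            if dur > 0:
                weights.append((k, pop, 2.0 * N * dur))
    w = np.array([x[2] for x in weights])
    alloc = rng.multinomial(n_loci, w / w.sum())
    mu_l = n_loci / w.sum()

    freqs: dict[str, np.ndarray] = {}
    born = np.zeros(n_loci, dtype=bool)

    # root standing variation: equilibrium 1/k over counts 1..2N-1
    two_n_root = max(int(round(2 * n_root)), 2)
    k_counts = np.arange(1, two_n_root)
    pk = (1.0 / k_counts) / np.sum(1.0 / k_counts)
    n_standing = alloc[0]
    root_pop = phases[0].sizes and list(phases[0].sizes)[0]
    x0 = np.zeros(n_loci)
    if n_standing:
        x0[:n_standing] = rng.choice(k_counts, size=n_standing, p=pk) / two_n_root
        born[:n_standing] = True
    # birth bookkeeping for new mutations
    births: dict[tuple[int, str], np.ndarray] = {}
    cursor = n_standing
    for (k, pop, _), n_mut in zip(weights[1:], alloc[1:]):
        idx = np.arange(cursor, cursor + n_mut)
        births[(k, pop)] = idx
        cursor += n_mut

    # the root-phase population inherits the standing variation
    first_pop = next(iter(phases[0].sizes))
    freqs[first_pop] = x0
    active: dict[str, np.ndarray] = {first_pop: np.flatnonzero(born)}

    for k, ph in enumerate(phases):
        for child, parent in ph.origins.items():
            if child not in freqs:
                freqs[child] = freqs[parent].copy()
                active[child] = active[parent].copy()
        # birth schedule within the phase: cohort indices sorted by generation
        sched: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pop in ph.sizes:
            idx = births.get((k, pop))
            if idx is not None and len(idx):
                gens = rng.integers(ph.t_young, ph.t_old, size=len(idx))
                order = np.argsort(-gens, kind="stable")
                sched[pop] = (gens[order], idx[order])
        cursor_of = {pop: 0 for pop in sched}
        for g in range(ph.t_old, ph.t_young, -1):
            for pop, N in ph.sizes.items():
                two_n = max(int(round(2 * N)), 2)
                if pop in sched:
                    gens, idx = sched[pop]
                    c = cursor_of[pop]
                    c2 = c + np.searchsorted(-gens[c:], -(g - 1), side="right")
                    if c2 > c:
                        newborn = idx[c:c2]
                        if pop not in freqs:
                            freqs[pop] = np.zeros(n_loci)
                            active[pop] = np.empty(0, dtype=np.int64)
                        freqs[pop][newborn] = 1.0 / two_n
                        active[pop] = np.concatenate([active[pop], newborn])
                        cursor_of[pop] = c2
                act = active.get(pop)
                if act is not None and len(act):
                    x = freqs[pop][act]
                    x = rng.binomial(two_n, x) / two_n
                    freqs[pop][act] = x
                    active[pop] = act[(x > 0) & (x < 1)]
    return freqs, mu_l


def simulate_split_sfs(
    model: SplitModel,
    sample_sizes: dict[str, int],
    n_loci: int,
    seed: int,
    outgroup_diploids: int = 0,
) -> SfsSimResult:
    """Per-locus forward Wright-Fisher simulation of the joint SFS.

    ``sample_sizes`` are haploid counts per in-model population; when
    ``outgroup_diploids > 0`` the model must carry an outgroup and per-locus
    outgroup derived counts are returned for negative ascertainment.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    for pop, n in sample_sizes.items():
        if n > 2 * model.pop_sizes[pop]:
            raise ValueError(f"sample size for {pop} exceeds 2N")
    include_og = outgroup_diploids > 0
    if include_og and model.outgroup_t_gen is None:
        raise ValueError("model has no outgroup to ascertain against")
    rng = np.random.default_rng(seed)
    phases = _phases_from_split_model(model, include_outgroup=include_og)
    freqs, mu_l = simulate_forward_phases(phases, model.n_ancestral, n_loci, rng)

    def draw(pop_size, x, n):
        # haplotypes drawn without replacement from the finite population
        two_n = max(int(round(2 * pop_size)), 2)
        k = np.rint(x * two_n).astype(np.int64)
        return rng.hypergeometric(k, two_n - k, n)

    sample_counts = {
        pop: draw(model.pop_sizes[pop], freqs[pop], n)
        for pop, n in sample_sizes.items()
    }
    out_counts = None
    if include_og:
        out_counts = draw(model.outgroup_size or model.n_ancestral,
                          freqs["OUT"], 2 * outgroup_diploids)

    pop_ids = tuple(sorted(sample_sizes))
    shape = tuple(sample_sizes[p] + 1 for p in pop_ids)
    counts = np.zeros(shape)
    np.add.at(counts, tuple(sample_counts[p] for p in pop_ids), 1.0)
    return SfsSimResult(
        counts=counts,
        pop_ids=pop_ids,
        sample_counts=sample_counts,
        outgroup_counts=out_counts,
        mu_l=mu_l,
    )


# ---------------------------------------------------------------------------
# IBD sharing


def tmrca_cutoff_generations(min_len_cm: float) -> float:
    """Length-implied TMRCA ceiling: ancestors older than ~100 / u(M)
    generations contribute essentially no segments of length >= u."""
    return 100.0 / (min_len_cm / 100.0)


def simulate_ibd_sharing(
    ne: float,
    n_diploid: int,
    genome: GenomeMap,
    min_len_cm: float,
    seed: int,
    population_labels: dict[str, str] | None = None,
) -> IBDSegmentSet:
    """IBD segments among all haplotype pairs of distinct individuals.

    Along a chromosome the pairwise TMRCA is piecewise constant with
    breakpoints at rate ``2t`` per Morgan (sequential Markovian coalescent
    with stationary Exp(2Ne) redraws); a constant-TMRCA run with
    ``t <= tau`` (the length-implied recency ceiling) is an IBD segment.
    Runs with TMRCA in ``dt`` start at rate ``2 t f(t) dt`` per Morgan and
    have Exp(2t) lengths, so the reported (length >= u) segments form a
    thinned Poisson process of intensity ``2 t f(t) e^{-2tu} dt`` whose
    starts fall on ``[0, L - u]``; lengths are ``u`` plus an Exp(2t) excess,
    truncated at the chromosome end.  Expected counts per pair decrease
    monotonically in Ne.
    """
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    if min_len_cm <= 0:
        raise ValueError("min_len_cm must be positive")
    rng = np.random.default_rng(seed)
    u_m = min_len_cm / 100.0
    tau = tmrca_cutoff_generations(min_len_cm)
    a = 1.0 / (2.0 * ne) + 2.0 * u_m

    # qualifying-start intensity per Morgan and the TMRCA law of survivors
    tgrid = np.linspace(0.0, tau, 4096)
    dens = tgrid * np.exp(-a * tgrid)  # prop. to 2 t f(t) e^{-2 t u}
    lam_q = (1.0 / ne) * np.trapezoid(dens, tgrid)
    cdf = np.cumsum(dens)
    cdf = cdf / cdf[-1]

    inds = [f"ind{i:03d}" for i in range(n_diploid)]
    chrom_m = np.array(genome.lengths_cm) / 100.0
    pair_i, pair_j = np.triu_indices(n_diploid, k=1)
    hap_combos = [(0, 0), (0, 1), (1, 0), (1, 1)]

    rows = {k: [] for k in ("id1", "hap1", "id2", "hap2", "chrom", "start_cm",
                            "end_cm", "length_cm")}
    n_pairs = len(pair_i)
    for name, L in zip(genome.names, chrom_m):
        span = max(L - u_m, 0.0)
        if span <= 0:
            continue
        counts = rng.poisson(lam_q * span, size=(n_pairs, 4))
        pr, hc = np.nonzero(counts)
        for p, h in zip(pr, hc):
            n_ev = counts[p, h]
            starts = rng.uniform(0.0, span, size=n_ev)
            t = np.interp(rng.random(n_ev), cdf, tgrid)
            lens = u_m + rng.exponential(1.0 / (2.0 * np.maximum(t, 1e-9)))
            ends = np.minimum(starts + lens, L)
            h1, h2 = hap_combos[h]
            for s, e in zip(starts, ends):
                rows["id1"].append(inds[pair_i[p]])
                rows["hap1"].append(h1)
                rows["id2"].append(inds[pair_j[p]])
                rows["hap2"].append(h2)
                rows["chrom"].append(name)
                rows["start_cm"].append(100.0 * s)
                rows["end_cm"].append(100.0 * e)
                rows["length_cm"].append(100.0 * (e - s))
    df = pd.DataFrame(rows)
    if population_labels is not None:
        df["across"] = [
            population_labels.get(a) != population_labels.get(b)
            for a, b in zip(df["id1"], df["id2"])
        ]
    return IBDSegmentSet(df)
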