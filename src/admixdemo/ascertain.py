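"""Negative ascertainment of Native-background variants.

Unphased genotypes make allele-specific ancestry at ancestry-heterozygous
sites uncertain, so instead of attributing alleles, variants are *negatively
ascertained*: any site carrying a derived allele in an outgroup panel
(African/European/Asian backgrounds), or whose only derived observations in
the admixed panel fall in segments without Native ancestry, is discarded.
Surviving sites are treated as lying on the Native background (the
perfect-ascertainment assumption).  European haplotypes still leak a small
number of private variants — overwhelmingly singletons — which is estimated
empirically by running the same scheme on mock all-European pseudo-samples
and subtracted from the Native spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .containers import (
    ANCESTRY_INDEX,
    AncestryGenotypeTable,
    DIPLOID_PAIRS,
    JointSFS,
    SplitModel,
)

__all__ = [
    "AscertainmentResult",
    "negative_ascertainment_filter",
    "singleton_bias_estimate",
    "ascertained_nat_sfs",
    "ascertain_simulated_sfs",
    "bottleneck_equivalence_report",
]

_NAT = ANCESTRY_INDEX["NAT"]
_PAIR_HAS_NAT = np.array([("NAT" in p) for p in DIPLOID_PAIRS])
_PAIR_NAT_COUNT = np.array([sum(x == "NAT" for x in p) for p in DIPLOID_PAIRS])
_PAIR_IS_EUR_EUR = np.array([p == ("EUR", "EUR") for p in DIPLOID_PAIRS])


@dataclass
class AscertainmentResult:
    """Retained sites with their Native haplotype and derived counts."""

    retained_idx: np.ndarray            # indices into the input table
    nat_haplotypes: np.ndarray          # per retained site
    nat_derived: np.ndarray             # per retained site
    removed_by_outgroup: np.ndarray     # site indices
    removed_by_non_nat: np.ndarray      # site indices
    bias_correction: np.ndarray | None = None   # per derived-count class

    def __post_init__(self):
        if np.any(self.nat_derived < 0) or np.any(self.nat_haplotypes < 0):
            raise ValueError("negative counts")
        if np.any(self.nat_derived > self.nat_haplotypes):
            raise ValueError("derived count exceeds NAT haplotypes")


def _nat_counts(table: AncestryGenotypeTable):
    """Per-site NAT haplotypes and NAT-attributed derived alleles.

    Under perfect ascertainment every derived allele of a NAT-carrying
    individual sits on a NAT haplotype, capped by the individual's NAT
    haplotype count.
    """
    G = np.maximum(table.genotypes, 0)
    called = (table.genotypes >= 0) & (table.ancestry >= 0)
    anc = np.clip(table.ancestry, 0, len(DIPLOID_PAIRS) - 1)
    nat_per_ind = np.where(called, _PAIR_NAT_COUNT[anc], 0)
    derived_nat = np.minimum(np.where(called, G, 0), nat_per_ind)
    return nat_per_ind.sum(axis=1), derived_nat.sum(axis=1)


def negative_ascertainment_filter(
    table: AncestryGenotypeTable,
    outgroup_genotypes: list[np.ndarray] | None = None,
) -> AscertainmentResult:
    """Drop sites observed in any outgroup panel or only on non-NAT segments.

    ``outgroup_genotypes`` are per-panel ``(n_sites, n_ind)`` genotype arrays
    on the same site coordinates ("observed" means at least one derived
    allele call, with no frequency threshold).  Idempotent.
    """
    n_sites = table.n_sites
    in_outgroup = np.zeros(n_sites, dtype=bool)
    for og in outgroup_genotypes or []:
        og = np.asarray(og)
        if og.shape[0] != n_sites:
            raise ValueError("outgroup panel has mismatched site coordinates")
        in_outgroup |= (og > 0).any(axis=1)

    called = (table.genotypes >= 0) & (table.ancestry >= 0)
    G = np.where(called, np.maximum(table.genotypes, 0), 0)
    anc = np.clip(table.ancestry, 0, len(DIPLOID_PAIRS) - 1)
    carrier_nat = (G > 0) & _PAIR_HAS_NAT[anc] & called
    carrier_any = (G > 0) & called
    non_nat_only = carrier_any.any(axis=1) & ~carrier_nat.any(axis=1)

    keep = ~in_outgroup & ~non_nat_only & carrier_any.any(axis=1)
    nat_haps, nat_der = _nat_counts(table)
    idx = np.flatnonzero(keep)
    return AscertainmentResult(
        retained_idx=idx,
        nat_haplotypes=nat_haps[idx],
        nat_derived=nat_der[idx],
        removed_by_outgroup=np.flatnonzero(in_outgroup),
        removed_by_non_nat=np.flatnonzero(~in_outgroup & non_nat_only),
    )


def singleton_bias_estimate(
    table: AncestryGenotypeTable,
    outgroup_genotypes: list[np.ndarray] | None,
    n_mock_diploids: int,
    seed: int = 0,
    max_count: int | None = None,
) -> np.ndarray:
    """Expected European leakage per derived-count class.

    Mock all-European pseudo-individuals are assembled per site from the
    genotypes of individuals whose local ancestry there is Eur/Eur; the same
    negative-ascertainment scheme is applied to them, and the surviving
    variant counts per frequency class estimate the bias (dominated by
    singletons) to subtract from the Native spectrum.
    """
    rng = np.random.default_rng(seed)
    called = (table.genotypes >= 0) & (table.ancestry >= 0)
    anc = np.clip(table.ancestry, 0, len(DIPLOID_PAIRS) - 1)
    eur_eur = called & _PAIR_IS_EUR_EUR[anc]
    n_eur = eur_eur.sum(axis=1)
    usable = n_eur >= n_mock_diploids
    if not usable.any():
        raise ValueError(
            f"no site carries {n_mock_diploids} Eur/Eur diploids; "
            f"maximum available is {int(n_eur.max(initial=0))}"
        )
    in_outgroup = np.zeros(table.n_sites, dtype=bool)
    for og in outgroup_genotypes or []:
        in_outgroup |= (np.asarray(og) > 0).any(axis=1)

    max_count = max_count or 2 * n_mock_diploids
    bias = np.zeros(max_count + 1)
    G = np.maximum(table.genotypes, 0)
    for s in np.flatnonzero(usable & ~in_outgroup):
        cols = np.flatnonzero(eur_eur[s])
        chosen = rng.choice(cols, size=n_mock_diploids, replace=False)
        d = int(G[s, chosen].sum())
        if 0 < d <= max_count:
            bias[d] += 1.0
    # rescale per-class leakage to the full panel's site count
    n_used = int((usable & ~in_outgroup).sum())
    n_total = int((~in_outgroup).sum())
    if n_used:
        bias *= n_total / n_used
    return bias


def ascertained_nat_sfs(
    result: AscertainmentResult,
    target_size: int,
    bias: np.ndarray | None = None,
) -> JointSFS:
    """Native-haplotype SFS at a fixed sample size.

    Per-site NAT haplotype counts vary, so each site is hypergeometrically
    projected to ``target_size`` haplotypes; an optional leakage correction
    vector is subtracted and truncated at zero.
    """
    if len(result.retained_idx) == 0:
        return JointSFS(counts=np.zeros(target_size + 1), pop_ids=("NAT",))
    if target_size > result.nat_haplotypes.max(initial=0):
        raise ValueError("target size exceeds the maximum NAT haplotype count")
    counts = np.zeros(target_size + 1)
    j = np.arange(target_size + 1)
    for n, d in zip(result.nat_haplotypes, result.nat_derived):
        if n >= target_size:
            counts += hypergeom.pmf(j, n, d, target_size)
    if bias is not None:
        b = np.zeros(target_size + 1)
        m = min(len(bias), target_size + 1)
        b[:m] = bias[:m]
        counts = np.maximum(counts - b, 0.0)
    return JointSFS(counts=counts, pop_ids=("NAT",))


# ---------------------------------------------------------------------------
# Simulation-facing helpers


def ascertain_simulated_sfs(sim_result) -> JointSFS:
    """Joint SFS of the in-model populations over loci with zero derived
    alleles in the simulated outgroup sample."""
    if sim_result.outgroup_counts is None:
        raise ValueError("simulation carried no outgroup sample")
    keep = sim_result.outgroup_counts == 0
    pops = sim_result.pop_ids
    arr = np.zeros(sim_result.counts.shape)
    np.add.at(arr, tuple(sim_result.sample_counts[p][keep] for p in pops), 1.0)
    return JointSFS(counts=arr, pop_ids=pops)


def bottleneck_equivalence_report(
    truth_model: SplitModel,
    in_sample_haploids: int,
    outgroup_diploids: int,
    n_loci: int,
    seed: int,
    in_pops: tuple[str, str] = ("pop1", "pop2"),
    outgroup_pop: str = "OUT",
    n_starts: int = 3,
) -> dict:
    """The negative-ascertainment validation harness.

    Simulates the truth model, removes every variant observed in the
    outgroup panel, fits the two-population root-bottleneck approximation
    (ancestral size fixed as scale anchor, theta fixed at the simulation's
    known mutation supply), and reports the inferred bottleneck time against
    the outgroup divergence together with the size and in-split biases.
    """
    from . import sfs_demography as sd
    from . import synthsim as ss

    sizes = {p: in_sample_haploids for p in in_pops}
    sizes[outgroup_pop] = 2 * outgroup_diploids
    sim = ss.simulate_split_sfs(truth_model, sizes, n_loci=n_loci, seed=seed)
    keep = sim.sample_counts[outgroup_pop] == 0
    n = in_sample_haploids
    arr = np.zeros((n + 1, n + 1))
    np.add.at(
        arr,
        (sim.sample_counts[in_pops[0]][keep], sim.sample_counts[in_pops[1]][keep]),
        1.0,
    )
    obs = JointSFS(counts=arr, pop_ids=in_pops)
    theta_true = 4.0 * truth_model.n_ancestral * sim.mu_l
    model, ll, theta = sd.fit_two_pop_bottleneck(
        obs,
        fixed={"n_ancestral": truth_model.n_ancestral, "theta": theta_true},
        n_starts=n_starts,
        seed=seed,
    )
    t_out = truth_model.t1_gen
    t_in = truth_model.t2_gen
    return {
        "model": model,
        "loglik": ll,
        "ascertained_segregating": float(obs.total_segregating()),
        "t_bottleneck_gen": model.t_bottleneck_gen,
        "t_outgroup_gen": t_out,
        "bottleneck_vs_outgroup": model.t_bottleneck_gen / t_out,
        "t_split_gen": model.t_split_gen,
        "t_split_vs_truth": model.t_split_gen / t_in,
        "size_vs_truth": {
            in_pops[0]: model.n1 / truth_model.pop_sizes[in_pops[0]],
            in_pops[1]: model.n2 / truth_model.pop_sizes[in_pops[1]],
        },
    }
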