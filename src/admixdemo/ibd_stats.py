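"""IBD-segment statistics: recent effective size and ancestry consistency.

The amount of identity-by-descent sharing between individuals reflects how
recently they share ancestors, hence the recent effective population size:
under a constant-size pairwise coalescent with recombination, the expected
number of IBD segments longer than ``u`` Morgans per haplotype pair is

    E[N >= u]  =  sum_chrom (L_c - u) * (1/Ne) * int_0^tau t e^{-a t} dt,
    a = 1/(2 Ne) + 2 u,

obtained by integrating the per-Morgan rate of recent-coalescence segment
starts (``2 t f(t)``, with ``f`` the Exp(2Ne) TMRCA density) against the
probability ``e^{-2 t u}`` that a segment of TMRCA ``t`` reaches length
``u``; ``tau`` is the length-implied recency ceiling.  The estimator inverts
this strictly decreasing map at the observed mean segments per pair.

Comparing local-ancestry labels on IBD haplotypes measures the mutual
consistency of the two inferences and, through the density of ancestry
switch points, helps date the recombination events that interrupted each
shared haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ANCESTRIES, AncestryTractSet, GenomeMap, IBDSegmentSet
from .synthsim import tmrca_cutoff_generations

__all__ = [
    "expected_segments_per_pair",
    "ibd_ne_from_counts",
    "IbdAncestryRecord",
    "annotate_ibd_ancestry",
    "switch_density_trend",
    "cross_within_summary",
    "non_ibd_control",
]


def expected_segments_per_pair(
    ne: float, min_len_cm: float, genome: GenomeMap
) -> float:
    """Expected IBD segments >= ``min_len_cm`` per haplotype pair at size Ne."""
    u = min_len_cm / 100.0
    tau = tmrca_cutoff_generations(min_len_cm)
    a = 1.0 / (2.0 * ne) + 2.0 * u
    integral = (1.0 - np.exp(-a * tau) * (1.0 + a * tau)) / a**2
    span = sum(max(l / 100.0 - u, 0.0) for l in genome.lengths_cm)
    return span * integral / ne


def ibd_ne_from_counts(
    segments: IBDSegmentSet,
    min_len_cm: float,
    n_pairs: int,
    genome: GenomeMap,
) -> float:
    """Invert the expected-count curve at the observed mean segments/pair.

    Returns ``inf`` when no qualifying segments are observed (the data put
    no upper bound on Ne).
    """
    if min_len_cm <= 0:
        raise ValueError("min_len_cm must be positive")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    obs = len(segments.filter_min_length(min_len_cm)) / n_pairs
    if obs == 0:
        return np.inf

    def gap(log_ne):
        return expected_segments_per_pair(np.exp(log_ne), min_len_cm, genome) - obs

    lo, hi = np.log(2.0), np.log(1e9)
    if gap(lo) < 0:  # more sharing than even Ne=2 predicts
        return 2.0
    if gap(hi) > 0:
        return np.inf
    return float(np.exp(brentq(gap, lo, hi, xtol=1e-10)))


# ---------------------------------------------------------------------------
# Ancestry annotation of IBD segments


@dataclass
class IbdAncestryRecord:
    """An IBD segment with the local-ancestry labels along its two haplotypes."""

    id1: str
    hap1: int
    id2: str
    hap2: int
    chrom: str
    start_cm: float
    end_cm: float
    length_cm: float
    majority_ancestry: str | None
    mismatch_rate: float
    switch_count: int
    missing: bool = False


def _labels_on_span(tracts: AncestryTractSet, ind, hap, chrom, start, end):
    """(boundaries, labels) of ancestry along [start, end) of one haplotype."""
    d = tracts.data
    sub = d[
        (d["individual"] == ind) & (d["hap"] == hap) & (d["chrom"] == chrom)
    ].sort_values("start_cm")
    if not len(sub):
        return None
    s = sub["start_cm"].to_numpy()
    e = sub["end_cm"].to_numpy()
    lab = sub["ancestry"].to_numpy()
    if start < s[0] - 1e-9 or end > e[-1] + 1e-9:
        return None
    keep = (e > start) & (s < end)
    s, e, lab = s[keep], e[keep], lab[keep]
    s[0], e[-1] = start, end
    return list(zip(s, e, lab))


def annotate_ibd_ancestry(
    segments: IBDSegmentSet, tracts: AncestryTractSet
) -> list[IbdAncestryRecord]:
    """Per-segment majority origin, per-haplotype label mismatch and switch
    count on the consensus labeling."""
    records = []
    for row in segments.data.itertuples():
        spans = []
        for ind, hap in ((row.id1, row.hap1), (row.id2, row.hap2)):
            spans.append(
                _labels_on_span(tracts, ind, hap, row.chrom, row.start_cm,
                                row.end_cm)
            )
        if any(sp is None for sp in spans):
            records.append(
                IbdAncestryRecord(
                    row.id1, row.hap1, row.id2, row.hap2, row.chrom,
                    row.start_cm, row.end_cm, row.length_cm,
                    None, np.nan, 0, missing=True,
                )
            )
            continue
        cuts = sorted(
            {row.start_cm, row.end_cm}
            | {s for sp in spans for s, _, _ in sp}
            | {e for sp in spans for _, e, _ in sp}
        )
        lens = np.diff(cuts)
        mids = 0.5 * (np.array(cuts[:-1]) + np.array(cuts[1:]))

        def label_at(sp, x):
            for s, e, lab in sp:
                if s - 1e-9 <= x < e + 1e-9:
                    return lab
            return sp[-1][2]

        l1 = np.array([label_at(spans[0], x) for x in mids])
        l2 = np.array([label_at(spans[1], x) for x in mids])
        mismatch = float(np.sum(lens[l1 != l2]) / max(np.sum(lens), 1e-12))
        # consensus labeling: cM-majority label per piece
        consensus = np.where(l1 == l2, l1, l1)  # ties broken toward hap1
        switch = int(np.sum(consensus[1:] != consensus[:-1]))
        totals = {a: float(np.sum(lens[(l1 == a)]) + np.sum(lens[(l2 == a)]))
                  for a in ANCESTRIES}
        majority = max(totals, key=totals.get)
        records.append(
            IbdAncestryRecord(
                row.id1, row.hap1, row.id2, row.hap2, row.chrom,
                row.start_cm, row.end_cm, row.length_cm,
                majority, mismatch, switch,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Switch-density trend


def switch_density_trend(
    records: list[IbdAncestryRecord],
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float]:
    """Slope of ancestry-switch-point density vs IBD length, with a one-sided
    bootstrap p-value (resampling individuals).

    Returns ``(slope, p)`` where ``p`` is the fraction of bootstrap slopes
    <= 0: small values support the prediction that longer (younger) IBD
    segments carry a higher density of post-admixture recombination marks.
    """
    recs = [r for r in records if not r.missing]
    if len(recs) < 10:
        raise ValueError("need at least 10 annotated records")
    lengths = np.array([r.length_cm for r in recs])
    if np.ptp(lengths) <= 0:
        raise ValueError("degenerate record set: all lengths equal")
    dens = np.array([r.switch_count / r.length_cm for r in recs])

    def wls_slope(x, y, w):
        xm = np.average(x, weights=w)
        ym = np.average(y, weights=w)
        return float(
            np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2)
        )

    slope = wls_slope(lengths, dens, lengths)

    # resampling unit: each record is owned by its first-listed individual,
    # so a record is drawn exactly as often as its owner (sharing a record
    # between both members would double-count it and shrink the bootstrap
    # variance)
    inds = sorted({r.id1 for r in recs})
    by_ind = {ind: [] for ind in inds}
    for k, r in enumerate(recs):
        by_ind[r.id1].append(k)
    rng = np.random.default_rng(seed)
    worse = 0
    done = 0
    for _ in range(n_boot):
        chosen = rng.choice(inds, size=len(inds), replace=True)
        idx = np.concatenate([by_ind[i] for i in chosen]).astype(int)
        x, y = lengths[idx], dens[idx]
        if np.ptp(x) <= 0:
            continue
        s = wls_slope(x, y, x)
        done += 1
        if s <= 0:
            worse += 1
    p = worse / max(done, 1)
    return slope, p


# ---------------------------------------------------------------------------
# Composition summaries


def cross_within_summary(
    records: list[IbdAncestryRecord],
    top_k: int,
    across_flags: dict[tuple, bool] | None = None,
) -> dict[str, dict[str, int]]:
    """Origin counts of the ``top_k`` longest within- and across-population
    IBD segments; ranking by cM length with (chrom, start) tie-break."""
    recs = [r for r in records if not r.missing]
    if top_k > len(recs):
        raise ValueError("top_k exceeds the number of records")

    def flag(r):
        if across_flags is None:
            return False
        return across_flags.get((r.id1, r.id2), False)

    out = {}
    for kind, is_across in (("within", False), ("across", True)):
        pool = [r for r in recs if flag(r) == is_across]
        pool.sort(key=lambda r: (-r.length_cm, r.chrom, r.start_cm))
        counts = {a: 0 for a in ANCESTRIES}
        for r in pool[:top_k]:
            if r.majority_ancestry is not None:
                counts[r.majority_ancestry] += 1
        out[kind] = counts
    return out


def non_ibd_control(
    records: list[IbdAncestryRecord], tracts: AncestryTractSet
) -> dict[str, float]:
    """Ancestry composition (cM fractions) of the non-IBD sister haplotypes
    at the loci where the alternate haplotypes are IBD — the background
    control for the composition of the IBD segments themselves."""
    totals = {a: 0.0 for a in ANCESTRIES}
    for r in records:
        if r.missing:
            continue
        for ind, hap in ((r.id1, 1 - r.hap1), (r.id2, 1 - r.hap2)):
            sp = _labels_on_span(tracts, ind, hap, r.chrom, r.start_cm, r.end_cm)
            if sp is None:
                continue
            for s, e, lab in sp:
                totals[lab] += e - s
    tot = sum(totals.values())
    if tot == 0:
        return {a: 0.0 for a in ANCESTRIES}
    return {a: v / tot for a, v in totals.items()}
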