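"""Core domain containers shared across the pipeline.

Genetic distances are handled in centiMorgans (cM) at every public surface;
internal model code converts to Morgans where per-Morgan rates are natural.
Ancestry labels are the three continental sources of the admixed American
populations modelled here: ``NAT`` (Native American), ``EUR`` (European) and
``AFR`` (African).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANCESTRIES = ("NAT", "EUR", "AFR")
ANCESTRY_INDEX = {a: i for i, a in enumerate(ANCESTRIES)}

#: Unordered diploid ancestry pairs, encoded 0..5.
DIPLOID_PAIRS = (
    ("NAT", "NAT"),
    ("NAT", "EUR"),
    ("NAT", "AFR"),
    ("EUR", "EUR"),
    ("EUR", "AFR"),
    ("AFR", "AFR"),
)
PAIR_CODE = {tuple(sorted(p)): c for c, p in enumerate(DIPLOID_PAIRS)}


def pair_code(a: str, b: str) -> int:
    """Code (0..5) for the unordered diploid ancestry pair ``{a, b}``."""
    return PAIR_CODE[tuple(sorted((a, b)))]


# Approximate genetic lengths of the 22 human autosomes, rescaled so the
# genome totals exactly 35 Morgans (3500 cM).
_AUTOSOME_MORGANS = np.array(
    [2.78, 2.63, 2.24, 2.14, 2.04, 1.92, 1.87, 1.70, 1.68, 1.81, 1.58,
     1.75, 1.26, 1.19, 1.41, 1.34, 1.29, 1.17, 1.08, 1.08, 0.62, 0.74]
)
_AUTOSOME_MORGANS = _AUTOSOME_MORGANS * (35.0 / _AUTOSOME_MORGANS.sum())


class InvalidHistoryError(ValueError):
    """Raised for migration histories violating the model invariants."""


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome names and genetic lengths (cM) of the genome analysed.

    Parameters
    ----------
    names, lengths_cm:
        Parallel sequences; lengths must be strictly positive.
    """

    names: tuple[str, ...]
    lengths_cm: tuple[float, ...]

    def __post_init__(self):
        if len(self.names) != len(self.lengths_cm) or not self.names:
            raise ValueError("names and lengths_cm must be non-empty and parallel")
        if any(l <= 0 for l in self.lengths_cm):
            raise ValueError("chromosome lengths must be strictly positive")

    @classmethod
    def default_autosomes(cls) -> "GenomeMap":
        """22 autosomes totalling 35 Morgans (human-autosome scale)."""
        return cls(
            names=tuple(f"chr{i}" for i in range(1, 23)),
            lengths_cm=tuple(float(l) * 100.0 for l in _AUTOSOME_MORGANS),
        )

    @property
    def total_cm(self) -> float:
        return float(sum(self.lengths_cm))

    @property
    def total_morgans(self) -> float:
        return self.total_cm / 100.0

    def length_of(self, name: str) -> float:
        return self.lengths_cm[self.names.index(name)]


class MigrationHistory:
    """Per-generation migrant fractions into the admixed population.

    ``m[t, p]`` is the fraction of the admixed population at generation ``t``
    before present that is replaced by migrants from source ``p`` (column
    order ``NAT, EUR, AFR``).  The founding generation ``T0`` is the largest
    ``t`` with migration, and must satisfy ``sum_p m[T0, p] == 1``: the
    population comes into existence fully made of migrants.  Row 0 and row 1
    must be migration-free (a generation-1 migrant would reach the present
    sample without any opportunity to recombine).
    """

    def __init__(self, m: np.ndarray):
        m = np.asarray(m, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(ANCESTRIES):
            raise InvalidHistoryError("m must be (T0+1, 3)")
        if np.any(m < 0) or np.any(np.isnan(m)):
            raise InvalidHistoryError("migrant fractions must be >= 0")
        totals = m.sum(axis=1)
        nz = np.nonzero(totals > 0)[0]
        if nz.size == 0:
            raise InvalidHistoryError("history has no migration (no founding)")
        t0 = int(nz[-1])
        if not np.isclose(totals[t0], 1.0):
            raise InvalidHistoryError(
                f"founding generation {t0} must have total migrant fraction 1, "
                f"got {totals[t0]:.6f}"
            )
        if np.any(totals[:t0] > 1 + 1e-12):
            raise InvalidHistoryError("total inflow exceeds 1 before founding")
        if t0 < 2 or np.any(totals[:2] > 0):
            raise InvalidHistoryError(
                "migration at generations 0-1 is not permitted (no time to recombine)"
            )
        self.m = m
        self.founding_generation = t0

    @property
    def total_inflow(self) -> np.ndarray:
        """``M[t] = sum_p m[t, p]``."""
        return self.m.sum(axis=1)

    def ancestry_proportions(self) -> np.ndarray:
        """Expected present-day ancestry proportions implied by the history.

        The probability that a present-day lineage entered the population at
        generation ``t`` from source ``p`` is
        ``m[t, p] * prod_{u < t} (1 - M[u])``.
        """
        M = self.total_inflow
        surv = np.concatenate([[1.0], np.cumprod(1.0 - M[:-1])])
        s = self.m * surv[:, None]
        return s.sum(axis=0)

    def entry_distribution(self) -> np.ndarray:
        """Joint distribution ``s[t, p]`` of (entry generation, source)."""
        M = self.total_inflow
        surv = np.concatenate([[1.0], np.cumprod(1.0 - M[:-1])])
        return self.m * surv[:, None]


@dataclass
class AncestryTractSet:
    """Per-haplotype contiguous ancestry segments with genetic coordinates.

    ``data`` columns: ``individual`` (str), ``hap`` (0/1), ``chrom`` (str),
    ``start_cm``, ``end_cm`` (floats, 0-based half-open in genetic
    coordinates), ``ancestry`` (NAT/EUR/AFR).  Segments tile each chromosome
    of each haplotype without gaps or overlaps.
    """

    data: pd.DataFrame
    genome: GenomeMap

    REQUIRED = ("individual", "hap", "chrom", "start_cm", "end_cm", "ancestry")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing tract columns: {sorted(missing)}")

    def validate_tiling(self, atol: float = 5e-4) -> None:
        # default tolerance matches the 4-decimal cM serialization
        """Check gap/overlap-free tiling of every (haplotype, chromosome)."""
        for (_, _, chrom), grp in self.data.groupby(
            ["individual", "hap", "chrom"], sort=False
        ):
            grp = grp.sort_values("start_cm")
            L = self.genome.length_of(chrom)
            starts = grp["start_cm"].to_numpy()
            ends = grp["end_cm"].to_numpy()
            if np.any(ends - starts <= 0):
                raise ValueError("non-positive tract length")
            edges_ok = (
                abs(starts[0]) < atol
                and abs(ends[-1] - L) < atol
                and np.allclose(ends[:-1], starts[1:], atol=atol)
            )
            if not edges_ok:
                raise ValueError(f"tracts do not tile {chrom} without gaps/overlaps")

    @property
    def individuals(self) -> list[str]:
        return list(dict.fromkeys(self.data["individual"]))

    def n_haplotypes(self) -> int:
        return len(self.data.groupby(["individual", "hap"], sort=False))

    def lengths_by_ancestry(self) -> dict[str, np.ndarray]:
        out = {}
        lens = (self.data["end_cm"] - self.data["start_cm"]).to_numpy()
        anc = self.data["ancestry"].to_numpy()
        for a in ANCESTRIES:
            out[a] = lens[anc == a]
        return out

    def subset_individuals(self, individuals: Iterable[str]) -> "AncestryTractSet":
        """Resample/subset by individual, renaming duplicates for bootstrap."""
        frames = []
        for k, ind in enumerate(individuals):
            sub = self.data[self.data["individual"] == ind].copy()
            sub["individual"] = f"bs{k}_{ind}"
            frames.append(sub)
        return AncestryTractSet(
            pd.concat(frames, ignore_index=True)
            if frames
            else self.data.iloc[:0].copy(),
            self.genome,
        )


@dataclass
class AncestralFrequencies:
    """Derived-allele frequencies per source population at each site."""

    freqs: np.ndarray  # (n_sites, 3), columns NAT/EUR/AFR, values in [0, 1]

    def __post_init__(self):
        f = np.asarray(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != len(ANCESTRIES):
            raise ValueError("freqs must be (n_sites, 3)")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("frequencies must lie in [0, 1]")
        self.freqs = f


@dataclass
class AncestryGenotypeTable:
    """Diploid genotypes paired with diploid local-ancestry states.

    Attributes
    ----------
    genotypes:
        ``(n_sites, n_ind)`` int8 array of derived-allele counts 0/1/2;
        -1 where the genotype is missing.
    ancestry:
        ``(n_sites, n_ind)`` int8 array of unordered diploid ancestry pair
        codes (see :data:`DIPLOID_PAIRS`); -1 where no ancestry call.
    chrom, pos_cm:
        Site coordinates (chromosome name, genetic position in cM).
    pos_bp:
        Optional integer physical positions (for VCF round-trips).
    individuals:
        Sample identifiers, one per column.
    hap_alleles, hap_ancestry:
        Optional ``(n_sites, n_ind, 2)`` phased per-haplotype alleles and
        ancestry labels (generator truth / phased emission only; the
        statistical models consume only the unphased fields).
    """

    genotypes: np.ndarray
    ancestry: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    individuals: list[str]
    pos_bp: np.ndarray | None = None
    hap_alleles: np.ndarray | None = None
    hap_ancestry: np.ndarray | None = None

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        a = np.asarray(self.ancestry, dtype=np.int8)
        if g.shape != a.shape:
            raise ValueError("genotypes and ancestry must share shape")
        if np.any((g < -1) | (g > 2)):
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")
        if np.any((a < -1) | (a >= len(DIPLOID_PAIRS))):
            raise ValueError("ancestry codes must be in {-1, 0..5}")
        self.genotypes, self.ancestry = g, a
        self.chrom = np.asarray(self.chrom)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, idx) -> "AncestryGenotypeTable":
        return AncestryGenotypeTable(
            genotypes=self.genotypes[idx],
            ancestry=self.ancestry[idx],
            chrom=self.chrom[idx],
            pos_cm=self.pos_cm[idx],
            individuals=list(self.individuals),
            pos_bp=None if self.pos_bp is None else self.pos_bp[idx],
            hap_alleles=None if self.hap_alleles is None else self.hap_alleles[idx],
            hap_ancestry=None
            if self.hap_ancestry is None
            else self.hap_ancestry[idx],
        )

    def take_individuals(self, cols, names=None) -> "AncestryGenotypeTable":
        cols = list(cols)
        return AncestryGenotypeTable(
            genotypes=self.genotypes[:, cols],
            ancestry=self.ancestry[:, cols],
            chrom=self.chrom,
            pos_cm=self.pos_cm,
            individuals=names or [self.individuals[c] for c in cols],
            pos_bp=self.pos_bp,
            hap_alleles=None
            if self.hap_alleles is None
            else self.hap_alleles[:, cols],
            hap_ancestry=None
            if self.hap_ancestry is None
            else self.hap_ancestry[:, cols],
        )


@dataclass
class IBDSegmentSet:
    """Pairwise IBD segments with cM lengths.

    ``data`` columns: ``id1, hap1, id2, hap2, chrom, start_cm, end_cm,
    length_cm`` and optionally ``across`` (bool: the pair spans two panel
    populations).
    """

    data: pd.DataFrame

    REQUIRED = ("id1", "hap1", "id2", "hap2", "chrom", "start_cm", "end_cm",
                "length_cm")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing IBD columns: {sorted(missing)}")
        if len(self.data):
            if np.any(self.data["length_cm"].to_numpy() <= 0):
                raise ValueError("IBD segment lengths must be positive")
            if np.any(self.data["id1"].to_numpy() == self.data["id2"].to_numpy()):
                raise ValueError("IBD pair members must be distinct individuals")

    def __len__(self) -> int:
        return len(self.data)

    def filter_min_length(self, min_len_cm: float) -> "IBDSegmentSet":
        return IBDSegmentSet(
            self.data[self.data["length_cm"] >= min_len_cm].reset_index(drop=True)
        )


@dataclass
class JointSFS:
    """Joint derived-allele site-frequency spectrum over 1-3 populations.

    ``counts[i1, ..., ik]`` is the (expected or observed) number of sites at
    derived sample counts ``i1..ik``; ``mask`` marks entries excluded from
    likelihoods (at minimum the fixed corners).
    """

    counts: np.ndarray
    pop_ids: tuple[str, ...]
    mask: np.ndarray | None = None
    folded: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != len(self.pop_ids):
            raise ValueError("counts dimensionality must match pop_ids")
        if self.mask is None:
            self.mask = self.default_mask(self.counts.shape)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.counts.shape:
            raise ValueError("mask shape mismatch")

    @staticmethod
    def default_mask(shape) -> np.ndarray:
        """Mask only the absent and fully-fixed corners."""
        mask = np.zeros(shape, dtype=bool)
        mask[(0,) * len(shape)] = True
        mask[tuple(n - 1 for n in shape)] = True
        return mask

    @property
    def sample_sizes(self) -> tuple[int, ...]:
        return tuple(n - 1 for n in self.counts.shape)

    def marginal(self, axis_keep: Sequence[int]) -> "JointSFS":
        axes = tuple(i for i in range(self.counts.ndim) if i not in axis_keep)
        counts = self.counts.sum(axis=axes)
        return JointSFS(
            counts=counts, pop_ids=tuple(self.pop_ids[i] for i in axis_keep)
        )

    def total_segregating(self) -> float:
        return float(self.counts[~self.mask].sum())


@dataclass
class PostContactBottleneck:
    """A fixed (non-inferred) recent bottleneck on one terminal branch."""

    pop_id: str
    start_gen: float      # generations before present at which decline starts
    duration_gen: float
    severity: float       # N_during / N_branch, in (0, 1]

    def __post_init__(self):
        if not (0 < self.severity <= 1):
            raise ValueError("severity must be in (0, 1]")
        if self.duration_gen < 0 or self.start_gen <= 0:
            raise ValueError("bottleneck times must be positive")


@dataclass
class SplitModel:
    """Three-population split model with a founding bottleneck.

    Backward in time: the three panels (sizes ``pop_sizes``) merge pairwise —
    the two later-splitting populations coalesce at ``t2_gen`` into an
    intermediate branch held at the recovered size, which merges with the
    first-splitting population at ``t1_gen``; the single ancestral Native
    branch has size ``r * n_bottleneck`` (the recovered size) back to
    ``t_recovery_gen``, size ``n_bottleneck`` between ``t_recovery_gen`` and
    ``t_found_gen`` (the founding bottleneck), and size ``n_ancestral`` before
    ``t_found_gen``.  Times are in generations before present.

    ``split_order`` names the population that split first.  An optional
    outgroup diverges from the root at ``outgroup_t_gen >= t_found_gen``.
    """

    n_ancestral: float
    t_found_gen: float
    n_bottleneck: float
    t_recovery_gen: float
    r: float
    t1_gen: float
    t2_gen: float
    pop_sizes: dict[str, float]
    split_order: str
    outgroup_t_gen: float | None = None
    outgroup_size: float | None = None
    post_contact: PostContactBottleneck | None = None

    def __post_init__(self):
        if sorted(self.pop_sizes) != sorted(set(self.pop_sizes)):
            raise ValueError("duplicate population ids")
        if len(self.pop_sizes) != 3:
            raise ValueError("exactly three in-model populations required")
        if self.split_order not in self.pop_sizes:
            raise ValueError("split_order must name one of the populations")
        ts = (self.t2_gen, self.t1_gen, self.t_recovery_gen, self.t_found_gen)
        if not all(t > 0 for t in ts) or not all(
            a <= b + 1e-9 for a, b in zip(ts, ts[1:])
        ):
            raise ValueError(
                "need 0 < t2 <= t1 <= t_recovery <= t_found (generations)"
            )
        if min(self.n_ancestral, self.n_bottleneck, *self.pop_sizes.values()) <= 0:
            raise ValueError("population sizes must be positive")
        if self.r < 1:
            raise ValueError("recovery ratio r must be >= 1")
        if self.outgroup_t_gen is not None and self.outgroup_t_gen < self.t_found_gen:
            raise ValueError("outgroup must split at or before the founding bottleneck")

    @property
    def n_recovered(self) -> float:
        return self.r * self.n_bottleneck

    @property
    def later_pair(self) -> tuple[str, str]:
        return tuple(p for p in sorted(self.pop_sizes) if p != self.split_order)


GENERATION_YEARS = 30.0


def generations_from_years(years: float, gen_years: float = GENERATION_YEARS) -> float:
    return years / gen_years


def years_from_generations(gens: float, gen_years: float = GENERATION_YEARS) -> float:
    return gens * gen_years
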