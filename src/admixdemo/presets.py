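"""Study-condition presets: the migration histories, demographic models and
sample sizes the recovery analyses are run under.

Reference quantities (admixture onsets, the CLM second Native pulse, the
IBD-based PUR size, split-scenario times, the MXL effective size and the
32-fold MXL/PUR ratio, panel sizes, the 16,000-year founding anchor at 30
years/generation) serve as generating truths for the recovery studies;
quantities without an established reference (founding ancestry fractions,
continuing-migration rates, the CLM branch size, desk-scale harness
population sizes) are fixed here once and documented in the methods note.
"""

from __future__ import annotations

import numpy as np

from .containers import GenomeMap, MigrationHistory, SplitModel
from .tracts_model import FAMILIES

# panel sizes with local-ancestry calls
N_DIPLOID = {"MXL": 68, "CLM": 66, "PUR": 64}

# --- ancestry-tract migration histories ------------------------------------

#: MXL: simultaneous three-way onset 15.1 generations ago with continuing
#: European and Native inflow.
MXL_TRACTS_FAMILY = "founding_plus_continuing"
MXL_TRACTS_PARAMS = np.array([15.1, 0.40, 0.05, 0.02, 0.02])

#: CLM: three-way founding 13.0 (13.02) generations ago plus a small second
#: Native pulse 4.8 generations ago.
CLM_TRACTS_FAMILY = "founding_plus_second_NAT_pulse"
CLM_TRACTS_PARAMS = np.array([13.02, 0.67, 0.08, 4.8, 0.05])

#: PUR: three-way founding with a second period of European and African
#: migration 6.8 generations ago.
PUR_TRACTS_FAMILY = "two_EUR_two_AFR_pulses"
PUR_TRACTS_PARAMS = np.array([16.0, 0.65, 0.15, 6.8, 0.15, 0.05])


def mxl_history() -> MigrationHistory:
    return FAMILIES[MXL_TRACTS_FAMILY].history(MXL_TRACTS_PARAMS)


def clm_history() -> MigrationHistory:
    return FAMILIES[CLM_TRACTS_FAMILY].history(CLM_TRACTS_PARAMS)


def pur_history() -> MigrationHistory:
    return FAMILIES[PUR_TRACTS_FAMILY].history(PUR_TRACTS_PARAMS)


# --- IBD --------------------------------------------------------------------

IBD_MIN_LEN_CM = 4.0
IBD_NE = {"MXL": 140_000.0, "CLM": 15_000.0, "PUR": 10_000.0}
IBD_N_DIPLOID_PUR = 55  # sequenced PUR individuals


# --- three-population split model -------------------------------------------

#: Native-branch effective sizes: MXL reference value; PUR 32-fold smaller;
#: CLM intermediate (no established reference; set between the two).
SPLIT_POP_SIZES = {"MXL": 64_000.0, "CLM": 15_000.0, "PUR": 2_000.0}
SPLIT_N_ANCESTRAL = 10_000.0
SPLIT_T_FOUND_GEN = 16_000.0 / 30.0     # founding anchor
SPLIT_T_RECOVERY_GEN = 14_000.0 / 30.0
SPLIT_N_BOTTLENECK = 30.0               # recovered size = 100 x 30 = 3,000
SPLIT_T1_GEN = 12_400.0 / 30.0
SPLIT_T2_GEN = 11_900.0 / 30.0
SPLIT_PROJECTED_SIZES = {"MXL": 40, "CLM": 20, "PUR": 10}
SPLIT_SIM_SIZES = {"MXL": 60, "CLM": 30, "PUR": 16}


def split_model() -> SplitModel:
    """The three-population split model with the ascertainment-equivalent
    founding bottleneck, at the documented default parameters."""
    return SplitModel(
        n_ancestral=SPLIT_N_ANCESTRAL,
        t_found_gen=SPLIT_T_FOUND_GEN,
        n_bottleneck=SPLIT_N_BOTTLENECK,
        t_recovery_gen=SPLIT_T_RECOVERY_GEN,
        r=100.0,
        t1_gen=SPLIT_T1_GEN,
        t2_gen=SPLIT_T2_GEN,
        pop_sizes=dict(SPLIT_POP_SIZES),
        split_order="MXL",
    )


# --- negative-ascertainment bottleneck-equivalence harness ------------------

#: Two sister populations diverged 12.1 kya, negatively ascertained against
#: 100 diploids from a population diverged 16.5 kya.  Population sizes are
#: desk-scale: small in-model populations with a much larger outgroup
#: population, keeping the panel close to the perfect-ascertainment regime.
ASCERT_T_IN_GEN = 12_100.0 / 30.0
ASCERT_T_OUT_GEN = 16_500.0 / 30.0
ASCERT_N_INMODEL = 500.0
ASCERT_N_OUTGROUP = 5_000.0
ASCERT_OUTGROUP_DIPLOIDS = 100
ASCERT_SAMPLE_HAPLOIDS = 20
ASCERT_N_LOCI = 2_000_000


def ascertainment_truth_model() -> SplitModel:
    """Constant-size truth for the ascertainment harness: no bottleneck; the
    'outgroup' is carried as the first-splitting in-model population."""
    return SplitModel(
        n_ancestral=ASCERT_N_INMODEL,
        t_found_gen=ASCERT_T_OUT_GEN + 50.0,
        n_bottleneck=ASCERT_N_INMODEL,
        t_recovery_gen=ASCERT_T_OUT_GEN + 10.0,
        r=1.0,
        t1_gen=ASCERT_T_OUT_GEN,
        t2_gen=ASCERT_T_IN_GEN,
        pop_sizes={
            "OUT": ASCERT_N_OUTGROUP,
            "pop1": ASCERT_N_INMODEL,
            "pop2": ASCERT_N_INMODEL,
        },
        split_order="OUT",
    )


def default_genome() -> GenomeMap:
    return GenomeMap.default_autosomes()
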