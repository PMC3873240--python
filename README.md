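# admixdemo

Demographic inference for three-way admixed American populations.

Admixed genomes from the Americas carry three interleaved histories: the
pre-Columbian demography of the Native American ancestors, the timing and
intensity of post-contact European and African migration, and the recent
growth of the admixed populations themselves. `admixdemo` implements the
statistical machinery to read each of these from a different signal, for
population geneticists working with local-ancestry-resolved panels
(Mexican-American, Colombian and Puerto Rican style cohorts with NAT / EUR /
AFR ancestry):

- **Ancestry-tract migration models** (`tracts_model`): the lengths of
  contiguous local-ancestry tracts are phase-type distributed under a Markov
  model whose states are (entry generation, source); a lineage that entered
  `t` generations ago recombines at rate `t − 1` per Morgan. Poisson ML over
  binned tract lengths recovers the onset and magnitude of migration pulses
  and continuing gene flow, with BIC-guided model-family selection and
  bootstrap CIs over individuals.
- **IBD-based recent effective size** (`ibd_stats`): the expected number of
  IBD segments longer than `u` Morgans per haplotype pair under a
  constant-size coalescent,
  `E[N≥u] = Σ_c (L_c − u)(1/Ne)(1 − e^{−aτ}(1+aτ))/a²` with
  `a = 1/(2Ne) + 2u`, is inverted at the observed mean count. Also:
  IBD–ancestry consistency, switch-point density trends, and the continental
  composition of the longest within/across-population segments.
- **Negative ascertainment** (`ascertain`): variants observed in non-Native
  panels, or only on non-Native segments, are discarded; the survivors form a
  Native-background SFS (hypergeometrically projected over variable per-site
  Native sample sizes) with an empirical singleton-leakage correction, plus
  the harness validating that this ascertainment acts like a drastic
  bottleneck at the outgroup divergence.
- **Joint-SFS demography** (`sfs_demography`): a three-population split model
  (ancestral size, founding bottleneck with 100× recovery, two split times,
  three branch sizes) fitted by Poisson composite likelihood over the three
  pairwise spectra, with θ profiled analytically, a deterministic
  frequency-grid diffusion engine with Richardson extrapolation, block
  bootstrap, and physical calibration anchored at a 16,000-year founding (30
  years/generation).
- **EM allele frequencies** (`em_freqs`): ancestry-specific allele
  frequencies from unphased genotypes and diploid local-ancestry calls, via a
  phasing-free genotype likelihood and a self-consistent EM over a 201-point
  frequency grid, with monomorphic-site correction, HPD intervals, and
  bootstrap differentiation tests.
- **Synthetic data** (`synthsim`): forward Wright–Fisher chromosome painting,
  genotypes on ancestry backgrounds with phase-switch errors, per-locus
  forward SFS simulation with outgroup sampling, and IBD sharing under the
  sequential Markov approximation — everything needed to exercise the
  pipeline end to end without external data.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

Simulate ancestry tracts for 68 diploids under a founding-plus-continuing
migration history with onset 15.1 generations ago, and refit it:

```python
import numpy as np
from admixdemo import presets, synthsim, tracts_model as tm

genome = presets.default_genome()              # 22 autosomes, 35 Morgans
family = tm.FAMILIES[presets.MXL_TRACTS_FAMILY]
history = family.history(presets.MXL_TRACTS_PARAMS)   # onset 15.1 ga

tracts = synthsim.simulate_admixed_tracts(history, genome, 68, seed=7)
obs = tm.tract_histogram(tracts, tm.default_bins(genome))
fit = tm.fit_tracts_model(obs, family, n_starts=10, seed=3)
print({k: round(v, 3) for k, v in zip(fit.param_names, fit.params)})
print("loglik", round(fit.loglik, 1), "BIC", round(fit.bic, 1))
```

prints

```
{'t_onset': 15.461, 'f_eur': 0.433, 'f_afr': 0.051, 'm_eur': 0.021, 'm_nat': 0.024}
loglik -332.5 BIC 716.5
```

— the refitted onset (15.5 generations ≈ 460 years at 30 years/generation)
recovers the generating 15.1 within this single replicate's sampling noise,
the founding African fraction (0.051) is essentially exact, and the
continuing European/Native inflow rates (0.021/0.024 per generation) match
the generating 0.02; averaging refits over 20 simulation seeds centres the
onset on the truth. The same pattern runs for IBD
(`synthsim.simulate_ibd_sharing` → `ibd_stats.ibd_ne_from_counts`), for the
SFS (`synthsim.simulate_split_sfs` → `sfs_demography.fit_split_model` →
`calibrate_physical`), and for the EM (`synthsim.assign_genotypes` →
`em_freqs.em_estimate`).

A thin CLI wraps the same functions:

```bash
admixdemo simulate tracts --config config.yaml --seed 1 --out out/
admixdemo fit-tracts --tracts out/tracts.tsv --family founding_plus_continuing \
    --seed 2 --out out/
admixdemo ibd-stats --ibd out/ibd.tsv --min-cm 4 --n-diploid 55 --out out/
```

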