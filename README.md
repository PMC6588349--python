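# tmdlab

Analysis pipeline for single-molecule and live-cell studies of receptor
transmembrane-domain (TMD) dimerization and allosteric modulation, of the kind
used to characterize metabotropic glutamate receptor 2 (mGluR2). It covers
four quantitative workflows, each paired with a synthetic-data generator with
known ground truth so every stage is testable without raw recordings:

1. **Photobleaching subunit counting** — detect discrete bleaching steps in
   per-spot fluorescence traces from single-molecule pulldown (SiMPull)
   movies, and summarize step-count distributions per movie and condition.
2. **Stoichiometry inference** — convert observed step-count distributions
   into monomer/dimer fractions through a binomial labeling-efficiency model,
   by closed form or full maximum likelihood with profile-likelihood
   confidence intervals.
3. **Live-cell FRET pharmacology** — ratiometric FRET from donor/acceptor
   channel pairs, baseline normalization, drug-response plateau amplitudes,
   Hill dose–response fits, and 10–90% response kinetics.
4. **Bilayer-modification quench rates** — stretched-exponential fits of
   stopped-flow Tl⁺ quench traces and control-normalized quench rates that
   report drug effects on lipid bilayer properties.

## The core model

A fluorescently labeled complex with `n` subunits bleaches in at most `n`
discrete steps, but each subunit carries a functional fluorophore only with
labeling efficiency `p` (≈ 0.8 for SNAP-tag labeling). Among *visible* spots
(≥ 1 fluorophore), a mixture with dimer fraction `f` shows two-step bleaching
with probability

    θ₂ = f·p² / (f·(2p − p²) + (1 − f)·p),

which inverts in closed form to

    f = θ₂ / (p + θ₂·(p − 1)).

Chance colocalization of an extra labeled molecule in the same
diffraction-limited spot (probability `b` ≈ 5–10%) promotes a spot's apparent
category by one step (1→2, 2→3+), setting the two-step background floor seen
for purely monomeric receptors. Downstream modules implement

* FRET = I_A / (I_D + I_A), normalized to the pre-drug baseline,
* Hill fits r(c) = Emax·cⁿ/(cⁿ + EC50ⁿ),
* 10–90% transition times (τ·ln 9 for a single exponential),
* % inverse agonism = 100·I_NAM/(I_NAM + I_Glu),
* stretched-exponential quench F(t) = F∞ + (F0 − F∞)·exp{−(t/τ₀)^β} with
  Rate = (β/τ₀)·(t/τ₀)^(β−1) evaluated at 2 ms.

## Worked example

Simulate a 5,000-spot SiMPull cohort at a true dimer fraction of 60% with 80%
labeling, count bleaching steps, and re-infer the dimer fraction:

```python
from tmdlab.pipeline import SimPullRunConfig, run_simpull_pipeline

bundle = run_simpull_pipeline(SimPullRunConfig(
    n_spots=5000, f_dimer=0.60, p=0.80, b=0.0, snr=5.0, seed=1))
print(round(100 * bundle["f_dimer_hat"], 1),
      [round(100 * x, 1) for x in (bundle["ci_low"], bundle["ci_high"])])
print(bundle["pooled_counts"])
```

prints

```
57.3 [55.1, 59.4]
{'1': 2879, '2': 2009, '3plus': 0, 'rejected': 112}
```

i.e. 41.1% of accepted spots bleach in two steps, the maximum-likelihood
inversion at p = 0.8 gives a dimer fraction of 57% (95% CI 55–59%), and at
the nearest-ten-percent precision such distributions are reported at, the
cohort reads as ~60% dimers. The same chain is available from a shell:

```sh
tmdlab simulate-simpull --n-spots 5000 --f-dimer 0.6 --seed 1 --out traces.csv
tmdlab count-steps --traces traces.csv --out steps.csv
tmdlab stoichiometry --counts steps.csv --p 0.8 --ml
```

Closed-form arithmetic, no simulation:

```python
from tmdlab import invert_dimer_fraction
print(round(100 * invert_dimer_fraction(0.45, 0.80), 1))   # 63.4
```

A 45% two-step fraction at 80% labeling corresponds to a ~60% dimer
population — the labeling-efficiency correction in action.

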