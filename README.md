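# clawkit

Quantitative analysis of phosphopeptide recognition by the FIP200 claw
domain.

Autophagy receptors dock onto the C-terminal "claw" domain of FIP200
through short FIR/LIR peptide motifs. The mitophagy regulator TNIP1 joins
this competition only after TBK1 phosphorylates its FIR motif (S122/S123):
the phosphopeptide then binds the claw tightly enough to displace receptor
peptides such as the CCPG1 FIR2 phosphopeptide. `clawkit` implements the
computational chain behind this picture for structural biologists and
biophysicists:

* **Single-site ITC isotherm fitting** (`clawkit.itc`) — forward model with
  displaced-volume correction and a weighted least-squares fitter returning
  K_D, N, ΔH with standard errors, ΔG/−TΔS decomposition, and an F-test
  no-binding decision rule for flat isotherms.
* **Three-state competition model** (`clawkit.competition`) — stationary
  occupancies of free/reporter-bound/competitor-bound claw, and the
  displacement laws

      y1(c) = 1 / (1 + a0·c)
      y2(c) = 1 / (1 + a0·exp(ΔE/kB·T)·c)

  where c is the competitor concentration (μM), a0 (μM⁻¹) absorbs the
  reporter-side rates and ΔE (kJ/mol) is the phosphorylation-induced change
  in the dissociation activation barrier. Includes `fit_a0` and curve
  prediction for log-scale displacement plots.
* **Umbrella-sampling post-processing** (`clawkit.wham`) — window-schedule
  construction (the canonical campaign: 0.5 Å spacing from 15–25 Å, 1.0 Å
  from 25–38 Å, 33 windows, 100 ns each = 3300 ns), a self-consistent 1-D
  WHAM solver, profile alignment, dissociation-barrier and ΔE extraction,
  and window-wise bootstrap errors.
* **Structure interface analysis** (`clawkit.structure`) — PDB I/O (gemmi),
  Kabsch superposition/RMSD, per-atom RMSF, hydrogen-bond/salt-bridge/
  hydrophobic-contact detection (phosphoserine aware), pocket listings, and
  plain-text interface reports.
* **Synthetic data** (`clawkit.synthetic`) — seeded generators for every
  input above with ground truth embedded in metadata, so the full pipeline
  is testable offline.

## Worked example

Fit a noisy synthetic titration (true K_D = 10 μM, N = 1, ΔH = −5 kcal/mol,
0.2 μcal heat noise, the 1 μl + 19×2 μl protocol at 20 °C):

```python
from clawkit import synthetic, itc
from clawkit.synthetic import GeneratorConfig

exp = synthetic.gen_itc_titration(10.0, 1.0, -5.0,
                                  GeneratorConfig(seed=1, noise_sd=0.2))
print(itc.fit_single_site(exp).summary())
```

```
Single-site ITC fit
----------------------------------------------
  KD             9.913 +/- 0.19 uM
  N             0.9997 +/- 0.002
  dH            -4.991 +/- 0.014 kcal/mol
  dG            -6.712 kcal/mol
  -TdS          -1.721 kcal/mol
  T              293.1 K
  resid         0.1145 ucal (rms)
```

The fitted K_D sits within two standard errors of the truth; ΔG = RT ln K_D
and −TΔS = ΔG − ΔH complete the thermodynamic decomposition.

Predict displacement of the reporter peptide by unmodified (y1) versus
phosphorylated (y2) competitor at a0 = 0.0006 μM⁻¹ and ΔE = 9.4 kJ/mol,
300 K:

```python
from clawkit import competition
params = competition.CompetitionParams(a0=0.0006, dE=9.4, temperature_K=300.0)
print(competition.predict_displacement_curve(params, [10, 100, 1000, 10000]))
```

```
 conc_uM       y1       y2
    10.0 0.994036 0.793714
   100.0 0.943396 0.277856
  1000.0 0.625000 0.037051
 10000.0 0.142857 0.003833
```

At 100 μM the unmodified competitor barely dents the reporter complex
(y1 = 0.94) while the phosphopeptide strips it to y2 = 0.28 — the
Boltzmann factor exp(ΔE/kBT) ≈ 43 shifts the half-displacement point by
that factor in concentration.

Recover a free-energy profile from umbrella windows and measure the
dissociation barrier with bootstrap errors:

```python
import numpy as np
from clawkit import synthetic, wham
from clawkit.constants import KB_KJ_PER_MOL_K

kT = KB_KJ_PER_MOL_K * 300
pmf = synthetic.double_well_pmf(barrier_kj=9.4)          # planted truth
centers = wham.build_window_schedule([(15, 25, 0.5), (25, 38, 1.0)])
wins = synthetic.gen_umbrella_samples(pmf, centers, 5000,
                                      synthetic.GeneratorConfig(seed=7), kT=kT)
prof, barrier = wham.bootstrap_pmf(wins, kT, n_boot=25, seed=7,
                                   plateau_range=(33, 38))
print(f"barrier = {barrier.barrier:.2f} +/- {barrier.error:.2f} kJ/mol")
```

```
barrier = 8.62 +/- 3.30 kJ/mol
```

The planted 9.4 kJ/mol barrier is recovered within the bootstrap interval;
the sizeable error is real — with a 10,000 kJ mol⁻¹ nm⁻² spring the biased
windows are only ~0.16 Å wide, so the 1.0 Å-spaced outer windows overlap
weakly and the window-to-window free-energy connections are noisy (see
`docs/methods.md`).

A command-line interface mirrors the library:

```sh
clawkit simulate itc --kd 10 --seed 1 --out titr.csv
clawkit itc-fit --in titr.csv --out fit.json
clawkit compete predict --a0 0.0006 --de 9.4 --out curve.csv
clawkit pipeline --seed 4 --outdir run/     # full synthetic end-to-end
```

## Layout

```
src/clawkit/
  constants.py     physical constants, unit conversions
  itc.py           TitrationExperiment, SingleSiteModel/Results
  competition.py   KineticRates, displacement laws, DisplacementModel
  wham.py          UmbrellaWindow, WhamEstimator, barriers, bootstrap
  structure/       PDB model + selections, superposition, contacts
  synthetic.py     seeded generators with embedded ground truth
  cli.py           `clawkit` executable
docs/methods.md    model assumptions, parameter choices, limitations
tests/             pytest suite (unit, property, end-to-end)
```
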