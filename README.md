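# kymoclear

Clearance-front kymograph analysis for single-molecule ssDNA-curtain
motor assays — with a fully ground-truthed synthetic movie generator,
so every stage of the pipeline is testable without raw microscopy data.

## The problem

In a ssDNA curtain assay, long single-stranded DNA molecules are
tethered between a chromium barrier (5' end) and a downstream pedestal,
coated with a fluorescent single-stranded-DNA-binding protein
(RPA-GFP), and imaged by two-color TIRF microscopy. A processive
3'→5' motor protein (such as the DNA polymerase θ helicase domain)
lands on the coated ssDNA and strips the protein coat as it
translocates. The growing protein-free gap is visualized either by a
fluorescent complementary oligonucleotide that tiles the exposed ssDNA
(magenta channel) or by influx of RPA-GFP into gaps cleared in a dark
RAD51 filament (green channel).

The per-molecule observable is a 1-D intensity profile along the
molecule, frame by frame. The analysis sums a 3-px-wide region of
interest, fits each frame's profile with a Gaussian (or a two-edge
Heaviside/boxcar), and reads the cleared extent off the full width at
half maximum (FWHM). From the FWHM(t) series, a continuous
flat–rise–flat changepoint fit yields each motor's

* **velocity** `v` — the slope of the cleared extent over the rising
  phase, in nt/s (one-sided expansion means the FWHM growth rate *is*
  the front speed);
* **processivity** `P` — the terminal plateau extent, in knt, with
  right-censoring for motors still moving at the movie end or squeezed
  against the 5' tether (population quartiles via Kaplan–Meier);
* **polarity** — which edge of the cleared region moves (3'→5' means
  the barrier-side edge recedes).

The package also counts diffraction-limited foci per unit molecule
length, builds photobleaching/influx intensity time courses, links
foci into trajectories (global minimum-cost matching), quantifies DNA
bridge survival (Kaplan–Meier), and fits ensemble EMSA titrations with
the one-site hyperbolic model `f = Bmax·[P]/(Kd+[P])`.

See `docs/methods.md` for the forward model, the PSF correction, and
the estimator design.

## Worked example

Simulate 15 motors drawn from the RPA-condition population (median
velocity 63 nt/s, IQR 28–117; median processivity 3.9 knt, IQR
2.7–5.1), render one two-channel movie per molecule at 15 s/frame and
signal-to-noise ≈ 5, run the full front-fitting pipeline on the
complementary-oligo channel, and summarize:

```python
import kymoclear as kc
from kymoclear.pipeline import condition_sim_config, simulate_and_recover
from kymoclear.simulate import MotorPopulation

pop = MotorPopulation(63.0, (28.0, 117.0), 3.9, (2.7, 5.1), n_motors=15)
config = condition_sim_config("rpa", n_frames=60)
events, summary, truth = simulate_and_recover(pop, config, mode="rpa", seed=42)
print(summary.to_string(index=False))
```

```
   statistic    median        q1        q3  n units
    velocity 59.506642 34.108863 91.293412 10  nt/s
processivity  3.434459  2.374689  4.021173 14   knt
```

The recovered medians sit near the configured 63 nt/s and 3.9 knt; `n`
differs between the two statistics because censored motors keep a
velocity but enter processivity only as a lower bound, and
boundary-limited motors (fronts that ran into the 5' tether) are
excluded from velocity. The `events` table carries one row per motor
with velocity, processivity, polarity, and the censoring flags.

Binding titrations work the same way from generated or measured data:

```python
from kymoclear.simulate import simulate_titration
from kymoclear.binding import fit_hyperbolic

concs = [0.0] + [2.0**k for k in range(10)]          # 0, 1 ... 512 nM
df = simulate_titration(39.0, 1.0, concs, noise_sd=0.03, replicates=3, seed=7)
wide = df.pivot_table(index="replicate", columns="conc_nM", values="fraction_bound")
print(fit_hyperbolic(wide.columns.to_numpy(), wide.to_numpy()).summary())
```

```
One-site hyperbolic binding fit
---------------------------------
replicates:        3
concentrations:    11 (max 512 nM)
Kd:                39 +/- 2.1 nM
Bmax:              0.974 +/- 0.021
converged:         True
```

A `kymoclear` command-line interface wraps the same stages
(`simulate`, `analyze`, `summarize`, `fit-binding`, `fixtures`); every
run writes its resolved configuration and a manifest with seeds and
output digests next to the results.

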