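# phosphenes

Simulation and model-based analysis of phosphene shape in epiretinal
prostheses.

Users of epiretinal implants (Argus I/II) do not see the tidy grid of
focal dots that a "scoreboard" view of the device would predict. Because
the electrode array sits on the nerve fiber layer, stimulation recruits
retinal ganglion cell **axons of passage**; antidromic activation makes
the percept appear at the *somas* of those axons, which lie along
stereotyped arcuate paths to the optic disc. Single-electrode percepts
are therefore often elongated streaks and wedges aligned with the local
fiber bundle. This package implements the full modeling pipeline for that
hypothesis, for researchers analyzing phosphene drawing data or designing
stimulation strategies:

* subject-specific retinal geometry (implant placement, optic-disc
  landmarks, electrode layouts for the 4×4 and 6×10 arrays);
* a spiral model of ganglion axon bundle trajectories,
  `phi(r) = phi0 + b(phi0) (r − r0)^c(phi0)` in a disc-centered polar
  frame, tailored to each eye's landmarks;
* two percept models:
  **scoreboard** `I = exp(−d²/2ρ²)` (isotropic Gaussian, spread ρ) and
  **axon map** `I = max over axon path of exp(−d_elec²/2ρ²)·exp(−d_soma²/2λ²)`
  (decay ρ orthogonal to fibers, λ along them), thresholded at `1/√e`;
* moment-based shape descriptors of binary drawings — area, axial
  orientation θ = ½ atan2(2µ′₁₁, µ′₂₀−µ′₀₂), elongation E = √(1−λ₂/λ₁);
* resampling statistics (within- vs across-electrode SEM consistency,
  orientation-alignment null models NM1/NM2, orientation variance
  explained, elongation–area correlation);
* model fitting by particle swarm optimization with
  leave-one-electrode-out cross-validation and Wilcoxon signed-rank model
  comparison;
* a synthetic-data generator with known ground truth, and drawing/trace
  I/O (touchscreen trace → flood-filled binary mask).

## Worked example

Generate a synthetic subject whose drawings come from a known axon map
(ρ* = 300 µm, λ* = 1000 µm), then fit and compare both models:

```python
import numpy as np
from phosphenes.geometry import Grid
from phosphenes.synth import SynthConfig, generate_dataset
from phosphenes.fit import loeo_cv, compare_models

grid = Grid((-24, 6), (-14, 14), 0.5)          # deg, 0.5 deg/pixel
cfg = SynthConfig(rho=300.0, lam=1000.0, n_electrodes=12, seed=42,
                  phi0_samples=200, axon_step=0.5)
geometry, axon_map, drawings, truth = generate_dataset(cfg, grid)

fit_axon = loeo_cv("axon_map", drawings, axon_map, grid, seed=0)
fit_score = loeo_cv("scoreboard", drawings, None, grid, seed=0)
print(fit_axon.summary)                        # param -> (mean, SEM) across folds
print(np.mean(fit_axon.fold_costs), np.mean(fit_score.fold_costs))
print(compare_models(fit_score, fit_axon)[:2])
```

Output:

```
{'rho': (303.1, 0.9), 'lam': (1035.0, 4.8)}
0.757 11.179
(78.0, 0.00048828125)
```

The cross-validated axon-map fit recovers the generating parameters
(ρ 303 ± 1 µm vs 300; λ 1035 ± 5 µm vs 1000; SEMs across the 12 folds),
and its held-out prediction error (mean cost 0.76, i.e. descriptor R²
close to 1) is an order of magnitude below the scoreboard model's (11.2),
a significant advantage on the paired per-electrode log errors (Wilcoxon
signed-rank statistic 78, p ≈ 5·10⁻⁴, N = 12). The alignment statistics
behave the same way on such data: drawn orientations sit ~19° from the
local bundle tangent where random orientations would sit at 45°
(`orientation_alignment_test`, NM1 p ≈ 0.001).

A command-line interface mirrors the library
(`phosphenes synth | describe | simulate | fit | nulltest | compare`).

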