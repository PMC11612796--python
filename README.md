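# onspv — simulated prosthetic vision for optic-nerve and retinal implants

`onspv` is a Python library and CLI for designing and comparing electrode
layouts for visual neuroprostheses by simulating the percepts they can
elicit. It targets researchers in visual neuroprosthetics and computational
neuroscience who want a quantitative, reproducible way to ask: *given an
electrode array on the optic nerve (or retina), what is the best image a
patient could possibly perceive?*

## The model

Each retinal ganglion cell (RGC) *i* is represented in three linked spaces:

* the **visual field**, by its receptive-field center (ρ<sub>RF</sub>,
  θ<sub>RF</sub>) in degrees and radius σ<sub>RF</sub>;
* the **retina**, by its soma position (ρ<sub>soma</sub>, θ<sub>soma</sub>) in mm;
* the **optic-nerve cross-section**, by its fiber position
  (ρ<sub>fiber</sub>, θ<sub>fiber</sub>) in mm.

A population of 10,000 cells is generated from a single stream of uniform
seed pairs (u<sub>ρ</sub>, u<sub>θ</sub>): fibers fill the nerve section
uniformly (θ = 2π·u<sub>θ</sub>, ρ = R<sub>ON</sub>·√u<sub>ρ</sub>), somas
are drawn from a tabulated RGC density d(ρ, θ) by 2-D inverse-transform
sampling (with the optic-disc ellipse voided of somas), and receptive-field
centers solve the cumulative-count equation
CC<sub>RF</sub>(ρ<sub>RF</sub>, θ) = CC<sub>soma</sub>(ρ<sub>soma</sub>, θ),
which captures the foveal displacement zone. Sharing the seeds across spaces
is what makes the map retinotopic.

Scenes are encoded linearly: cell *i*'s firing rate is the pixelwise product
of the scene with a Gaussian receptive-field image, calibrated so a white
scene drives 300 Hz. An electrode array is a tiling of rectangular cells
with a site at each center; the **partition rule** gives every fiber in a
cell the cell's maximum natural rate if at least 30% of its fibers are
active, else zero. Percepts are reconstructed as
perception ∝ Σ<sub>i</sub> FR<sub>i</sub>·RF<sub>i</sub>, normalized by the
receptive-field coverage of the living population.

On top of this sit degradation operators (local/global fiber shuffling with
a correction procedure, broken electrode sites, encapsulation-tissue fiber
depletion, three fiber-degeneration scenarios), a 31-node biophysical cable
model of optic-nerve fibers under extracellular sinusoidal stimulation
through an anisotropic point-source lead field, synthetic scene/video
generators with depth-to-gray coding, and scoring utilities for
psychophysics-style counting/ordering/classification tasks with
random-answer baselines.

## Worked example

```python
import numpy as np
from onspv import (build_population, check_retinotopy, SceneGeometry,
                   build_rf_stack, encode, best_perception, make_reduced_grid)
from onspv.encoding import reconstruct
from onspv.scenes import generate_static_fixture, colorize_instances, DepthGrayMap

pop = build_population(n=10000, seed=1)
report = check_retinotopy(pop)
print(f"radial retinotopy (mean Kendall tau over 12 sectors): {report['radial_tau_mean']:.3f}")
print(f"angular retinotopy (Kendall tau): {report['angular_tau']:.3f}")

geometry = SceneGeometry(width=320, height=240)
stack = build_rf_stack(pop, geometry)
instances, truth = generate_static_fixture(3, setting="table", seed=1, geometry=geometry)
scene = colorize_instances(instances, DepthGrayMap(setting="table"))

rates = encode(scene, pop, stack)
print(f"active RGCs: {np.sum(rates.rates > 0)} / {pop.n}, peak rate {rates.rates.max():.0f} Hz")

ideal = reconstruct(rates, pop, geometry, stack)
prosthetic = best_perception(scene, pop, make_reduced_grid(), stack=stack)
for name, p in [("encode/reconstruct", ideal), ("148-site optic-nerve grid", prosthetic)]:
    r = np.corrcoef(scene.data.ravel(), p.data.ravel())[0, 1]
    print(f"{name}: pixel correlation with the scene = {r:.3f}")
```

Output:

```
radial retinotopy (mean Kendall tau over 12 sectors): 0.981
angular retinotopy (Kendall tau): 1.000
active RGCs: 3771 / 10000, peak rate 246 Hz
encode/reconstruct: pixel correlation with the scene = 0.961
148-site optic-nerve grid: pixel correlation with the scene = 0.583
```

The retinotopy report confirms the generated map preserves radial and
angular order between retina and nerve. A three-object table scene drives
about a third of the population; reconstructing directly from the natural
rates keeps the scene nearly intact (r = 0.96), while forcing the rates
through the 148-site reduced optic-nerve grid — a 14×14 array whose central
2×2 sub-grids are merged to exploit foveal magnification — still yields a
recognizable percept (r = 0.58).

The same pipeline is scriptable from the shell (`onspv generate-model`,
`onspv best-perception`, `onspv degrade`, `onspv biophys-sim`,
`onspv make-fixtures`, `onspv spv-random`; see `onspv --help`).

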