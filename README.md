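# phaseseg

Multiphase image segmentation by explicit evolution of a scalar phase field,
for grayscale raster images (microscopy, OCR-style binary scans, MRI slices,
synthetic phantoms).  The package is aimed at people who want a small,
fully-inspectable PDE segmenter: every term of the energy, every stencil and
every extraction rule is a plain function with an oracle-backed test.

## The model

A single scalar field φ on the pixel grid encodes K phases through its
integer plateaus: pixels with φ ≈ k belong to phase k, and the half-integer
level sets φ = k + ½ are the segment contours.  Segmentation minimizes a
Mumford–Shah-type energy

```
E(φ) = ∫ [ BiC(⟨φ⟩)/ε² + |∇φ|²/2 + (λ/2) Σₖ (C_k − I₀)² sinc²(φ − k) ] dx
```

where ⟨φ⟩ = φ − ⌊φ⌋, `BiC` is a piecewise-cubic multi-well transition
potential (three selectable variants, including the published five-branch
form and a continuity-repaired B-spline form), ε sets the interface width,
I₀ is the intensity normalized to [0, 1], and

```
C_k = ∫ I₀ sinc²(φ − k) dx / ∫ sinc²(φ − k) dx
```

is the sinc²-weighted mean intensity of phase k — the weighted
least-squares fit value of that phase.  The field evolves by the gradient
descent (Allen–Cahn-type) flow

```
φ_t = −BiC'(⟨φ⟩)/ε² + Δφ − λ Σₖ (C_k − I₀)² d/dφ[sinc²(φ − k)]
```

discretized with a five-point Laplacian, mirrored (Neumann) boundaries, and
either forward Euler (default) or a three-level leapfrog scheme whose stiff
potential term is split across the outer time levels and solved by Picard
iteration.  φ is initialized as K·I₀; after the evolution the label map is
the half-open banding φ ∈ [k − ½, k + ½).  An optional subgrid mode
re-evaluates the potential derivative on an m×m bicubic-interpolated
refinement of the interface cells.

## Worked example

```python
from phaseseg import PhaseFieldSegmentation
from phaseseg.phantoms import PhantomSpec, generate_phantom

image, truth = generate_phantom(PhantomSpec(shape="stripes", n=128, k_phases=3))
res = PhaseFieldSegmentation(image, k_phases=3, dt=2e-6).fit()
print(res.summary())
print("accuracy vs truth:", round(res.accuracy(truth), 4))
```

prints

```
Phase-field segmentation results
==============================================
grid                    128 x 128 (h = 0.0078125)
phases K                3
scheme                  forward_euler
potential               literal_eq2 / double_well_printed
epsilon                 0.00187617
lambda                  30000
dt, steps               2e-06, 10
subgrid                 False (m = 2)
initial energy          7.735718e+03
final energy            6.824178e+03
----------------------------------------------
phase            C_k     area frac
0           0.000446        0.3359
1           0.333435        0.3359
2           0.586173        0.3281
==============================================
accuracy vs truth: 1.0
```

The three stripes are recovered exactly: each `C_k` sits at its stripe's
(sinc²-weighted) intensity, the area fractions are the stripe widths, and
the energy decreased over the ten steps.  `res.labels`, `res.masks`,
`res.phi` and `res.energy_trace` expose the raw arrays; `res.plot()` draws
the contours; `res.save(dir)` writes the label map, binary masks, a contour
overlay and the energy trace as files.

The same pipeline is available from the shell:

```
phaseseg make-phantom --shape disk --n 256 --k 2 --out phantom/
phaseseg segment phantom/phantom.png --k 2 --dt 2e-6 --steps 10 --out seg/
```

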