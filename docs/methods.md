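# Methods

This note records the models, conventions and numerical choices behind
spidiff, and what the synthetic-data tests do and do not establish about
real detector data.

## Geometry and resolution conventions

A detector is a single flat grid of square pixels a distance `L`
downstream of the interaction point. For a pixel at radius `r` from the
point where the forward beam pierces the detector plane, the full
scattering angle is `α = atan(r/L)`, the momentum transfer
`q = (4π/λ) sin(α/2)`, and the resolution

```
d = λ / (2 sin α)
```

— the **half-period (speckle) convention** standard in coherent
diffractive imaging, where one detector speckle samples one half-period
of the largest real-space feature. Under this convention, at 7 keV
(λ = 1.7712 Å, from λ[Å] = 12.3984/E[keV]) with a 217.4 mm camera length
and 110 μm pixels, 6.67 Å corresponds to a radius of 264.75 → 265 pixels.
The crystallographic convention `d = λ/(2 sin(α/2))` would give ≈ 13.3 Å
at the same radius and is **not** used anywhere in the package.

Pixel indices are 0-based `(row, col)`; a pixel's centre sits at integer
coordinates; the beam centre is real-valued and may lie off the grid
(offset detectors). Panel structure is represented only by an integer
label grid and a bad-pixel mask — no per-panel metrology. No polarization
or solid-angle-variation correction is applied before radial analysis:
at the largest in-scope scattering angle (~7.6°) both are sub-percent
effects, consistent with the flat-Ewald approximation used throughout.

## Calibration chain

Raw pixel values follow `A = pedestal + common_mode + γ·k + noise`.

* **Pedestal / read noise**: per-pixel mean and sample standard deviation
  (ddof = 1) over a dark stack; at least two darks required.
* **Common mode**: per-panel median of unmasked pixels below a signal cut
  (default `0.5 γ`, the single-photon decision boundary). The median is
  robust to the sparse photon signal; panels with no sub-threshold pixels
  are left unchanged and flagged. The estimator region (per panel) and
  the cut are design choices — finer per-ASIC regions would need real
  panel metadata.
* **Gain**: per-pixel histogram of pedestal-subtracted flat-field values
  (1 ADU bins over `[−5σ, 2.5·γ_guess]`), fit with a two-Gaussian mixture;
  `γ` is the separation of the fitted means. Fits are rejected (pixel
  masked) when the separation is below `3σ` of the noise peak or the
  optimiser fails. A histogram whose mass occupies exactly two bins (the
  noiseless limit) bypasses the degenerate Gaussian fit and returns the
  exact bin separation. Flat-field occupancy should be ≲ 0.5
  photons/pixel/frame so the 0- and 1-photon peaks dominate.
* **Photonization**: `k = ceil[(A − 0.5γ)/γ]`, placing thresholds halfway
  between photon peaks at `(n + 0.5)γ`. The formula goes negative for
  excursions below `−0.5γ`; counts are clamped at zero, since the Poisson
  model requires `k ≥ 0`. Statistical bad-pixel rejection is subsumed by
  the bad-pixel mask rather than being a separate pipeline stage.

## Expected-photon models

For fluence `Φ` (photons/μm²), classical electron radius `r_e` and
per-pixel solid angle `ΔΩ = (pixel/L)²` (flat approximation),

```
n_i = Φ r_e² ΔΩ |F(q_i)|².
```

* **Homogeneous sphere**: `F(q) = N_e · 3(sin u − u cos u)/u³`, `u = qR`.
  The electron count `N_e` comes from the quoted mass density
  (1.381 g/cm³ default) via 0.53 electrons/dalton, a protein-like
  average; composition being unknown, the absolute intensity scale is a
  convention, and every fit treats fluence as a free parameter that
  absorbs it. The first form-factor zero at `u = 4.4934` puts the first
  fringe minimum of a 71 nm sphere at 77.8 px on the 2.4 m geometry — a
  closed-form anchor used by the tests.
* **Icosahedral blob shell**: twelve identical spherical blobs at the
  vertices of a regular icosahedron, summed coherently with the
  flat-Ewald in-plane `q⃗`. This is a deliberately coarse,
  orientation-dependent synthetic stand-in for a full capsid electron
  density (which would require an atomic model): it preserves exact
  icosahedral symmetry and gives orientation-discriminating patterns,
  but its fringe structure is not that of a real virus. Orientations are
  unit quaternions, sampled uniformly via normalised 4-D Gaussians.

## Shot simulator — what it emulates

Defaults define the study conditions and are not tuned per test:

| parameter | default | rationale |
|---|---|---|
| fluence (median) | 5 × 10¹¹ ph/μm² | ~50–60 photons at the small-angle detector centre for 71 nm — visibly fringed hits |
| ln-fluence sd | 0.3 | SASE shot-to-shot intensity jitter (~30 %) |
| centre drift sd | 0.5 px/axis | the ~1 px beam-pointing drift seen in real runs |
| hit / cluster / dark / flat fractions | 0.10 / 0.02 / 0.05 / 0.02 | sparse-hit injection regime with interleaved calibration frames |
| background | 10⁻³ ph/px | clean post-aperture chamber |
| beamstop | r = 20 px, T = 0.01 | semi-transparent centre stop; uniform transmission, not computed from attenuator material tables |
| pedestal / read noise / gain | 20 / 3 / 33 ADU | photon-counting pixel detector at ~33 ADU/photon |

Clusters are **coherent** sums of k touching spheres displaced along
random directions: an incoherent same-size sum would be
fringe-identical to a single particle and undetectable by any size fit,
whereas coherent inter-particle interference moves power to lower q and
produces the out-of-window effective sizes that cluster rejection relies
on. Simulated detectors are scaled-down monolithic grids (256² vs the
real ~0.14 Mpix array) — all printed-number geometry checks use the real
distances and pixel size, so nothing physical depends on the grid size.
Determinism: one seed per run; frame `i` uses the substream keyed
`(seed, i)`, so frames are independent of evaluation order.

Not emulated: detector saturation and charge sharing, water-layer
scattering (a known potential confounder of the surprise statistic),
per-panel geometry errors, non-uniform beamstop transmission, and the
true capsid density. Passing tests therefore validate the statistical
machinery, not detector-specific systematics.

## Size fitting

Sphere patterns are radially symmetric, so frames are reduced to 1 px
annular bins (masked pixels excluded); sums of Poisson counts are
Poisson, so the binned likelihood is exact. At fixed diameter the fluence
MLE is analytic (`Φ* = Σk_b / Σt_b`), leaving a 1-D profile likelihood
scanned on a 0.5 nm grid over 40–120 nm and refined by bounded scalar
minimisation (tolerance 10⁻³ nm). `converged` is false when the optimum
sits on the search boundary. Goodness of fit is the Poisson deviance of
the binned fit; the single-particle window defaults to the closed
interval [60, 85] nm around the ~71 nm design size. The nominal beam
centre is used for binning; `center_of_intensity` is available as a
per-frame refiner when drift matters. Feeding the fitter real-valued
expected patterns (rather than integer counts) is supported and used for
self-consistency checks — note that *rounding* a noise-free pattern to
integers truncates the weak outer fringes and biases the fit by ~0.2 %,
which is why exactness checks use unrounded patterns.

## Surprise statistic

`S = −Σ log P(n_i, k_i)` in nats (the log base cancels in z). Per-pixel
moments of `log P(n, K)`, `K ~ Poisson(n)`, are computed by truncated
summation over `k = 0..K_max` with `K_max = ⌈n + 12√n + 30⌉`, whose
neglected tail is far below 10⁻¹²; `⟨S⟩` is the summed Poisson entropy
and `σ_S²` the summed per-pixel variance. Conventions for `n = 0`:
the pixel contributes nothing to `⟨S⟩`/`σ_S`, and forces `S = +∞`
(flagged, never hidden) if a photon was observed there; an optional
uniform background floor keeps `S` finite when models predict true
zeros. Minimisation scans a Cartesian (fluence × orientation) grid,
dropping the `ln k!` term during the scan (constant in the model) and
re-scoring the winner exactly; ties break to the first grid point.

The reported z is evaluated at the best-fit (Φ, Ω) — a post-selection
quantity. No selection correction is applied; with 10⁴-pixel frames the
selection bias is far below the N(0,1) width the calibration test
verifies. Two practical points established by the tests: (i) under the
true model z is standard normal to within a few percent; (ii) scoring at
a *fixed* mismatched fluence can drive z negative (an oversized model
expects more photons, and the entropy difference dominates), so
mismatch sensitivity is always assessed at the best-fit fluence — which
is also how per-frame assignments are meant to be used.

## Radial profiles and the signal limit

Annulus membership is by pixel-centre radius in half-open 1 px bins;
empty bins are NaN. The hit-vs-blank limit is the outer edge of the last
run of ≥ 3 consecutive bins with hit > 1.2 × blank (both knobs
configurable; the excess factor quantifies "consistently elevated").
The limit recovers a simulated post-sample aperture to within 2 bins —
except where the aperture coincides with a fringe minimum of the particle
itself, where there is no signal to truncate; the real experiment's
printed limit depends on aperture geometry that is not public, so it is
emulated qualitatively, not reproduced numerically.

## Hit finding

A frame is a hit iff ≥ 50 unmasked pixels carry ≥ 1 photon (both
inclusive, both configurable). On default study conditions this
separates particle frames from blanks and darks essentially perfectly on
a 128² grid; bright flat-field frames also trigger it (they are "lit" by
construction) and are separated downstream by the size fit, as the
worked example shows.

## CXI layout

Frame stacks at `/entry_1/instrument_1/detector_1/data` (chunked by
frame; integer dtype for photons, float for ADU), distance and pixel
size in metres, source energy in joules, per-frame identifiers at
`/entry_1/experiment_identifier` as fixed-width strings compared
lexically, plus a YAML geometry echo for exact round-tripping. Missing
optional metadata reads back as explicit `None`, never a default.
Selections are a single `timestamps` dataset; masks a 2-D dataset with
nonzero = bad.

## Known limitations

* The icosahedral blob shell is a synthetic stand-in; orientation
  recovery rates quoted by the tests are regression targets for this
  model, not statements about real capsids.
* Absolute fluence is a convention (composition unknown); only ratios
  and fitted values are meaningful.
* The gain fitter needs low-occupancy flat-fields and ≥ ~10³ frames per
  pixel for 5 %-level gains; it masks rather than guesses when fits fail.
* Common-mode region granularity, the deposited data's exact dataset
  paths, and the post-sample aperture geometry are not public; the
  package's choices are documented defaults, with a mapping shim
  possible at the I/O boundary if a deposit differs.
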