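# Methods

`tofprofile` integrates Bragg reflections from single-crystal time-of-flight
(TOF) Laue neutron data by fitting a physically factorized three-dimensional
profile to the reciprocal-space event histogram of each predicted peak, with
a traditional spherical peak-minus-background integrator running alongside as
the comparator. This note records the model, its assumptions, the tunable
parameters, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Coordinates and conventions

* Physics convention `|q| = 2π/d`; `q = 2π·UB·(h,k,l)` with **UB** the 3×3
  orientation matrix.
* The incident beam runs along +z. `two_theta` is the polar angle of **q**
  from +z; `phi_az` the azimuth in the laboratory xy plane, in (−π, π].
* Time of flight follows de Broglie: `t = m_n·L·λ/h` with `λ = 2d·sinθ`,
  i.e. `t = (4π·m_n/h)·L·sinθ/|q|`, θ the Bragg half-angle and L the total
  moderator-to-detector flight path of the panel the peak lands on.
* Detector panels are flat rectangles with 0-based (row, col) pixels; the
  scattered-ray direction of a q-vector is the direction of **q** itself
  (a plumbing convention — the synthetic generator and the pipeline share
  it, so it cancels identically).

## The peak model

For each predicted reflection, events are histogrammed over the box
(h±η, k±η, l±η) in fractional hkl (η = 0.25 by default; 0.2–0.5 changes
intensities little) on an odd voxel grid (31³ default) so the prediction is
a voxel center. The model for the voxel counts is

    ψ(v) = A · [ψ_IC(t(v)) × ψ_BVG(φ(v), 2θ(v))] + B

* **Radial/TOF factor** ψ_IC: the Ikeda–Carpenter moderator emission
  density — a fast storage term `(1−R)·(α³t′²/2)e^(−αt′)` plus a slow tail
  `R·[α³β/(α−β)³]·{e^(−βt′) − e^(−αt′)[1+(α−β)t′+½(α−β)²t′²]}`, `t′ = t−t0`
  — convolved with a Gaussian (detector timing, σ_g) and a top-hat (proton
  pulse). It integrates to exactly 1, always has a positive third moment
  (the long high-TOF tail), and requires α > β.
* **Angular factor** ψ_BVG: a bivariate Gaussian in (φ_az, 2θ) with widths
  σ_φ, σ_2θ and correlation ρ (which sets the peak's orientation on the
  detector).
* A and B are obtained by a two-parameter weighted **linear** least squares
  of the voxel counts against the unit-normalized 3D shape — the (2+1)-D
  strategy: two low-dimensional nonlinear fits plus one linear solve instead
  of a full 3D nonlinear fit.

The TOF coordinate of a voxel is computed with the *peak's* Bragg angle held
fixed: `t(v) = (4π m_n/h)·L·sinθ_peak/|q_v|`. This makes the TOF axis a pure
radial (`|q|`) coordinate, so the angular width of the peak cannot leak
dispersion broadening into the emission profile — the factorization stays
exact for a separable peak.

## Energy-dependent moderator parameters

(α, β, R, t0) depend on neutron energy. The dependence is carried as
fourth-order Padé approximants in `x = log10(E/eV)`,
`P(x) = (a0+…+a4x⁴)/(1+b1x+…+b4x⁴)`, valid over 10⁻⁵–100 eV, evaluated at
each peak's de Broglie energy to seed the TOF fit. `fit_pade` builds tables
from sampled parameter curves by linearized least squares.

The shipped default table is **synthetic**: a physically shaped stand-in
whose fast decay rate α rises with energy (pulses get shorter for hotter
neutrons), slow fraction R falls with energy, and β/t0 drift gently. The
curves are themselves rational in x, so the stored coefficients are exact.
Real instruments should drop in their own JSON table (schema in
`ModeratorTable.to_json`). At the reference energies of the synthetic
suites (5–100 meV): α ≈ 0.15–0.3 µs⁻¹, β ≈ 0.009–0.012 µs⁻¹, R ≈ 0.45–0.5,
t0 ≈ 2–2.5 µs.

## Background threshold search

The peak/background boundary is found on the nearest-neighbors smoothed
histogram (3×3×3 box mean with truncated edge neighborhoods): 16 candidate
levels are taken at quantiles (50th–99.5th percentile) of the smoothed
values; at each level the mask is the above-threshold voxels restricted to
the 26-connected component containing (or nearest to) the predicted center,
and the masked TOF histogram is fitted with the *expected* moderator profile
— shape frozen at the Padé seed, only position, Gaussian width, scale and
flat background free. The level whose reduced χ² is closest to 1 wins. A
fitted scale consistent with zero (< 2 standard errors) flags the box as
unfittable — there is nothing above background to integrate.

After the level is chosen, the TOF fit is refined with the decay parameters
free within ±50% of the Padé seed (the moderator characterization is a
starting point, not ground truth, for any particular peak). The proton-pulse
width is an instrument constant and is never fitted.

Two numerical points matter here:

* **Voxel radial window.** Events anywhere in a voxel share the voxel-center
  TOF, a top-hat smearing of width one voxel's radial extent (tens to ~150 µs
  depending on |q| and θ). This is carried as an explicit Gaussian-equivalent
  term σ_vox = extent/√12 inside the broadening model — never fitted — so the
  same smearing enters the TOF fit and the 3D shape evaluation. Without it,
  the sharp IC rise aliases the voxel grid and the fitted A is biased several
  percent at low |q|.
* **Frozen fine grid.** The convolution is evaluated on an oversampled
  uniform grid (≥4× bin density; resolving 1/α, σ, and the pulse width) that
  is constructed once per fit and held fixed, keeping the model smooth in its
  parameters; rebuilding the grid per evaluation makes the numerical Jacobian
  — and therefore every reported standard error — meaningless.

## Angular fit

The angular distribution is fitted on a 2D histogram in (φ_az, 2θ) (50×50
cells over the box's angular extent, radial direction summed). Because the
events were voxelized first, the observed histogram is the BVG *filtered
through the voxel grid* — one voxel's angular footprint spans ≈1.6 cells
here — and evaluating an analytic BVG at cell centers aliases that filter
(χ² ≈ 2–5 and parameter pulls about twice their standard errors, measured on
a 100-peak scene). The pipeline therefore fits the **marginal of the
voxelized 3D model**: the BVG evaluated at voxel centers, weighted by the
fitted radial profile mass and the q-space Jacobians, and binned into the
data's own cells (`fit_bvg_voxel`). The data are full radial column sums
(no mask truncation and no selection on fluctuations), the flat background
scales with the voxel count per cell, and the fit is windowed to the mask's
angular footprint. A second pass reweights by the model (Poisson variances
from the model, floored at one count) — weighting by observed counts biases
the widths low. With this construction χ² ≈ 1 and 99% of width/correlation
recoveries land within 3 standard errors on the strong synthetic suite.

The plain analytic fit (`fit_bvg`) remains available for genuinely 2D data.
Fits with fewer than 25 occupied angular cells raise an insufficient-counts
condition — the trigger for the library-transfer path below.

## 3D scaling, intensity, and error

The normalized shape S(v) multiplies the fitted radial density (with the
|dt/dq_r| ∝ t² Jacobian), the angular density (with the 1/(q² sin2θ)
Jacobian), normalized to unit sum over the box. A and B solve the linear
system by iteratively reweighted least squares with model-based Poisson
weights (three iterations, variances floored at one count; observed-count
weights would bias A low by 10–20% at these count levels). Negative
solutions are clipped to zero and the other parameter refitted. Off-detector
voxels (peaks near panel edges) are excluded from the fit; the model extends
over the full box, which is what recovers truncated intensity.

The intensity follows the 5%-of-maximum voxel rule: with
P = {v : S(v) > 0.05·max S},

    I = A·Σ_P S(v),
    σ²(I) = Σ_P (N_obs(v) + B_est) + σ_A²·(Σ_P S)²,

where B_est is the mean count over detector-accessible voxels outside the
peak mask (flagged if it disagrees with the fitted B by more than 3×). The
cut is applied to the background-subtracted model.

Two documented consequences of this estimator:

* The 5% cut discards model mass **scale-invariantly**: for any bivariate
  Gaussian, exactly 95% of the mass lies above a 5%-of-peak-density cut
  (r²/σ² is χ²₂), and the joint cut with the radial factor keeps
  f = Σ_P S ≈ 0.8–0.9 here. I is therefore a consistent *relative* intensity
  — a common-mode factor absorbed downstream by wavelength scaling — not an
  unbiased estimate of the total count; A is the unbiased total (recovered
  within 3σ_A for >99% of strong synthetic peaks). I also inherits a mild
  voxel-resolution dependence (≈5% between 31³ and 63³) through f, while A
  is stable to ≈1%.
* σ(I) books the full per-voxel Poisson variance plus the full fit variance
  and so over-covers the true replicate scatter of I ≈ f·A (measured
  empirical-to-reported ratio ≈ 0.6): errors are conservative, never
  underestimated.

## Weak and edge peaks: the strong-peak library

Angular shapes vary slowly across the detector, so reflections too weak to
support a free angular fit borrow the shape of a neighbor. Peaks are
classified by their raw spherical-integration event count and their
predicted distance to a panel edge:

| class        | rule                          | angular shape    |
|--------------|-------------------------------|------------------|
| strong       | > 500 events, > 15 px from edge | free fit; enters library |
| intermediate | 250–500 events                | free fit; never enters library |
| weak         | < 250 events                  | nearest library neighbor |
| edge         | ≤ 15 px from a panel edge (any brightness) | nearest library neighbor |

The library stores shape only (σ_φ, σ_2θ, ρ) indexed by (φ_az, 2θ); lookup
is the Euclidean nearest neighbor with azimuthal wrap-around, ties broken
toward more events then lexicographic hkl. At application time the means are
re-centered on the predicted peak position and the TOF direction is fitted
as usual from the moderator characterization. Library entries additionally
require an acceptable angular fit (χ² ≤ 50). Libraries serialize to JSON for
reuse across runs.

## Spherical integration

The comparator sums events in a sphere of radius 0.021 Å⁻¹ about the
prediction and subtracts a background shell (0.022–0.026 Å⁻¹) scaled by the
volume ratio `f = r³/(r_out³ − r_in³)`: `I = N_pk − f·N_sh`,
`σ² = N_pk + f²·N_sh`. An alternate tighter preset (0.018/0.019/0.022 Å⁻¹)
is provided. Counts are exact integers on raw events; a voxelized fallback
uses voxel-center membership. The raw in-sphere count (before subtraction)
is what classifies peaks as weak/strong.

## Rejection filters and output

A reflection survives only if every stage fit has χ² ≤ 50, I/σ(I) ≥ 1 under
**both** methods, and the center is ≥ 2 pixels from a panel edge. Filtering
is method-symmetric, so the profile and spherical reflection files contain
the identical peak set, differing only in intensities and errors. Output is
a SHELX-style fixed-width hkl file (4+4+4+8+8 columns) plus a TSV with full
diagnostics. No merging or wavelength normalization is performed — files are
intended for downstream scaling programs.

## Synthetic data generator

The generator is first-class, tested code: every pipeline stage has a
ground-truth oracle. It emulates

* IC-shaped emission times (tabulated inverse CDF on a 10⁴-point grid),
  plus Gaussian timing jitter (8 µs) and the proton-pulse top-hat (10 µs);
* bivariate-Gaussian angular spread whose widths shrink with scattering
  angle (σ = σ₀/(1+2θ), σ₀ = 0.012/0.010 rad) and whose correlation
  oscillates with azimuth (ρ = 0.4·sin 2φ) — fabricated trends with the
  qualitative behavior of real strong-peak libraries;
* flat Poisson background (0.02 neutrons per 31³-reference voxel);
* detector-edge truncation: events whose ray misses every panel are lost.

Each neutron's measured TOF is the nominal Bragg TOF at its sampled
direction plus its emission delay; the recorded q-vector is what a reduction
package would reconstruct from that TOF — so generator and pipeline agree on
conventions by construction.

The synthetic instrument: cubic 37 Å cell, 40 flat 512×512 panels (0.45 mm
pitch) tangent to a 0.9 m sphere covering 2θ ≈ 0.53–1.95 and φ ≈ ±1.14 with
≈0.035 rad gaps, L = 30.9 m. Standard suites: **strong** (500 peaks,
1000–5000 expected counts), **weak** (200 peaks, 30–250), **edge** (100
bright peaks placed 2–15 px from a panel edge with 10–40% predicted
truncation), **null** (background only). The acceptance script runs reduced
sizes (150/80/60/50) as its own choice of problem size.

What passing these suites does *not* show about real data: the generator
draws from the same parametric families the pipeline fits (no mosaic
asymmetry, no wavelength-dependent flux, no overlapping peaks, no detector
nonuniformity, no instrument-frame misalignment), and the moderator table
used to seed the fits is the table that generated the data, so seed quality
is optimistic. Recovery rates here validate the estimator machinery and its
error model, not the instrument model.

## Known limitations

* Overlapping reflections are not deconvolved; predictions should be checked
  for separation beyond the spherical background shell.
* The intensity I carries the structural ~10–20% 5%-rule deficit discussed
  above; use A when an absolute count estimate is needed.
* Goniometer handling is out of scope: each crystal orientation is an
  independent event list.
* Curved detectors and time-focusing corrections are not modelled.
* The classification boundary at 250 spherical events includes in-sphere
  background; peaks generated near the boundary can classify either way.
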