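# Methods

This note documents the physical model behind the package, the estimator
design, the synthetic-data generator, and the numerical and design choices
that were genuinely open.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Contrast model

A molecule of polarizability `α_m` inside a nanochannel of per-length
polarizability `α_c < 0` (a water channel in silica: the channel is a
*negative* perturbation of its surroundings) scatters coherently with the
channel.  Over a channel segment of length `L = 3π/2k` the collected
intensities are

```
I_c = c I₀ L |α_c|² k³ / 4          (channel alone)
I_m = c I₀ |α_m|² k⁴ / 6π           (molecule alone)
I_t ≈ I_c + I_m − 2√(I_c I_m)
```

so the differential image `I_t − I_c ≈ −2√(I_c I_m)` is *negative* (a dark
dip) and orders of magnitude larger than `I_m` — the channel acts as a
homodyne amplifier.  `nsm.optics.IntensityModel` implements these
identities on an arbitrary intensity scale; since the incident intensity
and collection efficiency of a specific instrument are not constrained
here, `α_c` defaults to a slab-contrast surrogate of magnitude
`A·|n_wall²−n_medium²|/(n_wall²+n_medium²)` and the model is used only for
consistency checks.  The analysis path never depends on absolute
intensities: everything is expressed in *relative* contrast, where the
mass readout

```
MW = iOC · A / (n̄ a),   n̄ = (1.5 n_m² + 0.5 n_w²)/(n_m² − n_w²)
```

needs only the channel area and two refractive indices.  Signs are kept
throughout (`n̄ < 0`, iOC < 0) so that positive mass emerges from the
product; magnitudes are shown at user-facing surfaces.  With
`a = 4.6×10⁻⁴ nm³/Da` the dimensions close: nm · nm² / (nm³/Da) = Da.
The default wavenumber corresponds to 600 nm, the center of the 450–750 nm
illumination band.

## Hindered diffusion

Confinement slows a sphere of radius `R_s` in a pore of equivalent radius
`r = √(A/π)` by the Dechadilok–Deen correlation `K(λ)`, `λ = R_s/r`
(polynomial over `(1−λ)⁻²`).  `K(0) = 1` exactly (the `λ ln λ` term is
handled in the limit) and `K` decreases monotonically on the domain used.
Because the correlation diverges unphysically toward `λ = 1`, the package
enforces a validity cap at `λ = 0.8` (error) and warns above `λ = 0.6`;
the molecules of interest sit at `λ ≲ 0.35`.

Radius from diffusivity is the root of `R − K(R/r)·k_BT/(6πηD) = 0`,
found with Brent's method on `(0, 0.8 r)` to 10⁻⁶ nm; if no root exists
below the cap the conversion fails loudly ("unresolvable confinement")
rather than extrapolating.  Defaults `T = 294.15 K`, `η = 0.978 mPa·s`
(water at 21 °C); all round trips use the same context forward and
backward, so recovered radii are insensitive to this choice.

The empirical globular scaling `R_s = b·MW^(1/3)` uses `b = 0.88 nm` with
MW in kDa — the unit reading that reproduces the literature radii of the
reference proteins (e.g. 0.88·66^(1/3) = 3.56 nm vs 3.5 nm for BSA).

## Synthetic-data generator

The generator emulates the reference recording conditions: 200 frames/s,
per-pixel relative contrast noise 5×10⁻⁵ (0.005 %, the processed-kymograph
level — the raw multi-kHz acquisition and frame averaging upstream of it
are not modeled separately), 15 µm field of view, 30 nm pixel pitch, and a
Gaussian line-spread function of σ = 100 nm (diffraction-limited FWHM
≈ 0.51·λ/NA ≈ 240 nm at λ = 600 nm, NA = 1.27).

Dynamics are overdamped 1-D Brownian motion at the hindered diffusivity,
optionally with drift, integrated in 20 substeps per frame; motion blur is
rendered by averaging the Gaussian profile over the substeps, which
matters because the r.m.s. intra-frame excursion (√(DΔt/3) ≈ 270 nm for
BSA at 5 ms) exceeds the PSF width.  The simulation domain defaults to
twice the field of view, centered, with reflecting ends; the field of view
itself is open — molecules drift in and out of view as in a real channel
much longer than the imaged region.  Transient wall binding is emulated by
freezing the position for a stated frame interval.  Occupancy is sampled
Poisson with mean `c·N_A·A·L` when a concentration is given.

What the generator does *not* emulate: transverse/axial motion (the
channel confines molecules to focus; an optional per-frame multiplicative
contrast jitter, default 0, stands in for residual axial variation),
photon shot noise and absolute radiometry, spatial drift of the
instrument, wall chemistry, and non-spherical diffusion.  Passing tests
therefore demonstrate correctness of the estimators under the stated
noise model, not robustness to every instrumental artifact.

## Preprocessing

Raw movies are collapsed across the channel's short axis (unweighted
mean), the empty-channel background is estimated as the per-pixel temporal
median (optionally in rolling blocks for long recordings with slow
drift), and contrast is `raw/(gain·background) − 1`, where the per-frame
global gain is the mean raw/background ratio over molecule-free pixels
(dips removed by one-sided sigma clipping).  This is exactly invariant to
global per-frame intensity scaling and to any static illumination
profile.  Known failure mode, covered by a test: a molecule stuck at one
position for the majority of frames leaks into the median background; an
occupancy check (fraction of frames far below the per-pixel 90th
percentile) warns when that regime is approached.

## Detection and localization

Each row is matched-filtered with a unit-sum Gaussian template and local
minima below κ = 5 times the filtered noise (robust MAD estimate) are
candidates.  Two details proved essential at 200 fps:

- **Template width.**  The per-frame profile is the PSF convolved with the
  intra-frame path; its width is ≈ √(σ_PSF² + DΔt/3).  Filtering at the
  bare PSF width shatters a fast molecule into several shallow minima.
  The template therefore defaults to the blur-corrected width of the
  fastest configured species, and same-frame minima closer than two
  template widths are merged (non-maximum suppression).

- **Integral, not amplitude.**  The per-frame integrated contrast `ioc_n`
  is a windowed sum (half-width max(800 nm, 5.5 template σ), local
  baseline from the median of a surrounding annulus, window clipped at the
  midpoint to any same-frame neighbor).  The integral is invariant to
  blur, whereas a fixed-σ amplitude fit underestimates iOC by tens of
  percent once the blur width exceeds the PSF.  A fixed-σ Gaussian
  Gauss–Newton fit is still computed and reported (`ioc_fit`) as a
  cross-check; for unblurred dips the two agree.

- **Position = centroid.**  The reported position is the baseline-
  subtracted centroid over the same window (two passes, the second on a
  recentered window).  The centroid is a *linear* functional of the
  contrast, so under motion blur the estimate is the time-averaged path
  plus white noise — precisely the statistics whose biases the CVE's
  covariance term cancels.  A nonlinear shape fit does not have this
  property and measurably biased D low for fast species.  The reported
  `loc_sigma` is the white-noise propagation through the weighted mean.

Candidates within the window half-width of the spatial edges are rejected
so integrals are never truncated; the surviving spatial interval (the
"detection band") is recorded and used below.

## Linking and filtering

Greedy nearest-neighbor linking frame to frame, gate
`4√(2 D_max Δt) + |v|Δt` (scaled by √gap across up to 3 missed frames),
ties broken by smaller displacement then larger |ioc|; each detection used
once.  At the sparse occupancies of interest (≲ 2 molecules per field of
view) ambiguity is rare; globally optimal assignment is out of scope.  In
flow mode the per-frame median displacement is subtracted before gating so
uniformly drifting particles link correctly.  Note that two identical
molecules that actually cross in 1-D are physically indistinguishable; the
zero-switch guarantee applies to molecules that stay farther apart than
the gate.

Trajectories shorter than 50 frames are dropped.  Transient binding is
excised by flagging spans where the rolling (50-point) standard deviation
of the position falls below 3× the median localization uncertainty — a
molecule that moves no more than its localization noise is stuck — and
re-emitting the surviving free segments.

## Per-trajectory estimation

iOC is the mean of `ioc_n`; MW follows from the contrast relation.  D is
the covariance-based estimator, computed only over displacements between
consecutive frames (gaps are skipped in both terms).  Negative estimates
(expected for noise-dominated fragments) are preserved and flagged rather
than truncated, so population means stay unbiased; radius conversion is
then skipped and flagged.  In flow mode the mean displacement is removed
first.

**Edge censoring.**  A displacement is only observed if its endpoint stays
inside the detection band, which censors large outward steps near the
band edges and biases D low for fast molecules (measured −6.6 % for BSA on
ground-truth positions).  When the detection band is known, the CVE
restricts itself to displacements *starting* more than 4 step-sigmas
inside the band, where endpoint censoring is negligible; this removes
most of the bias.  A residual deficit of order −2…−5 % remains for the
fastest species, dominated by blur-dependent detection dropout (the most
blurred frames — which carry the largest displacements — are the ones
that fall below the detection threshold).  This is a property of
finite-field-of-view, finite-exposure tracking itself, not of the
estimator, and is left uncorrected; the validation suite bounds its
effect on recovered population radii at a few percent.

No motion-blur correction term is added to the CVE: with linear
(centroid) localization the printed two-term form is already unbiased
under blur, which the tests verify directly.

## Population statistics

Each trajectory contributes `N_i/ΣN` counts at its estimate, so counts
integrate to exactly 1 and peak masses are relative concentrations.  Bin
width defaults to Freedman–Diaconis on the weighted sample using an
effective sample size `(Σw)²/Σw²`.  Gaussians are fitted by least squares
on the bin centers, initialized at the histogram mode, σ bounded positive;
multi-component fits require explicit initialization (no automatic model
selection).  If fewer than five bins are populated per component the
result falls back to weighted moments with the FWHM floored at one bin
width, and is marked as such.  FWHM = 2√(2 ln 2) σ throughout.

## Validation scenarios and problem sizes

`nsm.scenarios` fixes the reference recovery runs used by the test suite
and the reproduction script: 100 trajectories × 1000 steps for the
CVE/hindrance radius round trip (localization noise 30 nm, simulation
domain enlarged so the reflecting ends are never felt — the scenario
probes the estimator, not wall physics); 200 single-molecule scenes ×
500 frames for the full-pipeline mass recoveries; 300 scenes with lengths
uniform in 500–1100 frames for the resolution run.  The pytest suite runs
reduced versions (100 scenes) of the pipeline scenarios; sizes were chosen
so that sampling error is several times smaller than the tolerances being
checked.

## Known limitations

- Greedy linking; no multiple-hypothesis tracking or global assignment.
- No spatial drift registration or flat-field calibration from reference
  movies; instrument drift is reduced to per-frame global gain.
- The hindrance correlation assumes a hard neutral sphere and no-slip
  walls; slip, electrostatics and shape anisotropy (e.g. DNA, dimers) are
  outside the model — elongated molecules appear at a lower D than a
  globular protein of the same mass, which is observable but not modeled.
- Mass calibration assumes the protein mass polarizability; heterogeneous
  particles (vesicles, lipoproteins) have different and variable `a`, so
  their iOC is reported but not converted to a meaningful mass.
- Overlapping molecules closer than the window midpoint-split can bias
  each other's iOC; the sparse-occupancy regime makes this rare.
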