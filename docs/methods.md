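# Methods

## Model structure and assumptions

The quantity computed is the mean absorbed dose to one islet of
Langerhans, `D_islet = Σ_sources S · τ · A0`. Three sources are modelled
— kidneys, whole pancreas, and the islet itself — because radiolabeled
exendin accumulates almost exclusively in kidney and pancreas; activity
in the remainder of the body is neglected. Assumptions:

1. islets are homogeneously distributed through the pancreas, so the
   surrounding islets and the exocrine tissue can be merged into a
   single uniform "pancreas self-dose" source;
2. the kidney contribution to an islet equals the kidney contribution to
   the pancreas: at that distance only photons arrive, and photon
   absorption does not distinguish islet from exocrine tissue;
3. islets are spheres (50–400 μm) with activity uniform in their volume;
4. the target islet is not removed from the pancreas source, so the
   total is slightly overestimated (the double-counted mass is ~10⁻⁷ of
   the pancreas).

## Decay data

Each nuclide ships as a compact line list (YAML) holding gammas, Auger
and conversion-electron groups (In-111: half-life 67.2 h) and positron
branches (Ga-68: 1.1285 h). Full evaluated-decay-file detail is not
needed: every S-value in the model depends on the energy emitted per
decay per radiation kind, which the condensed groups preserve exactly
(Auger group: 14.7 electrons/decay, 6.75 keV/decay; conversion-electron
group: 0.16 electrons/decay, 26.0 keV/decay distributed over the four
principal K/L conversion energies 145–245 keV). The Auger group keeps
the two dominant discrete energies (8.5 eV, 350 eV) plus one residual
line (3.53 keV) that closes the yield and energy bookkeeping; all three
are far below the sphere sizes of interest in range, so the grouping is
dosimetrically neutral. The 511 keV annihilation photons are carried as
a gamma line with yield 1.78, and positron transport consequently does
not generate annihilation quanta itself.

Positron energies are sampled from the allowed-transition shape
`p·W·(Q−E)²` with a positron Coulomb factor (daughter Z = 30). The raw
shape means land within 1.2% of the tabulated branch means (836 and
353 keV); a linear energy rescale (factor < 1 for both branches, so the
endpoint is never exceeded) makes the sampler mean exact.

## Electron transport and sphere S-values

Electrons and positrons above a 1 keV cutoff follow straight tracks in
the continuous-slowing-down approximation. Collisional stopping power is
tabulated on a 600-point log grid (1 keV–3 MeV) from the Møller formula
with Z/A = 0.550, I = 74.7 eV, ρ = 1.04 g/cm³, and interpolated
log-log; the CSDA range is its cumulative inverse plus the small linear
remainder below the cutoff (so the 1 keV range is ≤ 0.1 μm). The
tabulation reproduces the standard soft-tissue CSDA ranges (e.g.
~600 μm at 245 keV, within 4% of published range tables). A track
deposits `E − E_exit`, where `E_exit` is the energy remaining at the
chord exit point, obtained from the inverse range table; residuals at or
below 1 keV deposit locally.

Not modelled, by design: multiple-scattering deflection, energy-loss
straggling, bremsstrahlung, and backscatter from the tissue surrounding
the sphere. At 50–400 μm the escape-versus-containment balance is set by
the range/chord geometry; path curvature shortens the effective chord
and backscatter returns some energy, effects of opposite sign and each
of order 10% here. The straight-track model reproduces independently
derived sphere S-values within ~10% at all tested sizes, well inside the
25% band the simplification is accepted at.

Photon self-absorption uses `1 − exp(−μ_en · 3R/4)` with mass
energy-absorption coefficients interpolated log-log from the standard
water tabulation; at these sizes the photon contribution to S is below
0.1%, which is why an analytic treatment replaces photon Monte Carlo.

Each Monte Carlo history is one decay at a position sampled uniformly in
the sphere; every electron line contributes its yield-weighted deposit
along an isotropic direction (positron energies drawn per history).
Sub-keV electrons and photons enter as per-decay constants with zero
variance, so a spectrum of only sub-keV lines reproduces the closed form
`S = E_mean/m` to machine precision — a structural check of the unit
chain `S[mGy/(MBq·h)] = E[J/decay]/m[kg] · 3.6×10¹²`. One
`numpy.random.default_rng` generator per run, seeded explicitly; the
seed is part of the result, and identical seeds give bit-identical
S-values. At 10⁶ histories the relative standard error is ~10⁻⁴ for
In-111 at 100 μm (the variance comes almost entirely from the partially
escaping conversion electrons), so runs of 10⁵–10⁶ histories — seconds
on one CPU — are comfortably converged.

## Organ S-values

The eight organ-level values (kidneys→pancreas and pancreas→pancreas,
male/female, both nuclides) are back-derived from published whole-organ
dose examples via `S = D/(τ·A0)` and packaged as CSV with the derivation
recorded in a provenance column. Only the healthy male and female
columns are used for derivation; the high/low-kidney-uptake and diabetic
scenarios then act as out-of-sample checks, which the model reproduces
to within one unit of the last printed digit. The table is replaceable
by a user CSV of the same schema, e.g. genuine phantom Monte Carlo
output.

## Time-integrated activity coefficients

`integrate_tac` applies the trapezoid rule to the measured,
decay-included curve and appends an analytic physical-decay-only tail
`A(t_last)/λ_phys` — the conservative MIRD convention. For trapped
kinetics (biological half-time ≫ observation window) the estimate is
within 5% of the closed-form integral even at the sparse 6-point
clinical schedule {0, 4, 24, 48, 96, 168} h; with substantial biological
clearance both the trapezoid (convex integrand) and the tail bias the
estimate high, i.e. conservatively.

Nuclide rescaling divides out one physical decay and multiplies in the
other, assuming identical tracer biology. Rat-to-human translation
scales τ by the ratio of organ-to-body mass fractions (Kirschner
method); defaults are rat pancreas 1 g / body 150 g, human pancreas
94.3 g (male) and 85 g (female), body 70.0/56.9 kg.

The pancreas partition gives the islet compartment the share
`r·f/(r·f + (1−f))` of `τ_pancreas` (f = islet volume fraction from the
histology area fraction — a stereological step justified by islet
sphericity; r = per-pixel islet:exocrine concentration ratio), and
divides by the islet count `N = f·M/(ρ·πd³/6)`. Per-islet τ therefore
scales exactly as d³ at fixed f, r, M, and the partition conserves
activity to 10⁻¹² relative. The measured r is never published; it is
treated as a calibration parameter (r ≈ 110 reproduces the published
100 μm per-islet τ at f = 0.02, M = 94.3 g).

## Autoradiography quantification

Background is the mean over three user-selected regions outside the
tissue; these regions live on the image grid and are deliberately not
warped during mask registration (they are selected on the
autoradiograph, not on histology). Registration is a similarity
transform (scale, rotation) applied to the histology masks with
nearest-neighbour label preservation, either supplied or grid-searched
by IoU between the transformed tissue mask and the image support
(thresholded on log intensity, since on the raw scale the bright islets
capture the Otsu threshold).

Spill-over is handled by dilating each islet label with nearest-label
expansion by 3× the PSF σ (config-exposed; ≥98% of a Gaussian kernel's
mass, and recovered ratios are stable within 3% for radii 3σ–5σ). The
per-islet value is the background-corrected core sum plus the
background- and exocrine-corrected ring sum, divided by the undilated
pixel count; negative totals clip at zero and a clip fraction above 5%
raises a warning. Ratios are means over islets within a section,
unweighted, then across sections. All corrections are affine, so the
ratio is exactly invariant to exposure scaling.

Known bias: PSF blur across the tissue rim mixes background into the
exocrine mean, inflating the ratio by a few percent at σ = 40 μm /
20 μm pixels. Recovery on synthetic sections is within 10% (ratio) and
15% (islet fraction) at σ ≤ 60 μm and exocrine SNR ≥ 10.

## Synthetic data

The generators emulate: bi-exponential-times-physical-decay kidney
curves at the clinical sampling times (defaults — uptake 0.32,
biological half-time 2000 h — chosen so the In-111 TIAC is ~30 MBq·h/MBq
and its Ga-68 counterpart ~0.5, matching the published volunteer-average
inputs, whose near-half-life ratio rules out fast biological clearance);
pancreas sections as an anisotropic tissue ellipse with ~2% islet area,
truncated log-normal islet diameters in 50–400 μm, a 100-fold
islet:exocrine ratio, Gaussian PSF spill-over (σ = 40 μm) and
scaled-Poisson noise; and rat biodistribution tables (9 animals,
18.5 ± 1.78 MBq injected). Every generator is seed-deterministic and
records its ground truth separately from its outputs.

Not emulated: real section shapes and tissue heterogeneity, islet
clustering, plate flat-field structure, deformable histology distortion,
and real renal kinetics beyond 1–2 exponentials. Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
image-formation model, not robustness to every artefact of real plates.

## Problem sizes and numerical defaults

Monte Carlo: 10⁶ histories per nuclide/diameter in the acceptance
script, 3×10⁵ in the test suite; both converge to relative standard
errors far below 1%. Synthetic sections are 512×512 at 20 μm pixels with
40 islets. The full 14-scenario suite plus all S-value computations runs
in seconds on one CPU.

## Limitations

* Organ S-values are back-derivations, not phantom Monte Carlo; they
  inherit the rounding of their source values (±1 in the last printed
  digit).
* The sphere transport is condensed-history CSDA without straggling or
  scattering; sphere S-values carry a model uncertainty of order 10%.
* Mean islet dose only: no position dependence within the pancreas (an
  islet near the kidneys receives more), no sub-cellular Auger
  dosimetry, and no risk modelling.
* A single representative islet diameter per scenario; real pancreata
  mix sizes.
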