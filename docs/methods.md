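# Methods

`ssxkit` implements, end to end and at desk scale, the data pipeline of a
room-temperature serial synchrotron crystallography (SSX) experiment in
which microcrystals flow through a capillary across a microfocus X-ray
beam and a pixel-array detector records snapshots at a fixed frame rate.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic data do and do not establish.

## Experiment arithmetic (`physics`)

Closed-form quantities that define the experiment:

* **Wavelength** λ = hc/E with hc = 12398.42 eV·Å. At the default
  9800 eV this gives 1.2651 Å; beamline write-ups round it to 1.27 Å.
* **Capillary flow.** Mean velocity v̄ = Q/(πR²); the laminar
  (Poiseuille) profile v(r) = 2v̄(1 − (r/R)²) with no-slip walls;
  Reynolds number Re = ρv̄D/µ. At the defaults (2.5 µl/min, 100 µm bore)
  v̄ = 5.3 mm/s, centerline 10.6 mm/s. The exact parabola gives
  3.8 mm/s at 10 µm from the wall; descriptions that quote "3 mm/s"
  there are rounding v̄ to 5. Viscosity is a config input with a water
  default (1 mPa·s): a PEG-rich crystal suspension is far more viscous
  (a quoted Re of 0.0115 at this flow implies ≈46 mPa·s), but no
  measured value exists to encode, so Re is reported, never asserted.
* **Transit time** across the focus: t = w_h/v, giving 0.9–3 ms over
  the laminar profile for the 9 µm focus; the simulator truncates its
  transit distribution to [1, 3] ms, absorbing the turbulence the
  profile does not model.
* **Dose.** A deliberate simplification of full radiation-damage codes:
  monochromatic thin-sample mass-energy-absorption,
  D = (flux·t / focus area) · E_ph · (µ_en/ρ), with µ_en/ρ defaulting
  to tabulated water values (5–20 keV grid, log-log interpolation).
  At the default beam it yields 0.092 MGy for 3 ms and 0.31 MGy for
  10 ms — the 0.1/0.3 MGy operating envelope. Photoelectron escape and
  composition effects are ignored; near 10 keV for µm-scale aqueous
  samples this is a tens-of-percent-level model, which matches how such
  doses are quoted.
* **Geometry.** Edge resolution d = λ/(2 sin θ), 2θ = atan(s/L) with s
  the shortest beam-center-to-edge distance: 2.09 Å for the default
  panel (2463×2527 px of 172 µm at 300 mm, centered beam).

## Synthetic snapshots (`simulator`)

The generator's defaults are the study conditions; they are fixed once
and the tests characterize the pipeline under them.

* **Arrivals.** Crystals per frame ~ Poisson(µ), µ = 0.3 — blanks,
  singles and occasional multiples; a `force_singles` switch exists for
  parameter-recovery studies. Orientations are uniform on SO(3)
  (normalized-quaternion sampling).
* **Intensities.** True intensities follow the acentric Wilson model:
  I(h) ~ Exponential with mean exp(−B s²/2), s = 1/d, B = 44.1 Å²
  (the overall B of the reference dataset). Centric statistics and
  multiplicity-ε corrections are not modelled. Symmetry mates share one
  amplitude; systematic absences of P4₃2₁2 ((0,0,l): l ≡ 0 mod 4;
  (h,0,0)/(0,k,0): even) are never generated.
* **Partiality.** Gaussian rocking profile in excitation error,
  p = exp(−ε²/2σ²), σ(q) the quadrature sum of mosaicity (default
  0.05°), divergence (1 mrad) and bandwidth (10⁻⁴) terms; reflections
  within 3σ are rendered. The merge never corrects for partiality — the
  Monte Carlo average absorbs it — so the simulator's model only needs
  to be plausible, not exact.
* **Photometry.** Spot photons = p · I · spot_scale ·
  (transit/reference) · size_scale. spot_scale = 4000 expected photons
  for an average full low-resolution reflection at the 3 ms reference
  transit: chosen once so that frames show a few tens of detectable
  peaks (between the 15-peak hit bound and the 200-peak multi bound)
  and high-resolution peaks carry tens of photons, the regime the
  method operates in. Crystal volumes are lognormal (σ = 0.3, mean 1).
* **Background.** Flat 0.5 photons/px plus a water ring: a Gaussian in
  s centered at 3.5 Å pseudo-resolution, amplitude 2.5 photons/px,
  width 0.02 Å⁻¹. No per-pixel background figures exist to copy; these
  levels make the background, not the crystal, the noise floor at high
  resolution, which is the documented regime of the experiment.
* **PSF and rolling.** Spots are pixel-integrated 2D Gaussians
  (σ = 1 px default, ±4σ stamp). 10% of crystals "roll" about the beam
  axis: their spots are smeared along constant-radius arcs of 5°,
  reproducing the observed azimuthal arcing. Rendering is Poisson
  end-to-end; a `poisson=False` mode returns the expected-value image
  for exact conservation tests.
* **Determinism.** One `SeedSequence` spawns independent child streams
  for structure factors, events and every frame, so stacks are
  bit-identical for a given seed and independent of evaluation order.
* **Measurement-level mode.** `simulate_measurements` skips image
  rendering and draws the integration-disc/annulus Poisson statistics
  directly at predicted reflections. It exists because convergence
  studies need thousands of patterns, where only the per-pattern
  measurement scatter matters; the image path remains the primary route
  and is what the headline cell-recovery result uses.

Not emulated: absorption, polarization, detector point spread beyond
the Gaussian PSF, pink-beam bandwidth, inter-crystal shadowing,
non-isomorphism between crystals. Passing tests therefore show the
*pipeline* is correct and convergent under the stated statistical
model, not that real capillary data would index at the same rate.

## Peak finding (`peakfind`)

Gradient-search detection: pixels above the global median plus the
25-count threshold are walked uphill to local maxima; each maximum gets
a local background (median of an 5–8 px annulus) and survives if its
background-subtracted height still exceeds the threshold; a region is
grown within 4 px while counts exceed background + 3σ_bg, and the
count-weighted centroid over that region is the peak position. The
threshold applies to background-subtracted height (a decision; raw
counts would make it background-dependent). Peaks touching masked
pixels or the panel border are dropped. Classification uses strict
bounds: >15 detected peaks is a hit, ≥200 flags a multi-crystal frame.

## Indexing (`indexing`)

Peaks are back-projected onto the Ewald sphere exactly (no small-angle
approximation). With the cell known a priori, indexing is an
orientation search implemented by pair matching: the ~10 lowest-|q|
peaks are matched to candidate reciprocal-lattice nodes by length
(±2.5×10⁻³ Å⁻¹) and pair angle (cos tolerance 6×10⁻³); each consistent
correspondence yields a two-vector Kabsch rotation; all candidates are
scored in one vectorized pass by the number of peaks within the q
tolerance (0.8 × half the minimum node spacing) of an integer node,
ties broken by rms residual. The best candidate is polished by
iterating full Kabsch refinement over its matched set. A rotation-grid
search was considered and rejected: covering SO(3) at the sub-1.5°
step the problem needs means millions of scored orientations per
frame, while pair matching reaches the same solutions in milliseconds.
Success requires ≥50% of peaks indexed (≥16 peaks); otherwise the
frame fails, mirroring the sub-100% indexing rates of real serial
datasets. The 422 orientation degeneracy is accepted — any
symmetry-equivalent rotation gives identical merged data after ASU
mapping.

Cell refinement alternates orientation Kabsch steps with closed-form
least-squares updates of the reciprocal axis lengths under the
tetragonal constraint (1/a from the h,k components, 1/c from l); a
triclinic option fits the full A = QHᵀ(HHᵀ)⁻¹ matrix and extracts the
cell from its metric. Ill-conditioned systems keep the prior cell and
flag it.

## Integration (`integrate`)

Reflections are predicted at the refined orientation out to the
configured d_min irrespective of detection, so weak spots contribute to
the merge. Each on-panel prediction is integrated as
I = Σ_disc − n_disc·b̂ with a 2 px disc (exactly 13 pixels under
center-of-pixel membership) and b̂ the mean of the 4–8 px annulus
(208 pixels). The mean, not the median, is the default background
statistic: the median of ~200 Poisson pixels at the 0.5 ph/px flat
level is integer-quantized to 0 and under-subtracts by ~6.5 photons
per disc — larger than a high-resolution reflection — which a Wilson
round-trip immediately exposes as a flattened B factor. The median
remains available for heavily spot-contaminated backgrounds.
σ propagates both Poisson terms:
σ² = Σ_disc + n_disc²·var(annulus)/n_annulus. Negative intensities are
retained. With the default σ = 1 px PSF the disc captures ≈84% of a
centered spot — a uniform scale factor the Monte Carlo merge absorbs;
a narrower PSF recovers truth photons to within 2%, and the test suite
pins both behaviors. Overlapping predicted discs are both retained
(the merge averages the contamination); integration is at predicted
centers, with no re-centering on detected peaks.

## Merging and statistics (`merge`)

ASU mapping is brute force: the lexicographically largest index among
the 16 Laue mates of 4/mmm (group generated by closure and verified
against an independent symmetry library in the tests). Merging is the
plain unscaled mean per unique reflection; σ(I) is the standard error
from the measurement scatter. Measurements are sorted before grouping,
which makes the merge exactly permutation-invariant without
compensated summation.

Half-set statistics split at the pattern level (all measurements of a
frame stay together — splitting measurements would correlate the
halves). R_split carries the conventional 1/√2 factor. CC* uses the
signed extension of sqrt(2CC/(1+CC)) below CC½ = 0 and is undefined at
CC½ ≤ −1/3. Shells are equal reciprocal-volume (uniform in 1/d³), 10
by default over 39.65–2.09 Å. Completeness compares against a
brute-force enumeration of theoretically observable unique reflections,
binned by the d of the ASU representative — for a cell that is only
approximately tetragonal, Laue mates differ slightly in d, and binning
by representative keeps observed and theoretical counts consistent.
The Wilson fit is a straight line through ln⟨I⟩ vs s²/2 over 15 bins;
non-positive shell means are excluded.

`convergence_analysis` recomputes the split metrics on seeded random
pattern subsets. R_split follows the Monte Carlo 1/√n law only once
most reflections have several measurements per half; below that it
saturates near the scatter ceiling (for exponentially distributed
measurements E|I₁−I₂| ≈ ⟨I⟩, i.e. R_split → ~1/√2), so slope checks
use grids of 150–1200 patterns where the asymptotic regime holds.

## Problem sizes

The shipped checks use: 200 single-crystal frames at the full default
detector for cell-parameter recovery (the acceptance script's
quantity); 1200 measurement-level patterns for the convergence slope
and the Wilson round trip; 5–12 frames on a 4×4-binned panel for
per-module oracles. These sizes were chosen as the smallest at which
the statistical assertions are stable at 3σ.

## Known limitations

* Known-cell indexing only; no ab initio autoindexing or multi-lattice
  deconvolution (multi-crystal frames are rejected by peak count).
* The partiality model and PSF are simulator conventions, not fitted
  to any instrument.
* V_M-style contents arithmetic is not computed; the solvent-content
  block of a full data-collection table is out of scope.
* The dose model ignores photoelectron escape, so it overestimates the
  dose to crystals much smaller than the photoelectron range.
* No post-refinement, scaling, detwinning or anisotropy correction:
  merging is deliberately the plain Monte Carlo mean.
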