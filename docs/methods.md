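# Methods

## Problem setting

`flimhca` analyses high-content FLIM screens of protein–protein proximity
at the budding-yeast kinetochore.  Kinetochore proteins cluster into one
or two diffraction-limited foci per cell; a donor fluorophore
(mTurquoise2, unFRETed lifetime ≈ 4 ns) attached to one protein reports
FRET to a nearby acceptor as a *reduction of the donor lifetime*, on the
scale of a few hundred picoseconds.  The instrument is a wide-field
time-gated system: an 80 MHz pulsed source (excitation period
T = 12.5 ns), a gated optical intensifier with a W = 4 ns gate, and a CCD
reading out 336 × 256 pixel frames at 615 nm pixel pitch.  One field of
view (FOV) yields 12 gated frames: five pre-bleach frames (to
photobleach background autofluorescence) followed by seven FLIM frames at
increasing gate delays.  Intensities are camera digital numbers (DN)
throughout; no photon conversion is attempted because the intensifier
gain is uncharacterized.

## Decay model and incomplete decays

At 80 MHz the interpulse period is comparable to the donor lifetime, so
emission excited by earlier pulses overlaps each period.  The continuous
emission of a monoexponential emitter with lifetime τ and per-period
amplitude A is the period-wrapped exponential

    f_p(t) = (A/τ) · e^(−t/τ) / (1 − e^(−T/τ)),  t ∈ [0, T),

whose integral over one period is A.  A gate at delay d records

    G(d) = ∫₀^W (IRF ⊛ f_p)((d + s) mod T) ds,

with ⊛ circular convolution over the period and a rectangular gate
profile (the true intensifier gate shape is not published; a measured
profile can be substituted by resampling the IRF).  The gate integral of
the wrapped exponential has a closed form, so for a sampled IRF the model
reduces to a weighted sum of closed-form terms — exact for an
instantaneous IRF, quadrature-limited (observed < 1e-5 relative against a
1 ps brute-force oracle) for smooth IRFs sampled on the internal
1.25 ps grid.  Dropping the wrapping ("single-pulse" model) is supported
only to demonstrate the resulting lifetime bias; fitting wrapped data
with it underestimates τ (about −40 ps at τ = 4 ns with the default
Gaussian IRF), which is why incomplete-decay handling is not optional.

## Reference reconvolution

Rather than deconvolving an explicit IRF, fitting uses the measured decay
R(t) of a reference dye of known lifetime (Coumarin 6 in ethanol,
τ_ref = 2.5 ns, sampled at 25 ps over the full period).  The identity

    D_τ = R + (1/τ_ref − 1/τ) · (R ⊛ P_τ),   P_τ(t) = e^(−t/τ)/(1 − e^(−T/τ)),

gives the model for any τ directly from R.  The convolution is evaluated
with an exponential integrator: between samples R is represented as
e^(−s/τ_ref) times a linear remainder, and R ⊛ P_τ solves the ODE
y′ = −y/τ + R with periodic boundary conditions, piecewise in closed
form.  The last grid interval is closed by exponential continuation
because the decay may jump at the period boundary (a new excitation
pulse).  This makes the identity *exact* (machine precision) whenever the
IRF is effectively instantaneous, and second-order accurate otherwise
(observed ≲ 2e-5 for a σ = 0.2 ns Gaussian IRF).  A short-lifetime
reference (quenched fluorescein, ≈ 100 ps) is used diagnostically: its
decay approximates the IRF itself, and the centroid of the extracted IRF
(∝ dR/dt + R/τ_ref) estimates the global time origin.  A single global
time-origin shift is supported; per-pixel IRF drift across the FOV is a
documented simplification and out of scope.

## Per-FOV image processing

1. **Intensity integration.**  All 12 frames are summed pixel-wise and
   n_frames × fixed_background (camera offset + ambient) is subtracted;
   negatives are clamped for segmentation only.
2. **Dead-cell exclusion.**  Dead cells appear as large *and* bright
   blobs.  Pixels above median + 8 × MAD of the cellular population
   (positive pixels above 20% of the positive median, which drops the dim
   out-of-cell tail) are grouped; components of ≥ 40 px are dilated by
   2 px into the exclusion mask.  Kinetochore foci also exceed the
   intensity threshold but never the area threshold.
3. **Focus detection (modified nonlinear top-hat).**  The intensity image
   is lightly blurred (Gaussian, σ = 0.7 px — a matched filter for
   sub-pixel spots); the score D(p) = S(p) − max(ring) compares each
   pixel with the 24-pixel boundary of its 7 × 7 window.  The threshold
   is 4 × a robust noise scale: MAD of raw horizontal neighbour
   differences over the illuminated area, propagated through the blur
   kernel's L2 norm — so detection is intensity-scale equivariant.
   Marked pixels are grouped; each component contributes its brightest
   raw pixel (ties → smallest row-major index).  Centers within 3 px of
   the frame edge, or whose 3 × 3 region touches the exclusion mask, are
   discarded.
4. **TVB subtraction.**  Each center is dilated to a 3 × 3 kinetochore
   region; the local time-varying background is the *median* of the
   surviving pixels of the 7 × 7 hollow square (excluded pixels and other
   foci's member pixels are removed from the ring; foci with < 8 ring
   pixels are dropped).  The median is subtracted per temporal frame;
   negative results are retained — clamping would bias dim decays upward.
   By construction any spatially uniform per-frame background cancels
   exactly; spatially *structured* autofluorescence does not, leaving a
   small residual contamination (≈ 5 ps at τ = 4 ns under default scene
   statistics).
5. **Image-wise fitting.**  The TVB-subtracted decays of all regions are
   summed ("image-wise" fitting) and fitted to the reconvolution model.
   Summation was chosen over a joint fit with per-region amplitudes: for
   a shared monoexponential τ the summed fit is the photon-optimal simple
   estimator.  The amplitude is profiled out in closed form (variable
   projection); τ is found by bounded search on [0.2, 8] ns (bracketing
   mTurquoise2 and autofluorescence while excluding degenerate solutions
   at 0 and T), seeded by the rapid-lifetime-determination estimate
   τ₀ = Δd / ln(G_i/G_j) from the first/last positive gates, with
   convergence tolerance 1e-4 ns.  Least squares is unweighted by
   default: after intensifier amplification and TVB subtraction the noise
   is neither Poisson nor known; an inverse-variance mode
   (var ≈ gain × max(signal, floor)) is available.
6. **QC gate.**  The total signal per image — kinetochore pixel count ×
   mean TVB-subtracted FLIM-frame intensity of those pixels, i.e. the
   pooled FLIM signal — must strictly exceed 1.2 × 10⁵ DN.  QC is
   computed after TVB subtraction so the statistic measures signal, not
   background.

## Strain statistics

QC-passing image-wise lifetimes are pooled per strain across wells and
runs.  Summaries follow box-plot conventions: quartiles by linear
interpolation, whiskers at 1.5 × IQR, and a notch-style 95% CI of the
median, median ± 1.57 × IQR/√n (the standard normal-assumption constant,
stated here so it is auditable).  Each query strain is compared with its
group's single donor-only negative control by a two-sided Wilcoxon
rank-sum test — exact when both samples have n ≤ 10 without ties,
otherwise the tie-corrected normal approximation with continuity
correction — at α = 0.05, Bonferroni-corrected by the number of query
strains in the group (positive controls are tested identically but never
counted).  Comparisons never cross groups.

## Synthetic instrument

The simulator renders what the analysis assumes, plus the nuisances it
must survive.  Scenes place non-overlapping elliptical cells (~40 per
full frame; min spacing 22 px, since cells are rigid bodies) of diffuse
autofluorescence (30 DN/px/period, τ = 2 ns, soft edges via a 1.5 px
blur), each carrying one kinetochore focus — or two separated 8–12 px
along the elongated cell's long axis for the ~40% of cells in anaphase;
metaphase sister clusters are unresolved and appear as one focus.  Foci
are sub-pixel Gaussian spots (σ = 0.35 px ≈ 215 nm) stamped by analytic
pixel-area integration, with amplitude 5 × 10⁴ DN/period (log-normal,
CV 0.2) — chosen so a single 9-pixel focus integrates to ~1.2 × 10⁵ DN
over the FLIM gates, the regime the QC threshold operates in.  A dead
cell (radius 7–11 px, 10⁵ DN/px/period, τ = 1.5 ns) appears in 25% of
FOVs.  Each frame scales every emitter by its closed-form gate signal;
bleaching multiplies frame k by (1 − 0.01)^k in acquisition order (which
is what makes excluding the pre-bleach frames from fitting testable);
Poisson noise is applied on a pseudo-photon scale with configurable gain
(default 1 DN/photon, the intensifier chain being uncharacterized); the
camera offset (100 DN, noise-free bias) is added last.  Same seed ⇒
bit-identical output; plates draw one seed-sequence substream per FOV.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: optical sectioning and disc
crosstalk, vignetting, IRF drift across the field, read noise and hot
pixels, cell-to-cell lifetime heterogeneity (the dominant source of the
240–1450 ps interquartile ranges seen in live cells; simulated spreads
are photon-limited and an order of magnitude tighter), acceptor-channel
imaging, and real strain biology.

## Validation studies and problem sizes

The acceptance studies (tests and `scripts/acceptance.py`) use these
sizes, chosen as the package's own trade-off between statistical
resolution and a desk-scale run: forward-model and reconvolution checks
against a 1 ps brute-force oracle (8 and 3 parameter combinations);
noiseless end-to-end recovery on a bare 96 × 96 focus scene (sub-ps
agreement requires no structured background, see TVB note above);
stochastic recovery at τ = 2.5 ns with 100 replicate FOVs near the QC
threshold vs a 1000-replicate oracle of the same process; segmentation
recall/precision at worst-case peak SNR 5 over 20 full-size FOVs;
screen-level power with 100 plates × 2 strains × 45 FOVs (96 × 96
frames, ~5 cells each) at Δτ = 250 ps and Δτ = 0.  Monotonicity of gate
signals in τ holds at fixed *peak* emission (amplitude ∝ τ); under
fixed per-period amplitude the early gates are non-monotone in τ, which
is a property of the normalization, not of the instrument.

## Known limitations

* Absolute lifetimes carry a common systematic from photobleaching
  during the gate sequence (≈ −120 ps at τ = 4 ns at the default 1%
  per-frame rate) and a small autofluorescence TVB residual; the screen
  is differential (query vs control on the same plate), so these cancel
  in Δτ to first order.
* The monoexponential model detects FRET but cannot quantify FRET
  fractions; seven gates do not constrain a biexponential.
* The rank-sum exact/asymptotic switch at n = 10 follows standard
  practice; near the boundary p-values can differ by up to ~0.02.
* Ring starvation (< 8 background pixels) silently drops foci in very
  crowded neighbourhoods; the count is logged.
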