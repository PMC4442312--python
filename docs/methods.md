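# Methods

## The measurement

SiMPull immunoprecipitates protein complexes from lysate onto an
antibody-coated, PEG-passivated slide and images them by TIRF, one
diffraction-limited spot per immobilized complex. Three quantities are
extracted: the number of fluorescent molecules per imaging area (a binding
readout, with a control antibody setting the nonspecific floor), the number
of photobleaching steps per spot (a subunit-counting readout), and the
percentage of spots in one color channel that coincide with spots in the
other (a co-complex readout). This package implements those three analyses
and a generative simulator that makes each one testable by parameter
recovery.

## Generative model (simulator)

A field of view is a homogeneous spatial Poisson process of immobilized
complexes. Conventions and defaults:

- **Geometry.** One field = one imaging area of 5000 µm². Pixel size
  defaults to 150 nm/px, chosen so that the conventional 2-px colocalization
  criterion equals one diffraction-limited spot (~300 nm); the default field
  is therefore 471 × 472 px (5002 µm²). PSF sigma defaults to 1 px
  (~150 nm), a standard visible-light TIRF approximation.
- **Complex composition.** Bait-captured complexes (density
  `surface_density`, default 0.02/µm² ≈ 100 per area — a typical "optimal
  single-molecule density" after lysate dilution) carry the channel-A
  label with a configurable copy-number distribution; with probability
  `co_complex_fraction` they also carry the channel-B partner at the same
  position. `partner_only_density` adds complexes carrying only the partner
  label: prey bound to the bait independently of the co-complex, which is
  what makes the bait channel the lower-density one on a real slide.
  `nonspecific_density` adds monomeric, channel-independent background
  binders (the control-antibody regime).
- **Photophysics.** Each subunit copy matures into an active chromophore
  with probability `maturation_prob` (default 0.75, a conventional estimate
  for YFP-class fluorescent proteins); non-matured copies are permanently
  dark. Each active fluorophore emits `unit_intensity` photons/frame
  (default 300) until it photobleaches; bleaching is memoryless with
  per-frame probability `bleach_prob_per_frame` (default 0.01), i.e.
  geometric bleach times matching exponential kinetics. No blinking is
  simulated; blinking-like traces are handled at the analysis level by
  rejection.
- **Camera.** Pixel values are Poisson(signal + background) plus Gaussian
  read noise (defaults 50 photons/px/frame and 2 photons), clipped at zero;
  gain is fixed at 1 (arbitrary photon units). Movie length defaults to 400
  frames — long enough that >98% of fluorophores bleach at the default
  rate; the ground truth records the unbleached fraction so this assumption
  is checkable. Exposure time, laser power and movie length are not
  constrained by published SiMPull protocols and are explicitly
  placeholders in the config.

For speed, background pixels draw their noise from a precomputed 2²⁰-entry
inverse-CDF table of the Poisson–Gaussian mixture (exact to ~10⁻⁶
probability resolution; pure, discrete Poisson when read noise is zero),
while pixels with non-negligible signal (>0.1 shot-noise s.d.) are drawn
per-pixel from the exact distribution. PSF tails below that cut contribute
<0.5% of a spot's integrated intensity. Everything is driven by one seeded
generator: the same seed yields bit-identical stacks and truth tables.

Not modeled (out of scope): stage drift, focus change, uneven TIRF
illumination, EM-gain excess noise, FRET, dye-specific blinking kinetics.
Passing recovery tests therefore demonstrates correctness of the analysis
under ideal optics, not robustness to instrument artifacts.

## Spot detection and counting

Spots are local maxima of the average projection of the first
`projection_frames` frames (default 10 — detect before appreciable
bleaching), thresholded at background + 5 robust s.d. (median and
1.4826 × MAD of the projection, insensitive to the spots themselves) and
refined by intensity-weighted centroid in a 5 × 5 window; centroid accuracy
(~0.1 px) is ample for a 2-px matching criterion, so no PSF fitting is
used. Maxima closer than `min_separation_px` collapse to the brighter one.
That merge radius defaults to 2 px — the same diffraction-limit criterion
used for colocalization; a wider merge radius measurably bends the
count-vs-density curve below slope 0.95 already at ~500 molecules per area,
which is the upper end of the usable density range (counting loss from
unresolvable overlap is ~2–3% there, the documented overlap regime).
Counts are rescaled to molecules per 5000 µm² when fields have a different
area; the mean ± s.d. (n−1) across replicate areas is the reported
quantification, and sample/control mean ratios ≥5 (configurable) pass the
specificity check.

## Step counting

A spot's trace is aperture photometry: sum over a 3-px-radius disk minus
the aperture-scaled median of a 5–7 px annulus, per frame. Spots without a
full photometry margin are rejected with an explicit reason.

Steps are fitted as a piecewise-constant staircase by greedy binary
segmentation: repeatedly insert the change point with the largest RSS
reduction, accept while the model-selection cost RSS/σ̂² + penalty·k·ln T
decreases (k change points, T frames, penalty default 3 — Schwarz-like,
each step adds a time and a level parameter). σ̂ is estimated robustly from
first differences (MAD/√2), which makes the penalty scale-free in intensity
units. After every insertion and every pruning step, change-point positions
are refined by coordinate descent (each point re-placed optimally between
its neighbors), which closes the gap to the global optimum: on 1–3-step
traces the greedy RSS matches an exact dynamic-programming search
(`simpull.validation.exact_staircase_fit`, O(kT²)) to within 1% in ≥99% of
noisy traces. Steps smaller than `min_step_size` and plateaus shorter than
`min_dwell_frames` (default 2) are pruned.

A fit is *accepted* only if all retained steps are downward, the count is
≤ `max_steps` (default 5), the final plateau is within 3 σ̂ of zero
(complete bleaching — traces that do not reach background cannot be
counted), and the smallest step exceeds 2 σ̂. Everything else is tallied by
rejection reason (`no_full_bleach`, `upward_step`, `too_many_steps`,
`low_snr`) so the discarded fraction is always visible; published SiMPull
work does not state its discard criteria, so these are reported rather than
matched to anything. Below step SNR ≈ 3 the fitter increasingly undercounts
and the step distribution should not be trusted; the validated regime is
SNR ≥ 5.

## Stoichiometry

With maturation probability m, a complex with n copies shows j ≤ n steps
with zero-truncated binomial probability
P(j | n, m) = C(n, j) mʲ(1−m)ⁿ⁻ʲ / (1 − (1−m)ⁿ) (conditioning on being
visible at all). The observed step histogram is modeled as a mixture over
n = 1..n_max (default 4; the support widens automatically if deeper
histograms appear) and the weights are fitted by EM with 10 restarts under
a fixed seed — the likelihood is concave in the weights, so restarts are
belt-and-braces. Species with weight ≥ 0.1 enter the dominant call (e.g.
"monomer + dimer"); 0.1 is chosen so that a genuine minor subpopulation of
two-copy complexes is called while fit noise is not. Because conventional
practice reports the raw histogram, the pipeline always fits twice: at the
configured m (default 0.75) and at m = 1 (no correction), and reports both.
Joint inference of m from the data is deliberately out of scope — it
requires calibration constructs.

The same dark-fraction logic corrects co-complex percentages: a monomeric
partner is visible above only a fraction m of the complexes that carry it,
so the true cohabitation fraction is observed/m, capped at 1 with the cap
flagged.

## Colocalization

Channel-B positions are first registered by subtracting the configured
channel offset (offset estimation from fiducials is out of scope). Candidate
pairs within the match radius (default 2 px) are sorted by distance (ties
by index, deterministic) and assigned greedily one-to-one, so no spot is
counted twice; at SiMPull densities greedy matching is indistinguishable
from optimal assignment. The percentage uses the lower-count channel of
each field as denominator — the two tagged preys are pulled down to
different extents, so the sparser channel is the limiting one. The Poisson
chance level 100(1 − e^(−λπr²)) for the denser channel is always reported
alongside and is *not* subtracted from the headline percentage (matching
how such percentages are conventionally reported); subtraction is available
behind the `chance_correct` flag. Condition comparisons report the mean
difference, ratio, and a two-sample z from the across-field s.d.

## Validation experiments and problem sizes

The acceptance battery (`simpull.experiments`, run by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: 500 traces
per 1–3-step condition at SNR 5 (300-frame traces, bleach rate 0.005/frame,
conditioned on complete bleaching — an uncounted, still-fluorescent trace
is a rejection in practice, not a miscount); 1000-trace histograms per pure
population at m = 0.75; 20 imaging areas per colocalization condition at
~100 bait complexes per area with the partner channel ~1.5–2× denser;
densities up to 500 molecules per area for linearity (3 fields each); and
100 replicate sample/control field pairs at a 10:1 specific:nonspecific
density ratio. Counting and colocalization experiments use 10–12-frame
movies with bleaching disabled — they measure detection and matching, and
a 10-frame window at the default bleach rate would otherwise conflate a
~2% density-independent early-bleaching loss into the linearity slope.
Colocalization recovery is asserted on the chance-corrected estimate
(measured ≈ 100f + chance·(1 − f), inverted analytically): at these
densities the chance floor is ~1%, a real bias of the raw percentage that
the null model exists to remove; both raw and corrected values are
reported.

## Numerical notes and edge cases

- Constant traces, all-zero histograms and empty channels return explicit
  rejections/flags rather than raising, except where the input is unusable
  (empty stack, saturated projection, nonpositive dilution factor).
- A zero-mean control quantification is floored at ε = 10⁻⁹ in the
  enrichment ratio and flagged.
- The expected-molecule-count guard rejects configurations above 0.5
  molecules/pixel (unresolvable overlap).
- s.d. uses the n−1 denominator everywhere; a single field reports NaN
  s.d. rather than 0.
- All randomness flows through `numpy.random.Generator` seeded from the
  config; per-field seeds are spawned from a `SeedSequence`, so reports are
  byte-identical across runs of the same config and seed.
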