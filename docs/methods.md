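# Methods

This note documents the models, conventions and numerical choices behind
`eegstates`, and what the synthetic-study validation does and does not
establish.

## Montage

The analysis montage is the 63-channel remainder of a 64-channel 10-10 cap
referenced to Cz. 52 channels belong to five cortical areas per
hemisphere — frontal (9), central (4), temporal (5), parietal (4),
occipital (4) each side; the five midline electrodes (Fz, CPz, Pz, POz, Oz)
and six inferior lateral electrodes (FT9/10, TP9/10, PO9/10) carry no area
and never enter region-aggregated statistics. The printed protocol lists we
follow contain one inconsistency on the right side (FC4 listed under both
frontal and central, FC6 never listed); we resolve it by mirror symmetry
with the left hemisphere — FC2, FC4 frontal and FC6 central — which keeps
the groups a partition. The mapping is a plain dict argument to
`make_montage`, so an alternative resolution is one call away. Electrode
positions come from the standard 10-05 layout, normalized to the unit
sphere; they are used only for bad-channel interpolation and for
constructing smooth synthetic topographies.

## Preprocessing

The pipeline deliberately excludes automated artifact detection (that is an
input: per-epoch bad-channel masks). What remains is fully specified:

- zero-phase 4th-order Butterworth band-pass, applied forward–backward
  (`sosfiltfilt`); bands 1–30 Hz for microstates, 8–10 / 10–12 Hz for power;
- average reference (idempotent; leaves GFP untouched);
- consecutive non-overlapping 2-s epochs, trailing partial epoch dropped;
- an epoch is kept iff (#bad channels / #channels) < 0.25; bad channels in
  kept epochs are replaced by an inverse-distance mean of the 4 nearest
  good channels. This interpolation is a declared stub standing in for
  spherical-spline interpolation; it is exact for spatially constant fields
  and adequate for the smooth synthetic topographies used here.

## Task-related power

Welch spectra use Hann tapers, 1000-sample windows with 500-sample overlap
at 500 Hz, density scaling, over the concatenated kept epochs of a run. The
spectrum is evaluated on a 4× zero-padded frequency grid (0.125 Hz
spacing): the spectral resolution is unchanged (srate/win = 0.5 Hz), but
composite-Simpson band integrals then sample the Hann line kernel finely
enough to integrate a narrow spectral peak accurately — on the native grid
Simpson recovers only 8/9 of an on-bin tone's power. Band edges are
inclusive and shared between the sub-bands, so lower + upper alpha power
equals 8–12 Hz power exactly.

TRP uses the natural log by default (`log10` is a flag); the reference is
the rest block at the start of the experiment, and the mean is taken over
the runs of a condition. TRP is therefore invariant to any common rescaling
of the recordings.

## Microstates

- **Peak maps.** GFP is the population (divide-by-N) spatial SD. Peaks are
  strict local maxima within an epoch; plateaus count once at their first
  sample; epoch boundary samples never qualify.
- **Modified k-means.** Polarity-invariant: maps are assigned by
  argmax_k (V·Γ_k)², the intensity is the signed projection of the assigned
  class, and each template update is the principal eigenvector of its
  members' scatter. Restarts (default 100) initialize from K distinct
  observed maps; convergence is a relative cost change below 1e-6 (cap 1000
  iterations); an emptied class is re-seeded from the worst-fit map. Peak
  maps are clustered raw (average-referenced, not GFP-normalized): the
  unit-norm templates and squared-projection assignment make the fit
  scale-aware; a `normalize_peaks`-style preprocessing can be applied by the
  caller if wanted.
- **Model selection.** The CV criterion multiplies the residual variance by
  ((N_S−1)/(N_S−1−N_K))², with the residual taken at each map's assigned
  class. It requires N_K < N_S−1.
- **Alignment.** Mean classes are built by evaluating all N_K! class
  permutations of each model against the running mean, scoring by the sum
  of absolute spatial correlations (Pearson across channels of
  average-referenced maps), sign-flipping each aligned template to positive
  correlation, averaging, renormalizing, and iterating until the
  assignments stabilize. A cap (default 10!) guards the factorial. The
  hierarchy averages runs → participant-conditions → conditions → global.
- **Backfitting.** Only GFP-peak maps are labelled (maximal |correlation|);
  every other sample inherits the temporally nearest peak's label, with the
  midpoint between neighbouring peaks as the boundary and ties to the
  earlier peak — some rule must cover the whole recording for coverage to
  be a fraction of recording time, and nearest-peak is the least committal.
  The first and last run of every 2-s epoch are removed (their true onset
  or offset is unknown); epochs with fewer than two peaks are excluded.
  No temporal smoothing is applied.
- **Parameters.** Per epoch, coverage_k is the fraction of retained samples
  labelled k and duration_k the mean length of retained class-k runs;
  per-run values average over epochs, durations only over epochs where the
  class occurs (absent class → coverage 0, duration NaN).
- **Letters.** Classes are sorted A–F by one-to-one |correlation| matching
  against a packaged reference set. That set
  (`data/canonical_maps_synthetic.csv`) is a synthetic stand-in built from
  low-order spherical-harmonic patterns shaped like the conventional
  A–F maps (left–right diagonal, right–left diagonal, anterior–posterior,
  fronto-central, symmetric posterior, anterior–posterior variant); any CSV
  with one column per channel can replace it.

## TANOVA and parametric statistics

TANOVA normalizes each participant map by its GFP, uses as effect statistic
the summed GFP of the deviations of level-mean maps from the grand-mean map
(for the interaction, of the double-centered cell means), and permutes
labels within participant — the factor's own labels for a main effect,
joint cell shuffling for the interaction, A/B swaps for the paired test.
P-values use the add-one estimator (1 + #{perm ≥ obs})/(1 + n_perm), so
they are never zero and are reproducible bit-for-bit under a fixed seed.
The effect statistic is the largest interpretive choice in the package:
the source protocols cite a generalized-dissimilarity randomization test
without printing a formula, and this is its natural multi-level form.

The within-subject ANOVA supports any number of within factors (the designs
used are 3×5×2, 4×6 and one-factor). For each effect the error term is the
effect × subject interaction; partial η² = SS_eff/(SS_eff+SS_err);
Greenhouse–Geisser ε is computed from the covariance of orthonormal
contrast scores (Kronecker products across factors) and applied when the
Mauchly test rejects sphericity at 0.05. The uncorrected F values are
cross-checked in the tests against `statsmodels`' repeated-measures ANOVA
on random tables.

Completion times are z-scored within participant — within each condition's
runs for the RUN analyses, across all nine tasks for the between-condition
analysis — and optionally averaged per condition. Both the normalized and
raw-seconds variants are available, since protocols report contrasts on
both scales.

## Synthetic study generator

The generator emulates the experiment's structure, not its biophysics:

- **Design.** Per participant one rest block (default 180 s; 90 s in the
  shipped analyses) and 3 runs × 3 task conditions at 500 Hz; task
  completion times are truncated-normal with means 54.047 / 92.785 /
  16.476 s (generation / evolution / evaluation), SDs 23.5 / 27.5 / 5.8 s,
  bounds 6–180 s. `max_render_seconds` caps only the rendered task EEG, not
  the behavioural times and not the rest block.
- **EEG model.** X(:,t) = a(t)·Γ_label(t) + pink + white, average
  referenced. The intensity a(t) = gain·(A sin(2πft+φ) + B·b(t)) combines a
  participant-specific alpha oscillation (f ~ U(9, 11) Hz, A = 50 µV per
  unit-norm template) with a broadband 1–30 Hz component (B = 18 µV):
  the polarity-inverting sinusoid gives two GFP peaks per alpha cycle and
  the broadband part densifies them (~25 peaks/s), as in real EEG. Because
  the whole intensity scales with the condition gain, in-band power scales
  with gain² and region TRP recovers ln(gain²) in any alpha sub-band.
  Pink (1/f-power) noise of 2 µV and white noise of 1 µV per channel define
  "moderate noise" (per-sample topography correlation ≈ 0.9 at peaks).
- **Templates.** Six smooth spherical-harmonic maps shaped like the
  conventional A–F classes, Löwdin-orthogonalized: with orthogonal planted
  templates a boundary mixture of two classes cannot masquerade as a third,
  which makes planted coverages identifiable. Participants get small random
  rotations of the group templates (correlation 0.95).
- **Sequences.** Semi-stable runs with gamma(shape 2) lengths, mean 120 ms
  (the upper end of the 60–125 ms range reported for microstate durations —
  chosen so the ~40 ms GFP-peak spacing resolves state boundaries), classes
  drawn with no immediate self-transition from weights adjusted so the
  chain's long-run coverage equals the requested per-condition weights.
- **Condition effects.** Alpha gains 1.0 / 0.70 / 0.85 / 0.65 (rest /
  generation / evolution / evaluation — suppression weakest during idea
  evolution, strongest during evaluation) applied as a scalar per condition;
  coverage weights favour classes C and D at rest, A and E during tasks,
  and suppress F during idea evolution. All gains and weights are config
  fields; `StudyConfig.null_effects()` switches every effect off.
- **Seeding.** All randomness flows from one master seed through named
  streams (participant, recording, times, stage), so changing one stage's
  draws never perturbs another's.

What the generator does *not* emulate: volume-conducted dipolar sources,
non-stationary within-block dynamics, eye/muscle/cardiac artifacts,
electrode drift, or condition-dependent spectral shape beyond the alpha
gain. Passing the recovery tests therefore shows the analysis chain is
correct and well calibrated on data satisfying its own model assumptions —
it does not certify performance on real recordings with artifacts or
template overlap.

## Validation design and problem sizes

The shipped analyses and the reproduction script use a 4-participant study
with 90-s rest blocks and task blocks rendered up to 30 s — roughly
20 minutes of 63-channel EEG — with 10 k-means restarts; model selection
(k = 1..10) is probed on four runs, one per condition. These sizes give
each condition 190–360 s of data, enough that Monte-Carlo error in the
planted-parameter recovery sits well below the quantities recovered.
Known estimator biases worth stating: peak-based backfitting merges states
that contain no GFP peak and misplaces boundaries by up to half the
inter-peak interval, inflating mean durations by ~5 % on average (up to
~10 % for individual classes) and leaving coverages nearly unbiased; the
recovery checks absorb these biases inside their 15 % bands. TANOVA
calibration uses 500 null replicates at 200 permutations (the binomial 95 %
band around α = 0.05 is ±1.9 %), and power uses 28 synthetic participants
with one condition's mean topography rotated to r = 0.8 against the others
at unit noise.

## Known limitations

- The bad-channel interpolation stub is inverse-distance, not spherical
  spline; real-data use should swap it.
- The TANOVA effect statistic is one defensible formalization of a
  topographic randomization test; others (e.g. L2 dissimilarity per
  permutation step) exist and can disagree in borderline cases.
- CV-based model selection needs moderate noise to be informative: on
  noiseless renderings the criterion keeps decreasing past the true K
  because boundary-mixture maps form real sub-clusters.
- `rm_anova_gg` assumes complete within-subject designs; unbalanced data
  are a hard error, not a mixed-model fallback.
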