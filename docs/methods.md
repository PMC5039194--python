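# Methods

This note documents the models, estimators and design choices behind
`phenorosette`, in the order data flows through the pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Experiment model

An experiment is accessions × treatments × replicates observed over an
ordered set of days. Treatments carry a nominal NaCl dose in
{0, 50, 100, 150} mM; dose-dependent effects in the generator scale
linearly per 100 mM. Plants are shuffled once (seeded) and assigned
row-major to trays of `rows × cols` pots (default 4 × 5 = 20; the last tray
may be partial), so treatments interleave across trays as on a real
conveyor platform. Tray images default to 2560 × 1920 px (the top-view
camera's native resolution) but every stage accepts scaled-down renders;
tests and the acceptance script use 640 × 480 (pot cells of 128 × 120 px)
to keep runtimes in seconds.

## Synthetic trays

Rosettes are fans of N rotated ellipses ("leaves", N ∈ [6, 12] by default)
with jittered angles and lengths, centred in the pot cell. The fan is not a
botanical model; it is chosen because area, slenderness and rotational
symmetry are controllable and the union of ellipses gives a pixel-exact
ground-truth mask. The linear scale of the fan is calibrated iteratively
(≤ 8 re-renders) until the painted pixel count is within 5% of the
growth-model target; the renderer's contract is 10%. Targets above 40% of
the pot cell raise an error — a leaf fan cannot fill a square cell.

Each leaf is painted in one colour drawn from a 9-green palette
(luminance-increasing, adjacent colours ~20–25 RGB units apart); overlaps
are resolved by paint order, and the recorded hue composition is the exact
pixel count of each palette colour inside the final mask. Soil is uniform
brown (120, 92, 60) plus Gaussian texture noise (σ = 4 by default; σ = 0
for zero-noise sweeps). A σ = 4 soil still segments cleanly because
speckles passing the colour threshold are isolated and fall to the
`min_object_px` filter.

## Growth model

Projected area is piecewise linear: slope `GR_early` through the end of
the first fitting interval, `GR_late` afterwards (including gap days),
plus additive Gaussian noise, clipped at zero. Default study conditions:
initial area 500 px (at 640 × 480), control growth 150 px/day, salt ratios
0.6 (early) and 0.5 (late) per 100 mM, 5% between-plant CV. The two
fitting-interval presets are (0–4, 7–11) and (0–3, 4–7), selectable in
configuration. Because the generator and the fitting stage share the same
two-phase linear form, zero-noise round trips are exact, which is the
point: discrepancies isolate estimator error, not model mismatch.

## Fluorescence model and protocols

Both protocols start with a 5 s measuring-flash window (Fo), an 800 ms
saturation pulse at 1200 µmol m⁻² s⁻¹ (Fm) and 17 s of dark before actinic
onset. Quenching kinetics: 70 s of actinic light at 210 µmol m⁻² s⁻¹ with
pulses 8/18/28/48/68 s after onset (L1–L4, Lss), then 100 s dark with
pulses at 30/60/90 s (D1–D3). Light curve: four 60 s steps at
95/210/320/440 µmol m⁻² s⁻¹ (L1–L4), one pulse ending at each step
boundary. Dark adaptation (15 min) precedes the trace and is not
simulated.

The generator's quenching dynamics are deliberately minimal:

* NPQ(t) = NPQ_max·(1 − e^(−t/τ_NPQ)) under light; exponential relaxation
  (τ_relax) in the dark. Defaults NPQ_max = 1.2, τ_NPQ = 20 s,
  τ_relax = 60 s — magnitudes and time scales typical of the fast
  (energy-dependent) quenching component in *Arabidopsis* at moderate
  light.
* qP relaxes from 1 (all PSII centres open after dark adaptation) toward a
  steady state (0.55 under constant light; per-step targets
  0.88/0.72/0.58/0.48 for the light curve) with τ_qP = 2.5 s.
* Levels follow in closed form: Fm′ = Fm/(1+NPQ), Fo′ by Oxborough–Baker,
  Ft = Fm′ − qP·(Fm′ − Fo′). The early competition between fast centre
  closure and slower NPQ build-up produces the Fp transient on the actinic
  rise without extra machinery.

Within each saturation pulse and the 200 ms Ft window before it, the model
clock is frozen at the pulse start: the pulse perturbs the photosystem,
and freezing makes window statistics equal model values exactly, giving
zero-noise round trips at machine precision. Traces are sampled at 50 Hz
(the fluorescence camera's frame rate); the long-experiment pipeline
config stores decimated 10 Hz traces to keep a 144-plant × 8-day run small.
Noise is additive Gaussian per sample — no camera noise model is published
for this class of instrument, so the magnitude is a free parameter.

### Level estimators

Fo and Ft(s) are window means (the 5 s flash window; the 200 ms before
pulse s). Fm and Fm′(s) are the **mean of the pulse-window samples**: the
pulse is a flat-top plateau, so the mean is exact at zero noise and
unbiased under noise, whereas the maximum of k noisy samples is biased
upward by ≈1.4σ — enough to corrupt NPQ at low-quenching states and Rfd at
realistic noise. `extract_levels(..., level_estimator="max")` restores the
max for traces whose pulse windows may contain a rising flank. Fp is
defined operationally as the peak of the 1 s moving-average-smoothed
signal on the actinic rise, identically in the extractor and in the
generator's ground truth. Rfd is computed against the steady state (Lss
for quenching, L4 for the light curve).

Division-guarded parameters (Fm′ = Fo′, Ft = 0) come back as NaN with the
state flagged, so one degenerate plant cannot abort a tray.

## Segmentation

Vegetation = (2G − R − B > 30) ∧ (G > 40) on 8-bit RGB. Cleaning removes
components below 20 px, applies morphological closing with a disk of
radius 1, and keeps the largest connected component (ties: lowest centroid
row, then column). Radius 1 closes single-pixel gaps without the
systematic rim inflation a radius-2 disk adds to thin leaves (measured as
a factor-2 difference in worst-case area error on rendered rosettes).
Cleaning is idempotent. Colour analysis (palette calibration and hue
labelling) uses vegetation-positive pixels *inside* the cleaned mask:
closing exists for area/shape and may annex soil-coloured pixels that
would otherwise contaminate the hue scale with a spurious 10th colour.
Tray detection and lens-distortion correction are out of scope; the grid
is declared in configuration and an identity hook preserves the pipeline
order where a distortion correction would sit.

## Morphometrics

Standard image-analysis definitions (the platform's own formulas are
proprietary): perimeter by the 4-direction Crofton estimator, chosen
because boundary-chain lengths with √2 diagonals overestimate a smooth
outline by ~5%, dragging the roundness of a perfect disk to ~0.91;
Crofton is near-unbiased (disk r = 60 → roundness 0.994). Roundness is
clipped at 1 against small-mask artefacts. Compactness is convex-hull
solidity; eccentricity and slenderness come from central second moments.
Rotational mass symmetry is 1 − CV of pixel mass over 36 equal angular
sectors about the centroid, clipped to [0, 1]; the sector grid is rotated
a quarter-bin so no lattice direction (0°, 45°, …) sits on a bin boundary,
which makes the trait exactly invariant under quarter turns; the centroid
pixel itself (undefined angle) is excluded. "Slenderness" is the
whole-rosette moment-ellipse axis ratio, not a per-leaf statistic.

## Colour segmentation

One global palette per experiment: rosette pixels pooled from the first,
middle and last measurement day and both treatments (optionally capped per
image, seeded) are clustered with k-means (k = 9 default, k-means++ with
10 restarts, fixed seed, Euclidean RGB). Hue numbering is data-dependent
in principle, so centroids are ordered by Rec. 601 luminance (dark →
light) to make "hue 1…9" stable. Per-pixel labels take the nearest
centroid, ties to the lowest index; abundance is counts / rosette area, a
probability vector by construction. Salt/control hue ratios flag a zero
control mean as missing rather than returning infinity.

## Growth rates and SIIT

Slopes are fitted per plant (not per accession-mean curve) with ordinary
least squares over closed day intervals, keeping R² and point counts as
diagnostics; per-plant values allow error bars downstream. SIIT divides a
salt plant's GR by the mean control GR of its accession over the same
interval. Negative fitted slopes are clipped to zero and flagged; a
non-positive control mean flags SIIT as missing.

## Statistics

* **ANOVA + Tukey.** F from explicit sums of squares (so all-equal groups
  give F = 0 rather than 0/0), pairwise Tukey–Kramer p from the
  studentized-range distribution, compact letter display via maximal
  cliques of the non-significance graph. With k = 2 the Tukey p equals the
  pooled-variance t-test p (q = t√2), which the tests verify, alongside a
  cross-check against an independent implementation.
* **Mann–Whitney.** Default `method="auto"`: exhaustive-permutation p
  (tie-exact) when both groups have ≤ 8 observations, otherwise the
  tie-corrected normal approximation with a 0.5 continuity correction.
  The exact route exists because no smooth approximation can track the
  permutation lattice at such sizes (at n = 2 per group the attainable
  p-values step by 1/6).
* **Standardisation.** "z-scoring per trait" with sample SD (ddof = 1);
  zero-variance columns are an error here and a warned drop in PCA.
* **PCA.** On the column-standardized matrix, mean-imputed if values are
  missing (flagged); full SVD so reconstruction from all components
  returns the standardized matrix to machine precision.
* **Ward clustering.** `scipy` Ward linkage on Euclidean rows; accessions
  and traits are clustered independently (default cuts: 3 row clusters,
  2 column clusters). For n = 4 the merges are verified against
  brute-force minimisation of the within-cluster SS increase.
* Multiple testing across traits/days is *not* corrected by default,
  matching the per-trait testing workflow; `benjamini_hochberg` is
  available for users who want FDR control.

The accession salt-response matrix feeds clustering with eight ChlF traits
(Fv/Fm, Fv′/Fm′, ΦP, qP, ΦNO, ΦNPQ, qN, NPQ) at the steady state of the
final fluorescence day, each as mean(salt)/mean(control) per accession,
joined with the accession-mean SIIT₁ and SIIT₂. Replicates are aggregated
by mean before accession-level clustering.

## Pipeline and determinism

Stages exchange data only through files (PNG masks/images, CSV tables,
YAML configs); the merged product is one long-format table
(plant, day, state, trait, value). Fluorescence trace CSVs carry columns
`time_s, signal, event`, where `event` labels samples inside protocol
windows (FoWin, FmPulse, L1…L4, Lss, D1…D3). All randomness flows from one
configured seed through fixed offsets (per-stage) and a CRC32 of the plant
id (per-trace), so re-running a pipeline with the same config reproduces
every output byte for byte; the run manifest records the config hash and
seed but no timestamps. Per-plant failures (missing trace, degenerate
levels, empty mask) are logged and skipped; structural errors abort.

## What the synthetic data does and does not show

The generator shares its functional forms with the estimators (piecewise
linear growth, single-exponential NPQ, exact palette colours), so passing
round-trip tests demonstrates correctness of the extraction chain — not
robustness to model misspecification. Real rosettes have serrated,
overlapping, moving leaves; real fluorescence induction has multi-phase
kinetics; real colour varies continuously. Absolute IoU or error levels
measured here are upper bounds on real-data performance. Known
limitations: no tray detection or lens correction, no leaf-level traits,
no plant tracking across repositioned pots, no OJIP/ETR analysis, and the
Gaussian noise magnitudes are conventions rather than instrument
estimates.
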