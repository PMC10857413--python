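# Methods

`cuffcomfort` models and analyzes within-subject cuff-pressure experiments:
pneumatic-cuff pressure applied to the thigh at 10, 20 and 30 kPa while
recording electrodermal activity (EDA), near-infrared-spectroscopy tissue
oxygen saturation (StO₂), and visual-analog-scale (VAS) discomfort ratings.
Because no per-subject laboratory recordings are publicly available, the
package pairs the analysis pipeline with a seeded synthetic-cohort
generator whose defaults emulate the two standard protocols:

* **1-min design** — 13 subjects, three 60-s pressure epochs in randomized
  order with 5-min rests, EDA only;
* **5-min design** — 10 subjects, 300-s epochs, EDA + NIRS.

Both begin with a 5-s, 60 kPa anchor stimulus whose VAS rating normalizes
each subject's discomfort scale.

## Signal models

### EDA

The simulated conductance (μS) is tonic + phasic + white measurement noise
(SD 0.003 μS, a modern amplifier's resolution-level noise).

**Tonic.** Subject baseline (≈6 μS) plus three pressure-locked terms:

* a small sustained rise, `tonic_gain · P` (default 0.002 μS/kPa), ramped
  with a 2-s raised cosine at epoch edges to avoid spectral splatter;
* an *adaptation dip*: a first-order relaxation (τ = 30 s) toward
  `−(0.185 + 0.0035 · P^1.38)` μS during pressure, recovering at rest.
  Tonic skin conductance habituates under sustained stimulation; the
  power-law pressure coupling is the Stevens form. The dip is what makes
  baseline-referenced mean SCL come out slightly *negative*, as the
  group-level reference values for these designs have it — absolute
  conductance cannot be negative, so such values must be
  change-from-baseline, and the pipeline defines mean SCL accordingly;
* an optional linear drift (default 0).

**Phasic.** Skin conductance responses (SCRs) arrive as an inhomogeneous
Poisson process: 1/min at rest, `1 + 0.40·P` per minute under pressure.
Each event adds a unit-peak Bateman kernel
`b(t) = A (e^{−t/τ_d} − e^{−t/τ_r})` with τ_r = 0.75 s, τ_d = 4 s — the
standard psychophysiology SCR shape. Amplitudes are lognormal (median
`0.13 · (1 + 0.03·P)` μS, log-SD 0.85) capped at 2 μS; single responses
beyond that are not physiological, and the cap keeps the heavy lognormal
tail from dominating cohort-level statistics.

### NIRS

A latent StO₂ trajectory relaxes at epoch onset toward

    S∞(P) = baseline − drop_max · (min(P, P_occ)/P_occ)^γ

with occlusion pressure P_occ = 20 kPa: above it the asymptote is constant
(vessels fully occluded — the vascular-occlusion plateau), below it the
response is convex (γ ≈ 2), which is what the reference decrease pattern
(11 → 56 → 58 pp) implies (a linear coupling cannot produce an 11 pp drop at
half the occlusion pressure alongside a 56 pp drop at occlusion). The
approach time constant shortens with pressure (τ_eff = τ·P_occ/P,
τ = 120 s): stronger compression occludes faster, which yields the small
but consistently positive 20 → 30 kPa increment. Recovery during rest uses
a separate fast constant (25 s) — post-occlusion reactive hyperemia is
rapid — so consecutive conditions do not contaminate each other's
baselines. Oxy/deoxy-hemoglobin are derived from the saturation at constant
total hemoglobin plus Gaussian noise (SD 1 a.u. on ~100 a.u.), so
oxyHb + deoxyHb is conserved and noise-free StO₂ round-trips the latent
trajectory exactly.

### VAS

`raw = clip(k · P/6 + ε, 0, 10)` with per-subject sensitivity k ≈ 0.85 and
ε ~ N(0, 0.5). The anchor rating at 60 kPa is generated by the same
stochastic rule (not pinned at 10), so the normalization
`100 · raw / anchor` is exercised nontrivially; values above 100% are legal
and logged.

### Heterogeneity and seeding

Subject profiles are drawn from independent truncated normals
(`PopulationParams`); dispersions are small relative to means so truncation
is essentially inactive. One master seed drives everything; per-subject,
per-signal substreams come from
`SeedSequence(master, spawn_key=(subject, stream))` with streams
0 = profile, 1 = condition order, 2 = EDA, 3 = NIRS, 4 = VAS. Every
simulated object is a pure function of (design, seed); manifests are
byte-reproducible.

## Analysis pipeline

1. **Decomposition** — phasic = zero-phase (forward–backward) 2nd-order
   Butterworth high-pass at f_c = 0.05 Hz; tonic = raw − phasic. Defining
   tonic as the exact complement guarantees lossless reconstruction
   (checked to 1e-9 μS). Recordings must be ≥ 10/f_c s for settling.
2. **SCR detection** — local maxima of the phasic trace (smoothed at 2 Hz
   for peak picking only); amplitude is the trough-to-peak rise of the
   *conductance* (smoothed phasic + tonic). Measuring on the conductance
   rather than the phasic trace alone restores the slow-wave share the
   high-pass removes — an isolated noise-free kernel is recovered at its
   injected amplitude (≈0.5% error), where a phasic-only reading loses
   ~8% — and it suppresses filter-rebound artifacts, whose conductance
   rise is negative. Threshold 0.01 μS; peaks closer than 1 s merged
   keeping the larger.
3. **EDA features per epoch** (epochs are half-open `[onset, offset)`):
   mean SCL = mean tonic over the epoch minus mean tonic over the 60 s
   immediately pre-onset; max SCR amplitude (0 if none); SCR count. The
   baseline window is 60 s rather than a token few seconds because the
   tonic component carries the low-frequency shot noise of incidental
   SCRs; a short reference window would swamp the small (~0.002 μS/kPa)
   pressure effect.
4. **StO₂** — per-sample `100·oxy/(oxy+deoxy)`; samples with non-positive
   total hemoglobin (or a ratio outside [0, 100] under noise) are flagged
   invalid, not raised. The *decrease* statistic tiles the epoch with 30-s
   blocks from onset (partial trailing blocks discarded) and subtracts the
   last full block's mean from the 30-s pre-onset baseline mean, in
   percentage points (absolute, not relative — occlusion drops StO₂ by
   tens of points). `block_stat="min"` is available where the minimum
   block is preferred.
5. **Inference** — one-way repeated-measures ANOVA per feature
   (F = MS_condition/MS_{condition×subject}; Greenhouse–Geisser ε and
   corrected p reported alongside, the sphericity-assumed p being the
   headline value), post hoc two-sided paired t-tests (uncorrected by
   default; Holm/Bonferroni by flag),
   pooled Pearson correlation of each feature against normalized VAS
   across all subject × condition rows (a single r per feature), and
   assumption checks
   (Shapiro–Wilk per condition, Mauchly's sphericity; k = 2 is trivially
   spherical). Standard tests run through pingouin/scipy; the test suite
   checks them against independent first-principles implementations
   (double-loop sums of squares, definitional correlation) to 1e-10.
   Degenerate inputs raise typed errors rather than returning NaN, with
   two documented conventions: zero condition sum-of-squares → F = 0,
   p = 1, and all-zero paired differences → t = 0, p = 1.
6. **Reporting** — "mean ± SD" cells, 3-decimal statistics, p-values
   display-floored at "0.000", "*" marking p < 0.05; stored JSON keeps
   full precision.

## Calibration

Population defaults were calibrated once, by simulation, so that cohort
feature summaries land inside the group-level reference bands for *both*
designs simultaneously, and frozen. Constraints that shaped them: epoch SCR
rates are pinned by the reference counts; amplitude medians by the reference
maximum amplitudes (a max-statistic over ~5–50 lognormal draws); and the
adaptation-dip parameters by the mean-SCL cells after accounting for the
DC that the SCR shot noise leaks into the tonic component (≈6 μS·s per
unit-amplitude kernel).

One tension is structural and worth stating plainly: the 5-min design's
reference mean-SCL increments (≈0.03 and 0.01 μS with ≈0.04 SDs) are
smaller than the shot-noise floor implied by the same design's SCR counts,
so *no* calibration can make cohort-mean SCL strictly non-decreasing in
~all replicates while also staying inside those bands. The defaults favor
the monotone qualitative finding (≈85% of replicates monotone, vs ≈67% at
the reference effect sizes themselves); the other features and the StO₂
decrease are monotone in ≥95% of replicates.

## Problem sizes and numerical choices

* Default sampling rates are 1 kHz (EDA) and 5 Hz (NIRS). Replicate
  studies and the acceptance script simulate EDA at 25 Hz — features agree
  with full-rate processing to within ~1% (tested) — and an anti-aliased
  `decimate_recording` helper provides the same speedup for 1 kHz inputs.
* The bundled `fast` preset also shortens rests to 150 s for exploratory
  sweeps; acceptance-grade runs keep the full 5-min rests.
* Piecewise first-order dynamics (dip, StO₂) are evaluated exactly per
  segment, not by ODE stepping; SCR kernels are truncated at 15·τ_d.
* Uniform sampling is validated to 1e-6 relative tolerance on read; epochs
  are half-open in seconds everywhere; file headers state units.

## What the synthetic data does not model

No motion artifacts, thermoregulatory or emotional SCRs, heartbeat or Mayer
waves in NIRS, instrument drift, or inter-signal coupling beyond the shared
pressure drive; inter-subject variability is independent-normal, not
identified from data. Passing tests therefore demonstrate that the
*pipeline* recovers known ground truth and reproduces the expected
qualitative pressure-response patterns under a plausible physiological
model — not that it has been validated on laboratory recordings. The
deconvolution-based decompositions (e.g. cvxEDA) that would sharpen SCR
separation at high rates are out of scope.
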