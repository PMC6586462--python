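# Methods

This note documents the models, defaults and design choices behind
`tftscreen`, in the order data flows through the package.

## Timer kinetic model

The tandem timer is modelled as a linear ODE system per fluorophore:
synthesis at rate β (AU/min) produces an immature (dark) species that
matures with first-order rate m_G (sfGFP) or m_C1 (mCherry; optionally two
sequential steps m_C1 then m_C2), and *every* species is degraded at the
first-order rate α of the tagged protein.  Degrading immature and mature
pools alike reflects that degradation acts on the protein, not on the
chromophore state.

Steady state (one-step mCherry):

    I_G = β m_G / (α (m_G + α)),   I_C = β m_C1 / (α (m_C1 + α))
    R(α) = I_C / I_G = m_C1 (m_G + α) / (m_G (m_C1 + α))

R is dimensionless, tends to 1 as α → 0 (stable protein), decreases
strictly monotonically in α, and approaches m_C1/m_G as α → ∞.  The
inversion α(R) has the closed form m_C1·m_G·(1−R)/(R·m_G − m_C1) in
one-step mode; two-step mode inverts the monotone forward map by bracketed
root finding.  R = 1 maps to the documented sentinel `half_life = inf`.
α = 0 is handled analytically (ratio limit 1, pools flagged unbounded),
never by division by zero.

Default maturation rates are m_G = ln2/6 min⁻¹ and m_C1 = ln2/40 min⁻¹ —
placeholders in the literature range for sfGFP and mCherry, exposed in the
config (`timer.mG`, `timer.mC1`, `timer.mC2`, `timer.mode`); they must be
calibrated per instrument before quantitative half-life inversion.
One-step mCherry maturation is the default because it admits the closed
forms used as test oracles; two-step is available where the mCherry
maturation delay itself matters.

Time courses propagate the linear system exactly with a matrix exponential
of the augmented (constant-input) system, so conservation properties hold
to solver-independent precision: with production off, immature+mature
pools of each fluorophore decay exactly as exp(−αt).

## Normalization chain

Order of operations: size-based QC → background correction and
screen-median scaling (raw scale) → log transform → per-plate spatial
correction → ratio channel from corrected logs.  The genome-wide screen
configuration uses no background subtraction; targeted and TA-array
configurations default to local non-fluorescent-control background
correction, mirroring how such screens are measured.

**QC.** A colony is a suspected failed cross when its size falls below
`min_size_fraction` (default 0.5) of the plate median size of passing
colonies.  The criterion is iterated to a fixed point, which makes the
filter idempotent (flagging can only raise the passing median, so a single
pass would not be).  Flagged colonies are excluded from every statistic
but never dropped from tables; replicate groups left with <2 passing
colonies are logged as reduced-confidence.

**Log transform.** Natural log by default (the base only rescales
z-scores).  The timer readout becomes additive: log_ratio = log mCherry −
log sfGFP.  Non-positive intensities are flagged `excluded` with NaN logs.

**Spatial correction.** A smooth surface f(row, col) is fitted per plate
and channel by 2-D locally weighted polynomial regression: tricube
weights over the `span` = 0.3 nearest fraction of colonies, polynomial
degree 2, one bisquare robustness iteration.  Corrected values are
value − f recentred so the plate median is exactly preserved; the fitted
surface is evaluated at and applied to every colony, flagged ones
included.  Degree 2 (rather than the more common local-linear fit) is
deliberate: local linear fits carry a curvature bias at plate edges for
bowl-shaped fields — the classic edge/centre artifact shape — which leaves
residuals correlated with the field; local quadratics reproduce linear and
quadratic surfaces exactly.  Degree, span, iterations and a
`median_filter` alternative are all in `NormalizationConfig`.  Plates with
fewer than 30 usable colonies fall back to median centring with a logged
warning.

**Background and median scaling.** With local controls, each colony's raw
intensity is reduced by the mean of its k = 4 nearest non-fluorescent
control colonies on the same plate; values driven to ≤ 0 are floored at
10⁻⁶ × the screen median and the colony flagged `excluded` (keeps the log
defined while marking the colony unreliable).  Median scaling divides each
channel by the screen-wide median over passing mutant colonies, making the
screen median exactly 1.

Reference-role colonies are included in the spatial fit by default (config
flag to exclude), since arrayed designs differ in how border/reference
positions are used.

## Scoring

Per readout (log sfGFP for abundance, log ratio for stability), robust
z-scores use the raw, *unscaled* MAD: z = (value − median)/MAD, with
median and MAD over all qc-passing mutant colonies pooled across plates.
The 1.4826 normal-consistency factor is available behind `scale_mad`
(default off), and a per-plate reference population behind
`reference="per_plate"`; pooling across plates is the default reading of
"the screen's central tendency".  A zero MAD raises a
degenerate-distribution error rather than emitting infinities.

Technical replicates are summarized by mean and sample SD (n−1) of their
z-scores; a one-sample two-sided t-test of the replicate z-scores against
0 (df = n−1) gives the per-gene p, and Benjamini–Hochberg step-up
adjustment across genes gives q.  The test is applied to z-scores (not raw
intensities) so the null is "no deviation from the screen centre" in
robust units; hit direction is enforced at thresholding time (positive z =
stabilization by default), keeping test and threshold orthogonal.  Genes
with no passing replicates, one replicate, or zero variance are reported
with a missing p and an explicit reason, never dropped.

## Hit calling

Verdict precedence per gene: `insufficient_data` (missing scores in either
screen) → `excluded_control_affected` (query z > 3 on both readouts but
|control z| ≥ 3 on either readout — the effect is not specific to the
query reporter, whatever its significance status) → `hit` (query z > 3
*and* q ≤ 0.05 on both readouts, control unaffected) → `not_hit`.  The
control criterion |z| < 3 operationalizes "control reporter unaffected";
the threshold is configurable.  All thresholds are echoed into the output
table and the run manifest, so verdicts are reproducible from the table
alone.

**Power of the dual-FDR leg.** With quadruplicate technical replicates the
per-gene t-test has 3 degrees of freedom, whose heavy tail bounds how
small p can get: |t| is ~2·δ/σ for a readout shift δ against per-colony
noise σ, and a k-fold change in degradation rate shifts the log-ratio by
at most ln k (timer-model bound), while the log-ratio noise is σ√2 when
channel noise is independent.  At genome scale the BH cutoff is roughly
0.05·(number of true effects)/m, so for a 3-fold stabilizer among
thousands of genes the ratio readout essentially cannot reach q ≤ 0.05
with n = 4, even though its z-score clears 3 comfortably.  The package
therefore always reports the z columns alongside q, and the benchmark
suite tracks the threshold-plus-control criterion separately
(`z_sensitivity`) from the full dual-FDR verdict.  Screens wanting a
powered FDR leg need more replicates or a variance-pooling test, which is
out of scope here.

**Fold-change screens** (TA-array style) compare background-corrected
mean GFP between mutant and wild-type backgrounds per strain: fold change
F = mutant mean / wt mean, two-sample Student's t-test on replicate
intensities, flagged at unadjusted p < 0.05 as such screens are
conventionally read, with BH q reported alongside as the stricter modern
filter.  **Targeted rescreens** rank strains by median-normalized sfGFP
(screen median = 1) with a t-test against a designated reference strain.

## Assays

**Chase fitting.** After translation shutoff the remaining protein decays
as exp(−αt).  Each replicate trace is divided by its loading control (if
any), normalized to t = 0, and log(value) is regressed on time by OLS
pooled across replicates: α = −slope, t½ = ln2/α, CI from the slope's
standard error with a t quantile at df = points − 2.  Log-linear least
squares (rather than nonlinear exponential fitting) matches how band
quantifications normalized to t = 0 are analysed and admits a closed-form
oracle; non-positive points are dropped with a warning, and a
non-negative slope is reported as "no detectable decay" with the t½ = ∞
sentinel rather than a spurious number.

**Flow summaries.** Per-replicate channel means are blank-corrected by the
mean of a non-fluorescent control, normalized to the wild-type sample
(wt ≡ 1 by construction), with the corrected mCherry/sfGFP ratio as the
stability readout and two-sample Student's t-tests against the wt
replicates.  Event gating and per-cell distribution modelling are out of
scope; input is a tidy per-event or per-replicate table.

## Synthetic screens

The generator emulates the statistical structure the analysis assumes:
1536- or 384-format plates; four technical replicates pinned as adjacent
2×2 blocks; per-gene expected intensities from the timer closed forms at
α = baseline × multiplier; per-colony log intensities = log expected +
spatial field + N(0, noise_sd) independently per channel; colony sizes
~N(100, 10) with a `dropout_rate` fraction of small failed crosses whose
fluorescence scales down with size.  Defaults: 4608 genes on 12 full
1536-format plates, baseline α = ln2/12 (the regime of a short-lived
mislocalized tail-anchored reporter; the control reporter is simulated at
the same baseline so both screens share dynamic range), noise_sd = 0.1,
dropout 2%, 20 planted 3-fold stabilizers and 5 confounders spread
deterministically across plates.  Confounders multiply α in *both*
screens, mimicking perturbations (organelle physiology, maturation
conditions) that move the timer readout non-specifically.

Spatial fields are multiplicative (additive in log) with `amplitude` the
peak log deviation, and are centred to zero mean over the plate grid:
they model *within-plate* structure, while a nonzero field mean would be
an inter-plate brightness offset that no per-plate correction can remove
(and which the generator does not claim to simulate).  Shapes: linear
gradient, radial bowl, and smooth-random surfaces built from three cosine
modes capped at 0.75 periods across the plate — plate artifacts (edge
drying, agar thickness, incubator gradients) vary at plate scale, which
is also the smoothness regime local regression assumes.

What the generator does **not** emulate — so what passing benchmarks do
not certify about real data: gene-to-gene baseline expression variability
(real screens have biological spread that inflates the MAD), correlated
channel noise from colony morphology (which would *reduce* ratio noise),
pinning-robot artifacts beyond smooth fields, autofluorescence spectra,
batch/plate-reader drift between plates, and growth dynamics.

Chase series are 2^(−t/t½) with multiplicative log-normal noise per
point; flow events are strain mean × unit-mean log-normal multipliers
plus blank offset.  All generators are pure functions of (config, seed).

## Benchmark problem sizes

`scripts/acceptance.py` and the acceptance tests run the pipeline end to
end at these sizes, chosen to give stable estimates on a single CPU:

- hit recovery: the full default screen (4608 genes × 4 replicates, both
  reporters), 20 seeds in the test suite, 10 in the script;
- null false-positive control: 1152-gene (3-plate) pure-null query
  screens, 100 seeds in the suite, 40 in the script — FDR behaviour under
  the null does not depend on screen size;
- spatial residuals: 1152-gene screens with 2-fold (ln 2) fields cycling
  linear/radial/smooth-random, 20 seeds (12 in the script); the statistic
  is the plate-centred correlation between corrected log values and the
  injected field, pooled over the run's plates;
- chase recovery: 1000 series (500 in the script) at t½ = 12 min, 5
  points, 3 replicates, 10% noise;
- timer consistency: 100 random parameter draws against LSODA integration
  to a 40/min-rate horizon.

## Numerical choices and degenerate inputs

Weighted local fits add a 10⁻¹⁰ ridge to the normal equations and fall
back to uniform k-NN weights for isolated evaluation points; coordinates
are rescaled for conditioning.  TSV readers parse floats in round-trip
mode so serialization is bit-exact.  Nearest-control and nearest-neighbour
selections use partial sorting; distance ties between controls are broken
arbitrarily (document layouts accordingly).  Empty layout positions are
flagged `excluded` at QC.  All randomness flows through
`numpy.random.default_rng` seeds; outputs are byte-identical across runs
and independent of thread count (the pipeline is single-threaded by
construction).

## Known limitations

- The dual-FDR hit verdict is conservative at n = 4 replicates (see
  "Power of the dual-FDR leg"); interpret hit lists together with the
  z-threshold candidate set.
- The timer inversion assumes maturation rates are known and constant;
  oxygen, temperature and vacuolar quenching violate this in ways the
  model does not capture, and proteasomal vs vacuolar degradation leave
  different fluorescent remnants that are not distinguished.
- Local regression cannot separate a true biological gradient arranged
  spatially (e.g. sorted libraries) from a technical field; randomized
  layouts are assumed.
- The chase fit assumes single-exponential decay; biphasic decays will be
  averaged, visible as low r².
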