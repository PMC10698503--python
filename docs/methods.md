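# Methods

Models, assumptions, parameters, and numerical choices for each `beadphos`
stage. All defaults are plain function/`SimConfig` arguments and can be
overridden.

## Library design

A library is a template string with exactly one acceptor slot `Z` (expanded
to pS and/or pT) and any number of variable slots `X`, each with a declared
residue set. Expansion is exhaustive and lexicographic, so library order is
deterministic; duplicate sequences are an error rather than silently dropped.
The built-in dephosphorylation panel (`build_dephos_panel`) uses the template
`LGAXXXZXLXXVSA` and produces 94 phosphopeptides balanced pS/pT and +1-Pro vs
+1-Ala (47/47), plus one unphosphorylated control, each on a distinct bead
code. Phosphosites are accepted in several notations (lowercase `t`, `pT`,
`(pT)`, `T(ph)`) and normalized to a canonical lowercase form.

## Bead decoding and QC

Beads carry a lanthanide-ratio vector; decoding assigns each bead to the
nearest code in Euclidean distance. A bead is left unassigned when the
nearest code is farther than `max_distance` (default: half the minimum
inter-code spacing) or when two codes tie within relative tolerance 1e-9.
Per-code summaries use the mean/SD or median/MAD of bead intensities within
each (code, condition, replicate) cell.

QC gate: per-bead start (t = 0) intensities of the unphosphorylated
negative-control code define a threshold `median + 1.5·SD`; a code passes
when its per-code median start intensity is at or above the threshold. This
flags synthesis failures (no peptide → no phospho-signal) before scoring.
At least two negative-control beads are required.

## Dephosphorylation scoring and kinetics

The score for one time course on the default grid
(0, 15, 30, 60, 120, 240 min) is

    score = 1 − mean(last n_final points) / I(0),    n_final = 3.

Scores are bounded above by 1 (complete loss); negative scores (signal
increase) are retained but flagged, since they indicate staining artifacts
rather than chemistry. The score never depends on any model fit.

Kinetics are summarized, where applicable, by a bounded nonlinear
least-squares fit of `I(t) = C + A·e^(−kt)` with all parameters ≥ 0
(`scipy.optimize.curve_fit`). Initialization: `A₀ = I(0) − I(end)`,
`C₀ = I(end)`, and `k₀` from a log-linear regression on baseline-subtracted
values. A fit is rejected (`fit_ok = False`) when the solver fails, when
`k ≤ 1e-9`, or when the amplitude is numerically zero
(`A ≤ 1e-9·max(max I, 1)`) — with no amplitude the rate is unidentifiable
even if the solver reports one. Replicates are aggregated as mean ± SD
(ddof = 1); a single replicate is marked low-confidence.

## Binding affinity

Equilibrium binding follows the Langmuir isotherm
`y(c) = y_max·c/(c + K_d)` on the default titration grid
(0, 15, 31, 62, 125, 250, 500, 1000, 2000 nM). Two-parameter local fits are
only trustworthy for peptides that approach saturation; for weak binders
`y_max` and `K_d` trade off and per-replicate estimates scatter over decades.
The global scheme therefore:

1. fits `(y_max, K_d)` locally on a saturating subset — curves whose maximum
   intensity exceeds an absolute threshold (default 12,000 units) or, in
   relative mode, the given quantile (default 75th) of curve maxima;
2. averages those `y_max` values into a shared plate-level `y_max`;
3. refits each curve with one free parameter, minimizing SSE over
   `log10 K_d ∈ [−2, 6]` with `scipy.optimize.minimize_scalar`
   (bounded, `xatol = 1e-10`).

`K_d` estimates above 5× the top concentration are reported but flagged
censored (extrapolated beyond the sampled range). Replicate `K_d`s aggregate
by mean or median, optionally in log space (geometric mean), which is less
biased under multiplicative error.

Free-energy differences use `ΔΔG = R·T·ln(K_d,var / K_d,ref)` with
R = 1.9872e−3 kcal/(mol·K) and T = 298.15 K by default, so a 10-fold affinity
loss is +1.364 kcal/mol. Substitution tables index ΔΔG by (position, residue)
relative to a reference sequence; reference residues sit at exactly 0 and
conflicting claims for one cell are an error.

## Phosphosite classification

TMT-style channels are normalized by equalizing channel sums to their mean,
then log2-transformed. Regulation per arm (PP1 or B55 inhibition vs control)
uses Welch's unequal-variance t-test with a conjunctive gate:
p < α (default 0.05) AND log2 fold change > 0.58 (≈1.5-fold). Sites are
classified PP1 / B55 / ambiguous (both) / unregulated. Note that at n = 3
replicates per group Welch's test is conservative (empirical null rate ≈0.03
at nominal 0.05); it is well calibrated by n = 10. The gate is one-sided on
purpose: these are loss-of-phosphatase experiments, so only increases count.

Missing label-free values are imputed from a width-shifted normal per column,
`N(μ − 1.8σ, (0.3σ)²)` with μ, σ from observed values (the standard
left-shifted imputation for values missing because they fall below detection);
at least 10 observed values per column are required. Interactors are called
at ≥2-fold enrichment over control AND p < 0.05 (Welch). Regulated sites are
joined onto the interactome to count substrates on vs off called interactors.

## Motif analysis

Sequence windows are ±7 residues around an S/T/Y center, padded with `_` at
protein ends; pads are excluded from all counts. Frequency logos are
per-position residue frequencies; enrichment logos are foreground − background
frequency differences tested per cell with a pooled two-proportion z-test
(Fisher's exact test optional), with pseudocount `1/(n + 20)`.

RVxF docking-motif scanning matches `[RK] x{0,1} [VI] x [FW]` — reported as
variant RVxF (length 4) or RxVxF (length 5) — where by default the core `x`
positions exclude proline and `X` (unknown residue) never matches; a strict
mode matches the consensus letters literally. Overlapping matches are all
reported, and phosphosites inside a match are annotated. A match's predicted
ΔΔG is the sum of the substitution-table cells its residues cover (flagged
partial when cells are missing). Phosphosites stratify as near/far from a
motif by a fixed sequence-position boundary (default 1000, inclusive) or by
radial distance to the nearest match.

## Synthetic data

All simulators draw from a single `numpy.random.default_rng(seed)`, so every
output is byte-reproducible. Problem sizes are this package's own choices,
picked to be large enough to measure recovery and small enough to run in
seconds.

- **Dephos**: the 95-code panel, ~55 beads/code, 3 replicates, 4 lanthanide
  channels with 2% code jitter. True rates come from a rule-based model
  (base 0.01/min; pT ×3; +1-Pro ×0.3; basic at −2/−3 ×1.5; acidic at +2
  ×0.5; control 0). Intensities are lognormal amplitudes (μ = ln 1000,
  σ = 0.25) over a background of 100, with 5% multiplicative and small
  additive noise; 5% of codes are planted synthesis failures (background
  only), which the QC gate should recover exactly.
- **Binding**: an RVxF substitution panel around `AKNSRVTFSEDDEII`
  (motif at 5–8) with planted ΔΔG per cell — core-position prolines strongly
  destabilizing (U(2.2, 2.8) kcal/mol), phosphorylated cells U(1.5, 2.2),
  others U(−0.5, 2.0) — converted to K_d around a 125 nM reference with
  y_max = 15,000 and 3% noise.
- **Phosphoproteome**: 5,000 sites with planted classes (10% PP1, 20% B55,
  2% both), effect sizes N(1.5, 0.2) truncated at 0.8, replicate noise 0.15;
  a 600-protein label-free table with 5% interactors (log2 effect 2.0, noise
  0.5) and logistic intensity-dependent (MNAR) missingness; and one long
  protein (`SYNLONG1`, 3,256 aa) carrying a single RxVxF motif at 504–508
  with 40 phosphosites planted near (≤1000) and 60 far, spaced ≥12 residues
  so flank edits never collide.

## Limitations

- The kinetic model is single-exponential; biphasic decays are summarized by
  the score only.
- The global-`y_max` scheme assumes a common saturation plateau across the
  panel; peptides with genuinely different `y_max` bias their `K_d`.
- `K_d` beyond ~5× the top concentration is extrapolated (flagged censored).
- Welch at n = 3 is conservative, not anti-conservative; detected-effect
  counts at small n understate weak effects.
- The simulators emulate assay structure and noise, not photophysics,
  bead-size variation, or peptide synthesis chemistry.
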