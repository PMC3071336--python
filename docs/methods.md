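# Methods

## Circuit models

The eRIC model is the four-element series–parallel network
Z(ω) = Rc + jωI + Rp/(1 + jωRpCp). Its real part falls monotonically
from Rc + Rp at DC to Rc at high frequency — the circuit's expression of
the frequency dependence of resistance caused by peripheral obstruction —
and its reactance crosses zero at

    ω_res² = (Rp²Cp − I) / (I Rp² Cp²),

defined only when Rp²Cp > I; otherwise the reactance is positive
everywhere and no resonance exists. The aRIC model shunts the whole eRIC
branch with an extrathoracic compliance Ce,
Z_aRIC = Z_eRIC/(1 + jωCe·Z_eRIC), which leaves the low-frequency
behaviour essentially untouched and raises apparent resistance above the
resonant frequency. Ce = 0 reproduces eRIC exactly, so the two families
are nested.

Conventions: ω = 2πf with f in Hz; resistances kPa·s/L, inertance
kPa·s²/L, compliances L/kPa. Rp = 0 or Cp = 0 are accepted by the
evaluators as degenerate branch limits but excluded from fitting bounds.
Both evaluators are verified in the tests against naive complex
series/parallel composition of the component impedances to 1e−12
relative.

## IOS indices

Grid lookups interpolate linearly in f (the IOS grid is close to uniform
over 3–35 Hz and the "Goldman triangle" picture of AX is itself
piecewise-linear); queries outside the grid span are refused rather than
extrapolated. Fres is the first negative-to-non-negative crossing of X,
linearly interpolated; with noisy replicate averages multiple crossings
can occur and the lowest-frequency one wins. AX integrates |X| by
trapezoids from 5 Hz to Fres, the crossing contributing a triangle.
Conventions for degenerate reactance shapes: X(5) ≥ 0 gives AX = 0
(resonance at or below 5 Hz); X < 0 over the whole grid leaves Fres and
AX undefined, reported as flagged missing values, never silently zero.

AX computed on a group-averaged spectrum is not the group mean of
per-subject AX — integration and averaging do not commute — so the two
are compared as a consistency band (±10%), not an equality.

## Parameter estimation

The objective is the unweighted sum of squared R and X residuals at the
fit frequencies (default 3, 5, 10, 15, 20, 25 Hz; 35 Hz supports index
interpolation but is excluded from fitting). R and X share units and
magnitude range in paediatric spectra, so equal absolute weighting is
appropriate.

Optimisation uses trust-region-reflective least squares in log-parameter
space (Ce, whose natural lower bound is 0, stays on the linear scale)
with bounds Rc, Rp ∈ [1e−3, 5] kPa·s/L, I ∈ [1e−5, 0.05] kPa·s²/L,
Cp ∈ [1e−3, 2] L/kPa, Ce ∈ [0, 0.1] L/kPa — a box generously spanning
physiological child values. Multi-start (default 8): one heuristic start
read off the spectrum (Rc from R at the top fit frequency, Rp from the
resistance drop, I from the top-frequency reactance, Cp from 1/(ω|X5|))
plus a seeded scrambled-Sobol' draw over the log-bounds box. The best
start wins; ties go to the lowest start index, making results
bit-reproducible for a given seed. A transparent log-lattice exhaustive
search (`grid_search_oracle`) serves as an independent lower-bound check:
the optimiser must never lose to the lattice.

Identifiability: on noiseless model-generated 6-point spectra all four
eRIC constants are recovered to better than 1e−6 relative. The recovery
test suite draws truths from the physiological paediatric range
(Rc 0.1–1 kPa·s/L, I 0.5–5 mPa·s²/L equivalent, Rp 0.1–1.5 kPa·s/L,
Cp 0.01–0.3 L/kPa) rather than the full optimisation box: in extreme
corners of the box (Rp near its floor) the peripheral branch contributes
nothing measurable and Cp is structurally unidentifiable from six
frequencies, a property of the model, not of the optimiser. When Cp is
large the peripheral corner frequency 1/(2πRpCp) falls below the 3 Hz
grid edge and Rp becomes weakly identified under noise; this visibly
inflates the variance of fitted Rp in small groups.

## Synthetic cohort generator

The generator emulates the study design: groups H (n=7) and SAI (n=19);
a 2006 baseline (pre-bronchodilator only) and a 2008 visit measured pre-
and post-bronchodilator. Per subject a latent eRIC parameter vector is
drawn log-normally around the group archetype means, parameterised so the
archetype mean is the arithmetic mean (σ² = ln(1+CV²),
μ = ln m − σ²/2), because published group values are arithmetic means.
Growth (2006→2008) and bronchodilator (pre→post) effects multiply the
latent parameters; measurement adds independent homoscedastic Gaussian
noise (default sd 0.01 kPa·s/L) to R and X at each grid frequency, with
the resistance channel redrawn (≤100 times) to stay positive.

Defaults. Rp and Cp archetype means follow the published group-mean
trajectories (SAI Rp 0.824, Cp 0.045; H Rp 0.501, Cp 0.115 at baseline);
the Rp/Cp growth and bronchodilator multipliers are the published percent
changes (e.g. SAI growth Rp ×0.73, Cp ×1.25; SAI bronchodilator Rp
×0.79, Cp ×1.35). No group means exist for Rc and I, and no dispersion
or effect sizes are published for them, so Rc = 0.35 (H) / 0.40 (SAI)
kPa·s/L, I = 0.0020 (H) / 0.0018 (SAI) kPa·s²/L, CV = 0.25 for all
parameters, and mild Rc effects (growth ×0.90, bronchodilator ×0.95;
I unchanged) are calibration choices, picked once so that synthetic
spectra resemble the published averaged curves (R5 ≈ 0.5–0.7 kPa·s/L,
Fres ≈ 15–22 Hz); all are overridable in `GroupArchetype`.

One cohort seed expands into per-record substreams through a CRC-32 hash
of (subject id, visit, condition), so growing the cohort never perturbs
existing subjects' draws.

What the generator does not emulate: within-session replicate structure
(device software averages 3–5 replicates upstream, so only the
post-average noise floor is modelled), frequency- or amplitude-dependent
noise, upper-airway shunt in the truth (generation is eRIC-based;
aRIC-true generation is available by fitting aRIC but is not the
default), demographic covariates, and any correlation between a
subject's baseline severity and their effect sizes. Passing tests
therefore demonstrate pipeline correctness and statistical power under
idealised noise, not robustness to artefacts of real paediatric
measurements (leaks, swallowing, vocalisation).

## Cohort statistics

Cell summaries are arithmetic means per (group, visit, condition,
model). Percent changes are computed on cell means, matching how a
published change table relates to its source mean tables, and rounded
half-away-from-zero to integer percent for display only. Within-subject
contrasts (growth; bronchodilator response) use the paired Student t on
(after − before); between-group contrasts use the Welch two-sample t with
Welch–Satterthwaite degrees of freedom, because a paired test is
impossible for the 19-vs-7 comparison. Zero-variance difference vectors
are reported as limiting values with an explicit flag. Correlations
(Cp vs AX, Rp vs fdR, and between-model parameter agreement) pool all
visit-conditions and report OLS slope, intercept and Pearson r. Raw
p-values carry a significance flag at α = 0.05; no multiple-testing
correction is applied, matching the study design being emulated.

## Problem sizes and determinism

The default test and acceptance runs use the study-sized cohort
(26 subjects, 78 records), 100-draw recovery sweeps and a 5-point
log-lattice for the oracle comparison; every stochastic step is driven by
an explicit seed and all pipeline outputs are byte-deterministic given
(data, options).

## Known limitations

Per-subject data from the original study are not available, so group
means and p-values from it can only be checked through the arithmetic
its printed tables make verifiable; standard errors for fitted parameters
are not computed; Mead-type six-element and constant-phase tissue models
are out of scope.
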