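# Methods

## Survival read-outs

All survival values are stored as dimensionless fractions in [0, ∞);
conversion to percent happens only at display time.

**FMCA survival index.** `SI = (mean treated − mean blank) / (mean control −
mean blank)`, with blanks and controls pooled per experiment. A negative
blank-corrected numerator is clipped to 0 rather than raised as an error:
wells with near-complete kill routinely read below blank plus instrument
noise, and the biologically meaningful value there is zero survival. A mean
control signal at or below the blank, by contrast, is a *degenerate plate* —
a failed experiment — and raises an error tagged with the experiment id.
The SI is invariant under a common gain factor applied to all signals.

**GFP monolayer SI** uses the same formula; blank wells are subtracted when
present and omitted from the formula otherwise (the blank term is an
instrument-background correction, and GFP imaging set-ups often provide
none).

**AUTO SI (spheroid GFP).** Each well is normalized to its own fluorescence
immediately before drug addition: `AUTO SI = signal(endpoint) /
signal(day 0)`. There is deliberately no control-well term, so an untreated
spheroid that doubles scores 2.0. Wells are paired by well coordinate; when
kinetic reads exist at intermediate timepoints they are stored in the well
table but only the first and last read enter the analysis. Because the
untreated fold-growth *g* enters every arm once, the raw Bliss ratio of AUTO
SI values equals ρ/g rather than ρ; `summarize_conditions(...,
auto_si_relative_to_control=True)` therefore re-expresses AUTO SI relative
to the same experiment's mean control AUTO SI — a clearly derived quantity —
and the reporting pipeline uses this normalized form when scoring spheroid
GFP screens. Duplicate-well AUTO SIs are averaged per condition (the
self-normalization is inherently per-well, so signal-level averaging does
not apply to this read-out).

**Clonogenic SF.** `SF = mean treated colonies / mean control colonies`,
with no plating-efficiency correction (single-cell suspensions from
dissociated spheroids do not admit a meaningful plating-efficiency
assessment in this design). Colony counts are validated as non-negative
integers on input.

**Aggregation order.** Within an experiment, duplicate wells are averaged at
the raw-signal level and normalized once, yielding exactly one value per
(experiment, condition). For equal duplicate counts this is numerically
identical to normalizing first and averaging after; the order is fixed for
determinism.

## Interaction scoring

Bliss independence defines the expected combination survival as the product
of the single-treatment survivals, `S_e = S_d × S_r`. Scoring proceeds per
combination condition:

1. within each experiment that carries all three arms, form
   `ratio = S_o / (S_d × S_r)` from that experiment's own values
   (per-experiment pairing; shared experiment-level effects cancel);
2. average the ratios across experiments;
3. test the ratios against 1 with a one-sample t-test, df = n − 1,
   two-tailed, α = 0.05 by default.

Significance (`p < α`) and synergistic tendency (mean ratio < 1, strict) are
stored as separate flags because the rendered tables mark them separately
(asterisk vs bold); a synergy *call* combining both is left to the consumer.
Ratios are tested untransformed by default; a `log_ratios` flag tests
log-ratios against 0 for sensitivity analysis (the reported mean stays
arithmetic). No multiple-testing correction is applied by default — the
Bliss deviation-from-additivity criterion is already conservative — but a
Holm step-down adjustment is available behind a flag.

**Inclusion filter.** A concentration enters tabular results only when its
*across-experiment mean* drug-only survival strictly exceeds 0.25. The mean
(rather than a per-experiment gate) is used because tables gate whole rows;
the boundary value 0.25 itself is excluded. Filtered rows render as "N/A"
and carry no ratios or statistics.

**Degenerate cases.** One experiment yields a ratio but no p-value;
replicate ratios identical to within 1e-12 (relative) are treated as
zero-variance and yield no test rather than a spuriously huge t statistic
from floating rounding residue; an expected survival of 0 (both single
treatments fully lethal) raises an undefined-ratio error; a combination
condition with no experiment carrying all three arms raises a pairing error.

## Synthetic screens

The generator emulates the screening design the analysis targets: 384-well
plates with blank wells, untreated controls, a 9-point half-log drug
concentration series, radiation arms at 4 and 6 Gy, the full combination
grid, duplicate wells per condition, and 5 independent experiments by
default (screens of this type run 3–7). Seeding densities (10,000
cells/spheroid, 1,000 cells/monolayer well) are carried as design metadata
only.

Ground truth: drug-only survival is a Hill curve `floor + (1 − floor) /
(1 + (c/EC50)^h)`; radiation-only survival is linear-quadratic
`exp(−αD − βD²)`; combination survival is `S_d · S_r · ρ`. Because ρ
multiplies survival only when both treatments are present, the single-agent
arms stay exactly on their marginal curves and the pipeline's mean
interaction ratio estimates ρ itself — parameter recovery is therefore a
sharp test of the whole pipeline, not of the generator.

**Radiation presets** are calibrated to the survival regime of HCT116
spheroid/monolayer screens: the spheroid clonogenic curve solves the 2×2
linear system through SF = 0.361 at 4 Gy and 0.0813 at 6 Gy, giving
α = −0.0724 Gy⁻¹, β = 0.0818 Gy⁻². A negative α is accepted when calibrated
from data: the curve is used only at the 4 and 6 Gy arms it was fitted
through (it exceeds 1 by at most ~2% below 1 Gy). Total-cell-kill read-outs
are far less radiation-sensitive than clonogenicity and are preset as pure
exponentials through SI = 0.931 (spheroid) and 0.743 (monolayer) at 6 Gy;
the monolayer clonogenic preset passes through SF = 0.10 at 4 Gy with a
conventional α/β of 10.

**Default drug panel** (invented archetypes spanning the screen's range): a
near-inert drug (EC50 5 mM), a potent drug whose top concentrations fall
below the 25% filter (EC50 2 µM, floor 0.02) — reproducing the "N/A at the
highest concentrations" table pattern — and a partial-kill drug (floor 0.5)
that stays included at every concentration.

**Noise model.** Fluorescent well signal =
`control_signal · S · exp(ε_exp) · exp(ε_well) + blank_level`, with ε terms
zero-mean Gaussian on the log scale, σ² = ln(1 + CV²); defaults: 10% well
CV, 5% between-experiment CV, control signal 10,000 AU over a 100 AU blank.
Multiplicative log-normal noise reflects the scale-proportional error of
plate fluorometry; the shared per-experiment factor models
experiment-to-experiment variability and cancels in interaction ratios, as
it does in a real paired design. Blanks carry well noise but no experiment
factor (instrument background, not biology). Spheroid GFP wells emit a
baseline read at 0 h and an endpoint read at 168 h with an untreated
fold-growth of 2. Clonogenic wells always draw Poisson colony counts with
mean `plating_cells · S` (200 cells plated by default); a deterministic
"zero-noise" clonogenic mode would require non-integer counts, so exact
identities are tested on the fluorescence read-outs and clonogenic
correctness is a law-of-large-numbers property (1% at 10⁴ wells).

## gamma-H2AX scoring

Extent bins map percent positive cells to plus signs with half-open
intervals — 0 → "−", (0, 25] → "+", (25, 50] → "++", (50, 75] → "+++",
(75, 100] → "++++" — so integer-percent conventions (1–25%, 26–50%, …) are
reproduced exactly while continuous inputs remain well-defined. Intensity
is graded 1–4. The weighted score adds plus count and intensity; a region
with no expression has no intensity and scores 0, making the attainable
range {0} ∪ [2, 8]. Inputs are human- or tool-supplied per spheroid region
(center, margin, periphery); image analysis is out of scope.

## What the simulations do and do not show

Passing tests on simulated screens demonstrate that the pipeline is
calibrated (exact ratios of 1 under additive ground truth), has nominal
type-I error under the modeled noise, and recovers a multiplicative
interaction factor without bias. Real screens add features the generator
does not model: spatial plate effects (edge evaporation, gradients),
non-log-normal outliers, drug-specific curve shapes that deviate from Hill,
radiation interactions that vary with concentration and dose in structured
ways, and oxygen/penetration gradients inside spheroids that make the
spheroid-vs-monolayer contrast mechanistic rather than statistical. Results
on simulated data therefore validate the *analysis*, not any biological
claim.

## Problem sizes and numerics

The statistical property checks use 1,000 simulated screens for the
false-positive rate and 500 replicates per interaction factor for recovery
(each screen: 9 concentrations × 2 doses × duplicate wells × 5–7
experiments), sizes at which the binomial 99% band and a ±0.03 recovery
tolerance are well resolved while the full suite runs in well under a
minute of simulation time. All simulation randomness flows through a single
`numpy` generator seeded per run; identical config + seed reproduces
byte-identical well tables. Condition ordering (drug, descending
concentration, dose) is a strict total order, making every CSV and rendered
table deterministic.

## Known limitations

- The interaction model is Bliss independence only; Loewe additivity,
  Chou–Talalay and response-surface models are out of scope.
- No IC50 curve fitting: only a log-linear half-effect interpolation helper
  is provided as plumbing.
- The t-test on 3–7 ratios has limited power and assumes approximate
  normality of ratios; the log-ratio variant is provided for checking
  sensitivity to that assumption.
- Plate geometry is metadata; no spatial normalization is attempted.
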