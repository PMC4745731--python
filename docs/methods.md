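# Methods

## Scoring model

`pascore` scores pathway activation per case sample by comparing each gene's
expression against the distribution of the same gene in a set of control
samples, then aggregates gated log fold-changes along signed pathway
definitions, and finally folds pathway activation over drug targets.

The pipeline is deliberately linear:

1. **CNR** — for gene *g* and case sample *s*,
   `CNR[g, s] = case[g, s] / mean(control[g, :])`, with the arithmetic mean
   of linear-scale control values. CNR is undefined (and the gene is
   excluded from scoring in that sample) when the case value or the control
   mean is not strictly positive.
2. **BTIF** — the gene contributes only when both a significance gate and a
   magnitude gate open: p < α from the deviation test below, and CNR outside
   `(fc_low, fc_high)` = (0.66, 1.5) by default. Both bounds and α are
   exposed on every interface.
3. **PAS** — `PAS[p, s] = Σ_n ARR(n,p) · BTIF(n,s) · log10(CNR(n,s))` over
   the pathway's members present in the measured gene universe. `lg` is read
   as log10; any other base would only rescale all PAS and DS uniformly.
4. **DS** — `DS[d, s] = Σ_t Σ_{p ∋ t} AMCF(p) · PAS[p, s]` over the drug's
   targets, honouring multiplicity: a pathway containing k targets of the
   drug contributes k times.

### Deviation test

The test of "this case value differs from the control distribution" is a
two-sided single-observation prediction-interval t-test on log2 values:
with m controls whose log2 values have mean m̄ and sample sd s,

    t = (x − m̄) / (s · √(1 + 1/m)),   df = m − 1.

Under multiplicative lognormal noise this is the exact level-α test that a
single new observation was drawn from the control law — unlike a one-sample
t-test it accounts for the variance of the new observation itself, not only
of the control mean. Degenerate case: when the control sd is zero, p is set
to 1 if the case log2 value equals the control mean and to 0 otherwise,
so perfectly constant controls either never or always pass the significance
gate (the fold-change gate still applies).

No multiple-testing correction is applied across genes: the gate is a
per-gene filter feeding a sum, not a discovery list. α is a tunable
parameter (default 0.05), and the two gates together make the per-gene
flagging rate strictly below α under the null.

### Missingness

A pathway with zero measured members has no evidence either way; its PAS is
reported as missing (`NA` in output tables), distinct from an exact 0, which
means "measured but no gene passed the gate". Drug scoring treats missing
PAS as a 0 contribution but decrements the per-drug `coverage` counter
(number of (target, pathway) pairs actually backed by a measured pathway),
so silent information loss is auditable. We chose contribution-0 over
missingness propagation so that a drug remains scoreable when one minor
pathway is unmeasured.

### Responder rules

Two rules are implemented: `cutoff` (DS > cutoff, default 250 — a magnitude
suited to genome-scale pathway collections where hundreds of gene terms
accumulate) and `nonzero`/`positive` (DS > 0). "Non-zero" is deliberately
read as *strictly positive*: a drug with DS < 0 targets pathways whose
blockade would, under the model, reinforce tumour-promoting signalling, so
it cannot mark predicted benefit. The cutoff is a free parameter on every
interface; 250 is the default used by the cohort-correlation analysis.

### Validation statistics

`correlate_with_trials` computes Pearson r between trial response rates and
predicted responder fractions, both on the percent scale, with a two-sided
p-value from the t distribution with n − 2 df. r is computed via
`numpy.corrcoef`, which returns ±1 exactly on colinear input; a constant
coordinate raises an error rather than returning NaN. `compare_cohorts`
builds the 2×2 responder table for two cohorts and applies Fisher's exact
test (two-sided by summation of tables with probability ≤ observed, via
`scipy.stats.fisher_exact`); the test suite cross-checks it against an
independent full-enumeration oracle. Sidedness is a convention choice: the
two-sided variant matches mainstream statistics libraries.

## Synthetic cohorts

The generator emulates the statistical structure the scoring model assumes,
nothing more: each gene has a log2 baseline drawn once from
Normal(`baseline_log2_mean` = 8, `baseline_log2_sd` = 2) (typical microarray
intensity scale), and every sample observes
`2^(baseline + Normal(0, noise_sigma))` — multiplicative lognormal noise,
the simplest model under which the log-scale prediction-interval test is
exact. Activated pathways shift the case generative mean: activator genes
×fold, repressor genes ×(1/fold), giving the closed form
`PAS = (#activators + #repressors) · log10(fold)` at zero noise. Pathways
partition the front of the gene universe, leftover genes form a null
background, and all randomness flows from one integer seed.

Default study conditions (20 cases, 20 controls, 10 genes per pathway,
fold 4, noise sigma 0.5) give a per-gene log2 effect of 2 against a noise sd
of 0.5 — a strong but realistic microarray-scale signal under which
on-target drugs out-score off-target drugs in essentially every replicate;
the acceptance script measures exactly this recovery rate at 100 replicates,
sized to run in seconds on one CPU.

`activator_fraction` (default 1.0) sets the activator/repressor mix of
generated pathways. It exists because the model's algebra needs both pure
activator pathways (whose zero-noise PAS is the simplest closed form) and
mixed-role pathways (to exercise the sign laws: role flips negate PAS,
killer-Mab mode cancels balanced roles to zero); `amcf` likewise makes the
mitosis flag of generated pathways explicit.

What the generator does **not** emulate: probe effects, batch structure,
tumour purity, gene–gene correlation beyond pathway-coherent fold changes,
heavy-tailed or count noise, or mutation-driven expression programs.
Passing tests therefore demonstrate the correctness and calibration of the
scoring machinery under its own assumptions, not clinical performance on
real cohorts.

## Numerical and design choices

- Gene identifiers are upper-cased at every ingest point; matching is exact
  string equality afterwards. ID mapping (probe→gene, aliases) is out of
  scope and must happen upstream.
- ARR and AMCF are restricted to {−1, +1}; file readers reject anything
  else. Graded role weights are a deliberate non-goal.
- Duplicate gene rows in expression input collapse to their mean with a
  logged warning; duplicate (pathway, gene) membership rows are an error,
  since a gene with genuinely dual roles cannot be represented in this
  model and silently picking a sign would be wrong.
- Drug ranking breaks ties on the aggregate score alphabetically, so output
  ordering is deterministic.
- The CLI pipeline writes a manifest (inputs with SHA-256, full parameter
  set, package version) sufficient to reproduce outputs byte for byte; all
  numeric TSV output uses a fixed `%.10g` format for the same reason.
- Example trial table: a small response-rate table
  (`src/pascore/data/example_trials.tsv`) ships with the package so the
  validation statistics can be exercised end to end; predicted fractions for
  it are simulated, as the expression cohorts behind real trial populations
  are not bundled.

## Limitations

- PAS is a qualitative activation measure; its magnitude depends on pathway
  size and on how many genes clear the gates, so scores are comparable
  across samples within one (cohort, pathway database) pair, not across
  databases.
- The DS cutoff default (250) is meaningful only at genome-scale pathway
  collections; small synthetic databases need the `positive` rule or a
  cutoff of matching magnitude.
- The control-vs-case comparison is cohort-level (each case against the
  full control set); paired designs are not modelled.
- No survival analysis, dosage, toxicity or combination-therapy modelling:
  the score ranks single agents by predicted counteraction of pathway
  activation only.
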