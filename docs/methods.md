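# Methods

## Differential screen

The disease signature comes from a two-group comparison of log2
intensities (microarray convention; a `log2_transform` flag applies
log2(x+1) to linear input). Per gene we use Welch's unequal-variance
t-test with Welch–Satterthwaite degrees of freedom and a two-sided p.
The original screen was run through a web re-analysis tool that does
not print its model; Welch's t is the defensible dependency-free choice
at these group sizes and is what this package implements.

Degenerate inputs follow fixed conventions: both groups constant with
equal means → (t = 0, p = 1); constant with unequal means → (±∞, 0).
Groups smaller than two samples are rejected.

A gene enters the signature iff `2^|log2FC| > fc_min` **and**
`p < p_max`, both strict inequalities, with defaults `fc_min = 1.3`
and `p_max = 0.1`. The fold-change cut is two-sided on the linear
scale — down-regulation is screened symmetrically. Thresholding uses
**raw** p-values by default; a `p_adjust` flag switches to
Benjamini–Hochberg adjusted values for users who want FDR control
(the default follows the plain "p < 0.1" reading). Signature lists are
ordered by ascending p, ties by descending fold change, then lexical
gene id, so outputs are deterministic.

## Connectivity score

Drug profiles are ranked by descending differential-expression
statistic with lexical gene-id tie-breaks. Each tag set's two-sided KS
enrichment is the larger of the two running-sum deviations (top
deviation `a`, bottom deviation `b`), signed toward the larger:
ES = a if a ≥ b else −b. Corner cases: ES ∈ [−1, 1]; when the tags
are the entire list, a = 0 and b = 1/n, so ES = −1/n (exactly −1 at
t = n = 1) — the formula, not the nominal open interval, is
authoritative, and an exhaustive brute-force test pins this down.

The per-drug score is `(ES_up − ES_down)/2` when the two ES disagree
in sign, else exactly 0. Scores are therefore bounded in [−1, 1] per
drug with **no** library-wide max/min normalisation — each drug's score
is independent of which other drugs are screened. The same-sign rule
yields structural (exact) zeros; the zero class uses a 1e−12 tolerance
purely to guard float noise. Signature genes absent from a profile are
dropped for that drug, with matched counts recorded; a drug whose
profile overlaps neither tag set raises a named "disjoint signature"
error and is skipped (and logged) in library scoring. Libraries are
reported sorted ascending by score — most-reversing first — with
lexical tie-breaks.

`permutation_null` calibrates a drug's score against random
re-orderings of its profile (seeded; add-one empirical two-sided p).

## Candidate funnel

Four set-filters, each idempotent, with status and BBB filters
commuting:

1. keep connectivity class ∈ {negative, zero};
2. keep market status ∈ {approved, nutraceutical}; a drug with no
   annotation record counts as unknown and is dropped (no safety
   record, no candidate);
3. keep BBB label = permeable (the label is a consumed annotation —
   upstream predictors do not disclose their method, so permeability is
   an input here, not a computation);
4. keep drugs whose docking energy is **strictly** more negative than
   the receptor's standard at **every** receptor in the three-receptor
   set (Nav1.2 / GABA α1-β1 / Cav3.1, standards −7.13 / −6.14 / −5.76
   kcal/mol). "Better than" is read strictly — a tie is not better —
   and a drug missing an energy at any receptor is excluded.
   Per-receptor better-than-standard counts are reported alongside.

The funnel report validates that every stage is a subset of its
predecessor (violations raise — they indicate a pipeline bug) and
records per-stage class breakdowns; it serialises to JSON and TSV and
echoes the resolved configuration for provenance.

## Synthetic data

All generators are pure functions of (config, seed); one global seed is
threaded to sub-generators through fixed stream offsets. Noise is
Normal throughout — the standard log2-scale microarray assumption; the
generators emulate statistical structure only, not probe-level
artefacts, dose–response series, or docking physics, so passing tests
demonstrate correctness of the screen's arithmetic and power under the
stated noise model, not performance on real platform data.

* **Expression**: per-gene baseline ~ N(7, 1) log2 units, i.i.d.
  N(0, σ_expr) noise; planted up/down genes shift cases by ±effect.
  Defaults are the conditions the screen is validated under:
  20 vs 20 samples, 50 up + 50 down planted among 2000 genes,
  effect = 1.0 log2 (≈ twice the log2 1.3 threshold), σ_expr = 0.3 —
  conditions under which recovery is expected to be essentially
  complete (sensitivity ≥ 0.95, no direction errors).
* **Perturbation library**: per drug, gene statistic =
  role_sign · α · planted_effect(gene) + N(0, σ_pert), with role_sign
  −1 for reversers, +1 for mimics, 0 for nulls. A fourth role,
  *concordant* (statistic = α · |planted_effect|), pushes both tag sets
  up together and is scored as a structural zero by the same-sign rule;
  it exists because exact zero-class counts cannot be planted with
  pure-noise nulls.
* **Annotations / docking**: status and BBB tables support both
  proportion-based generation (largest-remainder rounding, so totals
  are exact rather than sampled) and exact-count allocation;
  docking tables force planted winners below every standard and clamp
  every other drug to at least one receptor at or above its standard.

`funnel_study()` is the study-scale bundle: 1219 drugs (309 reversers,
690 concordant, 220 mimics) over 500 genes, annotated and docked by
exact-count allocation so that the cascade retains
1219 → 999 → 434 → 323 → 41 drugs with class splits 102/221 at the BBB
stage and 21/20 at the end, and per-receptor better-than-standard
counts 128/59/242. Two joint tables are not published for the
reference funnel and were chosen here as the minimal-assumption
allocations consistent with all published margins: the class split of
the 434 safe drugs (134 negative / 300 zero), and the receptor-subset
allocation for permeable non-winners (18 × {Nav1.2, GABA},
69 × {Nav1.2, Cav3.1}, 132 × {Cav3.1}, 63 × none). The published
114 "experimental and investigational" drugs are split 74/40 across
the two separate vocabulary terms; both are removed by the filter, so
the split is immaterial. 500 genes (not 2000) keeps the study-scale
bundle light; the signature screen's operating characteristics are
unchanged at that size.

## Numerical and design choices

* Strict inequalities everywhere thresholds are compared (fold change,
  p-value, docking energy): the conservative reading of "greater
  than" / "better than".
* Deterministic orderings (lexical tie-breaks in rankings, signatures
  and score tables) and fixed float formatting in writers, so a rerun
  with the same config is byte-identical.
* Scores are per-drug statistics; no cross-library normalisation, so
  adding or removing drugs never changes another drug's score or class.
* The receptor vocabulary is configurable but defaults locked to the
  three-receptor epilepsy panel with its marketed standards.

## Limitations

* The screen models one two-group contrast per run; probe-to-gene
  collapsing, batch correction and moderated (limma-style) variance
  estimation are out of scope.
* BBB permeability and docking energies are consumed annotations; the
  package neither predicts permeability nor runs docking.
* The synthetic library plants block-structured signal; real
  perturbation data has correlated genes, batch structure and
  cell-line heterogeneity that the generators do not emulate.
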