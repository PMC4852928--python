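# Methods

This note records the models, conventions and numerical choices behind
`codephen`, in the order the pipeline runs them.

## Data model

A coded event is (patient, code, date, source); codes are opaque strings of
up to five alphanumeric characters (trailing-dot padding allowed) whose
prefixes encode the terminology hierarchy — medication chapters start with a
lower-case letter, condition chapters with an upper case letter or digit.
No external code dictionary is consulted. Feature values are occurrence
*counts*, not presence flags; repeat codes on the same date are counted as
separate events (whether same-day repeats should be deduplicated is a
recording-practice question the package leaves to the user; counting
everything is the documented default). Patients present in the label file
but with no primary-care events are retained as all-zero rows — they mirror
the "no GP data" row of the validation tables. Screening derives presence
(count ≥ 1) from counts; the trees split on the counts themselves.

## Phase 1: relative-frequency screening

For code *x*, `rFeq(x) = (N_x,1 − N_x,2)/N` with `N_x,1`/`N_x,2` the carrier
counts among cases/controls and `N` all labelled patients. A second
convention, `denominator="carriers"`, divides by `N_x,1 + N_x,2` instead
(the conditional prevalence difference among carriers). Both are positive
exactly when `N_x,1 > N_x,2`, so the selected set — strict positivity — is
identical under either; the population form is the default. Ties in rFeq
break lexicographically by code so output order is deterministic. Codes
carried by nobody are emitted with rFeq 0 and unselected, keeping joins
total. No multiple-testing correction is applied: this is a deliberately
permissive univariate pre-filter whose errors the later phases absorb.
Note the class-imbalance behaviour: a code equally prevalent in both
classes has *negative* rFeq whenever controls outnumber cases, so under
realistic prevalence the screen is far stricter than "half the codes".

## Phase 2a: seed expansion and grouping

A selected code pulls in every dataset code sharing its prefix —
depth 3 for medication chapters, 4 for diagnosis chapters by default
(configurable 1–5) — or the same active ingredient when an ingredient map is
supplied. Overlapping groups are unioned transitively (union-find; the
result equals the connected components of the code-sharing graph) until
pairwise disjoint, so every code contributes to exactly one variable and a
grouped count is the exact sum of its members' counts. Prefix + ingredient
is the whole similarity notion: no free-text descriptions are used. An
expansion can be gated on out-of-bag accuracy (`evaluate_expansion`), with
the default tolerance 0 — never accept an accuracy loss.

## Phase 2b: the forest ranker

Trees are implemented natively so that split enumeration, importance
accounting and tie-breaking are fully specified and testable against
exhaustive enumeration:

* each tree trains on a uniform random subsample of exactly 2/3 of patients
  *without replacement*; the held-out third provides the out-of-bag
  estimate (majority vote over each patient's held-out trees);
* splits are threshold tests `count ≥ t`, with t the midpoints between
  consecutive distinct observed values, maximising the weighted Gini
  decrease over a random `sqrt(p)` feature subset;
* a feature's importance is the impurity decrease of its splits weighted by
  the fraction of training samples reaching the node, summed per tree and
  averaged over trees; ranks break ties by feature name;
* impurity is computed class-symmetrically from integer counts
  (`1 − (n₁² + n₂²)/n²`) so exactly-tied candidates compare bit-identically,
  and candidates within 1e−12 of the best decrease are treated as tied and
  resolved by (lower threshold, feature name).

Defaults where the procedure fixes no value: 500 trees, sqrt feature
subsets, unlimited depth, `min_leaf` 1, seeded `numpy` generators
throughout (fixed seed ⇒ identical forest). The bundled benchmark and
pipeline configurations use 30–100 trees — at a few thousand patients and
~100 features the importance ranking is already stable there, and the
experiments stay desk-scale.

## Phase 3: rule induction

A single binary tree is grown with C4.5 conventions: candidate splits with
positive information gain compete on *gain ratio* (gain over the entropy of
the branch-size split), restricted to candidates with at least average gain.
Two package-level choices deserve note:

* **MDL threshold penalty.** Each count-valued feature's gain at a node is
  charged `log2(#candidate cuts)/n`, the later-C4.5 correction for
  continuous attributes. Without it, noise features with many distinct
  counts buy spurious gain and noise trees grow essentially unbounded.
* **Pessimistic pruning.** A leaf's predicted errors are
  `n · U_cf(E, n)`, with `U_cf` the one-sided Clopper–Pearson upper
  binomial bound at confidence factor `cf` (default 0.25; for `E = 0` this
  is the closed form `1 − cf^{1/n}`). A subtree collapses to a leaf when
  the leaf's predicted errors do not exceed the subtree's sum, bottom-up;
  branch-lifting is not performed. Error-based pruning of this family
  under-prunes perfectly separated deep splits, so pure-noise trees shrink
  to a handful of leaves rather than always to a single leaf — the test
  suite asserts the measured behaviour (median ≤ 6 leaves at n = 200, some
  full collapses), not an idealised one.

Split ties (within 1e−9 of the best ratio) break by (feature name, lower
threshold); induction is fully deterministic. Degenerate input yields a
single majority-class leaf, ties predicting notRA (flagging a disease
requires a majority). Boosting, winnowing, soft thresholds and
cost-sensitive learning are out of scope.

Flattening emits one rule per leaf with conditions in root-to-leaf order and
confidence equal to the leaf's majority fraction; the ruleset's first-match
decision function is identical to the tree's (verified exhaustively on small
grids). Rulesets serialise to a line-oriented text format that round-trips.

## The RA rule engine

The eight predictors are seven count groups (QOF RA codes, psoriatic and
alternative-arthropathy exclusions, prednisolone, methotrexate,
sulphasalazine, leflunomide) plus INTENSITY_RA, the most severe
(lowest-numbered) of levels 1–4 whose code list the record intersects, 9
when none. The shipped default ruleset encodes the published logic —
psoriatic arthritis excludes outright; alternative arthropathy without RA
evidence excludes; diagnostic evidence (QOF code or intensity 1–2) plus any
medication-group evidence flags RA; default notRA — with presence (≥ 1)
thresholds, because exact fitted thresholds belong to a fitted tree, not to
the method. Both the code lists and the ruleset are configuration: the
shipped lists are synthetic placeholders aligned with the simulator, and a
transcribed or induced ruleset can be loaded verbatim. Only the prevalence
(ever-RA) algorithm is defined; incidence phenotyping is a different
problem.

## Validation under incomplete linkage

With linkage-table cells a, b, e (predicted RA against reference RA /
not RA / no reference) and c, d, f (predicted notRA likewise):

| metric | worst case | best case |
|---|---|---|
| sensitivity | a/(a+c) | (a+e)/((a+e)+c) |
| specificity | (d+f)/((d+f)+(b+e)) | (d+f)/((d+f)+b) |
| PPV | a/(a+b+e) | (a+e)/(a+b+e) |

The no-GP-data row is reported but excluded from every denominator — the
convention recovered by requiring the shipped tables' printed values to
reproduce (e.g. 86.7% = 1377/1588). Worst-case prevalence is
(a+c)/population. All arithmetic is exact integer ratio; percentages are
kept at full precision and rounded only for display, at the mixed 0–1
decimal places the published tables use.

Bracketing guarantees: the latent PPV lies inside [worst, best] cell-wise
((a+e_RA)/(a+b+e) is monotone in e_RA), and the latent sensitivity never
exceeds the best-case bound. The worst-case sensitivity, by contrast, is
exactly the linked-stratum sensitivity — an unbiased *estimate* of the
latent one, below it in roughly half of finite samples — so it bounds the
latent value in expectation only; tests and the acceptance script check
precisely these guarantees.

Two reporting discrepancies in the shipped published tables are documented
rather than reconciled: the data-driven table's printed worst-case
sensitivity "80%" is inconsistent with its own cells (1323/1588 = 83.3%,
matching the accompanying text's 83%, which this package treats as
authoritative), and the expert-knowledge table's printed worst-case PPV 28%
and best-case figures do not follow from its printed cells under any
denominator convention that reproduces every other value (the cells give
33.0% / 93.2% / 85.9%); those figures are not reproduction targets.

`prevalence_by_year` defines a cumulative-code prevalence: for each year,
records are rebuilt from events dated up to 31 December and re-classified,
so a monotone classifier yields a non-decreasing series.

## The synthetic generator

`simulate` draws, per patient: RA status Bernoulli(prevalence 0.17 by
default, the linked-stratum prevalence of the motivating study); linkage
Bernoulli(0.8) — labels are emitted for linked patients only, the rest form
the no-reference stratum while their latent truth is retained in the echo
for bracketing experiments; per planted group, presence with class-specific
probability (defaults p_case 0.6 / p_control 0.05 for predictive groups,
inverted 0.02/0.08 for the psoriatic exclusion) and, given presence, a
total count Poisson(mean 2–3) floored at 1 and spread uniformly over the
group's member codes (dose variants share a 3-character prefix, so
aggregation has real structure to find); 100 noise codes present with
probability 0.10 in both classes. Dates are uniform over 2000–2012.
Identical config including seed gives byte-identical output.

What it does *not* emulate: longitudinal disease trajectories, calendar
drift in coding practice, correlated comorbidity structure, or linkage
that depends on disease status. Passing recovery tests therefore
demonstrates that the machinery finds planted signal of realistic size
under partial linkage — not that real records behave this simply.

The default conditions (n = 2,000 patients, 17% prevalence, 0.6/0.05
differentials, 20 seeds for rate estimates) are the package's benchmark
study conditions and are used unchanged by the test suite and the
acceptance script. The real study's headline counts (43,100 codes → 900 →
37 → 8; Cardiff PPV 85.6%) are data-dependent and not desk-reproducible;
their structural echo — a strictly decreasing funnel and recovery of all
planted predictors — is what the pipeline is held to.

## Pipeline

`run_pipeline` chains the phases, serialising every artifact (events,
labels, screening table, groups, importances, ruleset, linkage table,
report) plus a manifest with seeds and the stage-count funnel; each stage
consumes only the previous stage's serialised artifacts, so runs are
resumable and byte-reproducible. `top_k` (default 40, clipped to the number
of groups) caps how many ranked groups enter induction. Stage failures
abort with the stage name.

## Known limitations

* Gain-ratio induction and pessimistic pruning approximate the proprietary
  C5.0 single-tree behaviour; boosted or winnowed C5.0 output will differ.
* The forest uses subsampling without replacement (as the method describes)
  rather than bootstrap; importances are mean-decrease-in-impurity and
  inherit its bias toward many-valued features, here mitigated but not
  removed by count-valued data.
* Scenario bounds assume unlinked patients received the same classifier as
  linked ones; informative linkage breaks the PPV bracketing guarantee.
* The shipped RA code lists are synthetic placeholders; real deployments
  must supply terminology lists, and results depend on them entirely.
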