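# Methods

## Overview

`trialmatch` implements rule-based trial eligibility surveillance over an
OMOP-style store: narrative notes are converted into structured concept
mentions, trial eligibility criteria are executable rules, and evidence is
aggregated in three levels — per-evidence rows, per-criterion verdicts, and
a per-trial match score.  Everything is deterministic: there is no trained
component, so identical inputs always produce identical outputs, and every
behaviour can be checked against small hand-computable examples or
brute-force oracles.

## Terminology and lexicons

The vocabulary store is a self-contained mini terminology with the shape of
the large licensed ones: concepts with a source code, a preferred name,
synonyms, one of six categories (condition, investigation, medication,
procedure, device, demographic), and an acyclic is-a hierarchy.
`descendants` is the reflexive-transitive closure under is-a; criteria use
it for "include children of the selected concept" semantics.

`build_lexicon` turns seed concepts into a surface-form dictionary: the
preferred name and (optionally) synonyms of each seed and (optionally) each
descendant.  Surfaces are normalized by case-folding, mapping dashes to
spaces, collapsing whitespace, and stripping edge punctuation — so
`Graft-versus-Host Disease` and `graft versus host disease` are one entry.
When two concepts contribute the same surface, the concept fewest is-a hops
from a seed wins, ties broken by smallest concept id.  This collision policy
is a package choice; homonym handling is genuinely open in dictionary-based
extraction, and closest-to-seed keeps trial-specific lexicons specific.

## Extraction

* **Segmentation** is rule-based (terminal punctuation + newlines); sentence
  spans partition the note text exactly, which makes span bookkeeping and
  property-testing trivial.  No trained sentence model is used, trading a
  little robustness on unusual prose for exact reproducibility.
* **Concept matching** is per-category dictionary lookup over token
  n-grams: case-insensitive, word-boundary anchored, longest match wins,
  matches never overlap within a category but may overlap across categories
  (a surface can be both a procedure cue and a device cue).  Matches never
  cross sentence boundaries.
* **Contextual attributes** use a trigger/scope mechanism in the ConText
  family: each trigger phrase asserts one of the six attributes over
  mentions within a directional scope, measured in tokens (default ≤ 6,
  per-rule), bounded by terminator phrases ("but", "however", ";") and the
  sentence.  A trigger occurrence strictly contained in a longer occurrence
  of another rule is suppressed, so "family history of" masks the
  "history of" trigger inside it and marks the mention as not-about-patient
  rather than historical.  The shipped trigger file
  (`src/trialmatch/data/context_triggers.tsv`) is small and auditable;
  "generic" is the least-operationalised attribute (triggers like
  "patients with", "risk of") and should be treated as advisory.
* **Demographics** are pattern-based: ages from `NN-year-old` / `NN yo` /
  `aged NN` (values outside [0, 130] are suppressed and logged) and gender
  from cue words.  **Result values**: the nearest number within six tokens
  after an investigation mention, with an optional unit token; connective
  words ("level", "is", ":") are skipped, any other intervening word cancels
  the attachment.
* **Allergy sections** start at a header line whose title begins with
  "allerg" and end at the next header or blank line; mentions inside get an
  allergen flag so a listed drug allergy is not mistaken for exposure.

## Criteria and matching

Five rule kinds cover the modelled criteria: `concept_presence` (with
optional descendant expansion), `age_threshold`, `gender_equals`,
`temporal_order`, `value_range`.  Polarity is inclusion or exclusion.

Evidence handling separates *recording* from *qualification*: every
matching coded event and every matching mention — affirmed and negated
alike — is written to the evidence table with its attribute snapshot, so a
reviewer sees both sides; only *qualifying* evidence drives verdicts.  The
default policy deems an NLP mention qualifying when it is affirmed: not
negated, not uncertain, not conditional, not generic, and about the
patient.  Historical mentions qualify by default (most trial conditions may
legitimately be in the past); both the criterion and the policy can forbid
them.  Structured rows always qualify when structured evidence is enabled.

Verdict semantics:

* inclusion presence — met iff ≥ 1 qualifying row; exclusion — met iff 0
  qualifying rows (our reading of "exclude all instances of a concept");
  for other kinds, exclusion polarity negates the predicate;
* age — computed from birth date at `as_of_date` (default: the latest event
  or note date in the store); if the birth date is absent, the most recent
  qualifying narrative age finding is used; if neither exists the criterion
  is *indeterminate*;
* gender — structured gender takes precedence over narrative cues;
* temporal order — the earliest qualifying date of set A must *strictly*
  precede the earliest of set B; ties fail.  NLP evidence is dated by its
  note's date (note-level granularity is all narrative text offers);
* value range — met iff any qualifying row's value satisfies the
  comparator; when the criterion names a unit, rows with a conflicting unit
  are ignored (rows with no unit are accepted).

Indeterminate criteria count as not met and are logged — conservative for a
surveillance tool whose cost model favours review of near-matches over
silent false eligibility.  Exclusion criteria are counted in `n_total` by
default; `score_trial(count_exclusions=False)` drops them from both counts.
Patients are ranked per trial by score fraction descending, ties broken by
person id, so output order is reproducible.

## Evaluation

Alignment of predicted against gold spans is per category.  The default is
`exact_span` (a true positive needs identical note, offsets and category) —
the strictest and most reproducible convention; `overlap` mode performs
greedy one-to-one matching of same-category overlapping spans, preferring
larger overlap then earlier start, for annotation styles with fuzzy
boundaries.

Metrics use recall = TP/(TP+FN), precision = TP/(TP+FP), F1 = harmonic
mean, all with the 0/0 → 0 convention (a category with no predictions and
no hits scores 0 across the board).  The micro row pools counts over
categories.  Macro rows average per-category values over the categories
selected by the macro policy; the default excludes categories with zero
predicted positives (TP+FP = 0) from the means, since an undefined
precision contributes no information.  Macro averages are computed over the
per-category values at report precision (three decimals), i.e. the macro
row summarizes the table as printed; at three decimals this can differ by
one unit in the last place from averaging unrounded values.

Trial-level accuracy: sensitivity and PPV of thresholded score fractions
(threshold 1.0 = "all criteria met"), and a rank-based ROC AUC computed
from mid-ranks, equivalent to exhaustive positive-negative pair comparison
with ties credited 0.5.

## Synthetic data

The generator emulates the study conditions rather than any real corpus:

* note lengths follow a log-normal targeting a mean of 423 words, truncated
  to [1, 9490] (σ = 1.1 — the shape is a package choice; only the mean and
  range are anchored);
* trials carry 7–29 rules over 2–12 concepts, spanning all five rule kinds;
* note text is template-based: planted cue phrases and mention sentences,
  filler drawn from a word list that is disjoint from lexicon surfaces and
  trigger heads.  Gold spans are therefore exact by construction, and the
  same seed regenerates byte-identical fixtures.

Label consistency is a construction invariant: an eligible patient receives
qualifying evidence (coded and/or narrative, per the structured/mention
rates) for *every* criterion of their assigned trial; a non-eligible
patient decisively misses at least one (no evidence for an inclusion rule,
affirmed evidence for an exclusion rule, an out-of-range value, a reversed
or tied temporal pair, a disqualifying age or gender).  Mentions that are
load-bearing for a label are always affirmed; the configured
negation/uncertainty/historical/family-history rates apply to distractor
mentions (concepts outside the patient's trial), so attribute noise never
flips a planted label.  Temporal-order evidence is planted as coded events
on both sides, because narrative evidence is dated only at note granularity.

What passing on this data does **not** show: robustness to real clinical
language (abbreviation ambiguity, misspellings, copy-forward text, section
conventions), lexicon coverage of real terminologies, or calibration of the
attribute classifier on natural negation patterns.  The generator's clean
configuration makes extraction perfect by design; its value is verifying
the *machinery* (spans, scopes, aggregation, scoring), not estimating field
accuracy.

The replication cohort (`gvhd_phototherapy_world`) fixes the published
design: 310 patients, a universally coded GVHD diagnosis, phototherapy only
in notes, nine designated eligible patients with affirmed mentions of both,
294 of the 301 others with a narrative GVHD mention and 30 with a narrative
phototherapy mention.

## Problem sizes and numerical choices

Unit and property tests run on worlds of 8–50 patients with 50–60-word
notes; the replication cohort runs at its full 310 patients and 423-word
mean note length.  Oracle checks (descendant closure, quadratic substring
scans, naive criterion re-evaluation, pairwise AUC) are kept at sizes where
exhaustive enumeration is instant.  Dates are ISO calendar dates without
times; character offsets are 0-based half-open; all sorting tie-breaks are
lexicographic on stable identifiers.

## Known limitations

* No machine-learned NER, attribute classification, abbreviation
  disambiguation, coreference, or temporal normalization beyond the
  historical flag.
* The criteria dialect covers the five modelled rule kinds only; importers
  for cohort-definition formats of external tools are future adapters.
* Persistence is CSV-per-table; there is no database engine, EHR
  connectivity, or web front end.
* The attribute trigger set is intentionally small; precision/recall of the
  "generic" and "conditional" flags on real text is unverified.
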