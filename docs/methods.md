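# Methods

## Scope and data model

`trialkg` operates on the legacy ClinicalTrials.gov "AllPublicXML" dialect:
one XML document per study, identified by an NCT id. The parser
(`registry_io`) reads three sections into a normalized `TrialRecord`: the
study design (arm groups with Experimental / *Comparator* / Other types,
conditions, intervention types), the outcome measures with their
statistical-analysis blocks (compared groups via `group_id` indirection,
p-value, method, parameter name/value, confidence-interval percent and
bounds), and the reported events (event title, body-system category,
serious/other, per-arm affected and at-risk counts; counts are accepted both
as attributes on `<counts>` and as child elements, covering dialect drift
across registry versions). Parsing is lossless for these fields: every
analysis block and event count element maps to exactly one in-memory
object, raw statistic strings are kept verbatim for provenance, and absent
sections yield empty lists rather than errors. Titles are
whitespace-normalized at parse time; decoding is UTF-8 with replacement.

Flattening produces one efficacy row per analysis block. Rows comparing a
number of groups other than two, and rows from trials without at least one
experimental and one comparator design arm, are flagged excluded: only
oriented two-arm comparisons can enter the downstream representation.

## Significance classification

Each retained row is labelled by a fixed rule cascade at the conventional
α = 0.05:

1. **p-value branch.** The raw string is compacted (blanks removed) and
   parsed as an optional relational operator (`<`, `<=`, `≤`, `=`, `>`,
   `>=`, `≥`; default equality) plus a decimal or scientific-notation
   number in [0, 1]. The label is positive iff the stated relation
   guarantees p ≤ 0.05 (`=`, `≤`, `<` with value ≤ 0.05) and negative iff
   it guarantees the opposite (`=` with value > 0.05, `>`/`≥` with value
   ≥ 0.05). An unresolvable bound (`<0.1`) yields indeterminate rather
   than a guess. A parseable p-value always pre-empts the interval branch.
   One deliberate edge: `≥ 0.05` exactly is treated as negative, reading
   the reported relation as a statement of non-significance; the case is of
   measure zero in practice.
2. **Confidence-interval branch** (no parseable p-value). The parameter
   name decides the null value by case-insensitive keywords: ratio-type
   (odds/hazard/risk/rate ratio, relative risk → null 1) or
   difference-type (difference, slope, change → null 0). The label is
   negative iff the closed interval contains the null, positive otherwise;
   boundary hits are logged. Unrecognized parameters, unparseable or
   reversed bounds exhaust the cascade: indeterminate.

Indeterminate rows are retained in tables but excluded from the knowledge
graph and from positive/negative tallies. No multiple-testing adjustment is
applied — rows are labelled exactly as reported. The interval-percent field
(90 vs 95) is carried as metadata only; the rule ignores it. Non-inferiority
analyses pass through the same cascade, flagged.

## Arm resolution

Analysis groups are oriented by similarity to the design arms. The default
embedding backend is a character-3-gram term-frequency vector over
lowercased, whitespace-normalized titles, compared by cosine. It is fully
deterministic, needs no model artifacts, and is robust to the drift actually
observed in group titles (dose suffixes, casing, abbreviations,
parentheticals). A transformer sentence encoder can be registered behind the
same `embed` contract (`arm_resolution.register_backend`); mean pooling over
token vectors is the recommended adapter choice.

Resolution: exact case-insensitive equality with a design title fixes a
group's role outright and cannot be overridden by any similarity score.
Otherwise each group inherits the role of its argmax-similarity design arm
(all design arms are candidates in multi-arm designs; ties break by document
order). If both groups inherit the same role, the bijective pairing — one
group per role — with the larger summed similarity wins. There is no
minimum-similarity threshold by default (bare argmax); an optional
`min_score` turns weak assignments into exclusions. Identical group titles
cannot be oriented and are excluded.

## Outcome typing

MeSH extraction is behind a pluggable, versioned contract with an optional
JSONL cache. The default `DictionaryExtractor` does word-boundary phrase
matching against a shipped **synthetic toy subset** of the MeSH tree
(`data/mesh_toy.tsv`, ≈190 rows over the D, E, C and F03 branches,
including the E05.318.308.980 survey branch). It exists so the typing rules
are exercisable offline and deterministically; it is not a redistribution
of MeSH, and a web-service indexer can be wrapped as another extractor.

Rules (multi-label): *biomarker* — any term under roots D or E, excluding
the E05.318.308.980 Surveys-and-Questionnaires branch and its descendants;
*PRO* — case-insensitive keyword match (Survey, Questionnaire, Patient
Reported, Patient-Reported, Scale, Score) against both the title and the
extracted MeSH names, with the matched source recorded per row; *clinical
endpoint* — any term under C or F03. Tree matching is segment-aware prefix
matching on dotted codes (F03 covers F03.600, never F030-like artifacts).
Where a single label is needed for tabulation, precedence is biomarker >
PRO > clinical endpoint (configurable). Conditions map to first-level MeSH
disease categories (C01…C26, F03) the same way.

## Safety linkage and co-occurrence

Serious events with affected ≥ 1 are retained; aggregation rows titled
"Total, serious adverse events" are dropped, as are records whose affected
count exceeds the at-risk denominator (quarantined with a diagnostic). Arm
matching to the efficacy groups tries an exact case/whitespace-insensitive
string match first, then falls back to embedding-cosine argmax; the method
used is recorded per record. Only records from trials with at least one
classified efficacy row are kept, with the retained fraction reported.

The category co-occurrence statistic is computed at trial level: for trial
t and category x, r_t(x) pools all of the trial's records in x by summing
affected and at-risk counts (the only order-independent pooling when a
category spans arms with different denominators); every unordered pair
(a, b) present in t contributes r_t(a)·r_t(b), summed over trials (an
indicator per trial, not a record count — the formulation is ambiguous
between the two and the indicator reading is documented and tested against
brute-force enumeration). Records without an at-risk denominator are
skipped here (logged) but still count in the affected-subject tables, where
trials with zero or multiple intervention types are excluded from the
by-type table so each count attributes to exactly one type.

## Knowledge graph

Node identity is (node type, normalized title) — the same outcome or arm
title reported by many trials is one node, and per-trial provenance
(NCT id, comparator, statistics, conditions, affected/at-risk ratio) lives
on the edges. Ids are content hashes, so identical corpora export
byte-identical files. Efficacy rows become `positive`/`negative` edges from
intervention arm to outcome; matched safety records become `has_ae` edges;
taxonomy attachments (`is_a`) link outcomes to outcome types, events to
categories, and arms to MeSH concepts. Multi-condition trials carry a
delimited condition list on the efficacy edge rather than duplicated
edges. Conservation holds by construction: positive + negative edges equal
the classified-and-assigned rows, `has_ae` edges equal the matched safety
records. Exports: Neo4j bulk-import CSV (`id:ID` / `:LABEL` / `:START_ID` /
`:END_ID` / `:TYPE` headers), GraphML, idempotent Cypher (MERGE on
type + title), and JSONL. Edge attributes carry statistics verbatim; the
graph never recomputes them.

## Synthetic corpus generator

The generator emulates exactly the registry dialect the parser accepts and
plants every truth it will be scored on. Per trial: an experimental drug
arm and a comparator (plus occasionally an Other arm), 1–4 outcomes with
1–2 analysis blocks each, and 0–6 serious events plus deliberately
droppable rows (totals, zero-affected, non-serious). Statistics are planted
so the intended label is guaranteed by construction: p-value spellings are
drawn from a dialect mix (plain 0.45, `<`-prefixed 0.20, `≤` 0.05,
scientific 0.10, unparseable 0.20), 30 % of decisive results are
CI-only (half ratio-type, half difference-type, 5 % with an unrecognized
parameter to exercise cascade exhaustion), and the positive share targets
0.44 — the share of statistically significant results observed in
registry-wide efficacy data. Outcome titles are composed from toy-MeSH
phrases and PRO keywords with known label sets, including the
survey-branch exclusion path. Title drift is emulated by seeded edits
(dose suffixes, casing, typos, dropped parentheticals) firing independently
with probability `title_noise` (default 0.1); analysis-section spellings
are fixed once per trial, and adverse-event arm titles drift further to
exercise the embedding fallback. Randomness is a single stream split per
trial by index, so corpora extend without reshuffling earlier trials.

What the generator does **not** emulate: realistic trial-size or p-value
distributions, free-text outcome prose beyond the planted templates,
multi-arm (>2 group) factorial designs, or encoder-specific semantic
drift. Passing tests therefore demonstrate that the rules, matching
procedure and graph assembly are implemented correctly and recover planted
truth under controlled noise — not that any particular accuracy holds on
real registry text with a particular pretrained encoder.

## Verification and problem sizes

The suite pins the printed worked examples (five p-value rows, five
arm-separation rows, five safety rows including the embedding-fallback
match), checks the CI rule against direct interval-membership evaluation on
a 200×200 bound grid for both parameter kinds, the co-occurrence statistic
against brute-force (trial, pair) enumeration on 100 seeded corpora of ≤ 20
trials (tolerance 1e-12), and the outcome rules against direct predicate
re-application on 1,000 generated titles. End-to-end recovery runs on a
200-trial corpus at title noise 0.2: significance labels match the manifest
on all rows, arm-assignment accuracy stays ≥ 0.95 with the lexical
backend, and edge counts equal the manifest exactly. These sizes keep the
whole suite in the seconds range while giving every cascade branch
double-digit coverage in expectation. The acceptance script uses the same
200-trial condition and recomputes everything from the given seed.

## Known limitations

- Multiple-testing adjustment is intentionally absent; labels are per-row.
- Analyses with more than two groups are excluded, not decomposed into
  pairwise comparisons.
- The toy MeSH dictionary covers only enough of the tree to exercise the
  rules; real-corpus coverage numbers require a full extractor behind the
  same contract.
- Co-occurrence weights are descriptive reporting statistics, not causal
  attributions of events to interventions.
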