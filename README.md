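# trialkg

Arm-level efficacy and safety results from ClinicalTrials.gov registry XML,
linked into a knowledge graph.

Registered trials post their results to the registry as structured XML, but
the statistical-analysis blocks are rarely used in evidence synthesis: the
compared groups are bare titles (not labelled intervention vs comparator),
significance is buried in heterogeneous p-value and confidence-interval
strings, and adverse events sit in a separate section whose arm titles drift
from the efficacy section's. `trialkg` turns a corpus of legacy
"AllPublicXML"-dialect documents into an analysis-ready representation for
evidence-synthesis and pharmacovigilance researchers:

- **per-arm efficacy results** labelled statistically *positive* /
  *negative* / *indeterminate*;
- **intervention vs comparator separation** of analysis groups by title
  similarity to the design-section arms;
- **MeSH-typed outcomes** (biomarker / patient-reported outcome / clinical
  endpoint);
- **arm-matched serious adverse events** (SAEs) with a ratio-weighted
  category co-occurrence network;
- a typed **knowledge graph** connecting all of the above, exportable to
  Neo4j bulk CSV, GraphML, Cypher, or JSONL.

A seeded synthetic-corpus generator emulates the registry dialect with known
ground truth, so the entire pipeline is testable offline.

## The rules at the core

**Significance.** Each two-arm analysis is labelled by a fixed cascade.
With a parseable p-value string: positive iff the stated relation guarantees
p ≤ 0.05, negative iff it guarantees p > 0.05, otherwise indeterminate (a
bound like `<0.1` is never guessed). Without a p-value but with a
confidence interval [L, U] on an effect parameter: for ratio-type parameters
(odds/hazard/risk ratio, null value 1), negative iff L ≤ 1 ≤ U, else
positive; for difference-type parameters (mean/risk difference, null value
0), the same with 0. Anything else is indeterminate. A reported p-value
always pre-empts the interval.

**Arm separation.** Design-section arms carry Experimental/Comparator
labels; analysis-section groups do not, and their titles drift
("Canagliflozin 50 mg" vs "Canagliflozin (JNJ-28431754)"). Each analysis
group inherits the role of the design arm with the highest embedding-cosine
similarity to its title; exact title equality short-circuits. The default
backend is a deterministic character-3-gram term-frequency cosine; any
sentence encoder can be plugged in behind the same contract.

**Outcome typing.** MeSH terms are attached to outcome titles by a pluggable
extractor (a shipped toy dictionary by default). An outcome is a *biomarker*
if any term sits under tree roots D or E — excluding the E05.318.308.980
Surveys-and-Questionnaires branch — a *PRO* if the title or a MeSH name
contains Survey / Questionnaire / Patient(-)Reported / Scale / Score, and a
*clinical endpoint* if any term sits under C or F03.

**SAE co-occurrence.** For trial *t* and category *x*, let
r_t(x) = Σ affected / Σ at-risk over the trial's serious events in *x*.
Every unordered category pair (a, b) both reporting affected subjects in *t*
adds r_t(a)·r_t(b) to the pair's weight: Σ_t c_t(a,b) · r_t(a) · r_t(b).

## Worked example

```bash
trialkg simulate --out corpus --n 50 --seed 7
trialkg classify --input corpus --out work
trialkg build-kg --input corpus --out kg
```

or equivalently in Python:

```python
from trialkg.synthetic import GeneratorConfig, generate_corpus
from trialkg.pipeline import run_pipeline

corpus_dir, manifest = generate_corpus(GeneratorConfig(n_trials=50, seed=7), "corpus")
result = run_pipeline(corpus_dir)
print(result.branch_counts.as_dict())
print(result.cooccurrence.edge_list()[:1])
```

which prints

```
{'total': 151, 'excluded': 5, 'p_value': 80, 'ci_ratio': 20,
 'ci_difference': 14, 'indeterminate': 32, 'positive': 54, 'negative': 60}
[('Psychiatric disorders', 'Skin and subcutaneous tissue disorders', 0.0163)]
```

Reading: the 50 trials yielded 151 analysis rows; 5 were excluded (not
exactly two groups, or no valid design labels), 80 were decided on the
p-value branch, 34 on a confidence-interval branch, and 32 remained
indeterminate, giving 54 positive vs 60 negative results. The heaviest SAE
co-occurrence edge in this corpus links psychiatric and skin disorders with
weight 0.0163 (the summed per-trial product of affected/at-risk ratios).
The knowledge-graph export contains one `positive`/`negative` edge per
classified row (54 + 60) and one `has_ae` edge per matched safety record.

`trialkg evaluate --input corpus` scores any synthetic corpus against its
ground-truth manifest (label agreement, arm-assignment accuracy, edge-count
conservation).

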