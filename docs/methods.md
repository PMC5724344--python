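# Methods

This note documents the retrieval model, the synthetic data it is tested
on, the numerical choices, and the limits of what the tests show.

## Retrieval model

### Visual side

Each slice is reduced to a bag of visual words:

1. **Windowing.** Raw HU are mapped through a brain display window
   (center 40 HU, width 80 HU) and clipped to [0, 1]. Without this, the
   ±1000 HU dynamic range of bone and air dominates gradients and
   soft-tissue texture — where lesions live — contributes almost nothing.
2. **Dense patch descriptors.** Patches of `patch`×`patch` pixels
   (default 16) on a stride-8 grid, full support only (no border
   padding). Each patch is divided into 4×4 cells; per cell an 8-bin,
   magnitude-weighted gradient-orientation histogram is accumulated
   (orientation = atan2 of the image gradient, bins uniform over 2π),
   giving a 128-d vector, L2-normalized. Patches whose [0, 1]-intensity
   variance is below 1e-4 are discarded: this removes air background and
   flat tissue while keeping edges and lesion texture. The descriptor is a
   standard dense gradient-histogram front end chosen for being
   dependency-light and well understood; it is configuration, not a claim
   that any particular production system used it.
3. **Vocabulary.** k-means (k-means++ initialization, fixed seed, one
   initialization, scikit-learn) over descriptors sampled from the corpus
   (cap 100 000, subsampled with the vocabulary seed). Default k = 256;
   desk-scale tests use k = 32–128 so that bags neither saturate (k too
   small: every image contains every word) nor fragment. Centroids are
   sorted lexicographically after fitting so the stored vocabulary is
   canonical. When a corpus yields fewer descriptors than k, k is clamped
   to the sample size.
4. **Quantization.** Nearest centroid by Euclidean distance; exact ties
   go to the lower centroid index, making quantization a pure function of
   (descriptor, centroids). Tested against an exhaustive scan.

**ROI semantics.** A region of interest selects descriptors of the
*full-image* grid whose patch centers fall inside the rectangle
(0-based, half-open `(r0, r1, c0, c1)`). The crop is deliberately not
re-gridded: this makes the ROI bag an exact subset of the whole-image bag,
which both the tests and the intuition "search by a part of this image"
rely on.

### Text side

Tokenization lowercases and splits on non-alphanumerics, recording
sentence boundaries (`. ! ?`). Negation filtering removes a cue word
(default lexicon `no, not, without, ei` — the last a slot for localized
cues; loadable from a one-per-line file) and everything after it up to the
sentence end. This cue-to-sentence-end rule is the simplest member of the
family of rules such systems use; it is known to be imperfect on real
prose (it over-prunes compound sentences), and the lexicon/rule seam is
the intended extension point. Stemming is Porter (hand-implemented from
the published algorithm; no stemming library is a dependency), behind a
registry so other languages or an identity stemmer can be swapped in.
Porter is not idempotent on arbitrary English ("coarse"→"coars"→"coar");
the pipeline never double-stems, and the finding stems that drive
matching are fixed points.

Field scope defaults to `report_only`: indexing the anamnesis makes a
study match a query merely because its *request* asked about the finding,
which is precisely the false-positive mode the scope option exists to
remove. `report_and_anamnesis` reproduces the wider behaviour.

No term weighting exists anywhere: term bags carry raw counts, text
scores count distinct matched stems, and frequency enters only as a tie
break. This is a modelling commitment (all words equal), not an omission.

### Index

One inverted index holds both modalities, terms namespaced `t:`/`v:`.
Initial build trains the vocabulary then indexes every study; background
indexing adds studies with the vocabulary frozen. Whether *text* stems
unseen in phase one should be indexed is genuinely open; the default is
open (dropping them silently degrades search), `strict_text=True`
preserves the closed reading. Studies that fail to index are skipped and
recorded as failed in the manifest — an ingest pipeline must not abort a
batch on one corrupt study. Persistence is `manifest.json` +
`postings.jsonl` (terms sorted, entries sorted by study then image, fixed
JSON separators) + the vocabulary (JSON manifest + CSV centroid matrix at
`%.17g`, which round-trips float64 exactly). SHA-256 checksums over the
postings text and centroid bytes are verified on load; serialization is
deterministic, which is what makes the batch-vs-incremental equivalence
test a byte comparison.

### Search

Orderings are total: text `(−distinct, −frequency, study_id)`, image
`(−best-image score, study_id)` with per-study images `(−score,
image_id)`, combined as in the README with ties in the trailing block
resolved image-before-text then by id. Caps (100 studies, 5 images per
study) are configuration constants. Filters (inclusive age range, exact
sex, exact study-code membership) are applied before truncation, so a
filtered page is not starved by cap-then-filter. `min_shared` (default 1)
is the threshold on shared visual words for an image to count as a match.

## Synthetic phantom studies

Each study renders an outer skull ellipse (1000 HU) around a brain
ellipse (40 HU) on air (−1000 HU), size 128 px and 12 slices by default
(64 px / 2 slices in the test suite, which exercises the same code at a
fraction of the cost), plus one of: a hyperdense blob (haemorrhage,
80 HU), a hypodense 120° wedge of an ellipse (infarct, 10 HU), five 2-px
bright dots (calcification, 400 HU), or nothing (normal). The palette
preserves the real contrast ordering (air ≪ infarct < brain < haemorrhage
≪ calcification < bone) — values are fixture constants, not radiometric
claims. Lesion center and axes are jittered uniformly per seed inside the
brain ellipse (conservative containment: the center must lie in the brain
ellipse shrunk by the lesion axes), so retrieval cannot key on one fixed
shape. Gaussian HU noise (default sd 3) is added per slice and values are
rounded to integers, as CT HU are; storage uses unsigned 16-bit with
rescale intercept −1024, so DICOM round trips are exactly lossless.

Reports are drawn from class-matched templates: every lesion class has
≥3 assertion templates, ≥2 negation templates, and question-form
anamneses. A lesion study asserts its own finding and negates one other
class's finding; a normal study's anamnesis asks about a random finding
and its report negates that same finding. This wiring is what lets the
negation filter and the field-scope distinction be tested end to end:
with both defaults on, a query for a finding returns exactly the studies
that assert it.

Corpus generation derives class counts by largest-remainder rounding
(remainder ties resolve in mix insertion order), and all per-study seeds,
ages (18–94), sexes and the class-assignment permutation derive from one
base seed.

**What the phantoms are not:** anatomy. No partial-volume effects, no
beam hardening, no 3-D lesion continuity (slices share one 2-D geometry),
no report language variability beyond the templates. Passing tests
therefore demonstrate that the machinery is correct and that the
representation separates *these* lesion classes above chance; they say
nothing quantitative about retrieval precision on hospital data.

## Evaluation harness

`precision_at_k` requires gapless ranks 1..n (an incomplete marking set
is an error, not a silent zero), uses denominator `min(k, n_results)`
when fewer than k results were returned, and is undefined (None) for
empty result lists. Because the aggregation of per-query precisions into
one number is ambiguous, both the per-query mean and the pooled
total-relevant/total-marked value are computed. The at-least-one-relevant
rate reports nearest-integer percent alongside the unrounded value.
Study-level precision@k treats a study as relevant iff any of its shown
images was marked relevant, over the first k distinct studies in rank
order — the appropriate unit when pages group up to five images per
study. SUS uses the standard odd/even contribution rule × 2.5; USE
medians exclude not-applicable items, use the mean-of-central-pair
convention for even counts, and default to the standard 8/11/4/7
item-to-dimension layout (configurable). Markings persist append-only to
CSV.

## Test and acceptance problem sizes

The suite runs entirely on generated data: corpora of 10–150 studies at
64 px / 1–2 slices with k = 32–128, chosen so the full run completes in
about a minute while keeping bags informative. The system-level checks
use the sizes their properties require: 150 studies for the 100-study
cap, 30 identical slices for the 5-image cap, 20 × 50-study corpora for
oracle-equivalence of all three search modes against brute-force linear
scans, 100 studies for exhaustive self-retrieval, and 40 ROI queries over
a 4-class balanced corpus for the above-chance check (mean study-level
P@10 ≈ 0.47 vs the 0.25 chance level; one-sided binomial test on pooled
relevant-study counts).

## Known limitations

* The negation rule over-prunes ("no fracture but extensive haemorrhage"
  loses the second clause); mitigate by extending the rule set, which is
  the designed seam.
* Visual-word bags at small k saturate on globally similar images (every
  head shares skull/brain structure), compressing score ranges; ROI
  queries are the practical remedy and mirror how a radiologist would
  query a finding.
* The Porter stemmer is English-only; the production-language analogue
  (e.g. Finnish morphology) is explicitly out of scope behind the stemmer
  interface.
* Combined-search normalization is per-candidate-set min–max, so a
  study's combined rank depends on which other studies matched; this is a
  documented design choice among several defensible merge rules.
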