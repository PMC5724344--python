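# ctsearch

Content-based retrieval for head-CT study corpora: one inverted index over
**stemmed report text** and **visual words**, with text, image, combined and
metadata-filtered search — plus a synthetic phantom-study generator and a
relevance/usability evaluation harness, so the whole pipeline can be built,
searched and scored without access to hospital data.

## Who this is for

Researchers and engineers prototyping or evaluating clinical
content-based image retrieval (CBIR): systems that let a radiologist query
a PACS/RIS archive with a free-text phrase, a CT slice, a region of
interest on a slice, or a combination, and get back similar *studies* (a
study = ordered slices + report + patient metadata, the unit of retrieval).

## The model

**Images** are represented as bags of visual words. Local descriptors are
computed on a dense grid of 16×16 patches (stride 8) over the
brain-windowed slice (window center 40 HU, width 80 HU): 4×4 cells × 8
gradient-orientation bins = a 128-d, L2-normalized histogram per patch,
with near-constant patches discarded. A k-means clustering (k = 256 by
default) of descriptors sampled from the corpus forms the vocabulary; each
descriptor maps to its nearest centroid w ∈ {0, …, k−1}.

**Text** is tokenized, negation-filtered (a cue such as *no/not/without*
suppresses the rest of its sentence) and stemmed (Porter by default,
pluggable). By default only the report body is indexed — the anamnesis (the
clinical question, e.g. *"Suspected haemorrhage?"*) is excluded because
questions would otherwise match as findings.

Both modalities share one inverted index `term → (study, image, count)`
with terms namespaced `t:<stem>` / `v:<word>`, built in two phases: an
initial corpus build that trains the vocabulary, then incremental
background indexing of new studies with the vocabulary frozen.

**Scoring** is deliberately uniform-weight: for a text query with stem set
Q, `score(study) = |{q ∈ Q : q in study}|` (ranked AND; frequency only
breaks ties); for an image query with word set W,
`score(image) = |W ∩ W_image|`, a study keeps its top-5 images and scores
the max; combined queries put both-modality matches first, ranked by the
sum of min–max-normalized per-modality scores. Result pages are capped at
100 studies and 5 shown images per study.

**Evaluation** implements precision@k (per-query mean and pooled),
study-level precision@k for image search (a study counts as relevant iff
any of its shown images is), the at-least-one-relevant rate (rounded to
integer percent), SUS scoring (0–100) and USE questionnaire medians.

## Worked example

```python
from ctsearch import (RunConfig, DescriptorConfig, generate_corpus,
                      build_initial_index, text_search, image_search)

studies, truth = generate_corpus(n=20, base_seed=7, image_size=64, n_slices=2)
config = RunConfig(vocab_k=128, descriptor=DescriptorConfig(patch=16, stride=8))
vocab, index = build_initial_index(studies, config)

page = text_search(index, "acute haemorrhage", config=config)
for s in page.studies[:3]:
    print(s.study_id, s.text_score, truth[s.study_id])
```

prints

```
S0008 2 haemorrhage
S0000 1 haemorrhage
S0010 1 haemorrhage
```

— S0008 matches both query stems (`acut`, `haemorrhag`) and outranks the
partial matches; normal studies whose reports only *negate* a haemorrhage
do not match at all. An image query with a slice of study S0003 returns
S0003 first (it shares its entire 49-word bag with itself):

```python
page = image_search(index, vocab, studies[3].slices[0], config=config)
print(page.study_ids()[0])   # -> S0003
```

The scripts in `examples/` walk through corpus generation, every search
mode, the relevance-evaluation protocol and questionnaire scoring; each
prints its numbers with a note on what they mean. There is also a thin CLI
(`ctsearch generate/build/update/search/mark/eval --help`).

## Limitations

The phantom generator produces geometric stand-ins, not anatomy; see
`docs/methods.md` for the model details, parameter choices, and what
synthetic results do and do not imply about hospital data.
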