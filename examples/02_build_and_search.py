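"""Build a unified text+image index and run every search mode against it.

Shows: text search (stemmed, negation-filtered, ranked AND), image search
(shared visual words, study-grouped with the 5-images-per-study cap),
combined search (both-modality block first), and metadata filtering.
"""

from ctsearch import (
    DescriptorConfig,
    Filters,
    RunConfig,
    build_initial_index,
    combined_search,
    generate_corpus,
    image_search,
    text_search,
)

studies, truth = generate_corpus(n=20, base_seed=7, image_size=64, n_slices=2)
config = RunConfig(vocab_k=128, descriptor=DescriptorConfig(patch=16, stride=8))
vocab, index = build_initial_index(studies, config)
print(f"indexed {len(index.study_ids())} studies, {len(index.postings)} terms "
      f"(stems + visual words), vocabulary k={vocab.k}")

page = text_search(index, "acute haemorrhage", config=config)
print("\ntext search 'acute haemorrhage' — score = distinct matched stems:")
for s in page.studies[:5]:
    print(f"  {s.study_id}  score={s.text_score}  truth={truth[s.study_id]}")

query_study = studies[3]
page = image_search(index, vocab, query_study.slices[0], config=config)
print(f"\nimage search with a slice of {query_study.study_id} "
      f"(truth {truth[query_study.study_id]}):")
for s in page.studies[:5]:
    print(f"  {s.study_id}  shared-words={s.image_score}  "
          f"images-shown={len(s.shown_images)}  truth={truth[s.study_id]}")
# the query's own study comes back first: its slice shares its whole bag

page = combined_search(index, vocab, "haemorrhage", query_study.slices[0],
                       config=config)
print("\ncombined search — both-modality matches always precede single-modality:")
for s in page.studies[:6]:
    print(f"  {s.study_id}  [{s.match_class}]  text={s.text_score} "
          f"image={s.image_score}")

filtered = text_search(index, "haemorrhage infarct calcification",
                       filters=Filters(age_range=(40, 70), sex="F"),
                       config=config)
print(f"\nfiltered search (age 40–70, sex F): {len(filtered)} studies "
      f"(filters apply before the 100-study cap)")
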