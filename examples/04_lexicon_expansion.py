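"""Expand a seed vocabulary through word-embedding neighborhoods.

Trains an embedding on a corpus with planted synonym classes, walks each
seed's top-20 cosine neighborhood to build the candidate set E, applies
accept/reject curation decisions to get the vocabulary V, and compares the
two backends (count-based PPMI+SVD vs skip-gram) on the same seeds.
"""

from pathlib import Path

from opiomine.corpus import load_corpus, preprocess
from opiomine.embedding import (
    TrainingParams,
    apply_curation,
    build_candidate_set,
    compare_models,
    semantic_neighborhood,
    train_embedding,
)
from opiomine.synth import SynonymClass, SyntheticSpec, generate_corpus, write_ndjson

classes = tuple(
    SynonymClass(name=f"class{i}", terms=tuple(f"slang{i}{j}" for j in range(4)))
    for i in range(5)
)
spec = SyntheticSpec(seed=0, n_authors=5, synonym_classes=classes,
                     n_context_windows=3000)
lines, _ = generate_corpus(spec)
path = Path("scratch_example_synonyms.ndjson")
write_ndjson(lines, path)
corpus = preprocess(load_corpus(path), min_lemma_freq=1)

model = train_embedding(corpus, TrainingParams(backend="svd", dim=30, min_count=5))
print(f"embedding vocabulary: {len(model.terms)} terms")
print("nearest neighbors of 'slang00' (shared context words first, then the"
      " planted synonyms; everything else trails far behind):")
for term, cos in semantic_neighborhood(model, "slang00", n=10):
    print(f"  {term:10s} cosine {cos:.3f}")

seeds = {sc.terms[0] for sc in classes}
expansion = build_candidate_set(model, seeds, n=20)
print(f"candidate set E: {len(expansion.candidate_set)} terms from {len(seeds)} seeds")

# curation: accept exactly the planted synonyms, reject everything else
decisions = []
for sc in classes:
    for t in sc.terms:
        if t in expansion.candidate_set:
            decisions.append((t, sc.name, "accept"))
for t in sorted(expansion.candidate_set):
    if not t.startswith("slang"):
        decisions.append((t, "noise", "reject"))
vocab = apply_curation(expansion, decisions)
print(f"curated vocabulary V: {len(vocab)} terms "
      f"({100 * len(vocab) / len(expansion.candidate_set):.1f}% accepted)")

sgns = train_embedding(
    corpus, TrainingParams(backend="sgns", dim=30, min_count=5, epochs=3, seed=0)
)
expansion_b = build_candidate_set(sgns, seeds, n=20)
apply_curation(
    expansion_b,
    [(t, "planted", "accept") for t in sorted(expansion_b.candidate_set)
     if t.startswith("slang")],
)
cmp = compare_models(expansion, expansion_b, corpus)
print(f"backend comparison: candidates {cmp.candidates_a} vs {cmp.candidates_b}, "
      f"accepted {cmp.accepted_pct_a}% vs {cmp.accepted_pct_b}%, "
      f"{cmp.common_terms} candidates in common")
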