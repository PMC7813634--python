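"""Find topic-relevant communities by iterative query expansion.

Starting from two seed terms, communities are ranked by how enriched their
language is for the query (log-lift), the query grows with the most
over-represented lemmas of the top communities, and the loop repeats until
nothing new is added.  The final inclusion judgment is manual; Fleiss kappa
quantifies how well independent annotators agree on it.
"""

from pathlib import Path

from opiomine.corpus import load_corpus, preprocess
from opiomine.retrieval import fleiss_kappa, iterate_retrieval, merge_years
from opiomine.synth import default_association_spec, generate_corpus, write_ndjson

path = Path("scratch_example_mentions.ndjson")
if not path.exists():
    lines, _ = generate_corpus(default_association_spec(seed=0, n_posts=2000))
    write_ndjson(lines, path)
corpus = preprocess(load_corpus(path), min_lemma_freq=1)

state = iterate_retrieval(corpus, ["heroin", "vein"], k=3, m=3, max_iter=3)
print(f"converged after {state.iteration} iteration(s)")
print(f"expanded query: {state.query_terms}")
print("community ranking (higher log-lift = more topical):")
for comm, score in state.ranked_communities:
    print(f"  {comm:12s} {score:+.3f}")

summary = merge_years([state], k=3)
print(f"merged top communities: {sorted(summary.merged_communities)}")

# three synthetic annotators screening five communities
ratings = [
    ["include", "include", "include"],
    ["include", "include", "exclude"],
    ["exclude", "exclude", "exclude"],
    ["include", "include", "include"],
    ["exclude", "include", "exclude"],
]
res = fleiss_kappa(ratings)
print(f"Fleiss kappa of the screen: {res.kappa:.3f} "
      f"(1 = perfect agreement, 0 = chance)")
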