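"""Ingest an NDJSON corpus and extract vocabulary mentions.

Reads posts, filters low-activity communities, segments and lemmatizes the
text, and matches every lemma against the packaged three-domain taxonomy
(substances, routes of administration, drug tampering).  Each hit becomes
a MentionRecord carrying its sentence index — the unit all downstream
counting uses.
"""

from collections import Counter
from pathlib import Path

from opiomine.corpus import load_corpus, match_terms, preprocess
from opiomine.synth import default_association_spec, generate_corpus, write_ndjson
from opiomine.taxonomy import load_default_taxonomy

path = Path("scratch_example_mentions.ndjson")
if not path.exists():
    lines, _ = generate_corpus(default_association_spec(seed=0, n_posts=2000))
    write_ndjson(lines, path)

corpus = load_corpus(path)
# synthetic corpora are small, so no frequency floor; production runs use 100
corpus = preprocess(corpus, min_lemma_freq=1)
taxonomy = load_default_taxonomy()
mentions = match_terms(corpus, taxonomy)

print(f"posts loaded:     {len(corpus)} ({corpus.skipped_count} lines skipped)")
print(f"communities:      {sorted(corpus.communities)}")
print(f"mention records:  {len(mentions)}")
by_domain = Counter(m.domain for m in mentions)
for domain, n in by_domain.most_common():
    top = Counter(
        m.class_label for m in mentions if m.domain == domain
    ).most_common(3)
    print(f"  {domain:10s} {n:6d} mentions; top classes: {top}")
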