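"""Generate a synthetic post corpus and inspect its realized statistics.

The generator emulates exactly the features the pipeline estimates: a
heavy-tailed posts-per-author distribution, deleted-author fractions by
post kind, a short-post-dominated sentence-count profile, and (optionally)
planted associations, synonyms and trends.
"""

import numpy as np

from opiomine.association import sentence_count_profile
from opiomine.synth import SyntheticSpec, generate_corpus, write_ndjson

spec = SyntheticSpec(seed=0, n_authors=2000)
lines, gt = generate_corpus(spec)
write_ndjson(lines, "scratch_example_corpus.ndjson")

profile = sentence_count_profile(gt.sentence_counts)
print(f"posts emitted:            {len(lines)}")
print(f"distinct cohort authors:  {len(gt.cohort)}")
print(f"deleted submissions:      {gt.deleted_submission_share:.1%} (target 25%)")
print(f"deleted comments:         {gt.deleted_comment_share:.1%} (target 7%)")
print(f"posts with <= 2 sentences: {profile['share_le_2']:.1%} (target 50%)")
print(f"posts with > 10 sentences: {profile['share_gt_10']:.1%} (target 20%)")

# the heavy tail: a tiny core of authors produces a large share of content
from collections import Counter

volumes = np.sort(
    np.array(list(Counter(p.true_author for p in gt.plans).values()))
)[::-1]
top1 = volumes[: max(1, len(volumes) // 100)].sum() / volumes.sum()
print(f"content share of top 1% of authors: {top1:.1%}")
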