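"""Composite sites and candidate enumeration for multi-finger designs.

Builds the composite site lengths for the standard finger-arrangement
strategies and enumerates the best-scoring candidate sites of a
three-finger domain from its rank code.
"""

from zfsite import FingerArrangement, annotate_overlap_loci, best_candidate_sites, build_composite_site, load_rank_tables
from zfsite.design import count_candidate_sites

for layout in ("321", "3211", "321321", "3213211", "32113211"):
    arr = FingerArrangement.parse(layout)
    overlaps = annotate_overlap_loci(arr)
    print(f"{layout:>9}: {arr.site_length:2d} bp site, {len(overlaps)} overlap contact(s)")

code = load_rank_tables()["SP1"]
total = count_candidate_sites([code] * 3, rank_cutoff=64)
print(f"\nfull three-finger site space: {total} candidates")
print("best five at rank cutoff 4:")
for c in best_candidate_sites([code] * 3, rank_cutoff=4, limit=5):
    print(f"  {c.site}  ranks={c.per_finger_ranks}  score={c.combined_rank_score}")
# Longer arrangements mean rarer sites (an 18-bp site is not expected
# twice in a 3 Gb genome); the score sums per-finger ranks, so the lowest
# scores combine each finger's strongest triplets.
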