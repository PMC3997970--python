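"""Stability grouping and base composition of the strongest binders.

Partitions the 64 screened triplets around the 500-count threshold and
summarises the G+C composition of the 26 strongest complexes.
"""

from zfsite import composition_summary, load_triplet_assay_table, stability_grouping

records = load_triplet_assay_table()

g = stability_grouping(records, threshold=500, inclusive=True)
print(f"strong (>= {g.threshold} counts): {len(g.strong)}")
print(f"weak (0 < count < {g.threshold}): {len(g.weak)}")
print(f"undetectable: {len(g.undetectable)} -> {sorted(g.undetectable)}")

c = composition_summary(records, top_k=26)
print(
    f"of the top {c.top_k}: {c.gc_rich} GC-rich ({c.gc_triplet} pure-GC), "
    f"{c.at_rich} AT-rich ({c.at_triplet} pure-AT)"
)
# A GC-rich majority among the strongest binders is expected for SP1
# (a GC-box factor), but the AT-rich minority shows the second finger
# can support complex formation on A/T-majority triplets too.
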