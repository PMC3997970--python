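"""Scan a genome for all 64 flanked 9-mers in one pass.

Builds a synthetic genome with every GGG+triplet+GGG site planted once,
scans it with the degenerate pattern GGGNNNGGG, and joins counts with
the SP1 rank code — the per-triplet off-target landscape.
"""

from zfsite import Genome, enumerate_triplets, load_rank_tables, offtarget_landscape

sites = ["GGG" + t + "GGG" for t in enumerate_triplets()]
genome = Genome({"synthetic": "TTATT".join(sites)})

code = load_rank_tables()["SP1"]
landscape = offtarget_landscape(code, genome=genome)
print(landscape.head(5).to_string(index=False))
print("total occurrences:", landscape["occurrences"].sum())
# Each row is one candidate off-target 9-mer: its rank in the recognition
# code (lower = longer-lived complex, higher cleavage risk for a nuclease)
# and how often it occurs in the scanned genome (here: once each, planted).
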