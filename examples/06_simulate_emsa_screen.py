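"""Simulate a noisy band-shift screen and measure rank recovery.

Draws synthetic count tables under a known true recognition code
(geometric decay + lognormal/Poisson noise) and checks how well the
derived code recovers the truth.
"""

import numpy as np

from zfsite import (
    EmsaSimulationConfig,
    compare_rank_codes,
    compute_rsr_code,
    load_rank_tables,
    simulate_emsa_counts,
)

truth = load_rank_tables()["SP1"]

noiseless = simulate_emsa_counts(EmsaSimulationConfig(true_code=truth, sigma=0.0, poisson=False))
exact = compute_rsr_code(noiseless).ranking == truth.ranking
print("noiseless screen recovers the true code exactly:", exact)

rhos = []
for seed in range(100):
    records = simulate_emsa_counts(EmsaSimulationConfig(true_code=truth, seed=seed))
    recovered = compute_rsr_code(records, protein_id="recovered")
    rhos.append(compare_rank_codes(truth, recovered).spearman_rho)
print(f"mean Spearman rho over 100 noisy screens: {np.mean(rhos):.3f} (min {min(rhos):.3f})")
# rho near 1 means the rank order survives realistic count noise; the
# residual disagreement concentrates in the low-count tail where
# neighbouring means differ by less than the Poisson noise.
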