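"""Sum-of-ranks iRoot scoring of genotype BLUPs.

Ranks genotypes per component trait, sums the ranks, and ranks the sums —
once for the topsoil-foraging category (TRL_GR, WID, TRL_Upper, all
higher-is-better) and once for steep-cheap-deep (TRL_GR up, steep LRA,
low solidity).
"""

import numpy as np
import pandas as pd

from rootpheno.ideotype import steep_cheap_deep_rank, topsoil_foraging_rank

rng = np.random.default_rng(0)
n = 50
blups = pd.DataFrame(
    {
        "TRL_GR": rng.normal(24.6, 4.6, n),
        "WID": rng.normal(18.7, 2.9, n),
        "TRL_Upper": rng.normal(150.9, 22.6, n),
        "LRA": rng.normal(50.2, 1.1, n),
        "SOL2": rng.normal(140.9, 9.6, n),
    },
    index=[f"PI{425000 + i}" for i in range(n)],
)

top = topsoil_foraging_rank(blups)
scd = steep_cheap_deep_rank(blups)
print("top 5, topsoil foraging (fast growth, wide, shallow-heavy):")
print(top.top(5)[["rank_TRL_GR", "rank_WID", "rank_TRL_Upper", "rank_sum", "final_rank"]])
print("\ntop 5, steep-cheap-deep (fast growth, steep laterals, low solidity):")
print(scd.top(5)[["rank_TRL_GR", "rank_LRA", "rank_SOL2", "rank_sum", "final_rank"]])
print(
    "\nfinal_rank 1 is the genotype whose per-trait ranks sum lowest —"
    "\nthe candidate to advance for that ideotype."
)
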