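"""Randomized incomplete block designs for growth-chamber experiments.

The reference layout is one seedling per slot, with each growth chamber
serving as one complete replicate of the panel: 4 blocks per chamber, each
block holding six complete sub-blocks of 12 genotypes and two incomplete
sub-blocks of 11, i.e. 94 slots per block and 376 per chamber.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Sub-block sizes within one block: six complete (12 slots) + two incomplete (11).
DEFAULT_SUBBLOCKS = (12, 12, 12, 12, 12, 12, 11, 11)

#: Per-chamber block specification: 4 blocks, each with the default sub-blocks.
DEFAULT_BLOCK_SPEC = tuple(DEFAULT_SUBBLOCKS for _ in range(4))


def generate_design(
    n_genotypes: int,
    n_chambers: int = 1,
    seed: int = 0,
    block_spec: tuple[tuple[int, ...], ...] | None = None,
) -> pd.DataFrame:
    """Randomize genotypes into a chamber/block/sub-block design.

    Each chamber is one replicate: every genotype occupies exactly one slot
    per chamber, and slot assignment is an independent random permutation per
    chamber.

    Parameters
    ----------
    n_genotypes:
        Must equal the total slot count per chamber implied by ``block_spec``
        (376 under the default 4-block layout).
    n_chambers:
        Number of chamber replicates.
    seed:
        RNG seed; identical seeds give identical designs.
    block_spec:
        Per-block tuples of sub-block sizes, overriding the default layout.

    Returns
    -------
    DataFrame with columns ``chamber, block, sub_block, slot, genotype,
    replicate`` (``replicate`` == chamber index; genotype ids are strings
    ``G0001``...).
    """
    spec = DEFAULT_BLOCK_SPEC if block_spec is None else tuple(tuple(b) for b in block_spec)
    slots_per_chamber = sum(sum(b) for b in spec)
    if n_genotypes != slots_per_chamber:
        raise ValueError(
            f"n_genotypes={n_genotypes} incompatible with design slot count "
            f"{slots_per_chamber} (blocks: {[sum(b) for b in spec]})"
        )
    rng = np.random.default_rng(seed)
    genotypes = np.array([f"G{i + 1:04d}" for i in range(n_genotypes)])
    rows = []
    for chamber in range(1, n_chambers + 1):
        order = rng.permutation(n_genotypes)
        i = 0
        for block, subblocks in enumerate(spec, start=1):
            for sub_block, size in enumerate(subblocks, start=1):
                for slot in range(1, size + 1):
                    rows.append(
                        (chamber, block, sub_block, slot, genotypes[order[i]], chamber)
                    )
                    i += 1
    return pd.DataFrame(
        rows, columns=["chamber", "block", "sub_block", "slot", "genotype", "replicate"]
    )
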