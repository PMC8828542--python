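"""Phenotype simulation under the chamber/block/sub-block mixed model.

Observations follow the same variance-component model the analysis fits:

    y = mu + chamber (fixed) + block + sub-block + genotype + residual

with the block, sub-block and genotype terms drawn as independent normal
random effects and per-genotype effects recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class VarianceComponents:
    """Variances of the random terms plus fixed chamber effects."""

    sigma2_g: float = 1.0
    sigma2_block: float = 0.25
    sigma2_subblock: float = 0.25
    sigma2_e: float = 1.0
    chamber_effects: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_block", "sigma2_subblock", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_phenotypes(
    design: pd.DataFrame,
    vc: VarianceComponents,
    traits: tuple[str, ...] = ("TRL",),
    mu: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a long-format trait table on the given design.

    Each trait gets independent random-effect draws. ``dropout`` removes
    rows missing-at-random, emulating blank (non-germinated) images.

    Returns
    -------
    (table, truth):
        ``table`` has the design columns plus one column per trait;
        ``truth[trait]['genotype_effects']`` maps genotype id to its true
        effect.
    """
    if not (0.0 <= dropout < 1.0):
        raise ValueError("dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chambers = np.sort(design["chamber"].unique())
    n_cham = len(chambers)
    cham_eff = np.asarray(vc.chamber_effects, dtype=float)
    if cham_eff.size == 0:
        cham_eff = np.zeros(n_cham)
    if cham_eff.size != n_cham:
        raise ValueError(
            f"{cham_eff.size} chamber effects supplied for {n_cham} chambers"
        )

    block_key = design["chamber"].astype(str) + ":" + design["block"].astype(str)
    sub_key = block_key + ":" + design["sub_block"].astype(str)
    b_codes, b_levels = pd.factorize(block_key)
    s_codes, s_levels = pd.factorize(sub_key)
    g_codes, g_levels = pd.factorize(design["genotype"])
    c_idx = design["chamber"].map({c: i for i, c in enumerate(chambers)}).to_numpy()

    table = design.copy()
    truth: dict = {}
    n = len(design)
    for trait in traits:
        u_b = rng.normal(0, np.sqrt(vc.sigma2_block), size=len(b_levels))
        u_s = rng.normal(0, np.sqrt(vc.sigma2_subblock), size=len(s_levels))
        u_g = rng.normal(0, np.sqrt(vc.sigma2_g), size=len(g_levels))
        e = rng.normal(0, np.sqrt(vc.sigma2_e), size=n)
        table[trait] = (
            mu + cham_eff[c_idx] + u_b[b_codes] + u_s[s_codes] + u_g[g_codes] + e
        )
        truth[trait] = {
            "genotype_effects": dict(zip(g_levels, u_g)),
            "block_effects": dict(zip(b_levels, u_b)),
            "subblock_effects": dict(zip(s_levels, u_s)),
        }
    if dropout > 0:
        keep = rng.random(n) >= dropout
        table = table.loc[keep].reset_index(drop=True)
    return table, truth
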