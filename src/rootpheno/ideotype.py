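"""Sum-of-ranks "iRoot" ideotype scoring.

Genotypes are ranked under each component trait (rank 1 = best in that
trait's preferred direction, ties averaged), the per-trait ranks are summed,
and the sums are ranked again to give the final ideotype ranking. Two
canonical categories are provided:

* **topsoil foraging** — fast TRL growth rate, wide systems, large upper
  root fraction (TRL_GR up, WID up, TRL_Upper up); suited to immobile
  topsoil phosphorus.
* **steep, cheap, and deep** — fast TRL growth rate, steep lateral angles,
  low solidity (TRL_GR up, LRA steepness up, SOL2 down); suited to water
  and mobile nitrogen capture at depth.

"Steep" is bound to steepness rather than a raw angle: under this package's
angle-from-vertical convention smaller LRA is steeper, and flipping the
convention flag reverses only that component's ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "IdeotypeSpec",
    "IdeotypeRanking",
    "rank_sum",
    "topsoil_foraging_rank",
    "steep_cheap_deep_rank",
    "TOPSOIL_FORAGING",
    "STEEP_CHEAP_DEEP",
]


@dataclass(frozen=True)
class IdeotypeSpec:
    """A category: component traits with per-trait preferred direction."""

    name: str
    traits: tuple[tuple[str, str], ...]  # (trait, "higher" | "lower")

    def __post_init__(self) -> None:
        if not self.traits:
            raise ValueError("at least one component trait required")
        for _, direction in self.traits:
            if direction not in ("higher", "lower"):
                raise ValueError(f"direction must be 'higher' or 'lower', got {direction!r}")


TOPSOIL_FORAGING = IdeotypeSpec(
    "topsoil_foraging", (("TRL_GR", "higher"), ("WID", "higher"), ("TRL_Upper", "higher"))
)

STEEP_CHEAP_DEEP = IdeotypeSpec(
    "steep_cheap_deep", (("TRL_GR", "higher"), ("LRA", "lower"), ("SOL2", "lower"))
)


@dataclass
class IdeotypeRanking:
    """Per-genotype component ranks, rank sums and final ranks."""

    category: str
    table: pd.DataFrame  # per-trait ranks, rank_sum, final_rank, tied
    excluded: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def final_rank(self) -> pd.Series:
        return self.table["final_rank"]

    def top(self, n: int = 5) -> pd.DataFrame:
        return self.table.nsmallest(n, "final_rank")


def rank_sum(blups: pd.DataFrame, spec: IdeotypeSpec) -> IdeotypeRanking:
    """Rank genotypes by the sum of per-trait ranks under ``spec``.

    ``blups`` is a per-genotype trait matrix (genotype index). Genotypes
    missing any component trait are excluded and reported. Per-trait ties
    receive average ranks; final ties on the rank sum are broken by
    genotype id (lexicographic) and flagged.
    """
    for trait, _ in spec.traits:
        if trait not in blups.columns:
            raise ValueError(f"component trait {trait!r} missing from the BLUP table")
    cols = [t for t, _ in spec.traits]
    complete = blups[cols].notna().all(axis=1)
    excluded = [str(g) for g in blups.index[~complete]]
    data = blups.loc[complete, cols]
    if data.empty:
        raise ValueError("no genotype has complete data for all component traits")

    out = pd.DataFrame(index=data.index)
    for trait, direction in spec.traits:
        vals = data[trait].to_numpy(dtype=float)
        out[f"rank_{trait}"] = rankdata(-vals if direction == "higher" else vals, method="average")
    out["rank_sum"] = out.sum(axis=1)

    order = np.lexsort((data.index.astype(str), out["rank_sum"].to_numpy()))
    final = np.empty(len(out), dtype=int)
    final[order] = np.arange(1, len(out) + 1)
    out["final_rank"] = final
    out["tied"] = out["rank_sum"].duplicated(keep=False)
    return IdeotypeRanking(
        category=spec.name,
        table=out.sort_values("final_rank"),
        excluded=excluded,
        meta={"traits": list(spec.traits), "angle_reference": "vertical"},
    )


def topsoil_foraging_rank(blups: pd.DataFrame) -> IdeotypeRanking:
    """Topsoil-foraging category: TRL_GR up, WID up, TRL_Upper up."""
    return rank_sum(blups, TOPSOIL_FORAGING)


def steep_cheap_deep_rank(
    blups: pd.DataFrame, angle_from_horizontal: bool = False
) -> IdeotypeRanking:
    """Steep-cheap-deep category: TRL_GR up, steep LRA, SOL2 down.

    With the default from-vertical angle convention, steeper = smaller LRA;
    set ``angle_from_horizontal=True`` if LRA was measured from the
    horizontal axis (steeper = larger), which reverses only the LRA
    component ordering. Accepts a ``SOL2`` column, falling back to ``SOL``.
    """
    sol_col = "SOL2" if "SOL2" in blups.columns else "SOL"
    lra_dir = "higher" if angle_from_horizontal else "lower"
    spec = IdeotypeSpec(
        "steep_cheap_deep",
        (("TRL_GR", "higher"), ("LRA", lra_dir), (sol_col, "lower")),
    )
    ranking = rank_sum(blups, spec)
    ranking.meta["angle_reference"] = "horizontal" if angle_from_horizontal else "vertical"
    return ranking
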