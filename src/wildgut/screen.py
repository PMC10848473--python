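"""Multi-population consensus differential-abundance screen.

One differential pool is built per disturbed population against the wild
reference (two-sided Mann-Whitney on per-sample abundances, raw p < alpha,
no within-pool multiplicity correction: the cross-pool consensus is the
error control).  Taxa present in at least ``min_support`` pools are retained
as consistently affected, with a majority consensus direction and a flag
when member pools disagree on sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UsageError
from .stats import mann_whitney_many

log = logging.getLogger(__name__)


@dataclass
class DifferentialPool:
    """Significant taxa for one population-vs-reference comparison."""

    label: str                 # e.g. "SHWP_vs_wild"
    population: str
    reference: str
    members: pd.DataFrame      # columns: taxon, direction, p_value

    @property
    def taxa(self) -> set[str]:
        return set(self.members["taxon"])

    def direction_of(self, taxon: str) -> int:
        row = self.members.loc[self.members["taxon"] == taxon]
        return int(row["direction"].iloc[0]) if len(row) else 0


def build_pools(
    abund: pd.DataFrame,
    meta: pd.DataFrame,
    reference: str,
    alpha: float = 0.05,
) -> list[DifferentialPool]:
    """One pool per non-reference population.

    ``abund`` is taxa x samples (relative abundances at the chosen rank);
    ``meta`` maps sample_id -> population.  Populations are processed in
    sorted label order so results are invariant to metadata row order.
    """
    if not 0 < alpha < 1:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    pop_of = meta.set_index("sample_id")["population"]
    pops = sorted(pop_of.unique())
    if reference not in pops:
        raise UsageError(f"reference population {reference!r} not in metadata")
    if len(pops) < 2:
        raise UsageError("need at least one non-reference population")

    samples = [s for s in abund.columns if s in pop_of.index]
    ref_samples = [s for s in samples if pop_of[s] == reference]
    pools = []
    for pop in pops:
        if pop == reference:
            continue
        pop_samples = [s for s in samples if pop_of[s] == pop]
        if len(pop_samples) < 2:
            log.warning(
                "population %s has %d sample(s); pool built with low power",
                pop,
                len(pop_samples),
            )
        x = abund[pop_samples].to_numpy(dtype=float)
        y = abund[ref_samples].to_numpy(dtype=float)
        informative = ~(
            (x == x[:, :1]).all(axis=1)
            & (y == y[:, :1]).all(axis=1)
            & (x[:, 0] == y[:, 0])
        )
        _, p_vals, directions = mann_whitney_many(x[informative], y[informative])
        rows = [
            {"taxon": taxon, "direction": int(d), "p_value": float(pv)}
            for taxon, d, pv in zip(abund.index[informative], directions, p_vals)
            if pv < alpha and d != 0
        ]
        pools.append(
            DifferentialPool(
                label=f"{pop}_vs_{reference}",
                population=pop,
                reference=reference,
                members=pd.DataFrame(rows, columns=["taxon", "direction", "p_value"]),
            )
        )
    return pools


def intersect_pools(pools: list[DifferentialPool]) -> pd.DataFrame:
    """Exact-subset membership counts (the UpSet-plot tabulation).

    Each taxon significant in >= 1 pool is assigned the signature of exactly
    the pools containing it; counts over signatures sum to the union size.
    """
    if not pools:
        raise UsageError("need at least one pool")
    membership: dict[str, tuple[str, ...]] = {}
    for taxon in sorted(set().union(*(p.taxa for p in pools))):
        membership[taxon] = tuple(p.label for p in pools if taxon in p.taxa)
    sig_counts: dict[tuple[str, ...], int] = {}
    for sig in membership.values():
        sig_counts[sig] = sig_counts.get(sig, 0) + 1
    rows = [
        {"signature": "&".join(sig), "n_pools": len(sig), "n_taxa": count}
        for sig, count in sorted(
            sig_counts.items(), key=lambda kv: (-len(kv[0]), kv[0])
        )
    ]
    return pd.DataFrame(rows, columns=["signature", "n_pools", "n_taxa"])


def consensus(pools: list[DifferentialPool], min_support: int = 6) -> pd.DataFrame:
    """Taxa supported by at least ``min_support`` pools.

    Returns columns taxon, support, pools, direction (majority sign; 0 on an
    exact tie) and conflict (True when member pools disagree on sign),
    sorted by decreasing support then taxon.
    """
    if not 1 <= min_support <= len(pools):
        raise UsageError(
            f"min_support must be in [1, {len(pools)}], got {min_support}"
        )
    rows = []
    for taxon in sorted(set().union(*(p.taxa for p in pools))):
        holding = [p for p in pools if taxon in p.taxa]
        if len(holding) < min_support:
            continue
        dirs = [p.direction_of(taxon) for p in holding]
        rows.append(
            {
                "taxon": taxon,
                "support": len(holding),
                "pools": "&".join(p.label for p in holding),
                "direction": int(np.sign(sum(dirs))),
                "conflict": len(set(dirs)) > 1,
            }
        )
    out = pd.DataFrame(
        rows, columns=["taxon", "support", "pools", "direction", "conflict"]
    )
    return out.sort_values(["support", "taxon"], ascending=[False, True]).reset_index(
        drop=True
    )
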