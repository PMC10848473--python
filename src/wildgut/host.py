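"""Host-factor association stages.

Covers sex/age effects on beta diversity (one- and two-factor PERMANOVA,
population entered first so the host trait is assessed conditional on it),
the per-taxon age correlation screen, and the kinship-vs-microbiota
similarity correlation with zero-relatedness pairs excluded (cross-population
pairs always have relatedness 0, and inter-population dissimilarity would
otherwise induce a spurious association).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import skbio

from .errors import InsufficientDataError, UsageError
from .io import OtuTable
from .kinship import RelatednessMatrix
from .stats import PermanovaResult, TestResult, bh_adjust, permanova, spearman

log = logging.getLogger(__name__)


def trait_permanova(
    dm: skbio.DistanceMatrix,
    meta: pd.DataFrame,
    trait: str,
    with_population: bool = False,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA of a host trait, optionally conditional on population.

    ``trait`` is ``'sex'`` (factor; samples with unknown sex dropped) or
    ``'age'`` (continuous covariate; samples with unknown age dropped).  With
    ``with_population`` the model is sequential ``population + trait``.
    """
    if trait not in ("sex", "age"):
        raise UsageError(f"trait must be 'sex' or 'age', got {trait!r}")
    m = meta.set_index("sample_id").loc[list(dm.ids)]
    if trait == "sex":
        keep = m["sex"].isin(["M", "F"])
    else:
        keep = m["age"].notna()
    if not keep.any() or m.loc[keep, trait].nunique() < 2:
        raise UsageError(f"trait {trait!r} is missing or constant")
    ids = list(m.index[keep])
    if len(ids) < len(dm.ids):
        log.info("trait_permanova: dropping %d sample(s) with unknown %s",
                 len(dm.ids) - len(ids), trait)
        dm = dm.filter(ids)
        m = m.loc[ids]
    terms: dict[str, pd.Series] = {}
    if with_population:
        if m["population"].nunique() < 2:
            raise UsageError("population factor is constant")
        terms["population"] = m["population"]
    if trait == "age":
        terms["age"] = m["age"].astype(float)
    else:
        terms["sex"] = m["sex"]
    return permanova(dm, terms, n_perm=n_perm, seed=seed)


def age_screen(
    abund: pd.DataFrame, meta: pd.DataFrame, min_n: int = 5
) -> pd.DataFrame:
    """Spearman correlation of each taxon's abundance with host age.

    ``abund`` is taxa x samples at the chosen rank.  Samples with unknown
    age are dropped; needs at least ``min_n`` aged samples.  Output columns
    taxon, rho, p_value, q_value sorted by q then taxon; constant taxa are
    skipped (rho undefined).
    """
    ages = meta.set_index("sample_id")["age"]
    samples = [s for s in abund.columns if s in ages.index and pd.notna(ages[s])]
    if len(samples) < min_n:
        raise InsufficientDataError(
            f"age screen needs >= {min_n} samples with known age, have {len(samples)}"
        )
    age = ages.loc[samples].to_numpy(dtype=float)
    rows = []
    for taxon in abund.index:
        vals = abund.loc[taxon, samples].to_numpy(dtype=float)
        if np.unique(vals).size == 1:
            continue
        res = spearman(vals, age)
        rows.append({"taxon": taxon, "rho": res.statistic, "p_value": res.p_value})
    out = pd.DataFrame(rows, columns=["taxon", "rho", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    else:
        out["q_value"] = []
    return out.sort_values(["q_value", "taxon"]).reset_index(drop=True)


def pairwise_table(
    dm: skbio.DistanceMatrix,
    meta: pd.DataFrame,
    rel: RelatednessMatrix,
) -> pd.DataFrame:
    """Per-pair microbiota distance and relatedness over distinct individuals.

    Pairs are unordered and enumerated once; individuals must have exactly
    one sample each.  Pairs whose individuals are absent from the
    relatedness matrix are assigned relatedness 0 (isolated founders).
    """
    m = meta.set_index("sample_id")
    sample_of = {m.loc[s, "individual_id"]: s for s in dm.ids if s in m.index}
    individuals = sorted(sample_of)
    known = set(rel.individual_ids)
    rows = []
    for a, b in itertools.combinations(individuals, 2):
        k = rel.k(a, b) if a in known and b in known else 0.0
        mm = rel.m(a, b) if a in known and b in known else 0.0
        rows.append(
            {
                "individual_1": a,
                "individual_2": b,
                "distance": dm[sample_of[a], sample_of[b]],
                "K": k,
                "M": mm,
            }
        )
    return pd.DataFrame(rows, columns=["individual_1", "individual_2", "distance", "K", "M"])


def kinship_association(
    dm: skbio.DistanceMatrix,
    meta: pd.DataFrame,
    rel: RelatednessMatrix,
    channel: str = "genetic",
    mantel_permutations: int = 0,
    seed: int = 0,
) -> TestResult:
    """Spearman correlation of microbiota distance with relatedness.

    Pairs with zero relatedness on the requested channel are excluded.  A
    negative rho means closer kin carry more similar microbiota.  With
    ``mantel_permutations > 0`` a permutation p (shuffling individuals of the
    relatedness matrix, Mantel-style) is reported instead of the analytic
    one — a robustness option, since pairs sharing an individual are not
    independent.
    """
    if channel not in ("genetic", "maternal"):
        raise UsageError(f"channel must be genetic|maternal, got {channel!r}")
    col = "K" if channel == "genetic" else "M"
    pairs = pairwise_table(dm, meta, rel)
    used = pairs[pairs[col] > 0]
    if len(used) < 3:
        raise InsufficientDataError(
            f"only {len(used)} pair(s) with nonzero {channel} relatedness"
        )
    res = spearman(used["distance"].to_numpy(), used[col].to_numpy())
    res.method = f"spearman-{channel}"
    if mantel_permutations > 0:
        rng = np.random.default_rng(seed)
        inds = sorted(
            set(used["individual_1"]) | set(used["individual_2"])
        )
        obs = res.statistic
        lookup = {}
        for _, r in pairs.iterrows():
            lookup[(r["individual_1"], r["individual_2"])] = r["distance"]
            lookup[(r["individual_2"], r["individual_1"])] = r["distance"]
        pair_list = list(zip(used["individual_1"], used["individual_2"]))
        exceed = 0
        for _ in range(mantel_permutations):
            relabel = dict(zip(inds, rng.permutation(inds)))
            dist_perm = [lookup[(relabel[a], relabel[b])] for a, b in pair_list]
            rho_p = spearman(np.asarray(dist_perm), used[col].to_numpy()).statistic
            if abs(rho_p) >= abs(obs) - 1e-12:
                exceed += 1
        res.p_value = (exceed + 1.0) / (mantel_permutations + 1.0)
        res.method += "-mantel"
    return res


def exclude_samples(
    tab: OtuTable, meta: pd.DataFrame, exclusion: list[str], reason: str = ""
) -> tuple[OtuTable, pd.DataFrame]:
    """Remove listed samples from the table and metadata, logging each one."""
    if not exclusion:
        return tab, meta
    known = set(meta["sample_id"])
    unknown = [s for s in exclusion if s not in known]
    if unknown:
        raise UsageError(f"unknown sample id(s) in exclusion list: {unknown}")
    for s in exclusion:
        log.info("excluding sample %s%s", s, f" ({reason})" if reason else "")
    new_meta = meta[~meta["sample_id"].isin(exclusion)].reset_index(drop=True)
    new_tab = tab.drop_samples([s for s in exclusion if s in tab.sample_ids])
    return new_tab, new_meta
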