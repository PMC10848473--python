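"""Statistical primitives used by the pipeline stages.

Two-group comparisons are Mann-Whitney U tests (exact enumeration for small
tie-free samples, otherwise the tie- and continuity-corrected normal
approximation).  Multiplicity control is Benjamini-Hochberg.  Community-level
group tests are PERMANOVA in the projection (hat-matrix) form, which
partitions the Gower-centered distance matrix by one or two terms with
sequential sums of squares and supports continuous covariates.  Indicator
taxa are scored with the Dufrene-Legendre IndVal statistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import skbio
from statsmodels.stats.multitest import multipletests

from .errors import UsageError

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    direction: int = 0

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _median_direction(x: np.ndarray, y: np.ndarray) -> int:
    d = np.median(x) - np.median(y)
    if d == 0:
        d = np.mean(x) - np.mean(y)
    return int(np.sign(d))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration when both groups have n <= 8 and the pooled
    data are tie-free; otherwise the normal approximation with tie and
    continuity corrections.  ``direction`` is the sign of median(x) -
    median(y), falling back to means on a median tie.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = x.size <= 8 and y.size <= 8 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method=f"mann-whitney-{method}",
        n=(x.size, y.size),
        direction=_median_direction(x, y),
    )


def mann_whitney_many(
    x: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Mann-Whitney tests for many taxa at once.

    ``x`` (taxa x n1) and ``y`` (taxa x n2) hold one group each; returns
    (U, p, direction) arrays identical to calling :func:`mann_whitney` per
    row, but batched for speed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise UsageError("mann_whitney_many expects aligned 2-D arrays")
    if x.shape[1] == 0 or y.shape[1] == 0:
        raise UsageError("mann_whitney_many requires non-empty groups")
    pooled = np.concatenate([x, y], axis=1)
    sorted_rows = np.sort(pooled, axis=1)
    tie_free = (np.diff(sorted_rows, axis=1) != 0).all(axis=1)
    small = x.shape[1] <= 8 and y.shape[1] <= 8

    n_taxa = x.shape[0]
    u = np.empty(n_taxa)
    p = np.empty(n_taxa)
    for mask, method in ((tie_free & small, "exact"), (~(tie_free & small), "asymptotic")):
        if not mask.any():
            continue
        res = scipy.stats.mannwhitneyu(
            x[mask], y[mask], alternative="two-sided", method=method,
            use_continuity=True, axis=1,
        )
        u[mask] = res.statistic
        p[mask] = np.minimum(1.0, res.pvalue)
    med = np.median(x, axis=1) - np.median(y, axis=1)
    mean_diff = x.mean(axis=1) - y.mean(axis=1)
    direction = np.sign(np.where(med != 0, med, mean_diff)).astype(int)
    return u, p, direction


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise UsageError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with average ranks and t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise UsageError("spearman requires paired vectors")
    if x.size < 3:
        raise UsageError("spearman requires n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise UsageError("spearman rho undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return TestResult(
        statistic=float(rho),
        p_value=min(1.0, float(p)),
        method="spearman",
        n=(x.size,),
        direction=int(np.sign(rho)),
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    """Sequential distance-based ANOVA table.

    ``table`` has one row per model term plus Residual and Total rows, with
    columns df, sum_sq, pseudo_F, R2 and p_value (permutation p; NaN for
    Residual/Total).
    """

    table: pd.DataFrame
    n_permutations: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def _model_matrix(values: pd.Series | np.ndarray, n: int) -> tuple[np.ndarray, int]:
    """Columns (without intercept) for one term; returns (matrix, df)."""
    s = pd.Series(values).reset_index(drop=True)
    if s.isna().any():
        raise UsageError("missing values in a PERMANOVA term")
    if pd.api.types.is_numeric_dtype(s) and s.nunique() > 8:
        v = s.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise UsageError("constant covariate in PERMANOVA")
        v = (v - v.mean()) / v.std()
        return v.reshape(n, 1), 1
    levels = pd.unique(s)
    if len(levels) < 2:
        raise UsageError("PERMANOVA factor must have at least two levels")
    dummies = np.column_stack([(s == lev).to_numpy(float) for lev in levels[1:]])
    return dummies, len(levels) - 1


def permanova(
    dm: skbio.DistanceMatrix,
    terms: dict[str, "pd.Series | np.ndarray | list"],
    n_perm: int | str = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One- or two-factor PERMANOVA with sequential sums of squares.

    ``terms`` maps term name -> per-sample values aligned with ``dm.ids``
    (categorical factors or continuous covariates; numeric vectors with more
    than 8 distinct values are treated as continuous).  The permutation null
    permutes sample labels freely; ``n_perm='all'`` enumerates every
    permutation (only sensible for very small n).
    """
    if not 1 <= len(terms) <= 2:
        raise UsageError("permanova supports 1 or 2 terms")
    n = len(dm.ids)
    exhaustive = n_perm == "all"
    if not exhaustive:
        n_perm = int(n_perm)
        if n_perm < 99:
            raise UsageError("n_perm must be >= 99 (or 'all')")

    d2 = dm.data.astype(float) ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * centering @ d2 @ centering
    ss_total = float(np.trace(g))

    names = list(terms)
    blocks, dfs = [], []
    for name in names:
        b, df = _model_matrix(terms[name], n)
        blocks.append(b)
        dfs.append(df)

    intercept = np.ones((n, 1))
    hats = []  # cumulative hat matrices
    x = intercept
    for b in blocks:
        x = np.hstack([x, b])
        hats.append(_hat(x))
    df_model = int(round(np.trace(hats[-1]))) - 1
    df_res = n - 1 - df_model
    if df_res <= 0:
        raise UsageError("no residual degrees of freedom")

    def stats_for(gmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fits = np.array([float(np.sum(h * gmat)) for h in hats])
        ss_seq = np.diff(np.concatenate([[0.0], fits]))
        ss_res = float(np.trace(gmat)) - fits[-1]
        # guard against an exactly-zero residual (perfectly separated groups)
        denom = max(ss_res, 1e-12 * max(abs(ss_total), 1.0)) / df_res
        f = (ss_seq / np.array(dfs)) / denom
        return ss_seq, np.append(f, ss_res)

    ss_seq, packed = stats_for(g)
    f_obs, ss_res = packed[:-1], float(packed[-1])

    rng = np.random.default_rng(seed)
    if exhaustive:
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        count = np.zeros(len(names))
        for perm in perms:
            gp = g[np.ix_(perm, perm)]
            _, pk = stats_for(gp)
            count += pk[:-1] >= f_obs - np.maximum(1e-12, 1e-8 * np.abs(f_obs))
        p_vals = count / len(perms)
        n_used = len(perms)
    else:
        count = np.zeros(len(names))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            _, pk = stats_for(gp)
            count += pk[:-1] >= f_obs - np.maximum(1e-12, 1e-8 * np.abs(f_obs))
        p_vals = (count + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    rows = []
    for i, name in enumerate(names):
        rows.append(
            {
                "term": name,
                "df": dfs[i],
                "sum_sq": ss_seq[i],
                "pseudo_F": f_obs[i],
                "R2": ss_seq[i] / ss_total,
                "p_value": p_vals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "sum_sq": ss_res,
            "pseudo_F": np.nan,
            "R2": ss_res / ss_total,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": ss_total,
            "pseudo_F": np.nan,
            "R2": 1.0,
            "p_value": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_used)


def pairwise_permanova(
    dm: skbio.DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """All two-group PERMANOVAs with BH-adjusted q-values."""
    groups = pd.Series(list(groups), index=list(dm.ids))
    levels = sorted(groups.unique())
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(levels, 2):
        ids = list(groups.index[groups.isin([a, b])])
        sub = dm.filter(ids)
        res = permanova(
            sub,
            {"group": groups.loc[ids]},
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        term = res.term("group")
        rows.append(
            {
                "group_1": a,
                "group_2": b,
                "pseudo_F": term["pseudo_F"],
                "R2": term["R2"],
                "p_value": term["p_value"],
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# IndVal
# ---------------------------------------------------------------------------


@dataclass
class IndValResult:
    taxon: str
    best_group: str
    specificity: float   # A
    fidelity: float      # B
    indval: float        # sqrt(A * B)
    p_value: float


def _indval_components(
    abund: np.ndarray, group_masks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B and IndVal per (group, taxon) for a taxa x samples array."""
    means = np.stack([abund[:, m].mean(axis=1) for m in group_masks])
    occ = np.stack([(abund[:, m] > 0).mean(axis=1) for m in group_masks])
    denom = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(denom > 0, means / denom, 0.0)
    return a, occ, np.sqrt(a * occ)


def indval(
    abund: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> list[IndValResult]:
    """Dufrene-Legendre indicator value analysis.

    ``abund`` is taxa x samples (counts or relative abundances); ``groups``
    assigns each sample column a group.  For each taxon, A (specificity) is
    its mean abundance in a group over the sum of its group means, B
    (fidelity) the within-group occurrence fraction, IndVal = sqrt(A*B),
    and the reported group maximises IndVal.  Significance is by permuting
    group labels.
    """
    groups = pd.Series(list(groups), index=list(abund.columns))
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise UsageError("indval requires at least two groups")
    if (groups.value_counts() < 1).any():
        raise UsageError("every group needs at least one sample")

    values = abund.to_numpy(dtype=float)
    keep = values.sum(axis=1) > 0
    if not keep.all():
        log.warning("indval: skipping %d all-zero taxa", int((~keep).sum()))
    values = values[keep]
    taxa = list(abund.index[keep])

    labels = groups.to_numpy()
    masks = [labels == lev for lev in levels]
    a, b, iv = _indval_components(values, masks)
    best = iv.argmax(axis=0)
    obs = iv.max(axis=0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(taxa))
    for _ in range(int(n_perm)):
        perm = rng.permutation(len(labels))
        pl = labels[perm]
        pmasks = [pl == lev for lev in levels]
        _, _, piv = _indval_components(values, pmasks)
        exceed += piv.max(axis=0) >= obs - 1e-12
    p = (exceed + 1.0) / (n_perm + 1.0)

    out = []
    for i, taxon in enumerate(taxa):
        gi = best[i]
        out.append(
            IndValResult(
                taxon=taxon,
                best_group=str(levels[gi]),
                specificity=float(a[gi, i]),
                fidelity=float(b[gi, i]),
                indval=float(iv[gi, i]),
                p_value=float(p[i]),
            )
        )
    return out


def indval_table(results: list[IndValResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "best_group": r.best_group,
                "A": r.specificity,
                "B": r.fidelity,
                "indval": r.indval,
                "p_value": r.p_value,
            }
            for r in results
        ]
    )
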