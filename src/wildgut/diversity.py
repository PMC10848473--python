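"""Alpha and beta diversity, rank aggregation, and ordination.

Alpha diversity reports observed OTUs, the Shannon index (log base 2 by
default, matching the classic amplicon-pipeline convention) and Faith's
phylogenetic diversity.  Beta diversity is weighted or unweighted UniFrac on
a rooted tree.  UniFrac and Faith's PD are delegated to scikit-bio; PCoA is
classical metric scaling implemented directly so that negative eigenvalues
are reported rather than silently corrected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode
from skbio.diversity import alpha as skbio_alpha
from skbio.diversity import beta_diversity

from .errors import UsageError, ValidationError
from .io import RANKS, OtuTable, TaxonomyMap

log = logging.getLogger(__name__)

UNIFRAC_MODES = ("unweighted", "weighted_normalized", "weighted_raw")

UNASSIGNED = "unassigned"


def _check_tree(tab: OtuTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    present = tab.counts.index[(tab.counts.to_numpy() > 0).any(axis=1)]
    for taxon in present:
        if taxon not in tips:
            raise ValidationError(f"taxon {taxon!r} absent from the tree")


def _check_rooted(tree: TreeNode) -> None:
    if len(tree.children) != 2:
        raise ValidationError(
            "tree must be rooted (bifurcating at the root) for UniFrac/PD"
        )


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of a count (or proportion) vector, in log-``base`` units."""
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("cannot compute Shannon index of an empty sample")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def alpha_diversity(
    tab: OtuTable, tree: TreeNode, shannon_base: float = 2.0
) -> pd.DataFrame:
    """Observed OTUs, Shannon index and Faith's PD per sample."""
    _check_tree(tab, tree)
    counts = tab.counts.to_numpy().T  # samples x taxa
    otu_ids = tab.taxon_ids
    records = []
    for i, sample in enumerate(tab.sample_ids):
        row = counts[i]
        records.append(
            {
                "sample_id": sample,
                "observed_otus": int((row > 0).sum()),
                "shannon": shannon(row, base=shannon_base),
                "faith_pd": float(
                    skbio_alpha.faith_pd(row, taxa=otu_ids, tree=tree)
                ),
            }
        )
    return pd.DataFrame.from_records(records)


def unifrac(
    tab: OtuTable, tree: TreeNode, mode: str = "weighted_normalized"
) -> skbio.DistanceMatrix:
    """Pairwise UniFrac distances between all samples of the table."""
    if mode not in UNIFRAC_MODES:
        raise UsageError(f"mode must be one of {UNIFRAC_MODES}, got {mode!r}")
    _check_rooted(tree)
    _check_tree(tab, tree)
    counts = tab.counts.to_numpy().T
    if (counts.sum(axis=1) == 0).any():
        raise ValidationError("zero-count sample in UniFrac input")
    kwargs: dict = {}
    if mode == "unweighted":
        metric = "unweighted_unifrac"
    else:
        metric = "weighted_unifrac"
        kwargs["normalized"] = mode == "weighted_normalized"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return beta_diversity(
            metric,
            counts,
            ids=tab.sample_ids,
            taxa=tab.taxon_ids,
            tree=tree,
            validate=True,
            **kwargs,
        )


def aggregate_rank(
    tab: OtuTable, tax: TaxonomyMap, rank: str, relative: bool = True
) -> pd.DataFrame:
    """Sum counts within each rank-level name; unknowns pool to 'unassigned'.

    Returns a names x samples DataFrame of relative abundances (or raw
    summed counts with ``relative=False``).
    """
    if rank not in RANKS:
        raise UsageError(f"rank must be one of {RANKS}, got {rank!r}")
    names = [tax.name_at(t, rank) or UNASSIGNED for t in tab.taxon_ids]
    grouped = tab.counts.groupby(pd.Index(names, name=rank)).sum()
    if relative:
        grouped = grouped / tab.counts.sum(axis=0)
    return grouped


def fb_ratio(phylum_abund: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Firmicutes/Bacteroidetes ratio from phylum abundances.

    ``phylum_abund`` is the phylum-level names x samples table from
    :func:`aggregate_rank`.  Samples with zero Bacteroidetes get a NaN ratio
    and are flagged; group summaries should exclude them.
    """
    if phylum_abund.index.name != "phylum":
        raise UsageError("fb_ratio requires a phylum-level aggregation")
    f = phylum_abund.loc["Firmicutes"] if "Firmicutes" in phylum_abund.index else pd.Series(0.0, index=phylum_abund.columns)
    b = phylum_abund.loc["Bacteroidetes"] if "Bacteroidetes" in phylum_abund.index else pd.Series(0.0, index=phylum_abund.columns)
    ratio = f / b.where(b > 0)
    n_undef = int(ratio.isna().sum())
    if n_undef:
        log.warning("%d sample(s) have zero Bacteroidetes; ratio undefined", n_undef)
    return pd.DataFrame(
        {
            "sample_id": phylum_abund.columns,
            "firmicutes": f.to_numpy(dtype=float),
            "bacteroidetes": b.to_numpy(dtype=float),
            "ratio": ratio.to_numpy(dtype=float),
        }
    )


@dataclass
class PcoaResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame          # samples x axes
    eigenvalues: np.ndarray            # all n, non-increasing (may be negative)
    proportion_explained: np.ndarray   # per retained axis

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def pcoa(dm: skbio.DistanceMatrix, axes: int = 2) -> PcoaResult:
    """Principal coordinates analysis (Gower's classical scaling).

    The doubly centered matrix ``-D**2 / 2`` is eigendecomposed; coordinates
    are eigenvectors scaled by the square root of their (non-negative)
    eigenvalues.  Negative eigenvalues are clamped to zero for coordinates
    but reported in ``eigenvalues``.
    """
    n = len(dm.ids)
    if axes < 1 or axes > n - 1:
        raise UsageError(f"axes must be in [1, {n - 1}], got {axes}")
    d2 = dm.data ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * centering @ d2 @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    clamped = np.clip(eigvals[:axes], 0.0, None)
    coords = eigvecs[:, :axes] * np.sqrt(clamped)
    total = np.clip(eigvals, 0.0, None).sum()
    prop = clamped / total if total > 0 else np.zeros(axes)
    cols = [f"PC{i + 1}" for i in range(axes)]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def rarefy(tab: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample to a common depth without replacement.

    Off by default in the pipeline; provided because depth standardisation
    before diversity computation is a legitimate analysis choice.
    """
    rng = np.random.default_rng(seed)
    totals = tab.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth < 1 or (totals < depth).any():
        raise UsageError("rarefaction depth exceeds a sample's total count")
    out = {}
    values = tab.counts.to_numpy()
    for j, sample in enumerate(tab.sample_ids):
        col = values[:, j]
        picked = rng.choice(np.repeat(np.arange(len(col)), col), size=depth, replace=False)
        out[sample] = np.bincount(picked, minlength=len(col))
    return OtuTable(pd.DataFrame(out, index=tab.counts.index))
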