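"""Readers and writers for every on-disk artifact of the pipeline.

Formats are deliberately plain text:

* OTU table — TSV, taxa as rows, samples as columns, header starting with
  ``#OTU ID``, optional trailing ``taxonomy`` column holding a
  semicolon-separated greengenes-style lineage (``k__...;p__...;...``).
* Taxonomy — two-column TSV (taxon id, lineage string).
* Phylogeny — newick with branch lengths on every non-root node.
* Pedigree — CSV with header ``individual,sire,dam``; empty field or ``0``
  means unknown parent.
* Sample metadata — TSV with columns ``sample_id, individual_id, population,
  status, sex, age``.
* Distance matrix — square TSV, identical header and first column.

All identifiers are opaque, case-sensitive, UTF-8 strings.  Numbers use a
decimal point, never locale separators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import skbio
from skbio import TreeNode

from .errors import FormatError, ValidationError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")

UNKNOWN = ""


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Non-negative integer count matrix, taxa (rows) x samples (columns)."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def validate(self) -> None:
        idx = self.counts.index
        cols = self.counts.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate taxon id: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("negative count encountered")
        colsums = vals.sum(axis=0)
        if (colsums == 0).any():
            bad = cols[np.asarray(colsums == 0)][0]
            raise ValidationError(f"sample {bad!r} has zero total count")

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (columns sum to 1)."""
        return self.counts / self.counts.sum(axis=0)

    def drop_samples(self, sample_ids: list[str]) -> "OtuTable":
        kept = self.counts.drop(columns=list(sample_ids))
        return OtuTable(kept)


@dataclass
class TaxonomyMap:
    """taxon id -> lineage of up to 7 named ranks; unknown ranks are ''."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tid, lin in self.lineages.items():
            if len(lin) != len(RANKS):
                raise ValidationError(
                    f"lineage for {tid!r} has {len(lin)} ranks, expected {len(RANKS)}"
                )

    def name_at(self, taxon_id: str, rank: str) -> str:
        """Rank name for a taxon, '' if unknown or taxon absent."""
        if rank not in RANKS:
            raise ValidationError(f"unknown rank {rank!r}")
        lin = self.lineages.get(taxon_id)
        if lin is None:
            return UNKNOWN
        return lin[RANKS.index(rank)]

    def covers(self, taxon_ids) -> bool:
        return all(t in self.lineages for t in taxon_ids)

    @staticmethod
    def parse_lineage(text: str) -> tuple[str, ...]:
        parts = [p.strip() for p in text.split(";")]
        out = [UNKNOWN] * len(RANKS)
        for i, part in enumerate(parts[: len(RANKS)]):
            for j, pref in enumerate(_RANK_PREFIXES):
                if part.startswith(pref):
                    out[j] = part[len(pref):]
                    break
            else:
                if part:
                    out[i] = part
        return tuple(out)

    @staticmethod
    def format_lineage(lineage: tuple[str, ...]) -> str:
        return ";".join(p + n for p, n in zip(_RANK_PREFIXES, lineage))


def read_otu_table(path) -> tuple[OtuTable, TaxonomyMap | None]:
    """Parse an OTU table TSV; a trailing taxonomy column is split off."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, comment=None)
    if df.columns[0] != "#OTU ID":
        raise FormatError(f"{path}: first header cell must be '#OTU ID'")
    df = df.set_index(df.columns[0])
    taxonomy = None
    if len(df.columns) and df.columns[-1].lower() == "taxonomy":
        tax_col = df.pop(df.columns[-1])
        taxonomy = TaxonomyMap(
            {tid: TaxonomyMap.parse_lineage(str(v)) for tid, v in tax_col.items()}
        )
    try:
        counts = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric count ({exc})") from None
    if not np.allclose(counts.to_numpy(), np.round(counts.to_numpy())):
        raise FormatError(f"{path}: counts must be integers")
    counts = counts.round().astype(np.int64)
    counts.index.name = "#OTU ID"
    return OtuTable(counts), taxonomy


def write_otu_table(table: OtuTable, path, taxonomy: TaxonomyMap | None = None) -> None:
    path = Path(path)
    out = table.counts.copy()
    out.index.name = "#OTU ID"
    if taxonomy is not None:
        out["taxonomy"] = [
            TaxonomyMap.format_lineage(taxonomy.lineages.get(t, (UNKNOWN,) * len(RANKS)))
            for t in out.index
        ]
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxonomy TSV needs 2 columns (id, lineage)")
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        raise FormatError(f"{path}: duplicate taxon id {ids[ids.duplicated()].iloc[0]!r}")
    return TaxonomyMap(
        {tid: TaxonomyMap.parse_lineage(str(lin)) for tid, lin in zip(ids, df.iloc[:, 1])}
    )


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#OTU ID\ttaxonomy\n")
        for tid, lin in tax.lineages.items():
            fh.write(f"{tid}\t{TaxonomyMap.format_lineage(lin)}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; every non-root node must carry a length."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    seen: set[str] = set()
    for tip in tree.tips():
        if tip.name is None or tip.name == "":
            raise FormatError("tree has an unlabelled leaf")
        if tip.name in seen:
            raise FormatError(f"duplicate leaf label {tip.name!r}")
        seen.add(tip.name)
    for node in tree.traverse(include_self=False):
        bl = node.length
        if bl is None:
            where = node.name or "internal node"
            raise FormatError(f"missing branch length at {where}")
        if not math.isfinite(bl) or bl < 0:
            raise ValidationError(f"invalid branch length {bl!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeRecord:
    individual_id: str
    sire_id: str | None = None
    dam_id: str | None = None


def _norm_parent(value) -> str | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "0", "nan", "NA"):
        return None
    return s


def read_pedigree(path) -> list[PedigreeRecord]:
    """Read pedigree CSV; referenced-but-undeclared parents become founders."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["individual", "sire", "dam"]:
        raise FormatError(f"{path}: header must be individual,sire,dam")
    records: list[PedigreeRecord] = []
    declared: set[str] = set()
    for _, row in df.iterrows():
        ind = str(row.iloc[0]).strip()
        if ind in declared:
            raise FormatError(f"{path}: individual {ind!r} appears twice")
        declared.add(ind)
        records.append(
            PedigreeRecord(ind, _norm_parent(row.iloc[1]), _norm_parent(row.iloc[2]))
        )
    referenced = {
        p for r in records for p in (r.sire_id, r.dam_id) if p is not None
    }
    for p in sorted(referenced - declared):
        records.append(PedigreeRecord(p))
    _check_acyclic(records)
    return records


def _check_acyclic(records: list[PedigreeRecord]) -> None:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(r.individual_id for r in records)
    for r in records:
        for p in (r.sire_id, r.dam_id):
            if p is not None:
                g.add_edge(r.individual_id, p)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    path = " -> ".join(u for u, _ in cycle)
    raise ValidationError(f"pedigree contains a cycle: {path}")


def write_pedigree(records: list[PedigreeRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual,sire,dam\n")
        for r in records:
            fh.write(f"{r.individual_id},{r.sire_id or ''},{r.dam_id or ''}\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "individual_id", "population", "status", "sex", "age"]


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    df = df[METADATA_COLUMNS].copy()
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample id {dup!r}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValidationError(
            f"individual {dup!r} contributes more than one sample"
        )
    bad_status = set(df["status"]) - {"wild", "AD"}
    if bad_status:
        raise ValidationError(f"status must be wild|AD, got {sorted(bad_status)}")
    bad_sex = set(df["sex"]) - {"M", "F", "unknown"}
    if bad_sex:
        raise ValidationError(f"sex must be M|F|unknown, got {sorted(bad_sex)}")
    age = pd.to_numeric(df["age"].replace({"unknown": np.nan, "": np.nan}))
    if (age.dropna() < 0).any():
        raise ValidationError("negative age encountered")
    df = df.copy()
    df["age"] = age
    return df.reset_index(drop=True)


def write_metadata(df: pd.DataFrame, path) -> None:
    out = df[METADATA_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def read_distance_matrix(path, tol: float = 1e-9) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column sample ids differ")
    vals = df.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError(f"{path}: non-finite distance")
    if np.abs(vals - vals.T).max(initial=0.0) > tol:
        raise ValidationError(f"{path}: matrix asymmetric beyond tolerance {tol}")
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    return skbio.DistanceMatrix(vals, ids=[str(i) for i in df.index])


def write_distance_matrix(dm: skbio.DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )
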