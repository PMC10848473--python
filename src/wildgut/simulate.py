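"""Synthetic study generator.

Emits complete, internally consistent studies — pedigree, phylogeny,
metadata, OTU counts and a ground-truth record — with the statistical
structure the analysis stages assume:

* nine populations (one undisturbed wild reference, one provisioned
  wild-fed group, seven captive colonies) at the default sizes
  10 / 14 / 7 / 3 / 24 / 6 / 33 / 17 / 9;
* taxa organised in phylum blocks that are clades of the simulated tree,
  so phylum-level composition shifts move UniFrac distances;
* disturbance (AD) effects: a log-fold shift per planted phylum
  (Bacteroidetes up; Firmicutes, Actinobacteria, Verrucomicrobia and
  Tenericutes down) plus a small set of strongly shifted "planted" genera;
* age-monotone genera (linear log-abundance slope against age);
* a heritable component: for each designated taxon an independent
  zero-mean multivariate-normal draw across individuals with covariance
  sigma_g^2 * K, where K is the path-counting kinship matrix of the
  simulated pedigree — so related individuals share abundance deviations
  on every heritable taxon;
* Dirichlet-multinomial count noise for realistic overdispersion.

Every byte of output is determined by the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from . import io as wio
from .errors import UsageError, ValidationError
from .io import OtuTable, PedigreeRecord, TaxonomyMap
from .kinship import PedigreeGraph, relatedness_matrix

WILD = "wild"
WILD_FED = "wild_fed"

DEFAULT_POPULATIONS: tuple[tuple[str, int, str], ...] = (
    ("wild", 10, "wild"),
    ("wild_fed", 14, "wild_fed"),
    ("CDZ", 7, "captive"),
    ("BJZ", 3, "captive"),
    ("BJWP", 24, "captive"),
    ("NJZ", 6, "captive"),
    ("SHWP", 33, "captive"),
    ("SHZ", 17, "captive"),
    ("HZZ", 9, "captive"),
)

# five phyla the disturbance shifts, plus neutral filler phyla
DEFAULT_PHYLUM_SHIFTS = {
    "Firmicutes": -0.8,
    "Bacteroidetes": 1.0,
    "Actinobacteria": -1.0,
    "Verrucomicrobia": -1.0,
    "Tenericutes": -0.8,
    "Proteobacteria": 0.0,
    "Spirochaetes": 0.0,
    "Fibrobacteres": 0.0,
}


@dataclass
class SimulationConfig:
    """Generator knobs; defaults are the study conditions being emulated."""

    populations: tuple[tuple[str, int, str], ...] = DEFAULT_POPULATIONS
    taxa_per_phylum: int = 25
    phylum_shifts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_SHIFTS)
    )
    n_planted_genera: int = 12
    planted_genus_effect: float = 6.0      # |log-fold| AD shift of planted genera
    n_age_genera: int = 12
    age_slope: float = 0.15                # log-abundance per year on age genera
    age_range: tuple[float, float] = (1.0, 25.0)
    heritability: float = 0.8              # sigma_g^2 of the liability kernel
    n_heritable_taxa: int = 60
    genetic_loading: float = 1.5
    population_effect_sd: float = 0.6      # per-(population, taxon) random effect
    sample_noise_sd: float = 0.4
    baseline_sd: float = 1.5
    dirichlet_concentration: float = 200.0
    depth_range: tuple[int, int] = (15000, 30000)
    pedigree_generations: int = 3
    founder_fraction: float = 0.4
    transfer_prob: float = 0.1             # cross-colony sire probability
    couple_reuse_prob: float = 0.6         # chance an offspring joins an existing couple

    def __post_init__(self) -> None:
        for _, size, kind in self.populations:
            if size < 1:
                raise UsageError("population sizes must be >= 1")
            if kind not in ("wild", "wild_fed", "captive"):
                raise UsageError(f"unknown population kind {kind!r}")
        if not 0.0 <= self.heritability <= 1.0:
            raise UsageError("heritability must lie in [0, 1]")
        for v in (self.planted_genus_effect, self.age_slope, *self.phylum_shifts.values()):
            if not np.isfinite(v):
                raise UsageError("effect sizes must be finite")

    @property
    def n_taxa(self) -> int:
        return self.taxa_per_phylum * len(self.phylum_shifts)

    @property
    def n_samples(self) -> int:
        return sum(size for _, size, _ in self.populations)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = [list(p) for p in self.populations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "populations" in d:
            d["populations"] = tuple(tuple(p) for p in d["populations"])
        for key in ("depth_range", "age_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def null_config(**overrides) -> SimulationConfig:
    """All effects zero: populations exchangeable, no heritable component."""
    base = dict(
        phylum_shifts={p: 0.0 for p in DEFAULT_PHYLUM_SHIFTS},
        n_planted_genera=0,
        planted_genus_effect=0.0,
        n_age_genera=0,
        age_slope=0.0,
        heritability=0.0,
        population_effect_sd=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def consensus_benchmark_config(**overrides) -> SimulationConfig:
    """Recovery benchmark: 12 planted genera among 188 null taxa.

    Phylum-block shifts and population random effects are off so the
    non-planted taxa are genuinely null in every pool; the planted genera
    carry the default AD effect.
    """
    base = dict(
        phylum_shifts={p: 0.0 for p in DEFAULT_PHYLUM_SHIFTS},
        population_effect_sd=0.0,
        n_age_genera=0,
        age_slope=0.0,
        heritability=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# Taxon catalog and taxonomy
# ---------------------------------------------------------------------------


def taxon_catalog(cfg: SimulationConfig) -> pd.DataFrame:
    """Deterministic taxon list: id, phylum, genus (one genus per OTU)."""
    rows = []
    i = 0
    for phylum in cfg.phylum_shifts:
        for j in range(cfg.taxa_per_phylum):
            i += 1
            rows.append(
                {
                    "taxon": f"OTU{i:04d}",
                    "phylum": phylum,
                    "genus": f"{phylum[:4]}_genus_{j + 1:03d}",
                }
            )
    return pd.DataFrame(rows)


def taxonomy_map(catalog: pd.DataFrame) -> TaxonomyMap:
    lineages = {}
    for _, row in catalog.iterrows():
        lineages[row["taxon"]] = (
            "Bacteria",
            row["phylum"],
            "",
            "",
            "",
            row["genus"],
            "",
        )
    return TaxonomyMap(lineages)


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(
    cfg: SimulationConfig, seed: int = 0
) -> tuple[list[PedigreeRecord], pd.DataFrame]:
    """Random multi-generation pedigree for the captive colonies.

    Wild and wild-fed individuals are isolated founders (their true pedigree
    is unobserved, so their relatedness to everyone is 0).  Captive colonies
    start from unrelated founders with both sexes represented; offspring are
    assigned to breeding couples (reused with some probability, so full
    sibships arise) and sires occasionally come from another colony.
    Returns the records and a per-individual table (individual, population,
    sex, generation).
    """
    rng = np.random.default_rng(seed)
    records: list[PedigreeRecord] = []
    info_rows = []
    males: dict[str, list[str]] = {}
    females: dict[str, list[str]] = {}
    captive_pops = [name for name, _, kind in cfg.populations if kind == "captive"]

    def add(ind, pop, sex, gen, sire=None, dam=None):
        records.append(PedigreeRecord(ind, sire, dam))
        info_rows.append(
            {"individual": ind, "population": pop, "sex": sex, "generation": gen}
        )
        (males if sex == "M" else females).setdefault(pop, []).append(ind)

    for name, size, kind in cfg.populations:
        if kind != "captive":
            for i in range(size):
                sex = "M" if rng.random() < 0.5 else "F"
                add(f"{name}_{i + 1:02d}", name, sex, 0)
            continue
        n_founders = max(2, int(round(cfg.founder_fraction * size))) if size >= 2 else size
        n_founders = min(n_founders, size)
        for i in range(n_founders):
            sex = "M" if i % 2 == 0 else "F"  # guarantee both sexes
            add(f"{name}_{i + 1:02d}", name, sex, 0)
        n_off = size - n_founders
        if n_off == 0:
            continue
        gens = max(1, cfg.pedigree_generations)
        per_gen = [n_off // gens] * gens
        for k in range(n_off - sum(per_gen)):
            per_gen[k] += 1
        couples: list[tuple[str, str]] = []
        idx = n_founders
        for g in range(1, gens + 1):
            # parents must already exist (earlier generations only)
            info = pd.DataFrame(info_rows)
            elig = info[(info["generation"] < g)]
            pop_m = list(elig[(elig["population"] == name) & (elig["sex"] == "M")]["individual"])
            pop_f = list(elig[(elig["population"] == name) & (elig["sex"] == "F")]["individual"])
            any_m = list(elig[(elig["sex"] == "M") & elig["population"].isin(captive_pops)]["individual"])
            if not pop_f or not (pop_m or any_m):
                raise UsageError(
                    f"colony {name}: no eligible mates for generation {g}"
                )
            for _ in range(per_gen[g - 1]):
                reuse = couples and rng.random() < cfg.couple_reuse_prob
                if reuse:
                    sire, dam = couples[rng.integers(len(couples))]
                else:
                    if pop_m and rng.random() >= cfg.transfer_prob:
                        sire = pop_m[rng.integers(len(pop_m))]
                    else:
                        pool = any_m or pop_m
                        sire = pool[rng.integers(len(pool))]
                    dam = pop_f[rng.integers(len(pop_f))]
                    couples.append((sire, dam))
                idx += 1
                sex = "M" if rng.random() < 0.5 else "F"
                add(f"{name}_{idx:02d}", name, sex, g, sire, dam)
    info = pd.DataFrame(info_rows)
    return records, info


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def simulate_tree(cfg: SimulationConfig, seed: int = 0) -> TreeNode:
    """Random rooted binary tree with phylum blocks as clades.

    Leaves within each phylum are joined by random coalescence, then the
    phylum-clade roots are joined the same way; every branch length is an
    independent exponential(1) draw.
    """
    if cfg.n_taxa < 2:
        raise UsageError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    catalog = taxon_catalog(cfg)

    def coalesce(nodes: list[TreeNode]) -> TreeNode:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            parent = TreeNode()
            for child in (a, b):
                child.length = float(rng.exponential(1.0))
                parent.append(child)
            nodes.append(parent)
        return nodes[0]

    clades = []
    for phylum in cfg.phylum_shifts:
        leaves = [
            TreeNode(name=t)
            for t in catalog.loc[catalog["phylum"] == phylum, "taxon"]
        ]
        clades.append(coalesce(leaves) if len(leaves) > 1 else leaves[0])
    root = coalesce(clades) if len(clades) > 1 else clades[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------


def simulate_metadata(
    cfg: SimulationConfig, ind_info: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """One sample per individual; ages uniform on the configured range."""
    rng = np.random.default_rng(seed)
    kind_of = {name: kind for name, _, kind in cfg.populations}
    lo, hi = cfg.age_range
    rows = []
    for _, r in ind_info.iterrows():
        rows.append(
            {
                "sample_id": f"S_{r['individual']}",
                "individual_id": r["individual"],
                "population": r["population"],
                "status": "wild" if kind_of[r["population"]] == "wild" else "AD",
                "sex": r["sex"],
                "age": round(float(rng.uniform(lo, hi)), 1),
            }
        )
    return pd.DataFrame(rows, columns=wio.METADATA_COLUMNS)


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery downstream."""

    taxa: pd.DataFrame         # taxon, phylum, genus, ad_direction, planted,
                               # age_slope, heritable_loading
    individuals: pd.DataFrame  # individual, population, liability
    config: dict

    def planted_genera(self) -> list[str]:
        return sorted(self.taxa.loc[self.taxa["planted"], "genus"])

    def ad_direction_of_genus(self) -> dict[str, int]:
        return {
            r["genus"]: int(np.sign(r["ad_direction"]))
            for _, r in self.taxa.iterrows()
        }

    def to_json(self, path) -> None:
        payload = {
            "taxa": self.taxa.to_dict(orient="records"),
            "individuals": self.individuals.to_dict(orient="records"),
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            taxa=pd.DataFrame(payload["taxa"]),
            individuals=pd.DataFrame(payload["individuals"]),
            config=payload["config"],
        )


def simulate_counts(
    cfg: SimulationConfig,
    ped: PedigreeGraph,
    meta: pd.DataFrame,
    seed: int = 0,
) -> tuple[OtuTable, TaxonomyMap, GroundTruth]:
    """Dirichlet-multinomial counts with the configured effect structure.

    Per-sample expected log relative abundance is
    ``baseline + population effect + AD shift + age slope * (age - mid) +
    liability * loading + sample noise``, softmaxed to proportions, then
    counts are drawn Dirichlet-multinomial at a random depth.
    """
    rng = np.random.default_rng(seed)
    catalog = taxon_catalog(cfg)
    n_taxa = len(catalog)
    taxa = list(catalog["taxon"])
    phylum = catalog["phylum"].to_numpy()

    # --- per-taxon structural assignments (seeded) ---
    base = rng.normal(0.0, cfg.baseline_sd, size=n_taxa)
    ad_shift = np.array([cfg.phylum_shifts[p] for p in phylum], dtype=float)
    planted = np.zeros(n_taxa, dtype=bool)
    if cfg.n_planted_genera > 0:
        if cfg.n_planted_genera > n_taxa:
            raise UsageError("more planted genera than taxa")
        # draw planted genera from the rarer half of the community and
        # alternate shift signs along the baseline ranking: the planted mass
        # added on one side then cancels the mass removed on the other, so
        # softmax renormalisation leaves the remaining taxa compositionally
        # null
        rare_half = np.argsort(base)[: max(cfg.n_planted_genera, n_taxa // 2)]
        chosen = rng.choice(rare_half, size=cfg.n_planted_genera, replace=False)
        chosen = chosen[np.argsort(base[chosen])]
        planted[chosen] = True
        signs = np.where(np.arange(cfg.n_planted_genera) % 2 == 0, 1.0, -1.0)
        # in shifted phyla the planted genus follows its phylum's direction
        for k, t in enumerate(chosen):
            ps = cfg.phylum_shifts[phylum[t]]
            if ps != 0:
                signs[k] = np.sign(ps)
        # centre the planted contrast on the baseline (wild -d/2, AD +d/2):
        # the group difference is the full effect, but neither side's
        # composition is dominated by the planted taxa, so the remaining
        # taxa stay compositionally null
        ad_shift = ad_shift.copy()
        ad_shift[chosen] += signs * cfg.planted_genus_effect
        base[chosen] -= signs * cfg.planted_genus_effect / 2.0
    age_slope = np.zeros(n_taxa)
    if cfg.n_age_genera > 0:
        # age-tracking genera come from the commoner half of the community:
        # count noise on rare taxa would otherwise bury the trend
        common = np.argsort(base)[-max(cfg.n_age_genera, n_taxa // 2):]
        age_idx = rng.choice(common, size=cfg.n_age_genera, replace=False)
        age_slope[age_idx] = cfg.age_slope * np.where(
            rng.random(cfg.n_age_genera) < 0.5, -1.0, 1.0
        )
    loading = np.zeros(n_taxa)
    if cfg.n_heritable_taxa > 0 and cfg.heritability > 0:
        # host-genetic effects are planted on the commoner half of the
        # community: abundant taxa both dominate abundance-weighted beta
        # diversity and carry proportionally less count noise, mirroring the
        # well-known heritable taxa which are common community members
        common_half = np.argsort(base)[-max(cfg.n_heritable_taxa, n_taxa // 2):]
        her_idx = rng.choice(
            common_half, size=min(cfg.n_heritable_taxa, n_taxa), replace=False
        )
        loading[her_idx] = cfg.genetic_loading * np.where(
            rng.random(len(her_idx)) < 0.5, -1.0, 1.0
        )

    # --- population random effects ---
    pops = [name for name, _, _ in cfg.populations]
    pop_eff = {
        p: rng.normal(0.0, cfg.population_effect_sd, size=n_taxa) for p in pops
    }

    # --- heritable genetic values from the path-counting kinship kernel ---
    # one independent MVN(0, sigma_g^2 * K) draw across individuals per
    # heritable taxon (the standard additive-genetic model): related
    # individuals share deviations on every heritable taxon, so community
    # distance decreases monotonically in K
    individuals = list(meta["individual_id"])
    n_ind = len(individuals)
    her_mask = loading != 0
    n_her = int(her_mask.sum())
    genetic = np.zeros((n_her, n_ind))
    if cfg.heritability > 0 and n_her > 0:
        rel = relatedness_matrix(ped, individuals, allow_missing=True)
        k_mat = rel.K + 1e-8 * np.eye(n_ind)
        chol = np.linalg.cholesky(k_mat)
        genetic = np.sqrt(cfg.heritability) * (
            rng.normal(size=(n_her, n_ind)) @ chol.T
        )
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    liability = genetic.mean(axis=0) if n_her else np.zeros(n_ind)

    # --- assemble per-sample expectations and draw counts ---
    mid_age = float(np.mean(cfg.age_range))
    depth_lo, depth_hi = cfg.depth_range
    counts = np.zeros((n_taxa, len(meta)), dtype=np.int64)
    for j, (_, row) in enumerate(meta.iterrows()):
        eta = base.copy()
        eta += pop_eff[row["population"]]
        if row["status"] == "AD":
            eta += ad_shift
        if pd.notna(row["age"]):
            eta += age_slope * (float(row["age"]) - mid_age)
        eta[her_mask] += loading[her_mask] * genetic[:, ind_index[row["individual_id"]]]
        eta += rng.normal(0.0, cfg.sample_noise_sd, size=n_taxa)
        p = np.exp(eta - eta.max())
        p /= p.sum()
        depth = int(rng.integers(depth_lo, depth_hi + 1))
        q = rng.gamma(cfg.dirichlet_concentration * p)
        qsum = q.sum()
        if qsum <= 0 or not np.isfinite(qsum):  # pathological concentration
            q = p
            qsum = 1.0
        counts[:, j] = rng.multinomial(depth, q / qsum)

    # guarantee sample-sum invariant (OtuTable requires positive columns)
    for j in range(counts.shape[1]):
        if counts[:, j].sum() == 0:
            counts[rng.integers(n_taxa), j] = 1

    table = OtuTable(pd.DataFrame(counts, index=taxa, columns=list(meta["sample_id"])))
    tax = taxonomy_map(catalog)
    truth_taxa = catalog.copy()
    truth_taxa["ad_direction"] = np.sign(ad_shift).astype(int)
    truth_taxa["ad_shift"] = ad_shift
    truth_taxa["planted"] = planted
    truth_taxa["age_slope"] = age_slope
    truth_taxa["heritable_loading"] = loading
    truth_ind = pd.DataFrame(
        {
            "individual": individuals,
            "population": list(meta["population"]),
            "liability": liability,
        }
    )
    truth = GroundTruth(taxa=truth_taxa, individuals=truth_ind, config=cfg.to_dict())
    return table, tax, truth


# ---------------------------------------------------------------------------
# Whole-study driver
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """An in-memory synthetic study plus (optionally) its on-disk paths."""

    config: SimulationConfig
    table: OtuTable
    taxonomy: TaxonomyMap
    tree: TreeNode
    metadata: pd.DataFrame
    pedigree: list[PedigreeRecord]
    truth: GroundTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _stage_seed(master: int, tag: str) -> int:
    """Stable per-stage substream below 2**31."""
    import hashlib

    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def simulate_study(
    cfg: SimulationConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> StudyData:
    """Generate a full study; write the file set when ``out_dir`` is given."""
    cfg = cfg or SimulationConfig()
    records, ind_info = simulate_pedigree(cfg, seed=_stage_seed(seed, "pedigree"))
    ped = PedigreeGraph(records)
    tree = simulate_tree(cfg, seed=_stage_seed(seed, "tree"))
    meta = simulate_metadata(cfg, ind_info, seed=_stage_seed(seed, "metadata"))
    table, tax, truth = simulate_counts(cfg, ped, meta, seed=_stage_seed(seed, "counts"))
    study = StudyData(cfg, table, tax, tree, meta, records, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "otu_table": out / "otu_table.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "tree": out / "tree.nwk",
            "metadata": out / "metadata.tsv",
            "pedigree": out / "pedigree.csv",
            "ground_truth": out / "ground_truth.json",
            "config": out / "sim_config.yaml",
        }
        try:
            wio.write_otu_table(table, paths["otu_table"])
            wio.write_taxonomy(tax, paths["taxonomy"])
            wio.write_tree(tree, paths["tree"])
            wio.write_metadata(meta, paths["metadata"])
            wio.write_pedigree(records, paths["pedigree"])
            truth.to_json(paths["ground_truth"])
            cfg.to_yaml(paths["config"])
        except OSError as exc:
            raise ValidationError(f"failed writing study to {out}: {exc}") from exc
        study.paths = paths
    return study
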