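"""End-to-end analysis orchestration.

Fixed stage order: load-or-simulate inputs -> sample exclusion -> pedigree
relatedness -> alpha diversity -> beta diversity (UniFrac) + PCoA ->
population PERMANOVA (overall and pairwise with BH correction) ->
consensus differential-abundance screen -> indicator taxa -> host trait
PERMANOVAs -> age correlation screen -> kinship-vs-microbiota association.
Every randomized stage derives its seed from the master seed plus a stage
tag, so adding a stage never perturbs the draws of earlier stages.  All
stage outputs are TSV (plus a JSON run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, diversity, host, io as wio, screen, stats
from .errors import InsufficientDataError, UsageError, WildgutError
from .kinship import PedigreeGraph, relatedness_matrix
from .simulate import SimulationConfig, simulate_study

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline configuration (thresholds follow the study conventions:
    raw p < 0.05 within differential pools, BH q < 0.05 for pairwise
    PERMANOVA, consensus support >= 6 of 8 pools)."""

    seed: int
    out_dir: str
    # either simulate...
    simulate: bool = True
    sim_config: dict = field(default_factory=dict)
    # ...or load from paths
    otu_table: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    metadata: str | None = None
    pedigree: str | None = None

    reference: str = "wild"
    ranks: tuple[str, ...] = ("phylum", "genus")
    alpha: float = 0.05
    min_support: int = 6
    q_threshold: float = 0.05
    n_perm: int = 999
    beta_metric: str = "weighted_normalized"
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise UsageError("a master seed is required")
        for thr in (self.alpha, self.q_threshold):
            if not 0 < thr < 1:
                raise UsageError("thresholds must lie in (0, 1)")
        if self.min_support < 1:
            raise UsageError("min_support must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise UsageError(f"invalid config key(s): {sorted(unknown)}")
        for key in ("ranks", "exclude"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def stage_seed(master: int, tag: str) -> int:
    h = hashlib.sha256(f"{master}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[str]
    outputs: dict[str, str]
    counts: dict[str, int]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "stages": self.stages,
                    "outputs": self.outputs,
                    "counts": self.counts,
                },
                indent=1,
                default=str,
            ),
            encoding="utf-8",
        )


def run_pipeline(cfg: RunConfig) -> RunManifest:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    outputs: dict[str, str] = {}
    counts: dict[str, int] = {}

    def record(stage: str, name: str, path: Path) -> None:
        stages.append(stage)
        outputs[name] = str(path)

    def fail(stage: str, exc: Exception):
        raise WildgutError(f"stage {stage!r} failed: {exc}") from exc

    # -- inputs -----------------------------------------------------------
    try:
        if cfg.simulate:
            sim_cfg = SimulationConfig.from_dict(cfg.sim_config)
            study = simulate_study(sim_cfg, seed=stage_seed(cfg.seed, "simulate"),
                                   out_dir=out / "study")
            table, tax, tree, meta = study.table, study.taxonomy, study.tree, study.metadata
            ped = PedigreeGraph(study.pedigree)
        else:
            for key in ("otu_table", "taxonomy", "tree", "metadata", "pedigree"):
                if getattr(cfg, key) is None:
                    raise UsageError(f"missing input path: {key}")
            table, inline_tax = wio.read_otu_table(cfg.otu_table)
            tax = inline_tax or wio.read_taxonomy(cfg.taxonomy)
            tree = wio.read_tree(cfg.tree)
            meta = wio.read_metadata(cfg.metadata)
            ped = PedigreeGraph(wio.read_pedigree(cfg.pedigree))
        stages.append("inputs")
    except Exception as exc:  # noqa: BLE001 - stage-tagged reraise
        fail("inputs", exc)

    counts["samples_in"] = len(meta)
    counts["taxa_in"] = len(table.taxon_ids)

    # -- exclusion --------------------------------------------------------
    try:
        table, meta = host.exclude_samples(table, meta, list(cfg.exclude),
                                           reason="configured exclusion")
        stages.append("exclude")
    except Exception as exc:
        fail("exclude", exc)
    counts["samples_analysed"] = len(meta)

    # -- relatedness ------------------------------------------------------
    try:
        individuals = list(meta["individual_id"])
        rel = relatedness_matrix(ped, individuals, allow_missing=True)
        kp, mp = out / "kinship_K.tsv", out / "kinship_M.tsv"
        pd.DataFrame(rel.K, index=individuals, columns=individuals).to_csv(kp, sep="\t")
        pd.DataFrame(rel.M, index=individuals, columns=individuals).to_csv(mp, sep="\t")
        record("kinship", "kinship_K", kp)
        outputs["kinship_M"] = str(mp)
    except Exception as exc:
        fail("kinship", exc)
    counts["individuals"] = len(individuals)

    # -- alpha diversity --------------------------------------------------
    try:
        alpha = diversity.alpha_diversity(table, tree)
        p = out / "alpha_diversity.tsv"
        alpha.to_csv(p, sep="\t", index=False)
        record("alpha", "alpha_diversity", p)
    except Exception as exc:
        fail("alpha", exc)

    # -- beta diversity + ordination -------------------------------------
    try:
        dm = diversity.unifrac(table, tree, mode=cfg.beta_metric)
        p = out / "distance_matrix.tsv"
        wio.write_distance_matrix(dm, p)
        record("beta", "distance_matrix", p)
        ord_res = diversity.pcoa(dm, axes=min(3, len(dm.ids) - 1))
        coords = ord_res.coordinates.copy()
        coords.index.name = "sample_id"
        p2 = out / "pcoa.tsv"
        coords.to_csv(p2, sep="\t")
        outputs["pcoa"] = str(p2)
    except Exception as exc:
        fail("beta", exc)

    # -- population PERMANOVA --------------------------------------------
    try:
        pop = meta.set_index("sample_id").loc[list(dm.ids), "population"]
        res = stats.permanova(dm, {"population": pop}, n_perm=cfg.n_perm,
                              seed=stage_seed(cfg.seed, "permanova"))
        p = out / "permanova_population.tsv"
        res.table.to_csv(p, sep="\t")
        record("permanova", "permanova_population", p)
        pw = stats.pairwise_permanova(dm, pop, n_perm=cfg.n_perm,
                                      seed=stage_seed(cfg.seed, "pairwise_permanova"))
        pw["significant"] = pw["q_value"] < cfg.q_threshold
        p2 = out / "permanova_pairwise.tsv"
        pw.to_csv(p2, sep="\t", index=False)
        outputs["permanova_pairwise"] = str(p2)
    except Exception as exc:
        fail("permanova", exc)

    # -- consensus screen + F/B ratio + indicator taxa --------------------
    try:
        for rank in cfg.ranks:
            abund = diversity.aggregate_rank(table, tax, rank)
            pools = screen.build_pools(abund, meta, reference=cfg.reference,
                                       alpha=cfg.alpha)
            counts[f"pools_{rank}"] = len(pools)
            pool_rows = [
                dict(pool=p_.label, **row)
                for p_ in pools
                for row in p_.members.to_dict(orient="records")
            ]
            pp = out / f"pools_{rank}.tsv"
            pd.DataFrame(pool_rows, columns=["pool", "taxon", "direction", "p_value"]).to_csv(
                pp, sep="\t", index=False
            )
            record(f"screen_{rank}", f"pools_{rank}", pp)
            ip = out / f"intersections_{rank}.tsv"
            screen.intersect_pools(pools).to_csv(ip, sep="\t", index=False)
            outputs[f"intersections_{rank}"] = str(ip)
            cp = out / f"consensus_{rank}.tsv"
            cons = screen.consensus(pools, min_support=min(cfg.min_support, len(pools)))
            cons.to_csv(cp, sep="\t", index=False)
            outputs[f"consensus_{rank}"] = str(cp)
            if rank == "phylum":
                fb = diversity.fb_ratio(abund)
                fp = out / "fb_ratio.tsv"
                fb.to_csv(fp, sep="\t", index=False)
                outputs["fb_ratio"] = str(fp)
            iv = stats.indval(abund, meta.set_index("sample_id").loc[list(abund.columns), "population"],
                              n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, f"indval_{rank}"))
            vp = out / f"indval_{rank}.tsv"
            stats.indval_table(iv).to_csv(vp, sep="\t", index=False)
            outputs[f"indval_{rank}"] = str(vp)
    except Exception as exc:
        fail("screen", exc)

    # -- host associations ------------------------------------------------
    try:
        host_rows = []
        for trait in ("sex", "age"):
            for with_pop in (False, True):
                try:
                    res = host.trait_permanova(
                        dm, meta, trait, with_population=with_pop,
                        n_perm=cfg.n_perm,
                        seed=stage_seed(cfg.seed, f"trait_{trait}_{with_pop}"),
                    )
                except (UsageError, InsufficientDataError) as exc:
                    log.warning("trait %s (population=%s) skipped: %s", trait, with_pop, exc)
                    continue
                term = res.term(trait)
                host_rows.append(
                    {
                        "trait": trait,
                        "model": "two-factor" if with_pop else "one-factor",
                        "df": term["df"],
                        "pseudo_F": term["pseudo_F"],
                        "R2": term["R2"],
                        "p_value": term["p_value"],
                    }
                )
        p = out / "host_trait_permanova.tsv"
        pd.DataFrame(host_rows).to_csv(p, sep="\t", index=False)
        record("host_traits", "host_trait_permanova", p)

        genus_abund = diversity.aggregate_rank(table, tax, "genus")
        ages = host.age_screen(genus_abund, meta)
        p2 = out / "age_screen_genus.tsv"
        ages.to_csv(p2, sep="\t", index=False)
        outputs["age_screen_genus"] = str(p2)

        kin_rows = []
        for channel in ("genetic", "maternal"):
            try:
                res = host.kinship_association(dm, meta, rel, channel=channel)
                kin_rows.append(
                    {
                        "channel": channel,
                        "rho": res.statistic,
                        "p_value": res.p_value,
                        "n_pairs": res.n[0],
                    }
                )
            except InsufficientDataError as exc:
                log.warning("kinship association (%s) skipped: %s", channel, exc)
        p3 = out / "kinship_association.tsv"
        pd.DataFrame(kin_rows).to_csv(p3, sep="\t", index=False)
        outputs["kinship_association"] = str(p3)
        stages.append("host_association")
    except Exception as exc:
        fail("host_association", exc)
    counts["pairs_kinship"] = int(len(meta) * (len(meta) - 1) // 2)

    manifest = RunManifest(
        config=cfg.__dict__,
        version=__version__,
        stages=stages,
        outputs=outputs,
        counts=counts,
    )
    mp = out / "manifest.json"
    manifest.to_json(mp)
    missing = [k for k, v in outputs.items() if not Path(v).exists()]
    if missing:
        raise WildgutError(f"manifest lists missing outputs: {missing}")
    log.info("pipeline complete: %d stages, %d outputs", len(stages), len(outputs))
    return manifest
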