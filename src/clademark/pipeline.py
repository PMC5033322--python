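"""End-to-end orchestration of the circumscription pipeline.

Stages (each toggleable): directional ANI + correlation clustering;
reciprocal-best-hit core genome; core-gene supermatrix + NJ tree;
orthogroup function repertoires + dendrogram comparison (ecotype
candidates); Random-Forest marker ranking; single-marker PCA
classification with outclass detection.  Every artifact in the report
bundle is stamped with the seed and a hash of the effective
configuration; reruns under the same seed/config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ani as ani_mod
from . import coregenome, markerrank, mlsa, pcaclass, repertoire
from .seqmodel import StrainSet

log = logging.getLogger("clademark.pipeline")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    # stage toggles
    run_ani: bool = True
    run_core: bool = True
    run_mlsa: bool = True
    run_repertoire: bool = True
    run_rank: bool = True
    run_classify: bool = True
    # parameters
    seed: int = 12345
    fragment_length: int = 1020
    min_identity_pct: float = 30.0
    min_fragment_coverage: float = 0.70
    ani_linkage: str = "complete"
    n_clusters: int | None = None
    reference_strain: str | None = None
    core_e_cutoff: float = 1e-30
    core_scope: str = "all"
    distance_model: str = "k80"
    n_boot: int = 1000
    orthogroup_e_cutoff: float = 1e-5
    mcl_inflation: float = 1.5
    n_trees: int = 100_000
    mtry: int | None = None
    importance_aggregate: str = "mean"
    pca_level: float = 0.95
    marker_gene: str | None = None  # default: top-ranked gene

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with Path(path).open("rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ReportBundle:
    config_hash: str
    seed: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    extras: dict[str, object] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": self.config_hash, "seed": self.seed}
        (outdir / "run_stamp.json").write_text(json.dumps(stamp, indent=2) + "\n")
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", na_rep="NA")
        for name, nwk in self.trees.items():
            (outdir / f"{name}.nwk").write_text(nwk + "\n")
        if self.errors:
            (outdir / "errors.json").write_text(json.dumps(self.errors, indent=2) + "\n")


def run_pipeline(cfg: PipelineConfig, ss: StrainSet) -> ReportBundle:
    """Execute the enabled stages in dependency order; stage failures are
    recorded and dependents skipped, never silently ignored."""
    bundle = ReportBundle(config_hash=cfg.config_hash(), seed=cfg.seed)
    t0 = time.time()
    labels = {
        s.id: s.claimed_species
        for s in ss.strains
        if s.claimed_species != "unknown" and s.id not in ss.outgroups
    }

    if cfg.run_ani:
        try:
            log.info("stage ani: %d strains", len(ss.ids))
            params = ani_mod.AniParams(
                fragment_length=cfg.fragment_length,
                min_identity_pct=cfg.min_identity_pct,
                min_fragment_coverage=cfg.min_fragment_coverage,
            )
            am = ani_mod.ani_matrix(ss, params)
            k = cfg.n_clusters or len(set(labels.values())) or None
            cc = ani_mod.correlation_clusters(
                am, linkage=cfg.ani_linkage, k=k, pairwise_complete=True
            )
            bundle.tables["ani_matrix"] = am.values
            bundle.tables["ani_correlation"] = cc.corr
            bundle.tables["ani_clusters"] = pd.DataFrame(
                {"strain": list(cc.labels or {}), "cluster": list((cc.labels or {}).values())}
            ).set_index("strain")
            bundle.extras["ani"] = am
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed
            bundle.errors["ani"] = repr(exc)

    core = None
    if cfg.run_core:
        try:
            ref_id = cfg.reference_strain or ss.ids[0]
            log.info("stage core: reference %s", ref_id)
            core = coregenome.blast_core_genes(
                ss.genomes[ref_id], ss, e_cutoff=cfg.core_e_cutoff, core_scope=cfg.core_scope
            )
            bundle.tables["core_genes"] = pd.DataFrame(
                {"family": [f.id for f in core], "n_members": [len(f.members) for f in core]}
            ).set_index("family")
        except Exception as exc:  # noqa: BLE001
            bundle.errors["core"] = repr(exc)

    phylo = None
    alignments = None
    if cfg.run_mlsa:
        if core is None:
            bundle.errors.setdefault("mlsa", "skipped: core stage unavailable")
        else:
            try:
                log.info("stage mlsa: %d families", len(core))
                alignments = [mlsa.align_family(f) for f in core]
                sm = mlsa.concatenate_alignments(alignments)
                trimmed, _ = mlsa.trim_conserved_blocks(sm)
                use = trimmed if trimmed.n_columns >= 4 else sm
                phylo = mlsa.nj_tree_with_bootstrap(
                    use, model=cfg.distance_model, n_boot=cfg.n_boot, seed=cfg.seed
                )
                bundle.trees["phylogenomic"] = phylo.newick()
                bundle.extras["supermatrix_columns"] = use.n_columns
            except Exception as exc:  # noqa: BLE001
                bundle.errors["mlsa"] = repr(exc)

    func_dendro = None
    if cfg.run_repertoire:
        try:
            log.info("stage repertoire")
            proteomes = {sid: ss.genomes[sid].proteome() for sid in ss.ids}
            og = repertoire.assign_orthogroups(
                proteomes, e_cutoff=cfg.orthogroup_e_cutoff, inflation=cfg.mcl_inflation
            )
            fm, prov = repertoire.build_function_matrix(og, ss.ids)
            func_dendro = repertoire.cluster_repertoire(
                fm, n_boot=min(cfg.n_boot, 200), seed=cfg.seed
            )
            bundle.tables["function_matrix"] = fm
            counts = repertoire.function_set_counts(
                fm, {"group": ss.group_ids} if ss.group_ids else {"all": ss.ids}
            )
            bundle.tables["function_counts"] = pd.DataFrame(counts).T
            if phylo is not None:
                cmp_res = repertoire.compare_dendrograms(phylo, func_dendro)
                bundle.tables["dendrogram_comparison"] = pd.DataFrame(
                    {
                        "metric": ["cophenetic_correlation", "bakers_gamma", "entanglement"],
                        "value": [
                            cmp_res.cophenetic_correlation,
                            cmp_res.bakers_gamma,
                            cmp_res.entanglement,
                        ],
                    }
                ).set_index("metric")
                bundle.tables["discordant_strains"] = pd.DataFrame(
                    cmp_res.discordant, columns=["strain", "score"]
                ).set_index("strain")
        except Exception as exc:  # noqa: BLE001
            bundle.errors["repertoire"] = repr(exc)

    ranking = None
    ft = None
    if cfg.run_rank:
        if core is None:
            bundle.errors.setdefault("rank", "skipped: core stage unavailable")
        elif not labels:
            bundle.errors.setdefault("rank", "skipped: no species labels")
        else:
            try:
                log.info("stage rank: %d genes", len(core))
                fams = alignments if alignments is not None else core
                rows = [s for s in ss.ids if s in labels]
                ft = markerrank.build_feature_table(
                    fams, organisms=ss.ids, rows=rows, labels=labels,
                    model=cfg.distance_model,
                )
                train_rows = [
                    s.id for s in ss.strains if s.role == "train" and s.id in labels
                ] or rows
                test_rows = [
                    s.id for s in ss.strains if s.role == "test" and s.id in labels
                ]
                forest = markerrank.train_species_forest(
                    ft, train_rows, n_trees=cfg.n_trees, seed=cfg.seed,
                    mtry=cfg.mtry, aggregate=cfg.importance_aggregate,
                )
                stats = markerrank.gene_distance_stats(fams, model=cfg.distance_model)
                err = None
                if test_rows:
                    conf, rate = markerrank.evaluate_forest(forest, ft, test_rows)
                    bundle.tables["confusion"] = conf
                    bundle.extras["misclassification_rate"] = rate
                    err = markerrank.per_gene_error_rates(
                        ft, train_rows, test_rows, n_trees=cfg.n_trees, seed=cfg.seed
                    )
                ranking = markerrank.rank_genes(stats, forest.gene_importance, err)
                bundle.tables["gene_ranking"] = ranking
            except Exception as exc:  # noqa: BLE001
                bundle.errors["rank"] = repr(exc)

    if cfg.run_classify:
        if core is None:
            bundle.errors.setdefault("classify", "skipped: core stage unavailable")
        else:
            try:
                marker = cfg.marker_gene or (
                    ranking.index[0] if ranking is not None else core[0].id
                )
                log.info("stage classify: marker %s", marker)
                fams = alignments if alignments is not None else core
                fam = next(
                    f
                    for f in fams
                    if (f.family_id if isinstance(f, mlsa.Alignment) else f.id) == marker
                )
                refs = [s for s in ss.ids if s in labels]
                model = pcaclass.fit_marker_pca(
                    fam, organisms=ss.ids, strains=ss.ids, model=cfg.distance_model
                )
                ellipses, skipped = pcaclass.class_ellipses(
                    model, labels, level=cfg.pca_level
                )
                calls = pcaclass.classify_strains(model, ellipses, ss.ids)
                bundle.tables["species_calls"] = pd.DataFrame(
                    [
                        {
                            "strain": c.strain_id,
                            "call": c.call,
                            "ambiguous": c.ambiguous,
                            **{f"md2_{k}": v for k, v in sorted(c.mahalanobis.items())},
                        }
                        for c in calls
                    ]
                ).set_index("strain")
                bundle.extras["marker"] = marker
                bundle.extras["pca_explained"] = list(
                    model.explained_variance_ratio[:2]
                )
                bundle.extras["ellipse_skipped_classes"] = skipped
            except Exception as exc:  # noqa: BLE001
                bundle.errors["classify"] = repr(exc)

    log.info("pipeline done in %.1fs (errors: %s)", time.time() - t0, list(bundle.errors))
    return bundle
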