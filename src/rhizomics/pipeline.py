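"""End-to-end orchestration from a single YAML config.

Stages run in dependency order (diversity -> assembly / network /
sourcetrack / ml); every stage writes plain TSV (plus newick and GraphML)
into the output directory and the run finishes with a JSON manifest holding
versions, derived seeds, parameters and input/output checksums.  One master
seed derives all stage seeds through a fixed offset table, so toggling a
stage never changes another stage's stream.  Wall-clock timings go to the
run log, not the manifest, keeping manifests byte-stable across re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .containers import CdTable, CommunityMatrix, validate_metadata
from .errors import EmptyNetworkError, RhizomicsError, SchemaError
from . import assembly as asm
from . import biomarkers as bm
from . import diversity as dv
from . import network as net
from . import sourcetracking as st
from . import synthetic as syn

log = logging.getLogger("rhizomics.pipeline")

STAGE_OFFSETS = {
    "synth": 1,
    "diversity": 2,
    "assembly": 3,
    "network": 4,
    "sourcetrack": 5,
    "ml": 6,
}

ALL_STAGES = ("diversity", "assembly", "network", "sourcetrack", "ml")


def stage_seed(master_seed: int, stage: str) -> int:
    return (master_seed * 1009 + STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    inputs: dict = field(default_factory=dict)   # table/tree/metadata/cd paths
    synth: dict | None = None                    # design/truth overrides
    params: dict = field(default_factory=dict)   # per-stage parameter blocks

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            inputs=raw.get("inputs", {}) or {},
            synth=raw.get("synth"),
            params=raw.get("params", {}) or {},
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_tree(path):
    from skbio import TreeNode

    return TreeNode.read(path)


def _build_design(synth_cfg: dict | None, seed: int) -> tuple[syn.StudyDesign, syn.PlantedTruth]:
    cfg = dict(synth_cfg or {})
    design_kwargs = dict(cfg.get("design", {}))
    design_kwargs.setdefault("seed", seed)
    if "niches" in design_kwargs:
        design_kwargs["niches"] = tuple(design_kwargs["niches"])
    design = syn.StudyDesign(**design_kwargs)
    truth_kwargs = cfg.get("truth", {})
    if truth_kwargs:
        truth = syn.default_truth(design, **truth_kwargs)
    else:
        truth = syn.default_truth(design)
    return design, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    manifest: dict = {
        "rhizomics_version": __version__,
        "master_seed": config.seed,
        "stages": list(config.stages),
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGE_OFFSETS},
        "parameters": config.params,
        "inputs": {},
        "outputs": {},
    }

    try:
        # ------------------------------------------------------------------ inputs
        if config.inputs:
            matrix = CommunityMatrix.from_tsv(config.inputs["table"])
            metadata = pd.read_csv(config.inputs["metadata"], sep="\t")
            validate_metadata(metadata, matrix)
            tree = _load_tree(config.inputs["tree"]) if "tree" in config.inputs else None
            cd = CdTable.from_tsv(config.inputs["cd"]) if "cd" in config.inputs else None
            for key, path in config.inputs.items():
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
        else:
            t0 = time.monotonic()
            design, truth = _build_design(config.synth, stage_seed(config.seed, "synth"))
            paths = syn.write_fixtures(config.outdir, design, truth)
            matrix = CommunityMatrix.from_tsv(paths["table"])
            metadata = pd.read_csv(paths["metadata"], sep="\t")
            tree = _load_tree(paths["tree"])
            cd = CdTable.from_tsv(paths["cd"])
            for key, path in paths.items():
                manifest["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}
            log.info("synth stage done in %.1fs", time.monotonic() - t0)

        if tree is not None:
            tips = {t.name for t in tree.tips()}
            extra = set(matrix.taxon_ids) - tips
            if extra:
                raise SchemaError(f"table taxa missing from tree: {sorted(extra)[:5]}")

        niche_order = [n for n in syn.NICHE_ORDER if n in set(metadata["niche"])] or sorted(
            set(metadata["niche"])
        )

        def out(name: str) -> str:
            return os.path.join(config.outdir, name)

        def register(name: str) -> None:
            manifest["outputs"][name] = _sha256(out(name))

        rarefied = None

        # ------------------------------------------------------------------ diversity
        if "diversity" in config.stages:
            t0 = time.monotonic()
            p = config.params.get("diversity", {})
            seed = stage_seed(config.seed, "diversity")
            rarefied = dv.rarefy(matrix, depth=p.get("depth", "min"), seed=seed)
            alpha = dv.alpha_diversity(rarefied)
            alpha = alpha.merge(metadata, on="sample_id")
            alpha.to_csv(out("alpha_diversity.tsv"), sep="\t", index=False)
            register("alpha_diversity.tsv")

            bc = dv.bray_curtis(rarefied)
            bc.to_csv(out("bray_curtis.tsv"), sep="\t", index_label="sample_id")
            register("bray_curtis.tsv")

            ord_res = dv.nmds(bc, k=2, seed=seed)
            ord_res.coordinates.assign(stress=ord_res.stress).to_csv(
                out("nmds.tsv"), sep="\t", index_label="sample_id"
            )
            register("nmds.tsv")

            meta_idx = metadata.set_index("sample_id").loc[bc.index]
            perm_rows = []
            for factor in ("niche", "cultivar"):
                res = dv.permanova(
                    bc, meta_idx[factor].to_numpy(),
                    n_permutations=p.get("n_permutations", 999), seed=seed, factor=factor,
                )
                perm_rows.append(asdict(res))
            pd.DataFrame(perm_rows).to_csv(out("permanova.tsv"), sep="\t", index=False)
            register("permanova.tsv")

            gd = dv.group_dissimilarity(bc, meta_idx["niche"].astype(str) + "|" + meta_idx["cultivar"].astype(str))
            gd.rename_axis("group").reset_index().to_csv(out("group_dissimilarity.tsv"), sep="\t", index=False)
            register("group_dissimilarity.tsv")
            log.info("diversity stage done in %.1fs", time.monotonic() - t0)

        # ------------------------------------------------------------------ assembly
        if "assembly" in config.stages:
            if tree is None:
                log.warning("assembly stage skipped: no phylogeny provided")
            else:
                t0 = time.monotonic()
                p = config.params.get("assembly", {})
                part = asm.assembly_by_group(
                    rarefied if rarefied is not None else matrix,
                    metadata, tree,
                    n_null=p.get("n_null", 999),
                    seed=stage_seed(config.seed, "assembly"),
                    orientation=p.get("orientation", "as_printed"),
                )
                part.per_pair.to_csv(out("assembly_pairs.tsv"), sep="\t", index=False)
                register("assembly_pairs.tsv")
                part.fractions.to_csv(out("assembly_fractions.tsv"), sep="\t", index_label="group")
                register("assembly_fractions.tsv")
                log.info("assembly stage done in %.1fs", time.monotonic() - t0)

        # ------------------------------------------------------------------ network
        if "network" in config.stages:
            t0 = time.monotonic()
            p = config.params.get("network", {})
            subsets = net.split_by_group(matrix, metadata)
            topo_rows, role_frames, curve_frames = [], [], []
            for gname, sub in sorted(subsets.items()):
                try:
                    filt = net.filter_taxa(
                        sub,
                        prevalence_min=p.get("prevalence_min", 0.75),
                        rel_abund_min=p.get("rel_abund_min", 0.0001),
                    )
                    cn = net.build_network(filt, rho_min=p.get("rho_min", 0.7), alpha=p.get("alpha", 0.05))
                except (EmptyNetworkError, RhizomicsError) as exc:
                    log.warning("network for %s skipped: %s", gname, exc)
                    continue
                cn.edges.assign(group=gname).to_csv(
                    out(f"network_edges_{gname}.tsv"), sep="\t", index=False
                )
                register(f"network_edges_{gname}.tsv")
                net.write_graphml(cn, out(f"network_{gname}.graphml"))
                register(f"network_{gname}.graphml")
                summary = net.topology(cn).as_dict()
                summary["group"] = gname
                summary["natural_connectivity"] = net.natural_connectivity(cn)
                topo_rows.append(summary)
                if cn.n_nodes >= 5:
                    curve = net.robustness_curve(cn).as_frame().assign(group=gname)
                    curve_frames.append(curve)
                roles = net.zi_pi(cn).assign(group=gname)
                role_frames.append(roles)
            if topo_rows:
                pd.DataFrame(topo_rows).to_csv(out("network_topology.tsv"), sep="\t", index=False)
                register("network_topology.tsv")
            if curve_frames:
                pd.concat(curve_frames).to_csv(out("network_robustness.tsv"), sep="\t", index=False)
                register("network_robustness.tsv")
            if role_frames:
                pd.concat(role_frames).to_csv(out("network_roles.tsv"), sep="\t", index=False)
                register("network_roles.tsv")
            log.info("network stage done in %.1fs", time.monotonic() - t0)

        # ------------------------------------------------------------------ sourcetrack
        if "sourcetrack" in config.stages:
            t0 = time.monotonic()
            p = config.params.get("sourcetrack", {})
            chain = st.niche_chain_sources(
                matrix, metadata, niche_order,
                seed=stage_seed(config.seed, "sourcetrack"),
                n_burnin=p.get("n_burnin", 100),
                n_draws=p.get("n_draws", 100),
                n_restarts=p.get("n_restarts", 10),
                alpha1=p.get("alpha1", 0.001),
                alpha2=p.get("alpha2", 0.001),
                beta=p.get("beta", 0.01),
            )
            chain.to_csv(out("source_proportions.tsv"), sep="\t", index=False)
            register("source_proportions.tsv")
            log.info("sourcetrack stage done in %.1fs", time.monotonic() - t0)

        # ------------------------------------------------------------------ ml
        if "ml" in config.stages:
            t0 = time.monotonic()
            p = config.params.get("ml", {})
            seed = stage_seed(config.seed, "ml")
            niches = p.get("niches", niche_order)
            models = bm.default_models(seed, n_trees=p.get("n_trees", 500))
            eval_rows, curve_rows, marker_rows, cd_rows = [], [], [], []
            for niche in niches:
                report, evals = bm.run_biomarker_workflow(
                    matrix, metadata, niche, cd=cd, seed=seed,
                    k_folds=p.get("k_folds", 5),
                    k_grid=p.get("k_grid"), models=models, n_trees=p.get("n_trees", 500),
                )
                for e in evals:
                    eval_rows.append({"niche": niche, "model": e.model, "average_error": e.average_error})
                curve_rows.append(report.curve.assign(niche=niche))
                te = report.test_evaluation
                marker_rows.append(
                    {
                        "niche": niche,
                        "best_model": report.best_model,
                        "selected_k": report.selected_k,
                        "biomarkers": ",".join(report.biomarkers),
                        "test_overall_accuracy": te.overall_accuracy,
                    }
                )
                if report.cd_correlations is not None:
                    cd_rows.append(report.cd_correlations.assign(niche=niche))
            pd.DataFrame(eval_rows).to_csv(out("ml_model_comparison.tsv"), sep="\t", index=False)
            register("ml_model_comparison.tsv")
            pd.concat(curve_rows).to_csv(out("ml_error_curves.tsv"), sep="\t", index=False)
            register("ml_error_curves.tsv")
            pd.DataFrame(marker_rows).to_csv(out("ml_biomarkers.tsv"), sep="\t", index=False)
            register("ml_biomarkers.tsv")
            if cd_rows:
                pd.concat(cd_rows).to_csv(out("ml_cd_correlations.tsv"), sep="\t", index=False)
                register("ml_cd_correlations.tsv")
            if cd is not None:
                baf = bm.bioaccumulation_factor(cd)
                cd.table.assign(bioaccumulation_factor=baf).to_csv(
                    out("bioaccumulation.tsv"), sep="\t", index=False
                )
                register("bioaccumulation.tsv")
            log.info("ml stage done in %.1fs", time.monotonic() - t0)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
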