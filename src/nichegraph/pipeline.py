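"""Pipeline orchestration: run every analysis stage on one dataset.

Stages run in dependency order on the synthetic study conditions (the
generator is the data source; external datasets can be analyzed through
the per-module library functions or the CLI verbs). Every run writes a
provenance manifest recording the package version, the seed, every
threshold, and a SHA-256 digest of each output file; with a fixed seed two
runs produce byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import colocalization as coloc
from . import communication as comm
from . import composition as compo
from . import deconvolution as deconv
from . import drivers as drv
from . import io as ngio
from . import niche_enrichment as enr
from . import preprocess as pp
from . import synthetic as syn

log = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate", "preprocess", "deconvolve", "coloc",
    "enrich", "comm", "drivers", "compose",
)

_DEPENDS = {
    "preprocess": ("simulate",),
    "deconvolve": ("simulate",),
    "coloc": ("deconvolve",),
    "enrich": ("deconvolve",),
    "comm": ("enrich",),
    "drivers": ("simulate",),
    "compose": ("simulate",),
}


@dataclass
class PipelineConfig:
    """Every tunable threshold, at its published default."""

    seed: int = 0
    stages: tuple = ALL_STAGES
    n_spots_per_sample: int = 400
    n_samples_per_condition: int = 1
    cells_per_sample: int = 600
    tau: float = 0.01
    cols_alpha_neighborhood: float = 0.05
    cols_alpha_graph: float = 0.01
    enrichment_alpha_heatmap: float = 0.05
    enrichment_alpha_constraint: float = 0.01
    de_p: float = 0.05
    de_min_expressed: float = 0.10
    tf_expr_alpha: float = 0.025
    tf_expr_min_logfc: float = 0.5
    tf_act_alpha: float = 0.025
    tf_act_min_diff: float = 0.5
    myof_act_alpha: float = 0.01
    ligand_top_k: int = 10
    ligand_min_recurrence: int = 2
    receptor_min_fraction: float = 0.05
    auc_atlas: float = 0.65
    auc_bulk: float = 0.6
    composition_fdr: float = 0.20
    composition_pseudocount: float = 0.1
    reference_cell_type: str = "Arterial"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages; outputs land under `outdir`, each stage in
    its own subdirectory. Returns the manifest (also written to
    manifest.json). A stage failure aborts with the stage name; outputs of
    completed stages are left in place."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in ALL_STAGES if s in set(config.stages)]
    for s in stages:
        missing = [d for d in _DEPENDS.get(s, ()) if d not in stages]
        if missing:
            raise StageError(f"stage {s!r} requires disabled stage(s) {missing}")

    gen_cfg = syn.default_config(
        seed=config.seed,
        n_spots_per_sample=config.n_spots_per_sample,
        n_samples_per_condition=config.n_samples_per_condition,
        cells_per_sample=config.cells_per_sample,
    )
    state: dict = {}
    manifest: dict = {
        "package": "nichegraph",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "stages"
        },
        "stages": {},
    }

    for stage in stages:
        sdir = outdir / stage
        sdir.mkdir(exist_ok=True)
        log.info("stage %s", stage)
        try:
            _STAGE_FNS[stage](config, gen_cfg, state, sdir)
        except Exception as e:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {stage!r} failed: {e}") from e
        files = sorted(p for p in sdir.rglob("*") if p.is_file())
        manifest["stages"][stage] = {
            str(p.relative_to(outdir)): _sha256(p) for p in files
        }

    ngio.write_json(outdir / "manifest.json", manifest)
    return manifest


# ---------------------------------------------------------------------------
# stage bodies

def _stage_simulate(config, gen_cfg, state, sdir):
    atlas, spots, truth = syn.generate_dataset(gen_cfg)
    state.update(atlas=atlas, spots=spots, truth=truth)
    ngio.write_mtx_triplet(sdir / "spots", spots.X, list(spots.obs_names),
                           list(spots.var_names))
    ngio.write_positions(sdir / "spots" / "tissue_positions.csv", spots.obs)
    ngio.write_mtx_triplet(sdir / "atlas", atlas.X, list(atlas.obs_names),
                           list(atlas.var_names))
    ngio.write_tsv(sdir / "atlas" / "cell_metadata.tsv", atlas.obs)
    (sdir / "ground_truth.json").write_text(truth.to_json() + "\n")


def _stage_preprocess(config, gen_cfg, state, sdir):
    spots = state["spots"]
    _, keep, report = pp.qc_filter(spots.X, list(spots.var_names),
                                   pp.QCThresholds(), mode="spot")
    report.index = spots.obs_names
    ngio.write_tsv(sdir / "spot_qc_report.tsv", report)
    state["spots_qc"] = spots[keep].copy()
    norm, kept = pp.normalize_logtp10k(state["spots_qc"].X)
    state["spots_norm"] = pd.DataFrame(
        norm, index=np.asarray(state["spots_qc"].obs_names)[kept],
        columns=list(spots.var_names),
    )
    atlas = state["atlas"]
    anorm, akept = pp.normalize_logtp10k(atlas.X)
    state["atlas_norm"] = pd.DataFrame(
        anorm, index=np.asarray(atlas.obs_names)[akept],
        columns=list(atlas.var_names),
    )
    fractions = {
        s: pp.assign_library_fraction(
            atlas.obs.loc[atlas.obs["sample"] == s, "cell_type"].value_counts(),
            gen_cfg.compartments,
        )
        for s in sorted(atlas.obs["sample"].unique())
    }
    ngio.write_json(sdir / "library_fractions.json", fractions)


def _stage_deconvolve(config, gen_cfg, state, sdir):
    atlas, spots, truth = state["atlas"], state.get("spots_qc", state["spots"]), state["truth"]
    profiles = deconv.build_reference_profiles(atlas, seed=config.seed)
    wm = deconv.decompose(spots, profiles, tau=config.tau,
                          cells_per_spot=truth.cells_per_spot)
    state["weights"] = wm
    deconv.write_weights_tsv(wm, sdir / "weights.tsv")
    calib = deconv.calibrate_threshold(wm)
    ngio.write_tsv(sdir / "calibration.tsv", calib, index=False)
    ngio.write_json(sdir / "calibration_best_tau.json",
                    {"best_tau": calib.attrs["best_tau"]})


def _stage_coloc(config, gen_cfg, state, sdir):
    wm, spots = state["weights"], state.get("spots_qc", state["spots"])
    masked = wm.masked()
    nets = {}
    for cond in gen_cfg.conditions:
        sub = (spots.obs["condition"] == cond).to_numpy()
        cols, p = coloc.compute_cols(masked, condition_mask=sub)
        p_adj = coloc.adjust_bh_pairs(p)
        net = coloc.build_network(cols, p_adj, mode="graph")
        net = coloc.partition_greedy(net)
        nets[cond] = net
        edges = pd.DataFrame(
            [
                {"type_a": a, "type_b": b, "cols": cols.loc[a, b],
                 "p": p.loc[a, b], "p_adj": p_adj.loc[a, b]}
                for a, b in coloc.edge_set(net)
            ]
        )
        ngio.write_tsv(sdir / f"edges_{cond}.tsv", edges, index=False)
        ngio.write_tsv(
            sdir / f"partition_{cond}.tsv",
            pd.DataFrame(
                {"cell_type": sorted(net.partition),
                 "community": [net.partition[t] for t in sorted(net.partition)],
                 "node_modularity": [net.node_modularity.get(t, 0.0)
                                     for t in sorted(net.partition)]}
            ),
            index=False,
        )
        ngio.write_graphml(sdir / f"network_{cond}.graphml", net.graph)
    state["cols_networks"] = nets
    stat, pval = coloc.compare_modularity(nets[gen_cfg.conditions[0]],
                                          nets[gen_cfg.conditions[1]])
    ngio.write_json(
        sdir / "modularity_comparison.json",
        {
            "Q": {c: nets[c].Q for c in nets},
            "wilcoxon_statistic": stat,
            "wilcoxon_p": pval,
        },
    )


def _stage_enrich(config, gen_cfg, state, sdir):
    wm, spots = state["weights"], state.get("spots_qc", state["spots"])
    categories = spots.obs["niche"]
    res = enr.enrich(wm.masked(), categories, mode="constraint")
    ngio.write_tsv(sdir / "enrichment_constraint.tsv", res, index=False)
    cmap = enr.constrain_communities(res)
    state["community_types"] = cmap
    ngio.write_json(sdir / "community_types.json", cmap)
    heat = enr.enrich(wm.masked(), categories, mode="heatmap")
    ngio.write_tsv(sdir / "enrichment_heatmap.tsv", heat, index=False)


def _stage_comm(config, gen_cfg, state, sdir):
    atlas = state["atlas"]
    lr_db = comm.LRDatabase.bundled()
    anorm = state.get("atlas_norm")
    for cond in gen_cfg.conditions:
        mask = (atlas.obs["condition"] == cond).to_numpy()
        sub = atlas[mask]
        vals = (anorm.loc[np.asarray(sub.obs_names)]
                if anorm is not None else pd.DataFrame(
                    sub.X.toarray(), index=sub.obs_names, columns=sub.var_names))
        relevant = comm.de_gate(vals.to_numpy(), sub.obs["cell_type"],
                                list(vals.columns))
        for mode in ("constrained", "unconstrained"):
            net = comm.constrain_and_build(
                relevant, lr_db,
                community_types=state.get("community_types"), mode=mode,
            )
            net = comm.centrality(net)
            edges = pd.DataFrame(
                [{"sender": u, "receiver": v, "n_interactions": d["weight"]}
                 for u, v, d in net.graph.edges(data=True)]
            )
            ngio.write_tsv(sdir / f"signaling_{cond}_{mode}.tsv", edges, index=False)
            ngio.write_tsv(
                sdir / f"centrality_{cond}_{mode}.tsv",
                pd.DataFrame(sorted(net.centrality.items()),
                             columns=["cell_type", "centrality"]),
                index=False,
            )
            ngio.write_graphml(sdir / f"signaling_{cond}_{mode}.graphml", net.graph)


def _stage_drivers(config, gen_cfg, state, sdir):
    atlas, truth = state["atlas"], state["truth"]
    anorm = state.get("atlas_norm")
    if anorm is None:
        norm, kept = pp.normalize_logtp10k(atlas.X)
        anorm = pd.DataFrame(norm, index=np.asarray(atlas.obs_names)[kept],
                             columns=list(atlas.var_names))
    obs = atlas.obs.loc[anorm.index]
    target = (obs["cell_type"] == "AberrantTrAT").to_numpy()
    background = obs["cell_type"].isin(["AT1", "AT2", "trAT"]).to_numpy()
    filler = [g for g in anorm.columns if g.startswith("G")][:7]
    tf_universe = list(truth.driver_tfs) + filler

    expr = drv.enrich_tf_expression(anorm, target, background, tf_universe,
                                    alpha=config.tf_expr_alpha,
                                    min_logfc=config.tf_expr_min_logfc)
    regulons = {r.tf: dict.fromkeys(r.targets, 1.0) for r in gen_cfg.planted_regulons}
    activity = drv.regulon_activity(anorm, regulons)
    act = drv.enrich_tf_activity(activity, target, background,
                                 alpha=config.tf_act_alpha,
                                 min_diff=config.tf_act_min_diff)
    union = drv.union_tfs(expr, act)
    pot = syn.make_potential_matrix(gen_cfg)
    ranked = drv.rank_ligands(list(union["tf"]), pot, k=config.ligand_top_k,
                              min_recurrence=config.ligand_min_recurrence)
    rmap = syn.receptor_map(gen_cfg)
    final = drv.filter_receptors(ranked, [atlas],
                                 [(atlas.obs["cell_type"] == "AberrantTrAT").to_numpy()],
                                 rmap, threshold=config.receptor_min_fraction)
    csgs = drv.auc_markers(anorm, obs["cell_type"], threshold=config.auc_atlas)
    ngio.write_tsv(sdir / "tf_expression.tsv", expr, index=False)
    ngio.write_tsv(sdir / "tf_activity.tsv", act, index=False)
    ngio.write_tsv(sdir / "tf_union.tsv", union, index=False)
    ngio.write_tsv(sdir / "ligands_ranked.tsv", ranked, index=False)
    ngio.write_tsv(sdir / "ligands_final.tsv", final, index=False)
    ngio.write_json(sdir / "csgs.json", csgs)
    state["driver_ligands"] = sorted(final.loc[~final["manual"], "ligand"])


def _stage_compose(config, gen_cfg, state, sdir):
    # per-sample counts from the same composition machinery as the atlas,
    # at a sample size where a per-condition test is defined
    cc = dataclasses.replace(
        gen_cfg, n_samples_per_condition=max(10, gen_cfg.n_samples_per_condition)
    )
    counts, cov = syn.simulate_composition_counts(cc)
    table = compo.CompositionTable(
        counts=counts, condition=cov["condition"],
        pseudocount=config.composition_pseudocount,
        reference=config.reference_cell_type,
        baseline_condition=gen_cfg.conditions[0],
    )
    res = compo.test_abundance(table, fdr=config.composition_fdr)
    ngio.write_tsv(sdir / "abundance_tests.tsv", res, index=False)
    ngio.write_tsv(sdir / "effect_summary.tsv", compo.effect_summary(res), index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "deconvolve": _stage_deconvolve,
    "coloc": _stage_coloc,
    "enrich": _stage_enrich,
    "comm": _stage_comm,
    "drivers": _stage_drivers,
    "compose": _stage_compose,
}
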