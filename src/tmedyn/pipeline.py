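"""End-to-end driver: simulate -> QC/normalize -> type -> archetypes ->
fitness -> dynamics -> imaging validation -> cross-species composition.

Every stage writes its outputs under the run directory and records a
sha256 digest in the run manifest, so each stage's output is traceable
to its inputs.  Stage seeds are derived independently from the run seed
(one sub-stream per stage), so changing e.g. only the imaging seed
leaves the scRNA-seq stages bit-identical.  A failure halts the run
with the completed-stage checkpoint on disk; rerunning with
``resume=True`` skips stages whose outputs already exist.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .archetypes import distance_to_archetype, t_ratio_test
from .containers import CountMatrix, LTQMatrix
from .crossspecies import log_center_by_species, species_weights, weighted_pca
from .dynamics import classify_temporal_pattern, prevalence_over_time
from .fitness import archetype_fitness_test, fitness_scores
from .hierarchy import run_pca, recursive_typing
from .hifi import annotate_hifi, cluster_hifi, compare_compositions, scale_markers
from .qc import estimate_ltq, qc_filter, snr_genes
from .synthetic import (
    default_hifi_panel,
    default_mode_locations,
    simulate_counts,
    simulate_hifi_intensities,
    simulate_normz,
    tumor_timecourse_config,
)

STAGES = ["simulate", "qc", "normalize", "typing", "archetypes",
          "fitness", "dynamics", "hifi", "crossspecies"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(seed: int, stage: str, overrides: dict | None = None) -> int:
    """Stage seeds derive independently from the run seed; a per-stage
    override in config {"seeds": {stage: int}} replaces the derived one
    without touching any other stage's stream."""
    if overrides and stage in overrides:
        return int(overrides[stage])
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def run_pipeline(config: dict | None = None, outdir: str | Path = "pipeline_out",
                 seed: int = 0, resume: bool = False) -> dict:
    """Run the full synthetic-data pipeline; returns the manifest dict
    (also written to ``outdir/manifest.json``)."""
    cfg = dict(config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed_overrides = cfg.get("seeds", {})
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_hash": hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "stages": {},
    }

    def record(stage, outputs, extra=None):
        manifest["stages"][stage] = {
            "seed": _stage_seed(seed, stage, seed_overrides),
            "outputs": {str(p.name): _digest(p) for p in outputs},
            **(extra or {}),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    def outputs_exist(*names):
        return resume and all((outdir / n).exists() for n in names)

    # ---------------------------------------------------------- simulate
    stage = "simulate"
    try:
        sim_cfg = tumor_timecourse_config(seed=_stage_seed(seed, stage, seed_overrides),
                                          **cfg.get("simulate", {}))
        counts_dir = outdir / "counts"
        if outputs_exist("counts/matrix.mtx", "truth.csv"):
            counts = CountMatrix.read_mtx(counts_dir)
            truth = pd.read_csv(outdir / "truth.csv", index_col=0)
        else:
            counts, gt = simulate_counts(sim_cfg)
            counts.write_mtx(counts_dir)
            truth = gt.cells
            truth.to_csv(outdir / "truth.csv")
            if gt.archetype_weights is not None:
                gt.archetype_weights.to_csv(outdir / "true_archetype_weights.csv")
        markers = sim_cfg.marker_table()
        markers.to_csv(outdir / "markers.csv", index=False)
        record(stage, [counts_dir / "matrix.mtx", outdir / "truth.csv", outdir / "markers.csv"],
               {"n_genes": counts.n_genes, "n_cells": counts.n_cells})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---------------------------------------------------------------- qc
    stage = "qc"
    try:
        qc_cfg = cfg.get("qc", {})
        filtered, qc_report = qc_filter(counts, return_report=True, **qc_cfg)
        with open(outdir / "qc_report.json", "w") as fh:
            json.dump(qc_report, fh, indent=2)
        record(stage, [outdir / "qc_report.json"], {"filter_removals": qc_report})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --------------------------------------------------------- normalize
    stage = "normalize"
    try:
        ltq = estimate_ltq(filtered)
        ltq.write_csv(outdir / "ltq.csv.gz", outdir / "gene_error.csv")
        record(stage, [outdir / "ltq.csv.gz", outdir / "gene_error.csv"])
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ------------------------------------------------------------ typing
    stage = "typing"
    try:
        tree = recursive_typing(
            ltq, markers, cell_totals=filtered.cell_totals(),
            seed=_stage_seed(seed, stage, seed_overrides), **cfg.get("typing", {}),
        )
        labels = tree.final_labels(ltq.n_cells)
        lab_df = pd.DataFrame({"cell_id": ltq.cell_ids, "cell_type": labels}).set_index("cell_id")
        lab_df.to_csv(outdir / "cell_types.csv")
        tree.to_json(outdir / "typing_tree.json")
        truth_aligned = truth.loc[ltq.cell_ids, "true_type"].to_numpy()
        typed = labels != "excluded"
        ari = float(adjusted_rand_score(truth_aligned[typed], labels[typed]))
        record(stage, [outdir / "cell_types.csv", outdir / "typing_tree.json"],
               {"ari_vs_truth": ari, "n_leaves": sum(1 for _ in tree.leaves()),
                "leaf_types": sorted(set(labels[typed]))})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -------------------------------------------------------- archetypes
    stage = "archetypes"
    try:
        arch_cfg = {"n_shuffles": 200, **cfg.get("archetypes", {})}
        target_type = arch_cfg.pop("cell_type", sim_cfg.simplex_spec.cell_type)
        mask = labels == target_type
        sub = ltq.subset(cell_mask=mask)
        genes = snr_genes(sub)
        pca = run_pca(sub.ltq[genes, :], n_pcs_max=3)
        scores3 = pca.scores[:, :3]
        fit = t_ratio_test(scores3, n_archetypes=4, seed=_stage_seed(seed, stage, seed_overrides), **arch_cfg)
        with open(outdir / "simplex.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        pd.DataFrame(fit.weights, index=sub.cell_ids,
                     columns=[f"archetype{i+1}" for i in range(4)]).to_csv(outdir / "archetype_weights.csv")
        record(stage, [outdir / "simplex.json", outdir / "archetype_weights.csv"],
               {"t_ratio": fit.t_ratio, "p_value": fit.p_value, "n_cells": int(mask.sum())})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ----------------------------------------------------------- fitness
    stage = "fitness"
    try:
        fit_cfg = cfg.get("fitness", {"effect": 2.0})
        # signature: genes boosted toward the first archetype in the simulation
        sig_genes = np.where(sim_cfg.simplex_spec.archetype_logrates[0]
                             > sim_cfg.simplex_spec.archetype_logrates[1:].max(axis=0) + 1.0)[0]
        gene_pos = pd.Index(sim_cfg.gene_ids).get_indexer(ltq.gene_ids)
        normz = simulate_normz(
            sim_cfg.n_genes, sig_genes, effect=fit_cfg.get("effect", 2.0),
            seed=_stage_seed(seed, stage, seed_overrides), gene_ids=sim_cfg.gene_ids,
        ).set_index("gene")["normz"]
        scores = fitness_scores(sub, normz)
        dist = distance_to_archetype(scores3, fit.archetypes)
        # the archetype whose closest cells are enriched in the signature
        sig_in_sub = pd.Index(sub.gene_ids).get_indexer(sim_cfg.gene_ids[sig_genes])
        sig_in_sub = sig_in_sub[sig_in_sub >= 0]
        mean_sig = sub.ltq[sig_in_sub, :].mean(axis=0)
        target = int(np.argmax([np.corrcoef(-dist[:, a], mean_sig)[0, 1] for a in range(4)]))
        test = archetype_fitness_test(scores.to_numpy(), dist[:, target],
                                      frac=fit_cfg.get("frac", 0.05))
        scores.to_frame().to_csv(outdir / "fitness_scores.csv")
        record(stage, [outdir / "fitness_scores.csv"],
               {"target_archetype": target, **test})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ---------------------------------------------------------- dynamics
    stage = "dynamics"
    try:
        meta = ltq.cell_meta
        totals = truth["timepoint"].value_counts().sort_index()
        pheno = pd.DataFrame({
            "phenotype": labels[labels != "excluded"],
            "timepoint": meta.loc[labels != "excluded", "timepoint"].to_numpy(),
        })
        prev = prevalence_over_time(pheno, totals)
        prev.to_csv(outdir / "prevalence.csv", index=False)
        patterns = {}
        for t in prev["phenotype"].unique():
            if t == "unlabeled":
                continue
            series = (prev[prev["phenotype"] == t]
                      .set_index("timepoint")["fraction"]
                      .reindex(sorted(totals.index)))
            patterns[t] = classify_temporal_pattern(series.to_numpy())
        with open(outdir / "temporal_patterns.json", "w") as fh:
            json.dump(patterns, fh, indent=2)
        record(stage, [outdir / "prevalence.csv", outdir / "temporal_patterns.json"],
               {"patterns": patterns})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # -------------------------------------------------------------- hifi
    stage = "hifi"
    try:
        hifi_cfg = cfg.get("hifi", {})
        comp, panel, gating = default_hifi_panel()
        n_hifi = hifi_cfg.get("n_cells", 5000)
        table, true_types = simulate_hifi_intensities(
            comp, panel, default_mode_locations(), n_hifi, seed=_stage_seed(seed, stage, seed_overrides))
        scaled, modes = scale_markers(table, gating, return_modes=True)
        clusters = cluster_hifi(scaled, seed=_stage_seed(seed, stage, seed_overrides))
        rules = {t: {"necessary": sorted(m)} for t, m in panel.items()}
        ann = annotate_hifi(clusters, scaled, rules)
        cell_types = clusters.map(lambda c: ann.get(int(c), "undetermined") if c >= 0 else "undetermined")
        est_comp = cell_types[cell_types != "undetermined"].value_counts(normalize=True)
        cmp_res = compare_compositions(est_comp, pd.Series(comp))
        pd.DataFrame({"cluster": clusters, "cell_type": cell_types,
                      "true_type": true_types}).to_csv(outdir / "hifi_cell_types.csv")
        modes.to_csv(outdir / "hifi_modes.csv")
        acc = float((cell_types == true_types).mean())
        record(stage, [outdir / "hifi_cell_types.csv", outdir / "hifi_modes.csv"],
               {"typing_accuracy": acc, "log_composition_r": cmp_res["pearson_r"]})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # ------------------------------------------------------ crossspecies
    stage = "crossspecies"
    try:
        rng = np.random.default_rng(_stage_seed(seed, stage, seed_overrides))
        mouse = (pd.crosstab(meta["sample"], truth.loc[ltq.cell_ids, "true_type"])
                 .pipe(lambda d: d.div(d.sum(axis=1), axis=0)))
        base = mouse.mean(axis=0).to_numpy()
        shift = np.exp(rng.normal(0, 0.5, size=len(base)))
        human_profile = base * shift / (base * shift).sum()
        human = rng.dirichlet(human_profile * 50, size=cfg.get("n_human_samples", 26))
        comp_df = pd.concat([
            mouse,
            pd.DataFrame(human, columns=mouse.columns,
                         index=[f"human{i:02d}" for i in range(human.shape[0])]),
        ])
        species = pd.Series(["mouse"] * len(mouse) + ["human"] * human.shape[0],
                            index=comp_df.index)
        centered = log_center_by_species(comp_df, species)
        w = species_weights(species)
        pca = weighted_pca(centered, w)
        pd.DataFrame(pca.scores[:, :3], index=comp_df.index,
                     columns=["PC1", "PC2", "PC3"]).assign(species=species).to_csv(
            outdir / "crossspecies_pcs.csv")
        record(stage, [outdir / "crossspecies_pcs.csv"],
               {"weights": {"mouse": float(1 / len(mouse)), "human": float(1 / human.shape[0])},
                "variance_explained": pca.variance_explained[:3].tolist()})
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    manifest["completed"] = STAGES
    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
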