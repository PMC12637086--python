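"""Generate the synthetic tumor time-course used by the whole analysis.

Writes the UMI count matrix (MTX triplet + metadata), the planted
ground truth (cell types, archetype weights, trajectory positions) and
the marker table under results/data/.
"""

from pathlib import Path

from tmedyn.synthetic import simulate_counts, tumor_timecourse_config

SEED = 7
OUT = Path("results/data")


def main() -> None:
    cfg = tumor_timecourse_config(seed=SEED)
    counts, truth = simulate_counts(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    counts.write_mtx(OUT)
    truth.cells.to_csv(OUT / "truth.csv")
    cfg.marker_table().to_csv(OUT / "markers.csv", index=False)
    if truth.archetype_weights is not None:
        truth.archetype_weights.to_csv(OUT / "true_archetype_weights.csv")
    if truth.trajectory_positions is not None:
        truth.trajectory_positions.rename("position").to_csv(OUT / "true_trajectory.csv")
    comp = truth.cells.groupby("timepoint")["true_type"].value_counts(normalize=True)
    print(f"simulated {counts.n_genes} genes x {counts.n_cells} cells "
          f"over {truth.cells['timepoint'].nunique()} timepoints -> {OUT}")
    print(comp.unstack().round(3))


if __name__ == "__main__":
    main()
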