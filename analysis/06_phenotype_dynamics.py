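"""Temporal dynamics of cell types and discretized phenotypes.

Computes per-timepoint prevalences (normalized to all cells sequenced
at that timepoint), classifies each type's series into stable
colonization / wave-like / progressive increase, and draws the Treg
trajectory as per-timepoint densities whose areas equal the type's
prevalence.  Writes results/dynamics/.
"""

import json
from pathlib import Path

import pandas as pd

from tmedyn.containers import LTQMatrix
from tmedyn.dynamics import (
    classify_temporal_pattern,
    phenotype_density,
    prevalence_over_time,
)

IN_DATA = Path("results/data")
IN_NORM = Path("results/normalized")
IN_TYPES = Path("results/typing")
OUT = Path("results/dynamics")


def main() -> None:
    ltq = LTQMatrix.read_csv(IN_NORM / "ltq.csv.gz", IN_NORM / "gene_error.csv")
    meta = pd.read_csv(IN_NORM / "cell_meta.csv", index_col=0)
    truth = pd.read_csv(IN_DATA / "truth.csv", index_col=0)
    types = pd.read_csv(IN_TYPES / "cell_types.csv").set_index("cell_id")

    labels = types.loc[ltq.cell_ids, "cell_type"].to_numpy()
    typed = labels != "excluded"
    totals = truth["timepoint"].value_counts().sort_index()
    pheno = pd.DataFrame({"phenotype": labels[typed],
                          "timepoint": meta.loc[typed, "timepoint"].to_numpy()})
    prev = prevalence_over_time(pheno, totals)
    patterns = {}
    for t in prev["phenotype"].unique():
        if t in ("unlabeled", "unresolved"):
            continue
        series = (prev[prev["phenotype"] == t].set_index("timepoint")["fraction"]
                  .reindex(sorted(totals.index)).to_numpy())
        patterns[t] = classify_temporal_pattern(series)

    # Treg 1D trajectory densities (planted positions as the 1D axis)
    traj = pd.read_csv(IN_DATA / "true_trajectory.csv", index_col=0)["position"]
    treg = traj.index.intersection(pd.Index(ltq.cell_ids))
    tp = truth.loc[treg, "timepoint"].to_numpy()
    dens = phenotype_density(traj.loc[treg].to_numpy(), tp, totals)

    OUT.mkdir(parents=True, exist_ok=True)
    prev.to_csv(OUT / "prevalence.csv", index=False)
    dens.to_csv(OUT / "treg_density.csv", index=False)
    with open(OUT / "patterns.json", "w") as fh:
        json.dump(patterns, fh, indent=2)
    print("temporal pattern per cell type:")
    for t, p in sorted(patterns.items()):
        print(f"  {t:12s} {p}")


if __name__ == "__main__":
    main()
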