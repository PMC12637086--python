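"""Cross-species composition PCA.

Builds per-sample cell-type compositions from the typed mouse
time-course, simulates a larger human cohort around a shifted profile,
centers log-compositions within each species and runs the
inverse-cohort-size weighted PCA.  Writes results/crossspecies/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tmedyn.crossspecies import log_center_by_species, species_weights, weighted_pca

IN_DATA = Path("results/data")
IN_NORM = Path("results/normalized")
IN_TYPES = Path("results/typing")
OUT = Path("results/crossspecies")
SEED = 41
N_HUMAN = 26


def main() -> None:
    meta = pd.read_csv(IN_NORM / "cell_meta.csv", index_col=0)
    types = pd.read_csv(IN_TYPES / "cell_types.csv").set_index("cell_id")
    labels = types.loc[meta.index, "cell_type"]
    keep = ~labels.isin(["excluded", "unresolved"])
    mouse = (pd.crosstab(meta.loc[keep, "sample"], labels[keep])
             .pipe(lambda d: d.div(d.sum(axis=1), axis=0)))

    rng = np.random.default_rng(SEED)
    base = mouse.mean(axis=0).to_numpy()
    shift = np.exp(rng.normal(0.0, 0.5, size=len(base)))
    human_profile = base * shift / (base * shift).sum()
    human = pd.DataFrame(rng.dirichlet(human_profile * 50, size=N_HUMAN),
                         columns=mouse.columns,
                         index=[f"human{i:02d}" for i in range(N_HUMAN)])
    comp = pd.concat([mouse, human])
    species = pd.Series(["mouse"] * len(mouse) + ["human"] * N_HUMAN, index=comp.index)

    centered = log_center_by_species(comp, species)
    w = species_weights(species)
    pca = weighted_pca(centered, w)

    OUT.mkdir(parents=True, exist_ok=True)
    scores = pd.DataFrame(pca.scores[:, :3], index=comp.index,
                          columns=["PC1", "PC2", "PC3"]).assign(species=species)
    scores.to_csv(OUT / "pcs.csv")
    with open(OUT / "summary.json", "w") as fh:
        json.dump({"weights": {"mouse": 1 / len(mouse), "human": 1 / N_HUMAN},
                   "variance_explained": pca.variance_explained[:3].tolist()}, fh, indent=2)
    print(f"{len(mouse)} mouse samples (weight 1/{len(mouse)}) + {N_HUMAN} human "
          f"(weight 1/{N_HUMAN}); PC1 explains "
          f"{pca.variance_explained[0] / pca.variance_explained.sum():.0%} of weighted variance")


if __name__ == "__main__":
    main()
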