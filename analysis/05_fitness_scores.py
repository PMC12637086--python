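"""CRISPR-weighted fitness of single macrophage-simplex cells.

Simulates a NormZ screen enriched (effect 2) in the gene signature of
the first archetype, scores every cell as LTQ . NormZ, and compares
the 5% of cells closest to that archetype against the rest
(rank-sum).  Writes results/fitness/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from tmedyn.archetypes import distance_to_archetype
from tmedyn.containers import LTQMatrix
from tmedyn.fitness import archetype_fitness_test, fitness_scores
from tmedyn.synthetic import simulate_normz, tumor_timecourse_config

IN_NORM = Path("results/normalized")
IN_ARCH = Path("results/archetypes")
IN_TYPES = Path("results/typing")
OUT = Path("results/fitness")
SEED = 23


def main() -> None:
    ltq = LTQMatrix.read_csv(IN_NORM / "ltq.csv.gz", IN_NORM / "gene_error.csv")
    types = pd.read_csv(IN_TYPES / "cell_types.csv").set_index("cell_id")
    mask = (types.loc[ltq.cell_ids, "cell_type"] == "macrophage").to_numpy()
    sub = ltq.subset(cell_mask=mask)
    weights = pd.read_csv(IN_ARCH / "weights.csv", index_col=0)

    # signature = genes boosted in archetype 1 of the generator config
    cfg = tumor_timecourse_config(seed=7)
    profiles = cfg.simplex_spec.archetype_logrates
    sig = np.where(profiles[0] > profiles[1:].max(axis=0) + 1.0)[0]
    normz = simulate_normz(cfg.n_genes, sig, effect=2.0, seed=SEED,
                           gene_ids=cfg.gene_ids).set_index("gene")["normz"]

    scores, n_shared = fitness_scores(sub, normz, return_n_shared=True)
    # target = fitted archetype most correlated with the planted signature
    sig_ids = pd.Index(cfg.gene_ids[sig]).intersection(pd.Index(sub.gene_ids))
    gidx = pd.Index(sub.gene_ids).get_indexer(sig_ids)
    mean_sig = sub.ltq[gidx, :].mean(axis=0)
    target = int(np.argmax([np.corrcoef(weights.iloc[:, a], mean_sig)[0, 1]
                            for a in range(weights.shape[1])]))
    import json as _json

    simplex = _json.loads((IN_ARCH / "simplex.json").read_text())
    arch = np.asarray(simplex["archetypes"])
    from tmedyn.hierarchy import run_pca
    from tmedyn.qc import snr_genes

    pca = run_pca(sub.ltq[snr_genes(sub), :], n_pcs_max=3)
    d = distance_to_archetype(pca.scores[:, :3], arch, which=target)
    res = archetype_fitness_test(scores, d, frac=0.05)

    OUT.mkdir(parents=True, exist_ok=True)
    scores.rename("fitness").to_csv(OUT / "fitness_scores.csv")
    with open(OUT / "test.json", "w") as fh:
        json.dump({"target_archetype": target, "n_shared_genes": n_shared, **res}, fh, indent=2)
    print(f"fitness over {n_shared} shared genes; archetype {target + 1} proximity test: "
          f"p = {res['p']:.2e}, direction = {res['direction']}")


if __name__ == "__main__":
    main()
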