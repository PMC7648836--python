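"""Spectral clustering of clinical deviation maps into subtypes.

Builds the cosine affinity over clinical subjects' Z-maps, partitions at
k=5, compares against the planted truth, and quantifies leave-one-out
stability. Optionally sweeps the model-order grid (K=2..10) by
cross-validated mean pairwise AUROC (--select-k).

Run after 02: python analysis/03_cluster_subtypes.py [--out DIR]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from ctstrat.clustering import (cosine_affinity, loo_stability,
                                select_model_order, spectral_cluster)
from ctstrat.io import write_json, write_tsv

parser = argparse.ArgumentParser()
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
parser.add_argument("--k", type=int, default=5)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--select-k", action="store_true",
                    help="also sweep K=2..10 (slow)")
args = parser.parse_args()
out = args.out

dev = pd.read_csv(out / "deviations.tsv", sep="\t")
cov = pd.read_csv(out / "covariates.tsv", sep="\t")
clinical = cov["group"].to_numpy() == "clinical"
z = dev.drop(columns="subject_id").to_numpy(float)[clinical]
ids = dev["subject_id"].to_numpy()[clinical]

solution = spectral_cluster(cosine_affinity(z, ids), args.k, seed=args.seed)
write_tsv(pd.DataFrame({"subject_id": ids, "cluster": solution.labels}),
          out / "clusters.tsv")
sizes = np.bincount(solution.labels)[1:]
print(f"k={args.k} cluster sizes: {sizes.tolist()}")

truth_path = out / "subtype_truth.tsv"
if truth_path.exists():
    truth = pd.read_csv(truth_path, sep="\t")["true_subtype"].to_numpy()
    ari = adjusted_rand_score(truth, solution.labels)
    print(f"ARI against planted subtypes: {ari:.3f}")

stability = loo_stability(z, args.k, seed=args.seed)
write_json({k: v for k, v in stability.items()}, out / "stability.json")
print(f"leave-one-out stability: mean ARI {stability['mean_ari']:.3f} "
      f"(sd {stability['sd_ari']:.3f})")

if args.select_k:
    report = select_model_order(z, range(2, 11), seed=args.seed,
                                subject_id=ids)
    write_json(report.to_dict(), out / "model_order.json")
    curve = ", ".join(f"K={k}: {a:.3f}" for k, a in
                      zip(report.k_grid, report.mean_pairwise_auroc))
    print(f"mean pairwise AUROC by model order: {curve}")
    print(f"argmax selects K={report.selected_k} (note: on cleanly "
          "separable planted subtypes this criterion saturates and "
          "prefers small K; see docs/methods.md)")
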