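#!/usr/bin/env python
"""Measure robustness of centralized and federated models to client dropout.

Re-trains both regimes with each silo excluded in turn (plus the all-clients
condition) over several seeds and reports the median test-AUC change per
dropped client. Writes results/dropout.tsv.
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np

from fedvar.evaluation import dropout_study
from fedvar.federation import AggregatorConfig
from fedvar.io import write_results_tsv
from fedvar.nn import MLP, MLPConfig
from fedvar.presets import clients_by_silo, desk_local_cfg, standardized_matrices

_spec = importlib.util.spec_from_file_location(
    "cohort_builder", Path(__file__).parent / "03_local_centralized_federated.py")
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
build_cohort = _mod.build_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--seeds", type=int, default=3)
    parser.add_argument("--out", type=Path, default=Path("results/dropout.tsv"))
    args = parser.parse_args()

    cohort = build_cohort(args.seed)
    tr, t1, _ = standardized_matrices(cohort)
    clients = clients_by_silo(tr)
    model = MLP(MLPConfig(input_dim=60, n_hidden=4))
    agg = AggregatorConfig(algorithm="fedprox", proximal_mu=0.01,
                           client_rate=0.5, n_rounds=20)
    results = dropout_study(clients, model, desk_local_cfg(), agg,
                            seeds=range(args.seeds), test_X=t1.X, test_y=t1.y)
    write_results_tsv(results, args.out)

    sizes = {c: len(v[0]) for c, v in clients.items()}
    for mode in ("federated", "centralized"):
        base = np.median([r.auc for r in results
                          if r.mode == mode and r.dropout_client is None])
        print(f"{mode}: all-clients median AUC {base:.3f}")
        for silo in sorted(clients, key=sizes.get, reverse=True):
            med = np.median([r.auc for r in results
                             if r.mode == mode and r.dropout_client == silo])
            print(f"  drop {silo} (n={sizes[silo]:3d}): {med:.3f} "
                  f"({med - base:+.3f})")
    print(f"{len(results)} results -> {args.out}")


if __name__ == "__main__":
    main()
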