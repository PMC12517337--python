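#!/usr/bin/env python
"""Enumerate every benchmarked federated-learning setting.

The benchmark crosses, per model family (MLP, sNDF): FedProx over local
learning rate x local optimizer x client rate x proximal mu, and each
adaptive server algorithm (FedAdagrad, FedAdam, FedYogi) over local learning
rate x local optimizer x client rate x server learning rate x adaptivity tau.
Writes the manifest to results/grid.json and prints the per-block counts.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from fedvar.evaluation import enumerate_grid


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results/grid.json"))
    args = parser.parse_args()

    grid = enumerate_grid()
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(grid, indent=1))

    by_block = Counter((g["model"], g["algorithm"]) for g in grid)
    for (model, alg), n in sorted(by_block.items()):
        print(f"{model:5s} {alg:10s}: {n:4d} settings")
    print(f"total: {len(grid)} settings -> {args.out}")


if __name__ == "__main__":
    main()
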