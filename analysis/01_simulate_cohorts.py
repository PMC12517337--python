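#!/usr/bin/env python
"""Simulate the three multi-silo variant cohorts and write them as TSV.

Builds desk-scale analogs of the three study scenarios: coding SNVs (6 silos,
contributions 64.8% down to 3%), non-coding SNVs (8 silos, 45.5% down to 2%),
and deletion CNVs (8 silos, one holding ~90%). Each cohort is balanced 1:1
per silo and split temporally into train / external-site test / later test.
Outputs one directory per variant type under results/cohorts/.
"""

import argparse
from pathlib import Path

from fedvar.cohorts import CohortConfig, SiloSpec, balance_classes, generate_cohort
from fedvar.io import write_cohort_tsv

SCENARIOS = {
    # fractions follow the real contributor skews; totals are desk-scale
    "coding_snv": (1000, (0.648, 0.13, 0.09, 0.06, 0.042, 0.03)),
    "noncoding_snv": (600, (0.455, 0.14, 0.12, 0.09, 0.08, 0.055, 0.04, 0.02)),
    "deletion_cnv": (700, (0.90, 0.022, 0.018, 0.015, 0.013, 0.012, 0.01, 0.01)),
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/cohorts"))
    args = parser.parse_args()

    for vtype, (total, fracs) in SCENARIOS.items():
        silos = tuple(
            SiloSpec(f"site_{i}", max(4, round(f * total)))
            for i, f in enumerate(fracs)
        )
        cfg = CohortConfig(vtype, silos, seed=args.seed, test1_n=150, test2_n=100,
                           class_separation=1.0)
        cohort = generate_cohort(cfg)
        train = balance_classes(cohort.train_records, seed=args.seed)
        out = args.out / vtype
        write_cohort_tsv(train, out / "train.tsv")
        write_cohort_tsv(cohort.test1, out / "test1.tsv")
        write_cohort_tsv(cohort.test2, out / "test2.tsv")
        sizes = {s: sum(1 for r in train if r.silo_id == s)
                 for s in sorted({r.silo_id for r in train})}
        biggest = max(sizes.values()) / sum(sizes.values())
        print(f"{vtype}: {len(train)} balanced training variants across "
              f"{len(sizes)} silos (largest holds {biggest:.1%}); "
              f"test1={len(cohort.test1)}, test2={len(cohort.test2)} -> {out}")


if __name__ == "__main__":
    main()
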