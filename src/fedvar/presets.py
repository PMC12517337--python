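"""Desk-scale study presets: the synthetic conditions the experiments run on.

The full study trains hundreds of models per setting; these presets fix the
reduced problem sizes used by the packaged experiments so that every driver,
test and reproduction script runs the same conditions. Three scenarios:

* ``separable_two_silo`` — a 2-silo IID coding-SNV cohort (1000 variants per
  silo, class means one pooled s.d. apart on every conservation coordinate)
  for the federated-vs-centralized comparison and score-similarity analysis.
* ``iid_null_cohort`` — a harder 2-silo IID cohort (class signal confined to
  5 coordinates at 0.8 s.d.) whose model AUC is far from saturation, used to
  calibrate the IID-repartition null.
* ``clustered_noniid_cohort`` — 6 small silos whose pathogenic variants are
  shifted in silo-specific random directions (3 s.d. per coordinate),
  emulating the clustering of pathogenic variants by client of origin
  observed in real CNV silos; the strong non-IID regime.

All presets standardize features with moments fitted on the training split.
"""

from __future__ import annotations

import numpy as np

from fedvar.cohorts import CohortConfig, SiloSpec, generate_cohort
from fedvar.features import FeatureMatrix, build_feature_matrix, fit_standardizer
from fedvar.federation import AggregatorConfig
from fedvar.nn import MLP, MLPConfig
from fedvar.optim import LocalTrainConfig

__all__ = [
    "standardized_matrices",
    "clients_by_silo",
    "separable_two_silo",
    "iid_null_cohort",
    "clustered_noniid_cohort",
    "desk_local_cfg",
    "desk_fedavg",
    "desk_mlp",
]

#: number of continuous payload coordinates of an SNV record
_N_SNV_COORDS = 35


def standardized_matrices(cohort) -> tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix]:
    """Encode (train, test1, test2) and z-score with training-split moments."""
    tr = build_feature_matrix(cohort.train_records)
    t1 = build_feature_matrix(cohort.test1)
    t2 = build_feature_matrix(cohort.test2)
    mean, scale = fit_standardizer(tr.X)
    for m in (tr, t1, t2):
        m.X = (m.X - mean) / scale
    return tr, t1, t2


def clients_by_silo(matrix: FeatureMatrix) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    return {
        str(s): (matrix.X[matrix.silo_id == s], matrix.y[matrix.silo_id == s])
        for s in np.unique(matrix.silo_id)
    }


def separable_two_silo(seed: int = 11):
    """2 x 1000 IID silos, class separation 1.0 s.d. on all 35 coordinates."""
    cfg = CohortConfig(
        "coding_snv",
        (SiloSpec("site_a", 1000), SiloSpec("site_b", 1000)),
        seed=seed,
        class_separation=1.0,
        test1_n=500,
        test2_n=500,
    )
    return generate_cohort(cfg)


def iid_null_cohort(seed: int = 0):
    """2 x 150 IID silos; weak signal (0.8 s.d. on 5 coordinates)."""
    cfg = CohortConfig(
        "coding_snv",
        (SiloSpec("site_a", 150), SiloSpec("site_b", 150)),
        seed=seed,
        class_separation=0.8,
        n_informative=5,
        test1_n=300,
        test2_n=300,
    )
    return generate_cohort(cfg)


def clustered_noniid_cohort(seed: int = 0, n_silos: int = 6, per_silo: int = 50,
                            cluster_shift: float = 3.0):
    """Small silos whose pathogenic variants cluster by silo of origin.

    Each silo's pathogenic records are offset by a silo-specific random sign
    pattern of magnitude ``cluster_shift`` per coordinate; benign records stay
    on the shared distribution, as do both test pools.
    """
    dir_rng = np.random.default_rng(777)  # fixed cluster directions
    specs = tuple(
        SiloSpec(
            f"site_{j}",
            per_silo,
            pathogenic_shift=tuple(
                dir_rng.choice([-1.0, 1.0], size=_N_SNV_COORDS) * cluster_shift
            ),
        )
        for j in range(n_silos)
    )
    cfg = CohortConfig(
        "coding_snv",
        specs,
        seed=seed,
        class_separation=0.8,
        n_informative=5,
        test1_n=300,
        test2_n=300,
    )
    return generate_cohort(cfg)


def desk_local_cfg(**overrides) -> LocalTrainConfig:
    """Client optimizer used by the desk-scale experiments (SGD, 10 epochs)."""
    base = dict(optimizer="sgd", learning_rate=0.01, batch_size=32, epochs=10)
    base.update(overrides)
    return LocalTrainConfig(**base)


def desk_fedavg(n_rounds: int = 8, **overrides) -> AggregatorConfig:
    return AggregatorConfig(algorithm="fedavg", n_rounds=n_rounds, **overrides)


def desk_mlp(input_dim: int = 60, n_hidden: int = 4) -> MLP:
    return MLP(MLPConfig(input_dim=input_dim, n_hidden=n_hidden))
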