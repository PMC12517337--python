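"""YAML experiment configuration shared by the CLI and the analysis drivers.

A single document holds sections mirroring the library's config objects:

.. code-block:: yaml

    cohort:
      variant_type: coding_snv
      silos: [{silo_id: a, n_variants: 500}, {silo_id: b, n_variants: 200}]
      class_separation: 1.0
      seed: 7
    model: {family: mlp, n_hidden: 5}
    local: {optimizer: sgd, learning_rate: 0.01, batch_size: 32, epochs: 10}
    aggregator: {algorithm: fedprox, proximal_mu: 0.01, client_rate: 0.5, n_rounds: 30}
    seeds: [0, 1, 2]

Unknown keys raise a schema error naming the field, so typos in algorithm or
optimizer names fail loudly before any computation starts.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path

import yaml

from fedvar.cohorts import CohortConfig, SiloSpec
from fedvar.federation import ALGORITHMS, AggregatorConfig
from fedvar.nn import MLP, ForestConfig, MLPConfig, NeuralDecisionForest
from fedvar.optim import LocalTrainConfig

__all__ = ["ConfigError", "load_config", "build_cohort_config", "build_model",
           "build_local_cfg", "build_aggregator_cfg", "manifest_dict"]


class ConfigError(ValueError):
    pass


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} in section {name!r}")


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    _check_keys(doc, {"cohort", "model", "local", "aggregator", "seeds", "output_dir"},
                "<root>")
    return doc


def build_cohort_config(section: dict) -> CohortConfig:
    _check_keys(section, {"variant_type", "silos", "split_date", "test1_n", "test2_n",
                          "seed", "class_separation", "n_informative"}, "cohort")
    silos = tuple(
        SiloSpec(**{k: v for k, v in s.items()}) for s in section.get("silos", [])
    )
    kwargs = {k: v for k, v in section.items() if k not in ("silos", "split_date")}
    if "split_date" in section:
        kwargs["split_date"] = _dt.date.fromisoformat(str(section["split_date"]))
    return CohortConfig(silo_specs=silos, **kwargs)


def build_model(section: dict, input_dim: int):
    family = section.get("family")
    if family == "mlp":
        _check_keys(section, {"family", "n_hidden", "use_batch_norm"}, "model")
        return MLP(MLPConfig(
            input_dim=input_dim,
            n_hidden=int(section.get("n_hidden", 5)),
            use_batch_norm=bool(section.get("use_batch_norm", False)),
        ))
    if family == "sndf":
        _check_keys(section, {"family", "n_trees", "depth", "feature_rate"}, "model")
        return NeuralDecisionForest(ForestConfig(
            input_dim=input_dim,
            n_trees=int(section.get("n_trees", 5)),
            depth=int(section.get("depth", 3)),
            feature_rate=float(section.get("feature_rate", 0.7)),
        ))
    raise ConfigError(f"unknown model family {family!r} (expected 'mlp' or 'sndf')")


def build_local_cfg(section: dict) -> LocalTrainConfig:
    allowed = {f.name for f in dataclasses.fields(LocalTrainConfig)} - {"anchor"}
    _check_keys(section, allowed, "local")
    return LocalTrainConfig(**section)


def build_aggregator_cfg(section: dict) -> AggregatorConfig:
    allowed = {f.name for f in dataclasses.fields(AggregatorConfig)}
    _check_keys(section, allowed, "aggregator")
    alg = section.get("algorithm", "fedavg")
    if alg not in ALGORITHMS:
        raise ConfigError(
            f"invalid aggregator.algorithm {alg!r}; expected one of {ALGORITHMS}"
        )
    return AggregatorConfig(**section)


def manifest_dict(doc: dict) -> dict:
    """Experiment manifest: the config document plus software version."""
    from fedvar import __version__

    return {"config": doc, "fedvar_version": __version__}
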