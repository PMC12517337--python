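"""TSV/JSON artifact I/O: cohort tables, feature manifests, result tables.

Cohort tables are plain TSV with one variant per row: the provenance columns
(variant_id, chromosome, silo_id, report_date as ISO-8601, label,
variant_type, length_bp) followed by the payload — flat columns for SNV
window/conservation payloads, a single JSON column for the nested CNV
gene/region tables.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fedvar.cohorts import SNV_TRACKS, VariantRecord
from fedvar.evaluation import ExperimentResult

__all__ = [
    "cohort_to_dataframe",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_feature_manifest",
    "read_feature_manifest",
    "results_to_dataframe",
    "write_results_tsv",
    "config_hash",
]

_BASE_COLUMNS = [
    "variant_id", "chromosome", "silo_id", "report_date",
    "label", "variant_type", "length_bp",
]


def cohort_to_dataframe(records: list[VariantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "variant_id": r.variant_id,
            "chromosome": r.chromosome,
            "silo_id": r.silo_id,
            "report_date": r.report_date.isoformat(),
            "label": r.label,
            "variant_type": r.variant_type,
            "length_bp": "" if r.length_bp is None else r.length_bp,
        }
        if r.variant_type == "deletion_cnv":
            row["payload_json"] = json.dumps(r.payload, sort_keys=True)
        else:
            row["window_seq"] = r.payload["window_seq"]
            for track in SNV_TRACKS:
                for p in range(5):
                    row[f"{track}_p{p + 1}"] = float(r.payload[track][p])
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_tsv(records: list[VariantRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort_to_dataframe(records).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str},
                     keep_default_na=False, float_precision="round_trip")
    records = []
    for _, row in df.iterrows():
        vtype = row["variant_type"]
        if vtype == "deletion_cnv":
            payload = json.loads(row["payload_json"])
            length_bp = int(row["length_bp"])
        else:
            payload = {"window_seq": row["window_seq"]}
            for track in SNV_TRACKS:
                payload[track] = np.array(
                    [float(row[f"{track}_p{p + 1}"]) for p in range(5)]
                )
            length_bp = None
        records.append(
            VariantRecord(
                variant_id=str(row["variant_id"]),
                chromosome=str(row["chromosome"]),
                silo_id=str(row["silo_id"]),
                report_date=_dt.date.fromisoformat(row["report_date"]),
                label=int(row["label"]),
                variant_type=vtype,
                payload=payload,
                length_bp=length_bp,
            )
        )
    return records


def write_feature_manifest(feature_names, path: str | Path, extra: dict | None = None) -> None:
    """JSON manifest freezing the feature order next to an encoded matrix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"n_features": len(feature_names), "feature_names": list(feature_names)}
    if extra:
        doc.update(extra)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))


def read_feature_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def results_to_dataframe(results: list[ExperimentResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def write_results_tsv(results: list[ExperimentResult], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results_to_dataframe(results).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable hash of a configuration document (field order irrelevant)."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
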