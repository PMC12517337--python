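"""Fixed-dimension feature encodings for SNVs and deletion CNVs.

SNVs are encoded into 60 features: a position-major one-hot encoding of the
5-nucleotide window centred on the mutated position over the alphabet
(A, C, G, T, N) — 25 values — followed by seven phyloP conservation tracks
(100-, 470-, 3-, 4-, 7-, 17- and 20-species alignments) evaluated at the five
window positions — 35 values.

Deletion CNVs are encoded into 38 features: 22 gene-based features aggregated
over the genes overlapping the CNV (maximum across genes for quantitative
scores, except minimum expression and the two shortest-path network features
where the minimum applies; presence of at least one gene with the attribute
for categorical flags; plus the overlapping-gene count) and 16 region-based
features (six regulatory coverage fractions, windowed maxima of recombination
rate, CADD and GERP, maximum gene density, four overlap flags, and distances
to the centromere and the closest telomere).

The flat feature order is frozen in ``SNV_FEATURE_NAMES`` and
``CNV_FEATURE_NAMES`` and written next to every encoded matrix as a JSON
manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fedvar.cohorts import (
    NUCLEOTIDES,
    REGION_FIELDS,
    SNV_TRACKS,
    VariantRecord,
)

__all__ = [
    "EncodingError",
    "SNV_FEATURE_NAMES",
    "CNV_FEATURE_NAMES",
    "MISSING_GENE_PATH_SENTINEL",
    "FeatureMatrix",
    "encode_snv",
    "encode_cnv",
    "build_feature_matrix",
    "fit_standardizer",
]


class EncodingError(ValueError):
    """Raised when a variant payload cannot be encoded."""


SNV_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"win{p}_{b}" for p in range(1, 6) for b in NUCLEOTIDES
) + tuple(f"{track}_p{p}" for track in SNV_TRACKS for p in range(1, 6))

#: Gene-based columns: aggregation rule is max across overlapping genes unless
#: suffixed _min; *_any flags mark presence of >= 1 gene with the attribute.
_CNV_GENE_COLUMNS: tuple[tuple[str, str, str], ...] = (
    # (column name, payload gene field, aggregation)
    ("n_genes", "", "count"),
    ("pli_max", "pli", "max"),
    ("loeuf_max", "loeuf", "max"),
    ("pnull_max", "pnull", "max"),
    ("ccr_max", "ccr", "max"),
    ("eds_max", "eds", "max"),
    ("hi_pred_max", "hi_pred", "max"),
    ("ts_pred_max", "ts_pred", "max"),
    ("ohnolog_any", "ohnolog", "any"),
    ("tf_any", "tf", "any"),
    ("crispr_max", "crispr", "max"),
    ("complex_any", "complex_member", "any"),
    ("expr_mean_max", "expr_mean", "max"),
    ("expr_min_min", "expr_min", "min"),
    ("phastcons_max", "phastcons", "max"),
    ("cpg_promoter_max", "cpg_promoter", "max"),
    ("ppi_degree_max", "ppi_degree", "max"),
    ("ppi_pagerank_max", "ppi_pagerank", "max"),
    ("ppi_betweenness_max", "ppi_betweenness", "max"),
    ("ppi_clustering_max", "ppi_clustering", "max"),
    ("sp_hi_min", "sp_hi", "min"),
    ("sp_ts_min", "sp_ts", "min"),
)

CNV_FEATURE_NAMES: tuple[str, ...] = tuple(c for c, _, _ in _CNV_GENE_COLUMNS) + REGION_FIELDS

#: Neutral value for min-aggregated shortest-path features when no gene
#: overlaps the CNV (a large network distance).
MISSING_GENE_PATH_SENTINEL = 10.0

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


def encode_snv(payload: dict) -> np.ndarray:
    """Encode one SNV payload into its 60-dimensional feature vector."""
    window = payload.get("window_seq")
    if not isinstance(window, str) or len(window) != 5:
        raise EncodingError(f"window_seq must be a 5-symbol string, got {window!r}")
    out = np.zeros(len(SNV_FEATURE_NAMES))
    for p, base in enumerate(window):
        if base not in _BASE_INDEX:
            raise EncodingError(f"unknown nucleotide {base!r} at window position {p + 1}")
        out[p * 5 + _BASE_INDEX[base]] = 1.0
    off = 25
    for track in SNV_TRACKS:
        vals = np.asarray(payload.get(track, ()), dtype=float)
        if vals.shape != (5,):
            raise EncodingError(f"track {track!r} must hold 5 values, got shape {vals.shape}")
        out[off:off + 5] = vals
        off += 5
    return out


def encode_cnv(payload: dict) -> np.ndarray:
    """Encode one deletion-CNV payload into its 38-dimensional feature vector.

    An empty gene table yields 0 for all max-aggregated scores and flags and
    ``MISSING_GENE_PATH_SENTINEL`` for the two shortest-path minima.
    """
    genes = payload.get("overlapping_genes", [])
    region = payload.get("region_values")
    if region is None:
        raise EncodingError("payload missing 'region_values'")
    out = np.zeros(len(CNV_FEATURE_NAMES))
    for j, (col, fld, agg) in enumerate(_CNV_GENE_COLUMNS):
        if agg == "count":
            out[j] = float(len(genes))
            continue
        try:
            vals = [float(g[fld]) for g in genes]
        except KeyError as e:
            raise EncodingError(f"gene table missing column {e.args[0]!r} (feature {col!r})")
        if agg == "max":
            out[j] = max(vals) if vals else 0.0
        elif agg == "min":
            if vals:
                out[j] = min(vals)
            else:
                out[j] = MISSING_GENE_PATH_SENTINEL if col.startswith("sp_") else 0.0
        elif agg == "any":
            out[j] = 1.0 if any(v > 0 for v in vals) else 0.0
    off = len(_CNV_GENE_COLUMNS)
    for j, fld in enumerate(REGION_FIELDS):
        if fld not in region:
            raise EncodingError(f"region_values missing column {fld!r}")
        v = float(region[fld])
        if fld.startswith("cov_"):
            v = float(np.clip(v, 0.0, 1.0))
        if fld.startswith("dist_"):
            v = max(v, 0.0)
        out[off + j] = v
    return out


@dataclass
class FeatureMatrix:
    """Encoded variants: feature matrix aligned with labels and provenance."""

    X: np.ndarray  # (n, d)
    y: np.ndarray  # (n,) in {0, 1}
    chromosome: np.ndarray  # (n,) str
    silo_id: np.ndarray  # (n,) str
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.chromosome) == len(self.silo_id) == n):
            raise ValueError("misaligned FeatureMatrix fields")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length does not match X columns")
        if np.isnan(self.X).any():
            raise ValueError("encoded matrix contains missing values")

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[mask],
            y=self.y[mask],
            chromosome=self.chromosome[mask],
            silo_id=self.silo_id[mask],
            feature_names=self.feature_names,
        )


def build_feature_matrix(records: list[VariantRecord]) -> FeatureMatrix:
    """Encode a homogeneous list of variant records into a FeatureMatrix.

    Row order follows input order. An empty input yields a 0-row matrix; the
    variant type is then unknowable, so the SNV schema is used by convention.
    """
    if not records:
        return FeatureMatrix(
            X=np.zeros((0, len(SNV_FEATURE_NAMES))),
            y=np.zeros(0, dtype=int),
            chromosome=np.zeros(0, dtype=object),
            silo_id=np.zeros(0, dtype=object),
            feature_names=SNV_FEATURE_NAMES,
        )
    vtypes = {r.variant_type for r in records}
    if len(vtypes) != 1:
        raise ValueError(f"mixed variant types cannot share a matrix: {sorted(vtypes)}")
    vtype = vtypes.pop()
    if vtype == "deletion_cnv":
        names = CNV_FEATURE_NAMES
        rows = [encode_cnv(r.payload) for r in records]
    else:
        names = SNV_FEATURE_NAMES
        rows = [encode_snv(r.payload) for r in records]
    return FeatureMatrix(
        X=np.vstack(rows),
        y=np.array([r.label for r in records], dtype=int),
        chromosome=np.array([r.chromosome for r in records], dtype=object),
        silo_id=np.array([r.silo_id for r in records], dtype=object),
        feature_names=names,
    )


def fit_standardizer(train_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means/scales fitted on training silos only (z-scoring).

    Returns ``(mean, scale)``; constant columns get scale 1 so the transform
    stays finite. Apply as ``(X - mean) / scale`` everywhere, including test
    pools — the federated pipeline fits this on the pooled training split
    before distribution, which leaks only per-feature first and second
    moments, not records.
    """
    mean = train_X.mean(axis=0)
    scale = train_X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return mean, scale
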