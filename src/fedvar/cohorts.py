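"""Synthetic multi-silo variant cohorts.

Real multi-institutional collections of clinically labeled variants (e.g.
ClinVar submissions attributed to their submitting laboratory) cannot be
shipped with the package, so this module generates cohorts with the same
statistical structure: heavily skewed silo sizes, a 1:1 pathogenic/benign
balance after downsampling, a temporal train/test split, a second test pool
drawn from institutions that did not participate in training, and an optional
per-silo feature-distribution shift that switches the cohort from IID to
non-IID.

Variant payloads are drawn from a two-class generative model: for SNVs, the
35 conservation-track values follow class-conditional Gaussians with shared
unit variance, the class means separated by ``class_separation`` standard
deviations on each informative coordinate; for deletion CNVs the same
construction drives per-gene constraint scores and region-level annotations.
A silo's ``feature_shift`` is added to the continuous payload means, so a
non-zero shift makes silos non-identically distributed while leaving the
class-conditional structure intact.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "CHROMOSOMES",
    "NUCLEOTIDES",
    "SNV_TRACKS",
    "GENE_FIELDS",
    "REGION_FIELDS",
    "VariantRecord",
    "SiloSpec",
    "CohortConfig",
    "Cohort",
    "InvalidConfigError",
    "generate_cohort",
    "balance_classes",
    "match_benign_by_length",
    "partition_random_iid",
]

#: Autosomes 1-22 plus X; chromosome Y is absent from the study design, which
#: trains one leave-one-chromosome-out classifier per symbol (23 in total).
CHROMOSOMES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X",)

NUCLEOTIDES = ("A", "C", "G", "T", "N")

#: Conservation tracks annotated on the 5-nucleotide window around an SNV.
SNV_TRACKS = (
    "phyloP100",
    "phyloP470",
    "phyloP3",
    "phyloP4",
    "phyloP7",
    "phyloP17",
    "phyloP20",
)

#: Per-gene annotation fields carried by a CNV payload (constraint scores,
#: functional flags, expression, conservation, promoter CpG density and
#: protein-protein-interaction network features).
GENE_FIELDS = (
    "pli",
    "loeuf",
    "pnull",
    "ccr",
    "eds",
    "hi_pred",
    "ts_pred",
    "ohnolog",
    "tf",
    "crispr",
    "complex_member",
    "expr_mean",
    "expr_min",
    "phastcons",
    "cpg_promoter",
    "ppi_degree",
    "ppi_pagerank",
    "ppi_betweenness",
    "ppi_clustering",
    "sp_hi",
    "sp_ts",
)

#: Region-level annotation fields of a CNV payload: regulatory coverage
#: fractions, windowed score maxima, gene density, overlap flags with regions
#: of interest, and distances to centromere/closest telomere (Mb).
REGION_FIELDS = (
    "cov_open_chromatin",
    "cov_tfbs",
    "cov_promoter",
    "cov_promoter_flank",
    "cov_ctcf",
    "cov_enhancer",
    "max_recombination",
    "max_cadd",
    "max_gerp",
    "max_gene_density",
    "overlap_har",
    "overlap_lad",
    "overlap_ucne",
    "overlap_sv_hotspot",
    "dist_centromere_mb",
    "dist_telomere_mb",
)

_GENE_FLAG_FIELDS = {"ohnolog", "tf", "complex_member"}
_REGION_COVERAGE_FIELDS = tuple(f for f in REGION_FIELDS if f.startswith("cov_"))
_REGION_FLAG_FIELDS = tuple(f for f in REGION_FIELDS if f.startswith("overlap_"))


class InvalidConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


@dataclass(frozen=True)
class VariantRecord:
    """One labeled variant with its silo attribution and raw annotations."""

    variant_id: str
    chromosome: str
    silo_id: str
    report_date: _dt.date
    label: int  # 1 = pathogenic, 0 = benign
    variant_type: str  # coding_snv | noncoding_snv | deletion_cnv
    payload: dict = field(compare=False)
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.variant_type == "deletion_cnv":
            if self.length_bp is None or self.length_bp < 1:
                raise ValueError("deletion_cnv requires length_bp >= 1")


@dataclass(frozen=True)
class SiloSpec:
    """Size, class mix and distribution shift of one contributing silo.

    ``feature_shift`` is an additive offset on the silo's continuous payload
    means: a scalar applies to every coordinate, a vector (length = number of
    continuous payload coordinates, or shorter — padded with zeros) shifts
    coordinates individually. Zero everywhere means the silo is identically
    distributed with the others.
    """

    silo_id: str
    n_variants: int
    feature_shift: float | tuple = 0.0  # additive mean offset; 0 => IID
    class_balance: float = 0.5  # raw fraction pathogenic before downsampling
    #: offset applied to pathogenic records only, emulating the observed
    #: clustering of pathogenic variants by their client of origin (the
    #: strong non-IID regime); 0 leaves classes co-located across silos.
    pathogenic_shift: float | tuple = 0.0

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise InvalidConfigError(
                f"silo {self.silo_id!r}: n_variants must be >= 2, got {self.n_variants}"
            )
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidConfigError(
                f"silo {self.silo_id!r}: class_balance must lie in (0, 1)"
            )


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic multi-silo cohort.

    ``class_separation`` is the standardized mean difference between the
    pathogenic and benign class on each informative payload coordinate;
    ``n_informative`` limits the signal to the first *k* continuous payload
    coordinates (``None`` = all), which controls how hard the classification
    task is without touching the cohort structure.
    """

    variant_type: str
    silo_specs: tuple[SiloSpec, ...]
    split_date: _dt.date = _dt.date(2020, 1, 1)
    test1_n: int = 200
    test2_n: int = 200
    seed: int = 0
    class_separation: float = 1.0
    n_informative: int | None = None

    def __post_init__(self) -> None:
        if self.variant_type not in ("coding_snv", "noncoding_snv", "deletion_cnv"):
            raise InvalidConfigError(f"unknown variant_type {self.variant_type!r}")
        if len(self.silo_specs) < 2:
            raise InvalidConfigError("a cohort needs at least 2 silos")
        ids = [s.silo_id for s in self.silo_specs]
        if len(set(ids)) != len(ids):
            raise InvalidConfigError(f"duplicate silo_id in {ids}")
        object.__setattr__(self, "silo_specs", tuple(self.silo_specs))


@dataclass
class Cohort:
    """Generated cohort: training records grouped by silo plus two test pools."""

    train: dict[str, list[VariantRecord]]
    test1: list[VariantRecord]
    test2: list[VariantRecord]
    config: CohortConfig

    @property
    def train_records(self) -> list[VariantRecord]:
        return [r for recs in self.train.values() for r in recs]


# ---------------------------------------------------------------------------
# payload generation
# ---------------------------------------------------------------------------

def _n_continuous(variant_type: str) -> int:
    if variant_type in ("coding_snv", "noncoding_snv"):
        return len(SNV_TRACKS) * 5
    # CNV: continuous class signal lives on the quantitative gene fields plus
    # the continuous region fields.
    return len(GENE_FIELDS) - len(_GENE_FLAG_FIELDS) + len(REGION_FIELDS) - len(_REGION_FLAG_FIELDS)


def _class_means(config: CohortConfig) -> np.ndarray:
    """Per-coordinate mean offsets of the pathogenic class (benign = 0)."""
    d = _n_continuous(config.variant_type)
    k = d if config.n_informative is None else min(config.n_informative, d)
    mu = np.zeros(d)
    mu[:k] = config.class_separation
    return mu


def _draw_snv_payload(rng: np.random.Generator, z: np.ndarray) -> dict:
    """Assemble an SNV payload from the continuous draw ``z`` (35 values)."""
    window = "".join(rng.choice(NUCLEOTIDES, p=[0.2475, 0.2475, 0.2475, 0.2475, 0.01])
                     for _ in range(5))
    payload: dict = {"window_seq": window}
    for i, track in enumerate(SNV_TRACKS):
        payload[track] = z[i * 5:(i + 1) * 5].copy()
    return payload


def _draw_cnv_payload(rng: np.random.Generator, z: np.ndarray, label: int) -> tuple[dict, int]:
    """Assemble a CNV payload (gene table + region values) from draw ``z``.

    The quantitative gene fields of every overlapping gene are centred on the
    class-conditional values in ``z``; flags are Bernoulli with a mild class
    tilt. Coverage fractions are squashed into [0, 1] and distances made
    non-negative, so invariants hold regardless of the Gaussian draw.
    """
    quant_gene = [f for f in GENE_FIELDS if f not in _GENE_FLAG_FIELDS]
    n_quant = len(quant_gene)
    length_bp = int(np.ceil(np.exp(rng.normal(11.0, 1.5))))  # ~60 kb median
    n_genes = rng.poisson(3)
    genes = []
    p_flag = 0.35 if label == 1 else 0.25
    for _ in range(n_genes):
        vals = z[:n_quant] + rng.normal(0.0, 0.5, size=n_quant)
        gene = dict(zip(quant_gene, vals))
        # clip fields with bounded definitions
        gene["pli"] = float(np.clip(_sigmoid(gene["pli"]), 0, 1))
        gene["pnull"] = float(np.clip(_sigmoid(gene["pnull"]), 0, 1))
        gene["sp_hi"] = float(abs(gene["sp_hi"]))
        gene["sp_ts"] = float(abs(gene["sp_ts"]))
        for flag in _GENE_FLAG_FIELDS:
            gene[flag] = int(rng.random() < p_flag)
        genes.append({k: (v if isinstance(v, int) else float(v)) for k, v in gene.items()})
    region_quant = [f for f in REGION_FIELDS if f not in _REGION_FLAG_FIELDS]
    rz = z[n_quant:n_quant + len(region_quant)]
    region: dict = {}
    for f, v in zip(region_quant, rz):
        if f in _REGION_COVERAGE_FIELDS:
            region[f] = float(np.clip(_sigmoid(v), 0.0, 1.0))
        elif f.startswith("dist_"):
            region[f] = float(abs(v))
        else:
            region[f] = float(v)
    for f in _REGION_FLAG_FIELDS:
        region[f] = int(rng.random() < p_flag)
    return {"overlapping_genes": genes, "region_values": region}, length_bp


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-float(x)))


def _shift_vector(shift, d: int) -> np.ndarray:
    """Normalize a scalar or (possibly short) vector shift to length ``d``."""
    if np.isscalar(shift):
        return np.full(d, float(shift))
    arr = np.asarray(shift, dtype=float).ravel()
    if len(arr) > d:
        raise InvalidConfigError(f"feature_shift longer ({len(arr)}) than payload ({d})")
    out = np.zeros(d)
    out[:len(arr)] = arr
    return out


def _draw_record(
    rng: np.random.Generator,
    config: CohortConfig,
    silo_id: str,
    shift,
    label: int,
    variant_id: str,
    date: _dt.date,
    pathogenic_shift=0.0,
) -> VariantRecord:
    mu = _class_means(config)
    loc = mu * label + _shift_vector(shift, len(mu))
    if label == 1:
        loc = loc + _shift_vector(pathogenic_shift, len(mu))
    z = rng.normal(loc, 1.0)
    chromosome = str(rng.choice(CHROMOSOMES))
    length_bp = None
    if config.variant_type == "deletion_cnv":
        payload, length_bp = _draw_cnv_payload(rng, z, label)
    else:
        payload = _draw_snv_payload(rng, z)
    return VariantRecord(
        variant_id=variant_id,
        chromosome=chromosome,
        silo_id=silo_id,
        report_date=date,
        label=label,
        variant_type=config.variant_type,
        payload=payload,
        length_bp=length_bp,
    )


def _uniform_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, max(span, 1))))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a multi-silo cohort plus two independent test pools.

    Training records are dated before ``config.split_date``; ``test2`` records
    are dated after it (later submissions); ``test1`` records predate the
    split but belong to pseudo-institutions absent from training (external
    sites). Test pools are drawn without silo shift, so they act as a neutral
    reference distribution for both IID and non-IID cohorts.
    """
    rng = np.random.default_rng(config.seed)
    before_start = config.split_date - _dt.timedelta(days=365)
    after_end = config.split_date + _dt.timedelta(days=365)

    train: dict[str, list[VariantRecord]] = {}
    for spec in config.silo_specs:
        n_path = int(round(spec.n_variants * spec.class_balance))
        n_path = min(max(n_path, 1), spec.n_variants - 1)
        labels = np.concatenate(
            [np.ones(n_path, dtype=int), np.zeros(spec.n_variants - n_path, dtype=int)]
        )
        rng.shuffle(labels)
        recs = []
        for i, lab in enumerate(labels):
            date = _uniform_date(rng, before_start, config.split_date - _dt.timedelta(days=1))
            recs.append(
                _draw_record(rng, config, spec.silo_id, spec.feature_shift,
                             int(lab), f"{spec.silo_id}_v{i}", date,
                             pathogenic_shift=spec.pathogenic_shift)
            )
        train[spec.silo_id] = recs

    def _test_pool(name: str, n: int, start: _dt.date, end: _dt.date) -> list[VariantRecord]:
        pool = []
        for i in range(n):
            lab = int(i % 2)  # balanced by construction
            date = _uniform_date(rng, start, end)
            pool.append(
                _draw_record(rng, config, name, 0.0, lab, f"{name}_v{i}", date)
            )
        return pool

    test1 = _test_pool("external_site", config.test1_n,
                       before_start, config.split_date - _dt.timedelta(days=1))
    test2_silos = [s.silo_id for s in config.silo_specs]
    test2 = _test_pool("later_submissions", config.test2_n, config.split_date, after_end)
    # test2 keeps its own pseudo-silo id; it emulates later submissions, and
    # attribution does not enter evaluation.
    del test2_silos
    return Cohort(train=train, test1=test1, test2=test2, config=config)


def balance_classes(records: list[VariantRecord], seed: int) -> list[VariantRecord]:
    """Downsample the majority class to a 1:1 label balance within each silo.

    Returns a subset of the input, preserving input order; deterministic for
    a fixed seed. Raises ``ValueError`` naming the silo if it holds a single
    label only.
    """
    rng = np.random.default_rng(seed)
    by_silo: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_silo.setdefault(r.silo_id, []).append(i)
    keep: set[int] = set()
    for silo_id, idx in by_silo.items():
        pos = [i for i in idx if records[i].label == 1]
        neg = [i for i in idx if records[i].label == 0]
        if not pos or not neg:
            raise ValueError(f"silo {silo_id!r} holds a single label; cannot balance")
        n = min(len(pos), len(neg))
        for group in (pos, neg):
            chosen = rng.choice(len(group), size=n, replace=False) if len(group) > n else np.arange(len(group))
            keep.update(group[j] for j in chosen)
    return [r for i, r in enumerate(records) if i in keep]


def match_benign_by_length(
    pathogenic: list[VariantRecord],
    benign_pool: list[VariantRecord],
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Pair each pathogenic deletion CNV with a distinct benign CNV of similar length.

    Greedy nearest-neighbour on |log-length difference|, processing pathogenic
    CNVs in descending length order. The matched benign record is returned as
    a copy carrying the pathogenic record's report date, emulating pairs
    submitted together.
    """
    for r in pathogenic + benign_pool:
        if r.variant_type != "deletion_cnv":
            raise ValueError("length matching applies to deletion CNVs only")
    if len(benign_pool) < len(pathogenic):
        raise ValueError(
            f"benign pool ({len(benign_pool)}) smaller than pathogenic list ({len(pathogenic)})"
        )
    remaining = list(benign_pool)
    pairs: list[tuple[VariantRecord, VariantRecord]] = []
    for p in sorted(pathogenic, key=lambda r: -r.length_bp):
        if not remaining:
            raise ValueError("benign pool exhausted during length matching")
        j = min(
            range(len(remaining)),
            key=lambda k: abs(math.log(remaining[k].length_bp) - math.log(p.length_bp)),
        )
        b = remaining.pop(j)
        pairs.append((p, replace(b, report_date=p.report_date)))
    return pairs


def partition_random_iid(
    train: dict[str, list[VariantRecord]],
    n_partitions: int,
    seed: int,
) -> Iterator[dict[str, list[VariantRecord]]]:
    """Yield random reassignments of all training records to the same silos.

    Every partition preserves the original per-silo sample sizes exactly while
    shuffling which records each silo holds, producing identically distributed
    virtual clients from a possibly non-IID original partition. Records are
    re-tagged with their new silo_id.
    """
    silo_ids = list(train.keys())
    sizes = [len(train[s]) for s in silo_ids]
    pool = [r for s in silo_ids for r in train[s]]
    rng = np.random.default_rng(seed)
    for _ in range(n_partitions):
        order = rng.permutation(len(pool))
        out: dict[str, list[VariantRecord]] = {}
        pos = 0
        for silo_id, n in zip(silo_ids, sizes):
            out[silo_id] = [
                dataclasses.replace(pool[k], silo_id=silo_id)
                for k in order[pos:pos + n]
            ]
            pos += n
        yield out
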