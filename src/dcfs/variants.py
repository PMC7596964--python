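"""Annotated somatic-variant records, the 3-step filter, and matrix building.

Somatic callers emit far more variants than are plausibly linked to a
tumor phenotype. The 3-step filter keeps only calls that are

1. protein-affecting: in a coding region (exonic, 3' UTR or 5' UTR) and
   nonsynonymous — synonymous and ambiguous calls are removed;
2. not common polymorphisms: absent from gnomAD, ESP6500 and ExAC —
   unless the variant is catalogued in COSMIC, in which case it is kept
   regardless (a known cancer variant is not disqualified by also being
   a known population variant);
3. reliable somatic signal: variant allele FREQ >= 10 (percent) in the
   tumor, FREQ exactly 0 in the matched normal, and a Fisher's exact
   test p-value <= 0.01.

The surviving calls are pivoted into a samples x variants matrix: one
column per distinct (chrom, pos, ref, alt) key, binary presence by
default or the tumor FREQ value on request.

Annotation is upstream (e.g. ANNOVAR output); this module consumes its
fields from a TSV with a configurable column mapping.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .matrix import POSITIVE, FeatureMatrix, normalize_class_label

logger = logging.getLogger(__name__)


class Region(str, enum.Enum):
    EXONIC = "exonic"
    UTR3 = "utr3"
    UTR5 = "utr5"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    OTHER = "other"


class Consequence(str, enum.Enum):
    NONSYNONYMOUS = "nonsynonymous"
    SYNONYMOUS = "synonymous"
    AMBIGUOUS = "ambiguous"
    OTHER = "other"


#: coding regions retained by step 1
CODING_REGIONS = frozenset({Region.EXONIC, Region.UTR3, Region.UTR5})


@dataclass(frozen=True)
class VariantKey:
    """Identity of a variant across samples (CHR/START/REF/ALT)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant call for one sample."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    region: Region
    consequence: Consequence
    in_gnomad: bool
    in_esp6500: bool
    in_exac: bool
    in_cosmic: bool
    tumor_freq: float
    normal_freq: float
    fisher_p: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, got {self.ref!r}")
        for name in ("tumor_freq", "normal_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
        if not 0.0 <= self.fisher_p <= 1.0:
            raise ValueError(f"fisher_p must be in [0, 1], got {self.fisher_p}")

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


def compute_freq(alt_reads: int, total_reads: int) -> float:
    """Variant allele FREQ: the percentage of reads carrying the variant.

    E.g. 6 variant-supporting reads out of 10 give (6/10)*100 = 60.
    """
    if total_reads < 1:
        raise ValueError("total_reads must be >= 1")
    if not 0 <= alt_reads <= total_reads:
        raise ValueError("alt_reads must be between 0 and total_reads")
    return (alt_reads / total_reads) * 100.0


def fisher_exact_p(tumor_alt: int, tumor_ref: int, normal_alt: int, normal_ref: int) -> float:
    """Two-sided Fisher's exact p on the tumor/normal alt/ref read table.

    Convenience for tables whose caller did not already report one; the
    filter itself only consumes the per-record ``fisher_p`` field.
    """
    _, p = fisher_exact([[tumor_alt, tumor_ref], [normal_alt, normal_ref]])
    return float(p)


# ---- the 3-step filter ---------------------------------------------------


def passes_step1(r: VariantRecord) -> bool:
    return r.region in CODING_REGIONS and r.consequence is Consequence.NONSYNONYMOUS


def passes_step2(r: VariantRecord) -> bool:
    return r.in_cosmic or not (r.in_gnomad or r.in_esp6500 or r.in_exac)


def passes_step3(r: VariantRecord, min_tumor_freq: float = 10.0, max_fisher_p: float = 0.01) -> bool:
    return r.tumor_freq >= min_tumor_freq and r.normal_freq == 0.0 and r.fisher_p <= max_fisher_p


def filter_step1(records) -> list[VariantRecord]:
    """Keep coding-region, nonsynonymous calls; order preserved."""
    return [r for r in records if passes_step1(r)]


def filter_step2(records) -> list[VariantRecord]:
    """Drop population-database variants unless COSMIC rescues them."""
    return [r for r in records if passes_step2(r)]


def filter_step3(records, min_tumor_freq: float = 10.0, max_fisher_p: float = 0.01) -> list[VariantRecord]:
    """Keep reliable somatic calls: tumor FREQ >= threshold, normal FREQ 0,
    Fisher p within bound."""
    return [r for r in records if passes_step3(r, min_tumor_freq, max_fisher_p)]


def failed_step(r: VariantRecord, min_tumor_freq: float = 10.0, max_fisher_p: float = 0.01) -> int:
    """First filter step the record fails (1-3), or 0 if it survives all."""
    if not passes_step1(r):
        return 1
    if not passes_step2(r):
        return 2
    if not passes_step3(r, min_tumor_freq, max_fisher_p):
        return 3
    return 0


@dataclass
class FilterReport:
    survivors: list[VariantRecord]
    counts: dict[str, int]  # record counts after each step


def filter_variants(records, min_tumor_freq: float = 10.0, max_fisher_p: float = 0.01) -> FilterReport:
    """Apply the 3 steps in order, reporting the post-step counts."""
    records = list(records)
    s1 = filter_step1(records)
    s2 = filter_step2(s1)
    s3 = filter_step3(s2, min_tumor_freq, max_fisher_p)
    return FilterReport(
        survivors=s3,
        counts={"input": len(records), "step1": len(s1), "step2": len(s2), "step3": len(s3)},
    )


# ---- table IO ------------------------------------------------------------

#: default column-name mapping of the annotated variant TSV
DEFAULT_COLUMNS = {
    "sample_id": "sample_id",
    "chrom": "chrom",
    "pos": "pos",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "region": "region",
    "consequence": "consequence",
    "in_gnomad": "in_gnomad",
    "in_esp6500": "in_esp6500",
    "in_exac": "in_exac",
    "in_cosmic": "in_cosmic",
    "tumor_freq": "tumor_freq",
    "normal_freq": "normal_freq",
    "fisher_p": "fisher_p",
}

_ANNOTATION_FIELDS = ("region", "consequence", "in_gnomad", "in_esp6500", "in_exac", "in_cosmic")


def _to_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    text = str(v).strip().lower()
    if text in {"1", "true", "t", "yes", "y"}:
        return True
    if text in {"0", "false", "f", "no", "n"}:
        return False
    raise ValueError(f"cannot interpret {v!r} as a boolean flag")


def read_variant_table(path, columns: dict | None = None, missing_policy: str = "drop") -> list[VariantRecord]:
    """Read an annotated variant TSV into records.

    ``missing_policy`` controls rows with missing annotation fields:
    "drop" (default) removes them with a logged warning; "keep" maps a
    missing region/consequence to "other" and missing flags to False.
    """
    if missing_policy not in ("drop", "keep"):
        raise ValueError("missing_policy must be 'drop' or 'keep'")
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        unknown = set(columns) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown record fields in column mapping: {sorted(unknown)}")
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in colmap.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    records: list[VariantRecord] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        raw = {field: getattr(row, colmap[field]) for field in colmap}
        incomplete = [f for f in _ANNOTATION_FIELDS if pd.isna(raw[f])]
        if incomplete:
            if missing_policy == "drop":
                n_dropped += 1
                continue
            for f in incomplete:
                raw[f] = "other" if f in ("region", "consequence") else False
        records.append(
            VariantRecord(
                sample_id=str(raw["sample_id"]),
                chrom=str(raw["chrom"]),
                pos=int(raw["pos"]),
                ref=str(raw["ref"]),
                alt=str(raw["alt"]),
                gene=str(raw["gene"]),
                region=Region(str(raw["region"]).lower()),
                consequence=Consequence(str(raw["consequence"]).lower()),
                in_gnomad=_to_bool(raw["in_gnomad"]),
                in_esp6500=_to_bool(raw["in_esp6500"]),
                in_exac=_to_bool(raw["in_exac"]),
                in_cosmic=_to_bool(raw["in_cosmic"]),
                tumor_freq=float(raw["tumor_freq"]),
                normal_freq=float(raw["normal_freq"]),
                fisher_p=float(raw["fisher_p"]),
            )
        )
    if n_dropped:
        logger.warning("dropped %d records with missing annotation fields", n_dropped)
    return records


def records_to_frame(records, min_tumor_freq: float = 10.0, max_fisher_p: float = 0.01) -> pd.DataFrame:
    """Tabulate records with a ``filter_step_failed`` audit column
    (0 = survives the full 3-step filter)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "gene": r.gene,
                "region": r.region.value,
                "consequence": r.consequence.value,
                "in_gnomad": r.in_gnomad,
                "in_esp6500": r.in_esp6500,
                "in_exac": r.in_exac,
                "in_cosmic": r.in_cosmic,
                "tumor_freq": r.tumor_freq,
                "normal_freq": r.normal_freq,
                "fisher_p": r.fisher_p,
                "filter_step_failed": failed_step(r, min_tumor_freq, max_fisher_p),
            }
        )
    return pd.DataFrame(rows)


# ---- matrix construction -------------------------------------------------


def build_matrix(records, labels: dict, encoding: str = "binary") -> FeatureMatrix:
    """Pivot records into a samples x variants matrix.

    One row per labeled sample (label-file order), one column per
    distinct variant key (first-appearance order). ``encoding``:
    "binary" sets e_sv = 1 where sample s carries variant v, "freq"
    stores the tumor FREQ instead (last record wins on duplicates).
    """
    if encoding not in ("binary", "freq"):
        raise ValueError("encoding must be 'binary' or 'freq'")
    records = list(records)
    labels = {str(k): normalize_class_label(v) for k, v in labels.items()}
    unlabeled = sorted({r.sample_id for r in records} - set(labels))
    if unlabeled:
        raise ValueError(f"records reference unlabeled samples: {unlabeled}")
    sample_ids = list(labels)
    sample_index = {s: i for i, s in enumerate(sample_ids)}
    keys: list[VariantKey] = []
    key_index: dict[VariantKey, int] = {}
    for r in records:
        if r.key not in key_index:
            key_index[r.key] = len(keys)
            keys.append(r.key)
    X = np.zeros((len(sample_ids), len(keys)))
    for r in records:
        value = 1.0 if encoding == "binary" else r.tumor_freq
        X[sample_index[r.sample_id], key_index[r.key]] = value
    c_pos = np.array([1 if labels[s] == POSITIVE else 0 for s in sample_ids])
    return FeatureMatrix(
        X=X, sample_ids=sample_ids, feature_ids=[str(k) for k in keys], c_pos=c_pos
    )


__all__ = [
    "Region",
    "Consequence",
    "CODING_REGIONS",
    "VariantKey",
    "VariantRecord",
    "compute_freq",
    "fisher_exact_p",
    "passes_step1",
    "passes_step2",
    "passes_step3",
    "filter_step1",
    "filter_step2",
    "filter_step3",
    "failed_step",
    "FilterReport",
    "filter_variants",
    "read_variant_table",
    "records_to_frame",
    "build_matrix",
    "DEFAULT_COLUMNS",
]
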