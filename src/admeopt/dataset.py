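"""Variant dataset: records, activity-derived labels, and TSV readers/writers.

The input dialect is the tab-separated score table produced by annotating
variants with ANNOVAR/dbNSFP: one row per single-nucleotide variant, one
column per prediction algorithm, with ``.`` or an empty cell marking a
score the method could not produce. The experimental ground truth is the
variant's in-vitro activity as a fraction of wild-type intrinsic
clearance; a variant is labeled deleterious when its activity is reduced
more than 2-fold (activity < 0.5).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .registry import AlgorithmSpec, registry_by_name


class Label(str, enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"


class ActivityBin(str, enum.Enum):
    """Graded functionality bins used for stratified evaluation."""

    LOF = "lof"                    # < 10% of wild-type activity
    DECREASED = "decreased"        # 10% <= activity < 50%
    MODERATE = "moderate"          # 50% <= activity <= 90%
    NEUTRAL_BIN = "neutral_bin"    # > 90% of wild-type activity


class MafBin(str, enum.Enum):
    VERY_RARE = "very_rare"  # MAF < 0.1%
    RARE = "rare"            # 0.1% <= MAF < 1%
    COMMON = "common"        # MAF >= 1%


#: Activity midpoints used when regressing consensus score on activity bin.
ACTIVITY_BIN_MIDPOINTS = {
    ActivityBin.LOF: 0.05,
    ActivityBin.DECREASED: 0.30,
    ActivityBin.MODERATE: 0.70,
    ActivityBin.NEUTRAL_BIN: 0.95,
}

#: Cell values treated as a missing score (ANNOVAR convention), plus empty.
MISSING_SENTINELS = (".", "")


def label_from_activity(activity: float, cutoff: float = 0.5) -> Label:
    """Dichotomize in-vitro activity: deleterious iff activity < cutoff.

    "More than 2-fold reduced" is strict, so an activity of exactly the
    cutoff is neutral.
    """
    if activity < 0:
        raise ValidationError(f"activity must be >= 0, got {activity}")
    return Label.DELETERIOUS if activity < cutoff else Label.NEUTRAL


def activity_bin(activity: float) -> ActivityBin:
    """Assign an activity to one of four graded functionality bins.

    Boundaries follow the strict "<10%" / ">90%" readings: lof is
    [0, 0.10), decreased [0.10, 0.50), moderate [0.50, 0.90] and
    neutral_bin (0.90, inf); 0.50 falls in moderate because deleterious
    requires a strictly more than 2-fold reduction.
    """
    if activity < 0:
        raise ValidationError(f"activity must be >= 0, got {activity}")
    if activity < 0.10:
        return ActivityBin.LOF
    if activity < 0.50:
        return ActivityBin.DECREASED
    if activity <= 0.90:
        return ActivityBin.MODERATE
    return ActivityBin.NEUTRAL_BIN


def maf_bin(maf: float) -> MafBin:
    """Bin a minor allele frequency: very rare <0.1%, rare <1%, common >=1%."""
    if not 0 <= maf <= 1:
        raise ValidationError(f"maf must be in [0, 1], got {maf}")
    if maf < 0.001:
        return MafBin.VERY_RARE
    if maf < 0.01:
        return MafBin.RARE
    return MafBin.COMMON


@dataclass
class VariantRecord:
    """One annotated variant with its experimental activity and scores.

    ``activity`` is the variant's intrinsic clearance relative to the
    wild-type allele; values above 1 (gain of function) are allowed.
    ``scores`` maps registry algorithm names to scores; algorithms that
    returned nothing are simply absent from the map.
    """

    variant_id: str
    activity: float
    gene: Optional[str] = None
    rsid: Optional[str] = None
    coords: Optional[tuple] = None  # (build, chrom, pos 1-based, ref, alt)
    aa_change: Optional[str] = None
    maf: Optional[float] = None
    scores: dict[str, float] = field(default_factory=dict)
    label_override: Optional[Label] = None

    def __post_init__(self):
        if self.activity < 0:
            raise ValidationError(
                f"{self.variant_id}: activity must be >= 0, got {self.activity}"
            )
        if self.maf is not None and not 0 <= self.maf <= 1:
            raise ValidationError(
                f"{self.variant_id}: maf must be in [0, 1], got {self.maf}"
            )

    @property
    def label(self) -> Label:
        if self.label_override is not None:
            return self.label_override
        return label_from_activity(self.activity)

    @property
    def bin(self) -> ActivityBin:
        return activity_bin(self.activity)

    def score(self, algorithm: str) -> Optional[float]:
        return self.scores.get(algorithm)


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_dataset`."""

    n_read: int
    n_kept: int
    n_excluded_all_missing: int
    excluded_ids: list[str] = field(default_factory=list)

    def __str__(self):
        return (
            f"{self.n_read} rows read, {self.n_kept} kept, "
            f"{self.n_excluded_all_missing} excluded (no score from any method)"
        )


@dataclass
class Dataset:
    """An ordered collection of variant records plus the algorithm registry."""

    records: list[VariantRecord]
    registry: list[AlgorithmSpec]

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise ValidationError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(rec.variant_id)
        known = {spec.name for spec in self.registry}
        for rec in self.records:
            unknown = set(rec.scores) - known
            if unknown:
                raise ValidationError(
                    f"{rec.variant_id}: scores for algorithms not in registry: "
                    f"{sorted(unknown)}"
                )

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def algorithm_names(self) -> list[str]:
        return [spec.name for spec in self.registry]

    def spec(self, algorithm: str) -> AlgorithmSpec:
        try:
            return registry_by_name(self.registry)[algorithm]
        except KeyError:
            raise ValidationError(f"unknown algorithm {algorithm!r}") from None

    def labels(self) -> list[Label]:
        return [rec.label for rec in self.records]

    def subset(self, variant_ids) -> "Dataset":
        wanted = set(variant_ids)
        return Dataset(
            records=[r for r in self.records if r.variant_id in wanted],
            registry=self.registry,
        )

    def missingness(self) -> dict[str, int]:
        """Number of records without a score, per algorithm."""
        return {
            name: sum(1 for rec in self.records if name not in rec.scores)
            for name in self.algorithm_names
        }


_META_COLUMNS = (
    "variant_id", "gene", "rsid", "build", "chrom", "pos", "ref", "alt",
    "aa_change", "activity", "maf", "label_override",
)


def _parse_float(cell, row_label, column) -> Optional[float]:
    if cell is None:
        return None
    text = str(cell).strip()
    if text in MISSING_SENTINELS or text.lower() == "nan":
        return None
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"cannot parse {text!r} as a number (row {row_label}, column {column!r})",
            row=row_label,
            column=column,
        ) from None


def load_dataset(
    path,
    registry: list[AlgorithmSpec],
    column_map: Optional[dict[str, str]] = None,
) -> tuple[Dataset, LoadReport]:
    """Read a tab-separated annotated score table into a :class:`Dataset`.

    Parameters
    ----------
    path
        TSV with a header row; required columns ``variant_id`` and
        ``activity``. One column per registry algorithm, matched by the
        algorithm's name, its ``input_column`` (the dbNSFP header), or an
        entry in ``column_map``.
    registry
        Algorithm specifications describing the score columns.
    column_map
        Optional mapping from file column name to registry algorithm name
        (e.g. ``{"SIFT_score": "SIFT"}``), overriding the defaults.

    Returns
    -------
    (Dataset, LoadReport)
        Records whose score cells are all missing are dropped (no method
        could assess them) and counted in the report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    for required in ("variant_id", "activity"):
        if required not in df.columns:
            raise SchemaError(f"required column {required!r} missing from {path}")

    # Resolve which file column feeds which algorithm.
    colmap: dict[str, str] = {}
    for spec in registry:
        if spec.name in df.columns:
            colmap[spec.name] = spec.name
        elif spec.input_column in df.columns:
            colmap[spec.name] = spec.input_column
    if column_map:
        for file_col, algo in column_map.items():
            if file_col in df.columns:
                colmap[algo] = file_col

    records: list[VariantRecord] = []
    excluded: list[str] = []
    seen_ids = set()
    for idx, row in df.iterrows():
        vid = str(row["variant_id"]).strip()
        if vid in seen_ids:
            raise ValidationError(f"duplicate variant_id {vid!r}")
        seen_ids.add(vid)
        activity = _parse_float(row["activity"], vid, "activity")
        if activity is None:
            raise ParseError(
                f"missing activity for variant {vid!r}", row=vid, column="activity"
            )
        scores = {}
        for algo, col in colmap.items():
            val = _parse_float(row.get(col), vid, col)
            if val is not None:
                scores[algo] = val
        if not scores:
            excluded.append(vid)
            continue

        maf = _parse_float(row.get("maf"), vid, "maf") if "maf" in df.columns else None
        coords = None
        if all(c in df.columns for c in ("chrom", "pos", "ref", "alt")):
            pos_val = str(row["pos"]).strip()
            if pos_val not in MISSING_SENTINELS:
                coords = (
                    str(row.get("build", "")).strip() or None,
                    str(row["chrom"]).strip(),
                    int(pos_val),
                    str(row["ref"]).strip(),
                    str(row["alt"]).strip(),
                )
        override = None
        if "label_override" in df.columns:
            cell = str(row["label_override"]).strip()
            if cell not in MISSING_SENTINELS:
                override = Label(cell)

        def _opt(col):
            if col not in df.columns:
                return None
            cell = str(row[col]).strip()
            return cell if cell not in MISSING_SENTINELS else None

        records.append(
            VariantRecord(
                variant_id=vid,
                activity=activity,
                gene=_opt("gene"),
                rsid=_opt("rsid"),
                coords=coords,
                aa_change=_opt("aa_change"),
                maf=maf,
                scores=scores,
                label_override=override,
            )
        )

    report = LoadReport(
        n_read=len(df),
        n_kept=len(records),
        n_excluded_all_missing=len(excluded),
        excluded_ids=excluded,
    )
    return Dataset(records=records, registry=registry), report


def dataset_from_frame(
    df: pd.DataFrame,
    registry: list[AlgorithmSpec],
    column_map: Optional[dict[str, str]] = None,
) -> Dataset:
    """Build a Dataset from an in-memory DataFrame (same dialect as the TSV).

    NaN cells count as missing; rows with no score from any method are
    dropped, matching :func:`load_dataset`.
    """
    for required in ("variant_id", "activity"):
        if required not in df.columns:
            raise SchemaError(f"required column {required!r} missing")
    colmap: dict[str, str] = {}
    for spec in registry:
        if spec.name in df.columns:
            colmap[spec.name] = spec.name
        elif spec.input_column in df.columns:
            colmap[spec.name] = spec.input_column
    if column_map:
        for file_col, algo in column_map.items():
            if file_col in df.columns:
                colmap[algo] = file_col

    records = []
    for _, row in df.iterrows():
        vid = str(row["variant_id"])
        scores = {}
        for algo, col in colmap.items():
            val = row[col]
            if val is None or (isinstance(val, float) and math.isnan(val)):
                continue
            if isinstance(val, str):
                val = _parse_float(val, vid, col)
                if val is None:
                    continue
            scores[algo] = float(val)
        if not scores:
            continue

        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return v

        maf = _opt("maf")
        override = _opt("label_override")
        records.append(
            VariantRecord(
                variant_id=vid,
                activity=float(row["activity"]),
                gene=_opt("gene"),
                rsid=_opt("rsid"),
                aa_change=_opt("aa_change"),
                maf=float(maf) if maf is not None else None,
                scores=scores,
                label_override=Label(override) if override else None,
            )
        )
    return Dataset(records=records, registry=registry)


def write_dataset(dataset: Dataset, path, provenance: Optional[str] = None) -> None:
    """Write a dataset back to the TSV dialect read by :func:`load_dataset`.

    Floats are rendered with ``repr`` (shortest round-trip form) so a
    write/load cycle reproduces every value bit-exactly; missing scores
    are written as ``.``.
    """

    def fmt(x):
        if x is None:
            return "."
        if isinstance(x, float):
            return repr(x)
        return str(x)

    names = dataset.algorithm_names
    has_coords = any(rec.coords for rec in dataset.records)
    has_override = any(rec.label_override for rec in dataset.records)
    header = ["variant_id", "gene", "rsid", "aa_change", "activity", "maf"]
    if has_coords:
        header = header[:4] + ["build", "chrom", "pos", "ref", "alt"] + header[4:]
    if has_override:
        header.append("label_override")
    header += names

    with open(path, "w", encoding="utf-8") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        fh.write("\t".join(header) + "\n")
        for rec in dataset.records:
            cells = [rec.variant_id, fmt(rec.gene), fmt(rec.rsid), fmt(rec.aa_change)]
            if has_coords:
                if rec.coords:
                    build, chrom, pos, ref, alt = rec.coords
                    cells += [fmt(build), chrom, str(pos), ref, alt]
                else:
                    cells += ["."] * 5
            cells += [repr(float(rec.activity)), fmt(rec.maf)]
            if has_override:
                cells.append(rec.label_override.value if rec.label_override else ".")
            cells += [fmt(rec.scores.get(name)) for name in names]
            fh.write("\t".join(cells) + "\n")
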