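"""Registry of in-silico prediction algorithms and their thresholds.

Each entry records how one upstream predictor (SIFT, CADD, ...) is read:
which way its score points (some flag deleterious variants with *low*
scores, some with *high* ones), the conventional cutoff quoted in the
literature, and the cutoff re-calibrated on pharmacogenetic activity data.
The default registry covers the 18 methods routinely annotated through
ANNOVAR/dbNSFP: eight functionality predictors, six evolutionary
conservation scores (PhyloP and PhastCons each in a vertebrate and a
mammalian flavor, and without literature cutoffs), and four ensemble
scores.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ValidationError


class Direction(str, enum.Enum):
    """Which side of the threshold is called deleterious (strict inequality)."""

    LESS = "deleterious_if_less"
    GREATER = "deleterious_if_greater"

    def flipped(self) -> "Direction":
        return Direction.GREATER if self is Direction.LESS else Direction.LESS


class Category(str, enum.Enum):
    FUNCTIONALITY = "functionality"
    CONSERVATION = "conservation"
    ENSEMBLE = "ensemble"


@dataclass(frozen=True)
class AlgorithmSpec:
    """One prediction method: orientation, cutoffs, score range, input column.

    ``conventional_threshold`` is the literature default (``None`` where the
    literature provides none); ``optimized_threshold`` is the cutoff that
    maximizes informedness on pharmacogenetic data. Both are interpreted
    with the strict inequality given by ``direction``.
    """

    name: str
    direction: Direction
    nominal_range: tuple[float, float]
    input_column: str
    category: Category
    conventional_threshold: Optional[float] = None
    optimized_threshold: Optional[float] = None

    def __post_init__(self):
        lo, hi = self.nominal_range
        if not lo < hi:
            raise ValidationError(
                f"{self.name}: nominal_range low must be < high, got ({lo}, {hi})"
            )
        for label, thr in (
            ("conventional", self.conventional_threshold),
            ("optimized", self.optimized_threshold),
        ):
            if thr is not None and not (lo <= thr <= hi):
                raise ValidationError(
                    f"{self.name}: {label} threshold {thr} outside nominal range ({lo}, {hi})"
                )

    def calls_deleterious(self, score: float, threshold: float) -> bool:
        """Strict-inequality call of a single score against a threshold."""
        if self.direction is Direction.LESS:
            return score < threshold
        return score > threshold

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "direction": self.direction.value,
            "conventional_threshold": self.conventional_threshold,
            "optimized_threshold": self.optimized_threshold,
            "nominal_range": list(self.nominal_range),
            "input_column": self.input_column,
            "category": self.category.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlgorithmSpec":
        return cls(
            name=d["name"],
            direction=Direction(d["direction"]),
            conventional_threshold=d.get("conventional_threshold"),
            optimized_threshold=d.get("optimized_threshold"),
            nominal_range=tuple(d["nominal_range"]),
            input_column=d["input_column"],
            category=Category(d["category"]),
        )


_LESS = Direction.LESS
_GREATER = Direction.GREATER
_FUN = Category.FUNCTIONALITY
_CON = Category.CONSERVATION
_ENS = Category.ENSEMBLE

# (name, direction, conventional, optimized, nominal_range, dbNSFP column, category)
_DEFAULT_ENTRIES = [
    ("SIFT", _LESS, 0.05, 0.0376, (0.0, 1.0), "SIFT_score", _FUN),
    ("PolyPhen-2", _GREATER, 0.447, 0.3841, (0.0, 1.0), "Polyphen2_HDIV_score", _FUN),
    ("LRT", _LESS, 0.001, 0.0025, (0.0, 1.0), "LRT_score", _FUN),
    ("MutationAssessor", _GREATER, 1.9, 2.0566, (-6.0, 6.5), "MutationAssessor_score", _FUN),
    ("FATHMM", _LESS, -1.5, 0.486, (-17.0, 11.0), "FATHMM_score", _FUN),
    ("FATHMM-MKL", _GREATER, 0.73, 0.3982, (0.0, 1.0), "fathmm-MKL_coding_score", _FUN),
    ("PROVEAN", _LESS, -2.5, -3.286, (-14.0, 14.0), "PROVEAN_score", _FUN),
    ("VEST3", _GREATER, 0.9, 0.4534, (0.0, 1.0), "VEST3_score", _FUN),
    ("GERP++", _GREATER, 4.4, 1.2482, (-12.5, 6.5), "GERP++_RS", _CON),
    ("SiPhy", _GREATER, 12.17, 7.2442, (0.0, 38.0), "SiPhy_29way_logOdds", _CON),
    ("PhyloP (vertebrate)", _GREATER, None, 0.5216, (-20.0, 10.0), "phyloP7way_vertebrate", _CON),
    ("PhyloP (mammalian)", _GREATER, None, 0.0461, (-20.0, 10.0), "phyloP20way_mammalian", _CON),
    ("PhastCons (vertebrate)", _GREATER, None, 0.07, (0.0, 1.0), "phastCons7way_vertebrate", _CON),
    ("PhastCons (mammalian)", _GREATER, None, 0.1872, (0.0, 1.0), "phastCons20way_mammalian", _CON),
    ("CADD", _GREATER, 15.0, 19.19, (0.0, 99.0), "CADD_phred", _ENS),
    ("DANN", _GREATER, 0.99, 0.9688, (0.0, 1.0), "DANN_score", _ENS),
    ("MetaSVM", _GREATER, 0.0, -0.3371, (-2.0, 3.0), "MetaSVM_score", _ENS),
    ("MetaLR", _GREATER, 0.5, 0.4039, (0.0, 1.0), "MetaLR_score", _ENS),
]


def default_registry() -> list[AlgorithmSpec]:
    """The 18-method registry with conventional and pharmacogenetically
    re-optimized thresholds.

    PhyloP and PhastCons carry no conventional threshold: the literature
    provides no standard cutoff for raw conservation scores.
    """
    return [
        AlgorithmSpec(
            name=name,
            direction=direction,
            conventional_threshold=conv,
            optimized_threshold=opt,
            nominal_range=rng,
            input_column=col,
            category=cat,
        )
        for name, direction, conv, opt, rng, col, cat in _DEFAULT_ENTRIES
    ]


def registry_by_name(registry: list[AlgorithmSpec]) -> dict[str, AlgorithmSpec]:
    return {spec.name: spec for spec in registry}


def save_registry(registry: list[AlgorithmSpec], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {"algorithms": [spec.to_dict() for spec in registry]},
            fh,
            sort_keys=False,
        )


def load_registry(path) -> list[AlgorithmSpec]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    return [AlgorithmSpec.from_dict(d) for d in payload["algorithms"]]
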