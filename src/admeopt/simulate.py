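"""Synthetic annotated score tables with known generative truth.

The generator emulates the structure of a pharmacogenetic benchmark
table: two activity classes spread over graded activity bins, one score
column per prediction algorithm with algorithm-specific scale,
orientation, discriminative power and missingness, and log-uniform minor
allele frequencies.

Scores follow an equal-variance binormal model with a graded mean: on a
raw standard-normal scale a variant scores N(d * severity, 1), where
severity is 1 below 10% of wild-type activity, declines linearly to 0 at
90%, and d = sqrt(2) * Phi^-1(AUC) is chosen per algorithm to hit its
target AUC for the severe-vs-neutral contrast. Partially functional
variants therefore receive intermediate scores — as real predictors
produce — while the extreme bins stay exactly binormal, so threshold
calibration and combination search can be checked against closed forms
(optimal raw cutoff d/2, maximal J = 2*Phi(d/2) - 1) by simulating only
the extreme bins. A shared latent factor with loading sqrt(rho) induces
the between-algorithm correlation real predictors show (they share
conservation features). Raw scores are mapped affinely onto each
algorithm's nominal range, negated first for deleterious-if-less methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy.stats import norm

from .dataset import Dataset, VariantRecord, label_from_activity
from .errors import ValidationError
from .registry import AlgorithmSpec, Category, Direction


def expected_max_informedness(d: float) -> float:
    """Closed-form maximal Youden index for equal-variance binormal scores
    separated by d standard deviations: J = 2*Phi(d/2) - 1."""
    if d < 0:
        raise ValidationError(f"separation d must be >= 0, got {d}")
    return float(2.0 * norm.cdf(d / 2.0) - 1.0)


def separation_for_auc(target_auc: float) -> float:
    """d such that the binormal AUC Phi(d / sqrt(2)) equals target_auc."""
    return float(np.sqrt(2.0) * norm.ppf(target_auc))


@dataclass(frozen=True)
class SyntheticAlgorithm:
    """Generative description of one simulated prediction method."""

    name: str
    direction: Direction
    nominal_range: tuple[float, float]
    target_auc: float
    missing_rate: float = 0.0
    category: Category = Category.FUNCTIONALITY

    def __post_init__(self):
        if not 0.5 < self.target_auc < 1.0:
            raise ValidationError(
                f"{self.name}: target_auc must be in (0.5, 1), got {self.target_auc}"
            )
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError(
                f"{self.name}: missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        lo, hi = self.nominal_range
        if not lo < hi:
            raise ValidationError(f"{self.name}: bad nominal_range ({lo}, {hi})")


# Activity intervals sampled within each bin. Neutral-bin activities run
# up to 1.2: mild gain-of-function values above wild type occur in vitro.
_BIN_INTERVALS = (
    ("lof", 0.0, 0.10),
    ("decreased", 0.10, 0.50),
    ("moderate", 0.50, 0.90),
    ("neutral_bin", 0.90, 1.20),
)

#: Raw-score support mapped onto the nominal range (mean 0/d plus 4 sd).
_RAW_PAD = 4.0


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror a realistic pharmacogenetic benchmark: 337 variants
    with roughly a third complete loss-of-function and a fifth
    functionally neutral, an 18-method panel with heterogeneous
    discriminative power, moderate between-method correlation, and MAFs
    log-uniform from 1e-5 to ~0.3 (most variants rare).
    """

    n_variants: int = 337
    bin_weights: tuple[float, float, float, float] = (0.32, 0.27, 0.20, 0.21)
    algorithms: list[SyntheticAlgorithm] = field(default_factory=lambda: default_panel())
    latent_correlation: float = 0.3
    maf_log10_range: tuple[float, float] = (-5.0, -0.5)
    seed: int = 1

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValidationError("n_variants must be >= 1")
        if abs(sum(self.bin_weights) - 1.0) > 1e-9:
            raise ValidationError(
                f"bin_weights must sum to 1, got {sum(self.bin_weights)}"
            )
        if any(w < 0 for w in self.bin_weights):
            raise ValidationError("bin_weights must be non-negative")
        if not 0.0 <= self.latent_correlation < 1.0:
            raise ValidationError("latent_correlation must be in [0, 1)")
        if not self.algorithms:
            raise ValidationError("need at least one algorithm")
        names = [a.name for a in self.algorithms]
        if len(set(names)) != len(names):
            raise ValidationError("algorithm names must be unique")
        lo, hi = self.maf_log10_range
        if not lo < hi <= 0:
            raise ValidationError("maf_log10_range must satisfy low < high <= 0")


@dataclass
class GenerativeTruth:
    """Per-algorithm ground truth of the generative model."""

    per_algorithm: dict[str, dict]

    def raw_threshold(self, name: str) -> float:
        return self.per_algorithm[name]["raw_threshold"]

    def mapped_threshold(self, name: str) -> float:
        return self.per_algorithm[name]["mapped_threshold"]

    def expected_j_max(self, name: str) -> float:
        return self.per_algorithm[name]["expected_j_max"]

    def slope(self, name: str) -> float:
        return self.per_algorithm[name]["slope"]

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"per_algorithm": self.per_algorithm}, fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "GenerativeTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(per_algorithm=yaml.safe_load(fh)["per_algorithm"])


def _affine(algo: SyntheticAlgorithm, d: float) -> tuple[float, float]:
    """(slope, intercept) mapping oriented raw scores onto nominal_range."""
    if algo.direction is Direction.GREATER:
        raw_lo, raw_hi = -_RAW_PAD, d + _RAW_PAD
    else:
        raw_lo, raw_hi = -(d + _RAW_PAD), _RAW_PAD
    lo, hi = algo.nominal_range
    slope = (hi - lo) / (raw_hi - raw_lo)
    return slope, lo - slope * raw_lo


def simulate_dataset(config: SyntheticConfig) -> tuple[Dataset, GenerativeTruth]:
    """Draw one dataset (and its generative truth) from the binormal model.

    Fully reproducible from ``config.seed``. Records that happen to lose
    every score to missingness keep the score of the least-missing
    algorithm, since a variant no method could assess would be excluded
    at load anyway.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    algos = config.algorithms
    m = len(algos)
    rho = config.latent_correlation

    bins = rng.choice(len(_BIN_INTERVALS), size=n, p=config.bin_weights)
    lows = np.array([iv[1] for iv in _BIN_INTERVALS])
    highs = np.array([iv[2] for iv in _BIN_INTERVALS])
    activity = rng.uniform(lows[bins], highs[bins])

    # graded effect size: full separation below 10% activity, none above 90%
    severity = np.clip((0.9 - activity) / 0.8, 0.0, 1.0)
    d_vec = np.array([separation_for_auc(a.target_auc) for a in algos])
    latent = rng.standard_normal(n)
    noise = rng.standard_normal((n, m))
    raw = (
        severity[:, None] * d_vec[None, :]
        + np.sqrt(rho) * latent[:, None]
        + np.sqrt(1.0 - rho) * noise
    )

    truth: dict[str, dict] = {}
    mapped = np.empty_like(raw)
    conv_thresholds = []
    for j, algo in enumerate(algos):
        d = d_vec[j]
        oriented = -raw[:, j] if algo.direction is Direction.LESS else raw[:, j]
        raw_thr = d / 2.0
        oriented_thr = -raw_thr if algo.direction is Direction.LESS else raw_thr
        slope, intercept = _affine(algo, d)
        mapped[:, j] = slope * oriented + intercept
        mapped_thr = slope * oriented_thr + intercept
        # an intentionally off-optimum "literature" cutoff at the neutral
        # class mean (oriented raw 0), so recalibration has something to gain
        conv_thr = intercept
        conv_thresholds.append(conv_thr)
        truth[algo.name] = {
            "target_auc": algo.target_auc,
            "d": float(d),
            "raw_threshold": float(raw_thr),
            "mapped_threshold": float(mapped_thr),
            "expected_j_max": expected_max_informedness(d),
            "slope": float(slope),
            "intercept": float(intercept),
            "direction": algo.direction.value,
            "missing_rate": algo.missing_rate,
        }

    missing = rng.random((n, m)) < np.array([a.missing_rate for a in algos])[None, :]
    # keep at least one score per record
    anchor = int(np.argmin([a.missing_rate for a in algos]))
    all_gone = missing.all(axis=1)
    missing[all_gone, anchor] = False

    lo10, hi10 = config.maf_log10_range
    maf = 10.0 ** rng.uniform(lo10, hi10, size=n)

    registry = [
        AlgorithmSpec(
            name=a.name,
            direction=a.direction,
            nominal_range=a.nominal_range,
            input_column=a.name,
            category=a.category,
            conventional_threshold=float(np.clip(conv_thresholds[j],
                                                 a.nominal_range[0],
                                                 a.nominal_range[1])),
            optimized_threshold=None,
        )
        for j, a in enumerate(algos)
    ]
    width = len(str(n))
    records = []
    for i in range(n):
        scores = {
            algos[j].name: float(mapped[i, j]) for j in range(m) if not missing[i, j]
        }
        records.append(
            VariantRecord(
                variant_id=f"sim{i + 1:0{width}d}",
                activity=float(activity[i]),
                gene="SIMGENE",
                maf=float(maf[i]),
                scores=scores,
            )
        )
    return Dataset(records=records, registry=registry), GenerativeTruth(truth)


# Target AUCs follow the spread observed for the 18 methods on
# pharmacogenetic data: ensemble scores up to 0.81, conservation scores
# down to 0.58, and one near-uninformative outlier (FATHMM-like, 0.51).
_PANEL = [
    ("SIFT", Direction.LESS, (0.0, 1.0), 0.74, 0.05, Category.FUNCTIONALITY),
    ("PolyPhen-2", Direction.GREATER, (0.0, 1.0), 0.77, 0.0, Category.FUNCTIONALITY),
    ("LRT", Direction.LESS, (0.0, 1.0), 0.75, 0.0, Category.FUNCTIONALITY),
    ("MutationAssessor", Direction.GREATER, (-6.0, 6.5), 0.78, 0.0, Category.FUNCTIONALITY),
    ("FATHMM", Direction.LESS, (-17.0, 11.0), 0.51, 0.05, Category.FUNCTIONALITY),
    ("FATHMM-MKL", Direction.GREATER, (0.0, 1.0), 0.73, 0.0, Category.FUNCTIONALITY),
    ("PROVEAN", Direction.LESS, (-14.0, 14.0), 0.76, 0.05, Category.FUNCTIONALITY),
    ("VEST3", Direction.GREATER, (0.0, 1.0), 0.80, 0.0, Category.FUNCTIONALITY),
    ("GERP++", Direction.GREATER, (-12.5, 6.5), 0.67, 0.0, Category.CONSERVATION),
    ("SiPhy", Direction.GREATER, (0.0, 38.0), 0.63, 0.0, Category.CONSERVATION),
    ("PhyloP (vertebrate)", Direction.GREATER, (-20.0, 10.0), 0.64, 0.0, Category.CONSERVATION),
    ("PhyloP (mammalian)", Direction.GREATER, (-20.0, 10.0), 0.64, 0.0, Category.CONSERVATION),
    ("PhastCons (vertebrate)", Direction.GREATER, (0.0, 1.0), 0.58, 0.0, Category.CONSERVATION),
    ("PhastCons (mammalian)", Direction.GREATER, (0.0, 1.0), 0.61, 0.0, Category.CONSERVATION),
    ("CADD", Direction.GREATER, (0.0, 99.0), 0.81, 0.0, Category.ENSEMBLE),
    ("DANN", Direction.GREATER, (0.0, 1.0), 0.75, 0.0, Category.ENSEMBLE),
    ("MetaSVM", Direction.GREATER, (-2.0, 3.0), 0.68, 0.0, Category.ENSEMBLE),
    ("MetaLR", Direction.GREATER, (0.0, 1.0), 0.68, 0.0, Category.ENSEMBLE),
]


def default_panel() -> list[SyntheticAlgorithm]:
    """An 18-method synthetic panel with realistic heterogeneity in
    discriminative power, orientation, score scale and missingness."""
    return [
        SyntheticAlgorithm(
            name=name,
            direction=direction,
            nominal_range=rng,
            target_auc=auc,
            missing_rate=miss,
            category=cat,
        )
        for name, direction, rng, auc, miss, cat in _PANEL
    ]
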