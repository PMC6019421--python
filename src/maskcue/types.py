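"""Core domain containers for the mask-detection pipeline.

The task being modelled is two-alternative categorization of single face
photographs as real faces or (hyper-realistic) masks.  The containers here
carry stimuli, landmark geometry, simulated observers, single-trial
responses, and the summary statistics the analysis stages exchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

import numpy as np


class Category(str, Enum):
    """Stimulus category in the categorization task."""

    REAL_FACE = "real_face"
    LOW_REALISM_MASK = "low_realism_mask"
    HIGH_REALISM_MASK = "high_realism_mask"

    @property
    def truth(self) -> str:
        """Ground-truth response label ("mask" or "face")."""
        return "face" if self is Category.REAL_FACE else "mask"


#: Minimum stimulus height accepted into a set (mirrors the source-image
#: inclusion rule of the emulated study design).
MIN_STIMULUS_HEIGHT = 150


@dataclass(frozen=True)
class LandmarkSet:
    """An ordered set of 2-D facial landmarks.

    Coordinates are pixels with the origin at the top-left corner,
    x rightward and y downward, 0-based.  ``schema`` names each point;
    two landmark sets are comparable only when their schemas match.
    """

    points: np.ndarray  # (n, 2) float array of (x, y)
    schema: Tuple[str, ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("landmark points must be an (n, 2) array")
        if pts.shape[0] != len(self.schema):
            raise ValueError(
                f"{pts.shape[0]} points but schema names {len(self.schema)}"
            )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def same_schema(self, other: "LandmarkSet") -> bool:
        return self.schema == other.schema

    def within_bounds(self, height: int, width: int) -> bool:
        x, y = self.points[:, 0], self.points[:, 1]
        return bool(
            (x >= 0).all() and (x <= width - 1).all()
            and (y >= 0).all() and (y <= height - 1).all()
        )


@dataclass
class StimulusImage:
    """A grayscale stimulus with its category and landmark geometry."""

    id: str
    category: Category
    pixels: np.ndarray  # (H, W) uint8
    landmarks: LandmarkSet

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        if px.shape[0] < MIN_STIMULUS_HEIGHT:
            raise ValueError(
                f"stimulus height {px.shape[0]} below minimum {MIN_STIMULUS_HEIGHT}"
            )
        if not self.landmarks.within_bounds(*px.shape):
            raise ValueError(f"landmarks outside image bounds for {self.id}")
        self.pixels = px

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def truth(self) -> str:
        return self.category.truth


@dataclass
class ObserverProfile:
    """Generative model of one simulated participant.

    The observer reads a standardized cue statistic from each of a fixed
    number of horizontal image bands, combines them with ``band_weights``,
    adds zero-mean Gaussian internal noise, and responds "mask" when the
    summed evidence exceeds ``criterion``.  With probability ``lapse_rate``
    the response is replaced by a fair coin flip.  ``prior_knowledge`` is a
    self-report rating on a 1-7 Likert scale, carried along for the
    individual-differences correlations.
    """

    id: str
    band_weights: np.ndarray
    internal_noise_sd: float
    criterion: float
    lapse_rate: float = 0.0
    prior_knowledge: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if w.ndim != 1 or (w < 0).any():
            raise ValueError("band_weights must be a 1-D non-negative vector")
        total = w.sum()
        if total <= 0:
            raise ValueError("band_weights must have positive sum")
        self.band_weights = w / total
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.5:
            raise ValueError("lapse_rate must lie in [0, 0.5]")
        if not 1 <= int(self.prior_knowledge) <= 7:
            raise ValueError("prior_knowledge must be an integer in 1..7")
        self.prior_knowledge = int(self.prior_knowledge)


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One categorization response."""

    participant_id: str
    stimulus_id: str
    condition: Category
    truth: str  # "mask" | "face"
    response: str  # "mask" | "face"
    rt_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.truth not in ("mask", "face") or self.response not in ("mask", "face"):
            raise ValueError("truth and response must be 'mask' or 'face'")
        expected = self.condition.truth
        if self.truth != expected:
            raise ValueError(
                f"truth={self.truth!r} inconsistent with condition={self.condition.value!r}"
            )
        if self.rt_ms is not None and not self.rt_ms > 0:
            raise ValueError("rt_ms must be positive when present")

    @property
    def correct(self) -> bool:
        return self.response == self.truth


@dataclass(frozen=True)
class GroupStats:
    """Mean, standard error and t-based confidence interval across participants."""

    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("SE must be non-negative")
        if not self.ci_low - 1e-12 <= self.mean <= self.ci_high + 1e-12:
            raise ValueError("mean must lie inside its confidence interval")


@dataclass(frozen=True)
class SDTSummary:
    """Signal-detection summary for one participant ("mask" = signal).

    ``dprime`` and ``criterion`` are computed from the corrected rates;
    ``pcorrect`` is the unbiased proportion correct (H + (1 - F)) / 2 and is
    always formed from the raw, uncorrected rates.
    """

    hit_rate: float
    fa_rate: float
    hit_rate_corrected: float
    fa_rate_corrected: float
    dprime: float
    criterion: float
    pcorrect: float
    n_signal: int
    n_noise: int
    correction: str = "loglinear"

    def __post_init__(self) -> None:
        if not (0.0 < self.hit_rate_corrected < 1.0 and 0.0 < self.fa_rate_corrected < 1.0):
            raise ValueError("corrected rates must lie strictly in (0, 1)")
        if not (np.isfinite(self.dprime) and np.isfinite(self.criterion)):
            raise ValueError("dprime and criterion must be finite")


@dataclass(frozen=True)
class TestResult:
    """A single inferential test statistic (t, F or r)."""

    name: str  # "t" | "F" | "r"
    value: float
    df: Tuple[int, ...]
    p: float
    effect_size: Optional[float] = None
    effect_size_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        for d in self.df:
            if d <= 0:
                raise ValueError("degrees of freedom must be positive")


@dataclass
class AverageImage:
    """A texture average of stimuli warped to a common mean shape."""

    label: str
    texture: np.ndarray  # (H, W) float, 0-255 scale
    shape: LandmarkSet  # mean-shape landmarks in the output frame
    stimulus_ids: Tuple[str, ...]
    weights: np.ndarray
    total_responses: Optional[int] = None  # response count behind a perceived average

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        if len(self.stimulus_ids) != w.size:
            raise ValueError("weights must align with stimulus_ids")
        self.weights = w


@dataclass
class DifferenceImage:
    """Signed pixelwise difference of two average images (mask minus face)."""

    values: np.ndarray  # (H, W) float, signed, unclipped
    minuend_label: str
    subtrahend_label: str

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass
class SliceCorrelationTable:
    """Per-slice Pearson correlations between two difference images.

    Slices are numbered 1-based from the top of the cropped image.  Slices
    where either vector has zero variance carry ``defined = False`` and a
    NaN correlation rather than a masquerading zero.
    """

    slice_index: np.ndarray  # (n,) int, 1-based top-down
    r: np.ndarray  # (n,) float, NaN where undefined
    defined: np.ndarray  # (n,) bool
    n_pixels: int  # pixels per slice vector
    comparison: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        ok = np.asarray(self.defined, dtype=bool)
        if (np.abs(r[ok]) > 1.0 + 1e-12).any():
            raise ValueError("defined correlations must lie in [-1, 1]")
        self.r = r
        self.defined = ok


def group_stats(values: Sequence[float], level: float = 0.95) -> GroupStats:
    """Mean, SE (sd/sqrt(n)) and t-distribution CI across participants."""
    from scipy import stats as _st

    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    n = int(v.size)
    m = float(v.mean())
    if n == 1:
        return GroupStats(mean=m, se=0.0, ci_low=m, ci_high=m, n=1, level=level)
    se = float(v.std(ddof=1) / np.sqrt(n))
    tcrit = float(_st.t.ppf(0.5 + level / 2.0, n - 1))
    return GroupStats(
        mean=m, se=se, ci_low=m - tcrit * se, ci_high=m + tcrit * se, n=n, level=level
    )
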