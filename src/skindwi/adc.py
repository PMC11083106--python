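"""Two-point ADC computation and first-order VOI statistics.

Both methods invert the mono-exponential decay between a low and a high
b-value:

    ADC = ln(S_high / S_low) / (b_low - b_high)

Method 1 applies this to the *mean* VOI signal at each b-value; method 2
applies it voxel-wise to build an ADC map, from which first-order
statistics (mean / median / min / max) are taken over the VOI. All ADC
values are in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from skindwi.io import DataError, DWIStudy, VOIMask

__all__ = [
    "BValuePair",
    "MeanSignalADC",
    "FirstOrderStats",
    "ADCResult",
    "select_bvalue_pair",
    "adc_from_mean_signal",
    "adc_map",
    "first_order_stats",
    "erode_mask",
    "compute_adc_result",
]

# acceptance window for the high b-value, s/mm^2
_HIGH_B_WINDOW = (700.0, 900.0)
_HIGH_B_PREFERRED = (800.0, 750.0)


@dataclass(frozen=True)
class BValuePair:
    """The (low, high) b-value pair used for two-point ADC estimation."""

    b_low: float
    b_high: float

    def __post_init__(self) -> None:
        if not self.b_low < self.b_high:
            raise DataError(
                f"b_low must be < b_high; got ({self.b_low}, {self.b_high})"
            )


def select_bvalue_pair(b_values) -> BValuePair:
    """Pick the two-point pair: lowest b plus the high b in [700, 900].

    Prefers exactly 800, then 750, then the window value closest to 800.
    Deterministic; raises if no b-value lies in the window.
    """
    bs = sorted(float(b) for b in b_values)
    if len(bs) < 2:
        raise DataError("need at least two b-values")
    b_low = bs[0]
    candidates = [b for b in bs if _HIGH_B_WINDOW[0] <= b <= _HIGH_B_WINDOW[1]]
    if not candidates:
        raise DataError(
            f"no b-value in [{_HIGH_B_WINDOW[0]:g}, {_HIGH_B_WINDOW[1]:g}] "
            f"s/mm^2; available: {bs}"
        )
    for pref in _HIGH_B_PREFERRED:
        if pref in candidates:
            return BValuePair(b_low, pref)
    b_high = min(candidates, key=lambda b: abs(b - 800.0))
    return BValuePair(b_low, b_high)


@dataclass(frozen=True)
class MeanSignalADC:
    """Method-1 result: ADC of the mean VOI signal, with provenance."""

    value: float  # mm^2/s
    s_mean_low: float
    s_mean_high: float
    is_negative: bool  # noise-dominated VOI flag

    def __float__(self) -> float:
        return self.value


def adc_from_mean_signal(
    study: DWIStudy, mask: VOIMask, pair: BValuePair
) -> MeanSignalADC:
    """ADC from the mean VOI signal at the two b-values (method 1).

    A negative result (mean signal rising with b, noise-dominated VOI) is
    returned with ``is_negative`` set rather than raised; *nonpositive*
    mean signal at either b-value is an error.
    """
    mask.check_congruent(study)
    s_low = float(study.volume_at(pair.b_low)[mask.data].mean())
    s_high = float(study.volume_at(pair.b_high)[mask.data].mean())
    if s_low <= 0 or s_high <= 0:
        raise DataError(
            f"nonpositive mean VOI signal (S_low={s_low}, S_high={s_high})"
        )
    value = float(np.log(s_high / s_low) / (pair.b_low - pair.b_high))
    return MeanSignalADC(
        value=value,
        s_mean_low=s_low,
        s_mean_high=s_high,
        is_negative=value < 0,
    )


def adc_map(
    study: DWIStudy, pair: BValuePair, mask: VOIMask | None = None
) -> np.ndarray:
    """Voxel-wise two-point ADC map (method 2), NaN where invalid.

    Voxels with nonpositive signal at either b-value cannot be
    log-transformed; they are marked NaN and excluded from downstream
    statistics (the exclusion count is reported there). If ``mask`` is
    given, voxels outside it are NaN as well.
    """
    s_low = study.volume_at(pair.b_low)
    s_high = study.volume_at(pair.b_high)
    valid = (s_low > 0) & (s_high > 0)
    if mask is not None:
        mask.check_congruent(study)
        valid &= mask.data
    out = np.full(study.spatial_shape, np.nan)
    out[valid] = np.log(s_high[valid] / s_low[valid]) / (
        pair.b_low - pair.b_high
    )
    return out


@dataclass(frozen=True)
class FirstOrderStats:
    """First-order summary of voxel-wise ADC over a VOI."""

    mean: float
    median: float
    min: float
    max: float
    n_voxels_used: int
    n_voxels_excluded: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
        }


def first_order_stats(adc_values: np.ndarray, mask: VOIMask) -> FirstOrderStats:
    """Mean/median/min/max of an ADC map over the valid VOI voxels.

    NaN voxels inside the VOI count as excluded; zero valid voxels is an
    error. The median of an even count is the midpoint average
    (numpy's convention).
    """
    vals = np.asarray(adc_values, dtype=float)[mask.data]
    valid = vals[np.isfinite(vals)]
    n_excluded = vals.size - valid.size
    if valid.size == 0:
        raise DataError("no valid voxels in VOI after exclusions")
    return FirstOrderStats(
        mean=float(valid.mean()),
        median=float(np.median(valid)),
        min=float(valid.min()),
        max=float(valid.max()),
        n_voxels_used=int(valid.size),
        n_voxels_excluded=int(n_excluded),
    )


def erode_mask(mask: VOIMask, rim_voxels: int = 1) -> VOIMask:
    """Erode a VOI by ``rim_voxels`` with a face-connected (6-neighbour)
    structuring element, mitigating partial-volume contamination at the
    VOI boundary. ``rim_voxels=0`` is the identity.
    """
    if rim_voxels < 0:
        raise DataError("rim_voxels must be >= 0")
    if rim_voxels == 0:
        return VOIMask(data=mask.data.copy(), name=mask.name)
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(
        mask.data, structure=structure, iterations=rim_voxels
    )
    if not eroded.any():
        raise DataError(
            f"erosion by {rim_voxels} voxel(s) empties the VOI; "
            "use rim_voxels=0 for this mask"
        )
    return VOIMask(data=eroded, name=mask.name)


@dataclass
class ADCResult:
    """Combined output of both ADC methods for one VOI."""

    adc_of_mean_signal: MeanSignalADC
    adc_map: np.ndarray = field(repr=False)
    summary: FirstOrderStats
    n_voxels_used: int
    n_voxels_excluded: int

    def __post_init__(self) -> None:
        s = self.summary
        # round-off tolerance: the mean of a constant field can differ
        # from min/max by a few ULP
        tol = 1e-9 * max(abs(s.min), abs(s.max), 1e-30)
        ordered = (
            s.min <= s.median <= s.max
            and s.min - tol <= s.mean <= s.max + tol
        )
        if not ordered:
            raise DataError("inconsistent first-order statistics ordering")


def compute_adc_result(
    study: DWIStudy, mask: VOIMask, pair: BValuePair
) -> ADCResult:
    """Run both ADC methods over one VOI and bundle the outputs."""
    mean_sig = adc_from_mean_signal(study, mask, pair)
    amap = adc_map(study, pair, mask=mask)
    summary = first_order_stats(amap, mask)
    if summary.n_voxels_used + summary.n_voxels_excluded != mask.voxel_count:
        raise DataError("voxel accounting mismatch")  # pragma: no cover
    return ADCResult(
        adc_of_mean_signal=mean_sig,
        adc_map=amap,
        summary=summary,
        n_voxels_used=summary.n_voxels_used,
        n_voxels_excluded=summary.n_voxels_excluded,
    )
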