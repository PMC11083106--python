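"""SNR estimation with Rician noise-floor correction, and the QC cutoff.

The noise level sigma is estimated from the mean signal of a background
region outside the body, where the magnitude signal is Rayleigh
distributed, via sigma = sqrt(2/pi) * mean(background). Tissue signal is
corrected for the Rician noise floor, S_corr ~= sqrt(S^2 - sigma^2), and
SNR = S_corr / sigma. Pathology cases whose high-b SNR drops below the
cutoff (default 2) are excluded; healthy-skin cases are exempt from the
cutoff but flagged as biased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from skindwi.adc import BValuePair
from skindwi.io import DataError, DWIStudy, VOIMask

__all__ = [
    "NoiseEstimate",
    "BValueSNR",
    "SNRReport",
    "estimate_sigma",
    "rician_correct",
    "compute_snr",
    "snr_qc_filter",
]

#: Rayleigh mean -> sigma conversion factor, sqrt(2/pi)
RAYLEIGH_FACTOR = math.sqrt(2.0 / math.pi)

DEFAULT_SNR_CUTOFF = 2.0
DEFAULT_EXEMPT_GROUPS = frozenset({"H"})


@dataclass(frozen=True)
class NoiseEstimate:
    """Noise floor estimated from a signal-free background ROI."""

    s_noise_mean: float
    sigma: float
    roi_voxel_count: int


def estimate_sigma(
    study: DWIStudy, noise_roi: VOIMask, b_value: float
) -> NoiseEstimate:
    """Estimate sigma from the background ROI at one b-value.

    sigma = sqrt(2/pi) * mean(ROI signal); valid for a single-channel
    magnitude reconstruction where background noise is Rayleigh.
    """
    noise_roi.check_congruent(study)
    vals = study.volume_at(b_value)[noise_roi.data]
    s_noise = float(vals.mean())
    return NoiseEstimate(
        s_noise_mean=s_noise,
        sigma=RAYLEIGH_FACTOR * s_noise,
        roi_voxel_count=int(vals.size),
    )


def rician_correct(
    tissue_signal: float, sigma: float
) -> tuple[float, bool]:
    """Remove the Rician noise floor from a measured magnitude signal.

    Returns ``(sqrt(S^2 - sigma^2), False)`` when S > sigma, and
    ``(0.0, True)`` (underflow flagged) when S <= sigma.
    """
    if tissue_signal < 0 or sigma < 0:
        raise DataError("tissue_signal and sigma must be non-negative")
    if sigma == 0:
        return float(tissue_signal), False
    if tissue_signal <= sigma:
        return 0.0, True
    return math.sqrt(tissue_signal**2 - sigma**2), False


@dataclass(frozen=True)
class BValueSNR:
    """SNR bookkeeping at a single b-value."""

    b_value: float
    tissue_signal: float
    corrected_signal: float
    sigma: float
    snr: float
    underflow: bool
    snr_is_infinite: bool


@dataclass
class SNRReport:
    """Per-case SNR at the low and high b-values plus the QC verdict."""

    case_id: str
    group: str | None
    low: BValueSNR
    high: BValueSNR
    cutoff: float
    exempt: bool
    passed: bool
    biased: bool  # set for exempt (healthy) cases below the cutoff


def _snr_at(
    study: DWIStudy,
    voi: VOIMask,
    noise_roi: VOIMask,
    b_value: float,
    use_corrected: bool,
) -> BValueSNR:
    est = estimate_sigma(study, noise_roi, b_value)
    s_tissue = float(study.volume_at(b_value)[voi.data].mean())
    corrected, underflow = rician_correct(s_tissue, est.sigma)
    numerator = corrected if use_corrected else s_tissue
    if est.sigma == 0:
        # noise-free data: SNR is not finite; flag rather than divide
        return BValueSNR(
            b_value=b_value,
            tissue_signal=s_tissue,
            corrected_signal=corrected,
            sigma=0.0,
            snr=math.inf,
            underflow=underflow,
            snr_is_infinite=True,
        )
    return BValueSNR(
        b_value=b_value,
        tissue_signal=s_tissue,
        corrected_signal=corrected,
        sigma=est.sigma,
        snr=numerator / est.sigma,
        underflow=underflow,
        snr_is_infinite=False,
    )


def compute_snr(
    study: DWIStudy,
    voi: VOIMask,
    noise_roi: VOIMask,
    pair: BValuePair,
    cutoff: float = DEFAULT_SNR_CUTOFF,
    exempt: bool = False,
    use_corrected: bool = True,
) -> SNRReport:
    """Compute the SNR report for one case at the two-point b-values.

    The pass/fail decision uses the *high*-b SNR (the limiting one);
    SNR exactly equal to the cutoff passes. ``use_corrected`` switches
    the SNR numerator between the Rician-corrected (default) and raw
    tissue signal.
    """
    voi.check_congruent(study)
    low = _snr_at(study, voi, noise_roi, pair.b_low, use_corrected)
    high = _snr_at(study, voi, noise_roi, pair.b_high, use_corrected)
    meets = high.snr >= cutoff
    return SNRReport(
        case_id=study.case_id,
        group=study.group,
        low=low,
        high=high,
        cutoff=cutoff,
        exempt=exempt,
        passed=meets or exempt,
        biased=exempt and not meets,
    )


def snr_qc_filter(
    reports: Iterable[SNRReport] | Mapping[str, SNRReport],
    cutoff: float = DEFAULT_SNR_CUTOFF,
    exempt_groups: frozenset[str] | set[str] = DEFAULT_EXEMPT_GROUPS,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Partition a cohort of SNR reports into included/excluded cases.

    Pathology cases with high-b SNR < cutoff are excluded; cases in
    ``exempt_groups`` are always retained but flagged biased when below
    the cutoff. Returns (included case_ids, excluded case_ids, QC table).
    """
    if isinstance(reports, Mapping):
        reports = list(reports.values())
    else:
        reports = list(reports)
    rows = []
    included: list[str] = []
    excluded: list[str] = []
    for rep in reports:
        exempt = rep.group in exempt_groups
        meets = rep.high.snr >= cutoff
        keep = meets or exempt
        (included if keep else excluded).append(rep.case_id)
        rows.append(
            {
                "case_id": rep.case_id,
                "group": rep.group,
                "snr_low_b": rep.low.snr,
                "snr_high_b": rep.high.snr,
                "sigma": rep.high.sigma,
                "passed": keep,
                "exempt": exempt,
                "biased": exempt and not meets,
                "reason": "" if keep else (
                    f"high-b SNR {rep.high.snr:.3g} < cutoff {cutoff:g}"
                ),
            }
        )
    return included, excluded, pd.DataFrame(rows)
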