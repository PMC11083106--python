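"""Seeded synthetic breast-skin DWI phantoms and cohort simulation.

A phantom is a simple geometric breast model on a 3D voxel grid: a ball
of "body" tissue whose outer shell is skin, an optional spherical lesion
embedded against the inner skin surface, and a signal-free corner for
background-noise estimation. Noise-free signal follows mono-exponential
decay S(b) = S0 * exp(-b * D(x)); magnitude noise is single-channel
Rician.

Cohorts emulate the statistical structure of the study population: one
phantom per case, with the VOI's true diffusivity drawn from a
group-specific truncated normal. Group distributions are parameterized
from the published per-group summary of the mean-signal ADC; the printed
"±" dispersion there is the standard error of the mean, so the
generating SD is reconstructed as SEM * sqrt(n). Healthy-skin cases get
single-slice VOIs of ~29 voxels and a low SNR target.

Units: ``GroupDistribution`` is on the printed scale (1e-3 mm^2/s);
``PhantomSpec`` diffusivities and all sampled values handed to the
signal model are in mm^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from skindwi.io import (
    DWIStudy,
    DataError,
    VOIMask,
    write_dwi_study,
    write_manifest,
    write_mask,
)

__all__ = [
    "GROUP_LABELS",
    "DEFAULT_GROUP_DISTRIBUTIONS",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_SNR_TARGETS",
    "GroupDistribution",
    "PhantomSpec",
    "GroundTruthRecord",
    "SkinPhantom",
    "CohortCase",
    "CohortSim",
    "add_rician_noise",
    "sample_group_diffusivity",
    "make_skin_phantom",
    "simulate_cohort",
]

GROUP_LABELS = ("PD", "IBC", "BSI", "SIBC", "H")

#: scale between printed ADC units (1e-3 mm^2/s) and internal mm^2/s
PRINTED_SCALE = 1e-3


@dataclass(frozen=True)
class GroupDistribution:
    """Truncated-normal generator for a group's true VOI diffusivity.

    All ADC fields are on the printed scale, 1e-3 mm^2/s. ``sd_adc`` is
    the generating standard deviation (for published groups,
    SEM * sqrt(n)); ``truncation_range`` forbids non-physical values.
    """

    group: str
    mean_adc: float
    sd_adc: float
    truncation_range: tuple[float, float]
    n_default: int

    def __post_init__(self) -> None:
        lo, hi = self.truncation_range
        if not lo < hi:
            raise DataError(
                f"{self.group}: degenerate truncation range ({lo}, {hi})"
            )
        if not (lo <= self.mean_adc <= hi):
            raise DataError(
                f"{self.group}: mean {self.mean_adc} outside range ({lo}, {hi})"
            )
        if self.sd_adc <= 0:
            raise DataError(f"{self.group}: sd_adc must be > 0")
        if self.n_default <= 0:
            raise DataError(f"{self.group}: n_default must be > 0")

    def truncnorm(self) -> stats.rv_continuous:
        """The scipy frozen truncated-normal, printed scale."""
        lo, hi = self.truncation_range
        a = (lo - self.mean_adc) / self.sd_adc
        b = (hi - self.mean_adc) / self.sd_adc
        return stats.truncnorm(a, b, loc=self.mean_adc, scale=self.sd_adc)


def _published(group, mean, sem, n, rng_pair) -> GroupDistribution:
    return GroupDistribution(
        group=group,
        mean_adc=mean,
        sd_adc=sem * math.sqrt(n),
        truncation_range=rng_pair,
        n_default=n,
    )


#: Per-group generating distributions for the mean-signal ADC
#: (printed scale, 1e-3 mm^2/s): mean, SEM and range as published,
#: SD reconstructed as SEM * sqrt(n). The healthy-skin entry reproduces
#: the *measured* (noise-biased) values; the true healthy diffusivity is
#: unknown and is a free parameter of the simulation.
DEFAULT_GROUP_DISTRIBUTIONS: dict[str, GroupDistribution] = {
    "PD": _published("PD", 0.95, 0.23, 3, (0.59, 1.37)),
    "IBC": _published("IBC", 1.86, 0.17, 5, (1.28, 2.18)),
    "BSI": _published("BSI", 1.88, 0.11, 11, (1.04, 2.30)),
    "SIBC": _published("SIBC", 1.38, 0.13, 11, (0.73, 1.98)),
    "H": _published("H", 0.48, 0.02, 58, (0.23, 0.85)),
}

#: published cohort sizes per group
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "PD": 3,
    "IBC": 5,
    "BSI": 11,
    "SIBC": 11,
    "H": 58,
}

#: high-b VOI SNR targets per group, matching the published per-group
#: mean SNR at the high b-value (healthy skin sits at the cutoff).
DEFAULT_SNR_TARGETS: dict[str, float] = {
    "PD": 14.0,
    "IBC": 59.0,
    "BSI": 56.0,
    "SIBC": 37.0,
    "H": 2.0,
}

#: published mean VOI voxel counts per group
DEFAULT_VOI_VOXELS: dict[str, int] = {
    "PD": 35,
    "IBC": 258,
    "BSI": 197,
    "SIBC": 46,
    "H": 29,
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, signal model and noise settings for one phantom.

    Diffusivities are in mm^2/s, b-values in s/mm^2. The body is a ball
    centred on the grid; ``skin_rim_thickness`` voxels of its outer
    shell are skin; the lesion is a ball that must fit inside the grid.
    The default body radius leaves the grid corners signal-free for the
    background-noise ROI.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    skin_rim_thickness: int = 2
    lesion_center: tuple[float, float, float] | None = None
    lesion_radius: float = 2.5
    S0: float = 1000.0
    true_adc_background: float = 1.0e-3
    true_adc_skin: float = 0.8e-3
    true_adc_lesion: float = 1.5e-3
    b_values: tuple[float, ...] = (50.0, 800.0)
    noise_sigma: float = 0.0
    seed: int = 0
    body_radius: float | None = None
    noise_roi_shape: tuple[int, int] = (8, 8)

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise DataError("grid_shape must be 3D with all extents >= 4")
        for name, d in (
            ("true_adc_background", self.true_adc_background),
            ("true_adc_skin", self.true_adc_skin),
            ("true_adc_lesion", self.true_adc_lesion),
        ):
            if d <= 0:
                raise DataError(f"{name} must be > 0 (got {d})")
        if self.noise_sigma < 0:
            raise DataError("noise_sigma must be >= 0")
        bs = tuple(float(b) for b in self.b_values)
        if len(bs) < 2 or any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise DataError(
                "b_values must be strictly increasing with >= 2 entries"
            )
        object.__setattr__(self, "b_values", bs)
        if self.S0 <= 0:
            raise DataError("S0 must be > 0")
        if self.skin_rim_thickness < 1:
            raise DataError("skin_rim_thickness must be >= 1")

    # -- derived geometry -------------------------------------------------

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, dtype=float) - 1.0) / 2.0

    @property
    def body_semi_axes(self) -> np.ndarray:
        """Semi-axes (voxels) of the body ellipsoid: a sphere when
        ``body_radius`` is set, otherwise fitted to the grid leaving
        >= 2 voxels of free space along each axis for the noise ROI."""
        if self.body_radius is not None:
            return np.full(3, float(self.body_radius))
        return np.maximum(
            np.asarray(self.grid_shape, dtype=float) / 2.0 - 2.0, 1.0
        )

    @property
    def resolved_lesion_center(self) -> np.ndarray:
        if self.lesion_center is not None:
            return np.asarray(self.lesion_center, dtype=float)
        # against the inner skin surface, along +x
        offset = (
            self.body_semi_axes[0]
            - self.skin_rim_thickness
            - self.lesion_radius
        )
        return self.center + np.array([max(offset, 0.0), 0.0, 0.0])


@dataclass(frozen=True)
class GroundTruthRecord:
    """Ground truth for one generated case (printed ADC scale)."""

    case_id: str
    group: str
    true_voi_adc: float  # 1e-3 mm^2/s
    noise_sigma: float
    voi_voxel_count: int


@dataclass
class SkinPhantom:
    """Bundle returned by :func:`make_skin_phantom`."""

    study: DWIStudy
    voi: VOIMask
    noise_roi: VOIMask
    ground_truth: GroundTruthRecord
    diffusivity_field: np.ndarray = field(repr=False)


def add_rician_noise(
    volume: np.ndarray, sigma: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Apply single-channel Rician noise to a noise-free magnitude image.

    Each voxel becomes sqrt((s + n1)^2 + n2^2) with n1, n2 independent
    zero-mean Gaussians of standard deviation ``sigma``. ``sigma=0``
    returns the input unchanged (same array values, new array).
    """
    if sigma < 0:
        raise DataError("sigma must be >= 0")
    vol = np.asarray(volume, dtype=float)
    if sigma == 0:
        return vol.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, size=vol.shape)
    n2 = rng.normal(0.0, sigma, size=vol.shape)
    return np.sqrt((vol + n1) ** 2 + n2**2)


def sample_group_diffusivity(
    dist: GroupDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` true VOI diffusivities for a group, in mm^2/s.

    Samples the group's truncated normal (printed scale) and converts to
    internal units; seeded and reproducible.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = dist.truncnorm().rvs(size=n, random_state=rng)
    return np.asarray(draws) * PRINTED_SCALE


# --------------------------------------------------------------------------
# phantom construction


def _ball(shape, center, radius) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = sum(
        ((g - c) / max(a, 1e-9)) ** 2
        for g, c, a in zip(grids, center, semi_axes)
    )
    return d2 <= 1.0


def _build_geometry(spec: PhantomSpec):
    """Return (body, skin, lesion, D-field) boolean masks / float array."""
    shape = spec.grid_shape
    semis = spec.body_semi_axes
    body = _ellipsoid(shape, spec.center, semis)
    inner = _ellipsoid(
        shape, spec.center, np.maximum(semis - spec.skin_rim_thickness, 0.0)
    )
    skin = body & ~inner

    lc = spec.resolved_lesion_center
    if np.any(lc - spec.lesion_radius < -0.5) or np.any(
        lc + spec.lesion_radius > np.asarray(shape) - 0.5
    ):
        raise DataError(
            f"lesion (center {tuple(lc)}, radius {spec.lesion_radius}) "
            f"extends outside the {shape} grid"
        )
    lesion = _ball(shape, lc, spec.lesion_radius) & body

    dfield = np.zeros(shape, dtype=float)
    dfield[body] = spec.true_adc_background
    dfield[skin] = spec.true_adc_skin
    dfield[lesion] = spec.true_adc_lesion
    return body, skin, lesion, dfield


def _noise_roi_mask(spec: PhantomSpec, body: np.ndarray) -> np.ndarray:
    """2D background box in the (0, 0, 0) grid corner, one slice."""
    nx, ny = spec.noise_roi_shape
    roi = np.zeros(spec.grid_shape, dtype=bool)
    roi[:nx, :ny, 0] = True
    if (roi & body).any():
        raise DataError(
            "noise ROI overlaps the body support; enlarge the grid or "
            "shrink body_radius"
        )
    return roi


def make_skin_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> SkinPhantom:
    """Generate one synthetic DWI study with mask, noise ROI and truth.

    The noise-free signal at each b-value is S0 * exp(-b * D(x)) inside
    the body and 0 outside; Rician noise is applied when
    ``spec.noise_sigma > 0``. The VOI is the lesion ball. Identical
    (spec, seed) reproduces identical voxel data bit-for-bit.
    """
    rng_seed = spec.seed if seed is None else seed
    body, skin, lesion, dfield = _build_geometry(spec)
    if not lesion.any():
        raise DataError("lesion does not intersect the body support")

    n_b = len(spec.b_values)
    volumes = np.zeros(spec.grid_shape + (n_b,), dtype=float)
    for i, b in enumerate(spec.b_values):
        clean = np.where(body, spec.S0 * np.exp(-b * dfield), 0.0)
        volumes[..., i] = add_rician_noise(
            clean, spec.noise_sigma, np.random.default_rng([rng_seed, i])
        )

    study = DWIStudy(
        volumes=volumes,
        b_values=spec.b_values,
        voxel_spacing=spec.voxel_spacing,
        case_id=f"phantom-{rng_seed}",
    )
    voi = VOIMask(data=lesion, name="lesion")
    noise_roi = VOIMask(data=_noise_roi_mask(spec, body), name="noise")
    truth = GroundTruthRecord(
        case_id=study.case_id,
        group="",
        true_voi_adc=spec.true_adc_lesion / PRINTED_SCALE,
        noise_sigma=spec.noise_sigma,
        voi_voxel_count=voi.voxel_count,
    )
    return SkinPhantom(
        study=study,
        voi=voi,
        noise_roi=noise_roi,
        ground_truth=truth,
        diffusivity_field=dfield,
    )


def single_slice_skin_voi(
    spec: PhantomSpec, n_voxels: int = 29
) -> np.ndarray:
    """Boolean VOI of ~``n_voxels`` skin voxels on the central slice.

    Emulates the healthy-skin delineation convention: one representative
    axial slice, a short contiguous arc of skin. Deterministic for a
    given spec.
    """
    body, skin, _, _ = _build_geometry(spec)
    z = spec.grid_shape[2] // 2
    sl = skin[:, :, z]
    idx = np.argwhere(sl)
    if idx.size == 0:
        raise DataError("no skin voxels on the central slice")
    center_xy = spec.center[:2]
    angles = np.arctan2(idx[:, 1] - center_xy[1], idx[:, 0] - center_xy[0])
    order = np.argsort(angles, kind="stable")
    chosen = idx[order[: min(n_voxels, len(idx))]]
    voi = np.zeros(spec.grid_shape, dtype=bool)
    voi[chosen[:, 0], chosen[:, 1], z] = True
    return voi


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortCase:
    """One simulated case with its measurement objects."""

    case_id: str
    group: str
    study: DWIStudy
    voi: VOIMask
    noise_roi: VOIMask
    ground_truth: GroundTruthRecord


@dataclass
class CohortSim:
    """A simulated cohort: cases plus ground-truth and manifest tables."""

    cases: list[CohortCase]
    ground_truth: pd.DataFrame
    manifest: pd.DataFrame


def _sigma_for_snr_target(
    spec: PhantomSpec, true_adc: float, snr_target: float
) -> float:
    """sigma such that noise-free VOI signal at the high b over sigma
    equals ``snr_target``; 0 disables noise."""
    if snr_target <= 0:
        return 0.0
    b_high = spec.b_values[-1]
    return spec.S0 * math.exp(-b_high * true_adc) / snr_target


def simulate_cohort(
    group_distributions: Mapping[str, GroupDistribution] | None = None,
    n_per_group: Mapping[str, int] | None = None,
    snr_targets: Mapping[str, float] | float | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    healthy_voi_voxels: int = 29,
    out_dir: str | Path | None = None,
) -> CohortSim:
    """Simulate a multi-group cohort of skin phantoms.

    Each case's true VOI diffusivity is drawn from its group's truncated
    normal; the noise sigma is set so the noise-free VOI signal at the
    high b-value over sigma equals the group's SNR target. Healthy-skin
    cases use a single-slice skin VOI of ~``healthy_voi_voxels`` voxels
    (the sampled diffusivity is assigned to the skin compartment);
    pathology cases use the 3D lesion VOI. If ``out_dir`` is given, all
    artifacts are written to disk (NIfTI + .bval + sidecar + masks +
    manifest/ground-truth CSVs).
    """
    dists = dict(DEFAULT_GROUP_DISTRIBUTIONS)
    if group_distributions:
        dists.update(group_distributions)
    sizes = dict(n_per_group) if n_per_group else dict(DEFAULT_GROUP_SIZES)
    for g in sizes:
        if g not in dists:
            raise DataError(
                f"unknown group label {g!r}; known: {sorted(dists)}"
            )
    if snr_targets is None:
        targets: Mapping[str, float] = DEFAULT_SNR_TARGETS
    elif isinstance(snr_targets, (int, float)):
        targets = {g: float(snr_targets) for g in sizes}
    else:
        targets = {**DEFAULT_SNR_TARGETS, **dict(snr_targets)}
    spec0 = base_spec if base_spec is not None else PhantomSpec()

    root = np.random.default_rng(seed)
    cases: list[CohortCase] = []
    truth_rows = []
    manifest_rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for group in sorted(sizes):
        n = sizes[group]
        if n == 0:
            continue
        group_tag = int.from_bytes(group.encode(), "little") % 2**31
        true_adcs = sample_group_diffusivity(
            dists[group], n, np.random.default_rng([seed, group_tag])
        )
        for k, d_true in enumerate(true_adcs):
            case_id = f"{group}-{k:03d}"
            case_seed = int(root.integers(2**31))
            snr_t = targets.get(group, 0.0)
            if group == "H":
                spec = replace(
                    spec0,
                    true_adc_skin=float(d_true),
                    noise_sigma=0.0,
                    seed=case_seed,
                )
                sigma = _sigma_for_snr_target(spec, float(d_true), snr_t)
                spec = replace(spec, noise_sigma=sigma)
                ph = make_skin_phantom(spec)
                voi = VOIMask(
                    data=single_slice_skin_voi(spec, healthy_voi_voxels),
                    name="skin",
                )
            else:
                spec = replace(
                    spec0,
                    true_adc_lesion=float(d_true),
                    noise_sigma=0.0,
                    seed=case_seed,
                )
                sigma = _sigma_for_snr_target(spec, float(d_true), snr_t)
                spec = replace(spec, noise_sigma=sigma)
                ph = make_skin_phantom(spec)
                voi = ph.voi
            study = ph.study
            study.case_id = case_id
            study.group = group
            truth = GroundTruthRecord(
                case_id=case_id,
                group=group,
                true_voi_adc=float(d_true) / PRINTED_SCALE,
                noise_sigma=sigma,
                voi_voxel_count=voi.voxel_count,
            )
            cases.append(
                CohortCase(
                    case_id=case_id,
                    group=group,
                    study=study,
                    voi=voi,
                    noise_roi=ph.noise_roi,
                    ground_truth=truth,
                )
            )
            truth_rows.append(
                {
                    "case_id": case_id,
                    "group": group,
                    "true_voi_adc": truth.true_voi_adc,
                    "noise_sigma": sigma,
                    "voi_voxel_count": truth.voi_voxel_count,
                }
            )
            if out is not None:
                img = out / f"{case_id}_dwi.nii.gz"
                bval = out / f"{case_id}.bval"
                sidecar = out / f"{case_id}.json"
                mpath = out / f"{case_id}_mask.nii.gz"
                npath = out / f"{case_id}_noise.nii.gz"
                write_dwi_study(
                    study,
                    img,
                    bval_path=bval,
                    sidecar_path=sidecar,
                    sidecar_extra={"noise_sigma": sigma, "seed": case_seed},
                )
                write_mask(voi, mpath, affine=study.affine)
                write_mask(ph.noise_roi, npath, affine=study.affine)
                manifest_rows.append(
                    {
                        "case_id": case_id,
                        "group": group,
                        "image": img.name,
                        "bval": bval.name,
                        "mask": mpath.name,
                        "noise_roi": npath.name,
                    }
                )
            else:
                manifest_rows.append(
                    {
                        "case_id": case_id,
                        "group": group,
                        "image": "",
                        "bval": "",
                        "mask": "",
                        "noise_roi": "",
                    }
                )

    truth_df = pd.DataFrame(
        truth_rows,
        columns=[
            "case_id",
            "group",
            "true_voi_adc",
            "noise_sigma",
            "voi_voxel_count",
        ],
    )
    manifest_df = pd.DataFrame(
        manifest_rows,
        columns=["case_id", "group", "image", "bval", "mask", "noise_roi"],
    )
    if out is not None:
        truth_df.to_csv(out / "ground_truth.csv", index=False)
        write_manifest(manifest_df, out / "manifest.csv")
    return CohortSim(
        cases=cases, ground_truth=truth_df, manifest=manifest_df
    )
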