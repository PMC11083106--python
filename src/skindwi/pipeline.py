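"""End-to-end orchestration: simulate or ingest a cohort, SNR QC,
ADC quantification, and the group-statistics report."""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from skindwi import __version__
from skindwi.adc import compute_adc_result, erode_mask, select_bvalue_pair
from skindwi.io import (
    DataError,
    read_dwi_study,
    read_manifest,
    read_mask,
    write_results,
)
from skindwi.phantom import (
    PRINTED_SCALE,
    CohortCase,
    PhantomSpec,
    simulate_cohort,
)
from skindwi.snr import compute_snr, snr_qc_filter
from skindwi.stats import (
    DEFAULT_FEATURES,
    pairwise_group_tests,
    roc_analysis,
    summarize_groups,
)

__all__ = ["RunConfig", "run_simulate", "analyze_cases", "run_analyze"]


@dataclass
class RunConfig:
    """Tunable knobs of an analysis run; all defaults match the study
    conventions (SNR cutoff 2 at the high b, healthy skin exempt,
    alpha 0.05, groups below n=5 descriptive only)."""

    snr_cutoff: float = 2.0
    exempt_groups: tuple[str, ...] = ("H",)
    erosion_rim: int = 0
    alpha: float = 0.05
    min_group_n: int = 5
    use_corrected_snr: bool = True
    correction: str | None = None
    features: tuple[str, ...] = DEFAULT_FEATURES
    roc_feature: str = "adc_of_mean_signal"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exempt_groups", "features"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: dict[str, int] | None = None,
    snr_targets: dict[str, float] | float | None = None,
    base_spec: PhantomSpec | None = None,
) -> Path:
    """Write a simulated phantom cohort (with ground truth) to disk."""
    out = Path(out_dir)
    sim = simulate_cohort(
        n_per_group=n_per_group,
        snr_targets=snr_targets,
        seed=seed,
        base_spec=base_spec,
        out_dir=out,
    )
    report = {
        "command": "simulate",
        "version": __version__,
        "seed": seed,
        "n_cases": len(sim.cases),
        "groups": sim.ground_truth["group"].value_counts().to_dict(),
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return out


def _load_cases(manifest: pd.DataFrame) -> list[CohortCase]:
    cases = []
    for row in manifest.itertuples(index=False):
        study = read_dwi_study(
            row.image, bval_path=row.bval,
            case_id=row.case_id, group=row.group,
        )
        voi = read_mask(row.mask, study)
        noise_roi = read_mask(row.noise_roi, study)
        cases.append(
            CohortCase(
                case_id=row.case_id,
                group=row.group,
                study=study,
                voi=voi,
                noise_roi=noise_roi,
                ground_truth=None,
            )
        )
    return cases


def analyze_cases(
    cases: Iterable[CohortCase], config: RunConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Run QC + quantification + statistics on in-memory cases.

    Returns the result tables: ``qc``, ``features`` (included cases,
    printed ADC scale), ``group_summary``, ``pairwise_tests``, ``roc``.
    """
    cfg = config or RunConfig()
    cases = list(cases)
    if not cases:
        raise DataError("no cases to analyze")

    reports = {}
    pairs = {}
    for case in cases:
        pair = select_bvalue_pair(case.study.b_values)
        pairs[case.case_id] = pair
        reports[case.case_id] = compute_snr(
            case.study,
            case.voi,
            case.noise_roi,
            pair,
            cutoff=cfg.snr_cutoff,
            exempt=case.group in cfg.exempt_groups,
            use_corrected=cfg.use_corrected_snr,
        )
    included, excluded, qc_table = snr_qc_filter(
        reports, cutoff=cfg.snr_cutoff, exempt_groups=set(cfg.exempt_groups)
    )

    feat_rows = []
    for case in cases:
        if case.case_id not in included:
            continue
        voi = (
            erode_mask(case.voi, cfg.erosion_rim)
            if cfg.erosion_rim
            else case.voi
        )
        res = compute_adc_result(case.study, voi, pairs[case.case_id])
        feat_rows.append(
            {
                "case_id": case.case_id,
                "group": case.group,
                "adc_mean": res.summary.mean / PRINTED_SCALE,
                "adc_median": res.summary.median / PRINTED_SCALE,
                "adc_min": res.summary.min / PRINTED_SCALE,
                "adc_max": res.summary.max / PRINTED_SCALE,
                "adc_of_mean_signal": res.adc_of_mean_signal.value
                / PRINTED_SCALE,
                "negative_adc_flag": res.adc_of_mean_signal.is_negative,
                "n_voxels_used": res.n_voxels_used,
                "n_voxels_excluded": res.n_voxels_excluded,
            }
        )
    features = pd.DataFrame(feat_rows)
    if features.empty:
        raise DataError("all cases excluded by SNR QC; nothing to analyze")

    summary = summarize_groups(features, features=cfg.features)
    groups = sorted(features["group"].unique())
    testable = [g for g in groups if g not in cfg.exempt_groups]
    if len(groups) >= 2:
        tests = pairwise_group_tests(
            features,
            features=cfg.features,
            alpha=cfg.alpha,
            min_group_n=cfg.min_group_n,
            correction=cfg.correction,
        )
    else:
        tests = pd.DataFrame(
            columns=[
                "feature", "group_a", "group_b", "n_a", "n_b",
                "statistic", "p_value", "significant", "descriptive_only",
            ]
        )

    roc_rows = []
    group_means = features.groupby("group")[cfg.roc_feature].mean()
    group_sizes = features.groupby("group").size()
    roc_groups = [g for g in testable if group_sizes[g] >= cfg.min_group_n]
    for ga, gb in itertools.combinations(roc_groups, 2):
        # positive class = group with the lower mean ADC (more malignant)
        pos, neg = (ga, gb) if group_means[ga] <= group_means[gb] else (gb, ga)
        r = roc_analysis(features, cfg.roc_feature, pos, neg)
        roc_rows.append(
            {
                "feature": cfg.roc_feature,
                "positive_group": pos,
                "negative_group": neg,
                "auc": r.auc,
                "youden_threshold": r.youden_threshold,
                "sensitivity": r.sensitivity_at_youden,
                "specificity": r.specificity_at_youden,
            }
        )
    roc = pd.DataFrame(
        roc_rows,
        columns=[
            "feature", "positive_group", "negative_group", "auc",
            "youden_threshold", "sensitivity", "specificity",
        ],
    )

    return {
        "qc": qc_table,
        "features": features,
        "group_summary": summary,
        "pairwise_tests": tests,
        "roc": roc,
    }


def run_analyze(
    manifest_path: str | Path,
    out_dir: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Ingest a cohort manifest, analyze it, and write the report."""
    cfg = config or RunConfig()
    manifest = read_manifest(manifest_path)
    cases = _load_cases(manifest)
    tables = analyze_cases(cases, cfg)
    excluded = tables["qc"].loc[~tables["qc"]["passed"]]
    report = {
        "command": "analyze",
        "version": __version__,
        "manifest": str(manifest_path),
        "config": asdict(cfg),
        "n_cases": len(cases),
        "n_included": int(tables["qc"]["passed"].sum()),
        "exclusions": excluded[["case_id", "group", "reason"]].to_dict(
            orient="records"
        ),
    }
    write_results(tables, out_dir, run_report=report)
    return Path(out_dir)
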