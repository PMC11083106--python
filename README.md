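# skindwi

Quantitative diffusion-weighted MRI (DWI) analysis of breast-skin
pathologies, as a tested, reusable pipeline:

- **phantom** (`skindwi.phantom`) — seeded synthetic breast-skin DWI
  studies with known ground-truth diffusivity: mono-exponential signal
  decay over two (or more) b-values, single-channel Rician noise at a
  controlled SNR, skin-rim geometry, group-specific truncated-normal
  diffusivity distributions for the five cohort groups
  (PD, IBC, BSI, SIBC, H) and cohort simulation with on-disk artifacts.
- **I/O** (`skindwi.io`) — NIfTI DWI stacks (axis order `(x, y, z, b)`),
  FSL `.bval` files / JSON sidecars, binary VOI masks (binarized at
  `> 0`), cohort manifests and result tables (CSV/JSON).
- **ADC quantification** (`skindwi.adc`) — two-point ADC by two methods:
  from the mean VOI signal, and voxel-wise maps with first-order VOI
  statistics (mean/median/min/max); b-pair selection (lowest b plus the
  high b in [700, 900] s/mm², preferring 800 then 750); face-connected
  mask erosion for partial-volume mitigation. Nonpositive-signal voxels
  are excluded (NaN) and counted, never clamped.
- **SNR QC** (`skindwi.snr`) — noise floor from a 2D background ROI
  (`sigma = sqrt(2/pi) * mean`), Rician noise-floor correction
  (`sqrt(S^2 - sigma^2)`), per-b SNR, and the inclusion cutoff of 2 at
  the high b-value (healthy skin exempt but flagged as biased).
- **group statistics** (`skindwi.stats`) — Lilliefors/KS normality
  screening, exact/asymptotic Wilcoxon rank-sum tests, pairwise group
  comparisons (small groups descriptive-only), empirical ROC with
  trapezoid AUC (= Mann-Whitney U / n1·n2) and Youden operating points,
  and group summary tables reporting SD, SEM and range.
- **pipeline** (`skindwi.pipeline`, `skindwi.cli`) — end-to-end
  simulate/ingest → SNR QC → ADC features → statistics, fully
  deterministic under a seed.

ADC units: mm²/s internally; all tabulated values are scaled to
10⁻³ mm²/s.

## CLI

```sh
# simulate an 88-case cohort of phantoms (default group sizes)
skindwi simulate --seed 1 --out cohort/

# custom cohort
echo '{"n_per_group": {"SIBC": 11, "BSI": 11}, "snr_targets": 50}' > cohort.json
skindwi simulate --config cohort.json --seed 1 --out cohort/

# analyze a cohort manifest (QC, features, summaries, tests, ROC)
skindwi analyze --manifest cohort/manifest.csv --out report/

# print (and optionally plot) the report
skindwi report --results report/ --plots
```

`analyze` writes `qc.csv`, `features.csv`, `group_summary.csv`,
`pairwise_tests.csv`, `roc.csv` and `run_report.json` (config echo and
machine-readable exclusion log). Exit codes: 0 ok, 1 usage error,
2 data error.

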