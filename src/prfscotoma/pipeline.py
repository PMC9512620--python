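"""End-to-end orchestration of simulated scotoma-mapping studies.

Wires the stages together: synthesize a full-field reference cohort
and a scotoma study cohort, fit every analysis scotoma-naively, run
the KDE border estimation, and compute the reliability battery.  All
randomness flows from one base seed through a documented derivation
(`derive_seeds`), so every artifact is regenerable from the manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitConfig, fit_population, fit_run, _CoarseEngine
from .io import write_curve, write_result_table
from .kde import scotoma_border_analysis
from .prf_model import ModelVariant
from .reproducibility import (
    correlation_report,
    group_mean_differences,
    match_voxels,
    threshold_sweep,
)
from .stimulus import StimulusConfig, build_sequence, reference_config, study_config
from .synthetic import (
    calibrate_amplitudes,
    sample_population,
    simulate_run,
    simulate_study,
    population_frame,
)

__all__ = [
    "PipelineConfig",
    "derive_seeds",
    "run_full_study",
    "scotoma_benchmark",
    "COMPARISONS",
]

#: the five run comparisons of the reliability battery
COMPARISONS = (
    ("s1_r1_vs_r2", "s1r1", "s1r2"),
    ("s2_r1_vs_r2", "s2r1", "s2r2"),
    ("r1_s1_vs_s2", "s1r1", "s2r1"),
    ("r2_s1_vs_s2", "s1r2", "s2r2"),
    ("combined_s1_vs_s2", "s1avg", "s2avg"),
)


def derive_seeds(base_seed: int, n: int, stream: int = 0) -> np.ndarray:
    """Deterministic per-stage child seeds, each below 2^31."""
    ss = np.random.SeedSequence([int(base_seed), int(stream)])
    return ss.generate_state(n).astype(np.int64) % (2**31)


@dataclass
class PipelineConfig:
    """Resolved configuration of a full simulated study."""

    # stimulus geometry (study condition); the reference condition is
    # derived from it with 0.4° steps, TR 1 s and no mask
    scotoma_radius_deg: float = 2.0
    grid_resolution: int = 101
    # simulation
    n_subjects: int = 5
    n_reference_subjects: int = 10
    n_vox: int = 600
    noise_sd: float = 1.0
    signal_sd: float = 1.0
    sigma_slope: float = 0.1
    sigma_intercept: float = 0.5
    n_reference_runs: int = 2
    # fitting
    variant: str = ModelVariant.GAUSSIAN_FITTED_HRF.value
    ve_threshold: float = 0.10
    fit_grid_resolution: int | None = 61
    # kde
    border_threshold: float = 0.1
    # reproducibility
    sweep_thresholds: tuple[float, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        # accept either a flat mapping or one nested into sections
        if raw and all(isinstance(v, dict) for v in raw.values()):
            flat = {}
            for section in raw.values():
                flat.update(section)
        else:
            flat = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "sweep_thresholds" in flat and flat["sweep_thresholds"] is not None:
            flat["sweep_thresholds"] = tuple(flat["sweep_thresholds"])
        return cls(**flat)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["sweep_thresholds"] = list(self.sweep_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def study_stimulus(self) -> StimulusConfig:
        return study_config(
            scotoma_radius_deg=self.scotoma_radius_deg,
            grid_resolution=self.grid_resolution,
        )

    def reference_stimulus(self) -> StimulusConfig:
        return reference_config(grid_resolution=self.grid_resolution)

    def fit_config(self) -> FitConfig:
        return FitConfig(
            variant=ModelVariant(self.variant), ve_threshold=self.ve_threshold
        )


def _fit_sequence(cfg: StimulusConfig, fit_grid_resolution: int | None):
    """Full-field aperture sequence used for (scotoma-naive) prediction.

    The forward model may run on a coarser raster than the simulation
    for speed; the Gaussian-aperture overlap converges quickly with
    raster resolution.
    """
    full = replace(cfg, scotoma_radius_deg=0.0)
    if fit_grid_resolution is not None:
        full = replace(full, grid_resolution=fit_grid_resolution)
    return build_sequence(full)


def _simulate_reference_subject(
    pop, seq, noise_sd, seeds, hrf_jitter_rng
) -> np.ndarray:
    """Average of the reference subject's runs (frame-wise mean)."""
    from .prf_model import CANONICAL_HRF

    runs = []
    for seed in seeds:
        delay = CANONICAL_HRF.peak_delay_s + hrf_jitter_rng.uniform(-0.8, 0.8)
        h = CANONICAL_HRF.with_peak(delay, CANONICAL_HRF.peak_dispersion_s)
        runs.append(simulate_run(pop, seq, h, noise_sd, seed=int(seed)).timeseries)
    return np.mean(runs, axis=0)


def scotoma_benchmark(
    seed: int,
    n_reference: int = 10,
    n_study: int = 5,
    n_vox: int = 600,
    noise_sd: float = 1.0,
    scotoma_radius_deg: float = 2.0,
    grid_resolution: int = 101,
    fit_grid_resolution: int | None = 61,
    ve_threshold: float = 0.10,
    verbose: bool = False,
) -> dict:
    """Scotoma border recovery under the study conditions.

    Simulates a full-field reference cohort (reference acquisition:
    0.4° steps, TR 1 s, runs averaged) and a study cohort with a
    central scotoma (0.8° steps, TR 2 s), fits all data scotoma-naively
    with the fitted-HRF Gaussian model, and estimates the border with
    the KDE comparison method.  Returns the per-subject borders, their
    mean, and the group-curve border.
    """
    ref_cfg = reference_config(grid_resolution=grid_resolution)
    study_cfg = study_config(
        scotoma_radius_deg=scotoma_radius_deg, grid_resolution=grid_resolution
    )
    ref_seq = build_sequence(ref_cfg)
    study_seq = build_sequence(study_cfg)
    full_study_seq = build_sequence(replace(study_cfg, scotoma_radius_deg=0.0))

    fitcfg = FitConfig(ve_threshold=ve_threshold)
    ref_fit_seq = _fit_sequence(ref_cfg, fit_grid_resolution)
    study_fit_seq = _fit_sequence(study_cfg, fit_grid_resolution)
    ref_engine = _CoarseEngine(ref_fit_seq, fitcfg)
    study_engine = _CoarseEngine(study_fit_seq, fitcfg)

    pop_seeds = derive_seeds(seed, n_reference + n_study, stream=1)
    run_seeds = derive_seeds(seed, 2 * n_reference + n_study, stream=2)
    hrf_rng = np.random.default_rng(int(derive_seeds(seed, 1, stream=3)[0]))

    ref_tables = []
    for i in range(n_reference):
        pop = sample_population(n_vox, seed=int(pop_seeds[i]))
        pop = calibrate_amplitudes(pop, ref_seq)
        ts = _simulate_reference_subject(
            pop, ref_seq, noise_sd, run_seeds[2 * i : 2 * i + 2], hrf_rng
        )
        ref_tables.append(
            fit_run(ts, ref_fit_seq, fitcfg, engine=ref_engine)
        )
        if verbose:
            print(f"reference subject {i + 1}/{n_reference} fitted")

    scot_tables = []
    for j in range(n_study):
        pop = sample_population(n_vox, seed=int(pop_seeds[n_reference + j]))
        # amplitudes calibrated on the full-field version of the study
        # stimulus: the ground truth is condition-invariant
        pop = calibrate_amplitudes(pop, full_study_seq)
        from .prf_model import CANONICAL_HRF

        delay = CANONICAL_HRF.peak_delay_s + hrf_rng.uniform(-0.8, 0.8)
        h = CANONICAL_HRF.with_peak(delay, CANONICAL_HRF.peak_dispersion_s)
        run = simulate_run(
            pop,
            study_seq,
            h,
            noise_sd,
            seed=int(run_seeds[2 * n_reference + j]),
        )
        scot_tables.append(
            fit_run(run.timeseries, study_fit_seq, fitcfg, engine=study_engine)
        )
        if verbose:
            print(f"study subject {j + 1}/{n_study} fitted")

    analysis = scotoma_border_analysis(
        ref_tables, scot_tables, ve_threshold=ve_threshold
    )
    analysis["reference_tables"] = ref_tables
    analysis["scotoma_tables"] = scot_tables
    return analysis


def run_full_study(
    config: PipelineConfig, out_dir, base_seed: int = 0
) -> Path:
    """Simulate, fit and analyse a complete study; write all artifacts.

    Output layout: ``ground_truth/``, ``fits/`` (six tables per study
    subject, one per reference subject), ``kde/`` (curves and border
    table), ``repro/`` (correlation and difference tables), plus the
    resolved config and a manifest with seeds and version.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fitcfg = config.fit_config()

    ref_cfg = config.reference_stimulus()
    study_cfg = config.study_stimulus()
    ref_seq = build_sequence(ref_cfg)
    study_seq = build_sequence(study_cfg)
    full_study_seq = build_sequence(replace(study_cfg, scotoma_radius_deg=0.0))
    ref_fit_seq = _fit_sequence(ref_cfg, config.fit_grid_resolution)
    study_fit_seq = _fit_sequence(study_cfg, config.fit_grid_resolution)
    ref_engine = _CoarseEngine(ref_fit_seq, fitcfg)
    study_engine = _CoarseEngine(study_fit_seq, fitcfg)

    n_ref = config.n_reference_subjects
    pop_seeds = derive_seeds(base_seed, n_ref + config.n_subjects, stream=1)
    ref_run_seeds = derive_seeds(base_seed, config.n_reference_runs * n_ref, stream=2)
    study_seeds = derive_seeds(base_seed, config.n_subjects, stream=4)
    hrf_rng = np.random.default_rng(int(derive_seeds(base_seed, 1, stream=3)[0]))

    # --- reference cohort -------------------------------------------------
    (out / "ground_truth").mkdir(parents=True, exist_ok=True)
    ref_tables = []
    for i in range(n_ref):
        pop = sample_population(
            config.n_vox,
            sigma_slope=config.sigma_slope,
            sigma_intercept=config.sigma_intercept,
            seed=int(pop_seeds[i]),
        )
        pop = calibrate_amplitudes(pop, ref_seq, target_sd=config.signal_sd)
        ts = _simulate_reference_subject(
            pop,
            ref_seq,
            config.noise_sd,
            ref_run_seeds[
                config.n_reference_runs * i : config.n_reference_runs * (i + 1)
            ],
            hrf_rng,
        )
        table = fit_run(ts, ref_fit_seq, fitcfg, engine=ref_engine)
        ref_tables.append(table)
        write_result_table(table, out / "fits" / f"reference_{i + 1:02d}.csv")
        population_frame(pop).to_csv(
            out / "ground_truth" / f"reference_{i + 1:02d}.csv", index=False
        )

    # --- study cohort ------------------------------------------------------
    subject_tables: list[dict[str, pd.DataFrame]] = []
    for j in range(config.n_subjects):
        pop = sample_population(
            config.n_vox,
            sigma_slope=config.sigma_slope,
            sigma_intercept=config.sigma_intercept,
            seed=int(pop_seeds[n_ref + j]),
        )
        pop = calibrate_amplitudes(pop, full_study_seq, target_sd=config.signal_sd)
        dataset = simulate_study(
            pop,
            study_cfg,
            noise_sd=config.noise_sd,
            base_seed=int(study_seeds[j]),
            seq=study_seq,
        )
        tables = fit_population(dataset, fitcfg, fit_seq=study_fit_seq)
        subject_tables.append(tables)
        for label, table in tables.items():
            write_result_table(
                table, out / "fits" / f"subject_{j + 1:02d}_{label}.csv"
            )
        population_frame(pop).to_csv(
            out / "ground_truth" / f"subject_{j + 1:02d}.csv", index=False
        )

    # --- KDE border estimation (per analysis label) ------------------------
    labels = list(subject_tables[0].keys())
    border_rows = []
    for label in labels:
        analysis = scotoma_border_analysis(
            ref_tables,
            [tabs[label] for tabs in subject_tables],
            ve_threshold=config.ve_threshold,
            threshold=config.border_threshold,
        )
        for j, (b, status) in enumerate(
            zip(analysis["subject_borders"], analysis["subject_statuses"])
        ):
            border_rows.append(
                {
                    "analysis": label,
                    "subject": j + 1,
                    "border_deg": b,
                    "status": status,
                    "level": "subject",
                }
            )
        border_rows.append(
            {
                "analysis": label,
                "subject": 0,
                "border_deg": analysis["group_border"],
                "status": analysis["group_status"],
                "level": "group_curve",
            }
        )
        write_curve(
            analysis["group_curve"].eval_ecc,
            analysis["group_curve"].value,
            out / "kde" / f"group_comparison_{label}.csv",
            value_name="kde_comp",
        )
    pd.DataFrame(border_rows).to_csv(out / "kde" / "borders.csv", index=False)

    # --- reliability battery ------------------------------------------------
    (out / "repro").mkdir(parents=True, exist_ok=True)
    rho_rows, diff_rows = [], []
    for label, key_a, key_b in COMPARISONS:
        pairs_by_subject = [
            match_voxels(tabs[key_a], tabs[key_b], config.ve_threshold)
            for tabs in subject_tables
        ]
        pairs_by_subject = [p for p in pairs_by_subject if len(p) >= 3]
        if not pairs_by_subject:
            continue
        report = correlation_report(pairs_by_subject, label=label)
        for param, rho in report.rho.items():
            rho_rows.append({"comparison": label, "parameter": param, "rho": rho})
        for ecc_limit, tag in ((None, "all"), (7.0, "lt7deg")):
            gmd = group_mean_differences(pairs_by_subject, ecc_limit=ecc_limit)
            for param, row in gmd.iterrows():
                diff_rows.append(
                    {
                        "comparison": label,
                        "parameter": param,
                        "scope": tag,
                        "mean_abs_diff": row["mean"],
                        "sem": row["sem"],
                    }
                )
    pd.DataFrame(rho_rows).to_csv(out / "repro" / "correlations.csv", index=False)
    pd.DataFrame(diff_rows).to_csv(out / "repro" / "differences.csv", index=False)

    if config.sweep_thresholds:
        sweeps = []
        for j, tabs in enumerate(subject_tables):
            sw = threshold_sweep(
                tabs["s1r1"], tabs["s1r2"], sorted(config.sweep_thresholds)
            )
            sw.insert(0, "subject", j + 1)
            sweeps.append(sw)
        pd.concat(sweeps).to_csv(out / "repro" / "threshold_sweep.csv", index=False)

    config.to_yaml(out / "config_resolved.yaml")
    manifest = {
        "package": "prfscotoma",
        "version": __version__,
        "base_seed": int(base_seed),
        "config": dataclasses.asdict(config) | {
            "sweep_thresholds": list(config.sweep_thresholds)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
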