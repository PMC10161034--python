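"""Study orchestration: cohort simulation -> segmentation -> metrics ->
statistics -> lower dose limit, with reproducible seeding and artifact
output (manifest, accuracy table, stats JSON)."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as io_mod
from .config import DosimetryConfig, StatsConfig, StudyConfig, config_to_dict
from .dosimetry import ConversionTable, compute_effective_dose, default_table
from .metrics import AccuracyRecord, make_record, read_records, records_to_frame, write_records
from .phantom import SubjectScans, simulate_cohort
from .segmentation import (
    SegmentationConfig,
    denoise,
    estimate_noise_sigma,
    ground_truth_volumes,
    quantify,
)
from .stats import (
    DoseBinResult,
    DoseLimit,
    derive_acceptable_accuracy,
    determine_dose_limit,
    dose_bin_tests,
    interval_effect_test,
    mann_whitney_u,
    truncation_effect_test,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StudyReport:
    config: dict
    stats: dict
    accuracy_csv: Path
    manifest_csv: Path
    stats_json: Path


# ---------------------------------------------------------------------------
# Record building
# ---------------------------------------------------------------------------


def build_accuracy_records(
    subjects: list[SubjectScans], seg_config: SegmentationConfig
) -> list[AccuracyRecord]:
    """Manual-limb and automated-limb accuracy records for a cohort.

    Manual records compare ground-truth fat volumes between the standard-dose
    and low-dose acquisitions (capturing positioning, drift and truncation
    only).  Automated records compare the stand-in segmentation of each
    low-dose reconstruction against that same reconstruction's own ground
    truth, with and without denoising, mirroring the use of same-scan manual
    values as reference for the dose-limit analysis.
    """
    records: list[AccuracyRecord] = []
    for subject in subjects:
        truth_std = ground_truth_volumes(subject.standard.truth)
        low0 = subject.low_dose[0]
        truth_low = ground_truth_volumes(low0.truth)
        for comp in ("SAT", "VAT"):
            records.append(
                make_record(
                    subject.subject_id,
                    comp,
                    truth_std[comp],
                    truth_low[comp],
                    source="manual",
                    days_between=low0.day_offset,
                    truncated=low0.truncated,
                    ssde_5_25=subject.standard.dose.ssde_5_25,
                    thickness=subject.standard.dose.thickness_mm,
                    denoised=False,
                )
            )
        for event in subject.low_dose:
            truth_event = ground_truth_volumes(event.truth)
            sigma_model = None
            for denoised in (False, True):
                measured, _ = quantify(event.volume, seg_config, apply_denoise=denoised)
                if denoised:
                    sigma_post = estimate_noise_sigma(denoise(event.volume, seg_config))
                else:
                    sigma_model = estimate_noise_sigma(event.volume)
                for comp in ("SAT", "VAT"):
                    records.append(
                        make_record(
                            event.subject_id,
                            comp,
                            truth_event[comp],
                            measured[comp],
                            source="auto",
                            days_between=event.day_offset,
                            truncated=event.truncated,
                            ssde_5_25=event.dose.ssde_5_25,
                            thickness=event.dose.thickness_mm,
                            denoised=denoised,
                        )
                    )
            logger.info(
                "noise checkpoints %s ssde=%.2f t=%.2f: post-noise sigma=%.1f HU, post-denoise sigma=%.1f HU",
                event.subject_id,
                event.dose.ssde,
                event.dose.thickness_mm,
                sigma_model,
                sigma_post,
            )
    return records


# ---------------------------------------------------------------------------
# Statistics stage
# ---------------------------------------------------------------------------


def _result_dict(result) -> dict:
    d = dataclasses.asdict(result)
    return {k: (None if isinstance(v, float) and math.isnan(v) else v) for k, v in d.items()}


def _fallback_levels(
    records: list[AccuracyRecord], reference: list[float], stats_cfg: StatsConfig
) -> list[DoseBinResult]:
    """One acceptability test per coarse-arm dose level."""
    levels = sorted({round(r.ssde_5_25, 6) for r in records})
    out = []
    for level in levels:
        acc = np.array([r.accuracy for r in records if round(r.ssde_5_25, 6) == level])
        test = mann_whitney_u(acc, reference, sidedness="one_less")
        out.append(
            DoseBinResult(
                low=float(level),
                high=float(level),
                n=int(acc.size),
                mean=float(acc.mean()),
                sd=float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
                p_value=test.p_value,
                small_n=acc.size < stats_cfg.small_n_min,
            )
        )
    return out


def compute_stats(
    records: list[AccuracyRecord],
    stats_cfg: StatsConfig,
    dosimetry_cfg: DosimetryConfig,
) -> dict:
    """The full statistical ladder on an accuracy-record table."""
    result: dict = {"alpha": stats_cfg.alpha}

    manual = [r for r in records if r.source == "manual"]
    if not manual:
        raise StageError("stats", "no manual records; confounder screens need them")

    try:
        result["truncation_test"] = {
            c: _result_dict(t) for c, t in truncation_effect_test(records).items()
        }
    except ValueError as exc:
        result["truncation_test"] = {"skipped": str(exc)}
    try:
        result["interval_test"] = {
            c: _result_dict(t)
            for c, t in interval_effect_test(records, stats_cfg.interval_cutoff_days).items()
        }
    except ValueError as exc:
        result["interval_test"] = {"skipped": str(exc)}

    limits: dict[str, DoseLimit] = {}
    result["acceptable_accuracy"] = {}
    result["dose_bins"] = {}
    result["fallback_levels"] = {}
    result["dose_limit"] = {}
    for comp in ("SAT", "VAT"):
        fixed = (
            stats_cfg.fixed_values[comp]
            if stats_cfg.acceptable_accuracy_mode == "fixed"
            else None
        )
        acceptable = derive_acceptable_accuracy(
            records,
            comp,
            rule="auto",
            cutoff_days=stats_cfg.interval_cutoff_days,
            alpha=stats_cfg.alpha,
            fixed_value=fixed,
        )
        reference = list(acceptable.reference_sample)
        result["acceptable_accuracy"][comp] = _result_dict(acceptable)

        fine = [
            r
            for r in records
            if r.source == "auto"
            and r.compartment == comp
            and r.denoised
            and r.thickness == stats_cfg.fine_thickness
        ]
        coarse = [
            r
            for r in records
            if r.source == "auto"
            and r.compartment == comp
            and r.denoised
            and r.thickness == stats_cfg.fallback_thickness
        ]
        bins = dose_bin_tests(
            fine,
            reference,
            bin_edges=stats_cfg.bin_edges,
            alpha=stats_cfg.alpha,
            small_n_min=stats_cfg.small_n_min,
        )
        fallbacks = _fallback_levels(coarse, reference, stats_cfg) if coarse else []
        limit = determine_dose_limit(bins, fallbacks, alpha=stats_cfg.alpha)
        limits[comp] = limit
        result["dose_bins"][comp] = [_result_dict(b) for b in bins]
        result["fallback_levels"][comp] = [_result_dict(b) for b in fallbacks]
        result["dose_limit"][comp] = _result_dict(limit)

    values = [l.limit for l in limits.values()]
    combined = None if any(v is None for v in values) else max(values)
    result["combined_limit_mGy"] = combined
    result["effective_dose_at_limit_mSv"] = (
        None
        if combined is None
        else compute_effective_dose(combined, dosimetry_cfg.scan_length_cm, dosimetry_cfg.k)
    )
    return result


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isinf(obj):
        return "inf"
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _dump_json(data: dict, path: Path) -> None:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, float) and math.isinf(obj):
            return "inf"
        return obj

    path.write_text(json.dumps(clean(data), indent=2, sort_keys=True, default=_json_default) + "\n")


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full study and write all artifacts under ``config.output_dir``."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = (
        ConversionTable.from_csv(config.dosimetry.conversion_table_path)
        if config.dosimetry.conversion_table_path
        else default_table()
    )

    logger.info("stage simulate: %d subjects", config.cohort.n_subjects)
    try:
        subjects = simulate_cohort(config.resolved_cohort(), table)
    except ValueError as exc:
        raise StageError("simulate", str(exc)) from exc

    manifest_rows = []
    for subject in subjects:
        for event in (subject.standard, *subject.low_dose):
            vol_path = mask_path = ""
            if config.save_volumes:
                stem = f"{event.subject_id}_{event.role}_t{event.dose.thickness_mm:g}_d{event.dose.ssde:g}"
                vol_path = str(io_mod.save_volume(out_dir / stem, event.volume, event.truth))
                mask_path = vol_path
            manifest_rows.append(
                {
                    "subject_id": event.subject_id,
                    "scan_role": event.role,
                    "day_offset": event.day_offset,
                    "ssde_mGy": event.dose.ssde,
                    "ssde_5_25_mGy": event.dose.ssde_5_25,
                    "thickness_mm": event.dose.thickness_mm,
                    "truncated": event.truncated,
                    "volume_path": vol_path,
                    "mask_path": mask_path,
                }
            )
    manifest_csv = io_mod.write_manifest(manifest_rows, out_dir / "manifest.csv")

    logger.info("stage segment+metrics")
    try:
        records = build_accuracy_records(subjects, config.segmentation)
    except ValueError as exc:
        raise StageError("segment", str(exc)) from exc
    accuracy_csv = write_records(records, out_dir / "accuracy_records.csv")

    logger.info("stage stats")
    try:
        stats = compute_stats(records, config.stats, config.dosimetry)
    except ValueError as exc:
        raise StageError("stats", str(exc)) from exc

    echo = config_to_dict(config)
    report = {"config": echo, "stats": stats}
    stats_json = out_dir / "stats.json"
    _dump_json(report, stats_json)

    if config.make_figures:
        try:
            _make_figures(records, stats, out_dir)
        except ImportError:
            logger.warning("matplotlib not available; skipping figures")

    return StudyReport(
        config=echo,
        stats=stats,
        accuracy_csv=accuracy_csv,
        manifest_csv=manifest_csv,
        stats_json=stats_json,
    )


def replay_stats(accuracy_csv: str | Path, config: StudyConfig) -> dict:
    """Re-run the statistics stage on a previously written accuracy table."""
    try:
        records = read_records(accuracy_csv)
    except ValueError as exc:
        raise StageError("stats", f"schema error: {exc}") from exc
    return compute_stats(records, config.stats, config.dosimetry)


def _make_figures(records, stats, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_frame(records)
    auto = df[df.source == "auto"]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, comp in zip(axes, ("SAT", "VAT")):
        sub = auto[auto.compartment == comp]
        for denoised, marker in ((False, "x"), (True, "o")):
            part = sub[sub.denoised == denoised]
            ax.scatter(
                part.ssde_5_25,
                part.accuracy,
                marker=marker,
                s=14,
                label="with NRT" if denoised else "without NRT",
            )
        ax.axhline(
            stats["acceptable_accuracy"][comp]["value"], color="red", ls="--", lw=1
        )
        ax.set_title(comp)
        ax.set_xlabel("SSDE$_{5.25}$ (mGy)")
    axes[0].set_ylabel("accuracy (%)")
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out_dir / "accuracy_vs_dose.png", dpi=120)
    plt.close(fig)
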