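"""Workflow orchestration: tie I/O, matching and calibration together.

Each workflow reads its inputs, runs the corresponding model, and writes a
deterministic set of artifacts into the output directory:

* ``ccs_records.tsv`` — the results table (fixed column order and sorting);
* ``calibration_*.json`` — fitted calibration coefficients where relevant;
* ``report.txt`` — a human-readable summary (counts, replicate statistics,
  flags), byte-identical across reruns on identical inputs;
* diagnostic figures when ``plots: true`` (failures degrade to warnings).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path

from .config import RunConfig
from .errors import DriftCCSError, InsufficientDataError
from .io import (
    CCSRecord,
    Feature,
    FrameMetadata,
    read_calibrants_csv,
    read_features_cef,
    read_features_csv,
    read_frame_metadata,
    read_targets_csv,
    write_ccs_records,
)
from .physics import get_buffer_gas
from .singlefield import (
    LinearCalibration,
    SingleFieldModel,
    assign_calibration_run,
    calibrate_features,
)
from .stepped import SteppedFieldModel, summarize_replicates
from .synth import (
    DriftScenario,
    SyntheticIon,
    TUNE_MIX_LIKE_IONS,
    make_single_field_campaign,
    make_stepped_field_campaign,
    make_twims_campaign,
)
from .targets import generate_target_ions, mass_error_ppm
from .twims import PolynomialTwimsModel, PowerTwimsModel

__all__ = ["run_workflow", "emit_report"]

logger = logging.getLogger(__name__)


def _read_features(path: Path) -> list[Feature]:
    if str(path).lower().endswith(".cef"):
        return read_features_cef(path)
    return read_features_csv(path)


def _group_by_run(features: list[Feature]) -> dict[str, list[Feature]]:
    out: dict[str, list[Feature]] = defaultdict(list)
    for f in features:
        out[f.run_id].append(f)
    return dict(out)


def _safe_plot(fn, *args, **kwargs) -> None:
    try:
        fn(*args, **kwargs)
    except Exception as exc:  # plotting must never fail a workflow
        logger.warning("figure generation failed: %s", exc)


# ---------------------------------------------------------------------------
# stepped-field workflow


def _run_stepped(config: RunConfig, outdir: Path) -> list[CCSRecord]:
    features = _read_features(config.features)
    metadata = read_frame_metadata(config.metadata)
    molecules = read_targets_csv(config.targets)
    gas = get_buffer_gas(config.gas)
    target_ions = generate_target_ions(molecules, config.adduct_specs(), config.polarity)
    logger.info("stepped: %d features, %d fields, %d target ions",
                len(features), len(metadata), len(target_ions))

    meta_by_run: dict[str, list[FrameMetadata]] = defaultdict(list)
    for m in metadata:
        meta_by_run[m.run_id].append(m)
    feats_by_run = _group_by_run(features)

    records: list[CCSRecord] = []
    ccs_by_ion: dict[tuple[str, str], list[float]] = defaultdict(list)
    for run_id in sorted(meta_by_run):
        run_meta = meta_by_run[run_id]
        per_field: dict[int, list[Feature]] = defaultdict(list)
        for f in feats_by_run.get(run_id, []):
            if f.field_id is not None:
                per_field[f.field_id].append(f)
        for target in target_ions:
            model = SteppedFieldModel(
                target, dict(per_field), run_meta, gas,
                tol_ppm=config.tolerance_ppm, max_rank=config.max_rank,
            )
            results = model.fit(r2_threshold=config.r2_threshold,
                                min_fields=config.min_fields)
            for i, rec in enumerate(results.to_records()):
                records.append(rec)
                if i == 0:  # best conformer feeds the replicate statistics
                    ccs_by_ion[(rec.name, rec.adduct)].append(rec.ccs)
            if config.plots and results.conformers:
                from .plotting import plot_stepped_fit
                safe = f"{target.name}_{target.adduct.label}".replace("/", "_")
                _safe_plot(plot_stepped_fit, results,
                           outdir / f"stepped_{run_id}_{safe}.png")
    _attach_replicate_stats(records, ccs_by_ion, outdir)
    return records


def _attach_replicate_stats(
    records: list[CCSRecord],
    ccs_by_ion: dict[tuple[str, str], list[float]],
    outdir: Path,
) -> None:
    lines = ["name\tadduct\tn\tmean_ccs\trsd_percent\tflags"]
    for (name, adduct) in sorted(ccs_by_ion):
        s = summarize_replicates(ccs_by_ion[(name, adduct)], name, adduct)
        lines.append(
            f"{s.name}\t{s.adduct}\t{s.n}\t{s.mean_ccs:.4f}\t"
            f"{s.rsd_percent:.4f}\t{';'.join(sorted(s.flags))}"
        )
    (outdir / "replicate_stats.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# single-field workflow


def _detect_calibrant_runs(
    feats_by_run: dict[str, list[Feature]], calibrants, tol_ppm: float
) -> set[str]:
    """A run is a calibrant run if at least two calibrants match in it."""
    cal_runs = set()
    for run_id, feats in feats_by_run.items():
        n = sum(
            1 for cal in calibrants
            if any(abs(mass_error_ppm(f.mz, cal.mz)) <= tol_ppm for f in feats)
        )
        if n >= 2:
            cal_runs.add(run_id)
    return cal_runs


def _run_single(config: RunConfig, outdir: Path) -> list[CCSRecord]:
    features = _read_features(config.features)
    metadata = read_frame_metadata(config.metadata)
    calibrants = read_calibrants_csv(config.calibrants)
    gas = get_buffer_gas(config.gas)

    feats_by_run = _group_by_run(features)
    meta_by_run: dict[str, list[FrameMetadata]] = defaultdict(list)
    for m in metadata:
        meta_by_run[m.run_id].append(m)

    cal_run_ids = _detect_calibrant_runs(feats_by_run, calibrants, config.tolerance_ppm)
    if not cal_run_ids:
        raise InsufficientDataError("no run matches >= 2 calibrants; cannot calibrate")
    logger.info("single: %d runs, %d detected calibrant runs", len(feats_by_run),
                len(cal_run_ids))

    calibrations: list[LinearCalibration] = []
    for run_id in sorted(cal_run_ids):
        model = SingleFieldModel(
            feats_by_run[run_id], calibrants, meta_by_run[run_id], gas,
            mode=config.mode, tol_ppm=config.tolerance_ppm,
        )
        res = model.fit()
        calibrations.append(res.calibration)
        res.calibration.write_json(outdir / f"calibration_{run_id}.json")
        if config.plots:
            from .plotting import plot_single_field_calibration
            _safe_plot(plot_single_field_calibration, res.calibration,
                       outdir / f"calibration_{run_id}.png")

    records: list[CCSRecord] = []
    for run_id in sorted(feats_by_run):
        if run_id in cal_run_ids:
            continue
        run_meta = meta_by_run.get(run_id)
        if not run_meta:
            logger.warning("run %s has no metadata; skipped", run_id)
            continue
        calibration, fallback = assign_calibration_run(run_meta[0], calibrations)
        extra = frozenset({"calibration_fallback"}) if fallback else frozenset()
        recs = calibrate_features(
            feats_by_run[run_id], calibration, gas,
            sample_conditions=run_meta, default_charge=config.default_charge,
            extra_flags=extra,
        )
        for r in recs:
            r.name = run_id
            r.adduct = f"z{r.charge_z}"
        records.extend(recs)
    return records


# ---------------------------------------------------------------------------
# traveling-wave workflow


def _run_twims(config: RunConfig, outdir: Path) -> list[CCSRecord]:
    features = _read_features(config.features)
    calibrants = read_calibrants_csv(config.calibrants)
    gas = get_buffer_gas(config.gas)
    logger.info("twims: %d features, %d calibrants, method=%s",
                len(features), len(calibrants), config.twims_method)

    if config.twims_method == "polynomial":
        model = PolynomialTwimsModel(
            features, calibrants, gas, degree_D=config.degree_D,
            t_acc=config.t_acc, tol_ppm=config.tolerance_ppm,
        )
    else:
        model = PowerTwimsModel(
            features, calibrants, gas, edc_C=config.edc_C,
            t_acc=config.t_acc, tol_ppm=config.tolerance_ppm,
        )
    res = model.fit()
    import json as _json
    (outdir / "calibration_twims.json").write_text(
        _json.dumps(res.calibration.to_json_dict(), indent=2) + "\n"
    )
    if config.plots:
        from .plotting import plot_twims_calibration
        _safe_plot(plot_twims_calibration, res.calibration,
                   outdir / "calibration_twims.png")
    records = res.predict(features, default_charge=config.default_charge)
    for r in records:
        r.name = f"mz{r.mz:.4f}"
        r.adduct = f"z{r.charge_z}"
    return records


# ---------------------------------------------------------------------------
# synthetic-campaign workflow


def _run_synth(config: RunConfig, outdir: Path) -> list[CCSRecord]:
    gas = get_buffer_gas(config.gas)
    if config.synth_kind == "stepped":
        ions = [SyntheticIon(t.name, t.mz, t.charge_z, t.ccs) for t in TUNE_MIX_LIKE_IONS]
        campaign = make_stepped_field_campaign(ions, gas=gas, seed=config.seed)
        campaign.write(outdir)
    elif config.synth_kind == "single":
        from .io import CalibrantIon
        cals = [
            CalibrantIon(t.name, t.mz, t.charge_z, t.ccs, t.polarity)
            for t in TUNE_MIX_LIKE_IONS
        ]
        samples = [SyntheticIon("sample_395", 395.1489, 1, 194.7)]
        scenario = DriftScenario(n_runs=30, pressure_model="step", seed=config.seed)
        campaign = make_single_field_campaign(cals, samples, scenario, gas=gas)
        campaign.write(outdir)
    else:
        from .io import CalibrantIon, write_features_csv
        cals = [
            CalibrantIon(t.name, t.mz, t.charge_z, t.ccs, t.polarity)
            for t in TUNE_MIX_LIKE_IONS
        ]
        samples = [SyntheticIon("sample_395", 395.1489, 1, 194.7)]
        campaign = make_twims_campaign(
            cals, samples, X_true=0.55, Y_true=25.0,
            t_acc=config.t_acc, edc_C=config.edc_C, gas=gas, seed=config.seed,
        )
        write_features_csv(campaign.calibrant_features + campaign.sample_features,
                           outdir / "features.csv")
    return []


# ---------------------------------------------------------------------------


def emit_report(records: list[CCSRecord], outdir: Path, config: RunConfig) -> Path:
    """Deterministic human-readable run summary (no timestamps)."""
    lines = [
        "driftccs run report",
        f"workflow: {config.workflow}",
        f"records: {len(records)}",
    ]
    if not records:
        lines.append("zero results")
    else:
        flagged = defaultdict(int)
        for r in records:
            for fl in r.flags:
                flagged[fl] += 1
        for fl in sorted(flagged):
            lines.append(f"flag {fl}: {flagged[fl]}")
        by_ion: dict[tuple[str, str], list[float]] = defaultdict(list)
        for r in records:
            if r.ccs is not None:
                by_ion[(r.name, r.adduct)].append(r.ccs)
        lines.append("per-ion statistics (name, adduct, n, mean CCS, %RSD):")
        for key in sorted(by_ion):
            s = summarize_replicates(by_ion[key], *key)
            lines.append(
                f"  {s.name}\t{s.adduct}\t{s.n}\t{s.mean_ccs:.4f}\t{s.rsd_percent:.4f}"
            )
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


_RUNNERS = {
    "stepped": _run_stepped,
    "single": _run_single,
    "twims": _run_twims,
    "synth": _run_synth,
}


def run_workflow(config: RunConfig) -> Path:
    """Execute the configured workflow; returns the output directory.

    Raises a :class:`DriftCCSError` subclass on any failure; partial outputs
    may exist but the results table is only written on success.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    records = _RUNNERS[config.workflow](config, outdir)
    if config.workflow != "synth":
        write_ccs_records(records, outdir / "ccs_records.tsv")
        emit_report(records, outdir, config)
    return outdir
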