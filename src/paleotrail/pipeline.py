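"""End-to-end orchestration from a YAML run configuration.

A run config selects stages (``simulate``, ``zooms``, ``calibrate``,
``mtdist``, ``niche``), gives their parameter blocks and input paths, one
output directory and one master seed. Stages execute in dependency order;
a JSON manifest records the config hash, seed, package versions, per-stage
outputs and every warning raised (age-bound swaps, regularized
covariances, clamped ages), so a run is auditable after the fact.
Re-running an identical config rewrites identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets
from .calibration import RadiocarbonDate, calibrate_date, hpd_intervals, load_curve
from .mtdna import SequenceAlignment, rank_dissimilarity
from .niche import ClimateField, box_timeseries, load_occurrences, run_monte_carlo
from .synth import (
    ClimateConfig,
    EnvelopeTruth,
    make_alignment,
    make_calcurve,
    make_climate,
    make_occurrences,
    make_peaklist,
)
from .zooms import MarkerTable, PeakList, classify_spectrum, summarize_assemblage
from .exceptions import ValidationError

__all__ = ["RunConfig", "run_config", "write_outputs"]

logger = logging.getLogger("paleotrail")

STAGES = ("simulate", "zooms", "calibrate", "mtdist", "niche")


@dataclass
class RunConfig:
    """Validated run configuration."""

    stages: list[str]
    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)  # stage name -> parameter block

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        stages = list(raw.get("stages", []))
        cfg = cls(
            stages=stages,
            out_dir=Path(raw.get("out_dir", "results")),
            seed=int(raw.get("seed", 0)),
            params={s: dict(raw.get(s, {})) for s in STAGES},
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            problems.append(f"unknown stage(s): {unknown}")
        if not isinstance(self.seed, int):
            problems.append("seed: must be a single integer")
        if "niche" in self.stages and "simulate" not in self.stages:
            if not self.params.get("niche", {}).get("climate"):
                problems.append(
                    "niche.climate: path to a climate NetCDF is required "
                    "when the simulate stage is not enabled"
                )
        if "mtdist" in self.stages and "simulate" not in self.stages:
            if not self.params.get("mtdist", {}).get("alignment"):
                problems.append(
                    "mtdist.alignment: FASTA path required without simulate"
                )
        for stage in self.stages:
            for key in ("climate", "alignment", "curve", "peaks", "markers",
                        "occurrences"):
                p = self.params.get(stage, {}).get(key)
                if p and not Path(p).exists():
                    problems.append(f"{stage}.{key}: path does not exist: {p}")
        if problems:
            raise ValidationError("; ".join(problems))

    def canonical_hash(self) -> str:
        payload = json.dumps(
            {
                "stages": self.stages,
                "seed": self.seed,
                "params": self.params,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_outputs(results: dict, out_dir) -> dict[str, str]:
    """Write stage results to ``out_dir``; returns {name: path} written.

    DataFrames go to CSV with headers, ClimateFields and xarray datasets
    to NetCDF, PeakLists/MarkerTables/alignments/curves through their own
    writers, everything else to JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=False)
        elif isinstance(obj, ClimateField):
            path = out_dir / f"{name}.nc"
            obj.to_netcdf(path)
        elif hasattr(obj, "to_netcdf"):  # xarray objects
            path = out_dir / f"{name}.nc"
            obj.to_netcdf(path, engine="scipy")
        elif isinstance(obj, (PeakList, MarkerTable)):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path)
        elif isinstance(obj, SequenceAlignment):
            path = out_dir / f"{name}.fasta"
            obj.to_fasta(path)
        else:
            path = out_dir / f"{name}.json"
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=2, default=str)
        written[name] = str(path)
    return written


def _stage_simulate(cfg: RunConfig, out: Path) -> dict[str, str]:
    p = cfg.params.get("simulate", {})
    climate_cfg = ClimateConfig(
        **{**{"seed": cfg.seed}, **p.get("climate_config", {})}
    )
    climate = make_climate(climate_cfg)
    boxes = datasets.region_boxes()
    truth = EnvelopeTruth(
        mean_T=p.get("truth_mean_T", -19.0),
        mean_P=p.get("truth_mean_P", 455.0),
        cov=np.array(p.get("truth_cov", [[25.0, 270.0], [270.0, 14400.0]])),
    )
    occurrences = make_occurrences(
        climate,
        truth,
        boxes,
        n_per_box=p.get("n_per_box", 10),
        age_uncertainty=p.get("age_uncertainty", 6000.0),
        seed=cfg.seed,
    )
    curve = make_calcurve(
        t_min=p.get("curve_t_min", 30_000.0),
        t_max=p.get("curve_t_max", 60_000.0),
        wiggle_amplitude=p.get("wiggle_amplitude", 150.0),
        curve_error=p.get("curve_error", 120.0),
        seed=cfg.seed,
    )
    alignment, planted = make_alignment(
        n_seqs=p.get("n_seqs", 8),
        length=p.get("aln_length", 16_600),
        planted_diffs=p.get("planted_diffs", [5, 9, 14, 23, 37, 55, 80]),
        missing_frac=p.get("missing_frac", 0.02),
        seed=cfg.seed,
    )
    markers = datasets.reference_markers()
    peaks = make_peaklist(
        p.get("peaklist_taxon", "Equus"),
        markers,
        jitter_sd=p.get("jitter_sd", 0.05),
        n_noise_peaks=p.get("n_noise_peaks", 10),
        seed=cfg.seed,
    )
    results = {
        "climate": climate,
        "occurrences": occurrences,
        "calcurve_frame": pd.DataFrame(
            {"cal_bp": curve.t, "c14_age": curve.mu, "error": curve.sig_c}
        ),
        "alignment": alignment,
        "peaklist": peaks,
        "planted_diffs": planted,
    }
    return write_outputs(results, out / "simulate")


def _stage_zooms(cfg: RunConfig, out: Path) -> dict[str, str]:
    p = cfg.params.get("zooms", {})
    markers = (
        MarkerTable.from_csv(p["markers"])
        if p.get("markers")
        else datasets.reference_markers()
    )
    tol = p.get("tol", 0.2)
    min_markers = p.get("min_markers", 4)
    if p.get("peaks"):
        peak_paths = sorted(Path().glob(p["peaks"])) or [Path(p["peaks"])]
        labelled = [(pp.stem, PeakList.from_csv(pp)) for pp in peak_paths]
    else:
        labelled = [("Star 1 (Z00113)", datasets.star1_peaks())]
    rows = []
    for label, peaks in labelled:
        a = classify_spectrum(peaks, markers, tol=tol, min_markers=min_markers)
        rows.append(
            {
                "spectrum": label,
                "taxon": a.taxon,
                "n_matched": a.n_matched,
                "matched_markers": ";".join(sorted(a.matched_markers)),
            }
        )
    return write_outputs({"assignments": pd.DataFrame(rows)}, out / "zooms")


def _stage_calibrate(cfg: RunConfig, out: Path) -> dict[str, str]:
    p = cfg.params.get("calibrate", {})
    if p.get("curve"):
        curve = load_curve(p["curve"])
    else:
        curve = make_calcurve(
            30_000.0, 60_000.0, wiggle_amplitude=150.0, curve_error=120.0,
            seed=cfg.seed,
        )
    if p.get("dates"):
        dates = [
            RadiocarbonDate(age=d["age"], sigma=d["sigma"],
                            lab_code=d.get("lab_code", ""))
            for d in p["dates"]
        ]
    else:
        dates = list(datasets.radiocarbon_dates().values())
    levels = p.get("levels", [0.683, 0.954])
    rows = []
    for date in dates:
        density = calibrate_date(date, curve)
        for level in levels:
            hpd = hpd_intervals(density, level)
            for older, younger in hpd.intervals:
                rows.append(
                    {
                        "lab_code": date.lab_code,
                        "c14_age": date.age,
                        "sigma": date.sigma,
                        "level": level,
                        "older_cal_bp": older,
                        "younger_cal_bp": younger,
                    }
                )
    return write_outputs({"intervals": pd.DataFrame(rows)}, out / "calibrate")


def _stage_mtdist(cfg: RunConfig, out: Path) -> dict[str, str]:
    p = cfg.params.get("mtdist", {})
    aln_path = p.get("alignment") or (
        cfg.out_dir / "simulate" / "alignment.fasta"
    )
    aln = SequenceAlignment.from_fasta(aln_path)
    focal = p.get("focal", aln.names[0])
    ranked = rank_dissimilarity(aln, focal)
    frame = pd.DataFrame(
        [
            {
                "focal": r.seq_a,
                "other": r.seq_b,
                "n_diff": r.n_diff,
                "n_comparable": r.n_comparable,
            }
            for r in ranked
        ]
    )
    return write_outputs({"pairwise_differences": frame}, out / "mtdist")


def _stage_niche(cfg: RunConfig, out: Path) -> dict[str, str]:
    p = cfg.params.get("niche", {})
    climate_path = p.get("climate") or (cfg.out_dir / "simulate" / "climate.nc")
    field = ClimateField.from_netcdf(climate_path)
    records = load_occurrences(
        p["occurrences"] if p.get("occurrences") else datasets.starosele_occurrences()
    )
    boxes = datasets.region_boxes()
    if p.get("boxes"):
        from .niche import RegionBox

        boxes = {
            b["label"]: RegionBox(
                b["label"], b["lon_min"], b["lon_max"], b["lat_min"], b["lat_max"]
            )
            for b in p["boxes"]
        }
    ensemble = run_monte_carlo(
        records,
        boxes,
        k_per_box=p.get("k_per_box", 2),
        field=field,
        n_members=p.get("n_members", 5000),
        seed=cfg.seed,
        distance_mode=p.get("distance_mode", "quadratic"),
    )
    series_frames = []
    for label in boxes:
        bs = box_timeseries(ensemble, boxes[label])
        series_frames.append(
            pd.DataFrame(
                {"box": label, "time_bp": bs.time, "mean_suitability": bs.mean}
            )
        )
    results = {
        "suitability_mean": ensemble.mean_dataset(),
        "box_timeseries": pd.concat(series_frames, ignore_index=True),
    }
    return write_outputs(results, out / "niche")


_RUNNERS = {
    "simulate": _stage_simulate,
    "zooms": _stage_zooms,
    "calibrate": _stage_calibrate,
    "mtdist": _stage_mtdist,
    "niche": _stage_niche,
}


def run_config(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.canonical_hash(),
        "seed": cfg.seed,
        "versions": {
            "paleotrail": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "warnings": [],
    }
    ordered = [s for s in STAGES if s in cfg.stages]
    for stage in ordered:
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs = _RUNNERS[stage](cfg, out)
            except Exception as exc:
                logger.error("stage %s failed: %s", stage, exc)
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["warnings"].extend(
            f"{stage}: {w.message}" for w in caught
        )
        manifest["stages"][stage] = {
            "outputs": outputs,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        logger.info("stage %s done in %.2fs", stage,
                    manifest["stages"][stage]["elapsed_s"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
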