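"""End-to-end orchestration: simulate -> detect -> classify -> noise ->
aggregate -> fit, with a machine-readable run manifest.

Configuration is a nested dict (usually loaded from YAML) with one block per
stage; every block is optional and falls back to the stage defaults.  A run
writes every intermediate artifact as CSV/JSON next to the WAV files, so any
stage can be audited or re-run in isolation, and is deterministic given the
seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import detect as det
from . import gee, noise, scene, solar
from .audio import AudioSegment, hour_filename, parse_hour_filename, read_wav, write_wav

__all__ = ["load_config", "run_pipeline", "validate_io", "simulate_site"]

DEFAULT_CONFIG = {
    "site": {"id": "synthetic", "latitude": -62.38, "longitude": 81.8},
    "seed": 0,
    "simulate": {
        "start": "2014-03-01T00:00:00",
        "n_hours": 48,
        "fs": 250.0,
        "pulse": {},  # PulseTrainSpec overrides
        "noise": {},  # NoiseSpec overrides
        "transients": {"rate_per_hour": 0.0},
        "presence": {
            "intercept_logit": 0.0,
            "regime_logit_effects": {"dawn": 0.0, "day": -1.0, "dusk": 0.0, "night": 1.0},
            "ar1_rho": 0.5,
        },
    },
    "spectrogram": {},  # SpectrogramParams overrides
    "detector": {},  # DetectorConfig overrides
    "regime": {},  # RegimeConfig overrides
    "noise_metric": {},  # NoiseConfig overrides
    "model": {"noise_col": "noise_p20_db", "reference": "night", "cov_struct": "ar1"},
}


def _merged(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merged(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a pipeline config YAML and fill unset fields with defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merged(cfg, yaml.safe_load(fh) or {})
    return _merged(cfg, overrides)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def simulate_site(cfg: dict, out_dir: str | Path) -> dict:
    """Render one hourly WAV per simulated hour plus ground-truth CSVs.

    Light regimes for the site's hour grid drive a Gaussian-copula AR1
    presence series; present hours receive a stereotyped pulse train at the
    configured SNR.  Returns counts for the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = cfg["simulate"]
    site = cfg["site"]
    loc = solar.GeoLocation(site["latitude"], site["longitude"])
    start = datetime.fromisoformat(sim["start"]).replace(tzinfo=timezone.utc)
    hours = [start + timedelta(hours=h) for h in range(int(sim["n_hours"]))]
    regimes = solar.classify_series(loc, hours, solar.RegimeConfig(**cfg["regime"]))["regime"].tolist()

    pres_spec = scene.PresenceSeriesSpec(seed=int(cfg["seed"]), **sim["presence"])
    presence = scene.generate_presence_series(pres_spec, regimes, start_time=start, site=site["id"])
    presence.to_csv(out_dir / "truth_presence.csv", index=False)

    pulse_spec = scene.PulseTrainSpec(**sim["pulse"])
    noise_spec = scene.NoiseSpec(**sim["noise"])
    tr_cfg = sim.get("transients") or {}
    tr_spec = scene.TransientSpec(**tr_cfg) if tr_cfg.get("rate_per_hour", 0) else None

    truth_rows = []
    n_pulses = 0
    for h, (hour_start, present) in enumerate(zip(hours, presence["presence"])):
        seg, truth = scene.render_scene(
            [pulse_spec] if present else [],
            noise_spec,
            tr_spec,
            start_time=hour_start,
            duration=3600.0,
            fs=float(sim["fs"]),
            seed=int(cfg["seed"]) * 100003 + h,
            site=site["id"],
        )
        write_wav(out_dir / hour_filename(site["id"], hour_start), seg)
        frame = truth.to_frame()
        frame["utc_hour"] = hour_start.isoformat()
        truth_rows.append(frame)
        n_pulses += len(truth.pulse_times)
    pd.concat(truth_rows, ignore_index=True).to_csv(out_dir / "truth_scene.csv", index=False)
    return {"n_hours": len(hours), "n_true_pulses": n_pulses, "n_present_hours": int(presence["presence"].sum())}


def _stage_configs(cfg: dict):
    params = det.SpectrogramParams(**_tuplify(cfg["spectrogram"]))
    detector = det.DetectorConfig(**_tuplify(cfg["detector"]))
    regime_cfg = solar.RegimeConfig(**cfg["regime"])
    noise_cfg = noise.NoiseConfig(**cfg["noise_metric"])
    return params, detector, regime_cfg, noise_cfg


def run_pipeline(cfg: dict, out_dir: str | Path, wav_paths: list[Path] | None = None) -> dict:
    """Run the full stage chain and write a manifest.

    When ``wav_paths`` is None the synthetic-scene stage generates the hourly
    WAVs first.  Any stage error aborts with the stage name attached.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "seed": cfg["seed"], "stages": {}, "warnings": []}
    site = cfg["site"]
    loc = solar.GeoLocation(site["latitude"], site["longitude"])
    params, detector, regime_cfg, noise_cfg = _stage_configs(cfg)

    stage = "simulate"
    try:
        if wav_paths is None:
            manifest["stages"][stage] = simulate_site(cfg, out_dir)
            wav_paths = sorted(out_dir.glob(f"{site['id']}_*.wav"))
        manifest["input_files"] = [p.name for p in wav_paths]

        stage = "detect"
        det_frames, hour_starts = [], []
        for path in wav_paths:
            seg = read_wav(path)
            hour_starts.append(seg.start_time)
            events = det.detect(seg, detector, params)
            det_frames.append(det.events_to_frame(events, seg))
        detections = pd.concat(det_frames, ignore_index=True) if det_frames else pd.DataFrame()
        detections.to_csv(out_dir / "detections.csv", index=False)
        n_cand = int(len(detections))
        n_acc = int(detections["accepted"].sum()) if n_cand else 0
        manifest["stages"][stage] = {
            "n_candidates": n_cand,
            "n_accepted": n_acc,
            "n_rejected": n_cand - n_acc,
        }

        stage = "classify"
        regimes = solar.classify_series(loc, hour_starts, regime_cfg, with_altitude=True)
        regimes.to_csv(out_dir / "regimes.csv", index=False)
        manifest["stages"][stage] = {"n_hours": int(len(regimes))}

        stage = "noise"
        noise_rows = []
        for path in wav_paths:
            seg = read_wav(path)
            series = noise.band_levels(seg, noise_cfg)
            noise_rows.append(noise.hourly_percentile(series, noise_cfg))
        noise_tbl = pd.concat(noise_rows, ignore_index=True)
        noise_tbl = noise_tbl.rename(columns={"p_db": "noise_p20_db"})
        noise_tbl.to_csv(out_dir / "noise.csv", index=False)
        manifest["stages"][stage] = {"n_hours": int(len(noise_tbl))}

        stage = "aggregate"
        accepted_times = detections.loc[detections["accepted"], "utc_time"] if n_cand else []
        hourly = agg.hourly_presence(accepted_times, hour_starts)
        hourly["site"] = site["id"]
        hourly["utc_hour"] = pd.to_datetime(hourly["utc_hour"], utc=True)
        regimes["utc_hour"] = pd.to_datetime(regimes["utc_hour"], utc=True)
        noise_tbl["utc_hour"] = pd.to_datetime(noise_tbl["utc_hour"], utc=True)
        hourly = hourly.merge(regimes[["utc_hour", "regime"]], on="utc_hour", how="left")
        hourly = hourly.merge(noise_tbl[["utc_hour", "noise_p20_db"]], on="utc_hour", how="left")
        hourly.to_csv(out_dir / "hourly.csv", index=False)
        dd_table, totals = agg.detection_days(hourly)
        dd_table.to_csv(out_dir / "detection_days.csv", index=False)
        matrix = agg.presence_matrix(hourly)
        pd.DataFrame(matrix).to_csv(out_dir / "presence_matrix.csv", index=False)
        if totals["n_detection_days"]:
            agg.regime_proportions(dd_table).to_csv(out_dir / "regime_summary.csv", index=False)
        manifest["stages"][stage] = totals

        stage = "fit"
        model_cfg = cfg["model"]
        if totals["n_detection_days"] >= 2 and dd_table["presence"].nunique() > 1:
            try:
                res = gee.fit_gee(
                    dd_table,
                    noise_col=model_cfg.get("noise_col"),
                    reference=model_cfg.get("reference", "night"),
                    cov_struct=model_cfg.get("cov_struct", "ar1"),
                )
            except ValueError as exc:
                if "separation" not in str(exc) or model_cfg.get("noise_col") is None:
                    raise
                # near-constant noise covariates can separate small datasets;
                # refit on light regime alone and record the downgrade
                manifest["warnings"].append(f"noise covariate dropped from the model: {exc}")
                res = gee.fit_gee(
                    dd_table,
                    noise_col=None,
                    reference=model_cfg.get("reference", "night"),
                    cov_struct=model_cfg.get("cov_struct", "ar1"),
                )
            report = {
                "coefficients": res.params.to_dict(),
                "robust_se": res.bse.to_dict(),
                "robust_cov": res.cov_robust.values.tolist(),
                "ar1_alpha": res.ar1_alpha,
                "n_obs": res.n_obs,
                "n_clusters": res.n_clusters,
                "converged": res.converged,
                "contrasts": res.contrasts().assign(pair=lambda d: d["pair"].map(list)).to_dict("records"),
                "letters": res.letters(),
                "durbin_watson": res.durbin_watson(),
                "acf": res.acf(max_lag=min(12, res.n_obs - 1)).tolist(),
            }
            with open(out_dir / "report.json", "w") as fh:
                json.dump(report, fh, indent=2)
            manifest["stages"][stage] = {"converged": res.converged, "n_clusters": res.n_clusters}
        else:
            manifest["warnings"].append("fit skipped: fewer than two detection days with mixed presence")
            manifest["stages"][stage] = {"skipped": True}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def validate_io(paths: list[str | Path]) -> list[dict]:
    """Validate WAV headers and CSV schemas; returns a list of issues (empty = ok)."""
    from scipy.io import wavfile

    issues: list[dict] = []
    for path in map(Path, paths):
        if not path.exists():
            issues.append({"file": path.name, "issue": "missing"})
            continue
        if path.suffix.lower() == ".wav":
            try:
                _, data = wavfile.read(path)
            except Exception as exc:
                issues.append({"file": path.name, "issue": f"unreadable: {exc}"})
                continue
            if data.ndim != 1:
                issues.append({"file": path.name, "issue": f"channels={data.shape[1]} unsupported"})
            if data.dtype not in (np.int16, np.int32, np.float32, np.float64, np.uint8):
                issues.append({"file": path.name, "issue": f"sample format {data.dtype} unsupported"})
            try:
                parse_hour_filename(path.name)
            except ValueError:
                issues.append({"file": path.name, "issue": "filename not <site>_<YYYYMMDDTHH>.wav"})
        elif path.suffix.lower() == ".csv":
            df = pd.read_csv(path)
            if "utc_hour" in df.columns:
                try:
                    pd.to_datetime(df["utc_hour"], utc=True, format="ISO8601")
                except (ValueError, TypeError):
                    issues.append({"file": path.name, "issue": "utc_hour not ISO 8601"})
                if df["utc_hour"].duplicated().any():
                    issues.append({"file": path.name, "issue": "duplicate utc_hour values"})
    return issues
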