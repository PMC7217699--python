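"""End-to-end pipeline: generate a synthetic session, analyse it, report.

Every run writes a manifest (inputs, parameters, seed, package version,
outputs, per-stage timings) so any result can be reproduced from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, io
from .cystometry import detect_nvcs, detect_voids, eus_burst_metrics, process_emg
from .ephys import phase_profile, pressure_rate_xcorr
from .params import ModelParams
from .synthetic import GeneratorConfig, generate_recording

log = logging.getLogger("micturition")


def build_generator_config(cfg: dict) -> GeneratorConfig:
    """Assemble a GeneratorConfig from a flat config mapping.

    Model parameters live under the ``model`` key, generator settings
    under ``generator``; both sections are optional.
    """
    model = ModelParams.from_dict(cfg.get("model", {}))
    gen = dict(cfg.get("generator", {}))
    return GeneratorConfig(model=model, **gen)


def run_pipeline(out_dir, config: Optional[dict] = None, n_voids: int = 8, seed: int = 0) -> dict:
    """generate -> analyse -> report; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or {}
    gen_cfg = build_generator_config(cfg)
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "n_voids": int(n_voids),
        "config": cfg,
        "stages": {},
        "outputs": [],
    }

    def _stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    def _done(name, t0, *paths):
        manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        manifest["outputs"] += [str(p) for p in paths]
        log.info("stage %s done in %.2fs", name, manifest["stages"][name])

    try:
        t0 = _stage("generate")
        rec = generate_recording(gen_cfg, n_voids=n_voids, seed=seed)
        p_path = out / "pressure.csv"
        io.write_trace(p_path, rec.pressure)
        s_path = out / "spikes.csv"
        io.write_spikes(s_path, rec.units)
        e_path = out / "emg.csv"
        io.write_trace(e_path, rec.emg)
        _done("generate", t0, p_path, s_path, e_path)

        t0 = _stage("cystometry")
        voids = detect_voids(rec.pressure)
        vt = [v.peak_time for v in voids]
        nvcs = detect_nvcs(rec.pressure, void_times=vt)
        import pandas as pd

        v_path = out / "voids.csv"
        io.write_table(v_path, pd.DataFrame([vars(v) for v in voids]))
        n_path = out / "nvcs.csv"
        io.write_table(n_path, pd.DataFrame([vars(e) for e in nvcs]))
        env = process_emg(rec.emg)
        bursts = eus_burst_metrics(rec.emg, [(t - 10, t + 10) for t in vt])
        b_path = out / "eus_bursts.csv"
        io.write_table(b_path, pd.DataFrame(bursts))
        _done("cystometry", t0, v_path, n_path, b_path)

        t0 = _stage("ephys")
        results = []
        for u in rec.units:
            xc = pressure_rate_xcorr(u, rec.pressure)
            prof = phase_profile(u, vt, n_phases=10, zscore=True)
            results.append(
                {
                    "unit_id": u.unit_id,
                    "n_spikes": u.n_spikes,
                    "xcorr_peak_lag_s": xc.peak_lag,
                    "xcorr_peak_r": float(xc.values.max()),
                    "final_decile_z": float(prof.zscored[-1]),
                }
            )
        u_path = out / "units.json"
        u_path.write_text(json.dumps(results, indent=1))
        _done("ephys", t0, u_path)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise

    m_path = out / "manifest.json"
    m_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
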