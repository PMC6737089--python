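"""End-to-end orchestration: config validation, staged run, machine-readable report.

A run is configured by a single YAML/JSON mapping with exactly one input
source — a ``synthetic`` generation block or an ``inputs`` block of file
paths — plus optional stage-parameter blocks.  Every analysis constant
(neuropil coefficient 0.9, 10-s baseline window, ANOVA p < 0.01, 10 shuffle
repeats, the collapse b grid) surfaces as a config default rather than a
hard-coded literal, and all randomness derives from the single ``seed``,
so identical config + seed reproduces the report byte-for-byte.
"""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import yaml

from . import io as akio
from .avalanches import classify_evoked, extract_ensembles, shuffle_raster, summarize_by_level
from .containers import SpikeProbRaster, StimulusProtocol
from .errors import ConfigError, DegenerateSampleError, EmptyTailError, StageError
from .popstats import compare_groups, neuron_stats_table, pairwise_xcorr
from .powerlaw_stats import collapse_scan, fit_alpha_ks, fit_models_mle
from .synthetic import make_stimulus_protocol, synth_fluorescence, synth_session
from .traces import compute_dff, neuropil_correct, optimize_lambda_thr, responsive_neurons
from .tuning import compute_rf, tuning_vs_scale

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "run_pipeline"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "avakit_out",
    "synthetic": None,  # block: see examples/pipeline_demo.yaml
    "inputs": None,  # block: {raster: .h5, protocol: .csv}
    "threshold": {"lambda_thr": None, "n_candidates": 40},
    "preprocess": {"window_s": 10.0, "alpha_np": 0.9, "p_crit": 0.01},
    "shuffle": {"n_repeats": 10},
    "fit": {"x_min": 1, "alpha_lo": -4.0, "alpha_hi": -1.01, "alpha_step": 0.01},
    "collapse": {"b_lo": -0.5, "b_hi": 0.5, "b_step": 0.001},
    "tuning": {"n_bins": 8},
    "figures": False,
}

SYNTH_DEFAULTS: dict = {
    "n_neurons": 120,
    "protocol": {
        "freq_lo": 3000.0, "freq_hi": 48000.0, "tones_per_octave": 2,
        "levels": [40.0, 60.0, 80.0], "reps": 5, "stim_dur": 1.0,
        "isi_range": [4.0, 6.0], "frame_rate": 30.0,
    },
    "branching_param": 1.0,
    "drive_rate": 0.02,
    "rate_ongoing": 0.0,
    "tuning_width": 0.5,
    "evoked_drive_per_level": [0.05, 0.1, 0.2],
    "fluorescence": None,  # block: {kernel_tau, np_contamination, noise_sd}
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    """Read a YAML (or JSON — YAML superset) config and apply defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("config must be a mapping")
    cfg = _merge(DEFAULT_CONFIG, user)
    if cfg.get("synthetic") is not None:
        cfg["synthetic"] = _merge(SYNTH_DEFAULTS, cfg["synthetic"])
    return cfg


def validate_config(config: dict) -> list[str]:
    """Return an empty list iff the config is runnable; else named violations."""
    v: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, config)
    has_synth = cfg.get("synthetic") is not None
    has_inputs = cfg.get("inputs") is not None
    if has_synth == has_inputs:
        v.append("exactly one of 'synthetic' and 'inputs' must be present")
    if has_inputs and not (cfg["inputs"] or {}).get("raster"):
        v.append("inputs.raster: path required")
    if not isinstance(cfg.get("seed"), int):
        v.append("seed: must be an integer")
    col = cfg["collapse"]
    if col["b_lo"] < -0.5 or col["b_hi"] > 0.5:
        v.append("collapse.b_lo/b_hi: the scan range is bounded to [-0.5, 0.5]")
    if col["b_step"] <= 0:
        v.append("collapse.b_step: must be positive")
    fit = cfg["fit"]
    if not (fit["alpha_lo"] < fit["alpha_hi"] <= -1.0):
        v.append("fit.alpha_lo/alpha_hi: slope grid must satisfy lo < hi <= -1")
    if fit["x_min"] < 1:
        v.append("fit.x_min: must be >= 1")
    pre = cfg["preprocess"]
    if not (0 < pre["p_crit"] < 1):
        v.append("preprocess.p_crit: must be in (0, 1)")
    if pre["window_s"] <= 0:
        v.append("preprocess.window_s: must be positive")
    if cfg["shuffle"]["n_repeats"] < 1:
        v.append("shuffle.n_repeats: must be >= 1")
    if has_synth:
        syn = _merge(SYNTH_DEFAULTS, cfg["synthetic"])
        if syn["n_neurons"] < 2:
            v.append("synthetic.n_neurons: must be >= 2")
        if len(syn["evoked_drive_per_level"]) != len(syn["protocol"]["levels"]):
            v.append("synthetic.evoked_drive_per_level: one entry per sound level")
    return v


def _fit_block(values: np.ndarray, fit_cfg: dict) -> dict:
    """KS slope + MLE model comparison for one sample, as a report block."""
    grid = np.round(
        np.arange(fit_cfg["alpha_lo"], fit_cfg["alpha_hi"] + 1e-9, fit_cfg["alpha_step"]), 10
    )
    out: dict = {"n": int(values.size)}
    try:
        ks = fit_alpha_ks(values, alpha_grid=grid, x_min=fit_cfg["x_min"])
        mle = fit_models_mle(values, x_min=fit_cfg["x_min"])
    except (EmptyTailError, DegenerateSampleError) as e:
        out["error"] = str(e)
        return out
    out.update(
        alpha_ks=ks.alpha_hat, ks_distance=ks.ks_distance,
        alpha_mle=mle.alpha_hat, llr=mle.llr, llr_p=mle.p_value,
        loglik_pl=mle.loglik_pl, loglik_exp=mle.loglik_exp,
    )
    return out


def run_pipeline(
    config: dict,
    output_dir: str | Path | None = None,
    stop_after: str | None = None,
) -> dict:
    """Execute all applicable stages and write artifacts plus a JSON report.

    Stage order: input (synthesize or load) -> threshold -> avalanches
    (+ shuffle null) -> power-law fits (+ collapse if a protocol with
    several levels is present) -> tuning (if fluorescence is available) ->
    population stats.  ``stop_after`` names a stage to finish early at.
    A stage failure raises ``StageError`` naming the stage; artifacts
    written so far stay on disk next to a failure marker.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigError("; ".join(problems))
    cfg = _merge(DEFAULT_CONFIG, config)
    if cfg.get("synthetic") is not None:
        cfg["synthetic"] = _merge(SYNTH_DEFAULTS, cfg["synthetic"])
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": cfg, "stages": {}}
    ss = np.random.SeedSequence(cfg["seed"])
    seed_synth, seed_shuffle, seed_fluor = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )

    def fail(stage: str, exc: Exception) -> StageError:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        akio.save_json(out / "report.json", report)
        return StageError(stage, str(exc))

    # ---- input ----------------------------------------------------------
    stage = "input"
    try:
        protocol: StimulusProtocol | None
        pairs = None
        if cfg["synthetic"] is not None:
            syn = cfg["synthetic"]
            pp = syn["protocol"]
            protocol = make_stimulus_protocol(
                freq_lo=pp["freq_lo"], freq_hi=pp["freq_hi"],
                tones_per_octave=pp["tones_per_octave"], levels=pp["levels"],
                reps=pp["reps"], stim_dur=pp["stim_dur"],
                isi_range=tuple(pp["isi_range"]), frame_rate=pp["frame_rate"],
                seed=seed_synth,
            )
            raster, truth = synth_session(
                protocol, n_neurons=syn["n_neurons"],
                branching_param=syn["branching_param"], drive_rate=syn["drive_rate"],
                rate_ongoing=syn["rate_ongoing"], tuning_width=syn["tuning_width"],
                evoked_drive_per_level=syn["evoked_drive_per_level"], seed=seed_synth,
            )
            akio.save_raster_h5(out / "raster.h5", raster, truth)
            akio.save_protocol_csv(out / "protocol.csv", protocol)
            if syn["fluorescence"] is not None:
                fl = syn["fluorescence"]
                pairs = synth_fluorescence(
                    raster, kernel_tau=fl.get("kernel_tau", 0.7),
                    np_contamination=fl.get("np_contamination", 0.0),
                    noise_sd=fl.get("noise_sd", 0.0), seed=seed_fluor,
                )
        else:
            raster, _ = akio.load_raster_h5(cfg["inputs"]["raster"])
            protocol = (
                akio.load_protocol_csv(cfg["inputs"]["protocol"])
                if cfg["inputs"].get("protocol") else None
            )
        report["stages"][stage] = {
            "n_neurons": raster.n_neurons, "n_frames": raster.n_frames,
            "frame_rate": raster.frame_rate,
            "n_trials": len(protocol) if protocol else 0,
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise fail(stage, e) from e


    if stop_after == "input":
        akio.save_json(out / "report.json", report)
        return report

    # ---- threshold -------------------------------------------------------
    stage = "threshold"
    try:
        thr_cfg = cfg["threshold"]
        if thr_cfg.get("lambda_thr") is not None:
            lam_thr = float(thr_cfg["lambda_thr"])
            binary = raster.threshold(lam_thr)
            curve = None
        else:
            scan = optimize_lambda_thr(raster)
            lam_thr, binary, curve = scan.lambda_thr, scan.raster, scan.curve
            curve.to_csv(out / "threshold_scan.csv", index=False)
        report["stages"][stage] = {"lambda_thr": lam_thr}
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e) from e


    if stop_after == "threshold":
        akio.save_json(out / "report.json", report)
        return report

    # ---- avalanches ------------------------------------------------------
    stage = "avalanches"
    try:
        catalog = extract_ensembles(binary, with_members=True)
        if protocol is not None and len(protocol):
            classify_evoked(catalog, protocol)
        catalog.to_frame(protocol).to_csv(out / "ensembles.csv", index=False)
        shuf = shuffle_raster(
            raster, lam_thr, n_repeats=cfg["shuffle"]["n_repeats"], seed=seed_shuffle
        )
        shuf_catalog = extract_ensembles(shuf.threshold(lam_thr), with_members=False)
        report["stages"][stage] = {
            "n_ensembles": len(catalog),
            "n_evoked": int(catalog.evoked_mask.sum()),
            "n_ensembles_shuffled": len(shuf_catalog),
            "shuffle_repeats": cfg["shuffle"]["n_repeats"],
        }
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e) from e


    if stop_after == "avalanches":
        akio.save_json(out / "report.json", report)
        return report

    # ---- power-law fits --------------------------------------------------
    stage = "fit"
    try:
        fit_cfg = cfg["fit"]
        ongoing = ~catalog.evoked_mask
        blocks = {
            "ongoing_size": _fit_block(catalog.sizes[ongoing], fit_cfg),
            "ongoing_duration": _fit_block(catalog.durations[ongoing], fit_cfg),
            "shuffled_size": _fit_block(shuf_catalog.sizes, fit_cfg),
            "shuffled_duration": _fit_block(shuf_catalog.durations, fit_cfg),
        }
        has_evoked = protocol is not None and bool(catalog.evoked_mask.any())
        if has_evoked:
            ev = catalog.evoked_mask
            blocks["evoked_size"] = _fit_block(catalog.sizes[ev], fit_cfg)
            blocks["evoked_duration"] = _fit_block(catalog.durations[ev], fit_cfg)
            summary = summarize_by_level(catalog, protocol)
            summary.table.to_csv(out / "level_summary.csv", index=False)
            blocks["level_trend"] = {
                "rho_size": summary.rho_size, "p_size": summary.p_size,
                "rho_duration": summary.rho_duration, "p_duration": summary.p_duration,
            }
            levels_of = np.asarray([t.level_db for t in protocol.trials])
            by_level = {}
            for L in protocol.levels:
                sel = [
                    e.size for e in catalog.ensembles
                    if e.evoked and levels_of[e.stimulus_id] == L
                ]
                if len(sel) >= 50:
                    by_level[float(L)] = np.asarray(sel)
            if len(by_level) >= 2 and "alpha_ks" in blocks["evoked_size"]:
                col = cfg["collapse"]
                res = collapse_scan(
                    by_level, alpha=blocks["evoked_size"]["alpha_ks"],
                    b_grid=(col["b_lo"], col["b_hi"], col["b_step"]),
                )
                blocks["collapse_size"] = {
                    "b_hat": res.b_hat, "degenerate": res.degenerate,
                }
        report["stages"][stage] = blocks
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e) from e


    if stop_after == "fit":
        akio.save_json(out / "report.json", report)
        return report

    # ---- tuning (needs fluorescence + protocol) --------------------------
    stage = "tuning"
    try:
        if pairs is not None and protocol is not None and len(protocol):
            pre = cfg["preprocess"]
            dffs = []
            for p in pairs:
                d_soma = compute_dff(p.f_soma, frame_rate=raster.frame_rate,
                                     window_s=pre["window_s"], neuron_id=p.neuron_id)
                d_np = compute_dff(p.f_neuropil, frame_rate=raster.frame_rate,
                                   window_s=pre["window_s"], neuron_id=p.neuron_id)
                dffs.append(neuropil_correct(d_soma, d_np, alpha_np=pre["alpha_np"]))
            mask, pvals = responsive_neurons(dffs, protocol, p_crit=pre["p_crit"])
            np.savetxt(
                out / "responsive.csv",
                np.column_stack([np.arange(mask.size), pvals, mask]),
                delimiter=",", header="neuron_id,p_value,responsive", comments="",
                fmt=["%d", "%.6g", "%d"],
            )
            rfs = {d.neuron_id: compute_rf(d, protocol) for d in dffs}
            tuning_blocks = {}
            for metric in ("iqr_bf", "bandwidth"):
                for axis in ("size", "duration"):
                    table, rho, p = tuning_vs_scale(
                        catalog, rfs, metric=metric, axis=axis,
                        n_bins=cfg["tuning"]["n_bins"],
                    )
                    table.to_csv(out / f"tuning_{metric}_vs_{axis}.csv", index=False)
                    tuning_blocks[f"{metric}_vs_{axis}"] = {"rho": rho, "p": p}
            tuning_blocks["n_responsive"] = int(mask.sum())
            report["stages"][stage] = tuning_blocks
        else:
            report["stages"][stage] = {"skipped": "no fluorescence traces or no protocol"}
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e) from e


    if stop_after == "tuning":
        akio.save_json(out / "report.json", report)
        return report

    # ---- population stats ------------------------------------------------
    stage = "stats"
    try:
        if protocol is not None and len(protocol):
            stim = protocol.stimulus_mask(raster.n_frames)
        else:
            stim = np.zeros(raster.n_frames, dtype=bool)
        ongoing_tab = neuron_stats_table(binary, ~stim, condition="ongoing")
        tables = [ongoing_tab]
        block = {
            "ongoing_rate_mean": float(ongoing_tab["rate_hz"].mean()),
            "ongoing_cv_mean": float(ongoing_tab["cv_isi"].mean(skipna=True)),
        }
        if stim.any():
            evoked_tab = neuron_stats_table(binary, stim, condition="evoked")
            tables.append(evoked_tab)
            z, p = compare_groups(ongoing_tab["rate_hz"], evoked_tab["rate_hz"])
            block.update(
                evoked_rate_mean=float(evoked_tab["rate_hz"].mean()),
                rate_ranksum_z=z, rate_ranksum_p=p,
            )
        import pandas as pd

        pd.concat(tables).to_csv(out / "neuron_stats.csv", index=False)
        corr = pairwise_xcorr(raster)
        off = corr.offdiag()
        block.update(
            xcorr_mean=float(off.mean()),
            xcorr_frac_above_0p1=float((off > 0.1).mean()),
            n_excluded_constant=int(corr.excluded.size),
        )
        report["stages"][stage] = block
    except Exception as e:  # noqa: BLE001
        raise fail(stage, e) from e

    if cfg.get("figures"):
        try:
            from .plots import render_report_figures

            render_report_figures(report, catalog, shuf_catalog, out)
        except Exception as e:  # noqa: BLE001
            raise fail("figures", e) from e

    akio.save_json(out / "report.json", report)
    return report
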