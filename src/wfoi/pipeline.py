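"""End-to-end pipeline orchestration and session containers.

One :class:`RunConfig` drives the full stage order: read -> demultiplex
-> dark subtraction -> (optional) landmark alignment -> masking ->
relative intensity -> absorption change -> haemoglobin inversion ->
fluorescence correction -> epoching -> response metrics -> behaviour
statistics.  Every run writes its artifacts plus a machine-readable
provenance record (config hash, package version, per-stage parameters)
so identical configs reproduce identical outputs.

On-disk layout of a session directory (all open formats):
``stack.tif`` interleaved frames, ``acquisition.yaml`` channel cycle and
frame rate, ``landmarks.json``, ``protocol.yaml``, and after a run a
``results.h5`` container with per-channel and derived datasets, a
``metrics.csv`` of per-trial metrics and a ``stats.json`` report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from . import __version__
from .errors import InvalidArgumentError, StageError
from .fluorescence import FluorescenceSeries, lsr_correct, mbll_correct, no_correction
from .hemodynamics import absorption_change, isosbestic_proxy, solve_haemoglobin
from .metrics import (
    StimulusProtocol,
    behaviour_split,
    epoch_extract,
    recovery_time_t90,
    response_auc,
    undershoot_auc,
)
from .group_stats import cohens_d_pooled, levene, welch_t_p
from .phantom import PhantomSession
from .registration import LandmarkAnnotation, fit_alignment, warp
from .spectra import (
    ExtinctionTable,
    PathlengthTable,
    extinction_matrix,
    load_default_extinction,
    load_default_pathlengths,
)
from .stack_io import (
    ChannelSequence,
    FrameStack,
    demultiplex,
    read_stack,
    relative_series,
    subtract_dark,
    write_stack,
)

__all__ = ["RunConfig", "run_pipeline", "save_phantom", "load_session_inputs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see module docstring).

    ``correction_method`` is one of {'lsr', 'mbll', 'none'};
    ``baseline`` is 'full-mean' or a [t0, t1] window in seconds;
    ``epoch_window`` is (pre_s, post_s) around each train onset.
    """

    session_dir: str
    out_dir: str
    correction_method: str = "lsr"
    baseline: object = "full-mean"
    dark: float = 0.0
    align: bool = False
    bregma_ref: tuple = (16.0, 32.0)
    global_mean_subtract: bool = False
    epoch_window: tuple = (2.0, 15.0)
    calcium_auc_window: tuple | None = None   # default: the stimulation epoch
    hb_auc_window: tuple = (0.0, 10.0)
    roi: str = "auto"                          # brightest-response pixel block
    extinction_csv: str | None = None
    pathlengths_yaml: str | None = None
    seed: int = 0

    def validate(self):
        if self.correction_method not in ("lsr", "mbll", "none"):
            raise InvalidArgumentError(
                f"correction_method must be lsr|mbll|none, got {self.correction_method!r}")
        sd = Path(self.session_dir)
        for name in ("stack.tif", "acquisition.yaml", "protocol.yaml"):
            if not (sd / name).exists():
                raise InvalidArgumentError(f"missing input file {sd / name}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# session directory I/O


def save_phantom(session: PhantomSession, outdir) -> Path:
    """Write a simulated session to disk in the standard directory layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_stack(outdir / "stack.tif", session.frames.astype(np.float32))

    seq = [{"label": c.label, "wavelength_nm": c.wavelength_nm, "role": c.role}
           for c in session.sequence]
    with open(outdir / "acquisition.yaml", "w") as fh:
        yaml.safe_dump({"frame_rate_hz": session.config.frame_rate_hz,
                        "sequence": seq, "dark": 0.0, "start_offset": 0}, fh)
    with open(outdir / "protocol.yaml", "w") as fh:
        yaml.safe_dump({
            "train_onsets": [float(x) for x in session.protocol.train_onsets],
            "pulses_per_train": session.protocol.pulses_per_train,
            "pulse_duration_s": session.protocol.pulse_duration_s,
            "pulse_rate_hz": session.protocol.pulse_rate_hz,
            "labels": [str(x) for x in session.trial_labels],
        }, fh)
    with open(outdir / "landmarks.json", "w") as fh:
        json.dump({"bregma": list(session.landmarks.bregma_px),
                   "lambda": list(session.landmarks.lambda_px)}, fh)
    with h5py.File(outdir / "truth.h5", "w") as h5:
        h5.create_dataset("d_hbo_t_uM", data=session.d_hbo_t)
        h5.create_dataset("d_hhb_t_uM", data=session.d_hhb_t)
        h5.create_dataset("f_true_t", data=session.f_true_t)
        h5.create_dataset("spatial_map", data=session.spatial_map)
        h5.create_dataset("mask", data=session.mask.astype(np.uint8))
        h5.create_dataset("trial_amplitudes", data=session.trial_amplitudes)
    return outdir


def load_session_inputs(session_dir):
    """Load stack, acquisition config, protocol and optional landmarks."""
    sd = Path(session_dir)
    with open(sd / "acquisition.yaml") as fh:
        acq = yaml.safe_load(fh)
    frames, timestamps = read_stack(sd / "stack.tif",
                                    frame_rate_hz=acq["frame_rate_hz"])
    sequence = ChannelSequence.from_config(acq["sequence"])
    with open(sd / "protocol.yaml") as fh:
        prot_cfg = yaml.safe_load(fh)
    protocol = StimulusProtocol(
        np.asarray(prot_cfg["train_onsets"], dtype=float),
        pulses_per_train=int(prot_cfg.get("pulses_per_train", 4)),
        pulse_duration_s=float(prot_cfg.get("pulse_duration_s", 0.2)),
        pulse_rate_hz=float(prot_cfg.get("pulse_rate_hz", 1.0)))
    labels = prot_cfg.get("labels")
    landmarks = None
    lm_path = sd / "landmarks.json"
    if lm_path.exists():
        with open(lm_path) as fh:
            lm = json.load(fh)
        landmarks = LandmarkAnnotation(tuple(lm["bregma"]), tuple(lm["lambda"]))
    return {"frames": frames, "timestamps": timestamps, "sequence": sequence,
            "acquisition": acq, "protocol": protocol, "labels": labels,
            "landmarks": landmarks}


# --------------------------------------------------------------------------
# full pipeline


def _merge_channels(stacks: list[FrameStack]) -> dict:
    """Merge demuxed cycle slots that share a channel label (e.g. 470 x2)."""
    merged: dict[str, FrameStack] = {}
    for s in stacks:
        label = s.channel.label
        if label not in merged:
            merged[label] = s
        else:
            prev = merged[label]
            order = np.argsort(np.concatenate([prev.timestamps, s.timestamps]))
            data = np.concatenate([prev.data, s.data])[order]
            ts = np.concatenate([prev.timestamps, s.timestamps])[order]
            idx = np.concatenate([prev.frame_indices, s.frame_indices])[order]
            merged[label] = FrameStack(data, ts, channel=prev.channel,
                                       frame_indices=idx)
    return merged


def _auto_roi(hb_map, mask, block: int = 3) -> np.ndarray:
    """Boolean ROI: a small block around the strongest-response pixel."""
    score = np.where(mask, hb_map, -np.inf)
    r, c = np.unravel_index(np.argmax(score), score.shape)
    roi = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    roi[max(0, r - block):min(h, r + block + 1),
        max(0, c - block):min(w, c + block + 1)] = True
    return roi & mask


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages for one session; returns results and writes artifacts.

    Raises :class:`StageError` naming the failing stage.  Re-running with
    an identical config and inputs reproduces numerically identical
    outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        inputs = load_session_inputs(config.session_dir)
        table = (ExtinctionTable.from_csv(config.extinction_csv)
                 if config.extinction_csv else load_default_extinction())
        paths = (PathlengthTable.from_yaml(config.pathlengths_yaml)
                 if config.pathlengths_yaml else load_default_pathlengths())
        protocol = inputs["protocol"]

        stage = "demultiplex"
        slots = demultiplex(inputs["frames"], inputs["timestamps"],
                            inputs["sequence"],
                            start_offset=int(inputs["acquisition"].get("start_offset", 0)))

        stage = "dark-subtraction"
        dark = inputs["acquisition"].get("dark", config.dark)
        slots = [subtract_dark(s, dark) for s in slots]
        channels = _merge_channels(slots)

        stage = "alignment"
        transform = None
        if config.align and inputs["landmarks"] is not None:
            transform = fit_alignment(inputs["landmarks"], config.bregma_ref)
            channels = {
                lab: FrameStack(warp(s.data, transform, "bilinear"),
                                s.timestamps, channel=s.channel,
                                frame_indices=s.frame_indices)
                for lab, s in channels.items()}

        stage = "masking"
        some = next(iter(channels.values()))
        mean_img = some.data.mean(axis=0)
        mean_img = np.nan_to_num(mean_img, nan=0.0)
        from .registration import mask_from_threshold
        mask = mask_from_threshold(mean_img, 0.1)

        stage = "relative-intensity"
        baseline = (config.baseline if config.baseline == "full-mean"
                    else tuple(config.baseline))
        relative = {lab: relative_series(s, baseline)
                    for lab, s in channels.items()}

        stage = "haemoglobin-inversion"
        refl = [s for s in channels.values()
                if s.channel.role == "reflectance"]
        refl_lams = sorted({s.channel.wavelength_nm for s in refl})
        hb = None
        hb_predictor = None
        if len(refl_lams) >= 2:
            l1, l2 = refl_lams[0], refl_lams[-1]
            r1 = next(relative[s.channel.label] for s in refl
                      if s.channel.wavelength_nm == l1)
            r2 = next(relative[s.channel.label] for s in refl
                      if s.channel.wavelength_nm == l2)
            a1 = absorption_change(r1, paths.get(l1))
            a2 = absorption_change(r2, paths.get(l2))
            zmat = extinction_matrix(table, l1, l2)
            # the two reflectance series are offset by the cycle timing;
            # pair frames one-to-one in acquisition order
            n = min(len(a1.delta_mua), len(a2.delta_mua))
            a1.delta_mua, a2.delta_mua = a1.delta_mua[:n], a2.delta_mua[:n]
            a1.timestamps = a1.timestamps[:n]
            hb = solve_haemoglobin(a1, a2, zmat)
            hb_predictor = ("d_hbt", hb.d_hbt, hb.timestamps)
        elif len(refl_lams) == 1:
            r = next(iter(
                relative[s.channel.label] for s in refl))
            proxy = isosbestic_proxy(r, table)
            results["proxy_percent"] = proxy
            hb_predictor = ("proxy", proxy, r.timestamps)
        results["hb"] = hb

        stage = "fluorescence-correction"
        fluor_labels = [s.channel.label for s in channels.values()
                        if s.channel.role == "fluorescence-excitation"]
        corrected = None
        fit = None
        if fluor_labels:
            lab = fluor_labels[0]
            f = FluorescenceSeries(relative[lab].ratios,
                                   timestamps=relative[lab].timestamps)
            if config.correction_method == "none":
                corrected = no_correction(f)
            elif config.correction_method == "mbll":
                lam_ex = channels[lab].channel.wavelength_nm
                lam_em = 530.0
                if hb is None:
                    raise StageError(stage, "MBLL correction needs two "
                                     "reflectance wavelengths")
                zx = extinction_matrix(table, lam_ex, lam_em)
                dmua_ex = (zx.matrix[0, 0] * _resample_stack(hb.d_hbo, hb.timestamps, f.timestamps)
                           + zx.matrix[0, 1] * _resample_stack(hb.d_hhb, hb.timestamps, f.timestamps)) * 1e-6
                dmua_em = (zx.matrix[1, 0] * _resample_stack(hb.d_hbo, hb.timestamps, f.timestamps)
                           + zx.matrix[1, 1] * _resample_stack(hb.d_hhb, hb.timestamps, f.timestamps)) * 1e-6
                from .hemodynamics import AbsorptionChange
                corrected = mbll_correct(
                    f, AbsorptionChange(dmua_ex, lam_ex),
                    AbsorptionChange(dmua_em, lam_em),
                    paths.get(lam_ex), paths.get(lam_em))
            else:  # lsr
                if hb_predictor is None:
                    raise StageError(stage, "LSR correction needs a "
                                     "haemodynamic predictor channel")
                name, pred_stack, pred_ts = hb_predictor
                pred = _resample_stack(pred_stack, pred_ts, f.timestamps)
                fit, corrected = lsr_correct(f, pred)
            if config.global_mean_subtract:
                from .registration import global_mean_subtract as gms
                corrected = FluorescenceSeries(
                    gms(corrected.f_rel - 1.0, mask) + 1.0,
                    timestamps=corrected.timestamps)
        results["fluorescence"] = corrected
        results["regression_fit"] = fit

        stage = "epoching-metrics"
        metrics_rows = []
        labels = inputs["labels"]
        roi = None
        if hb is not None:
            map_img = np.abs(hb.d_hbt).mean(axis=0)
            roi = _auto_roi(np.nan_to_num(map_img), mask)
        elif corrected is not None:
            roi = _auto_roi(np.abs(corrected.f_rel - 1).mean(axis=0), mask)
        epochs = {}
        if roi is not None:
            stim_win = (0.0, protocol.train_duration_s)
            if corrected is not None:
                tr = corrected.f_rel[:, roi].mean(axis=1)
                epochs["calcium"] = epoch_extract(
                    100.0 * (tr - 1.0), corrected.timestamps, protocol,
                    window=config.epoch_window, labels=labels)
            if hb is not None:
                tr = hb.d_hbt[:, roi].mean(axis=1)
                epochs["hbt"] = epoch_extract(
                    tr, hb.timestamps, protocol,
                    window=config.epoch_window, labels=labels)
            for name, em in epochs.items():
                win = (config.calcium_auc_window or stim_win) if name == "calcium" \
                    else tuple(config.hb_auc_window)
                for i in range(em.n_trials):
                    metrics_rows.append({
                        "signal": name, "trial": i, "label": em.labels[i],
                        "auc": response_auc(em.data[i], em.time_s, win),
                        "t90_s": recovery_time_t90(em.data[i], em.time_s, protocol),
                        "post_auc_abs": undershoot_auc(em.data[i], em.time_s, protocol),
                    })
        results["epochs"] = epochs
        results["roi"] = roi
        results["mask"] = mask

        stage = "statistics"
        stats_report = {}
        for name, em in epochs.items():
            if labels is None:
                continue
            split = behaviour_split(em)
            rest, loco = split["rest"], split["locomotion"]
            if rest.n_trials >= 2 and loco.n_trials >= 2:
                win = ((config.calcium_auc_window or (0.0, protocol.train_duration_s))
                       if name == "calcium" else tuple(config.hb_auc_window))
                auc_r = np.array([response_auc(r, em.time_s, win) for r in rest.data])
                auc_l = np.array([response_auc(r, em.time_s, win) for r in loco.data])
                t, df, p = welch_t_p(auc_r, auc_l)
                stats_report[name] = {
                    "n_rest": len(auc_r), "n_locomotion": len(auc_l),
                    "mean_rest": float(auc_r.mean()), "sd_rest": float(auc_r.std(ddof=1)),
                    "mean_locomotion": float(auc_l.mean()),
                    "sd_locomotion": float(auc_l.std(ddof=1)),
                    "welch_t": t, "welch_df": df, "welch_p": p,
                    "cohens_d": cohens_d_pooled(auc_r, auc_l),
                    "levene_F": levene(auc_r, auc_l)[0],
                    "levene_p": levene(auc_r, auc_l)[1],
                }
        results["stats"] = stats_report

        stage = "write-outputs"
        _write_outputs(out, config, results, metrics_rows, transform)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise StageError(stage, str(exc)) from exc
    return results


def _resample_stack(stack, src_ts, dst_ts):
    """Nearest-neighbour temporal resampling of a (t, h, w) stack."""
    idx = np.clip(np.searchsorted(src_ts, dst_ts), 0, len(src_ts) - 1)
    # snap to the nearer neighbour
    left = np.clip(idx - 1, 0, len(src_ts) - 1)
    use_left = np.abs(src_ts[left] - dst_ts) < np.abs(src_ts[idx] - dst_ts)
    idx = np.where(use_left, left, idx)
    return np.asarray(stack)[idx]


def _resample_to(predictor, dst_ts):
    if predictor is None:
        return None
    name, stack, ts = predictor
    return _resample_stack(stack, ts, dst_ts)


def _write_outputs(out: Path, config: RunConfig, results: dict,
                   metrics_rows: list, transform) -> None:
    import pandas as pd

    with h5py.File(out / "results.h5", "w") as h5:
        hb = results.get("hb")
        if hb is not None:
            g = h5.create_group("hb")
            g.create_dataset("d_hbo_uM", data=hb.d_hbo)
            g.create_dataset("d_hhb_uM", data=hb.d_hhb)
            g.create_dataset("d_hbt_uM", data=hb.d_hbt)
            g.create_dataset("timestamps", data=hb.timestamps)
            g.attrs["wavelengths_nm"] = hb.wavelengths_nm
        fl = results.get("fluorescence")
        if fl is not None:
            g = h5.create_group("fluorescence")
            g.create_dataset("f_rel_corrected", data=fl.f_rel)
            g.create_dataset("timestamps", data=fl.timestamps)
            g.attrs["method"] = config.correction_method
        fit = results.get("regression_fit")
        if fit is not None:
            g = h5.create_group("regression")
            g.create_dataset("beta0", data=fit.beta0)
            g.create_dataset("beta1", data=fit.beta1)
        if results.get("mask") is not None:
            h5.create_dataset("mask", data=results["mask"].astype(np.uint8))
        if results.get("roi") is not None:
            h5.create_dataset("roi", data=results["roi"].astype(np.uint8))

    if metrics_rows:
        pd.DataFrame(metrics_rows).to_csv(out / "metrics.csv", index=False)
    if results.get("stats"):
        with open(out / "stats.json", "w") as fh:
            json.dump(results["stats"], fh, indent=2)

    provenance = {
        "package": "wfoi", "version": __version__,
        "config": asdict(config), "config_hash": config.config_hash(),
        "alignment": None if transform is None else {
            "rotation_rad": transform.rotation, "scale": transform.scale,
            "pivot": list(transform.pivot), "offset": list(transform.offset)},
        "coordinate_convention": "0-based (row, col); row increases caudally "
                                 "after alignment",
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
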