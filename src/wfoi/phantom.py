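"""Forward optical phantom: simulated sessions with known ground truth.

The phantom prescribes haemoglobin concentration changes and a true
fluorescence field on a pixel grid, then renders the interleaved
multi-LED stack a camera would record through the exponential
Beer-Lambert forward model:

* reflectance channel at wavelength l:
  ``I = I0 * vignette * drift(t) * exp(-dmu_a(l) * X(l))`` with
  ``dmu_a(l) = (zeta_HbO(l) * d_HbO + zeta_HHb(l) * d_HHb)`` (molar);
* fluorescence channel:
  ``I = I0 * vignette * drift(t) * F_true
  * exp(-(dmu_a(l_ex) * X_ex + dmu_a(l_em) * X_em))``.

Haemodynamic responses follow a stimulus-locked double-gamma kernel
inside a smooth responsive disc; calcium transients are per-pulse
rise/decay exponentials.  Per-trial amplitudes jitter multiplicatively,
and designated "locomotion" trials are scaled up to emulate the larger
responses seen during movement.  Read (Gaussian) and shot (Poisson)
noise are applied last.  All ground truth is retained in separable
(time profile x spatial map) form, which is lossless and compact.

Two random streams keep the determinism contract: ``seed`` drives the
measurement noise only, while ``amplitude_seed`` drives the trial
amplitude jitter that is part of the ground truth — so different noise
seeds share identical truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidArgumentError
from .metrics import StimulusProtocol
from .registration import LandmarkAnnotation
from .spectra import (
    ExtinctionTable,
    PathlengthTable,
    load_default_extinction,
    load_default_pathlengths,
    to_natural_log_coefficient,
    interpolate_extinction,
)
from .stack_io import Channel, ChannelSequence

__all__ = ["PhantomConfig", "PhantomSession", "simulate_session",
           "recovery_report", "default_sequence"]


def default_sequence() -> ChannelSequence:
    """The 4-slot LED cycle 470 -> 530 -> 470 -> 656 nm."""
    return ChannelSequence((
        Channel("LED470", 470.0, "fluorescence-excitation"),
        Channel("LED530", 530.0, "reflectance"),
        Channel("LED470", 470.0, "fluorescence-excitation"),
        Channel("LED656", 656.0, "reflectance"),
    ))


def double_gamma(t, peak_s: float = 2.0, undershoot_peak_s: float = 8.0,
                 undershoot_frac: float = 0.2, shape: float = 6.0):
    """Canonical double-gamma haemodynamic kernel, 0 for t < 0.

    Each gamma bump ``(t/peak)^shape * exp(-(t-peak)*shape/peak)`` has
    unit analytic peak, so the kernel shape is independent of the
    sampling grid; the positive lobe peaks at ~1 (minus the small
    undershoot contribution at ``peak_s``).
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gamma_bump(tt, peak):
        return (tt / peak) ** shape * np.exp(-(tt - peak) * shape / peak)

    out[pos] = gamma_bump(tp, peak_s) - undershoot_frac * gamma_bump(
        tp, undershoot_peak_s)
    return out


def calcium_transient(t, rise_s: float = 0.05, decay_s: float = 0.4):
    """Unit-analytic-peak rise/decay calcium transient, 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    g = (1.0 - np.exp(-tp / rise_s)) * np.exp(-tp / decay_s)
    t_peak = rise_s * np.log1p(decay_s / rise_s)
    g_peak = (1.0 - np.exp(-t_peak / rise_s)) * np.exp(-t_peak / decay_s)
    out[pos] = g / g_peak
    return out


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the forward simulation (see module docstring)."""

    shape: tuple[int, int] = (64, 64)
    frame_rate_hz: float = 20.0          # interleaved camera rate
    duration_s: float = 440.0
    sequence: ChannelSequence = field(default_factory=default_sequence)
    baseline_counts: dict = field(default_factory=lambda: {
        "LED470": 4000.0, "LED530": 8000.0, "LED656": 12000.0})
    protocol: StimulusProtocol = field(default_factory=lambda:
        StimulusProtocol.regular(10.0, 20.0, 21))

    # responsive region: smooth disc, centre and radius as grid fractions
    region_center: tuple[float, float] = (0.5, 0.5)
    region_radius_frac: float = 0.25

    # haemodynamic kernel (double-gamma) and amplitudes, uM at region centre
    d_hbo_peak_um: float = 10.0
    d_hhb_peak_um: float = -3.0
    hemo_peak_s: float = 2.0
    hemo_undershoot_s: float = 8.0
    hemo_undershoot_frac: float = 0.2

    # calcium kernel (per stimulus pulse), relative-fluorescence amplitude
    calcium_amplitude: float = 0.05
    calcium_rise_s: float = 0.05
    calcium_decay_s: float = 0.4

    # trial-to-trial structure; locomotion scales the haemodynamic response
    # far more than the calcium response, so the gains are separate
    amplitude_cv: float = 0.25
    locomotion_trials: tuple = ()
    locomotion_gain: float = 3.5
    locomotion_gain_hemo: float = 9.6
    amplitude_seed: int = 1234

    # optics / nuisance terms
    vignetting_strength: float = 0.15
    drift_amplitude: float = 0.0
    drift_period_s: float = 60.0
    read_noise_sd: float = 0.0
    poisson_noise: bool = False
    emission_wavelength_nm: float = 530.0
    # hold haemoglobin truth constant within each LED cycle: haemodynamics
    # are slow relative to the cycle, and the hold makes the interleaved
    # forward model exactly invertible channel-by-channel
    hemo_hold_per_cycle: bool = True

    extinction: ExtinctionTable | None = None
    pathlengths: PathlengthTable | None = None
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise InvalidArgumentError("rates and durations must be > 0")
        h, w = self.shape
        r, c = self.region_center
        if not (0 <= r <= 1 and 0 <= c <= 1) or self.region_radius_frac <= 0:
            raise InvalidArgumentError("responsive region must lie inside the grid")

    def with_(self, **kw) -> "PhantomConfig":
        return replace(self, **kw)


@dataclass
class PhantomSession:
    """A simulated session: rendered stack plus lossless ground truth.

    Ground truth is separable: each quantity is a time profile times the
    spatial map; :meth:`truth_field` expands it for arbitrary frame
    indices.
    """

    frames: np.ndarray               # (t, h, w) noisy counts
    timestamps: np.ndarray
    sequence: ChannelSequence
    config: PhantomConfig
    protocol: StimulusProtocol
    spatial_map: np.ndarray          # (h, w) in [0, 1]
    d_hbo_t: np.ndarray              # (t,) uM at region centre
    d_hhb_t: np.ndarray
    f_true_t: np.ndarray             # (t,) relative fluorescence at centre
    trial_amplitudes: np.ndarray
    trial_labels: np.ndarray
    landmarks: LandmarkAnnotation = None
    mask: np.ndarray = None

    def truth_field(self, quantity: str, frame_indices=None) -> np.ndarray:
        """Expand a truth quantity to (t, h, w) for the given frame indices.

        ``quantity`` in {'d_hbo', 'd_hhb', 'f_true'}; note fluorescence
        is ``1 + amplitude * map`` while the haemoglobin fields are pure
        ``amplitude * map``.
        """
        idx = np.arange(len(self.timestamps)) if frame_indices is None else frame_indices
        if quantity == "d_hbo":
            return self.d_hbo_t[idx, None, None] * self.spatial_map[None]
        if quantity == "d_hhb":
            return self.d_hhb_t[idx, None, None] * self.spatial_map[None]
        if quantity == "f_true":
            return 1.0 + (self.f_true_t[idx] - 1.0)[:, None, None] * self.spatial_map[None]
        raise InvalidArgumentError(f"unknown truth quantity {quantity!r}")

    def channel_indices(self, label: str) -> np.ndarray:
        """Raw frame indices belonging to a channel label."""
        L = len(self.sequence)
        slots = [i for i, ch in enumerate(self.sequence) if ch.label == label]
        n = len(self.timestamps)
        return np.sort(np.concatenate(
            [np.arange(s, n, L) for s in slots])) if slots else np.array([], int)


def _spatial_map(shape, center_frac, radius_frac) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    r0, c0 = center_frac[0] * (h - 1), center_frac[1] * (w - 1)
    radius = radius_frac * min(h, w)
    rho = np.hypot(rr - r0, cc - c0) / radius
    # raised-cosine disc: 1 at centre, smooth to 0 at the rim
    return np.where(rho < 1.0, 0.5 * (1.0 + np.cos(np.pi * rho)), 0.0)


def _vignette(shape, strength) -> np.ndarray:
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    rho2 = (((rr - (h - 1) / 2) / (h / 2)) ** 2
            + ((cc - (w - 1) / 2) / (w / 2)) ** 2)
    return 1.0 - strength * rho2 / 2.0


def simulate_session(config: PhantomConfig) -> PhantomSession:
    """Render a complete interleaved session from a :class:`PhantomConfig`."""
    cfg = config
    table = cfg.extinction or load_default_extinction()
    paths = cfg.pathlengths or load_default_pathlengths()

    h, w = cfg.shape
    n_frames = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n_frames) / cfg.frame_rate_hz
    L = len(cfg.sequence)

    # ---- ground-truth time profiles -------------------------------------
    amp_rng = np.random.default_rng(cfg.amplitude_seed)
    n_trains = cfg.protocol.n_trains
    amps = np.clip(amp_rng.normal(1.0, cfg.amplitude_cv, size=n_trains), 0.2, None)
    amps_ca = amps.copy()
    amps_hemo = amps.copy()
    labels = np.array(["rest"] * n_trains, dtype=object)
    for k in cfg.locomotion_trials:
        labels[k] = "locomotion"
        amps_ca[k] *= cfg.locomotion_gain
        amps_hemo[k] *= cfg.locomotion_gain_hemo

    hemo = np.zeros(n_frames)
    ca = np.zeros(n_frames)
    for k, onset in enumerate(cfg.protocol.train_onsets):
        hemo += amps_hemo[k] * double_gamma(
            t - onset, peak_s=cfg.hemo_peak_s,
            undershoot_peak_s=cfg.hemo_undershoot_s,
            undershoot_frac=cfg.hemo_undershoot_frac)
        for j in range(cfg.protocol.pulses_per_train):
            ca += amps_ca[k] * calcium_transient(
                t - (onset + j / cfg.protocol.pulse_rate_hz),
                rise_s=cfg.calcium_rise_s, decay_s=cfg.calcium_decay_s)

    d_hbo_t = cfg.d_hbo_peak_um * hemo
    d_hhb_t = cfg.d_hhb_peak_um * hemo
    f_true_t = 1.0 + cfg.calcium_amplitude * ca
    if cfg.hemo_hold_per_cycle:
        cycle_start = (np.arange(n_frames) // L) * L
        d_hbo_t = d_hbo_t[cycle_start]
        d_hhb_t = d_hhb_t[cycle_start]

    smap = _spatial_map(cfg.shape, cfg.region_center, cfg.region_radius_frac)
    vig = _vignette(cfg.shape, cfg.vignetting_strength)
    drift = 1.0 + cfg.drift_amplitude * np.sin(2 * np.pi * t / cfg.drift_period_s)

    # natural-log extinction coefficients per wavelength of interest
    def zeta(lam):
        return to_natural_log_coefficient(np.array(interpolate_extinction(table, lam)))

    em_lam = cfg.emission_wavelength_nm
    z_em = zeta(em_lam)
    x_em = paths.get(em_lam)

    # ---- render frames ---------------------------------------------------
    frames = np.empty((n_frames, h, w), dtype=float)
    for slot, chan in enumerate(cfg.sequence):
        idx = np.arange(slot, n_frames, L)
        i0 = cfg.baseline_counts[chan.label]
        x_c = paths.get(chan.wavelength_nm)
        z_c = zeta(chan.wavelength_nm)
        # molar absorption-change profile at the region centre, cm^-1
        mua_t = (z_c[0] * d_hbo_t[idx] + z_c[1] * d_hhb_t[idx]) * 1e-6
        atten = np.exp(-mua_t[:, None, None] * smap[None] * x_c)
        if chan.role == "fluorescence-excitation":
            mua_ex_t = mua_t  # excitation-band absorption change
            mua_em_t = (z_em[0] * d_hbo_t[idx] + z_em[1] * d_hhb_t[idx]) * 1e-6
            atten = np.exp(-(mua_ex_t * x_c + mua_em_t * x_em)[:, None, None]
                           * smap[None])
            f_field = 1.0 + (f_true_t[idx] - 1.0)[:, None, None] * smap[None]
            frames[idx] = i0 * vig[None] * drift[idx, None, None] * f_field * atten
        else:
            frames[idx] = i0 * vig[None] * drift[idx, None, None] * atten

    noise_rng = np.random.default_rng(cfg.seed)
    if cfg.poisson_noise:
        frames = noise_rng.poisson(np.maximum(frames, 0.0)).astype(float)
    if cfg.read_noise_sd > 0:
        frames = frames + noise_rng.normal(0.0, cfg.read_noise_sd, frames.shape)

    landmarks = LandmarkAnnotation(
        bregma_px=(0.25 * (h - 1), 0.5 * (w - 1)),
        lambda_px=(0.85 * (h - 1), 0.5 * (w - 1)))
    mask = vig > 0  # whole illuminated field

    return PhantomSession(frames=frames, timestamps=t, sequence=cfg.sequence,
                          config=cfg, protocol=cfg.protocol, spatial_map=smap,
                          d_hbo_t=d_hbo_t, d_hhb_t=d_hhb_t, f_true_t=f_true_t,
                          trial_amplitudes=amps, trial_labels=labels,
                          landmarks=landmarks, mask=mask)


def recovery_report(truth: np.ndarray, estimate: np.ndarray,
                    region_mask=None) -> dict:
    """Error metrics of a recovered field against ground truth.

    Returns overall and (optionally) in-region RMSE, peak-amplitude
    relative error, and Pearson correlation.  Shapes must match.
    """
    truth = np.asarray(truth, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if truth.shape != est.shape:
        raise InvalidArgumentError(
            f"truth shape {truth.shape} != estimate shape {est.shape}")

    def _metrics(a, b):
        diff = b - a
        rmse = float(np.sqrt(np.mean(diff ** 2)))
        max_abs = float(np.max(np.abs(diff)))
        peak_t = np.max(np.abs(a))
        peak_rel = float(abs(np.max(np.abs(b)) - peak_t) / peak_t) if peak_t > 0 else np.nan
        if np.std(a) > 0 and np.std(b) > 0:
            corr = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
        else:
            corr = np.nan
        return {"rmse": rmse, "max_abs_error": max_abs,
                "peak_rel_error": peak_rel, "correlation": corr}

    out = {"overall": _metrics(truth, est)}
    if region_mask is not None:
        m = np.asarray(region_mask, dtype=bool)
        out["region"] = _metrics(truth[..., m], est[..., m])
    return out
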