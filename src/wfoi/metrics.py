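"""Stimulus-evoked response metrics.

A stimulation session delivers repeated trains of brief pulses (e.g. 21
trains of 4 x 200 ms pulses at 1 Hz, one train every 20 s).  The
operations here cut a region-of-interest trace into per-train epochs,
and compute the evoked-response metrics used for method and behaviour
comparisons:

* AUC — trapezoidal area under the baseline-subtracted response over an
  integration window (calcium: the stimulation epoch; haemoglobin: 0-10 s
  after train onset; maps: 0-5 s);
* t90 — time after the response peak at which the trace has recovered 90%
  of its peak deviation back toward baseline, measured from the stimulus
  train offset (anchor configurable), with linear interpolation between
  samples;
* |PostAUC| — absolute area of the below-baseline (undershoot) lobe over
  a window anchored at train offset;
* cumulative response maps — pixel-wise summed responses across trains,
  min-max normalised over the brain mask;
* behaviour split — partition of epochs into rest / locomotion groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "StimulusProtocol",
    "EpochMatrix",
    "epoch_extract",
    "response_auc",
    "recovery_time_t90",
    "undershoot_auc",
    "cumulative_map",
    "behaviour_split",
    "NOT_RECOVERED",
    "NO_PEAK",
]

# sentinels for t90: response never recovered in-window / no detectable peak
NOT_RECOVERED = float("inf")
NO_PEAK = float("nan")


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus train timing.

    ``train_onsets`` are seconds from record start; each train delivers
    ``pulses_per_train`` pulses of ``pulse_duration_s`` at
    ``pulse_rate_hz``.
    """

    train_onsets: np.ndarray
    pulses_per_train: int = 4
    pulse_duration_s: float = 0.2
    pulse_rate_hz: float = 1.0

    def __post_init__(self):
        onsets = np.asarray(self.train_onsets, dtype=float)
        if onsets.ndim != 1 or len(onsets) == 0:
            raise InvalidArgumentError("train_onsets must be a non-empty 1-D array")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise InvalidArgumentError("train_onsets must be strictly increasing")
        if len(onsets) > 1 and np.any(np.diff(onsets) <= self.train_duration_s):
            raise InvalidArgumentError(
                "inter-train interval must exceed the train duration")
        object.__setattr__(self, "train_onsets", onsets)

    @property
    def train_duration_s(self) -> float:
        """Onset-to-offset duration of one pulse train."""
        return ((self.pulses_per_train - 1) / self.pulse_rate_hz
                + self.pulse_duration_s)

    @property
    def n_trains(self) -> int:
        return len(self.train_onsets)

    @classmethod
    def regular(cls, first_onset_s: float, interval_s: float, n_trains: int,
                **kw) -> "StimulusProtocol":
        onsets = first_onset_s + interval_s * np.arange(n_trains)
        return cls(onsets, **kw)


@dataclass
class EpochMatrix:
    """Trials x samples matrix of per-train response segments.

    ``time_s`` is relative to train onset (negative = pre-stimulus);
    ``labels`` holds one behaviour label per trial from
    {'rest', 'locomotion', 'unlabeled'}; ``dropped_trials`` records train
    indices skipped because their window fell off the record.
    """

    data: np.ndarray
    time_s: np.ndarray
    labels: np.ndarray = None
    dropped_trials: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.data.shape[1] != len(self.time_s):
            raise InvalidArgumentError("time axis must match epoch length")
        if self.labels is None:
            self.labels = np.full(self.data.shape[0], "unlabeled", dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != self.data.shape[0]:
                raise InvalidArgumentError("one label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def epoch_extract(trace, timestamps, protocol: StimulusProtocol,
                  window: tuple[float, float] = (2.0, 15.0),
                  baseline_subtract: bool = True,
                  labels=None) -> EpochMatrix:
    """Cut a 1-D trace into per-train epochs aligned to train onsets.

    ``window = (pre_s, post_s)`` spans ``[-pre_s, post_s]`` around each
    onset.  The per-trial baseline (mean over ``[-pre_s, 0)``) is
    subtracted when ``baseline_subtract`` is true.  Trains whose window
    falls off the record are dropped and reported in ``dropped_trials``.
    """
    trace = np.asarray(trace, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    if trace.ndim != 1 or trace.shape != ts.shape:
        raise InvalidArgumentError("trace and timestamps must be matching 1-D arrays")
    pre_s, post_s = float(window[0]), float(window[1])
    dt = float(np.median(np.diff(ts)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    rel_t = dt * np.arange(-n_pre, n_post + 1)

    rows, kept_labels, dropped = [], [], []
    for k, onset in enumerate(protocol.train_onsets):
        i0 = int(np.searchsorted(ts, onset))
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > len(trace):
            dropped.append(k)
            continue
        seg = trace[lo:hi].copy()
        if baseline_subtract:
            seg -= seg[:n_pre].mean() if n_pre > 0 else 0.0
        rows.append(seg)
        if labels is not None:
            kept_labels.append(labels[k])
    if not rows:
        raise InvalidArgumentError("no train fits inside the record")
    return EpochMatrix(np.array(rows), rel_t,
                       labels=np.array(kept_labels, dtype=object) if labels is not None else None,
                       dropped_trials=dropped)


def _window_slice(time_s, t0, t1):
    sel = (time_s >= t0) & (time_s <= t1)
    if not np.any(sel):
        raise InvalidArgumentError(f"window [{t0}, {t1}] s selects no samples")
    return sel


def response_auc(epoch_row, time_s, window: tuple[float, float]) -> float:
    """Trapezoidal area under the (baseline-subtracted) trace over a window.

    ``window`` is (start, end) in seconds on the epoch time axis (0 =
    train onset).  Units: signal x seconds.
    """
    row = np.asarray(epoch_row, dtype=float)
    t = np.asarray(time_s, dtype=float)
    t0, t1 = float(window[0]), float(window[1])
    if t0 < t[0] or t1 > t[-1]:
        raise InvalidArgumentError(
            f"window [{t0}, {t1}] s outside epoch [{t[0]}, {t[-1]}] s")
    sel = _window_slice(t, t0, t1)
    return float(np.trapezoid(row[sel], t[sel]))


def recovery_time_t90(epoch_row, time_s, protocol: StimulusProtocol,
                      noise_floor: float = 0.0,
                      anchor: str = "train-offset") -> float:
    """Post-stimulus 90% recovery time.

    Let P be the peak absolute deviation from the pre-stimulus baseline
    (the epoch is assumed already baseline-subtracted, so baseline = 0)
    at or after train onset.  t90 is the first time after the peak at
    which ``|trace| <= 0.1 * P``, measured from the anchor (stimulus
    train offset by default, or ``'peak'``), with linear interpolation
    between samples.  Returns ``NOT_RECOVERED`` (+inf) if the level is
    never reached in-window and ``NO_PEAK`` (NaN) if the peak deviation
    does not exceed ``noise_floor``.
    """
    row = np.asarray(epoch_row, dtype=float)
    t = np.asarray(time_s, dtype=float)
    post = t >= 0
    dev = np.abs(row)
    if not np.any(post):
        raise InvalidArgumentError("epoch has no post-onset samples")
    i_peak = int(np.argmax(np.where(post, dev, -np.inf)))
    peak = dev[i_peak]
    if not (peak > noise_floor):
        return NO_PEAK
    level = 0.1 * peak
    if anchor == "train-offset":
        t_anchor = protocol.train_duration_s
    elif anchor == "peak":
        t_anchor = t[i_peak]
    else:
        raise InvalidArgumentError(f"unknown t90 anchor {anchor!r}")
    for i in range(i_peak, len(t) - 1):
        if dev[i] > level >= dev[i + 1]:
            # linear interpolation of the crossing time
            frac = (dev[i] - level) / (dev[i] - dev[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]) - t_anchor)
    if dev[i_peak] <= level:  # degenerate: already at level
        return float(t[i_peak] - t_anchor)
    return NOT_RECOVERED


def undershoot_auc(epoch_row, time_s, protocol: StimulusProtocol,
                   window: tuple[float, float] = (0.0, 2.0),
                   anchor: str = "train-offset") -> float:
    """Absolute area of the below-baseline lobe over a post-stimulus window.

    ``window`` is relative to the anchor (train offset by default, or
    ``'onset'``); the integrand is ``min(trace, 0)`` on the
    baseline-subtracted epoch, and the absolute integral is returned.
    """
    row = np.asarray(epoch_row, dtype=float)
    t = np.asarray(time_s, dtype=float)
    if anchor == "train-offset":
        shift = protocol.train_duration_s
    elif anchor == "onset":
        shift = 0.0
    else:
        raise InvalidArgumentError(f"unknown undershoot anchor {anchor!r}")
    t0, t1 = float(window[0]) + shift, float(window[1]) + shift
    if t0 < t[0] or t1 > t[-1]:
        raise InvalidArgumentError(
            f"window [{t0}, {t1}] s outside epoch [{t[0]}, {t[-1]}] s")
    sel = _window_slice(t, t0, t1)
    neg = np.minimum(row[sel], 0.0)
    return float(abs(np.trapezoid(neg, t[sel])))


def cumulative_map(stack, timestamps, protocol: StimulusProtocol,
                   integration_window: tuple[float, float] = (0.0, 5.0),
                   pre_s: float = 2.0, mask=None) -> np.ndarray:
    """Pixel-wise cumulative stimulus-locked response map, min-max normalised.

    For each train, the per-pixel baseline (mean over ``[-pre_s, 0)``) is
    subtracted and the response integrated over ``integration_window``
    (seconds after onset); the integrals are summed across trains and the
    map min-max normalised to [0, 1] over in-mask pixels (out-of-mask
    pixels are set to 0).  A flat map returns all zeros with a warning.
    """
    import warnings

    data = np.asarray(stack, dtype=float)
    ts = np.asarray(timestamps, dtype=float)
    dt = float(np.median(np.diff(ts)))
    n_pre = int(round(pre_s / dt))
    t0, t1 = integration_window
    acc = np.zeros(data.shape[1:], dtype=float)
    n_used = 0
    for onset in protocol.train_onsets:
        i0 = int(np.searchsorted(ts, onset))
        sel = (ts >= onset + t0) & (ts <= onset + t1)
        if i0 - n_pre < 0 or not np.any(sel) or ts[-1] < onset + t1:
            continue
        base = data[i0 - n_pre:i0].mean(axis=0) if n_pre > 0 else 0.0
        acc += np.trapezoid(data[sel] - base, ts[sel], axis=0)
        n_used += 1
    if n_used == 0:
        raise InvalidArgumentError("no train window fits inside the record")
    if mask is None:
        mask = np.ones(acc.shape, dtype=bool)
    vals = acc[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("cumulative map is flat; returning all zeros")
        return np.zeros_like(acc)
    out = np.zeros_like(acc)
    out[mask] = (acc[mask] - lo) / (hi - lo)
    return out


def behaviour_split(epochs: EpochMatrix) -> dict:
    """Partition epochs by behaviour label, preserving trial order.

    Returns ``{'rest': EpochMatrix, 'locomotion': EpochMatrix,
    'unlabeled': EpochMatrix, 'counts': {...}}``; unlabeled trials are
    excluded from both behavioural groups.
    """
    out = {}
    counts = {}
    for name in ("rest", "locomotion", "unlabeled"):
        sel = epochs.labels == name
        counts[name] = int(sel.sum())
        out[name] = EpochMatrix(epochs.data[sel].reshape(-1, len(epochs.time_s)),
                                epochs.time_s,
                                labels=epochs.labels[sel])
    assert sum(counts.values()) == epochs.n_trials
    out["counts"] = counts
    return out
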