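"""Haemoglobin-absorption correction of fluorescence time series.

Haemoglobin absorbs both the excitation and the emission light of
GFP-family sensors, so blood-volume dynamics contaminate raw fluorescence.
Two corrections are provided behind one interface, plus a pass-through:

* attenuation-model (MBLL) correction — multiplies the raw relative
  fluorescence by ``exp(dmu_a_ex * X_ex + dmu_a_em * X_em)``, undoing the
  modelled absorption along the excitation and emission paths; requires
  the (experiment-specific) pathlengths X_ex, X_em;
* pixel-wise least-squares regression (LSR) — fits
  ``F_raw(t) = b0 + b1 * Hb(t) + eps(t)`` at each pixel against a
  haemodynamic predictor (d[HbT] or the isosbestic reflectance proxy) and
  keeps the residuals as the corrected signal;
* no correction — identity, so the three methods share one call signature.

``compare_methods`` reproduces the method-comparison statistics: per-method
median recovery time t90 and median post-stimulus undershoot area
|PostAUC|, an omnibus Kruskal-Wallis test, and Bonferroni-corrected
pairwise Mann-Whitney tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError
from .hemodynamics import AbsorptionChange

__all__ = [
    "FluorescenceSeries",
    "RegressionFit",
    "MethodComparison",
    "mbll_correct",
    "lsr_correct",
    "no_correction",
    "compare_methods",
]


@dataclass
class FluorescenceSeries:
    """Relative fluorescence F/F0 per pixel, (t, h, w), dimensionless."""

    f_rel: np.ndarray
    timestamps: np.ndarray | None = None

    def __post_init__(self):
        self.f_rel = np.asarray(self.f_rel, dtype=float)
        if self.f_rel.ndim != 3:
            raise InvalidArgumentError(
                f"fluorescence must be (t, h, w), got {self.f_rel.shape}")

    def as_percent_change(self) -> np.ndarray:
        """dF/F0 in percent: ``100 * (f_rel - 1)``."""
        return 100.0 * (self.f_rel - 1.0)


@dataclass
class RegressionFit:
    """Per-pixel OLS fit of fluorescence on the haemodynamic predictor.

    ``beta0``/``beta1`` are (h, w) intercept and slope maps; ``residuals``
    the (t, h, w) residual series; ``failed`` flags pixels where the
    predictor had zero variance (slope forced to 0 there).
    """

    beta0: np.ndarray
    beta1: np.ndarray
    residuals: np.ndarray
    failed: np.ndarray = field(default=None)


def _check_shapes(*stacks):
    shapes = {np.asarray(s).shape for s in stacks}
    if len(shapes) != 1:
        raise InvalidArgumentError(f"co-registered stacks required, got shapes {shapes}")


def mbll_correct(f: FluorescenceSeries, dmua_ex: AbsorptionChange,
                 dmua_em: AbsorptionChange, x_ex_cm: float,
                 x_em_cm: float) -> FluorescenceSeries:
    """Attenuation-model correction.

    ``F_corr = F_raw * exp(dmu_a(l_ex) * X_ex + dmu_a(l_em) * X_em)``
    pixel-wise per frame.  Exactly inverts a purely multiplicative
    haemoglobin attenuation when the same absorption changes and
    pathlengths are used.
    """
    if not (x_ex_cm > 0 and x_em_cm > 0):
        raise InvalidArgumentError("pathlengths must be > 0")
    _check_shapes(f.f_rel, dmua_ex.delta_mua, dmua_em.delta_mua)
    factor = np.exp(dmua_ex.delta_mua * float(x_ex_cm)
                    + dmua_em.delta_mua * float(x_em_cm))
    return FluorescenceSeries(f.f_rel * factor, timestamps=f.timestamps)


def lsr_correct(f: FluorescenceSeries, hb) -> tuple[RegressionFit, FluorescenceSeries]:
    """Pixel-wise least-squares regression correction.

    Fits ``F_raw(t) = b0 + b1 * Hb(t) + eps(t)`` by ordinary least squares
    at every pixel; the corrected series is the residual re-offset by +1
    so it stays in relative-fluorescence units with mean 1.  ``hb`` may be
    a single trace ``(t,)`` shared by all pixels or a per-pixel stack
    ``(t, h, w)``.  Pixels whose predictor has zero variance are flagged
    ``failed``: there b1 = 0 and the output is the mean-centred input + 1.
    """
    F = f.f_rel
    t, h, w = F.shape
    if t < 3:
        raise InvalidArgumentError("regression requires >= 3 time points")
    hb = np.asarray(hb, dtype=float)
    if hb.ndim == 1:
        if hb.shape[0] != t:
            raise InvalidArgumentError("predictor length must match time axis")
        hb = np.broadcast_to(hb[:, None, None], F.shape)
    elif hb.shape != F.shape:
        raise InvalidArgumentError(
            f"predictor shape {hb.shape} incompatible with {F.shape}")

    hb_mean = hb.mean(axis=0)
    f_mean = F.mean(axis=0)
    hb_c = hb - hb_mean
    cov = (hb_c * (F - f_mean)).sum(axis=0)
    var = (hb_c ** 2).sum(axis=0)
    failed = var == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = np.where(failed, 0.0, cov / np.where(failed, 1.0, var))
    beta0 = f_mean - beta1 * hb_mean
    residuals = F - (beta0 + beta1 * hb)
    corrected = FluorescenceSeries(residuals + 1.0, timestamps=f.timestamps)
    return RegressionFit(beta0, beta1, residuals, failed=failed), corrected


def no_correction(f: FluorescenceSeries) -> FluorescenceSeries:
    """Identity pass-through, so all correction methods share one interface."""
    return f


@dataclass
class MethodComparison:
    """Per-method medians and the across-method test statistics."""

    methods: list[str]
    median_t90_s: dict
    median_abs_postauc: dict
    n_epochs: dict
    kruskal_t90: tuple[float, float]  # (H, p)
    kruskal_postauc: tuple[float, float]
    pairwise_t90: dict  # (m1, m2) -> Bonferroni-corrected p
    pairwise_postauc: dict


def _pairwise_mwu_bonferroni(samples: dict, alternative: str = "two-sided") -> dict:
    names = list(samples)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    out = {}
    for a, b in pairs:
        _, p = stats.mannwhitneyu(samples[a], samples[b], alternative=alternative)
        out[(a, b)] = min(1.0, float(p) * len(pairs))
    return out


def compare_methods(t90_samples: dict, postauc_samples: dict) -> MethodComparison:
    """Compare correction methods on epoch-wise t90 and |PostAUC| samples.

    ``t90_samples`` and ``postauc_samples`` map method name -> 1-D array
    of per-epoch values (t90 in seconds; undershoot areas as absolute
    values).  Requires >= 2 methods with >= 3 epochs each.  Runs a
    Kruskal-Wallis omnibus test per metric and Bonferroni-corrected
    two-sided Mann-Whitney tests on each method pair (raw p multiplied by
    the number of pairs, capped at 1).
    """
    if set(t90_samples) != set(postauc_samples) or len(t90_samples) < 2:
        raise InvalidArgumentError(
            "need >= 2 methods with both t90 and PostAUC samples")
    for name, vals in list(t90_samples.items()) + list(postauc_samples.items()):
        if len(np.atleast_1d(vals)) < 3:
            raise InvalidArgumentError(f"method {name!r} has < 3 epochs")

    def _kruskal(samples):
        groups = [np.asarray(v, dtype=float) for v in samples.values()]
        if all(np.array_equal(g, groups[0]) for g in groups[1:]) and all(
                np.ptp(g) == 0 for g in groups):
            # all observations tied: H degenerates to 0 by convention
            return 0.0, 1.0
        h, p = stats.kruskal(*groups)
        return float(h), float(p)

    methods = list(t90_samples)
    return MethodComparison(
        methods=methods,
        median_t90_s={m: float(np.median(t90_samples[m])) for m in methods},
        median_abs_postauc={m: float(np.median(np.abs(postauc_samples[m])))
                            for m in methods},
        n_epochs={m: int(len(np.atleast_1d(t90_samples[m]))) for m in methods},
        kruskal_t90=_kruskal(t90_samples),
        kruskal_postauc=_kruskal(postauc_samples),
        pairwise_t90=_pairwise_mwu_bonferroni(t90_samples),
        pairwise_postauc=_pairwise_mwu_bonferroni(postauc_samples),
    )
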