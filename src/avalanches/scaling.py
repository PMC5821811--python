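"""Size-duration scaling and the critical-exponent scaling relation.

At criticality the mean avalanche duration grows as a power of size,
<T>(S) ~ S^gamma, and the three exponents are tied together by

    (alpha - 1) / (tau - 1) = 1 / gamma.

``fit_gamma`` estimates gamma by unweighted least squares of log10 mean
duration against log10 size over log-spaced size bins; the relation check
predicts each exponent from the other two with first-order (linear) error
propagation and tests overlap at combined 2-sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .extraction import AvalancheCatalog

__all__ = [
    "SizeDurationScaling",
    "ScalingRelationCheck",
    "fit_gamma",
    "scaling_relation_check",
]


@dataclass
class SizeDurationScaling:
    bin_centers: np.ndarray
    mean_durations: np.ndarray
    gamma: float
    gamma_2sigma: float
    fit_range: tuple[float, float]
    n_bins_used: int

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "gamma_2sigma": self.gamma_2sigma,
            "fit_range": list(self.fit_range),
            "n_bins_used": self.n_bins_used,
        }


@dataclass
class ScalingRelationCheck:
    """Measured vs scaling-relation-predicted exponents, each value +/- 2sigma."""

    measured: dict  # {"tau": (value, 2sigma), ...}
    predicted: dict
    consistent: dict  # {"tau": bool, ...}

    def to_dict(self) -> dict:
        return {
            "measured": {k: list(v) for k, v in self.measured.items()},
            "predicted": {k: list(v) for k, v in self.predicted.items()},
            "consistent": self.consistent,
        }


def fit_gamma(
    catalog: AvalancheCatalog,
    s_min: float,
    s_max: float,
    bins_per_decade: int = 10,
) -> SizeDurationScaling:
    """Least-squares slope of log10 <T> vs log10 S over log-spaced size bins.

    Sizes in [s_min, s_max] are binned at ``bins_per_decade`` log-spaced
    bins per decade; each populated bin contributes its geometric center
    and the arithmetic mean duration of its avalanches.  Requires at least
    5 populated bins.  The reported uncertainty is twice the regression
    slope's standard error.
    """
    if not (0 < s_min < s_max):
        raise InvalidParameterError("require 0 < s_min < s_max")
    mask = catalog.fit_mask & (catalog.sizes >= s_min) & (catalog.sizes <= s_max)
    S = catalog.sizes[mask].astype(np.float64)
    T = catalog.durations[mask].astype(np.float64)
    n_edges = max(2, int(np.ceil(np.log10(s_max / s_min) * bins_per_decade)) + 1)
    edges = np.geomspace(s_min, s_max * (1 + 1e-12), n_edges)
    idx = np.digitize(S, edges) - 1

    centers, means = [], []
    for b in range(n_edges - 1):
        sel = idx == b
        if np.any(sel):
            centers.append(np.sqrt(edges[b] * edges[b + 1]))
            means.append(T[sel].mean())
    if len(centers) < 5:
        raise InsufficientDataError(
            f"only {len(centers)} populated log-bins in [{s_min}, {s_max}] (need >= 5)"
        )
    centers = np.asarray(centers)
    means = np.asarray(means)
    res = stats.linregress(np.log10(centers), np.log10(means))
    return SizeDurationScaling(
        bin_centers=centers, mean_durations=means,
        gamma=float(res.slope), gamma_2sigma=2.0 * float(res.stderr),
        fit_range=(float(s_min), float(s_max)), n_bins_used=len(centers),
    )


def scaling_relation_check(
    tau: tuple[float, float],
    alpha: tuple[float, float],
    gamma: tuple[float, float],
) -> ScalingRelationCheck:
    """Test (alpha - 1)/(tau - 1) = 1/gamma with propagated uncertainties.

    Each argument is (value, 2sigma).  Each exponent is predicted from the
    other two — gamma_pred = (tau-1)/(alpha-1), alpha_pred = 1 +
    (tau-1)/gamma, tau_pred = 1 + gamma*(alpha-1) — with first-order
    variance propagation; an exponent is consistent when |measured -
    predicted| does not exceed the measured and propagated 2-sigma summed
    in quadrature.
    """
    (t, dt2), (a, da2), (g, dg2) = tau, alpha, gamma
    if t <= 1 or a <= 1:
        raise InvalidParameterError("scaling relation requires tau > 1 and alpha > 1")
    if g <= 0:
        raise InvalidParameterError("scaling relation requires gamma > 0")
    st, sa, sg = dt2 / 2.0, da2 / 2.0, dg2 / 2.0

    g_pred = (t - 1.0) / (a - 1.0)
    g_pred_sig = np.hypot(st / (a - 1.0), (t - 1.0) * sa / (a - 1.0) ** 2)
    a_pred = 1.0 + (t - 1.0) / g
    a_pred_sig = np.hypot(st / g, (t - 1.0) * sg / g**2)
    t_pred = 1.0 + g * (a - 1.0)
    t_pred_sig = np.hypot((a - 1.0) * sg, g * sa)

    measured = {"tau": (t, 2 * st), "alpha": (a, 2 * sa), "gamma": (g, 2 * sg)}
    predicted = {
        "tau": (float(t_pred), float(2 * t_pred_sig)),
        "alpha": (float(a_pred), float(2 * a_pred_sig)),
        "gamma": (float(g_pred), float(2 * g_pred_sig)),
    }
    consistent = {
        k: bool(abs(measured[k][0] - predicted[k][0])
                <= np.hypot(measured[k][1], predicted[k][1]))
        for k in measured
    }
    return ScalingRelationCheck(measured=measured, predicted=predicted, consistent=consistent)
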