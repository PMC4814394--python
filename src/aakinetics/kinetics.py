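"""Closed-form two-compartment postprandial amino-acid kinetics.

The model describes the plasma concentration of an amino acid (or an
aggregate such as total amino acids) after ingestion of a protein drink.
Amino acids leave the stomach pool at a constant (zeroth-order) rate ``k1``
until the pool is exhausted at the emptying time ``x0 / k1``, and are
cleared from plasma at a first-order rate ``k3``:

    dX/dt = -k1,            X(0) = x0   (stomach, until X hits 0)
    dY/dt =  k1 - k3 * Y,   Y(0) = y0   (plasma, while the stomach empties)
    dY/dt =      - k3 * Y               (plasma, after emptying)

which has the piecewise closed form

    Y(t) = k1/k3 + (y0 - k1/k3) * exp(-k3 t)                  for t <= x0/k1
    Y(t) = [k1/k3 * exp(k3 x0/k1) + (y0 - k1/k3)] * exp(-k3 t)  for t > x0/k1

Back-flow from plasma to stomach is assumed negligible, so the model has
exactly four parameters. A one-compartment first-order-absorption
(Bateman) alternative is also provided; on real postprandial data it
systematically underestimates the concentration peak, which is the
diagnostic used to reject it in favour of the zeroth-order form.

Units are the caller's contract: times in minutes, concentrations in one
consistent unit (mmol/L expected), ``k1`` in concentration/min, ``k3`` in
1/min. No unit conversion is performed anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "KineticParams",
    "FirstOrderParams",
    "TimeWindow",
    "stomach_concentration",
    "emptying_time",
    "plasma_concentration",
    "plasma_concentration_first_order",
    "auc",
]


class InvalidParameterError(ValueError):
    """Raised when kinetic parameters violate their constraints."""


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the zeroth-order-appearance / first-order-clearance model.

    Attributes
    ----------
    k1 : float
        Plasma-appearance rate constant (concentration/min, zeroth order).
    k3 : float
        Plasma-clearance rate constant (1/min, first order).
    x0 : float
        Initial stomach amino-acid concentration (same unit as plasma).
    y0 : float
        Baseline (pre-ingestion) plasma concentration.
    """

    k1: float
    k3: float
    x0: float
    y0: float

    def __post_init__(self) -> None:
        for name in ("k1", "k3", "x0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.y0) or self.y0 < 0:
            raise InvalidParameterError(f"y0 must be finite and >= 0, got {self.y0!r}")

    @property
    def emptying_time(self) -> float:
        """Time at which the stomach pool is exhausted, x0 / k1 (min)."""
        return self.x0 / self.k1


@dataclass(frozen=True)
class FirstOrderParams:
    """Parameters of the first-order-absorption (Bateman) alternative model.

    ``ka`` is the stomach-emptying rate constant (1/min); the remaining
    fields match :class:`KineticParams`. The removable singularity at
    ``ka == k3`` is handled by a limit form.
    """

    ka: float
    k3: float
    x0: float
    y0: float

    def __post_init__(self) -> None:
        for name in ("ka", "k3", "x0"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.y0) or self.y0 < 0:
            raise InvalidParameterError(f"y0 must be finite and >= 0, got {self.y0!r}")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open-in-spirit integration window [t_start, t_end], minutes."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_start) and math.isfinite(self.t_end)):
            raise ValueError("window bounds must be finite")
        if self.t_start < 0:
            raise ValueError(f"t_start must be >= 0, got {self.t_start}")
        if self.t_end <= self.t_start:
            raise ValueError(
                f"t_end must exceed t_start, got [{self.t_start}, {self.t_end}]"
            )


#: Default AUC window: the 0-120 min sampling window of a postprandial trial.
DEFAULT_WINDOW = TimeWindow(0.0, 120.0)


def _check_times(t: np.ndarray) -> None:
    if np.any(t < 0):
        raise ValueError("time must be non-negative")


def stomach_concentration(p: KineticParams, t):
    """Stomach amino-acid concentration X(t) = max(x0 - k1 t, 0).

    Vectorizes over ``t``; negative times raise ``ValueError``.
    """
    t = np.asarray(t, dtype=float)
    _check_times(t)
    x = np.maximum(p.x0 - p.k1 * t, 0.0)
    return x if x.ndim else float(x)


def emptying_time(p: KineticParams) -> float:
    """Stomach-emptying time x0 / k1 in minutes."""
    return p.emptying_time


def _plasma_zeroth(k1, k3, x0, y0, t):
    """Vectorized piecewise evaluation; all args broadcastable arrays.

    Both branches are written with non-positive exponents only, so extreme
    emptying times cannot overflow.
    """
    plateau = k1 / k3
    te = x0 / k1
    rising = plateau + (y0 - plateau) * np.exp(-k3 * t)
    # decay branch rewritten as plateau*exp(-k3(t-te)) + (y0-plateau)*exp(-k3 t)
    after = t > te
    decay = plateau * np.exp(-k3 * np.where(after, t - te, 0.0)) + (
        y0 - plateau
    ) * np.exp(-k3 * t)
    return np.where(after, decay, rising)


def _plasma_zeroth_grad(k1, k3, x0, y0, t):
    """Gradient of Y(t) w.r.t. (log k1, log k3, log x0, y0).

    Used by the fitting layer; scalar parameters, array ``t``. Derived by
    branchwise differentiation of the closed form; continuous across the
    emptying time except for the x0 component, whose one-sided limit at
    the kink is taken from the decay branch.
    """
    t = np.asarray(t, dtype=float)
    P = k1 / k3
    te = x0 / k1
    E = np.exp(-k3 * t)
    after = t > te
    dt_after = np.where(after, t - te, 0.0)
    Eshift = np.exp(-k3 * dt_after)  # e^{-k3 (t - te)} on the decay branch
    g = np.empty((4,) + t.shape)
    # rising branch
    g_l1_r = P * (1.0 - E)
    g_l3_r = -P * (1.0 - E) + k3 * t * E * (P - y0)
    g_lx_r = np.zeros_like(t)
    # decay branch
    g_l1_d = k1 * (Eshift * (1.0 / k3 - te) - E / k3)
    g_l3_d = Eshift * (-P - P * k3 * dt_after) + E * (P + P * k3 * t - y0 * k3 * t)
    g_lx_d = x0 * Eshift
    g[0] = np.where(after, g_l1_d, g_l1_r)
    g[1] = np.where(after, g_l3_d, g_l3_r)
    g[2] = np.where(after, g_lx_d, g_lx_r)
    g[3] = E
    return g


def plasma_concentration(p: KineticParams, t):
    """Plasma concentration Y(t) of the zeroth-order-appearance model.

    Piecewise closed form: exponential approach to the plateau k1/k3 while
    the stomach empties, pure first-order washout afterwards. Continuous at
    the emptying time. Vectorizes over ``t``.
    """
    t = np.asarray(t, dtype=float)
    _check_times(t)
    y = _plasma_zeroth(p.k1, p.k3, p.x0, p.y0, t)
    return y if y.ndim else float(y)


def plasma_concentration_first_order(p: FirstOrderParams, t):
    """Plasma concentration of the Bateman (first-order absorption) model.

    Y(t) = y0 e^{-k3 t} + x0 ka/(k3-ka) (e^{-ka t} - e^{-k3 t}); when
    |ka - k3| < 1e-8 k3 the limit form y0 e^{-kt} + x0 k t e^{-kt} is used.
    """
    t = np.asarray(t, dtype=float)
    _check_times(t)
    ka, k3, x0, y0 = p.ka, p.k3, p.x0, p.y0
    if abs(ka - k3) < 1e-8 * k3:
        k = 0.5 * (ka + k3)
        y = (y0 + x0 * k * t) * np.exp(-k * t)
    else:
        y = y0 * np.exp(-k3 * t) + x0 * ka / (k3 - ka) * (
            np.exp(-ka * t) - np.exp(-k3 * t)
        )
    return y if y.ndim else float(y)


def _auc_zeroth(k1, k3, x0, y0, a, b):
    """Analytic AUC of the piecewise model over [a, b]; broadcastable args.

    Splits at the emptying time te = x0/k1:
      rising branch:  integral of P + (y0-P) e^{-k3 t}
      decay branch:   integral of [P e^{k3 te} + (y0-P)] e^{-k3 t},
    with the decay-branch constant folded into non-positive exponents.
    """
    plateau = k1 / k3
    amp = y0 - plateau
    te = x0 / k1
    # segment within the rising branch: [a1, b1]
    a1 = np.minimum(a, te)
    b1 = np.minimum(b, te)
    seg1 = plateau * (b1 - a1) + amp / k3 * (np.exp(-k3 * a1) - np.exp(-k3 * b1))
    # segment within the decay branch: [a2, b2]
    a2 = np.maximum(a, te)
    b2 = np.maximum(b, te)
    seg2 = plateau / k3 * (
        np.exp(-k3 * np.maximum(a2 - te, 0.0)) - np.exp(-k3 * np.maximum(b2 - te, 0.0))
    ) + amp / k3 * (np.exp(-k3 * a2) - np.exp(-k3 * b2))
    return seg1 + seg2


def auc(p: KineticParams, window: TimeWindow = DEFAULT_WINDOW) -> float:
    """Analytic area under Y(t) over the window, in concentration * minutes.

    The baseline is not subtracted (total AUC); windows straddling the
    emptying time are split there and integrated branchwise.
    """
    if not isinstance(window, TimeWindow):
        window = TimeWindow(*window)
    return float(_auc_zeroth(p.k1, p.k3, p.x0, p.y0, window.t_start, window.t_end))
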