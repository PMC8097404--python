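"""Electrophysiology curve fits: Boltzmann G(V), Hill concentration–response,
and single-exponential relaxation kinetics.

The models follow the two-electrode voltage-clamp analysis conventions for
KCNQ1-type channels.  Conductance–voltage data (tail-current amplitudes
plotted against the preceding activation voltage) are fitted with

    G(V) = Gmin + (Gmax − Gmin) / (1 + exp[(V50 − V)·s]),

where V50 is the half-activation voltage (mV) and s the slope factor
(mV⁻¹; s > 0 gives an activating curve).  Treatment effects are summarized
per cell as ΔV50 = V50,treated − V50,control and ΔGmax =
Gmax,treated/Gmax,control − 1.  Concentration dependence is fitted with the
Hill form

    ΔEffect([L]) = ΔEffect_max / (1 + (L50/[L])^|H|),

with |H| constrained (to 1 by default, the standard robustness constraint
when solubility caps the accessible concentration range) and the direction
sign of H recorded as metadata rather than fitted.  Current relaxations are
fitted with I(t) = A·exp(−t/τ) + C over a window following the capacitive
transient.

Each model object is constructed from data and ``fit()`` returns a results
object carrying parameter estimates, standard errors (from the
least-squares covariance), diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ArgumentError, FitError
from .synthetic import boltzmann, hill

__all__ = [
    "GVCurve",
    "BoltzmannModel",
    "BoltzmannResults",
    "HillModel",
    "HillResults",
    "ExponentialDecayModel",
    "TauResults",
    "EffectSummary",
    "gv_from_tails",
    "effect_summary",
]


@dataclass
class GVCurve:
    """Tail-current amplitude vs preceding activation voltage."""

    voltage: np.ndarray  # mV, strictly increasing
    conductance: np.ndarray  # arbitrary units

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if self.voltage.shape != self.conductance.shape:
            raise ArgumentError("voltage and conductance must have equal length")
        if np.any(np.diff(self.voltage) <= 0):
            raise ArgumentError("voltages must be strictly increasing")


def gv_from_tails(records, blank_s: float = 0.005, window_s: float = 0.015) -> GVCurve:
    """Build a G(V) curve from tail-current records.

    ``records`` is either a two-column table (activation voltage, tail
    amplitude), passed through unchanged, or a mapping
    ``voltage -> (time_s, current)`` of tail traces, in which case the
    amplitude is the mean current over ``[blank_s, blank_s + window_s]``
    after stepping to the tail voltage (the blank skips the capacitive
    transient).  Duplicate activation voltages are an error.
    """
    if isinstance(records, pd.DataFrame):
        v = records.iloc[:, 0].to_numpy(dtype=float)
        g = records.iloc[:, 1].to_numpy(dtype=float)
    elif isinstance(records, dict):
        v, g = [], []
        for volt, (t, i) in sorted(records.items()):
            t = np.asarray(t, dtype=float)
            i = np.asarray(i, dtype=float)
            sel = (t >= blank_s) & (t <= blank_s + window_s)
            if not sel.any():
                raise ArgumentError(
                    f"no samples in measurement window for voltage {volt}"
                )
            v.append(float(volt))
            g.append(float(i[sel].mean()))
        v, g = np.array(v), np.array(g)
    else:
        raise ArgumentError("records must be a DataFrame or a voltage->trace mapping")
    if len(np.unique(v)) != len(v):
        raise ArgumentError("duplicate activation voltages")
    order = np.argsort(v)
    return GVCurve(voltage=v[order], conductance=g[order])


# ---------------------------------------------------------------------------
# Results machinery
# ---------------------------------------------------------------------------

@dataclass
class _Results:
    params: np.ndarray
    bse: np.ndarray
    param_names: list[str]
    fittedvalues: np.ndarray
    resid: np.ndarray
    nobs: int
    model: object = field(repr=False, default=None)
    extra: dict = field(default_factory=dict)

    def __getattr__(self, name):
        names = object.__getattribute__(self, "param_names")
        if name in names:
            return float(object.__getattribute__(self, "params")[names.index(name)])
        raise AttributeError(name)

    @property
    def ssr(self) -> float:
        return float(np.sum(self.resid**2))

    @property
    def rsquared(self) -> float:
        tot = float(np.sum((self.fittedvalues + self.resid
                            - np.mean(self.fittedvalues + self.resid)) ** 2))
        return 1.0 - self.ssr / tot if tot > 0 else np.nan

    def summary(self) -> str:
        lines = [f"{type(self).__name__}", "=" * 44]
        lines.append(f"{'parameter':<14}{'estimate':>14}{'std err':>14}")
        for n, p, e in zip(self.param_names, self.params, self.bse):
            se = f"{e:.4g}" if np.isfinite(e) else "(fixed)" if e == 0 else "nan"
            lines.append(f"{n:<14}{p:>14.6g}{se:>14}")
        lines.append("-" * 44)
        lines.append(f"n = {self.nobs}, SSR = {self.ssr:.6g}, R^2 = {self.rsquared:.4f}")
        for k, v in self.extra.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def _safe_curve_fit(f, x, y, p0, bounds=(-np.inf, np.inf), what="curve"):
    try:
        popt, pcov = curve_fit(f, x, y, p0=p0, bounds=bounds, maxfev=20000)
    except Exception as exc:
        raise FitError(f"{what} fit did not converge: {exc}",
                       diagnostics={"p0": list(np.atleast_1d(p0))}) from exc
    with np.errstate(invalid="ignore"):
        bse = np.sqrt(np.diag(pcov))
    return popt, bse


# ---------------------------------------------------------------------------
# Boltzmann G(V)
# ---------------------------------------------------------------------------

class BoltzmannResults(_Results):
    """Fitted G(V) parameters; G(v50) = (gmin+gmax)/2 by construction."""

    def predict(self, v) -> np.ndarray:
        return boltzmann(v, *self.params)


class BoltzmannModel:
    """Boltzmann fit of a conductance–voltage curve."""

    param_names = ["gmin", "gmax", "v50", "s"]

    def __init__(self, curve: GVCurve):
        if curve.voltage.size < 5:
            raise ArgumentError("need at least 5 G(V) points spanning the transition")
        self.curve = curve

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, voltage_col="voltage_mV",
                       conductance_col="conductance") -> "BoltzmannModel":
        return cls(GVCurve(df[voltage_col].to_numpy(), df[conductance_col].to_numpy()))

    def _initial_guess(self) -> np.ndarray:
        v, g = self.curve.voltage, self.curve.conductance
        gmin0, gmax0 = float(g.min()), float(g.max())
        if gmax0 - gmin0 <= 1e-12 * max(abs(gmax0), 1.0):
            raise FitError("degenerate flat G(V) data")
        frac = (g - gmin0) / (gmax0 - gmin0)
        v50_0 = float(np.interp(0.5, frac, v)) if np.all(np.diff(frac) >= 0) else float(
            v[np.argmin(np.abs(frac - 0.5))]
        )
        # slope factor from the 25–75% rise span of a logistic: V75-V25 = 2 ln3 / s
        v25 = float(v[np.argmin(np.abs(frac - 0.25))])
        v75 = float(v[np.argmin(np.abs(frac - 0.75))])
        span = v75 - v25
        s0 = 2.0 * np.log(3.0) / span if abs(span) > 1e-9 else 0.1
        return np.array([gmin0, gmax0, v50_0, s0])

    def fit(self, initial_guess=None) -> BoltzmannResults:
        v, g = self.curve.voltage, self.curve.conductance
        p0 = np.asarray(initial_guess, float) if initial_guess is not None else self._initial_guess()
        popt, bse = _safe_curve_fit(boltzmann, v, g, p0, what="Boltzmann")
        fitted = boltzmann(v, *popt)
        return BoltzmannResults(
            params=popt, bse=bse, param_names=list(self.param_names),
            fittedvalues=fitted, resid=g - fitted, nobs=v.size, model=self,
        )


# ---------------------------------------------------------------------------
# Hill concentration–response
# ---------------------------------------------------------------------------

class HillResults(_Results):
    def predict(self, conc) -> np.ndarray:
        return hill(conc, self.effect_max, self.l50, self.extra.get("hill_magnitude", 1.0))


class HillModel:
    """Constrained Hill fit of a concentration–effect table.

    ``hill_magnitude`` (|H|) is fixed rather than fitted; ``direction_sign``
    records whether the underlying effect grows more negative (−1, e.g. a
    V50 shift) or positive (+1, e.g. a Gmax increase) — it is metadata, not
    a fit parameter.  ``fix_effect_max`` optionally pins the saturating
    effect, reducing the fit to L50 alone.
    """

    def __init__(self, concentration, effect, hill_magnitude: float = 1.0,
                 fix_effect_max: float | None = None, direction_sign: int | None = None):
        c = np.asarray(concentration, dtype=float)
        e = np.asarray(effect, dtype=float)
        if c.size < 3:
            raise ArgumentError("need at least 3 concentrations")
        if np.any(c <= 0):
            raise ArgumentError("concentrations must be positive")
        if np.allclose(e, 0.0):
            raise FitError("all-zero effects; nothing to fit")
        self.conc, self.effect = c, e
        self.hill_magnitude = abs(hill_magnitude)
        self.fix_effect_max = fix_effect_max
        self.direction_sign = direction_sign if direction_sign is not None else (
            -1 if np.mean(e) < 0 else 1
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conc_col="concentration_uM",
                       effect_col="effect", **kw) -> "HillModel":
        return cls(df[conc_col].to_numpy(), df[effect_col].to_numpy(), **kw)

    def fit(self) -> HillResults:
        c, e = self.conc, self.effect
        h = self.hill_magnitude
        l50_0 = float(c[np.argmin(np.abs(e - 0.5 * e[np.argmax(np.abs(e))]))])
        l50_0 = max(l50_0, 1e-6)
        if self.fix_effect_max is None:
            emax0 = float(e[np.argmax(np.abs(e))]) * 1.2

            def f(x, emax, l50):
                return hill(x, emax, l50, h)

            popt, bse = _safe_curve_fit(
                f, c, e, [emax0, l50_0],
                bounds=([-np.inf, 1e-12], [np.inf, np.inf]), what="Hill",
            )
            params = popt
            names = ["effect_max", "l50"]
        else:
            emax = self.fix_effect_max

            def f(x, l50):
                return hill(x, emax, l50, h)

            popt, bse = _safe_curve_fit(
                f, c, e, [l50_0], bounds=([1e-12], [np.inf]), what="Hill",
            )
            params = np.array([emax, popt[0]])
            bse = np.array([0.0, bse[0]])
            names = ["effect_max", "l50"]
        fitted = hill(c, params[0], params[1], h)
        return HillResults(
            params=params, bse=bse, param_names=names,
            fittedvalues=fitted, resid=e - fitted, nobs=c.size, model=self,
            extra={
                "hill_magnitude": h,
                "hill_sign": self.direction_sign,
                "constraints": {
                    "hill_fixed": h,
                    "effect_max_fixed": self.fix_effect_max,
                },
            },
        )


# ---------------------------------------------------------------------------
# Single-exponential relaxation
# ---------------------------------------------------------------------------

class TauResults(_Results):
    def predict(self, t) -> np.ndarray:
        return self.amplitude * np.exp(-np.asarray(t, float) / self.tau) + self.offset


class ExponentialDecayModel:
    """I(t) = A·exp(−t/τ) + C fitted over a window after the capacitive blank."""

    param_names = ["amplitude", "tau", "offset"]

    def __init__(self, time, current, window: tuple[float, float] | None = None,
                 blank_s: float = 0.0):
        t = np.asarray(time, dtype=float)
        i = np.asarray(current, dtype=float)
        if t.shape != i.shape:
            raise ArgumentError("time and current must have equal length")
        lo = blank_s if window is None else max(window[0], blank_s)
        hi = t[-1] if window is None else window[1]
        if hi > t.max() + 1e-12 or lo < t.min() - 1e-12:
            raise ArgumentError("fit window outside the trace")
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 4:
            raise ArgumentError("fit window contains too few samples")
        self.t, self.i = t[sel], i[sel]
        self.window = (float(lo), float(hi))

    def fit(self, initial_guess=None) -> TauResults:
        t, i = self.t, self.i
        if initial_guess is None:
            c0 = float(i[-1])
            a0 = float(i[0] - c0)
            if abs(a0) < 1e-15:
                a0 = 1e-3
            tau0 = max((t[-1] - t[0]) / 3.0, 1e-9)
            p0 = [a0, tau0, c0]
        else:
            p0 = list(initial_guess)

        def f(x, a, tau, c):
            return a * np.exp(-x / tau) + c

        popt, bse = _safe_curve_fit(
            f, t, i, p0, bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            what="exponential",
        )
        fitted = f(t, *popt)
        return TauResults(
            params=popt, bse=bse, param_names=list(self.param_names),
            fittedvalues=fitted, resid=i - fitted, nobs=t.size, model=self,
            extra={"window_s": self.window},
        )


# ---------------------------------------------------------------------------
# Effect summaries
# ---------------------------------------------------------------------------

@dataclass
class EffectSummary:
    """Per-cell treatment effect from paired Boltzmann fits."""

    delta_v50: float  # mV, treated - control
    delta_gmax_percent: float  # 100*(Gmax_treated/Gmax_control - 1)


def effect_summary(control: BoltzmannResults, treated: BoltzmannResults) -> EffectSummary:
    """ΔV50 and ΔGmax (as %) from control/treated fits on the same cell."""
    return EffectSummary(
        delta_v50=treated.v50 - control.v50,
        delta_gmax_percent=100.0 * (treated.gmax / control.gmax - 1.0),
    )
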