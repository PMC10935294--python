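"""Enzyme-inhibition assay mathematics.

Covers the quantitative side of an ACE-inhibition study:

* inhibition rate from HPLC-quantified hippuric acid (control / sample /
  blank concentrations),
* IC50 from a dose-response series via a two-parameter log-logistic fit
  (upper asymptote fixed at 100%),
* Michaelis–Menten fits per inhibitor concentration, both by the
  Lineweaver–Burk double-reciprocal line and by nonlinear least squares,
* inhibition-mode classification (competitive / non-competitive /
  uncompetitive / mixed) from the pattern of apparent Km and Vmax changes
  against the uninhibited control,
* pre/post-digestion stability comparison of replicate IC50 values
  (Welch's unequal-variance t-test).

The module is unit-agnostic: substrate in mM, velocities in whatever rate
unit the assay produced, inhibitor concentrations in mg/mL or µM — labels are
carried through, never converted, and classification depends only on ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Inhibition rate (hippuric-acid assay)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayMeasurement:
    """Hippuric-acid concentrations of one inhibition assay (consistent units).

    ``ha_control`` is the uninhibited reaction, ``ha_sample`` the reaction with
    inhibitor, ``ha_blank`` the enzyme-free blank.
    """

    ha_control: float
    ha_sample: float
    ha_blank: float

    def __post_init__(self) -> None:
        if min(self.ha_control, self.ha_sample, self.ha_blank) < 0:
            raise ValueError("HA concentrations must be non-negative")
        if self.ha_control <= self.ha_blank:
            raise ValueError(
                "control HA must exceed the blank; otherwise the inhibition "
                "rate is undefined"
            )


def inhibition_rate(m: AssayMeasurement) -> float:
    """Percent inhibition: 100 × (HAc − HAs) / (HAc − HAblank)."""
    return 100.0 * (m.ha_control - m.ha_sample) / (m.ha_control - m.ha_blank)


# ---------------------------------------------------------------------------
# Dose-response IC50
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponse:
    """A fitted dose-response curve: inhibition% = 100 / (1 + (IC50/c)^h)."""

    concentrations: np.ndarray
    inhibition_pct: np.ndarray
    ic50: float
    hill: float
    rss: float
    method: str  # "log-logistic" or "interpolation"

    def curve(self, c: np.ndarray) -> np.ndarray:
        return _log_logistic(np.asarray(c, float), self.ic50, self.hill)


def _log_logistic(c: np.ndarray, ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + (ic50 / c) ** hill)


def fit_dose_response(concentrations: Sequence[float],
                      inhibition_pct: Sequence[float]) -> DoseResponse:
    """Fit IC50 (and Hill slope) to (concentration, % inhibition) points.

    Requires ≥ 4 points whose inhibitions bracket the 50% level; fits the
    two-parameter log-logistic in log-parameter space, falling back to
    monotone log-linear interpolation across the 50% crossing when the
    nonlinear fit fails (``method`` records which path produced the IC50).
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(inhibition_pct, float)
    if c.shape != y.shape or c.size < 4:
        raise ValueError("need at least 4 (concentration, inhibition) points")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    if np.any((y < -10) | (y > 110)):
        raise ValueError("inhibition values outside the [-10, 110]% band")
    if y.max() < 50 or y.min() > 50:
        lo, hi = y.min(), y.max()
        raise ValueError(
            f"inhibition range [{lo:.1f}%, {hi:.1f}%] does not bracket 50%; "
            "extend the concentration series toward the "
            + ("higher" if hi < 50 else "lower") + " end"
        )

    order = np.argsort(c)
    c, y = c[order], y[order]

    # interpolation start/fallback: first crossing of 50% on the log-c axis
    idx = int(np.argmax(y >= 50)) if y[0] < 50 else 0
    if idx == 0:
        ic50_interp = c[0]
    else:
        x0, x1 = np.log10(c[idx - 1]), np.log10(c[idx])
        y0, y1 = y[idx - 1], y[idx]
        ic50_interp = 10 ** (x0 + (50 - y0) * (x1 - x0) / (y1 - y0))

    try:
        popt, _ = optimize.curve_fit(
            lambda cc, log_ic50, log_h: _log_logistic(cc, 10 ** log_ic50, 10 ** log_h),
            c, y, p0=[np.log10(ic50_interp), 0.0], maxfev=10_000,
        )
        ic50, hill = 10 ** popt[0], 10 ** popt[1]
        rss = float(np.sum((y - _log_logistic(c, ic50, hill)) ** 2))
        method = "log-logistic"
    except RuntimeError:
        ic50, hill = float(ic50_interp), float("nan")
        rss = float("nan")
        method = "interpolation"
    return DoseResponse(c, y, float(ic50), float(hill), rss, method)


# ---------------------------------------------------------------------------
# Michaelis–Menten / Lineweaver–Burk fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticSeries:
    """(substrate, velocity) points measured at one inhibitor concentration."""

    inhibitor_conc: float
    substrate_mM: np.ndarray
    velocity: np.ndarray
    inhibitor_unit: str = "mg/mL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrate_mM", np.asarray(self.substrate_mM, float))
        object.__setattr__(self, "velocity", np.asarray(self.velocity, float))
        if self.substrate_mM.size < 3:
            raise ValueError("a kinetic series needs at least 3 substrate levels")
        if np.any(self.substrate_mM <= 0) or np.any(self.velocity <= 0):
            raise ValueError("substrate and velocity must be positive")


@dataclass(frozen=True)
class KineticFit:
    """Apparent Michaelis–Menten parameters of one series."""

    km: float
    vmax: float
    method: str  # "double-reciprocal" or "nonlinear"
    km_se: float
    vmax_se: float
    inhibitor_conc: float = 0.0


def fit_mm(series: KineticSeries, method: str = "double-reciprocal") -> KineticFit:
    """Fit Km and Vmax to one kinetic series.

    ``double-reciprocal`` regresses 1/v on 1/S (the Lineweaver–Burk line) and
    reads Km = slope/intercept, Vmax = 1/intercept; ``nonlinear`` fits
    v = Vmax·S/(Km+S) by least squares.  Standard errors are propagated from
    the respective fit covariance.
    """
    S, v = series.substrate_mM, series.velocity
    if method == "double-reciprocal":
        res = stats.linregress(1.0 / S, 1.0 / v)
        slope, intercept = res.slope, res.intercept
        if intercept <= 0:
            raise ValueError(
                "double-reciprocal intercept is non-positive; data are "
                "inconsistent with Michaelis–Menten saturation"
            )
        vmax = 1.0 / intercept
        km = slope / intercept
        # delta-method SEs from the line's slope/intercept errors
        vmax_se = res.intercept_stderr / intercept ** 2
        km_se = abs(km) * np.hypot(
            res.stderr / slope if slope != 0 else 0.0,
            res.intercept_stderr / intercept,
        )
    elif method == "nonlinear":
        p0 = [float(v.max()), float(np.median(S))]
        popt, pcov = optimize.curve_fit(
            lambda s, vmax, km: vmax * s / (km + s), S, v, p0=p0, maxfev=10_000
        )
        vmax, km = float(popt[0]), float(popt[1])
        if km <= 0 or vmax <= 0:
            raise ValueError("nonlinear fit produced non-positive parameters")
        perr = np.sqrt(np.diag(pcov))
        vmax_se, km_se = float(perr[0]), float(perr[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return KineticFit(float(km), float(vmax), method, float(km_se),
                      float(vmax_se), series.inhibitor_conc)


# ---------------------------------------------------------------------------
# Inhibition-mode classification
# ---------------------------------------------------------------------------

class InhibitionMode(str, Enum):
    COMPETITIVE = "competitive"
    NON_COMPETITIVE = "non-competitive"
    UNCOMPETITIVE = "uncompetitive"
    MIXED = "mixed"
    NONE = "none"


@dataclass(frozen=True)
class ModeCall:
    """A classified inhibition mechanism with its numeric evidence."""

    mode: InhibitionMode
    km_rel_change: tuple[float, ...]    # (Km_app − Km0)/Km0 per inhibitor level
    vmax_rel_change: tuple[float, ...]
    monotone: bool
    warning: str | None = None


def classify_inhibition(control: KineticFit,
                        inhibited: Sequence[KineticFit],
                        tolerance: float = 0.2) -> ModeCall:
    """Classify the inhibition mechanism from apparent-parameter changes.

    Relative Km and Vmax changes versus the uninhibited control are evaluated
    at the highest inhibitor level (largest signal); a parameter "changed"
    when its relative change exceeds ``tolerance`` (default 20%, an explicit
    stand-in for reading Lineweaver–Burk intersection patterns by eye):

    * Km ↑, Vmax constant  → competitive
    * Vmax ↓, Km constant  → non-competitive
    * both ↓ with the Km/Vmax ratio preserved → uncompetitive
    * both changed otherwise → mixed
    * neither changed → none

    The parameter trends must be monotone in inhibitor concentration;
    otherwise the call is still made but flagged with a warning.
    """
    if control is None:
        raise ValueError("a control (zero-inhibitor) fit is required")
    if not inhibited:
        raise ValueError("at least one inhibited fit is required")
    fits = sorted(inhibited, key=lambda f: f.inhibitor_conc)
    dkm = tuple((f.km - control.km) / control.km for f in fits)
    dvmax = tuple((f.vmax - control.vmax) / control.vmax for f in fits)

    top_dkm, top_dvmax = dkm[-1], dvmax[-1]
    km_changed = abs(top_dkm) > tolerance
    vmax_changed = abs(top_dvmax) > tolerance

    if not km_changed and not vmax_changed:
        mode = InhibitionMode.NONE
    elif km_changed and top_dkm > 0 and not vmax_changed:
        mode = InhibitionMode.COMPETITIVE
    elif vmax_changed and top_dvmax < 0 and not km_changed:
        mode = InhibitionMode.NON_COMPETITIVE
    elif top_dkm < 0 and top_dvmax < 0 and _ratio_preserved(control, fits[-1],
                                                            tolerance):
        mode = InhibitionMode.UNCOMPETITIVE
    else:
        mode = InhibitionMode.MIXED

    monotone = _is_monotone(dkm) and _is_monotone(dvmax)
    warning = None if monotone else (
        "apparent-parameter trends are not monotone in inhibitor "
        "concentration; classification may be unreliable"
    )
    return ModeCall(mode, dkm, dvmax, monotone, warning)


def _ratio_preserved(control: KineticFit, top: KineticFit,
                     tolerance: float) -> bool:
    r0 = control.km / control.vmax
    r1 = top.km / top.vmax
    return abs(r1 - r0) / r0 <= tolerance


def _is_monotone(changes: Sequence[float]) -> bool:
    seq = (0.0, *changes)
    diffs = np.diff(seq)
    return bool(np.all(diffs >= -1e-9) or np.all(diffs <= 1e-9))


# ---------------------------------------------------------------------------
# Digestion-stability comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityVerdict:
    """Outcome of a pre- vs post-digestion IC50 comparison."""

    stable: bool
    p_value: float
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    fold_change: float
    alpha: float
    degenerate: bool = False

    def row(self) -> dict:
        """Mean ± SD layout matching a pre/post comparison table."""
        return {
            "IC50 before digestion": f"{self.pre_mean:.2f} ± {self.pre_sd:.2f}",
            "IC50 after digestion": f"{self.post_mean:.2f} ± {self.post_sd:.2f}",
            "p": self.p_value,
            "stable": self.stable,
        }


def compare_stability(pre_ic50: Sequence[float], post_ic50: Sequence[float],
                      alpha: float = 0.05,
                      max_fold_change: float = 2.0) -> StabilityVerdict:
    """Welch's two-sample comparison of replicate IC50s before/after digestion.

    The peptide is called *stable* when the difference is not significant at
    ``alpha`` AND the post/pre mean ratio stays below ``max_fold_change``.
    ``alpha = 0`` can never reject and is flagged as degenerate.
    """
    pre = np.asarray(pre_ic50, float)
    post = np.asarray(post_ic50, float)
    if pre.size < 3 or post.size < 3:
        raise ValueError("need at least 3 replicates per condition")
    if np.allclose(pre, post):
        p = 1.0
    else:
        p = float(stats.ttest_ind(pre, post, equal_var=False).pvalue)
    fold = float(post.mean() / pre.mean())
    significant = p < alpha
    return StabilityVerdict(
        stable=(not significant) and fold < max_fold_change,
        p_value=p,
        pre_mean=float(pre.mean()), pre_sd=float(pre.std(ddof=1)),
        post_mean=float(post.mean()), post_sd=float(post.std(ddof=1)),
        fold_change=fold,
        alpha=alpha,
        degenerate=(alpha == 0),
    )


def lineweaver_burk_table(series: Sequence[KineticSeries]) -> "np.ndarray":
    """Double-reciprocal data table (1/S, 1/v per inhibitor level) for plotting."""
    import pandas as pd
    rows = [
        {
            "inhibitor_conc": s.inhibitor_conc,
            "inv_substrate": 1.0 / sub,
            "inv_velocity": 1.0 / vel,
        }
        for s in series
        for sub, vel in zip(s.substrate_mM, s.velocity)
    ]
    return pd.DataFrame(rows)
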