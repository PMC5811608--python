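"""Prothrombinase progress-curve kinetics.

The continuous chromogenic assay couples two reactions: prothrombinase
(concentration E0) activates prothrombin (S0, far below the activation KM)
to thrombin pseudo-first-order with rate k_spec * E0, and the thrombin
generated hydrolyses the chromogenic reporter FPF-pNA (C0) releasing pNA
read as absorbance:

    thrombin(t) = S0 * (1 - exp(-k_spec * E0 * t))
    dC/dt       = -kcat_c * thrombin(t) * C / (KM_c + C)
    A(t)        = baseline + epsilon_path * (C0 - C(t))

Early on, A(t) ~ 1/2 * epsilon_path * v_c * k_spec * E0 * S0 * t^2 with
v_c = kcat_c * C0 / (KM_c + C0): the parabolic onset.  The single free
parameter of interest is the activation specificity constant
k_spec = kcat/KM (M^-1 s^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

logger = logging.getLogger("protconf")


@dataclass(frozen=True)
class KineticParams:
    """Assay constants.  Concentration defaults are the assay conditions
    (10 nM prothrombin, 2.5 pM factor Xa, 24 uM FPF-pNA); ``kcat_c`` and
    ``KM_c`` for thrombin on FPF-pNA are documented placeholders that must
    be supplied from calibration for quantitative work. ``epsilon_path`` is
    the absorbance per molar pNA (extinction coefficient x path length).
    ``activity_factor`` scales kcat_c for constructs whose product enzyme
    hydrolyses the reporter at reduced efficiency (e.g. the disulfide-locked
    closed form, whose fragment-1 stays attached to the autolysis loop)."""

    k_spec: float = 3.8e8        # M^-1 s^-1
    e0: float = 2.5e-12          # M prothrombinase
    s0: float = 1.0e-8           # M prothrombin
    kcat_c: float = 50.0         # s^-1, placeholder
    km_c: float = 1.0e-5         # M, placeholder
    c0: float = 2.4e-5           # M chromogenic substrate
    epsilon_path: float = 9920.0 # A / M (pNA at 405 nm, 1 cm)
    baseline: float = 0.0
    activity_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_spec", "e0", "s0", "kcat_c", "c0", "epsilon_path",
                     "activity_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.km_c <= 0:
            raise ValueError("KM_c must be positive")


@dataclass
class ProgressCurve:
    """Absorbance versus time, optionally with per-point uncertainty."""

    t: np.ndarray
    a: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.a = np.asarray(self.a, float)
        if len(self.t) != len(self.a):
            raise ValueError("t and A must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, float)
            if len(self.sigma) != len(self.t):
                raise ValueError("sigma length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def to_csv(self, path: str | Path) -> None:
        d = {"t_s": self.t, "A": self.a}
        if self.sigma is not None:
            d["sigma"] = self.sigma
        pd.DataFrame(d).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProgressCurve":
        df = pd.read_csv(path)
        sigma = df["sigma"].to_numpy() if "sigma" in df else None
        return cls(df["t_s"].to_numpy(), df["A"].to_numpy(), sigma)


def progress_model(params: KineticParams, t: np.ndarray) -> ProgressCurve:
    """Noiseless coupled activation/hydrolysis progress curve at times t."""
    t = np.asarray(t, float)
    if len(t) == 0:
        return ProgressCurve(t, np.zeros(0))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    kobs = params.k_spec * params.e0
    vmax = params.kcat_c * params.activity_factor
    if kobs == 0 or params.s0 == 0 or vmax == 0 or params.c0 == 0:
        return ProgressCurve(t, np.full(len(t), params.baseline))

    def rhs(tau: float, y: np.ndarray) -> list[float]:
        thr = params.s0 * -np.expm1(-kobs * tau)
        c = max(y[0], 0.0)
        return [-vmax * thr * c / (params.km_c + c)]

    t_eval = t if t[0] == 0 else np.concatenate(([0.0], t))
    sol = solve_ivp(
        rhs, (0.0, float(t[-1])), [params.c0], t_eval=t_eval,
        method="LSODA", rtol=1e-9, atol=params.c0 * 1e-12, max_step=np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"progress-curve integration failed: {sol.message}")
    c = sol.y[0][-len(t):]
    a = params.baseline + params.epsilon_path * (params.c0 - c)
    return ProgressCurve(t, a)


def early_time_quadratic(params: KineticParams) -> float:
    """Coefficient b of the parabolic onset A ~ baseline + b t^2."""
    v_c = params.kcat_c * params.activity_factor * params.c0 / (params.km_c + params.c0)
    return 0.5 * params.epsilon_path * v_c * params.k_spec * params.e0 * params.s0


@dataclass(frozen=True)
class SpecificityFit:
    """Estimated activation specificity constant kcat/KM."""

    k_spec: float                # M^-1 s^-1
    stderr: float
    baseline: float
    rel_err: float
    method: str
    flat: bool = False


def fit_specificity_constant(
    curve: ProgressCurve,
    known: KineticParams,
    method: str = "curve",
) -> SpecificityFit:
    """Estimate k_spec from a progress curve with all other constants known.

    ``method='curve'``: weighted nonlinear least squares of the full coupled
    model in (k_spec, baseline); standard error from the Jacobian.
    ``method='slope'``: linearized fit of the parabolic onset A = a + b t^2
    over the first 5 % of the signal range.
    """
    if len(curve) < 10:
        raise ValueError("need at least 10 points")
    span = float(curve.a.max() - curve.a.min())
    if span <= 0 or not np.isfinite(span):
        return SpecificityFit(0.0, np.inf, float(curve.a.mean()), np.inf,
                              method, flat=True)
    w = 1.0 / curve.sigma if curve.sigma is not None else np.ones(len(curve))

    if method == "slope":
        lim = curve.a.min() + 0.05 * span
        m = curve.a <= lim
        if m.sum() < 3:
            m = np.zeros(len(curve), bool)
            m[: max(3, len(curve) // 20)] = True
        x = curve.t[m] ** 2
        coef, *_ = np.linalg.lstsq(
            np.column_stack((np.ones(int(m.sum())), x)), curve.a[m], rcond=None)
        b = coef[1]
        v_c = known.kcat_c * known.activity_factor * known.c0 / (known.km_c + known.c0)
        denom = 0.5 * known.epsilon_path * v_c * known.e0 * known.s0
        k = float(max(b, 0.0) / denom)
        return SpecificityFit(k, np.nan, float(coef[0]), np.nan, "slope",
                              flat=k == 0.0)
    if method != "curve":
        raise ValueError("method must be 'curve' or 'slope'")

    # initial guess from the parabolic onset
    init = fit_specificity_constant(curve, known, method="slope")
    k0 = init.k_spec if init.k_spec > 0 else 1e8

    def resid(x: np.ndarray) -> np.ndarray:
        p = replace(known, k_spec=abs(x[0]) * 1e8, baseline=x[1])
        return w * (progress_model(p, curve.t).a - curve.a)

    res = least_squares(resid, x0=[k0 / 1e8, float(curve.a[0])],
                        method="lm", xtol=1e-12, ftol=1e-12)
    k_hat = abs(res.x[0]) * 1e8
    dof = max(1, len(curve) - 2)
    s2 = float(np.sum(res.fun ** 2) / dof)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * s2
        se = float(np.sqrt(cov[0, 0]) * 1e8)
    except np.linalg.LinAlgError:
        se = np.inf
    rel = se / k_hat if k_hat > 0 else np.inf
    logger.info("k_spec fit: %.3e +/- %.3e M^-1 s^-1 (%s)", k_hat, se, method)
    return SpecificityFit(k_hat, se, float(res.x[1]), rel, "curve",
                          flat=k_hat == 0.0)
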