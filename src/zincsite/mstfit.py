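"""Binding-curve fitting for microscale thermophoresis (MST) titrations.

Two models are supported. The law of mass action accounts for ligand depletion
when the protein concentration C_P is comparable to K_d:

    F(C_Zn) = F_u + (F_b - F_u) * [(C_Zn + C_P + K_d)
              - sqrt((C_Zn + C_P + K_d)^2 - 4 C_P C_Zn)] / (2 C_P)

The Hill equation assesses cooperativity:

    F(C_Zn) = F_u + (F_b - F_u) / (1 + (EC50 / C_Zn)^n)

Raw responses are not pre-normalized: the unbound/bound plateaus F_u and F_b
are fitted alongside the affinity parameters. Confidence intervals are
case-resampling bootstrap percentile intervals (seeded).

The module also computes chelator-buffered free metal concentrations for the
1:1 complexation equilibrium used to prepare nanomolar Zn2+ solutions with
NTA (K_d = 14 nM) or citrate (K_d = 12 uM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MSTCurve",
    "MassActionFit",
    "HillFit",
    "ChelatorSystem",
    "FitError",
    "fit_mass_action",
    "fit_hill",
    "free_metal",
    "total_for_free",
    "read_curves",
    "CHELATOR_KD",
]

#: dissociation constants of the chelators used to buffer free Zn2+ (molar)
CHELATOR_KD = {"NTA": 14e-9, "citrate": 12e-6}


class FitError(RuntimeError):
    """Raised when a binding-curve fit cannot be performed or fails."""


@dataclass
class MSTCurve:
    """One titration: responses vs free metal concentration at fixed pH."""

    site_label: str
    pH: float
    zn_free: np.ndarray  # molar, pooled over replicates
    response: np.ndarray
    replicate: np.ndarray
    protein_conc: float  # molar

    def __post_init__(self) -> None:
        self.zn_free = np.asarray(self.zn_free, float)
        self.response = np.asarray(self.response, float)
        self.replicate = np.asarray(self.replicate)
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")
        if np.any(self.zn_free < 0):
            raise ValueError("zn_free must be non-negative")
        if np.unique(self.zn_free).size < 4:
            raise ValueError("need >= 4 distinct concentrations to fit")


@dataclass
class MassActionFit:
    kd: float
    f_unbound: float
    f_bound: float
    ci68: dict[str, tuple[float, float]]
    ci95: dict[str, tuple[float, float]]
    residual_rms: float
    titration_regime: bool = False  # K_d below C_P: binding curve degenerates


@dataclass
class HillFit:
    ec50: float
    hill_n: float
    f_unbound: float
    f_bound: float
    ci68: dict[str, tuple[float, float]]
    residual_rms: float


@dataclass
class ChelatorSystem:
    chelator_total: float
    chelator_kd: float
    metal_total: float

    def __post_init__(self) -> None:
        if self.chelator_total < 0 or self.metal_total < 0:
            raise ValueError("totals must be non-negative")
        if self.chelator_kd <= 0:
            raise ValueError("chelator_kd must be positive")


def mass_action_response(
    c_zn: np.ndarray, kd: float, f_u: float, f_b: float, c_p: float
) -> np.ndarray:
    s = c_zn + c_p + kd
    disc = np.maximum(s * s - 4.0 * c_p * c_zn, 0.0)
    frac = (s - np.sqrt(disc)) / (2.0 * c_p)
    return f_u + (f_b - f_u) * frac


def hill_response(
    c_zn: np.ndarray, ec50: float, n: float, f_u: float, f_b: float
) -> np.ndarray:
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c_zn > 0, (ec50 / np.maximum(c_zn, 1e-300)) ** n, np.inf)
    return f_u + (f_b - f_u) / (1.0 + ratio)


def _check_variation(curve: MSTCurve) -> None:
    if np.ptp(curve.response) < 1e-12 or np.allclose(
        curve.response, curve.response.mean(), atol=1e-12, rtol=0.0
    ):
        raise FitError("response has no variation across concentrations")


def _multistart_grid(zn: np.ndarray) -> np.ndarray:
    pos = zn[zn > 0]
    lo, hi = math.log10(pos.min()) - 2.0, math.log10(pos.max()) + 2.0
    return 10.0 ** np.linspace(lo, hi, 12)


def _fit_once_mass_action(zn, resp, c_p, k_starts):
    f_lo, f_hi = resp.min(), resp.max()
    span = max(f_hi - f_lo, 1e-12)
    best = None
    for k0 in k_starts:
        for f_u0, f_b0 in ((f_lo, f_hi), (f_hi, f_lo)):
            try:
                popt, _ = curve_fit(
                    lambda c, lk, fu, fb: mass_action_response(c, 10.0 ** lk, fu, fb, c_p),
                    zn,
                    resp,
                    p0=(math.log10(k0), f_u0, f_b0),
                    bounds=((-30, f_lo - 5 * span, f_lo - 5 * span),
                            (3, f_hi + 5 * span, f_hi + 5 * span)),
                    maxfev=5000,
                )
            except (RuntimeError, ValueError):
                continue
            pred = mass_action_response(zn, 10.0 ** popt[0], popt[1], popt[2], c_p)
            sse = float(np.sum((pred - resp) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt)
    if best is None:
        raise FitError("mass-action fit did not converge from any start")
    return best


def _bootstrap(zn, resp, fit_one, n_boot, seed, names):
    rng = np.random.default_rng(seed)
    n = zn.size
    draws = {k: [] for k in names}
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            _, popt = fit_one(zn[idx], resp[idx])
        except FitError:
            continue
        for k, v in zip(names, popt):
            draws[k].append(v)
    ci68, ci95 = {}, {}
    for k in names:
        arr = np.asarray(draws[k])
        if arr.size < 10:
            ci68[k] = (math.nan, math.nan)
            ci95[k] = (math.nan, math.nan)
        else:
            ci68[k] = tuple(np.percentile(arr, [16.0, 84.0]))
            ci95[k] = tuple(np.percentile(arr, [2.5, 97.5]))
    return ci68, ci95


def fit_mass_action(
    curve: MSTCurve, n_boot: int = 1000, seed: int = 0
) -> MassActionFit:
    """Least-squares law-of-mass-action fit of (K_d, F_u, F_b).

    Multi-start initialization over a log-spaced K_d grid covering the data's
    concentration range plus two decades on either side. Bootstrap percentile
    confidence intervals use ``n_boot`` case resamples of the pooled points.
    A fitted K_d below the protein concentration is flagged as the titration
    regime, where the curve no longer determines K_d well.
    """
    _check_variation(curve)
    zn, resp, c_p = curve.zn_free, curve.response, curve.protein_conc
    k_starts = _multistart_grid(zn)

    sse, popt = _fit_once_mass_action(zn, resp, c_p, k_starts)
    kd = 10.0 ** popt[0]
    f_lo, f_hi = resp.min(), resp.max()
    span = max(f_hi - f_lo, 1e-12)

    def fit_one_boot(z, r):
        # resample refits start from the full-data optimum (cheap, stable)
        try:
            p, _ = curve_fit(
                lambda c, lk, fu, fb: mass_action_response(c, 10.0 ** lk, fu, fb, c_p),
                z, r, p0=popt,
                bounds=((-30, f_lo - 5 * span, f_lo - 5 * span),
                        (3, f_hi + 5 * span, f_hi + 5 * span)),
                maxfev=2000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(str(exc)) from exc
        return 0.0, p

    ci68, ci95 = ({}, {})
    if n_boot > 0:
        ci68, ci95 = _bootstrap(zn, resp, fit_one_boot, n_boot, seed, ["log10_kd", "f_unbound", "f_bound"])
        for ci in (ci68, ci95):
            if "log10_kd" in ci:
                lo, hi = ci.pop("log10_kd")
                ci["kd"] = (10.0 ** lo, 10.0 ** hi)
    return MassActionFit(
        kd=float(kd),
        f_unbound=float(popt[1]),
        f_bound=float(popt[2]),
        ci68=ci68,
        ci95=ci95,
        residual_rms=math.sqrt(sse / zn.size),
        titration_regime=bool(kd < c_p),
    )


def fit_hill(curve: MSTCurve, n_boot: int = 1000, seed: int = 0) -> HillFit:
    """Least-squares Hill fit of (EC50, n, F_u, F_b)."""
    _check_variation(curve)
    zn, resp = curve.zn_free, curve.response
    f_lo, f_hi = resp.min(), resp.max()
    span = max(f_hi - f_lo, 1e-12)
    starts = _multistart_grid(zn)

    def fit_one(z, r):
        best = None
        for e0 in starts:
            for n0 in (0.5, 1.0, 2.0, 3.0):
                for f_u0, f_b0 in ((f_lo, f_hi), (f_hi, f_lo)):
                    try:
                        popt, _ = curve_fit(
                            lambda c, le, n, fu, fb: hill_response(c, 10.0 ** le, n, fu, fb),
                            z,
                            r,
                            p0=(math.log10(e0), n0, f_u0, f_b0),
                            bounds=((-30, 0.05, f_lo - 5 * span, f_lo - 5 * span),
                                    (3, 20, f_hi + 5 * span, f_hi + 5 * span)),
                            maxfev=5000,
                        )
                    except (RuntimeError, ValueError):
                        continue
                    pred = hill_response(z, 10.0 ** popt[0], popt[1], popt[2], popt[3])
                    sse = float(np.sum((pred - r) ** 2))
                    if best is None or sse < best[0]:
                        best = (sse, popt)
        if best is None:
            raise FitError("Hill fit did not converge from any start")
        return best

    sse, popt = fit_one(zn, resp)

    def fit_one_boot(z, r):
        try:
            p, _ = curve_fit(
                lambda c, le, n, fu, fb: hill_response(c, 10.0 ** le, n, fu, fb),
                z, r, p0=popt,
                bounds=((-30, 0.05, f_lo - 5 * span, f_lo - 5 * span),
                        (3, 20, f_hi + 5 * span, f_hi + 5 * span)),
                maxfev=2000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(str(exc)) from exc
        return 0.0, p

    ci68 = {}
    if n_boot > 0:
        ci68, _ = _bootstrap(zn, resp, fit_one_boot, n_boot, seed,
                             ["log10_ec50", "hill_n", "f_unbound", "f_bound"])
        lo, hi = ci68.pop("log10_ec50")
        ci68["ec50"] = (10.0 ** lo, 10.0 ** hi)
    return HillFit(
        ec50=float(10.0 ** popt[0]),
        hill_n=float(popt[1]),
        f_unbound=float(popt[2]),
        f_bound=float(popt[3]),
        ci68=ci68,
        residual_rms=math.sqrt(sse / zn.size),
    )


def free_metal(system: ChelatorSystem) -> float:
    """Free metal concentration for the 1:1 chelation equilibrium M + L <-> ML.

    Positive root of M^2 + (L_t - M_t + K_d) M - K_d M_t = 0 from the two mass
    balances M_t = M + ML and L_t = L + ML with K_d = [M][L]/[ML].
    """
    kd, lt, mt = system.chelator_kd, system.chelator_total, system.metal_total
    if lt == 0:
        return mt
    b = lt - mt + kd
    m = (-b + math.sqrt(b * b + 4.0 * kd * mt)) / 2.0
    return max(m, 0.0)


def total_for_free(
    target_free: float, chelator_total: float, chelator_kd: float
) -> float:
    """Total metal needed to buffer a target free concentration (inverse op)."""
    if target_free < 0:
        raise ValueError("target_free must be non-negative")
    complexed = chelator_total * target_free / (chelator_kd + target_free)
    return target_free + complexed


def read_curves(path, protein_conc: float) -> list[MSTCurve]:
    """Read titrations from the tidy CSV dialect.

    Columns: site,ph,zn_free_M,replicate,response (header required;
    concentrations in molar). Returns one pooled curve per (site, pH).
    """
    df = pd.read_csv(path)
    required = {"site", "ph", "zn_free_M", "replicate", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing CSV columns: {sorted(missing)}")
    curves = []
    for (site, ph), grp in df.groupby(["site", "ph"], sort=True):
        curves.append(
            MSTCurve(
                site_label=str(site),
                pH=float(ph),
                zn_free=grp["zn_free_M"].to_numpy(float),
                response=grp["response"].to_numpy(float),
                replicate=grp["replicate"].to_numpy(),
                protein_conc=protein_conc,
            )
        )
    return curves


def curves_to_frame(curves: Sequence[MSTCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for z, r, rep in zip(c.zn_free, c.response, c.replicate):
            rows.append(
                {"site": c.site_label, "ph": c.pH, "zn_free_M": z,
                 "replicate": rep, "response": r}
            )
    return pd.DataFrame(rows)
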