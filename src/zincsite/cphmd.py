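"""Analysis of constant-pH MD titration coordinates.

Each titratable residue carries a continuous titration coordinate lambda in
[0, 1] per trajectory frame. A frame counts as deprotonated when lambda > 0.8
and protonated when lambda < 0.2 (strict inequalities; boundary values and the
intermediate band are excluded). Per-residue deprotonation fractions

    S = N_deprot / (N_deprot + N_prot)

are fitted across the pH replica ladder with the generalized
Henderson-Hasselbalch (Hill) form S(pH) = 1 / (1 + 10^(n*(pKa - pH))).
Frames can also be mapped to protonation microstates (S-labels) and
histogrammed; a frame is dropped from the microstate histogram if ANY site
residue sits in the intermediate band. Estimates from the two protomers of a
homodimer are combined as mean +/- average absolute deviation from the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "LambdaSeries",
    "ProtonationCounts",
    "HillLangmuirFit",
    "MicrostateDistribution",
    "count_protonation",
    "deprotonation_fraction",
    "fit_hill_langmuir",
    "microstate_distribution",
    "combine_protomers",
    "read_lambda_csv",
    "lambda_to_frame",
]


class AnalysisError(ValueError):
    """Raised for undefined fractions, degenerate fits or misaligned series."""


@dataclass
class LambdaSeries:
    """Titration-coordinate time series for one residue at one replica pH."""

    residue_label: str
    protomer: str
    ph: float
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, float)
        if self.frames.size == 0:
            raise ValueError("frames must be non-empty")
        if np.any((self.frames < 0) | (self.frames > 1)):
            raise ValueError("lambda values must lie in [0, 1]")


@dataclass(frozen=True)
class ProtonationCounts:
    n_deprot: int
    n_prot: int
    n_excluded: int


@dataclass
class HillLangmuirFit:
    pka: float
    hill_n: float
    residual_rms: float
    coupled: bool = False  # poor single-residue fit: use the coupled model


@dataclass
class MicrostateDistribution:
    """Per-pH probability over S-labelled protonation states."""

    ph: float
    probabilities: dict[str, float]
    n_frames_used: int


def count_protonation(
    series: LambdaSeries, lo: float = 0.2, hi: float = 0.8
) -> ProtonationCounts:
    """Classify frames into protonated / deprotonated / excluded.

    lambda > hi counts as deprotonated, lambda < lo as protonated; anything
    in between, including values exactly at the thresholds, is excluded.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")
    lam = series.frames
    n_deprot = int(np.count_nonzero(lam > hi))
    n_prot = int(np.count_nonzero(lam < lo))
    return ProtonationCounts(n_deprot, n_prot, lam.size - n_deprot - n_prot)


def deprotonation_fraction(counts: ProtonationCounts) -> float:
    """S = N_deprot / (N_deprot + N_prot)."""
    denom = counts.n_deprot + counts.n_prot
    if denom == 0:
        raise AnalysisError("all frames excluded: deprotonation fraction undefined")
    return counts.n_deprot / denom


def hill_langmuir(ph: np.ndarray, pka: float, n: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (n * (pka - ph)))


def fit_hill_langmuir(
    s_by_ph: Sequence[tuple[float, float]],
    coupled_rms_threshold: float | None = None,
) -> HillLangmuirFit:
    """Fit deprotonation fractions vs pH with the Hill-Langmuir form.

    Requires >= 4 pH points. Raises for curves with no pH response. When
    ``coupled_rms_threshold`` is given, fits with residual RMS above it are
    flagged as coupled (the single-residue form cannot describe them).
    """
    pts = sorted(s_by_ph)
    if len(pts) < 4:
        raise AnalysisError("need >= 4 pH points for a Hill-Langmuir fit")
    ph = np.array([p for p, _ in pts])
    s = np.array([v for _, v in pts])
    if np.ptp(s) < 1e-9:
        raise AnalysisError("deprotonation fraction constant across pH")
    # midpoint crossing as pKa start
    pka0 = float(ph[np.argmin(np.abs(s - 0.5))])
    best = None
    for n0 in (0.5, 1.0, 2.0):
        try:
            popt, _ = curve_fit(
                hill_langmuir, ph, s, p0=(pka0, n0),
                bounds=((-10, 0.05), (24, 20)), maxfev=5000,
            )
        except (RuntimeError, ValueError):
            continue
        rms = float(np.sqrt(np.mean((hill_langmuir(ph, *popt) - s) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise AnalysisError("Hill-Langmuir fit did not converge")
    (pka, n), rms = best
    coupled = coupled_rms_threshold is not None and rms > coupled_rms_threshold
    return HillLangmuirFit(pka=float(pka), hill_n=float(n),
                           residual_rms=rms, coupled=coupled)


def microstate_distribution(
    series_set: Mapping[str, LambdaSeries] | Sequence[LambdaSeries],
    site: Sequence[str],
    lo: float = 0.2,
    hi: float = 0.8,
) -> MicrostateDistribution:
    """Histogram frames over S-labelled protonation microstates.

    ``site`` lists residue labels in bit order (bit i of the S-label integer
    encoding is residue i). All series must share frame count and pH. A frame
    is dropped when any residue's lambda falls in the excluded band.
    """
    if not isinstance(series_set, Mapping):
        series_set = {s.residue_label: s for s in series_set}
    try:
        series = [series_set[lab] for lab in site]
    except KeyError as exc:
        raise AnalysisError(f"missing series for residue {exc}") from exc
    n_frames = {s.frames.size for s in series}
    if len(n_frames) != 1:
        raise AnalysisError(f"mismatched frame counts: {sorted(n_frames)}")
    phs = {s.ph for s in series}
    if len(phs) != 1:
        raise AnalysisError(f"mismatched replica pH values: {sorted(phs)}")
    lam = np.stack([s.frames for s in series], axis=1)  # (frames, residues)
    deprot = lam > hi
    prot = lam < lo
    valid = np.all(deprot | prot, axis=1)
    codes = (prot[valid].astype(np.int64) * (1 << np.arange(len(site)))).sum(axis=1)
    counts = np.bincount(codes, minlength=1 << len(site))
    used = int(valid.sum())
    probs = {}
    if used:
        for k, c in enumerate(counts):
            if c:
                probs[f"S{k}"] = c / used
    return MicrostateDistribution(ph=phs.pop(), probabilities=probs,
                                  n_frames_used=used)


def combine_protomers(values: Sequence[float]) -> tuple[float, float]:
    """Mean and average absolute deviation from the mean over protomers."""
    if len(values) < 2:
        raise AnalysisError("need >= 2 per-protomer values to aggregate")
    arr = np.asarray(values, float)
    mean = float(arr.mean())
    return mean, float(np.abs(arr - mean).mean())


def read_lambda_csv(path) -> list[LambdaSeries]:
    """Read the tidy lambda CSV dialect: ph,protomer,residue,frame,lambda.

    Frames are ordered by the ``frame`` column within each
    (ph, protomer, residue) group.
    """
    df = pd.read_csv(path)
    required = {"ph", "protomer", "residue", "frame", "lambda"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing CSV columns: {sorted(missing)}")
    out = []
    for (ph, protomer, residue), grp in df.groupby(
        ["ph", "protomer", "residue"], sort=True
    ):
        grp = grp.sort_values("frame")
        out.append(
            LambdaSeries(
                residue_label=str(residue),
                protomer=str(protomer),
                ph=float(ph),
                frames=grp["lambda"].to_numpy(float),
            )
        )
    return out


def lambda_to_frame(series: Iterable[LambdaSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for i, lam in enumerate(s.frames):
            rows.append({"ph": s.ph, "protomer": s.protomer,
                         "residue": s.residue_label, "frame": i, "lambda": lam})
    return pd.DataFrame(rows)
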