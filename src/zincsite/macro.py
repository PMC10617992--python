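"""Macroscopic summaries of a microscopic binding-site model.

Coupling energies quantify how protonation of one residue shifts the
microscopic pKa of a partner (W > 0 is anti-cooperative). Effective pKa's are
obtained by fitting a residue's model-derived metal-free titration curve with
the Hill-Langmuir form; strongly coupled residue pairs that this form cannot
describe are instead summarized with the two-proton coupled titration model

    N_prot(pH) = [10^(pK1-pH) + 2*10^(pK1+pK2-2pH)]
                 / [1 + 10^(pK1-pH) + 10^(pK1+pK2-2pH)]

whose pK1 and pK2 are the effective pKa's of binding the first and the second
proton. The metal-free condition is approximated by [Zn2+] = 1e-20 M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .cphmd import HillLangmuirFit, fit_hill_langmuir
from .statespace import (
    Condition,
    Microstate,
    SiteModel,
    deprotonation_fraction_model,
    microstate_pka,
)

__all__ = [
    "CouplingResult",
    "CoupledTitrationFit",
    "ProtonCountCurve",
    "coupling_energy",
    "proton_count_curve",
    "fit_coupled_titration",
    "effective_pka",
    "coupled_titration_nprot",
    "ZN_FREE_APPROX",
    "COUPLED_FIT_RMS_THRESHOLD",
]

#: near-zero free metal concentration standing in for the metal-free condition
ZN_FREE_APPROX = 1e-20
#: Hill-Langmuir residual RMS above which a residue is flagged as coupled
COUPLED_FIT_RMS_THRESHOLD = 0.02


class MacroError(ValueError):
    pass


@dataclass
class CouplingResult:
    residue_pair: tuple[str, str]
    context: Microstate
    w: float  # pKa units
    path_check: float  # |W(i|j) - W(j|i)|, 0 for consistent models


@dataclass
class CoupledTitrationFit:
    pk1: float  # first proton (higher effective affinity)
    pk2: float
    residual_rms: float


@dataclass
class ProtonCountCurve:
    ph: np.ndarray
    n_prot: np.ndarray  # expected protons on the designated pair, in [0, 2]


def coupling_energy(
    model: SiteModel,
    residue_i: str,
    residue_j: str,
    context: Microstate | None = None,
) -> CouplingResult:
    """W = pKa(i | j deprotonated) - pKa(i | j protonated) in a context.

    Both residues must be deprotonated in the context (default: the fully
    deprotonated metal-free state). The same quantity evaluated with the
    roles of i and j swapped must agree for a consistent model; the absolute
    difference is reported as ``path_check``.
    """
    ri, rj = model.residue(residue_i), model.residue(residue_j)
    if context is None:
        context = Microstate((0,) * model.n_residues, False)
    if context.protons[ri.bit_index] or context.protons[rj.bit_index]:
        raise MacroError("both residues must be deprotonated in the context")
    pka_i_free = microstate_pka(model, residue_i, context)
    pka_i_jprot = microstate_pka(model, residue_i, context.with_proton(rj.bit_index))
    pka_j_free = microstate_pka(model, residue_j, context)
    pka_j_iprot = microstate_pka(model, residue_j, context.with_proton(ri.bit_index))
    w_ij = pka_i_free - pka_i_jprot
    w_ji = pka_j_free - pka_j_iprot
    return CouplingResult(
        residue_pair=(residue_i, residue_j),
        context=context,
        w=w_ij,
        path_check=abs(w_ij - w_ji),
    )


def proton_count_curve(
    model: SiteModel,
    residue_pair: tuple[str, str],
    ph_grid: np.ndarray,
    zn_free: float = ZN_FREE_APPROX,
) -> ProtonCountCurve:
    """Expected protons bound to a residue pair, N = 2 - (S_i + S_j)."""
    ph_grid = np.asarray(ph_grid, float)
    i, j = residue_pair
    n = np.array(
        [
            2.0
            - deprotonation_fraction_model(model, i, Condition(ph, zn_free))
            - deprotonation_fraction_model(model, j, Condition(ph, zn_free))
            for ph in ph_grid
        ]
    )
    return ProtonCountCurve(ph=ph_grid, n_prot=n)


def coupled_titration_nprot(
    ph: np.ndarray, pk1: float, pk2: float, strict_printed_form: bool = False
) -> np.ndarray:
    """Two-proton coupled titration model.

    The default numerator uses pK1 in the singly protonated term, the form
    consistent with the binding-polynomial denominator;
    ``strict_printed_form`` swaps in pK2 there instead.
    """
    x1 = 10.0 ** ((pk2 if strict_printed_form else pk1) - ph)
    single = x1
    double = 10.0 ** (pk1 + pk2 - 2.0 * ph)
    denom = 1.0 + 10.0 ** (pk1 - ph) + double
    return (single + 2.0 * double) / denom


def fit_coupled_titration(
    curve: ProtonCountCurve, strict_printed_form: bool = False
) -> CoupledTitrationFit:
    """Least-squares (pK1, pK2) fit of a proton-count curve.

    The labeling with pK1 >= pK2 is returned (the first proton binds with the
    higher effective affinity).
    """
    n = curve.n_prot
    if np.ptp(n) < 1e-9:
        raise MacroError("degenerate proton-count curve: no titration")

    def f(ph, pk1, pk2):
        return coupled_titration_nprot(ph, pk1, pk2, strict_printed_form)

    # midpoints of the two transitions as starts
    ph = curve.ph
    try:
        pk10 = float(ph[np.argmin(np.abs(n - 0.5))])
        pk20 = float(ph[np.argmin(np.abs(n - 1.5))])
    except ValueError:
        pk10, pk20 = 9.0, 5.0
    best = None
    for p0 in ((max(pk10, pk20), min(pk10, pk20)), (10.0, 4.0), (8.0, 6.0)):
        try:
            popt, _ = curve_fit(f, ph, n, p0=p0, maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        rms = float(np.sqrt(np.mean((f(ph, *popt) - n) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise MacroError("coupled titration fit did not converge")
    (pk1, pk2), rms = best
    if pk1 < pk2:
        pk1, pk2 = pk2, pk1
    return CoupledTitrationFit(pk1=float(pk1), pk2=float(pk2), residual_rms=rms)


def effective_pka(
    model: SiteModel,
    residue: str,
    zn_free: float = ZN_FREE_APPROX,
    ph_grid: np.ndarray | None = None,
) -> HillLangmuirFit:
    """Effective pKa of a residue under the metal-free condition.

    The model's deprotonation fraction is evaluated on a pH grid (default
    0..14, step 0.05) and fitted with the Hill-Langmuir form. Fits with
    residual RMS above 0.02 are flagged coupled: the residue titrates with a
    partner and should be summarized with the coupled titration model.
    """
    if ph_grid is None:
        ph_grid = np.arange(0.0, 14.0 + 1e-9, 0.05)
    pts = [
        (float(ph), deprotonation_fraction_model(model, residue, Condition(ph, zn_free)))
        for ph in ph_grid
    ]
    return fit_hill_langmuir(pts, coupled_rms_threshold=COUPLED_FIT_RMS_THRESHOLD)
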