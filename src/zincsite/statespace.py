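"""Microscopic thermodynamic model of a metal binding site with titratable residues.

A binding site with R titratable residues has 2**R protonation microstates, each
of which can additionally carry a bound metal ion, for 2**(R+1) states in total.
Every state stores a reference free energy ``g`` in units of k_B T: the pH- and
concentration-independent part of the state free energy. The all-deprotonated,
metal-free state is the reference with g = 0. At a condition (pH, free metal
concentration) the full reduced free energy of a state is

    beta*G(s, b) = g(s, b) + n_protons(s) * ln(10) * pH - b * ln([X] / c0)

so that along any single protonation edge beta*dG = ln(10) * (pH - pKa) and
along any metal binding edge beta*dG = beta*dG0_bind - ln([X]/c0), with the
standard concentration c0 = 1 M.

States are ordered canonically: the proton bit-vector read as a little-endian
integer, with the metal-free block first. The protonation microstate with
integer encoding k carries the label ``Sk`` (S0 = no protons).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

LN10 = math.log(10.0)

__all__ = [
    "LN10",
    "TitratableResidue",
    "Microstate",
    "Condition",
    "SiteModel",
    "ConsistencyEdge",
    "enumerate_microstates",
    "model_from_parameters",
    "free_energy",
    "state_probabilities",
    "bound_fraction",
    "deprotonation_fraction_model",
    "apparent_kd",
    "microstate_pka",
    "fit_consistent_potentials",
    "solve_potentials",
    "model_to_json",
    "model_from_json",
    "state_label_table",
]


class ModelError(ValueError):
    """Raised for invalid model construction or queries."""


@dataclass(frozen=True)
class TitratableResidue:
    """One titratable residue of a binding site, e.g. ``D51`` or ``H155``."""

    label: str
    bit_index: int


@dataclass(frozen=True)
class Microstate:
    """One protonation/bound assignment of the site.

    ``protons`` is a tuple of 0/1 flags ordered by residue bit index
    (1 = protonated); ``zinc_bound`` marks the metal-bound branch.
    """

    protons: tuple[int, ...]
    zinc_bound: bool

    @property
    def n_protons(self) -> int:
        return sum(self.protons)

    @property
    def proton_code(self) -> int:
        """Little-endian integer encoding of the proton bit-vector."""
        return sum(b << i for i, b in enumerate(self.protons))

    def index(self) -> int:
        """Position in the canonical state order (metal-free block first)."""
        return self.proton_code + (int(self.zinc_bound) << len(self.protons))

    @property
    def label(self) -> str:
        base = f"S{self.proton_code}"
        return base + (":Zn" if self.zinc_bound else "")

    def with_proton(self, bit_index: int) -> "Microstate":
        if self.protons[bit_index]:
            raise ModelError(f"residue bit {bit_index} already protonated")
        bits = list(self.protons)
        bits[bit_index] = 1
        return Microstate(tuple(bits), self.zinc_bound)


@dataclass(frozen=True)
class Condition:
    """External condition: pH and free metal concentration in molar."""

    pH: float
    zn_free: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pH):
            raise ModelError("pH must be finite")
        if self.zn_free < 0:
            raise ModelError("zn_free must be non-negative")


def enumerate_microstates(n_residues: int) -> list[Microstate]:
    """All 2**(n_residues+1) states in canonical order.

    Proton bit-vectors are enumerated as little-endian integers 0..2**R-1,
    first with the metal-free flag, then the metal-bound block in the same
    protonation order.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    states = []
    for bound in (False, True):
        for code in range(1 << n_residues):
            bits = tuple((code >> i) & 1 for i in range(n_residues))
            states.append(Microstate(bits, bound))
    return states


class SiteModel:
    """Node free energies over all (protonation x metal-bound) states of a site.

    ``g`` is an array of length 2**(R+1) in canonical state order, in k_B T,
    with g = 0 for the all-deprotonated metal-free state.
    """

    def __init__(
        self,
        residues: Sequence[TitratableResidue],
        g: np.ndarray,
        c0: float = 1.0,
    ) -> None:
        labels = [r.label for r in residues]
        if len(set(labels)) != len(labels):
            raise ModelError("residue labels must be unique")
        if sorted(r.bit_index for r in residues) != list(range(len(residues))):
            raise ModelError("bit_index values must be 0..R-1 without gaps")
        self.residues = sorted(residues, key=lambda r: r.bit_index)
        g = np.asarray(g, dtype=float)
        n_states = 1 << (len(residues) + 1)
        if g.shape != (n_states,):
            raise ModelError(f"g must have shape ({n_states},)")
        if not np.all(np.isfinite(g)):
            raise ModelError("all reference free energies must be finite")
        if g[0] != 0.0:
            raise ModelError("reference state free energy must be exactly 0")
        self.g = g
        self.c0 = float(c0)
        # cached structure arrays for vectorized evaluation
        R = len(residues)
        codes = np.arange(1 << R)
        nprot = np.array([bin(c).count("1") for c in codes])
        self.n_protons = np.concatenate([nprot, nprot])
        self.bound = np.concatenate(
            [np.zeros(1 << R, bool), np.ones(1 << R, bool)]
        )
        self._bits = np.stack(
            [(codes >> i) & 1 for i in range(R)], axis=1
        ) if R else np.zeros((1, 0), int)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_states(self) -> int:
        return self.g.size

    def states(self) -> list[Microstate]:
        return enumerate_microstates(self.n_residues)

    def residue(self, label: str) -> TitratableResidue:
        for r in self.residues:
            if r.label == label:
                return r
        raise KeyError(f"unknown residue {label!r}")

    def beta_G(self, cond: Condition) -> np.ndarray:
        """Reduced free energies of all states at a condition (+inf allowed)."""
        with np.errstate(divide="ignore"):
            ln_x = np.log(cond.zn_free / self.c0) if cond.zn_free > 0 else -np.inf
        G = self.g + self.n_protons * LN10 * cond.pH
        G = np.where(self.bound, G - ln_x, G)
        return G


def model_from_parameters(
    intrinsic_pkas: Mapping[str, float],
    pair_couplings: Mapping[tuple[str, str], float] | None = None,
    binding_g0: float | Mapping[int, float] | Callable[[int], float] = 0.0,
) -> SiteModel:
    """Build a SiteModel from intrinsic pKa's, pairwise couplings and binding
    free energies.

    The metal-free branch is
        g(s) = -ln10 * sum_{i in s} pKa_i + ln10 * sum_{i<j in s} W_ij
    and the bound branch adds ``binding_g0`` (scalar, mapping from protonation
    code, or callable of the protonation code) in k_B T. The microscopic pKa of
    residue i with all partners deprotonated equals its intrinsic pKa; a
    positive coupling W_ij lowers the pKa of i by W_ij when j is protonated
    (anti-cooperative).
    """
    labels = list(intrinsic_pkas)
    residues = [TitratableResidue(lab, i) for i, lab in enumerate(labels)]
    for v in intrinsic_pkas.values():
        if not math.isfinite(v):
            raise ModelError("intrinsic pKa values must be finite")
    W = np.zeros((len(labels), len(labels)))
    if pair_couplings:
        index = {lab: i for i, lab in enumerate(labels)}
        for (a, b), w in pair_couplings.items():
            if a not in index or b not in index:
                raise ModelError(f"coupling references unknown residue ({a}, {b})")
            if not math.isfinite(w):
                raise ModelError("couplings must be finite")
            W[index[a], index[b]] = w
            W[index[b], index[a]] = w
    pka = np.array([intrinsic_pkas[lab] for lab in labels])
    R = len(labels)
    M = 1 << R
    codes = np.arange(M)
    bits = np.stack([(codes >> i) & 1 for i in range(R)], axis=1) if R else np.zeros((1, 0), int)
    g_free = -LN10 * bits @ pka + 0.5 * LN10 * np.einsum("si,ij,sj->s", bits, W, bits)
    if callable(binding_g0):
        g0 = np.array([float(binding_g0(int(c))) for c in codes])
    elif isinstance(binding_g0, Mapping):
        try:
            g0 = np.array([float(binding_g0[int(c)]) for c in codes])
        except KeyError as exc:
            raise ModelError(f"missing binding parameter for state {exc}") from exc
    else:
        g0 = np.full(M, float(binding_g0))
    if not np.all(np.isfinite(g0)):
        raise ModelError("binding free energies must be finite")
    return SiteModel(residues, np.concatenate([g_free, g_free + g0]))


def free_energy(model: SiteModel, state: Microstate, cond: Condition) -> float:
    """Reduced free energy beta*G of one state at a condition.

    Returns +inf for a bound state at zero free metal (state excluded).
    """
    idx = state.proton_code + (int(state.zinc_bound) << model.n_residues)
    return float(model.beta_G(cond)[idx])


def _probabilities(G: np.ndarray) -> np.ndarray:
    finite = np.isfinite(G)
    if not finite.any():
        raise FloatingPointError("all states have infinite free energy")
    shift = G[finite].min()
    w = np.where(finite, np.exp(-(G - shift)), 0.0)
    return w / w.sum()


def state_probabilities(model: SiteModel, cond: Condition) -> np.ndarray:
    """Boltzmann probability of every state in canonical order.

    Evaluated with a max-shift (log-sum-exp) so that pKa's far from the pH do
    not overflow; probabilities sum to 1 to within 1e-12.
    """
    return _probabilities(model.beta_G(cond))


def bound_fraction(model: SiteModel, cond: Condition) -> float:
    """Equilibrium probability that the site carries a metal ion, <X>."""
    P = state_probabilities(model, cond)
    return float(P[model.bound].sum())


def deprotonation_fraction_model(
    model: SiteModel, residue: str, cond: Condition
) -> float:
    """Probability that a residue is deprotonated, summed over microstates."""
    r = model.residue(residue)
    P = state_probabilities(model, cond)
    code = np.concatenate([np.arange(1 << model.n_residues)] * 2)
    deprot = ((code >> r.bit_index) & 1) == 0
    return float(P[deprot].sum())


def apparent_kd(
    model: SiteModel,
    pH: float,
    bracket: tuple[float, float] = (1e-30, 1e3),
    rtol: float = 1e-10,
) -> float:
    """Free metal concentration at half-maximal occupancy at the given pH.

    Solved by bisection on log10 concentration; the site occupancy is monotone
    in the free metal concentration, so the root is unique.
    """
    from scipy.optimize import brentq

    lo, hi = math.log10(bracket[0]), math.log10(bracket[1])

    def f(logc: float) -> float:
        return bound_fraction(model, Condition(pH, 10.0 ** logc)) - 0.5

    if f(lo) > 0 or f(hi) < 0:
        raise ModelError(
            f"half-occupancy not bracketable in [{bracket[0]:g}, {bracket[1]:g}] M"
        )
    logk = brentq(f, lo, hi, xtol=1e-13, rtol=8.9e-16)
    kd = 10.0 ** logk
    return float(kd)


def microstate_pka(
    model: SiteModel, residue: str, context_state: Microstate
) -> float:
    """Microscopic pKa of a residue in a given protonation context.

    pKa = [g(context) - g(context + proton)] / ln10, with the bound flag of the
    context preserved. The residue must be deprotonated in the context.
    """
    r = model.residue(residue)
    if context_state.protons[r.bit_index]:
        raise ModelError(f"{residue} already protonated in context")
    shift = int(context_state.zinc_bound) << model.n_residues
    i = context_state.proton_code + shift
    j = context_state.with_proton(r.bit_index).proton_code + shift
    return float((model.g[i] - model.g[j]) / LN10)


@dataclass(frozen=True)
class ConsistencyEdge:
    """A measured free-energy difference between two adjacent states."""

    from_state: Microstate
    to_state: Microstate
    delta_g: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ModelError("sigma must be positive")
        a, b = self.from_state, self.to_state
        proton_flips = bin(a.proton_code ^ b.proton_code).count("1")
        bind_flip = a.zinc_bound != b.zinc_bound
        if proton_flips + bind_flip != 1:
            raise ModelError(
                "edge states must differ by exactly one proton or the bound flag"
            )


def solve_potentials(
    edges: Iterable[tuple[object, object, float, float]],
    reference: object,
) -> dict[object, float]:
    """Maximum-likelihood node potentials from noisy edge differences.

    Minimizes sum(((g_to - g_from - delta_g) / sigma)**2) over node potentials
    with the reference node fixed at 0, via weighted linear least squares.
    Raises if the edge graph does not connect every node to the reference.
    """
    edges = list(edges)
    graph = nx.Graph()
    graph.add_node(reference)
    for a, b, _, _ in edges:
        graph.add_edge(a, b)
    reachable = nx.node_connected_component(graph, reference)
    unreachable = set(graph.nodes) - reachable
    if unreachable:
        raise ModelError(f"states not connected to reference: {sorted(map(str, unreachable))}")
    nodes = [n for n in graph.nodes if n != reference]
    col = {n: k for k, n in enumerate(nodes)}
    A = np.zeros((len(edges), len(nodes)))
    y = np.zeros(len(edges))
    for row, (a, b, dg, sigma) in enumerate(edges):
        w = 1.0 / sigma
        if b != reference:
            A[row, col[b]] += w
        if a != reference:
            A[row, col[a]] -= w
        y[row] = dg * w
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    out = {reference: 0.0}
    out.update({n: float(v) for n, v in zip(nodes, sol)})
    return out


def fit_consistent_potentials(
    edges: Sequence[ConsistencyEdge], n_residues: int
) -> SiteModel:
    """Thermodynamically consistent SiteModel from noisy edge measurements."""
    states = enumerate_microstates(n_residues)
    ref = states[0]
    keyed = [
        (e.from_state, e.to_state, e.delta_g, e.sigma) for e in edges
    ]
    pot = solve_potentials(keyed, ref)
    g = np.zeros(len(states))
    for s in states:
        if s not in pot:
            raise ModelError(f"states not connected to reference: ['{s.label}']")
        g[s.proton_code + (int(s.zinc_bound) << n_residues)] = pot[s]
    residues = [TitratableResidue(f"R{i}", i) for i in range(n_residues)]
    return SiteModel(residues, g)


def state_label_table(model: SiteModel) -> list[dict]:
    """Index <-> S-label mapping emitted alongside every model file."""
    rows = []
    for s in model.states():
        rows.append(
            {
                "index": s.proton_code + (int(s.zinc_bound) << model.n_residues),
                "label": s.label,
                "protons": list(s.protons),
                "zinc_bound": s.zinc_bound,
            }
        )
    return rows


def model_to_json(model: SiteModel) -> str:
    obj = {
        "residues": [r.label for r in model.residues],
        "g": {str(i): float(v) for i, v in enumerate(model.g)},
        "c0": model.c0,
        "state_labels": state_label_table(model),
    }
    return json.dumps(obj, indent=1)


def model_from_json(text: str) -> SiteModel:
    obj = json.loads(text)
    labels = obj["residues"]
    residues = [TitratableResidue(lab, i) for i, lab in enumerate(labels)]
    n_states = 1 << (len(labels) + 1)
    g = np.array([obj["g"][str(i)] for i in range(n_states)])
    return SiteModel(residues, g, c0=obj.get("c0", 1.0))
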