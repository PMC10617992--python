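"""Monte-Carlo inference of microscopic pKa's and binding free energies.

Given a target observable -- metal bound fractions over a (pH, [Zn2+]) grid
from binding assays, or protonation microstate probabilities over a pH ladder
from constant-pH MD -- the inference walks a parameter vector (per-residue
intrinsic pKa's plus a standard binding free energy per protonation
microstate) with a Metropolis scheme that minimizes the RMSD between computed
and target observables.

Each proposal adds an independent Uniform(-h, h) draw (default half-width
h = 0.2, in pKa units for protonation parameters and k_BT for binding
parameters) to every parameter simultaneously; parameters in a tie group
share one draw and therefore remain equal forever. In finite-temperature
mode a proposal is accepted with probability min(1, exp(-dRMSD / r)) with a
small fictional temperature r (default 1e-4) and the walk stops once the
RMSD falls to the target cutoff. In zero-temperature mode only strictly
downhill moves are accepted, with a step budget (default 2000) and a stall
stop after 100 consecutive rejections; the zero-temperature runs are how the
per-target RMSD cutoffs are calibrated in the first place.

Replicate runs (default 50) use independent seed streams split from a master
seed; parameter estimates are reported as mean and standard deviation over
replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .statespace import LN10, SiteModel, model_from_parameters

__all__ = [
    "MCSettings",
    "TargetObservable",
    "ParameterVector",
    "ReplicateResult",
    "InferenceResult",
    "SiteModelBuilder",
    "initialize_parameters",
    "observable_rmsd",
    "mc_step",
    "run_inference",
    "run_replicates",
]


@dataclass(frozen=True)
class MCSettings:
    """Controls of the Monte-Carlo refinement."""

    rmsd_cutoff: float
    r: float = 1e-4
    step_half_width: float = 0.2
    max_steps: int = 2000          # zero-temperature step budget
    stall_window: int = 100        # consecutive rejections before stopping
    n_replicates: int = 50
    seed: int = 0
    mode: str = "finite"           # "finite" | "zero_temperature"
    hard_step_limit: int = 1_000_000  # finite-mode termination guarantee
    per_parameter_sweep: bool = False  # sensitivity variant: one param at a time

    def __post_init__(self) -> None:
        if self.mode not in ("finite", "zero_temperature"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "finite" and self.r <= 0:
            raise ValueError("fictional temperature r must be > 0 in finite mode")
        if self.rmsd_cutoff <= 0:
            raise ValueError("rmsd_cutoff must be > 0")


@dataclass(frozen=True)
class TargetObservable:
    """Target data the model is refined against.

    kind="bound_fraction": points are (pH, zn_free, value).
    kind="microstate_probability": points are (pH, state_label, value); the
    free metal concentration is pinned to ``zn_free_microstate`` (near-zero,
    emulating metal-free titration).
    """

    kind: str
    points: tuple
    zn_free_microstate: float = 1e-20

    def __post_init__(self) -> None:
        if self.kind not in ("bound_fraction", "microstate_probability"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if len(self.points) < 1:
            raise ValueError("target needs at least one point")
        for pt in self.points:
            if not (0.0 <= pt[-1] <= 1.0):
                raise ValueError("target values must lie in [0, 1]")

    def compile(self, n_residues: int) -> "_CompiledTarget":
        ph = np.array([p[0] for p in self.points])
        vals = np.array([p[-1] for p in self.points])
        if self.kind == "bound_fraction":
            zn = np.array([p[1] for p in self.points])
            rows = None
        else:
            zn = np.full(ph.size, self.zn_free_microstate)
            rows = np.array([int(str(p[1]).lstrip("S")) for p in self.points])
            if np.any(rows >= (1 << n_residues)):
                raise ValueError("state label outside the model's state space")
        return _CompiledTarget(self.kind, ph, np.log(zn), rows, vals)


@dataclass(frozen=True)
class _CompiledTarget:
    kind: str
    ph: np.ndarray
    ln_zn: np.ndarray
    state_rows: np.ndarray | None
    values: np.ndarray


@dataclass
class ParameterVector:
    """Named parameters addressing a SiteModel's degrees of freedom.

    ``kinds`` marks each entry "pka" or "g0"; ``tie_groups`` lists index
    groups constrained to share a value (and a proposal draw).
    """

    names: list[str]
    kinds: list[str]
    values: np.ndarray
    tie_groups: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        for grp in self.tie_groups:
            v = self.values[list(grp)]
            if not np.allclose(v, v[0], atol=0.0, rtol=0.0):
                raise ValueError(f"tie group {grp} members differ")

    def copy(self) -> "ParameterVector":
        return ParameterVector(list(self.names), list(self.kinds),
                               self.values.copy(), self.tie_groups)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def draw_indices(self) -> list[list[int]]:
        """Index groups that receive one shared proposal draw each."""
        tied = {i for grp in self.tie_groups for i in grp}
        groups = [list(grp) for grp in self.tie_groups]
        groups.extend([[i] for i in range(self.values.size) if i not in tied])
        return groups


class SiteModelBuilder:
    """Maps a ParameterVector to a SiteModel with an additive free branch.

    Parameters are the R intrinsic pKa's (names = residue labels) followed by
    one standard binding free energy per protonation microstate
    (names ``g0:Sk``). Evaluation is vectorized for the MC loop.
    """

    def __init__(self, residue_labels: Sequence[str]) -> None:
        self.residue_labels = list(residue_labels)
        R = len(self.residue_labels)
        self.n_residues = R
        M = 1 << R
        codes = np.arange(M)
        self.bits = (
            np.stack([(codes >> i) & 1 for i in range(R)], axis=1)
            if R else np.zeros((1, 0), int)
        )
        nprot = self.bits.sum(axis=1)
        self.n_protons = np.concatenate([nprot, nprot]).astype(float)
        self.bound = np.concatenate([np.zeros(M, bool), np.ones(M, bool)])

    @property
    def n_parameters(self) -> int:
        return self.n_residues + (1 << self.n_residues)

    def g_array(self, values: np.ndarray) -> np.ndarray:
        R = self.n_residues
        pka = values[:R]
        g0 = values[R:]
        g_free = -LN10 * self.bits @ pka
        return np.concatenate([g_free, g_free + g0])

    def build(self, params: ParameterVector) -> SiteModel:
        R = self.n_residues
        pkas = dict(zip(self.residue_labels, params.values[:R]))
        g0 = {k: float(v) for k, v in enumerate(params.values[R:])}
        return model_from_parameters(pkas, None, g0)

    def rmsd(self, values: np.ndarray, target: _CompiledTarget) -> float:
        G = self.g_array(values)[:, None] + self.n_protons[:, None] * LN10 * target.ph
        G = np.where(self.bound[:, None], G - target.ln_zn, G)
        G -= G.min(axis=0)
        w = np.exp(-G)
        Z = w.sum(axis=0)
        if target.kind == "bound_fraction":
            computed = w[self.bound].sum(axis=0) / Z
        else:
            # probability of the labelled metal-free protonation microstate
            computed = w[target.state_rows, np.arange(target.ph.size)] / Z
        return float(np.sqrt(np.mean((computed - target.values) ** 2)))


def target_from_curves(curves, f_unbound: float, f_bound: float) -> TargetObservable:
    """Bound-fraction target from MST curves.

    Responses are mapped back to bound fractions through the response scale
    (F_u, F_b) and clipped to [0, 1]; replicate points are kept individually.
    """
    points = []
    for c in curves:
        frac = (np.asarray(c.response) - f_unbound) / (f_bound - f_unbound)
        frac = np.clip(frac, 0.0, 1.0)
        points.extend((float(c.pH), float(z), float(v))
                      for z, v in zip(c.zn_free, frac))
    return TargetObservable(kind="bound_fraction", points=tuple(points))


def initialize_parameters(
    cphmd_pkas: Mapping[str, float],
    mst_kd: float,
    tie_labels: Sequence[Sequence[str]] = (),
) -> tuple[ParameterVector, SiteModelBuilder]:
    """Starting parameters: CpHMD pKa's, binding energies from a measured K_d.

    Every per-state binding free energy starts at ln(K_d / c0) in k_BT (an
    additive model with no protonation-binding coupling). ``tie_labels``
    lists residue groups constrained to share a pKa (e.g. the two symmetric
    histidines of site B); tied residues are initialized at their common mean.
    """
    if mst_kd <= 0:
        raise ValueError("mst_kd must be positive")
    labels = list(cphmd_pkas)
    builder = SiteModelBuilder(labels)
    g0 = math.log(mst_kd / 1.0)
    values = np.array([float(cphmd_pkas[lab]) for lab in labels]
                      + [g0] * (1 << len(labels)))
    names = labels + [f"g0:S{k}" for k in range(1 << len(labels))]
    kinds = ["pka"] * len(labels) + ["g0"] * (1 << len(labels))
    groups = []
    for grp in tie_labels:
        idx = tuple(labels.index(lab) for lab in grp)
        values[list(idx)] = values[list(idx)].mean()
        groups.append(idx)
    return (
        ParameterVector(names, kinds, values, tuple(groups)),
        builder,
    )


def observable_rmsd(model: SiteModel, target: TargetObservable) -> float:
    """RMSD between model-computed and target observable values."""
    compiled = target.compile(model.n_residues)
    # evaluate on the raw g array: no additive assumption required
    G = model.g[:, None] + model.n_protons[:, None] * LN10 * compiled.ph
    G = np.where(model.bound[:, None], G - compiled.ln_zn, G)
    G -= G.min(axis=0)
    w = np.exp(-G)
    Z = w.sum(axis=0)
    if compiled.kind == "bound_fraction":
        computed = w[model.bound].sum(axis=0) / Z
    else:
        computed = w[compiled.state_rows, np.arange(compiled.ph.size)] / Z
    return float(np.sqrt(np.mean((computed - compiled.values) ** 2)))


def mc_step(
    params: ParameterVector,
    builder: SiteModelBuilder,
    target: TargetObservable | _CompiledTarget,
    settings: MCSettings,
    rng: np.random.Generator,
    current_rmsd: float | None = None,
) -> tuple[ParameterVector, bool, float]:
    """One Metropolis step; returns (new params, accepted, new current RMSD)."""
    compiled = (
        target if isinstance(target, _CompiledTarget)
        else target.compile(builder.n_residues)
    )
    if current_rmsd is None:
        current_rmsd = builder.rmsd(params.values, compiled)
    groups = params.draw_indices()
    proposal = params.values.copy()
    h = settings.step_half_width
    for grp in groups:
        proposal[grp] += rng.uniform(-h, h)
    new_rmsd = builder.rmsd(proposal, compiled)
    delta = new_rmsd - current_rmsd
    if settings.mode == "zero_temperature":
        accept = delta < 0
    else:
        accept = delta < 0 or rng.random() < math.exp(-delta / settings.r)
    if accept:
        out = params.copy()
        out.values = proposal
        return out, True, new_rmsd
    return params, False, current_rmsd


@dataclass
class ReplicateResult:
    params: ParameterVector
    final_rmsd: float
    n_steps: int
    n_accepted: int
    converged: bool
    rmsd_trace: np.ndarray = field(repr=False, default=None)


@dataclass
class InferenceResult:
    replicates: list[ReplicateResult]
    mean: dict[str, float]
    sd: dict[str, float | None]

    @property
    def n_converged(self) -> int:
        return sum(r.converged for r in self.replicates)


def run_inference(
    initial: ParameterVector,
    builder: SiteModelBuilder,
    target: TargetObservable,
    settings: MCSettings,
    rng: np.random.Generator | None = None,
) -> ReplicateResult:
    """One replicate of the MC refinement (see module docstring)."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    compiled = target.compile(builder.n_residues)
    values = initial.values.copy()
    groups = initial.draw_indices()
    h = settings.step_half_width
    rmsd = builder.rmsd(values, compiled)
    trace = [rmsd]
    n_acc = 0
    steps = 0
    consecutive_rej = 0
    zero_t = settings.mode == "zero_temperature"
    limit = settings.max_steps if zero_t else settings.hard_step_limit
    # zero-temperature runs minimize to a stall: they are how cutoffs get
    # calibrated, so the cutoff does not stop them early
    converged = (not zero_t) and rmsd <= settings.rmsd_cutoff
    while not converged and steps < limit:
        if settings.per_parameter_sweep:
            grp = groups[steps % len(groups)]
            proposal = values.copy()
            proposal[grp] += rng.uniform(-h, h)
        else:
            proposal = values.copy()
            for grp in groups:
                proposal[grp] += rng.uniform(-h, h)
        new_rmsd = builder.rmsd(proposal, compiled)
        delta = new_rmsd - rmsd
        if zero_t:
            accept = delta < 0
        else:
            accept = delta < 0 or rng.random() < math.exp(-delta / settings.r)
        steps += 1
        if accept:
            values = proposal
            rmsd = new_rmsd
            n_acc += 1
            consecutive_rej = 0
        else:
            consecutive_rej += 1
        trace.append(rmsd)
        if zero_t:
            if consecutive_rej >= settings.stall_window:
                break
        elif rmsd <= settings.rmsd_cutoff:
            converged = True
    final = initial.copy()
    final.values = values
    return ReplicateResult(
        params=final,
        final_rmsd=rmsd,
        n_steps=steps,
        n_accepted=n_acc,
        converged=rmsd <= settings.rmsd_cutoff,
        rmsd_trace=np.asarray(trace),
    )


def run_replicates(
    initial: ParameterVector,
    builder: SiteModelBuilder,
    target: TargetObservable,
    settings: MCSettings,
) -> InferenceResult:
    """Independent MC replicates with split seed streams; aggregates mean/SD."""
    if settings.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    streams = np.random.SeedSequence(settings.seed).spawn(settings.n_replicates)
    reps = []
    for ss in streams:
        reps.append(
            run_inference(initial, builder, target, settings,
                          rng=np.random.default_rng(ss))
        )
    mat = np.stack([r.params.values for r in reps])
    mean = dict(zip(initial.names, map(float, mat.mean(axis=0))))
    if len(reps) > 1:
        sd = dict(zip(initial.names, map(float, mat.std(axis=0, ddof=1))))
    else:
        sd = {name: None for name in initial.names}
    return InferenceResult(replicates=reps, mean=mean, sd=sd)
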