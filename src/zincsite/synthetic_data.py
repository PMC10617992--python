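"""Synthetic MST titrations and constant-pH-MD-like lambda series.

Generators draw from ground-truth SiteModels so that every pipeline stage
(curve fitting, titration analysis, Monte-Carlo inference) can be exercised
and validated against known parameters without any external data.

The MST design emulates the experimental layout: triplicate titrations at
pH 5.6, 6.0, 6.5, 7.0 and 7.4, a 16-point two-fold serial dilution of free
Zn2+, protein at tens of nanomolar, Gaussian response noise, and optional
chelator buffering (NTA, K_d = 14 nM, or citrate, K_d = 12 uM) that converts
the free concentrations into the total Zn2+ one would actually pipette.

The lambda design emulates pH-replica-exchange titration output: a 30-value
pH ladder from 1.5 to 11.5, per-frame microstate dynamics modelled as a
Markov chain whose stationary distribution is the truth model's metal-free
Boltzmann distribution, and lambda emission from bands well inside the
0.2/0.8 classification thresholds, with a configurable fraction of
intermediate (excluded) frames. Two protomer copies are generated
independently. The Markov switching is a stand-in for simulation dynamics:
autocorrelation is a nuisance parameter here, not a fidelity claim.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import mstfit
from .cphmd import LambdaSeries, lambda_to_frame
from .mstfit import MSTCurve, total_for_free
from .statespace import (
    Condition,
    SiteModel,
    bound_fraction,
    model_from_parameters,
    model_to_json,
    state_probabilities,
)

__all__ = [
    "MSTDesign",
    "LambdaDesign",
    "PH_LADDER_30",
    "generate_mst_dataset",
    "generate_lambda_series",
    "write_fixtures",
    "site_a_truth",
    "site_b_truth",
]

#: the 30-replica pH ladder used for titration simulations
PH_LADDER_30 = (
    1.5, 1.75, 2.0, 2.5, 2.75, 3.0, 3.25, 3.5, 3.75, 4.0,
    4.25, 4.5, 4.75, 5.0, 5.25, 5.5, 6.0, 6.5, 7.0, 7.5,
    8.0, 8.5, 8.75, 9.0, 9.5, 10.0, 10.25, 10.5, 11.0, 11.5,
)

#: CpHMD-derived intrinsic pKa's for the transport-site (site A) residues
SITE_A_PKAS = {"D47": 3.84, "D51": 2.92, "H155": 7.97, "D159": 4.87}
#: and for the site B residues
SITE_B_PKAS = {"D70": 2.06, "H73": 8.08, "H77": 8.12}


@dataclass(frozen=True)
class MSTDesign:
    """Design of a synthetic MST titration experiment."""

    ph_values: tuple[float, ...] = (5.6, 6.0, 6.5, 7.0, 7.4)
    n_concentrations: int = 16
    top_concentration: float = 1e-4  # molar free Zn2+, two-fold dilutions below
    dilution_factor: float = 2.0
    protein_conc: float = 5e-8  # molar, within the assay's 8-100 nM range
    noise_sd: float = 0.02
    n_replicates: int = 3
    f_unbound: float = 0.0
    f_bound: float = 1.0
    chelator: str = "none"  # none | NTA | citrate
    chelator_total: float = 2e-4
    seed: int = 0

    def concentrations(self) -> np.ndarray:
        return self.top_concentration / self.dilution_factor ** np.arange(
            self.n_concentrations
        )


@dataclass(frozen=True)
class LambdaDesign:
    """Design of a synthetic lambda time-series set."""

    ph_ladder: tuple[float, ...] = PH_LADDER_30
    n_frames: int = 6000
    switch_prob: float = 0.1
    intermediate_fraction: float = 0.0
    band_protonated: tuple[float, float] = (0.0, 0.15)
    band_deprotonated: tuple[float, float] = (0.85, 1.0)
    protomers: tuple[str, ...] = ("A", "B")
    seed: int = 0


def site_a_truth(binding_kd_ph7: float = 16e-9) -> SiteModel:
    """Site-A-like truth: CpHMD pKa's, Zn2+ binds the fully deprotonated state.

    The standard binding free energy is chosen so that the apparent K_d at
    pH 7 equals ``binding_kd_ph7`` (16 nM by default). Protonated states
    carry a steep binding penalty, so metal binding competes with protons.
    """
    pkas = SITE_A_PKAS
    # metal-free partition function at pH 7 for the additive model
    zf = float(np.prod([1.0 + 10.0 ** (p - 7.0) for p in pkas.values()]))
    g0_bare = float(np.log(binding_kd_ph7 / zf))
    penalty = 15.0  # k_BT per proton retained in the bound state

    def g0(code: int) -> float:
        return g0_bare + penalty * bin(code).count("1")

    return model_from_parameters(pkas, None, g0)


def site_b_truth(binding_kd_ph7: float = 1.18e-6) -> SiteModel:
    """Site-B-like 3-residue truth with the same construction as site A."""
    pkas = SITE_B_PKAS
    zf = float(np.prod([1.0 + 10.0 ** (p - 7.0) for p in pkas.values()]))
    g0_bare = float(np.log(binding_kd_ph7 / zf))
    penalty = 15.0

    def g0(code: int) -> float:
        return g0_bare + penalty * bin(code).count("1")

    return model_from_parameters(pkas, None, g0)


def generate_mst_dataset(
    truth: SiteModel, design: MSTDesign, site_label: str = "siteA"
) -> tuple[list[MSTCurve], dict]:
    """Simulate MST titration curves from a truth model.

    Per pH and free concentration the truth bound fraction is mapped onto the
    response scale [F_u, F_b] and Gaussian noise of SD ``noise_sd`` is added
    independently per replicate. With a chelator selected, the total metal
    required to buffer each free concentration is recorded alongside.
    """
    rng = np.random.default_rng(design.seed)
    concs = design.concentrations()
    curves = []
    record = {
        "site": site_label,
        "design": {
            "ph_values": list(design.ph_values),
            "concentrations_M": [float(c) for c in concs],
            "protein_conc_M": design.protein_conc,
            "noise_sd": design.noise_sd,
            "n_replicates": design.n_replicates,
            "f_unbound": design.f_unbound,
            "f_bound": design.f_bound,
            "chelator": design.chelator,
            "seed": design.seed,
        },
        "truth_model": json.loads(model_to_json(truth)),
        "per_ph": [],
    }
    for ph in design.ph_values:
        frac = np.array(
            [bound_fraction(truth, Condition(ph, c)) for c in concs]
        )
        clean = design.f_unbound + (design.f_bound - design.f_unbound) * frac
        zn, resp, rep = [], [], []
        for r in range(design.n_replicates):
            noise = (
                rng.normal(0.0, design.noise_sd, clean.size)
                if design.noise_sd > 0 else 0.0
            )
            zn.extend(concs)
            resp.extend(clean + noise)
            rep.extend([r] * concs.size)
        per_ph = {"ph": ph, "bound_fraction_truth": frac.tolist()}
        if design.chelator != "none":
            kd = mstfit.CHELATOR_KD[design.chelator]
            per_ph["total_zn_M"] = [
                total_for_free(c, design.chelator_total, kd) for c in concs
            ]
        record["per_ph"].append(per_ph)
        curves.append(
            MSTCurve(
                site_label=site_label,
                pH=ph,
                zn_free=np.array(zn),
                response=np.array(resp),
                replicate=np.array(rep),
                protein_conc=design.protein_conc,
            )
        )
    return curves, record


def _markov_states(
    probs: np.ndarray, n_frames: int, switch_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov chain over microstates: fresh stationary draw with switch_prob."""
    draws = rng.choice(probs.size, size=n_frames, p=probs)
    if switch_prob >= 1.0:
        return draws
    keep = rng.random(n_frames) < switch_prob
    keep[0] = True
    idx = np.where(keep, np.arange(n_frames), 0)
    idx = np.maximum.accumulate(idx)
    return draws[idx]


def generate_lambda_series(
    truth: SiteModel, design: LambdaDesign
) -> list[LambdaSeries]:
    """Simulate per-residue lambda series over the pH ladder.

    Per replica pH the metal-free protonation microstates evolve as a Markov
    chain with the truth Boltzmann distribution as stationary law; residue
    lambdas are emitted uniformly from the protonated or deprotonated band,
    and a fraction of frames is replaced with intermediate values in
    (0.2, 0.8) that the classifier must exclude.
    """
    rng = np.random.default_rng(design.seed)
    R = truth.n_residues
    M = 1 << R
    out = []
    for protomer in design.protomers:
        for ph in design.ph_ladder:
            p_all = state_probabilities(truth, Condition(ph, 1e-20))
            p_free = p_all[:M]
            p_free = p_free / p_free.sum()
            states = _markov_states(p_free, design.n_frames, design.switch_prob, rng)
            for res in truth.residues:
                protonated = (states >> res.bit_index) & 1
                lo_p, hi_p = design.band_protonated
                lo_d, hi_d = design.band_deprotonated
                lam = np.where(
                    protonated == 1,
                    rng.uniform(lo_p, hi_p, design.n_frames),
                    rng.uniform(lo_d, hi_d, design.n_frames),
                )
                if design.intermediate_fraction > 0:
                    mask = rng.random(design.n_frames) < design.intermediate_fraction
                    lam[mask] = rng.uniform(
                        np.nextafter(0.2, 1.0), 0.8, int(mask.sum())
                    )
                out.append(
                    LambdaSeries(
                        residue_label=res.label,
                        protomer=protomer,
                        ph=float(ph),
                        frames=lam,
                    )
                )
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    output_dir, seed: int = 0, n_frames: int = 400
) -> dict:
    """Write a canonical small fixture set and return its manifest.

    Emits site-A-like (4 residues) and site-B-like (3 residues) truth models,
    MST titration CSVs and lambda CSVs in the dialects the fitting modules
    consume, plus a manifest of seeds and SHA-256 checksums. ``n_frames`` is
    kept small by default so the fixtures stay plain-text friendly.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": seed, "files": {}}

    truths = {"siteA": site_a_truth(), "siteB": site_b_truth()}
    for name, truth in truths.items():
        model_path = outdir / f"{name}_truth.json"
        model_path.write_text(model_to_json(truth))

        mst_design = MSTDesign(seed=seed)
        curves, record = generate_mst_dataset(truth, mst_design, site_label=name)
        mst_path = outdir / f"{name}_mst.csv"
        mstfit.curves_to_frame(curves).to_csv(mst_path, index=False)
        (outdir / f"{name}_mst_truth_record.json").write_text(
            json.dumps(record["design"], indent=1)
        )

        lam_design = LambdaDesign(
            ph_ladder=tuple(PH_LADDER_30[::3]), n_frames=n_frames, seed=seed + 1
        )
        series = generate_lambda_series(truth, lam_design)
        lam_path = outdir / f"{name}_lambda.csv"
        lambda_to_frame(series).to_csv(
            lam_path, index=False, float_format="%.4f"
        )
    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][path.name] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
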