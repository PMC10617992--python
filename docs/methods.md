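# Methods

## The microscopic binding-site model

A binding site with R titratable residues is modelled as a set of
2^(R+1) microstates: every assignment of protonated/deprotonated to the R
residues, with and without a Zn²⁺ ion bound. Each state carries a reference
free energy g in units of k_BT — the part that does not depend on pH or
metal concentration — with the all-deprotonated, metal-free state fixed at
g = 0 (only free-energy differences are observable, so the reference is a
gauge choice; all computed observables are independent of it). The full
reduced free energy at a condition is

    βG(s, b) = g(s, b) + n_H(s)·ln10·pH − b·ln([Zn²⁺]/c⁰)

with c⁰ = 1 M. This construction makes thermodynamic consistency
*structural*: free energies are node potentials on the state graph, so
every cycle closes exactly and microscopic pK_a's (edge differences
divided by ln 10) are path independent by construction. This is the reason
the package stores node potentials rather than edge parameters; a
constructor taking intrinsic pK_a's, pairwise couplings W_ij (in pK_a
units; positive = anti-cooperative) and per-state binding free energies is
the default generative parameterization, and arbitrary higher-order
coupling can be expressed by supplying the per-state table directly.

All stored energies are β-reduced (k_BT). Temperature appears explicitly
only in the transport module, where free energies are needed in J/mol.

Numerical choices: partition functions are evaluated with a max-shift
(log-sum-exp), so pK_a's far from the working pH cannot overflow. A bound
state at zero free metal has weight exactly 0 (+∞ free energy). The
apparent K_d — the free concentration at half occupancy — is found by
Brent root search on log₁₀ concentration inside [10⁻³⁰, 10³] M, a bracket
wide enough for any physically meaningful affinity; occupancy is strictly
monotone in the free concentration, so the root is unique.

The consistency solver performs weighted linear least squares
(minimizing Σ((g_to − g_from − Δg)/σ)²) over node potentials with the
reference node eliminated; edges must connect every state to the
reference, and unreachable states are named in the error. Edge inputs must
join states differing by exactly one proton or the bound flag.

Out of scope by design: conformational states (inward/outward-facing,
occluded), cooperativity across the two protomers of the dimer, and the
binuclear C-terminal site. Sites are treated as independent.

## MST binding curves

The law-of-mass-action fit uses the depletion-aware quadratic form with
the protein concentration C_P as a known constant and (K_d, F_u, F_b) as
free parameters; the raw response scale is absorbed into F_u/F_b rather
than pre-normalized. K_d is fitted on a log scale with a multi-start grid
covering the data's concentration range ±2 decades, which avoids local
minima at extreme Hill coefficients. Confidence intervals (68% and 95%)
are case-resampling bootstrap percentile intervals, 1000 draws by default,
seeded; resample refits start from the full-data optimum. A fitted K_d
below C_P is flagged as the "titration regime", where the curve no longer
determines K_d well. Replicate titrations are pooled and fitted jointly.
Plain (unweighted) least squares is used throughout.

Chelator buffering solves the 1:1 complexation equilibrium M + L ⇌ ML
as the positive root of a quadratic in the free metal; the inverse
(total needed for a target free concentration) is closed form. NTA
(K_d = 14 nM) and citrate (K_d = 12 μM) are built in.

## Titration-coordinate analysis

λ frames classify with strict inequalities — deprotonated above 0.8,
protonated below 0.2 — and values exactly at a threshold are excluded, as
is the intermediate band. Per-residue deprotonation fractions use
per-residue exclusion only; microstate histograms drop a frame if *any*
site residue is intermediate, the conservative reading for a joint state
assignment (the alternative, rounding intermediate residues to the nearest
state, would manufacture state counts from undecided frames). The two
protomers of the homodimer are analyzed independently for pK_a's — the
error bar is the average absolute deviation of the per-protomer values
from their mean — and concatenated for microstate histograms, which doubles
the sampling.

The λ tables use a tidy CSV dialect (ph, protomer, residue, frame,
lambda), one file per site, keeping the module independent of any
particular simulation package's output layout; converters from specific
tools are an extension point.

## Monte-Carlo refinement

The parameter vector holds one intrinsic pK_a per residue (additive free
branch) plus one standard binding free energy per protonation microstate —
the node-potential degrees of freedom of the model. Proposals add
independent Uniform(−0.2, 0.2) draws (pK_a units / k_BT) to *all*
parameters simultaneously; members of a tie group (e.g. a symmetric
histidine pair) share one draw and therefore remain exactly equal forever.
Acceptance follows min(1, e^(−ΔRMSD/r)) with fictional temperature
r = 10⁻⁴, on the order of typical per-step RMSD changes. Finite-temperature
production runs stop when the RMSD reaches the per-target cutoff (site A
bound fraction: 0.0760; site B: 0.0995; microstate-distribution targets:
0.0382/0.0447), with a hard step limit to guarantee termination on
misspecified targets (unconvergence is flagged, not raised).
Zero-temperature runs accept only strictly downhill moves and stop at a
step budget (2000) or after 100 consecutive rejections; they run to their
floor — the cutoff does not stop them — because their achieved minimum is
what calibrates the cutoff in the first place. Replicates (50 by default)
use independent streams spawned from the master seed and report
per-parameter means and standard deviations; the full replicate set is
bitwise reproducible under the master seed.

A known and deliberate limitation: binding isotherms, even across several
pH values, determine the model only through the apparent K_d at each
measured pH. With the per-state binding energies free, the bound-branch
energies can absorb any free-branch change, so individual pK_a's lie in
flat directions of the RMSD and drift during refinement (an unbiased
random walk of roughly 0.12·√(accepted steps) pK_a units). Refined models
therefore reproduce apparent K_d's tightly — replicate spread well within
2-fold in the packaged experiments — while individual effective pK_a's
spread by ±1 or more. The inference is a *refinement guided by* the
simulation-derived starting values, not an independent determination of
the microscopic model; `analysis/04_mst_inference.py` prints both spreads
so the contrast is visible.

## Macroscopic summaries

The coupling energy W between residues i and j is evaluated both as
pK_a(i | j deprotonated) − pK_a(i | j protonated) and with the roles
swapped; the absolute difference (path check) must vanish for consistent
models and is reported. Effective pK_a's come from fitting the model's
metal-free deprotonation curve (pH 0–14, step 0.05, [Zn²⁺] = 10⁻²⁰ M as
the metal-free stand-in) with the Hill–Langmuir form; a residual RMS above
0.02 flags the residue as coupled, in which case the expected proton count
of the pair, N(pH) = 2 − (S_i + S_j), is fitted with the two-proton
coupled titration model

    N(pH) = [10^(pK1−pH) + 2·10^(pK1+pK2−2pH)] / [1 + 10^(pK1−pH) + 10^(pK1+pK2−2pH)].

This numerator is the binding-polynomial-consistent form: it is the unique
choice for which two independent, equal sites give the statistical-factor
split pK1 − pK2 = 2·log₁₀2 ≈ 0.602. A variant with pK2 in the
single-proton numerator term circulates in the literature and is available
behind `strict_printed_form=True`, but it is inconsistent with the
denominator and is not the default. Labels are normalized to pK1 ≥ pK2
(the first proton binds with the higher effective affinity). The 0.02
flag threshold is a package choice: well below visible curve distortion,
well above fit noise on a 281-point grid.

## Transport energetics

For a cycle moving n Zn²⁺ out and m H⁺ in, the net exported charge is
z = 2n − m. With V_m ≡ ψ_in − ψ_out (physiological values negative), the
electrical term of the cycle free energy is −zFV_m, so exporting positive
charge against an inside-negative potential is penalized. Setting ΔG = 0
gives log₁₀([Zn]ₒ/[Zn]ᵢ) = (m·ΔpH + zFV_m/(RT·ln10))/n with
ΔpH = pH_in − pH_out. The default temperature is 298.15 K and temperature
is an explicit argument everywhere. Constants: R = 8.314462618 J/(mol·K),
F = 96485.332 C/mol. No kinetics are modelled; these are equilibrium
statements only.

## Synthetic data: what it does and does not emulate

The MST generator reproduces the experimental design — pH 5.6, 6.0, 6.5,
7.0, 7.4; a 16-point two-fold dilution from 10⁻⁴ M free Zn²⁺; protein at
50 nM (within the assay's 8–100 nM range); three replicates with Gaussian
response noise (SD 0.02); optional NTA/citrate buffering recording the
total metal to pipette. Responses are the truth model's bound fraction at
the *free* concentration mapped onto [F_u, F_b]: ideal chelator buffering,
no protein depletion of the free pool and no thermophoresis physics.
Fits of such data with the depletion-aware formula therefore use its
binding-regime limit (vanishing C_P) when exact round-trip recovery is the
point. The site-A-like truth uses the titration-simulation pK_a's
(D47 3.84, D51 2.92, H155 7.97, D159 4.87) with Zn²⁺ binding only the
fully deprotonated state (a 15 k_BT per-proton penalty — effectively
strict competition, consistent with metal coordination requiring
deprotonated ligands) and the standard binding free energy chosen so the
apparent K_d at pH 7 is 16 nM; the site-B-like truth mirrors this with
(D70 2.06, H73 8.08, H77 8.12) and 1.18 μM.

The λ generator draws, per replica pH of the 30-value ladder
(1.5–11.5), a Markov chain over the metal-free protonation microstates
whose stationary law is the truth Boltzmann distribution; each frame
switches to a fresh stationary draw with probability 0.1, otherwise
repeats. The switching probability is a nuisance parameter standing in for
simulation autocorrelation — no claim of dynamical fidelity is made, and
passing tests say nothing about replica-exchange mixing in real
simulations. λ values are emitted uniformly from bands strictly inside the
classification thresholds ([0, 0.15] protonated, [0.85, 1] deprotonated),
with an optional fraction of frames replaced by intermediate values in
(0.2, 0.8) that the classifier must exclude. Protomer copies are
independent. Everything is deterministic under the design seed.

## Problem sizes used in the packaged experiments

The shipped analyses and tests run at the scale of the study design they
emulate: 5 pH × 16 concentrations × 3 replicates for titrations, the
30-value pH ladder with 6000 frames per replica for titration-coordinate
recovery, 50 Monte-Carlo replicates for inference, and 100 random models
(up to 5 residues) for the Boltzmann-oracle cross-checks. The fixture
writer emits 400-frame λ files so that on-disk artifacts stay small;
full-length series are generated in memory where needed.
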