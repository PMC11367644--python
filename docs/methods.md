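# Methods

This note records the models implemented in `clawkit`, the assumptions and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the known limitations.

## Single-site ITC isotherm

A titration injects titrant X (peptide, syringe concentration `X_s` mM)
into a cell of volume `V0` μl containing macromolecule M (claw domain,
`M_0` mM). After cumulative injected volume `ΔV`, the overfill-cell
(perfusion) concentration corrections are the standard instrument forms

    M_t = M_0 (1 − ΔV/2V0) / (1 + ΔV/2V0)
    X_t = X_s (ΔV/V0) (1 − ΔV/2V0)

The bound concentration follows the mass-action quadratic with the root in
[0, 1] fractional saturation:

    [MX] = ½ [ (n·M_t + X_t + K_d) − sqrt((n·M_t + X_t + K_d)² − 4 n M_t X_t) ]

and the differential heat of injection i, with displaced-volume
compensation, is

    ΔQ_i = Q_i − Q_{i−1} + (dV_i / V0)(Q_i + Q_{i−1})/2,   Q_i = ΔH·V0·[MX]_i

Units compose so that mM·μl·kcal/mol = μcal, the natural heat unit.

**Fitting.** Weighted least squares over (ln K_d, ln N, ΔH) — the log
parameterisation enforces positivity and conditions the problem uniformly
across c-values (c = n·M_0/K_d). The priming injection (1 μl) is
down-weighted to zero by default, the universal ITC practice for the
diffusion-corrupted first peak; this is configurable. A deterministic
multi-start ladder (K_d ∈ {0.1, 1, 10, 100, 1000} μM × N ∈ {0.5, 1, 2},
ΔH seeded from total heat / total titrant) guards against local minima;
the best converged residual wins. Standard errors come from the
Gauss-Newton covariance s²(JᵀJ)⁻¹ at the optimum, delta-transformed back
from the log scale.

**No-binding rule.** Reported "no detectable binding" outcomes need a
criterion: the fitter compares the 3-parameter isotherm against a
constant-offset model with an F-test (2 extra parameters) and declares
no binding when the isotherm fails to improve at level α = 0.01 (default,
configurable), or when the signal is numerically zero.

**Defaults.** Cell 0.25 mM / syringe 4 mM, 20 °C (293.15 K), 1 μl + 19×2 μl
schedule — the protocol of the titrations being modelled. The working cell
volume, 200 μl, is a PEAQ-class instrument value; it is not stated with the
protocol and only sets the overall heat scale, not the fitted parameters'
recoverability. R = 1.98720425864083e-3 kcal mol⁻¹ K⁻¹ lives in
`constants.py` alongside kB = 0.0083144626 kJ mol⁻¹ K⁻¹; ΔG = RT ln K_d
(K_d in molar), −TΔS = ΔG − ΔH.

## Three-state competition model

A claw domain exchanges between free (0), reporter-bound (1), and
competitor-bound (2) states with association rates u1, u2 (diffusion
controlled, hence proportional to peptide concentrations) and dissociation
rates w1, w2 (transition-state theory: set by the activation barrier of the
unbinding free-energy profile). Two algebraic variants of the stationary
reporter occupancy are shipped:

* `detailed_balance` (default): P1 = u1·w2 / (w1·w2 + u1·w2 + u2·w1), the
  stationary distribution of the explicit 3-state rate matrix (tested
  against a null-space computation on 1000 random rate sets). This form
  depends on the competitor's dissociation rate and reduces to the
  displacement law y = 1/(1 + a0·c) used everywhere downstream.
* `printed`: P1 = u1·w2 / (w1·w2 + u1·w2 + u2·w2). In this form w2 cancels
  algebraically (P1 = u1/(w1+u1+u2)) so the competitor off-rate drops out —
  inconsistent with a model whose whole point is that phosphorylation
  changes that off-rate's barrier. The implementation asserts the
  cancellation; the variant is retained for fidelity and comparison.

**Sign convention for ΔE.** The phosphopeptide law multiplies a0 by a
Boltzmann factor. Under the default `enhancing` convention the factor is
exp(+|ΔE|/kB·T), so a positive reported barrier difference strengthens
competition (y2 ≤ y1) — the physically meaningful reading given that
phosphorylation tightens binding. The literal `printed` convention,
exp(−ΔE/kB·T), is also implemented; every output records which convention
produced it. Whether ΔE means barrier(unmodified) − barrier(phospho) or the
reverse cannot be fixed from the displacement data alone, which is exactly
why both conventions are first-class. `delta_barrier` likewise echoes its
operand order (barrier(b) − barrier(a)) in metadata so the two modules
compose with an explicit convention.

**a0 fitting.** One-parameter least squares on ln a0 with the standard
error from the single-parameter curvature at the optimum. A series with no
displacement (all fractions 1) is rejected as unidentifiable. A single
informative point reduces to the closed form a0 = (1/y − 1)/c.

Defaults: T = 300 K (the simulation temperature of the free-energy
calculations the ΔE input comes from).

## Umbrella sampling and WHAM

Windows restrain a 1-D reaction coordinate (domain-peptide centre-of-mass
distance, Å) with harmonic springs quoted in kJ mol⁻¹ nm⁻² (the simulation
package's unit) and converted internally by 1 nm² = 100 Å². The canonical
schedule builder uses half-open segments [start, stop): each boundary is
owned by the segment starting there and the global stop is excluded. For
the campaign segments (15→25 by 0.5, 25→38 by 1.0) this yields 20 + 13 = 33
windows — the only simple convention that does; inclusive endpoints would
give 34. The convention is recorded in the schedule manifest, which also
books total sampled time (33 × 100 ns = 3300 ns).

**Estimator.** Binned WHAM on a shared grid (default 200 bins over the
sampled range):

    ρ(x) = Σ_i h_i(x) / Σ_i N_i exp[(F_i − b_i(x))/kT]
    F_i  = −kT ln Σ_x ρ(x) exp[−b_i(x)/kT]

Numerical choices:

* The bias factor per bin is the **bin average** of exp(−b_i/kT) (8-point
  midpoint quadrature), not a single centre-point evaluation: with a
  10,000 kJ mol⁻¹ nm⁻² spring the bias varies by ~1 kT across a default
  bin and centre-point evaluation visibly biases the profile.
* The self-consistent equations are solved by Newton minimisation of the
  equivalent convex likelihood over g_i = F_i/kT (gauge g_0 = 0), followed
  by the plain self-consistent iteration until the documented convergence
  metric max|ΔF_i| < 1e-7 kT is met. Plain iteration alone needs >10⁵
  sweeps at this tolerance; Newton reaches machine precision in tens of
  steps.
* Empty bins are masked NaN, never interpolated; profiles are aligned
  min-zero by default, with plateau-zero available.
* A structural coverage check rejects window sets leaving a gap more than
  6σ (σ = sqrt(kT/k)) from every restraint centre with no samples in
  between, naming the gap — relative free energies across such a gap would
  be unconstrained noise.

**Barriers.** The dissociation barrier is mean(plateau bins) − global
minimum, with the plateau range a required user input (the unbound shelf of
the profile). A profile whose global minimum falls inside the plateau range
is flagged pathological (no bound state below the plateau). Errors come
from a window-wise bootstrap: resample each window's observations with
replacement, re-solve, take the standard deviation across replicates per
bin and for the barrier. Replicate failures are counted; more than 20%
failures aborts.

**Intrinsic precision at the campaign's settings.** sqrt(kT/k) ≈ 0.16 Å,
so windows spaced 1.0 Å apart overlap only in ~3σ tails. Each of the ~13
outer window-to-window connections then rests on tens of tail samples,
contributing ~0.3 kT of noise, and the connections random-walk to a
barrier uncertainty of 2–3 kJ/mol at 5×10³ independent samples per window.
The bootstrap reports exactly this, and it matches the ±2.15 kJ/mol scale
quoted for real campaigns with these settings. Tighter answers need closer
outer windows or softer springs, not more iterations.

## Structure interface analysis

PDB files are read and written with gemmi. Author residue numbering and
insertion codes are preserved (the literature cites author numbers like
K1569 or F125); waters are dropped; alternate locations resolve to the
highest-occupancy conformer, ties broken alphabetically; phospho-residues
(SEP/TPO/PTR) written as HETATM are kept as peptide residues, with their
phosphate oxygens in both the H-bond acceptor and charged-atom sets —
phosphosite recognition is the point of the analyses.

Selections use AND-joined clauses (`chain A and resi 1560-1594 and name
CA`): `chain`, `resi` (ranges/lists), `name`, `resn`.

* **Superposition**: Kabsch SVD with the proper-rotation correction
  (det = +1; reflections excluded); collinear inputs are rejected. The
  test suite checks the RMSD against an independent Horn quaternion oracle
  to 1e-9 on random instances.
* **Cα pairing** by (mapped chain, residue number); unmatched residues are
  dropped and counted, and the matched count is reported in the
  "185-185 atoms" style of crystallographic comparisons.
* **RMSF**: frames are superposed on a fit subset (all atoms by default)
  onto the first frame or the iterated ensemble mean (two refinement
  rounds); RMSF_i = sqrt(mean_frames |r_i − ⟨r_i⟩|²).
* **Hydrogen bonds** (X-ray structures carry no hydrogens): heavy-atom
  N/O···N/O pairs across groups within 3.5 Å (default), different
  residues, plus an antecedent angle ≥ 90° at the donor (antecedent = the
  nearest covalently bonded heavy atom, ≤1.9 Å, in the donor's residue);
  a pair qualifies if either atom passes as donor, and the lone nitrogen
  is reported as donor. Categories: backbone atoms are {N, CA, C, O}.
* **Contacts**: hydrophobic = C···C within 4.5 Å; charge-charge = basic
  nitrogens (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2) against acidic/phosphate
  oxygens (Asp OD*, Glu OE*, O1P/O2P/O3P/OP1-3) within 4.0 Å. Cutoffs are
  arguments everywhere because published figures quote distances, not
  criteria.
* **Contact-number profile**: inter-group heavy-atom pair count per frame
  ordered by the frame's reaction-coordinate value — the diagnostic that
  contacts decay to zero as the centre-of-mass distance grows.

All detections are invariant under rigid motions (tested with random
rotations) and symmetric in the group arguments.

## Synthetic generators

All generators take a `GeneratorConfig(seed, noise_sd, replicate_count)`
and are bit-reproducible for a fixed seed; every artifact embeds its exact
generating parameters in metadata so recovery tests need no side channel.

* **ITC**: forward-model heats plus Gaussian noise of `noise_sd` μcal.
  The default `noise_sd = 0` gives the exact model; the noisy recovery
  studies use 0.2 μcal, a realistic per-injection integration noise for a
  modern calorimeter. Protocol defaults mirror the titrations modelled
  (1 μl + 19×2 μl, 0.25/4 mM, 20 °C).
* **Umbrella windows**: the biased density p(x) ∝ exp(−[U(x) + k/2
  (x−c)²]/kT) is tabulated on a refined grid (8 sub-bins per PMF bin) and
  sampled by inverse-CDF with linear interpolation inside sub-bins —
  deterministic, exact for a 1-D coordinate, no MCMC burn-in questions.
  Samples are independent, so n samples here correspond to n *effective*
  samples of a correlated MD trajectory; the generator does not emulate
  autocorrelation, which is one reason real campaigns need 100 ns to
  achieve what 5×10³ independent draws do here.
* **Competition series**: fractions from the displacement law with
  truncated-Gaussian noise resampled into (0, 1] — fractions are physical
  proportions.
* **Toy complex**: an idealised two-chain model (8-residue "domain" strand,
  5-residue "peptide" strand ending in phosphoserine) with exactly 5
  backbone N···O=C hydrogen bonds at 2.90 Å, one C···C hydrophobic contact
  at 4.00 Å, and one Lys NZ···phosphate oxygen pair at 3.80 Å — planted
  outside the 3.5 Å H-bond cutoff so the planted counts are unambiguous.
  Geometry is idealised (straight strands, partial side chains), which is
  sufficient for contact/superposition logic but is not a physically
  relaxed structure.

**What passing tests show, and don't.** Round-trip tests prove the
estimators invert their own generative models at the stated noise levels.
They do not certify behaviour against instrument baseline drift, MD
autocorrelation, force-field error, or crystallographic disorder — none of
which the generators emulate.

## The planted free-energy profile

`double_well_pmf` builds a bound Gaussian well (depth = the requested
barrier below the unbound plateau, default 9.4 kJ/mol, centred at 17 Å,
width 1.2 Å) plus a small transition hump (3 kJ/mol at 24 Å) on a
14–39 Å grid — the canonical shape of a peptide-unbinding profile with the
crystal-structure state at the global minimum and a flat unbound shelf.
The plateau range used for barrier extraction in the round-trip studies is
33–38 Å.

## Problem sizes in the shipped studies

The test suite and acceptance script run the full 33-window schedule at
5×10³ independent samples per window (the round-trip study), 2×10³ for the
shared fixtures, and 25 bootstrap replicates — sizes chosen so every
statistical claim is testable in seconds while keeping the outer-segment
overlap regime of the real campaign. The statistical property tests
(bootstrap error scaling and coverage) run on a compact 0.5 Å-spacing
schedule where the estimator is well conditioned, because those tests probe
the bootstrap, not the sparse-overlap pathology documented above.

## Known limitations

* No multi-site or competitive-ITC isotherms; inputs are integrated
  per-injection heats, not raw power traces.
* ΔE is an input to the competition model, never estimated from
  displacement data (it comes from free-energy profiles or literature).
* WHAM is 1-D, binned, without autocorrelation-based effective-sample-size
  correction (an extension point); metadynamics bias reconstruction is out
  of scope.
* The PDB reader handles the coordinate records the analyses need; no
  symmetry-mate generation, no mmCIF beyond gemmi's defaults, no electron
  density.
* The selection language is intentionally small: chain/resi/name/resn with
  AND only.
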