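"""Umbrella-sampling post-processing: schedules, WHAM, barriers, bootstrap.

The estimator combines biased histograms from harmonically restrained
windows along a 1-D reaction coordinate (a domain-peptide centre-of-mass
distance, in Angstrom) into one unbiased potential of mean force via the
self-consistent weighted-histogram equations

    rho(x) = sum_i h_i(x) / sum_i N_i exp[(F_i - b_i(x)) / kT]
    F_i    = -kT ln sum_x rho(x) exp[-b_i(x) / kT]

with b_i(x) = k/2 (x - c_i)^2 the restraint evaluated at bin centres.
Spring constants are taken in kJ mol^-1 nm^-2 and converted to act on
Angstrom displacements. Iteration stops when the largest change in any
window free energy falls below ``tol`` (in kT); the gauge is fixed by
F_0 = 0.  Bins with zero total counts are masked (NaN), never interpolated
silently.

Dissociation barriers are measured as mean(plateau region) minus the global
minimum of the profile; errors come from a window-wise bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import SPRING_NM2_TO_A2

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "BarrierResult",
    "WhamConvergenceError",
    "build_window_schedule",
    "schedule_manifest",
    "WhamEstimator",
    "wham_solve",
    "align_profile",
    "dissociation_barrier",
    "delta_barrier",
    "bootstrap_pmf",
]

DEFAULT_SPRING_KJ_MOL_NM2 = 10_000.0


class WhamConvergenceError(RuntimeError):
    """Raised when the self-consistent iteration fails to converge."""

    def __init__(self, residual_kt: float, max_iter: int):
        self.residual_kt = residual_kt
        self.max_iter = max_iter
        super().__init__(
            f"WHAM did not converge after {max_iter} iterations "
            f"(last max|dF| = {residual_kt:.3g} kT)"
        )


@dataclass
class UmbrellaWindow:
    """One restrained window: centre (A), spring (kJ/mol/nm^2), samples (A)."""

    center: float
    spring_k: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.spring_k <= 0:
            raise ValueError("spring constant must be positive")
        self.samples = np.asarray(self.samples, dtype=float)

    def bias_kj(self, x: np.ndarray) -> np.ndarray:
        """Restraint energy (kJ/mol) at coordinate x in Angstrom."""
        k_a2 = self.spring_k * SPRING_NM2_TO_A2
        return 0.5 * k_a2 * (np.asarray(x) - self.center) ** 2

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# center_A={self.center} spring_kJ_mol_nm2={self.spring_k}\n")
            fh.write("sample_A\n")
            np.savetxt(fh, self.samples, fmt="%.6f")

    @classmethod
    def from_csv(cls, path) -> "UmbrellaWindow":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            fh.readline()  # column header
            samples = np.loadtxt(fh, ndmin=1)
        return cls(
            center=float(meta["center_A"]),
            spring_k=float(meta["spring_kJ_mol_nm2"]),
            samples=samples,
        )


@dataclass
class PMFProfile:
    """Free energy (kJ/mol) vs. reaction coordinate (A).

    Unpopulated bins are NaN in ``free_energy`` and flagged in ``populated``.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    kT: float
    stderr: np.ndarray | None = None
    alignment: str = "min_zero"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.free_energy = np.asarray(self.free_energy, dtype=float)
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def populated(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "bin_center_A": self.bin_centers,
                "pmf_kJ_mol": self.free_energy,
                "stderr_kJ_mol": (
                    self.stderr if self.stderr is not None
                    else np.full_like(self.free_energy, np.nan)
                ),
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# kT_kJ_mol={self.kT} alignment={self.alignment}\n")
            df.to_csv(fh, index=False)


@dataclass
class BarrierResult:
    """Dissociation barrier (plateau minus global minimum), kJ/mol."""

    barrier: float
    error: float = math.nan
    delta_between_profiles: float = math.nan
    metadata: dict = field(default_factory=dict)


def build_window_schedule(
    segments: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    """Window centres from (start, stop, spacing) segments, half-open.

    Each segment owns its start; the global stop is excluded, so touching
    segments cannot duplicate a centre.  The canonical dissociation schedule
    [(15, 25, 0.5), (25, 38, 1.0)] yields 20 + 13 = 33 centres.
    """
    if not segments:
        raise ValueError("need at least one segment")
    centers: list[float] = []
    prev_stop = -math.inf
    for start, stop, spacing in segments:
        if spacing <= 0:
            raise ValueError(f"spacing must be positive, got {spacing}")
        if start >= stop:
            raise ValueError(f"segment start {start} must be below stop {stop}")
        if start < prev_stop:
            raise ValueError(f"segment starting at {start} overlaps previous")
        n = int(math.ceil((stop - start) / spacing - 1e-9))
        centers.extend(start + i * spacing for i in range(n))
        prev_stop = stop
    out = np.asarray(centers)
    if np.any(np.diff(out) <= 0):
        raise ValueError("segments produce non-increasing centers")
    return out


def schedule_manifest(
    segments: Sequence[tuple[float, float, float]],
    ns_per_window: float,
    spring_k: float = DEFAULT_SPRING_KJ_MOL_NM2,
) -> dict:
    """Bookkeeping for a window schedule: centres, count, total sampled time."""
    centers = build_window_schedule(segments)
    return {
        "segments": [list(s) for s in segments],
        "convention": "half-open [start, stop)",
        "centers_A": centers.tolist(),
        "n_windows": int(centers.size),
        "ns_per_window": ns_per_window,
        "total_ns": float(ns_per_window * centers.size),
        "spring_kJ_mol_nm2": spring_k,
    }


class WhamEstimator:
    """Self-consistent 1-D WHAM over a shared bin grid.

    Parameters
    ----------
    windows : restrained windows with samples.
    kT : thermal energy, kJ/mol (all windows share it).
    n_bins : number of histogram bins over the sampled range.
    tol : convergence threshold on max|dF_i| in kT.
    max_iter : iteration cap; exceeding it raises WhamConvergenceError.
    bin_range : optional (lo, hi) override of the binning range.
    """

    def __init__(
        self,
        windows: Sequence[UmbrellaWindow],
        kT: float,
        n_bins: int = 200,
        tol: float = 1e-7,
        max_iter: int = 100_000,
        bin_range: tuple[float, float] | None = None,
    ):
        if not windows:
            raise ValueError("need at least one window")
        if any(w.samples.size == 0 for w in windows):
            raise ValueError("every window needs samples")
        if kT <= 0:
            raise ValueError("kT must be positive")
        self.windows = list(windows)
        self.kT = kT
        self.n_bins = int(n_bins)
        self.tol = tol
        self.max_iter = int(max_iter)
        self.bin_range = bin_range

    def _edges(self) -> np.ndarray:
        if self.bin_range is not None:
            lo, hi = self.bin_range
        else:
            lo = min(w.samples.min() for w in self.windows)
            hi = max(w.samples.max() for w in self.windows)
            if hi <= lo:
                hi = lo + 1e-6
        return np.linspace(lo, hi, self.n_bins + 1)

    def _check_overlap(self, counts: np.ndarray, centers: np.ndarray) -> None:
        """Reject window sets whose restraints leave an uncovered gap.

        A bin is covered if it lies within 6 sigma (sigma = sqrt(kT/k)) of
        some window's restraint centre, or is itself populated.  An
        uncovered, unpopulated stretch separating populated bins means the
        relative free energies across it are unconstrained.
        """
        populated = counts.sum(axis=0) > 0
        covered = np.zeros_like(populated)
        for w in self.windows:
            sigma = math.sqrt(self.kT / (w.spring_k * SPRING_NM2_TO_A2))
            covered |= np.abs(centers - w.center) <= 6.0 * sigma
        pop_idx = np.flatnonzero(populated)
        if pop_idx.size == 0:
            raise ValueError("no populated bins")
        interior = slice(pop_idx[0], pop_idx[-1] + 1)
        bad = ~(covered | populated)
        bad_idx = np.flatnonzero(bad[interior]) + pop_idx[0]
        if bad_idx.size:
            lo, hi = centers[bad_idx[0]], centers[bad_idx[-1]]
            raise ValueError(
                "disconnected window coverage: no restraint or samples "
                f"between {lo:.3f} and {hi:.3f} A"
            )

    @staticmethod
    def _newton_g(u: np.ndarray, n_i: np.ndarray, h_x: np.ndarray,
                  max_newton: int = 60) -> np.ndarray:
        """Minimise the convex WHAM likelihood over g_i = F_i/kT (g_0 = 0).

        The self-consistent equations are the stationarity conditions of
        Omega(g) = sum_x h_x ln D_x - sum_i N_i g_i with
        D_x = sum_i N_i exp(g_i - u_ix); Newton steps on the (n_w - 1)
        free components converge quadratically, with step halving as a
        safeguard.
        """
        n_w = u.shape[0]
        g = np.zeros(n_w)
        if n_w == 1:  # gauge fixes everything
            return g

        def omega_grad_hess(g):
            logw = g[:, None] - u + np.log(n_i)[:, None]  # ln(N_i W_ix)
            m = logw.max(axis=0)
            W = np.exp(logw - m)
            D = W.sum(axis=0)  # D_x * exp(-m)
            omega = float(h_x @ (np.log(D) + m) - n_i @ g)
            r = W / D  # responsibility of window i for bin x
            grad = r @ h_x - n_i
            H = -(r * h_x) @ r.T
            H[np.diag_indices_from(H)] += grad + n_i
            return omega, grad, H

        omega, grad, H = omega_grad_hess(g)
        for _ in range(max_newton):
            free = slice(1, n_w)  # gauge: g_0 = 0
            try:
                step = np.linalg.solve(
                    H[free, free] + 1e-12 * np.eye(n_w - 1), -grad[free]
                )
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            for _ in range(40):
                trial = g.copy()
                trial[free] += scale * step
                new_omega, new_grad, new_H = omega_grad_hess(trial)
                if new_omega <= omega + 1e-12 * abs(omega):
                    g, omega, grad, H = trial, new_omega, new_grad, new_H
                    break
                scale *= 0.5
            if np.max(np.abs(grad[free])) < 1e-10 * max(h_x.sum(), 1.0):
                break
        return g

    def fit(self) -> PMFProfile:
        kT = self.kT
        edges = self._edges()
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = np.stack(
            [np.histogram(w.samples, bins=edges)[0] for w in self.windows]
        ).astype(float)
        self._check_overlap(counts, centers)
        n_i = counts.sum(axis=1)
        h_x = counts.sum(axis=0)

        # B[i, x] = bin average of exp(-b_i/kT), by 8-point midpoint
        # quadrature inside each bin: with stiff springs the bias varies
        # by ~1 kT across a bin, so a single centre-point evaluation
        # biases the profile noticeably.
        nq = 8
        width = edges[1] - edges[0]
        offsets = (np.arange(nq) + 0.5) / nq - 0.5
        xq = centers[None, :] + offsets[:, None] * width  # (nq, n_bins)
        B = np.mean(
            [np.stack([np.exp(-w.bias_kj(row) / kT) for w in self.windows])
             for row in xq],
            axis=0,
        )
        with np.errstate(divide="ignore"):
            u = -np.log(B)

        # Newton warm start on the likelihood, then self-consistent polish
        # until the documented convergence metric (max|dF| in kT) is met.
        logf = self._newton_g(u, n_i, h_x)
        logf -= logf[0]
        f = np.exp(logf)
        rho = np.zeros_like(h_x)
        residual = math.inf
        for _ in range(self.max_iter):
            denom = (n_i * f) @ B
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = np.where(denom > 0, h_x / denom, 0.0)
            rho_sum = rho.sum()
            if rho_sum <= 0:
                raise WhamConvergenceError(math.inf, self.max_iter)
            rho /= rho_sum
            z = B @ rho
            new_logf = -np.log(z)
            new_logf -= new_logf[0]  # gauge: F_0 = 0
            residual = float(np.max(np.abs(new_logf - logf)))
            logf = new_logf
            f = np.exp(logf)
            if residual < self.tol:
                break
        else:
            raise WhamConvergenceError(residual, self.max_iter)

        with np.errstate(divide="ignore"):
            pmf = np.where(rho > 0, -kT * np.log(rho), np.nan)
        profile = PMFProfile(
            bin_centers=centers,
            free_energy=pmf,
            kT=kT,
            metadata={
                "n_windows": len(self.windows),
                "n_bins": self.n_bins,
                "tol_kT": self.tol,
                "residual_kT": residual,
            },
        )
        return align_profile(profile, "min_zero")


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    kT: float,
    n_bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bin_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Functional wrapper around :class:`WhamEstimator`."""
    return WhamEstimator(
        windows, kT, n_bins=n_bins, tol=tol, max_iter=max_iter, bin_range=bin_range
    ).fit()


def align_profile(
    pmf: PMFProfile,
    mode: str = "min_zero",
    plateau_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Additively shift a profile so its reference level is zero.

    ``min_zero``: global minimum at zero.  ``plateau_zero``: mean over the
    plateau_range at zero.  Shape-preserving and idempotent.
    """
    fe = pmf.free_energy
    if mode == "min_zero":
        shift = np.nanmin(fe)
    elif mode == "plateau_zero":
        if plateau_range is None:
            raise ValueError("plateau_zero alignment needs a plateau_range")
        lo, hi = plateau_range
        mask = (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi) & np.isfinite(fe)
        if not mask.any():
            raise ValueError(f"no populated bins in plateau range {plateau_range}")
        shift = float(np.mean(fe[mask]))
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return replace(
        pmf,
        bin_centers=pmf.bin_centers.copy(),
        free_energy=fe - shift,
        stderr=None if pmf.stderr is None else pmf.stderr.copy(),
        alignment=mode,
        metadata={**pmf.metadata, "alignment_shift_kJ_mol": float(shift)},
    )


def dissociation_barrier(
    pmf: PMFProfile, plateau_range: tuple[float, float]
) -> BarrierResult:
    """Barrier = mean(plateau) - global minimum, kJ/mol.

    The plateau is the unbound region of the profile; the global minimum is
    the bound state. A plateau below the minimum flags a pathological
    profile.
    """
    fe = pmf.free_energy
    if not np.isfinite(fe).any():
        raise ValueError("profile has no populated bins")
    lo, hi = plateau_range
    mask = (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi) & np.isfinite(fe)
    if not mask.any():
        raise ValueError(f"no populated bins in plateau range {plateau_range}")
    plateau = float(np.mean(fe[mask]))
    minimum = float(np.nanmin(fe))
    min_x = float(pmf.bin_centers[np.nanargmin(fe)])
    if lo <= min_x <= hi:
        raise ValueError(
            f"pathological profile: global minimum at {min_x:.3g} A lies "
            "inside the plateau range (no bound state below the plateau)"
        )
    barrier = plateau - minimum
    return BarrierResult(
        barrier=barrier,
        metadata={"plateau_range_A": [lo, hi], "plateau_kJ_mol": plateau,
                  "minimum_kJ_mol": minimum},
    )


def delta_barrier(
    pmf_a: PMFProfile, pmf_b: PMFProfile, plateau_range: tuple[float, float]
) -> BarrierResult:
    """Barrier difference barrier(b) - barrier(a) between two profiles.

    The operand order (and hence the sign) is echoed in the metadata so the
    downstream competition model receives an explicit convention.
    """
    ba = dissociation_barrier(pmf_a, plateau_range)
    bb = dissociation_barrier(pmf_b, plateau_range)
    return BarrierResult(
        barrier=bb.barrier,
        delta_between_profiles=bb.barrier - ba.barrier,
        metadata={
            "convention": "barrier(b) - barrier(a)",
            "barrier_a_kJ_mol": ba.barrier,
            "barrier_b_kJ_mol": bb.barrier,
            "plateau_range_A": list(plateau_range),
        },
    )


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    kT: float,
    n_boot: int,
    seed: int,
    plateau_range: tuple[float, float] | None = None,
    n_bins: int = 200,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    replicate_seeds: Sequence[int] | None = None,
) -> tuple[PMFProfile, BarrierResult | None]:
    """Window-wise bootstrap of the WHAM solution.

    Each replicate resamples every window's observations with replacement
    and re-solves; the per-bin standard deviation across replicates is the
    profile's standard error, likewise for the barrier when a plateau_range
    is given.  ``replicate_seeds`` overrides the per-replicate RNG seeds
    (e.g. to force identical draws).  More than 20% failed replicates is an
    error.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    base = wham_solve(windows, kT, n_bins=n_bins, tol=tol, max_iter=max_iter)
    bin_range = (base.bin_centers[0] - 1e-9, base.bin_centers[-1] + 1e-9)
    # re-solve on the base grid so replicate profiles share bins
    edges_lo = base.bin_centers[0] - 0.5 * (base.bin_centers[1] - base.bin_centers[0])
    edges_hi = base.bin_centers[-1] + 0.5 * (base.bin_centers[1] - base.bin_centers[0])
    bin_range = (edges_lo, edges_hi)

    if replicate_seeds is None:
        ss = np.random.SeedSequence(seed)
        replicate_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n_boot)]
    elif len(replicate_seeds) != n_boot:
        raise ValueError("replicate_seeds length must equal n_boot")

    profiles, barriers, failures = [], [], 0
    for rep_seed in replicate_seeds:
        rng = np.random.default_rng(rep_seed)
        resampled = [
            UmbrellaWindow(
                w.center, w.spring_k,
                w.samples[rng.integers(0, w.samples.size, w.samples.size)],
            )
            for w in windows
        ]
        try:
            prof = wham_solve(
                resampled, kT, n_bins=n_bins, tol=tol,
                max_iter=max_iter, bin_range=bin_range,
            )
        except (WhamConvergenceError, ValueError):
            failures += 1
            continue
        profiles.append(prof.free_energy)
        if plateau_range is not None:
            try:
                barriers.append(dissociation_barrier(prof, plateau_range).barrier)
            except ValueError:
                failures += 1

    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"bootstrap unstable: {failures}/{n_boot} replicates failed"
        )

    stack = np.vstack(profiles)
    with warnings.catch_warnings():
        # bins unpopulated in every replicate are legitimately all-NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        stderr = np.nanstd(stack, axis=0, ddof=0)
    profile = replace(
        base,
        bin_centers=base.bin_centers.copy(),
        free_energy=base.free_energy.copy(),
        stderr=stderr,
        metadata={**base.metadata, "n_boot": n_boot, "boot_failures": failures},
    )
    barrier_result = None
    if plateau_range is not None:
        point = dissociation_barrier(base, plateau_range)
        barrier_result = BarrierResult(
            barrier=point.barrier,
            error=float(np.std(barriers, ddof=0)) if barriers else math.nan,
            metadata={**point.metadata, "n_boot": n_boot},
        )
    return profile, barrier_result
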