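"""Single-site ITC isotherm: forward model and weighted least-squares fit.

The forward model is the standard one-site total-heat expression for a
perfusion (overfill) calorimeter cell: concentrations of macromolecule M and
titrant X after each injection are corrected for the displaced cell volume,
the bound concentration follows from the quadratic mass-action root in
[0, 1] fractional saturation, and the differential heat of injection i is

    dQ_i = Q_i - Q_{i-1} + (dV_i / V0) * (Q_i + Q_{i-1}) / 2

with Q_i = dH * V0 * [MX]_i the cumulative heat content of the cell.

Units: cell/syringe concentrations in mM, volumes in ul, Kd in uM,
enthalpies in kcal/mol, heats in ucal (mM * ul = nmol; nmol * kcal/mol =
ucal).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import R_KCAL_PER_MOL_K

__all__ = [
    "TitrationExperiment",
    "SingleSiteModel",
    "SingleSiteResults",
    "isotherm_heats",
    "fit_single_site",
    "thermo_decompose",
]

#: 1 ul initial (priming) injection followed by 19 x 2 ul, the protocol used
#: for every titration modelled here.
DEFAULT_INJECTION_SCHEDULE: tuple[float, ...] = (1.0,) + (2.0,) * 19

#: Working cell volume of a MicroCal PEAQ-type calorimeter, ul.
DEFAULT_CELL_VOLUME_UL = 200.0

DEFAULT_TEMPERATURE_K = 293.15  # 20 C


@dataclass
class TitrationExperiment:
    """One ITC run: per-injection heats plus the concentrations behind them.

    Parameters
    ----------
    cell_conc_mM : macromolecule (claw domain) concentration in the cell.
    syringe_conc_mM : titrant (peptide) concentration in the syringe.
    injections : ordered (volume_ul, heat_ucal) pairs.
    cell_volume_ul : active cell volume.
    temperature_K : experiment temperature.
    metadata : free-form provenance (ground truth for synthetic runs).
    """

    cell_conc_mM: float
    syringe_conc_mM: float
    injections: list[tuple[float, float]]
    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL
    temperature_K: float = DEFAULT_TEMPERATURE_K
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cell_conc_mM <= 0 or self.syringe_conc_mM <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume_ul <= 0:
            raise ValueError("cell volume must be positive")
        if len(self.injections) < 3:
            raise ValueError("need at least 3 injections")
        if any(v <= 0 for v, _ in self.injections):
            raise ValueError("injection volumes must be positive")

    @property
    def volumes_ul(self) -> np.ndarray:
        return np.array([v for v, _ in self.injections], dtype=float)

    @property
    def heats_ucal(self) -> np.ndarray:
        return np.array([q for _, q in self.injections], dtype=float)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "injection_index": np.arange(1, len(self.injections) + 1),
                "volume_ul": self.volumes_ul,
                "heat_ucal": self.heats_ucal,
            }
        )
        with open(path, "w") as fh:
            fh.write(
                f"# cell_conc_mM={self.cell_conc_mM} "
                f"syringe_conc_mM={self.syringe_conc_mM} "
                f"cell_volume_ul={self.cell_volume_ul} "
                f"temperature_K={self.temperature_K}\n"
            )
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TitrationExperiment":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header line")
            meta = dict(tok.split("=") for tok in header[1:].split())
            df = pd.read_csv(fh)
        return cls(
            cell_conc_mM=float(meta["cell_conc_mM"]),
            syringe_conc_mM=float(meta["syringe_conc_mM"]),
            injections=list(zip(df["volume_ul"], df["heat_ucal"])),
            cell_volume_ul=float(meta.get("cell_volume_ul", DEFAULT_CELL_VOLUME_UL)),
            temperature_K=float(meta.get("temperature_K", DEFAULT_TEMPERATURE_K)),
            metadata={"source": str(path)},
        )


def isotherm_heats(
    kd_uM: float, n_sites: float, dH_kcal: float, exp: TitrationExperiment
) -> np.ndarray:
    """Per-injection heats (ucal) of the single-site model.

    Uses the displaced-volume concentration correction and the physically
    admissible (fractional saturation in [0, 1]) root of the mass-action
    quadratic.
    """
    if kd_uM <= 0:
        raise ValueError("kd must be positive")
    if n_sites <= 0:
        raise ValueError("stoichiometry must be positive")
    dv = exp.volumes_ul
    v0 = exp.cell_volume_ul
    vtot = np.cumsum(dv)
    # standard overfill-cell dilution factors
    mt = exp.cell_conc_mM * (1 - vtot / (2 * v0)) / (1 + vtot / (2 * v0))
    xt = exp.syringe_conc_mM * (vtot / v0) * (1 - vtot / (2 * v0))
    kd_mM = kd_uM * 1e-3
    b = n_sites * mt + xt + kd_mM
    disc = b * b - 4.0 * n_sites * mt * xt
    if np.any(disc < 0):
        raise ValueError("invalid parameters: negative discriminant")
    mx = 0.5 * (b - np.sqrt(disc))  # bound complex, mM; the root in [0, 1] saturation
    q = dH_kcal * v0 * mx  # cumulative heat content, ucal
    q_prev = np.concatenate([[0.0], q[:-1]])
    return q - q_prev + (dv / v0) * (q + q_prev) / 2.0


@dataclass
class SingleSiteResults:
    """Fitted single-site binding parameters with uncertainties.

    kd in uM, enthalpies in kcal/mol. ``no_binding`` is set when the
    isotherm is statistically indistinguishable from a constant offset.
    """

    kd_uM: float
    kd_se: float
    n_sites: float
    n_se: float
    dH_kcal: float
    dH_se: float
    temperature_K: float
    residual_norm_ucal: float
    no_binding: bool
    converged: bool
    n_obs: int
    metadata: dict = field(default_factory=dict)

    @property
    def dG_kcal(self) -> float:
        return R_KCAL_PER_MOL_K * self.temperature_K * math.log(self.kd_uM * 1e-6)

    @property
    def minus_TdS_kcal(self) -> float:
        return self.dG_kcal - self.dH_kcal

    def summary(self) -> str:
        if self.no_binding:
            return "Single-site ITC fit: no detectable binding (flat isotherm)"
        lines = [
            "Single-site ITC fit",
            "-" * 46,
            f"  KD      {self.kd_uM:12.4g} +/- {self.kd_se:.2g} uM",
            f"  N       {self.n_sites:12.4g} +/- {self.n_se:.2g}",
            f"  dH      {self.dH_kcal:12.4g} +/- {self.dH_se:.2g} kcal/mol",
            f"  dG      {self.dG_kcal:12.4g} kcal/mol",
            f"  -TdS    {self.minus_TdS_kcal:12.4g} kcal/mol",
            f"  T       {self.temperature_K:12.4g} K",
            f"  resid   {self.residual_norm_ucal:12.4g} ucal (rms)",
        ]
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "kd_uM": self.kd_uM,
            "kd_se": self.kd_se,
            "n_sites": self.n_sites,
            "n_se": self.n_se,
            "dH_kcal": self.dH_kcal,
            "dH_se": self.dH_se,
            "dG_kcal": None if self.no_binding else self.dG_kcal,
            "minus_TdS_kcal": None if self.no_binding else self.minus_TdS_kcal,
            "temperature_K": self.temperature_K,
            "residual_norm_ucal": self.residual_norm_ucal,
            "no_binding": self.no_binding,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


class SingleSiteModel:
    """Weighted least-squares fit of the single-site isotherm.

    The priming injection is down-weighted to zero by default (its heat is
    corrupted by diffusion across the syringe tip during equilibration).
    Parameters are fitted on a log scale for Kd and N to enforce positivity
    and condition the problem across c-values.

    A deterministic multi-start ladder (Kd grid x N grid, dH seeded from the
    observed heat scale) guards against local minima; the converged start
    with the lowest residual wins.
    """

    KD_STARTS_UM = (0.1, 1.0, 10.0, 100.0, 1000.0)
    N_STARTS = (0.5, 1.0, 2.0)

    def __init__(
        self,
        experiment: TitrationExperiment,
        first_injection_weight: float = 0.0,
        no_binding_alpha: float = 0.01,
    ):
        self.experiment = experiment
        self.weights = np.ones(len(experiment.injections))
        self.weights[0] = first_injection_weight
        self.no_binding_alpha = no_binding_alpha

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        log_kd, log_n, dh = theta
        model = isotherm_heats(
            math.exp(log_kd), math.exp(log_n), dh, self.experiment
        )
        return np.sqrt(self.weights) * (model - self.experiment.heats_ucal)

    def _dh_start(self) -> float:
        # total observed heat / total titrant injected, a stoichiometric-limit guess
        exp = self.experiment
        w = self.weights > 0
        total_q = float(np.sum(exp.heats_ucal[w]))
        moles = float(np.sum(exp.volumes_ul[w]) * exp.syringe_conc_mM)  # nmol
        guess = total_q / moles if moles > 0 else 0.0
        return guess if abs(guess) > 1e-12 else -1.0

    def fit(self, init: tuple[float, float, float] | None = None) -> SingleSiteResults:
        """Fit (Kd, N, dH); ``init`` overrides the multi-start ladder."""
        exp = self.experiment
        heats = exp.heats_ucal
        w = self.weights
        n_eff = int(np.sum(w > 0))

        starts: list[tuple[float, float, float]]
        if init is not None:
            starts = [init]
        else:
            dh0 = self._dh_start()
            starts = [
                (kd0, n0, dh)
                for kd0 in self.KD_STARTS_UM
                for n0 in self.N_STARTS
                for dh in (dh0, 2.0 * dh0)
            ]

        best = None
        for kd0, n0, dh0 in starts:
            theta0 = np.array([math.log(kd0), math.log(n0), dh0])
            try:
                sol = optimize.least_squares(
                    self._residuals, theta0, method="lm",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=20000,
                )
            except (ValueError, FloatingPointError):
                continue
            if not sol.success:
                continue
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol

        if best is None:
            return SingleSiteResults(
                kd_uM=math.nan, kd_se=math.nan, n_sites=math.nan, n_se=math.nan,
                dH_kcal=math.nan, dH_se=math.nan,
                temperature_K=exp.temperature_K,
                residual_norm_ucal=math.nan, no_binding=False,
                converged=False, n_obs=n_eff,
            )

        ssr_fit = float(2 * best.cost)
        # constant-offset null model (weighted mean heat)
        mean_q = float(np.sum(w * heats) / np.sum(w))
        ssr_null = float(np.sum(w * (heats - mean_q) ** 2))
        no_binding = self._no_binding(ssr_null, ssr_fit, n_eff)

        dof = max(n_eff - 3, 1)
        s2 = ssr_fit / dof
        jac = best.jac
        try:
            cov = s2 * np.linalg.inv(jac.T @ jac)
            se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            se = np.full(3, math.nan)

        log_kd, log_n, dh = best.x
        kd = math.exp(log_kd)
        n_sites = math.exp(log_n)
        return SingleSiteResults(
            kd_uM=kd, kd_se=kd * se[0],
            n_sites=n_sites, n_se=n_sites * se[1],
            dH_kcal=dh, dH_se=se[2],
            temperature_K=exp.temperature_K,
            residual_norm_ucal=math.sqrt(ssr_fit / max(n_eff, 1)),
            no_binding=no_binding, converged=True, n_obs=n_eff,
            metadata={"ssr_null": ssr_null, "ssr_fit": ssr_fit},
        )

    def _no_binding(self, ssr_null: float, ssr_fit: float, n_eff: int) -> bool:
        """F-test of the 3-parameter isotherm against a constant offset.

        Declares no binding when the isotherm does NOT improve on the flat
        model at level ``no_binding_alpha``, or when the signal itself is
        numerically zero.
        """
        scale = float(np.sum(self.experiment.heats_ucal**2))
        if ssr_null <= 1e-12 * max(scale, 1.0) or scale < 1e-20:
            return True
        dof = n_eff - 3
        if dof <= 0:
            return False
        if ssr_fit <= 0:
            return False  # perfect structured fit
        f_stat = ((ssr_null - ssr_fit) / 2.0) / (ssr_fit / dof)
        p = stats.f.sf(max(f_stat, 0.0), 2, dof)
        return bool(p > self.no_binding_alpha)


def fit_single_site(
    exp: TitrationExperiment,
    init: tuple[float, float, float] | None = None,
    **kwargs,
) -> SingleSiteResults:
    """Functional wrapper around :class:`SingleSiteModel`."""
    return SingleSiteModel(exp, **kwargs).fit(init=init)


def thermo_decompose(
    fit: SingleSiteResults, temperature_K: float | None = None
) -> tuple[float, float, float]:
    """(dG, dH, -TdS) in kcal/mol from a binding fit.

    dG = R*T*ln(Kd in molar); the identity dG = dH + (-TdS) holds by
    construction.
    """
    if fit.no_binding:
        raise ValueError("cannot decompose thermodynamics: no binding detected")
    t = fit.temperature_K if temperature_K is None else temperature_K
    dg = R_KCAL_PER_MOL_K * t * math.log(fit.kd_uM * 1e-6)
    return dg, fit.dH_kcal, dg - fit.dH_kcal
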