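"""Three-state competition model for peptide displacement.

A claw domain D exchanges between three states: free, bound to a reporter
peptide (state 1, e.g. a phosphorylated CCPG1 FIR peptide), and bound to a
competitor peptide (state 2, a TNIP1 FIR peptide).  With diffusion-controlled
association (on-rates proportional to peptide concentration) and
dissociation rates set by the activation barrier of the unbinding
free-energy profile (transition-state theory), the stationary fraction of
reporter complex reduces to a one-parameter displacement law:

    y1(c) = 1 / (1 + a0 * c)                       (unmodified competitor)
    y2(c) = 1 / (1 + a0 * exp(dE / kB T) * c)      (phosphorylated, enhancing)

where c is the competitor concentration (uM), a0 (uM^-1) absorbs the
reporter-side rates, and dE (kJ/mol) is the difference in dissociation
activation barrier caused by phosphorylation.  Two sign conventions are
shipped: ``enhancing`` (default) applies exp(+|dE|/kBT) so a positive
reported barrier difference strengthens competition; ``printed`` applies
exp(-dE/kBT) literally.

The stationary three-state occupancies are also exposed directly, in two
variants: ``detailed_balance`` (default; the competitor's dissociation rate
appears, consistent with the displacement law above) and ``printed`` (the
algebraic form in which the competitor dissociation rate cancels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .constants import KB_KJ_PER_MOL_K

__all__ = [
    "KineticRates",
    "CompetitionParams",
    "p1_stationary",
    "stationary_distribution",
    "y_unmodified",
    "y_phospho",
    "DisplacementModel",
    "DisplacementFit",
    "fit_a0",
    "predict_displacement_curve",
    "conc_to_rate",
]


@dataclass(frozen=True)
class KineticRates:
    """Association/dissociation rates of the two binding channels.

    u1/w1: reporter complex on/off; u2/w2: competitor complex on/off.
    Units are arbitrary inverse time; only ratios matter at stationarity.
    """

    u1: float
    w1: float
    u2: float
    w2: float

    def __post_init__(self) -> None:
        if min(self.u1, self.w1, self.u2, self.w2) < 0:
            raise ValueError("rates must be nonnegative")
        if self.w1 == 0 and self.w2 == 0:
            raise ValueError("at least one dissociation rate must be positive")


@dataclass(frozen=True)
class CompetitionParams:
    """Displacement-law parameter set.

    a0 in uM^-1; dE in kJ/mol; kB pinned in kJ mol^-1 K^-1.
    """

    a0: float
    dE: float = 0.0
    temperature_K: float = 300.0
    kB: float = KB_KJ_PER_MOL_K
    sign_convention: str = "enhancing"  # or "printed"

    def __post_init__(self) -> None:
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.sign_convention not in ("enhancing", "printed"):
            raise ValueError(f"unknown sign convention {self.sign_convention!r}")

    @property
    def kT(self) -> float:
        return self.kB * self.temperature_K

    @property
    def boltzmann_factor(self) -> float:
        """Multiplier on a0 for the phosphorylated competitor."""
        if self.sign_convention == "enhancing":
            return math.exp(abs(self.dE) / self.kT)
        return math.exp(-self.dE / self.kT)


def conc_to_rate(conc_uM: float | np.ndarray):
    """Diffusion-controlled association rate for a given concentration.

    Unit proportionality: the diffusion-limited prefactor is absorbed into
    a0, exactly as the displacement law does.
    """
    return np.asarray(conc_uM, dtype=float)


def stationary_distribution(rates: KineticRates) -> tuple[float, float, float]:
    """(P_free, P_reporter, P_competitor) of the three-state exchange.

    Detailed balance on the star-shaped network: P1/P0 = u1/w1,
    P2/P0 = u2/w2.
    """
    r = rates
    denom = r.w1 * r.w2 + r.u1 * r.w2 + r.u2 * r.w1
    if denom == 0:
        raise ValueError("undefined stationary state: all fluxes vanish")
    return (
        r.w1 * r.w2 / denom,
        r.u1 * r.w2 / denom,
        r.u2 * r.w1 / denom,
    )


def p1_stationary(rates: KineticRates, variant: str = "detailed_balance") -> float:
    """Probability of the reporter complex (state 1).

    ``detailed_balance``: u1 w2 / (w1 w2 + u1 w2 + u2 w1), the stationary
    solution of the explicit rate matrix.  ``printed``: the algebraically
    equivalent-looking form u1 w2 / (w1 w2 + u1 w2 + u2 w2), in which w2
    cancels so the competitor dissociation rate drops out entirely.
    """
    r = rates
    if variant == "detailed_balance":
        return stationary_distribution(rates)[1]
    if variant == "printed":
        denom = r.w1 * r.w2 + r.u1 * r.w2 + r.u2 * r.w2
        if denom == 0:
            raise ValueError("undefined stationary state: zero denominator")
        return r.u1 * r.w2 / denom
    raise ValueError(f"unknown variant {variant!r}")


def _check_conc(conc) -> np.ndarray:
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    return c


def y_unmodified(a0: float, conc_uM):
    """Reporter-complex fraction against the unmodified competitor."""
    if a0 <= 0:
        raise ValueError("a0 must be positive")
    c = _check_conc(conc_uM)
    out = 1.0 / (1.0 + a0 * c)
    return float(out) if out.ndim == 0 else out


def y_phospho(params: CompetitionParams, conc_uM):
    """Reporter-complex fraction against the phosphorylated competitor."""
    c = _check_conc(conc_uM)
    out = 1.0 / (1.0 + params.a0 * params.boltzmann_factor * c)
    return float(out) if out.ndim == 0 else out


@dataclass
class DisplacementFit:
    """Result of fitting the one-parameter displacement law."""

    a0: float
    a0_se: float
    residual_norm: float
    n_obs: int
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            "Displacement-law fit\n"
            f"  a0    {self.a0:.6g} +/- {self.a0_se:.2g} uM^-1\n"
            f"  rms   {self.residual_norm:.3g} (fraction units, n={self.n_obs})"
        )


class DisplacementModel:
    """Least-squares estimation of a0 from (concentration, fraction) data.

    The fraction of intact reporter complex y is modelled as
    y = 1/(1 + a0 c); a0 is fitted on a log scale (positivity), with the
    standard error from the one-parameter curvature at the optimum.
    """

    def __init__(self, concentrations_uM: Sequence[float], fractions: Sequence[float]):
        c = _check_conc(concentrations_uM)
        y = np.asarray(fractions, dtype=float)
        if c.shape != y.shape or c.size < 1:
            raise ValueError("concentrations and fractions must align")
        if np.any(y <= 0) or np.any(y > 1):
            raise ValueError("fractions must lie in (0, 1]")
        if np.all(y >= 1.0 - 1e-12):
            raise ValueError("no displacement observed: a0 unidentifiable")
        if c.size < 2 and c.size != 1:
            raise ValueError("need at least one informative point")
        self.conc = c
        self.frac = y

    def fit(self) -> DisplacementFit:
        c, y = self.conc, self.frac
        # closed-form start from the most-displaced point
        i = int(np.argmin(y))
        a0_start = (1.0 / y[i] - 1.0) / c[i] if c[i] > 0 else 1e-3
        a0_start = max(a0_start, 1e-12)

        def resid(log_a0: np.ndarray) -> np.ndarray:
            return 1.0 / (1.0 + np.exp(log_a0[0]) * c) - y

        sol = optimize.least_squares(
            resid, np.array([math.log(a0_start)]),
            method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        a0 = float(np.exp(sol.x[0]))
        r = resid(sol.x)
        ssr = float(r @ r)
        dof = max(c.size - 1, 1)
        # curvature of SSR wrt a0 itself (delta method from the log scale)
        dyda = -c / (1.0 + a0 * c) ** 2
        curv = float(dyda @ dyda)
        se = math.sqrt(ssr / dof / curv) if curv > 0 else math.inf
        return DisplacementFit(
            a0=a0, a0_se=se,
            residual_norm=math.sqrt(ssr / c.size),
            n_obs=int(c.size),
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame,
        conc_col: str = "conc_uM", frac_col: str = "fraction",
    ) -> "DisplacementModel":
        return cls(df[conc_col].to_numpy(), df[frac_col].to_numpy())


def fit_a0(concentrations_uM, fractions) -> DisplacementFit:
    """Functional wrapper around :class:`DisplacementModel`."""
    return DisplacementModel(concentrations_uM, fractions).fit()


def predict_displacement_curve(
    params: CompetitionParams, concentrations_uM: Sequence[float]
) -> pd.DataFrame:
    """Table (conc_uM, y1, y2) for unmodified vs. phosphorylated competitor.

    Suitable for log-scale plotting of displacement curves; columns agree
    pointwise with :func:`y_unmodified` / :func:`y_phospho`.
    """
    c = _check_conc(list(concentrations_uM))
    df = pd.DataFrame(
        {
            "conc_uM": c,
            "y1": y_unmodified(params.a0, c) if c.size else np.array([]),
            "y2": y_phospho(params, c) if c.size else np.array([]),
        }
    )
    df.attrs["sign_convention"] = params.sign_convention
    df.attrs["a0_uM_inv"] = params.a0
    df.attrs["dE_kJ_mol"] = params.dE
    df.attrs["temperature_K"] = params.temperature_K
    return df
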