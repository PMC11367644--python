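"""Seeded generators for every input the analysis stages consume.

Each generator embeds its exact ground-truth parameters in the returned
object's metadata, so recovery tests need no side channel, and is
bit-reproducible under a fixed :class:`GeneratorConfig` seed.

The study conditions emulated here: a titration of 1 ul + 19 x 2 ul peptide
injections into a 0.25 mM domain cell at 20 C; umbrella windows restrained
by a 10,000 kJ mol^-1 nm^-2 spring along a centre-of-mass distance; a
displacement series following the one-parameter competition law; and a toy
domain-peptide complex with planted backbone hydrogen bonds, one
hydrophobic contact, and one lysine-phosphate salt bridge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .competition import CompetitionParams, y_phospho, y_unmodified
from .constants import KB_KJ_PER_MOL_K
from .itc import (
    DEFAULT_CELL_VOLUME_UL,
    DEFAULT_INJECTION_SCHEDULE,
    DEFAULT_TEMPERATURE_K,
    TitrationExperiment,
    isotherm_heats,
)
from .structure.model import Atom, StructureModel
from .wham import DEFAULT_SPRING_KJ_MOL_NM2, UmbrellaWindow

__all__ = [
    "GeneratorConfig",
    "PmfSpec",
    "double_well_pmf",
    "gen_itc_titration",
    "gen_umbrella_samples",
    "gen_competition_series",
    "gen_toy_complex",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed, observable-space noise level, and replicate count."""

    seed: int = 0
    noise_sd: float = 0.0
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PmfSpec:
    """Known ground-truth free-energy profile on a uniform grid.

    grid_min/grid_max in Angstrom, values in kJ/mol at the bin centres.
    """

    grid_min: float
    grid_max: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.grid_min >= self.grid_max:
            raise ValueError("grid_min must be below grid_max")
        if len(self.values) < 2:
            raise ValueError("need at least 2 bins")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("free energies must be finite")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = np.linspace(self.grid_min, self.grid_max, self.n_bins + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    def energy(self, x) -> np.ndarray:
        """Linear interpolation of the profile at coordinates x (A)."""
        return np.interp(np.asarray(x, dtype=float), self.bin_centers,
                         np.asarray(self.values))


def double_well_pmf(
    barrier_kj: float = 9.4,
    grid_min: float = 14.0,
    grid_max: float = 39.0,
    n_bins: int = 500,
    well_center: float = 17.0,
    well_width: float = 1.2,
    hump_height: float = 3.0,
    hump_center: float = 24.0,
    hump_width: float = 1.5,
) -> PmfSpec:
    """Bound-well / plateau profile with a known dissociation barrier.

    The bound state sits in a Gaussian well of depth ``barrier_kj`` below
    the unbound plateau, with a small transition hump between them — the
    shape of a domain-peptide unbinding free-energy profile.  The plateau
    minus the global minimum equals ``barrier_kj`` exactly.
    """
    edges = np.linspace(grid_min, grid_max, n_bins + 1)
    x = 0.5 * (edges[:-1] + edges[1:])
    u = (
        barrier_kj
        - barrier_kj * np.exp(-((x - well_center) ** 2) / (2 * well_width**2))
        + hump_height * np.exp(-((x - hump_center) ** 2) / (2 * hump_width**2))
    )
    return PmfSpec(grid_min=grid_min, grid_max=grid_max, values=tuple(u))


def gen_itc_titration(
    kd_uM: float,
    n_sites: float,
    dH_kcal: float,
    cfg: GeneratorConfig,
    cell_conc_mM: float = 0.25,
    syringe_conc_mM: float = 4.0,
    schedule_ul: Sequence[float] = DEFAULT_INJECTION_SCHEDULE,
    cell_volume_ul: float = DEFAULT_CELL_VOLUME_UL,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> TitrationExperiment:
    """Noisy single-site titration with known (KD, N, dH) ground truth."""
    if kd_uM <= 0 or n_sites <= 0:
        raise ValueError("non-physical binding parameters")
    if cell_conc_mM <= 0 or syringe_conc_mM <= 0:
        raise ValueError("concentrations must be positive")
    if not schedule_ul:
        raise ValueError("injection schedule must be non-empty")
    blank = TitrationExperiment(
        cell_conc_mM=cell_conc_mM,
        syringe_conc_mM=syringe_conc_mM,
        injections=[(float(v), 0.0) for v in schedule_ul],
        cell_volume_ul=cell_volume_ul,
        temperature_K=temperature_K,
    )
    heats = isotherm_heats(kd_uM, n_sites, dH_kcal, blank)
    if cfg.noise_sd > 0:
        heats = heats + cfg.rng().normal(0.0, cfg.noise_sd, heats.size)
    return TitrationExperiment(
        cell_conc_mM=cell_conc_mM,
        syringe_conc_mM=syringe_conc_mM,
        injections=list(zip(blank.volumes_ul, heats)),
        cell_volume_ul=cell_volume_ul,
        temperature_K=temperature_K,
        metadata={
            "truth": {"kd_uM": kd_uM, "n_sites": n_sites, "dH_kcal": dH_kcal},
            "noise_sd_ucal": cfg.noise_sd,
            "seed": cfg.seed,
        },
    )


def gen_umbrella_samples(
    pmf: PmfSpec,
    centers: Sequence[float],
    n_per_window: int,
    cfg: GeneratorConfig,
    spring_k: float = DEFAULT_SPRING_KJ_MOL_NM2,
    kT: float = KB_KJ_PER_MOL_K * 300.0,
    oversample: int = 8,
) -> list[UmbrellaWindow]:
    """Boltzmann samples from a known profile under harmonic restraints.

    For each window the biased density p(x) ~ exp(-[U(x) + k/2 (x-c)^2]/kT)
    is tabulated on a refined grid (``oversample`` sub-bins per PMF bin) and
    sampled by inverse-CDF with linear interpolation inside sub-bins — a
    deterministic, exact scheme for a 1-D coordinate.  Spring constants are
    in kJ mol^-1 nm^-2 and converted to Angstrom internally.
    """
    centers = list(centers)
    if not centers:
        raise ValueError("need at least one window center")
    if n_per_window < 1:
        raise ValueError("n_per_window must be positive")
    if spring_k <= 0 or kT <= 0:
        raise ValueError("spring constant and kT must be positive")
    for c in centers:
        if not (pmf.grid_min <= c <= pmf.grid_max):
            raise ValueError(f"center {c} outside PMF grid")

    n_fine = pmf.n_bins * oversample
    edges = np.linspace(pmf.grid_min, pmf.grid_max, n_fine + 1)
    x = 0.5 * (edges[:-1] + edges[1:])
    dx = edges[1] - edges[0]
    u = pmf.energy(x)
    rng = cfg.rng()

    windows = []
    for c in centers:
        w = UmbrellaWindow(center=float(c), spring_k=float(spring_k),
                           samples=np.empty(0))
        etot = u + w.bias_kj(x)
        logp = -(etot - etot.min()) / kT
        p = np.exp(logp)
        p /= p.sum()
        cdf = np.concatenate([[0.0], np.cumsum(p)])
        cdf[-1] = 1.0
        uni = rng.random(n_per_window)
        idx = np.searchsorted(cdf, uni, side="right") - 1
        idx = np.clip(idx, 0, n_fine - 1)
        frac = (uni - cdf[idx]) / np.maximum(cdf[idx + 1] - cdf[idx], 1e-300)
        w.samples = edges[idx] + frac * dx
        windows.append(w)
    return windows


def gen_competition_series(
    a0: float,
    dE: float,
    concentrations_uM: Sequence[float],
    cfg: GeneratorConfig,
    kT: float | None = None,
    temperature_K: float = 300.0,
    sign_convention: str = "enhancing",
) -> pd.DataFrame:
    """Displacement fractions vs. competitor concentration, with noise.

    Noise is truncated Gaussian, resampled until each fraction lies in
    (0, 1] — fractions are physical proportions.  ``dE = 0`` reproduces the
    unmodified-competitor law exactly.
    """
    conc = np.asarray(list(concentrations_uM), dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    if kT is not None:
        temperature_K = kT / KB_KJ_PER_MOL_K
    if dE == 0:
        frac = np.asarray(y_unmodified(a0, conc), dtype=float).reshape(conc.shape)
    else:
        params = CompetitionParams(
            a0=a0, dE=dE, temperature_K=temperature_K,
            sign_convention=sign_convention,
        )
        frac = np.asarray(y_phospho(params, conc), dtype=float).reshape(conc.shape)
    truth = frac.copy()
    if cfg.noise_sd > 0:
        rng = cfg.rng()
        noisy = np.full_like(frac, np.nan)
        pending = np.ones(frac.shape, dtype=bool)
        while pending.any():
            draw = frac[pending] + rng.normal(0.0, cfg.noise_sd, int(pending.sum()))
            ok = (draw > 0) & (draw <= 1)
            idx = np.flatnonzero(pending)[ok]
            noisy[idx] = draw[ok]
            pending[idx] = False
        frac = noisy
    df = pd.DataFrame({"conc_uM": conc, "fraction": frac, "fraction_true": truth})
    df.attrs.update(
        {
            "a0_uM_inv": a0, "dE_kJ_mol": dE, "temperature_K": temperature_K,
            "sign_convention": sign_convention,
            "noise_sd": cfg.noise_sd, "seed": cfg.seed,
        }
    )
    return df


# ---------------------------------------------------------------------
# toy domain-peptide complex with planted interactions


def gen_toy_complex(cfg: GeneratorConfig | None = None) -> StructureModel:
    """Two-chain toy complex with planted, counted interactions.

    Chain A ("domain", 8 residues) and chain B ("peptide", 5 residues,
    C-terminal phosphoserine) are idealised strands with exactly:

    * 5 backbone N(H)...O=C hydrogen bonds at 2.90 A (peptide amide N of
      residues B101-B105 to the carbonyl O of A1-A5),
    * 1 hydrophobic C-C contact at 4.00 A (A4 LEU CB to B104 VAL CG1),
    * 1 charge-charge pair at 3.80 A (A8 LYS NZ to B105 SEP O1P) — outside
      the 3.5 A hydrogen-bond cutoff by construction.

    The planted counts are recorded in the metadata.  The generator is
    deterministic; ``cfg`` is accepted for interface uniformity.
    """
    atoms: list[Atom] = []
    # domain chain A: residues 1..8, backbone along x, carbonyl O toward +y
    resnames_a = ["ALA", "ALA", "ALA", "LEU", "ALA", "ALA", "ALA", "LYS"]
    for k, resn in enumerate(resnames_a):
        x0 = 8.0 * k
        atoms += [
            Atom("A", k + 1, "", resn, "N", "N", x0, 0.0, 0.0),
            Atom("A", k + 1, "", resn, "CA", "C", x0 + 1.45, 0.0, 0.0),
            Atom("A", k + 1, "", resn, "C", "C", x0 + 2.9, 0.0, 0.0),
            Atom("A", k + 1, "", resn, "O", "O", x0 + 2.9, 1.23, 0.0),
        ]
        if resn == "LEU":  # hydrophobic probe (residue A4, k=3)
            atoms.append(Atom("A", k + 1, "", resn, "CB", "C", x0 + 1.45, 1.5, 3.0))
        if resn == "LYS":  # side chain reaching the peptide phosphate
            atoms.append(Atom("A", k + 1, "", resn, "CE", "C", 36.0, 14.7, 0.0))
            atoms.append(Atom("A", k + 1, "", resn, "NZ", "N", 36.0, 13.25, 0.0))

    # peptide chain B: residues 101..105, amide N 2.90 A above domain O
    resnames_b = ["ALA", "ALA", "ALA", "VAL", "SEP"]
    for m, resn in enumerate(resnames_b):
        xn = 8.0 * m + 2.9
        het = resn == "SEP"
        atoms += [
            Atom("B", 101 + m, "", resn, "N", "N", xn, 4.13, 0.0, het=het),
            Atom("B", 101 + m, "", resn, "CA", "C", xn + 1.45, 5.0, 0.0, het=het),
            Atom("B", 101 + m, "", resn, "C", "C", xn + 2.9, 4.13, 0.0, het=het),
            Atom("B", 101 + m, "", resn, "O", "O", xn + 2.9, 5.36, 0.0, het=het),
        ]
        if resn == "VAL":  # hydrophobic probe (residue B104)
            atoms.append(Atom("B", 101 + m, "", resn, "CG1", "C", 25.45, 5.5, 3.0))
        if resn == "SEP":  # phosphoserine side chain + phosphate
            atoms += [
                Atom("B", 101 + m, "", resn, "CB", "C", 36.35, 5.8, 1.0, het=True),
                Atom("B", 101 + m, "", resn, "OG", "O", 36.0, 6.6, 0.0, het=True),
                Atom("B", 101 + m, "", resn, "P", "P", 36.0, 8.0, 0.0, het=True),
                Atom("B", 101 + m, "", resn, "O1P", "O", 36.0, 9.45, 0.0, het=True),
                Atom("B", 101 + m, "", resn, "O2P", "O", 34.8, 7.3, 0.6, het=True),
                Atom("B", 101 + m, "", resn, "O3P", "O", 37.2, 7.3, -0.6, het=True),
            ]

    return StructureModel(
        atoms,
        metadata={
            "name": "synthetic toy domain-peptide complex",
            "planted": {
                "backbone_hbonds": 5,
                "hbond_distance_A": 2.9,
                "hydrophobic_contacts": 1,
                "hydrophobic_distance_A": 4.0,
                "charge_contacts": 1,
                "charge_distance_A": 3.8,
            },
            "domain_selection": "chain A",
            "peptide_selection": "chain B",
            "seed": cfg.seed if cfg is not None else None,
        },
    )
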