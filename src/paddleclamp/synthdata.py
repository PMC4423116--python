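"""Synthetic spectra, titrations, inhibition experiments and toy complexes.

Every downstream analysis in this package — partition and quenching
fits, occupancy inversion, SASA/grafting geometry — can be exercised on
data produced here, with known ground truth and seeded noise. The
generators emulate the statistical structure of the real experiments:

* Trp emission spectra (300-450 nm) that blue-shift and brighten with
  the membrane-bound fraction of toxin,
* lipid titrations following the mole-fraction partition model,
* linear Stern-Volmer acrylamide quenching,
* steady-state current pairs under the four-independent-site occupancy
  model,
* ideal alpha-helix + rigid toxin-placeholder 3-D complexes for the
  superposition, SASA and grafting code.

Noise is multiplicative Gaussian with a fixed relative SD (a shot-noise
approximation that keeps intensities positive at small SD); all
generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc

from .spectro import (
    AVAILABLE_FRACTION,
    WATER_MOLARITY,
    EmissionSpectrum,
    QuenchSeries,
    TitrationSeries,
    evaluate_partition_model,
)
from .occupancy import InhibitionRecord, fraction_unbound_model

__all__ = [
    "SpectrumParams",
    "PartitionScenario",
    "InhibitionScenario",
    "ToyComplexSpec",
    "gen_emission_spectrum",
    "gen_partition_titration",
    "gen_quench_titration",
    "gen_inhibition_experiment",
    "gen_toy_complex",
    "ideal_helix",
    "DEFAULT_LIPID_GRID_MM",
    "DEFAULT_ACRYLAMIDE_GRID_M",
]

#: Total-lipid grid (mM) spanning >2 decades around the half-saturation
#: point of mole-fraction coefficients near 5e6 (half-max available
#: lipid ~ 55.3/K ~ 1e-5 M ~ 0.02 mM total at 60% availability).
DEFAULT_LIPID_GRID_MM = (0.0, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 2.0)
#: Acrylamide grid (M) up to the 0.3 M working concentration.
DEFAULT_ACRYLAMIDE_GRID_M = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3)


@dataclass
class SpectrumParams:
    """Shape parameters of a synthetic Trp emission band."""

    lambda_max: float = 350.0  # nm
    width: float = 30.0        # nm
    amplitude: float = 1.0     # AU
    asymmetry: float = 0.25    # >0 skews the red tail, as real Trp bands do

    def __post_init__(self) -> None:
        if not 300 <= self.lambda_max <= 450:
            raise ValueError("lambda_max must lie in [300, 450] nm")
        if self.width <= 0 or self.amplitude <= 0:
            raise ValueError("width and amplitude must be positive")


@dataclass
class PartitionScenario:
    """Ground truth for a lipid-titration experiment."""

    K: float = 4.6e6
    f_max: float = 2.3
    lipid_grid_mM: tuple = DEFAULT_LIPID_GRID_MM
    available_fraction: float = AVAILABLE_FRACTION
    water_molarity: float = WATER_MOLARITY
    noise_sd: float = 0.0  # relative
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.lipid_grid_mM, dtype=float)
        if self.K <= 0:
            raise ValueError("K must be positive")
        if self.f_max <= 1:
            raise ValueError("f_max must exceed 1")
        if np.any(grid < 0) or 0.0 not in grid:
            raise ValueError("lipid grid must be non-negative and include 0")
        if not 0 < self.available_fraction <= 1:
            raise ValueError("available_fraction must be in (0, 1]")
        if self.water_molarity <= 0:
            raise ValueError("water_molarity must be positive")


@dataclass
class InhibitionScenario:
    """Ground truth for a four-site occupancy experiment."""

    kd_true_nM: float = 224.0
    toxin_concentrations_nM: tuple = (56.0, 112.0, 224.0, 454.0, 908.0)
    n_sites: int = 4
    voltages_mV: tuple = (-20.0, -10.0, 0.0, 10.0)
    i0_nA: float = 5.0
    noise_sd: float = 0.0  # relative, on currents
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kd_true_nM <= 0:
            raise ValueError("kd_true must be positive")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if np.any(np.asarray(self.toxin_concentrations_nM) <= 0):
            raise ValueError("toxin concentrations must be positive")


@dataclass
class ToyComplexSpec:
    """Geometry of a toy helix + rigid toxin-placeholder complex."""

    helix_length: int = 18            # residues
    helix_rise: float = 1.5           # Angstrom per residue
    helix_twist: float = 100.0        # degrees per residue
    toxin_atom_count: int = 24
    placement_offset: tuple = (8.0, 0.0, 0.0)  # Angstrom, from helix axis
    toxin_radius: float = 3.0         # Angstrom, placeholder ball radius
    seed: int = 0

    def __post_init__(self) -> None:
        if self.helix_length < 4:
            raise ValueError("helix needs at least 4 residues")
        if self.helix_rise <= 0:
            raise ValueError("rise must be positive")
        if not 0 < self.helix_twist < 180:
            raise ValueError("twist must be in (0, 180) degrees")
        if self.toxin_atom_count < 1:
            raise ValueError("toxin needs at least one atom")


def gen_emission_spectrum(
    params: SpectrumParams,
    grid=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> EmissionSpectrum:
    """Synthetic Trp emission band on a wavelength grid.

    The line shape is an asymmetric Gaussian: the width below the peak
    is ``width`` and above the peak ``width * (1 + asymmetry)``, giving
    the red-tailed band typical of Trp emission. Noiseless spectra peak
    exactly at ``params.lambda_max`` (up to grid resolution).
    """
    if grid is None:
        grid = np.arange(300.0, 451.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if grid[0] < 300 or grid[-1] > 450:
        raise ValueError("grid must lie within [300, 450] nm")
    d = grid - params.lambda_max
    w = np.where(d < 0, params.width, params.width * (1.0 + params.asymmetry))
    y = params.amplitude * np.exp(-0.5 * (d / w) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + noise_sd * rng.standard_normal(y.shape))
    return EmissionSpectrum(wavelengths=grid, intensities=np.clip(y, 0.0, None))


def gen_partition_titration(scenario: PartitionScenario) -> TitrationSeries:
    """Lipid titration following F/F0 = 1 + (f_max-1)*K[L]/([W]+K[L]).

    Noise is multiplicative Gaussian (relative SD ``noise_sd``); the
    zero-lipid point is left noise-free at exactly 1 to represent the
    normalisation reference.
    """
    grid = np.asarray(scenario.lipid_grid_mM, dtype=float)
    mean = np.asarray(evaluate_partition_model(
        scenario.K, scenario.f_max, grid,
        scenario.available_fraction, scenario.water_molarity,
    ))
    resp = mean.copy()
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        noise = 1.0 + scenario.noise_sd * rng.standard_normal(mean.shape)
        resp = mean * noise
        resp[grid == 0] = 1.0
    return TitrationSeries(
        lipid_total_mM=grid, response=resp,
        available_fraction=scenario.available_fraction,
        water_molarity=scenario.water_molarity,
    )


def gen_quench_titration(
    k_sv: float,
    quencher_grid_M=DEFAULT_ACRYLAMIDE_GRID_M,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> QuenchSeries:
    """Stern-Volmer series F0/F = 1 + K_sv*[Q] with seeded noise."""
    if k_sv < 0:
        raise ValueError("k_sv must be non-negative")
    q = np.asarray(quencher_grid_M, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative quencher concentration")
    mean = 1.0 + k_sv * q
    ratio = mean.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = mean * (1.0 + noise_sd * rng.standard_normal(mean.shape))
        ratio[q == 0] = 1.0
    return QuenchSeries(quencher_M=q, ratio=ratio)


def gen_inhibition_experiment(scenario: InhibitionScenario) -> list[InhibitionRecord]:
    """Paired steady-state currents under the n-site occupancy model.

    At each toxin concentration and weak-depolarisation voltage, the
    control current I0 is drawn around ``i0_nA`` and the equilibrium
    current is I = I0 * F_u with F_u = (K_d/(K_d+[T]))^n; current noise
    is multiplicative Gaussian on both I0 and I independently.
    """
    rng = np.random.default_rng(scenario.seed)
    records: list[InhibitionRecord] = []
    for conc in scenario.toxin_concentrations_nM:
        fu = fraction_unbound_model(conc, scenario.kd_true_nM, scenario.n_sites)
        for v in scenario.voltages_mV:
            i0 = scenario.i0_nA
            i = i0 * fu
            if scenario.noise_sd > 0:
                i0 = i0 * (1.0 + scenario.noise_sd * rng.standard_normal())
                i = i * (1.0 + scenario.noise_sd * rng.standard_normal())
            records.append(InhibitionRecord(
                toxin_nM=float(conc), voltage_mV=float(v),
                I0_nA=float(i0), I_nA=float(i),
            ))
    return records


def ideal_helix(
    n_res: int,
    rise: float = 1.5,
    twist: float = 100.0,
    radius: float = 2.3,
    chain_id: str = "A",
    res_name: str = "ALA",
) -> struc.AtomArray:
    """C-alpha trace of an ideal alpha-helix along +z.

    Residue i sits at angle i*twist and height i*rise on a cylinder of
    the given radius (2.3 A, the canonical C-alpha helix radius).
    """
    if n_res < 1:
        raise ValueError("need at least one residue")
    i = np.arange(n_res)
    ang = np.deg2rad(twist) * i
    coord = np.column_stack([
        radius * np.cos(ang), radius * np.sin(ang), rise * i,
    ])
    atoms = struc.AtomArray(n_res)
    atoms.coord = coord.astype(np.float32)
    atoms.chain_id = np.full(n_res, chain_id)
    atoms.res_id = i + 1
    atoms.res_name = np.full(n_res, res_name)
    atoms.atom_name = np.full(n_res, "CA")
    atoms.element = np.full(n_res, "C")
    atoms.hetero = np.zeros(n_res, dtype=bool)
    return atoms


def gen_toy_complex(spec: ToyComplexSpec) -> struc.AtomArray:
    """Toy complex: ideal helix (chain A) + rigid toxin ball (chain B).

    The toxin placeholder is a deterministic Fibonacci-sphere cloud of
    carbon atoms of radius ``toxin_radius`` centred at
    ``placement_offset`` from the helix midpoint, one atom per pseudo
    residue, so chain selections, clash screens and SASA all have
    something realistic to chew on.
    """
    helix = ideal_helix(spec.helix_length, spec.helix_rise, spec.helix_twist)

    n = spec.toxin_atom_count
    k = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.column_stack([
        r * np.cos(golden * k), r * np.sin(golden * k), z,
    ]) * spec.toxin_radius
    centre = np.array([0.0, 0.0, spec.helix_rise * (spec.helix_length - 1) / 2.0])
    pts = pts + centre + np.asarray(spec.placement_offset, dtype=float)

    toxin = struc.AtomArray(n)
    toxin.coord = pts.astype(np.float32)
    toxin.chain_id = np.full(n, "B")
    toxin.res_id = k + 1
    toxin.res_name = np.full(n, "TOX")
    toxin.atom_name = np.array([f"C{j+1}" for j in k])
    toxin.element = np.full(n, "C")
    toxin.hetero = np.ones(n, dtype=bool)
    return helix + toxin
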