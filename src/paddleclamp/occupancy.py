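"""Toxin occupancy energetics from steady-state ionic currents.

A voltage-sensor toxin bound to any one of a channel's four
voltage-sensing domains prevents opening at weak depolarisations, so the
ratio of steady-state currents before and after toxin equilibration
(I/I0, measured in a voltage window where toxin-bound channels stay
shut) directly reports the fraction of channels with no toxin bound:

    F_u = I/I0 = (K_d / (K_d + [T]))^n        (n = 4 independent sites)

which inverts exactly to the apparent dissociation constant

    K_d = (1 / (1 - F_u^(1/n)) - 1) * [T].

An alanine scan then converts the K_d of each point mutant into a
binding free-energy perturbation DDG = R*T*ln(K_d_mut / K_d_wt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE_K",
    "WEAK_DEPOL_WINDOW_MV",
    "InhibitionRecord",
    "KdEstimate",
    "DdgEntry",
    "GVCurve",
    "fraction_unbound",
    "fraction_unbound_model",
    "kd_four_site",
    "aggregate_kd",
    "ddg_from_kd",
    "fit_concentration_response",
    "gv_from_tails",
    "load_alanine_scan_table",
    "recompute_alanine_scan",
    "NoInhibitionError",
    "CompleteBlockError",
    "PlateauError",
]

#: Gas constant, kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3
#: Default analysis temperature, K.
DEFAULT_TEMPERATURE_K = 298.15
#: Depolarisation window (mV) where toxin-bound channels do not open.
WEAK_DEPOL_WINDOW_MV = (-20.0, 10.0)


class NoInhibitionError(ValueError):
    """F_u >= 1: the toxin produced no measurable inhibition."""


class CompleteBlockError(ValueError):
    """F_u <= 0: complete block, K_d not resolvable."""


class PlateauError(ValueError):
    """No voltages passed the plateau check."""


@dataclass
class InhibitionRecord:
    """One paired current measurement at one voltage and toxin dose."""

    toxin_nM: float
    voltage_mV: float
    I0_nA: float
    I_nA: float
    cell_id: str = ""
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.I0_nA <= 0:
            raise ValueError("control current I0 must be positive")

    @property
    def f_u(self) -> float:
        return self.I_nA / self.I0_nA


@dataclass
class KdEstimate:
    toxin_label: str
    kd_nM: float
    kd_sem_nM: float
    n_cells: int
    single_cell: bool = False


@dataclass
class DdgEntry:
    mutant: str
    ratio: float
    ddg_kcal_mol: float
    temperature_K: float = DEFAULT_TEMPERATURE_K


@dataclass
class GVCurve:
    voltages_mV: np.ndarray
    conductance: np.ndarray
    v_half_mV: float = float("nan")
    slope_mV: float = float("nan")
    degenerate: bool = False


def fraction_unbound_model(toxin_nM, kd_nM: float, n_sites: int = 4):
    """Forward model: F_u = (K_d / (K_d + [T]))^n."""
    t = np.asarray(toxin_nM, dtype=float)
    out = (kd_nM / (kd_nM + t)) ** n_sites
    return out if out.ndim else float(out)


def fraction_unbound(
    records: list[InhibitionRecord],
    plateau_tolerance: float = 0.10,
    voltage_window_mV: tuple[float, float] = WEAK_DEPOL_WINDOW_MV,
) -> dict[float, float]:
    """Average I/I0 over plateau voltages, per toxin concentration.

    Records are restricted to the weak-depolarisation window, sorted by
    voltage, and a plateau check drops voltages where F_u changes by
    more than ``plateau_tolerance`` (relative) from the adjacent lower
    voltage -- a rising F_u with V means toxin-bound channels have begun
    to open and the occupancy readout is no longer valid. Records with
    F_u > 1 + tolerance (current increased) are flagged, not clipped.
    """
    lo, hi = voltage_window_mV
    by_conc: dict[float, list[InhibitionRecord]] = {}
    for rec in records:
        if lo <= rec.voltage_mV <= hi:
            by_conc.setdefault(rec.toxin_nM, []).append(rec)
    if not by_conc:
        raise PlateauError("no records inside the weak-depolarisation window")
    out: dict[float, float] = {}
    for conc, recs in by_conc.items():
        recs.sort(key=lambda r: r.voltage_mV)
        fus = np.array([r.f_u for r in recs])
        for r, fu in zip(recs, fus):
            if fu > 1.0 + plateau_tolerance:
                r.flagged = True
        keep = np.ones(len(recs), dtype=bool)
        last = fus[0]
        for i in range(1, len(recs)):
            if last > 0 and abs(fus[i] - last) / last > plateau_tolerance:
                keep[i] = False
            else:
                last = fus[i]
        if not keep.any():
            raise PlateauError(f"empty plateau set at {conc} nM")
        out[conc] = float(fus[keep].mean())
    return out


def kd_four_site(F_u: float, toxin_nM: float, n_sites: int = 4) -> float:
    """Invert the n-independent-site occupancy model for K_d (nM).

    K_d = (1 / (1 - F_u^(1/n)) - 1) * [T]; exact algebraic inverse of
    ``fraction_unbound_model``.
    """
    if toxin_nM <= 0:
        raise ValueError("toxin concentration must be positive")
    if F_u >= 1:
        raise NoInhibitionError(f"F_u = {F_u} >= 1: no inhibition, K_d unbounded")
    if F_u <= 0:
        raise CompleteBlockError(f"F_u = {F_u} <= 0: complete block")
    root = F_u ** (1.0 / n_sites)
    return (1.0 / (1.0 - root) - 1.0) * toxin_nM


def aggregate_kd(kd_values, toxin_label: str = "") -> KdEstimate:
    """Mean and SEM of per-cell K_d values (SEM with n-1 denominator)."""
    vals = np.asarray(list(kd_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no K_d values to aggregate")
    n = int(vals.size)
    if n == 1:
        return KdEstimate(toxin_label, float(vals[0]), 0.0, 1, single_cell=True)
    sem = float(vals.std(ddof=1) / np.sqrt(n))
    return KdEstimate(toxin_label, float(vals.mean()), sem, n)


def ddg_from_kd(
    kd_mut_nM: float,
    kd_wt_nM: float,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    mutant: str = "",
) -> DdgEntry:
    """Binding free-energy perturbation DDG = R*T*ln(K_d_mut / K_d_wt)."""
    if kd_mut_nM <= 0 or kd_wt_nM <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    ratio = kd_mut_nM / kd_wt_nM
    ddg = GAS_CONSTANT_KCAL * temperature_K * float(np.log(ratio))
    return DdgEntry(mutant=mutant, ratio=float(ratio), ddg_kcal_mol=ddg,
                    temperature_K=temperature_K)


def fit_concentration_response(
    F_u, toxin_nM, n_sites: int = 4
) -> tuple[float, float]:
    """Fit K_d (nM) to F_u versus toxin concentration; returns (kd, stderr).

    A single point reduces exactly to the algebraic inversion.
    """
    fu = np.atleast_1d(np.asarray(F_u, dtype=float))
    t = np.atleast_1d(np.asarray(toxin_nM, dtype=float))
    if fu.shape != t.shape:
        raise ValueError("F_u and toxin concentration lengths differ")
    if fu.size == 1:
        return kd_four_site(float(fu[0]), float(t[0]), n_sites), 0.0
    if fu.size < 3:
        raise ValueError("need one point or at least 3 concentrations")
    # initialise from the point nearest half-root occupancy
    mid = int(np.argmin(np.abs(fu - 0.5**n_sites)))
    k0 = max(float(t[mid]), 1e-3)
    try:
        popt, pcov = curve_fit(
            lambda x, kd: fraction_unbound_model(x, kd, n_sites),
            t, fu, p0=[k0], bounds=(1e-9, np.inf), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"concentration-response fit failed: {err}") from err
    return float(popt[0]), float(np.sqrt(pcov[0, 0]))


def gv_from_tails(voltages_mV, tail_currents, fit_boltzmann: bool = True) -> GVCurve:
    """Normalised conductance-voltage relation from tail-current amplitudes.

    Conductance is the tail amplitude normalised to its maximum. The
    optional Boltzmann fit G/Gmax = 1/(1+exp(-(V-V1/2)/k)) is a summary
    convenience for activation-shift phenotypes.
    """
    v = np.asarray(voltages_mV, dtype=float)
    tails = np.asarray(tail_currents, dtype=float)
    if v.shape != tails.shape:
        raise ValueError("voltages and tails lengths differ")
    if np.any(np.diff(v) <= 0):
        raise ValueError("voltages must be increasing")
    gmax = tails.max()
    if gmax <= 0:
        raise ValueError("all-zero tail currents: degenerate G-V")
    g = tails / gmax
    curve = GVCurve(voltages_mV=v, conductance=g)
    if not fit_boltzmann:
        return curve
    if np.ptp(g) < 1e-6:
        curve.degenerate = True
        return curve
    v0 = float(np.interp(0.5, g, v)) if g[0] < 0.5 < g[-1] else float(v.mean())
    try:
        # free amplitude absorbs incomplete saturation of the max tail
        popt, _ = curve_fit(
            lambda x, vh, k, a: a / (1.0 + np.exp(-(x - vh) / k)),
            v, g, p0=[v0, 10.0, 1.0], maxfev=20000,
        )
        curve.v_half_mV, curve.slope_mV = float(popt[0]), float(popt[1])
    except RuntimeError:
        curve.degenerate = True
    return curve


# ---------------------------------------------------------------------------
# Alanine-scan table (printed apparent affinities for GxTx-1E mutants)

def load_alanine_scan_table() -> pd.DataFrame:
    """Packaged alanine-scan table: per-mutant K_d, SEM, fold-change, DDG.

    The wild-type row carries ratio 1.0 and no DDG. Columns:
    toxin, kd_nM, kd_sem_nM, ratio, ddg_kcal_mol.
    """
    with resources.files("paddleclamp.data").joinpath(
        "gxtx1e_alanine_scan.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def recompute_alanine_scan(
    table: pd.DataFrame | None = None,
    wt_label: str | None = None,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> pd.DataFrame:
    """Recompute fold-change and DDG from the K_d column of a scan table.

    Adds ``ratio_calc`` and ``ddg_calc`` columns next to the printed
    values so pre-rounding discrepancies are visible.
    """
    if table is None:
        table = load_alanine_scan_table()
    table = table.copy()
    if wt_label is None:
        wt_label = table.loc[table["ratio"] == 1.0, "toxin"].iloc[0]
    kd_wt = float(table.loc[table["toxin"] == wt_label, "kd_nM"].iloc[0])
    entries = [
        ddg_from_kd(kd, kd_wt, temperature_K, mutant=name)
        for name, kd in zip(table["toxin"], table["kd_nM"])
    ]
    table["ratio_calc"] = [e.ratio for e in entries]
    table["ddg_calc"] = [e.ddg_kcal_mol for e in entries]
    return table
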