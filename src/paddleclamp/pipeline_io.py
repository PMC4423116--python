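"""Shared table I/O, run configuration and the pipeline driver.

Tables are plain CSV (comma-separated, UTF-8, ``.`` decimal, header
mandatory) with units declared in the column names (``_nM``, ``_mM``,
``_mV`` ...), because the source experiments mix nM/uM/mM across
figures and silent unit drift is the classic failure mode here.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .occupancy import (
    DEFAULT_TEMPERATURE_K,
    InhibitionRecord,
    aggregate_kd,
    fraction_unbound,
    kd_four_site,
    recompute_alanine_scan,
)
from .spectro import (
    AVAILABLE_FRACTION,
    WATER_MOLARITY,
    QuenchSeries,
    TitrationSeries,
    fit_mole_fraction_partition,
    fit_stern_volmer,
)

__all__ = [
    "SCHEMAS",
    "SchemaError",
    "ParseError",
    "read_table",
    "write_titration",
    "write_quench",
    "write_inhibition_records",
    "RunConfig",
    "ResultBundle",
    "run_pipeline",
]

logger = logging.getLogger("paddleclamp")

#: Required columns per table schema.
SCHEMAS: dict[str, tuple[str, ...]] = {
    "titration": ("lipid_mM", "response"),
    "quench": ("quencher_M", "ratio"),
    "currents": ("cell_id", "toxin_nM", "voltage_mV", "I0_nA", "I_nA"),
    "kd_table": ("toxin", "kd_nM", "kd_sem_nM", "ratio", "ddg_kcal_mol"),
    "spectrum": ("wavelength_nm", "intensity"),
}


class SchemaError(ValueError):
    """A required column is missing."""


class ParseError(ValueError):
    """A cell failed to parse; carries the 1-based line number."""


def _validate_numeric(df: pd.DataFrame, columns, path, skip_bad: bool) -> pd.DataFrame:
    bad_rows: list[int] = []
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        bad_rows.extend(bad)
        df[col] = coerced
    bad_rows.extend(df.index[df[columns].isna().any(axis=1)].tolist())
    bad_rows = sorted(set(bad_rows))
    if bad_rows:
        lines = [i + 2 for i in bad_rows]  # +1 header, +1 one-based
        if not skip_bad:
            raise ParseError(f"{path}: non-numeric or missing cells at lines {lines}")
        logger.warning("%s: skipping %d bad rows at lines %s", path, len(lines), lines)
        df = df.drop(index=bad_rows).reset_index(drop=True)
    return df


def read_table(path, schema: str, skip_bad: bool = False):
    """Read and validate a CSV against a named schema.

    Returns the typed object the schema maps to: a
    :class:`~paddleclamp.spectro.TitrationSeries`, a
    :class:`~paddleclamp.spectro.QuenchSeries`, a list of
    :class:`~paddleclamp.occupancy.InhibitionRecord`, or a DataFrame
    for tabular schemas.
    """
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    numeric = [c for c in required if c not in ("cell_id", "toxin")]
    df = _validate_numeric(df, numeric, path, skip_bad)

    if schema == "titration":
        kwargs = {}
        if "available_fraction" in df.columns:
            kwargs["available_fraction"] = float(df["available_fraction"].iloc[0])
        if "water_molarity" in df.columns:
            kwargs["water_molarity"] = float(df["water_molarity"].iloc[0])
        return TitrationSeries(
            lipid_total_mM=df["lipid_mM"].to_numpy(),
            response=df["response"].to_numpy(),
            **kwargs,
        )
    if schema == "quench":
        return QuenchSeries(
            quencher_M=df["quencher_M"].to_numpy(),
            ratio=df["ratio"].to_numpy(),
        )
    if schema == "currents":
        return [
            InhibitionRecord(
                toxin_nM=float(r.toxin_nM), voltage_mV=float(r.voltage_mV),
                I0_nA=float(r.I0_nA), I_nA=float(r.I_nA), cell_id=str(r.cell_id),
            )
            for r in df.itertuples()
        ]
    return df


def write_titration(series: TitrationSeries, path) -> None:
    pd.DataFrame({
        "lipid_mM": series.lipid_total_mM,
        "response": series.response,
    }).to_csv(path, index=False)


def write_quench(series: QuenchSeries, path) -> None:
    pd.DataFrame({
        "quencher_M": series.quencher_M,
        "ratio": series.ratio,
    }).to_csv(path, index=False)


def write_inhibition_records(records, path) -> None:
    pd.DataFrame([
        {"cell_id": r.cell_id, "toxin_nM": r.toxin_nM, "voltage_mV": r.voltage_mV,
         "I0_nA": r.I0_nA, "I_nA": r.I_nA}
        for r in records
    ]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run configuration and pipeline driver

@dataclass
class RunConfig:
    """Declarative description of a pipeline run.

    ``stages`` maps stage names to their input tables; physical
    parameters default to the standard analysis conditions and are all
    overridable. The config serialises losslessly through JSON.
    """

    stages: dict = field(default_factory=dict)
    temperature_K: float = DEFAULT_TEMPERATURE_K
    available_fraction: float = AVAILABLE_FRACTION
    water_molarity: float = WATER_MOLARITY
    probe_radius_A: float = 1.4
    sasa_points: int = 960
    clash_cutoff_A: float = 2.5
    plateau_tolerance: float = 0.10
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("temperature_K", "available_fraction", "water_molarity",
                     "probe_radius_A", "clash_cutoff_A", "plateau_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Per-stage outputs plus provenance."""

    outputs: dict = field(default_factory=dict)
    config_digest: str = ""
    version: str = ""
    timestamp: float = 0.0

    def numeric_digest(self) -> str:
        """Hash of the numeric outputs only (provenance excluded), for
        determinism checks."""
        text = json.dumps(self.outputs, sort_keys=True, default=_jsonify)
        return hashlib.sha256(text.encode()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute the configured stages in dependency order.

    Supported stages (each an entry in ``config.stages``):

    * ``"partition"`` / ``"dequench"``: {"table": path} — fit K_x/K_dx.
    * ``"stern_volmer"``: {"table": path} — fit K_sv.
    * ``"occupancy"``: {"table": path} — currents to F_u and K_d.
    * ``"alanine_scan"``: {"table": path or null} — recompute the
      fold-change/DDG table (packaged reference table if null).

    Identical config + inputs give byte-identical numeric outputs.
    """
    logging.basicConfig(level=config.log_level)
    bundle = ResultBundle(config_digest=config.digest(), version=__version__,
                          timestamp=time.time())
    order = ["partition", "dequench", "stern_volmer", "occupancy", "alanine_scan"]
    for stage in order:
        if stage not in config.stages:
            continue
        spec = config.stages[stage] or {}
        logger.info("stage %s: %s", stage, spec)
        try:
            if stage in ("partition", "dequench"):
                series = read_table(spec["table"], "titration")
                series.available_fraction = config.available_fraction
                series.water_molarity = config.water_molarity
                fit = fit_mole_fraction_partition(
                    series, "partition" if stage == "partition" else "dequench"
                )
                bundle.outputs[stage] = {
                    "K": fit.K, "f_max": fit.f_max, "K_stderr": fit.K_stderr,
                    "f_max_stderr": fit.f_max_stderr, "rss": fit.rss,
                    "n_points": fit.n_points, "degenerate": fit.degenerate,
                }
            elif stage == "stern_volmer":
                series = read_table(spec["table"], "quench")
                fit = fit_stern_volmer(series)
                bundle.outputs[stage] = {
                    "k_sv": fit.k_sv, "intercept": fit.intercept,
                    "k_sv_stderr": fit.k_sv_stderr, "rss": fit.rss,
                }
            elif stage == "occupancy":
                records = read_table(spec["table"], "currents")
                fu = fraction_unbound(records, config.plateau_tolerance)
                kds = [kd_four_site(f, c) for c, f in sorted(fu.items()) if f < 1]
                est = aggregate_kd(kds, toxin_label=spec.get("label", ""))
                bundle.outputs[stage] = {
                    "f_u": {str(c): f for c, f in sorted(fu.items())},
                    "kd_nM": est.kd_nM, "kd_sem_nM": est.kd_sem_nM,
                    "n": est.n_cells,
                }
            elif stage == "alanine_scan":
                table = None
                if spec.get("table"):
                    table = read_table(spec["table"], "kd_table")
                out = recompute_alanine_scan(table, temperature_K=config.temperature_K)
                bundle.outputs[stage] = out.to_dict(orient="records")
        except Exception as err:
            raise RuntimeError(
                f"stage {stage!r} failed on input {spec!r}: {err}"
            ) from err
    return bundle
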