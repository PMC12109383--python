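"""Run configuration, study orchestration and consolidated reporting.

``run_study`` drives every analysis stage over a dataset directory (real
or synthetic, see :func:`quenchlab.study.write_study_dataset`), skipping
stages whose inputs are absent, and returns a :class:`StudyReport` that
serializes deterministically to JSON and renders the three summary tables
(quenching constants, thermodynamic parameters, secondary-structure
composition) as Markdown.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import antioxidant as ax
from . import cd as cdmod
from . import quenching, synchronous, thermo, titration
from .exceptions import ConfigError, DataError
from .spectra import read_spectra_long

__all__ = ["RunConfig", "StudyReport", "run_study", "REPORT_SCHEMA", "validate_report"]

logger = logging.getLogger("quenchlab")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one study run.

    All tunable defaults of the pipeline live here so a report can embed
    the exact configuration that produced it.
    """

    data_dir: str = "."
    tau0: float = quenching.TAU0_DEFAULT
    kq_threshold: float = quenching.KQ_DIFFUSION_LIMIT
    volume_convention: str = "nominal"
    response_mode: str = "peak"
    fix_intercept: bool = False
    epsilon_dh: float = 100.0
    epsilon_ds: float = 1.0
    stock_conc: float = 1e-3
    base_volume_L: float = 3.0e-3
    reported_dh: float | None = None  # J/mol, for discrepancy checking
    reported_ds: float | None = None  # J/(mol K)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau0 <= 0 or self.kq_threshold <= 0:
            raise ConfigError("tau0 and kq_threshold must be positive")
        if self.volume_convention not in ("nominal", "additive"):
            raise ConfigError(f"unknown volume convention {self.volume_convention!r}")
        if self.response_mode not in ("peak", "fixed_wavelength"):
            raise ConfigError(f"unknown response mode {self.response_mode!r}")

    @classmethod
    def from_toml(cls, path, **overrides) -> "RunConfig":
        """Load a flat TOML config; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update(overrides)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class StudyReport:
    """Consolidated study output: one JSON-serializable mapping."""

    data: dict

    def to_json(self) -> str:
        """Deterministic JSON: sorted keys, fixed separators."""
        return json.dumps(self.data, sort_keys=True, indent=1)

    def to_markdown(self) -> str:
        return render_markdown(self.data)


def _fit_dict(obj) -> dict:
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def run_study(config: RunConfig) -> StudyReport:
    """Execute every stage whose inputs exist under ``config.data_dir``.

    Expected files (all optional; missing ones mark the stage skipped):

    * ``titration_manifest.csv`` + referenced spectrum CSVs — quenching and
      thermodynamics;
    * ``sync_trp.csv`` / ``sync_tyr.csv`` — synchronous analysis;
    * ``cd_*.csv`` (+ optional ``basis.csv``) — CD deconvolution;
    * ``assay_reads.csv`` + ``trolox_standards.csv`` — TEAC.
    """
    root = Path(config.data_dir)
    logger.info(
        "defaults in force: tau0=%.3g s, volume_convention=%s, response_mode=%s",
        config.tau0,
        config.volume_convention,
        config.response_mode,
    )
    report: dict = {"config": config.as_dict(), "stages": {}, "warnings": []}
    caught: list[str] = []

    def _record(ws) -> None:
        caught.extend(f"{w.category.__name__}: {w.message}" for w in ws)

    # --- quenching + thermodynamics -------------------------------------
    manifest = root / "titration_manifest.csv"
    if manifest.exists():
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            by_temp = titration.read_titration_manifest(
                manifest, config.stock_conc, config.base_volume_L, config.volume_convention
            )
            sv_fits, dl_fits = [], []
            for temp in sorted(by_temp):
                table = titration.build_quench_table(
                    by_temp[temp], temp, config.response_mode
                )
                sv_fits.append(
                    quenching.stern_volmer_fit(table, config.tau0, config.fix_intercept)
                )
                dl_fits.append(quenching.double_log_fit(table))
            mech = quenching.classify_mechanism(sv_fits, config.kq_threshold)
        _record(ws)
        report["quenching"] = {
            "per_temperature": [
                {"stern_volmer": _fit_dict(sv), "double_log": _fit_dict(dl)}
                for sv, dl in zip(sv_fits, dl_fits)
            ],
            "mechanism": _fit_dict(mech),
        }
        report["stages"]["quenching"] = "ok"

        if len(dl_fits) >= 2:
            vh = thermo.vant_hoff([(f.temperature, f.ka) for f in dl_fits])
            notes = thermo.discrepancy_notes(vh, config.reported_dh, config.reported_ds)
            gibbs_rows = [
                dataclasses.asdict(thermo.gibbs(vh.dh, vh.ds, f.temperature))
                for f in dl_fits
            ]
            for row, f in zip(gibbs_rows, dl_fits):
                row["spontaneous"] = bool(row["dg"] < 0)
            force = thermo.classify_forces(
                vh.dh, vh.ds, config.epsilon_dh, config.epsilon_ds
            )
            report["thermo"] = {
                "vant_hoff": _fit_dict(vh),
                "gibbs": gibbs_rows,
                "forces": _fit_dict(force),
                "notes": notes,
            }
            report["stages"]["thermo"] = "ok"
        else:
            report["stages"]["thermo"] = "skipped"
            logger.info("thermo stage skipped: fewer than 2 temperatures")
    else:
        report["stages"]["quenching"] = "skipped"
        report["stages"]["thermo"] = "skipped"
        logger.info("quenching stage skipped: no titration manifest")

    # --- synchronous ----------------------------------------------------
    trp_path, tyr_path = root / "sync_trp.csv", root / "sync_tyr.csv"
    if trp_path.exists() and tyr_path.exists():
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            summaries = {}
            for path, dl in ((trp_path, 60.0), (tyr_path, 15.0)):
                spectra = read_spectra_long(path)
                pairs = tuple(
                    (float(s.meta[titration.LIGAND_CONC_KEY]), s)
                    for s in spectra.values()
                )
                series = synchronous.SyncSeries(dl, pairs)
                summaries[series.residue_label] = synchronous.analyze_sync(series)
            comparison = synchronous.compare_contributions(
                summaries["Trp"], summaries["Tyr"]
            )
        _record(ws)
        report["synchronous"] = {
            "Trp": _fit_dict(summaries["Trp"]),
            "Tyr": _fit_dict(summaries["Tyr"]),
            "comparison": comparison,
        }
        report["stages"]["synchronous"] = "ok"
    else:
        report["stages"]["synchronous"] = "skipped"
        logger.info("synchronous stage skipped: sync CSVs absent")

    # --- CD -------------------------------------------------------------
    cd_paths = sorted(root.glob("cd_*.csv"))
    if cd_paths:
        basis_path = root / "basis.csv"
        basis = cdmod.read_basis_csv(basis_path) if basis_path.exists() else None
        fractions = {}
        for path in cd_paths:
            label = path.stem.removeprefix("cd_")
            spec = cdmod.read_cd_csv(path)
            fractions[label] = cdmod.deconvolve(spec, basis)
        labels = list(fractions)
        deltas = {}
        if len(labels) >= 2:
            deltas = cdmod.composition_delta(fractions[labels[0]], fractions[labels[-1]])
        report["cd"] = {
            "fractions_by_ratio": {
                k: {**v.as_dict(), "residual_norm": v.residual_norm}
                for k, v in fractions.items()
            },
            "delta_first_to_last": deltas,
        }
        report["stages"]["cd"] = "ok"
    else:
        report["stages"]["cd"] = "skipped"
        logger.info("cd stage skipped: no cd_*.csv files")

    # --- antioxidant ----------------------------------------------------
    reads_path, std_path = root / "assay_reads.csv", root / "trolox_standards.csv"
    if reads_path.exists() and std_path.exists():
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            reads_df = pd.read_csv(reads_path)
            std_df = pd.read_csv(std_path)
            teac: dict = {}
            curves: dict = {}
            for assay, grp in std_df.groupby("assay"):
                kind = "reducing_power" if assay == "FRAP" else "percent_rate"
                curves[assay] = ax.calibrate_trolox(
                    list(zip(grp["trolox_mg_per_L"], grp["response"])), kind
                )
            for (assay, sample), grp in reads_df.groupby(["assay", "sample_id"]):
                roles = dict(zip(grp["role"], grp["absorbance"].astype(float)))
                read = ax.AssayRead(assay=assay, absorbances=roles, sample_id=sample)
                resp = ax.assay_response(read)
                if assay not in curves:
                    raise DataError(f"no Trolox standards for assay {assay!r}")
                result = ax.to_teac(resp, curves[assay])
                teac.setdefault(assay, {})[sample] = dataclasses.asdict(result)
        _record(ws)
        report["antioxidant"] = {
            "curves": {k: dataclasses.asdict(v) for k, v in curves.items()},
            "teac": teac,
        }
        report["stages"]["antioxidant"] = "ok"
    else:
        report["stages"]["antioxidant"] = "skipped"
        logger.info("antioxidant stage skipped: assay CSVs absent")

    report["warnings"] = sorted(set(caught))
    validate_report(report)
    return StudyReport(report)


# A deliberately small structural schema (JSON Schema draft-7 subset):
# enough to catch a malformed report, validated on every run.
REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["config", "stages", "warnings"],
    "properties": {
        "config": {"type": "object"},
        "stages": {"type": "object"},
        "warnings": {"type": "array", "items": {"type": "string"}},
        "quenching": {
            "type": "object",
            "required": ["per_temperature", "mechanism"],
            "properties": {
                "per_temperature": {"type": "array", "items": {"type": "object"}},
                "mechanism": {"type": "object"},
            },
        },
        "thermo": {
            "type": "object",
            "required": ["vant_hoff", "gibbs", "forces", "notes"],
        },
        "synchronous": {"type": "object", "required": ["Trp", "Tyr", "comparison"]},
        "cd": {"type": "object", "required": ["fractions_by_ratio"]},
        "antioxidant": {"type": "object", "required": ["curves", "teac"]},
    },
}

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "number": (int, float),
    "boolean": bool,
}


def validate_report(data, schema: dict | None = None, path: str = "$") -> None:
    """Validate a report against :data:`REPORT_SCHEMA` (subset of JSON Schema).

    Supports ``type``, ``required``, ``properties`` and ``items``; raises
    :class:`DataError` on the first violation.
    """
    schema = REPORT_SCHEMA if schema is None else schema
    expected = schema.get("type")
    if expected and not isinstance(data, _TYPES[expected]):
        raise DataError(f"{path}: expected {expected}, got {type(data).__name__}")
    if expected == "object":
        for key in schema.get("required", []):
            if key not in data:
                raise DataError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in data:
                validate_report(data[key], sub, f"{path}.{key}")
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(data):
            validate_report(item, schema["items"], f"{path}[{i}]")


def render_markdown(report: dict) -> str:
    """Render the quenching / thermodynamics / CD summary tables as Markdown."""
    lines: list[str] = ["# Study report", ""]
    if "quenching" in report:
        lines += [
            "## Quenching constants and binding parameters",
            "",
            "| T (K) | Ksv (L/mol) | Kq (L/mol/s) | R (SV) | n | Ka (L/mol) | R (dl) |",
            "|---|---|---|---|---|---|---|",
        ]
        for row in report["quenching"]["per_temperature"]:
            sv, dl = row["stern_volmer"], row["double_log"]
            lines.append(
                f"| {sv['temperature']:g} | {sv['ksv']:.3g} | {sv['kq']:.3g} "
                f"| {sv['r']:.4f} | {dl['n']:.3f} | {dl['ka']:.3g} | {dl['r']:.4f} |"
            )
        mech = report["quenching"]["mechanism"]
        lines += ["", f"Mechanism: **{mech['label']}** "
                  f"(min Kq = {mech['min_kq']:.3g} L/mol/s, "
                  f"Ksv trend {mech['ksv_temperature_trend']})", ""]
    if "thermo" in report:
        vh = report["thermo"]["vant_hoff"]
        lines += [
            "## Thermodynamic parameters",
            "",
            "| T (K) | dH (kJ/mol) | dG (kJ/mol) | dS (J/mol/K) |",
            "|---|---|---|---|",
        ]
        for row in report["thermo"]["gibbs"]:
            lines.append(
                f"| {row['temperature']:g} | {vh['dh'] / 1000:.2f} "
                f"| {row['dg'] / 1000:.2f} | {vh['ds']:.2f} |"
            )
        lines += ["", f"Dominant force: **{report['thermo']['forces']['label']}**"]
        for note in report["thermo"]["notes"]:
            lines.append(f"- NOTE: {note}")
        lines.append("")
    if "cd" in report:
        lines += [
            "## Secondary-structure composition",
            "",
            "| ratio | alpha-helix (%) | beta-sheet (%) | beta-turn (%) | random coil (%) |",
            "|---|---|---|---|---|",
        ]
        for label, frac in report["cd"]["fractions_by_ratio"].items():
            lines.append(
                f"| {label} | {frac['alpha_helix'] * 100:.1f} | "
                f"{frac['beta_sheet'] * 100:.1f} | {frac['beta_turn'] * 100:.1f} | "
                f"{frac['random_coil'] * 100:.1f} |"
            )
        lines.append("")
    return "\n".join(lines)
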