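"""Configuration-driven orchestration of the full analysis.

Ingests a sample sheet (leaflet compositions, ion conditions, normalization
data, explicit asymmetric/symmetric pairing), per-sample time-course CSVs
and a curvature table; fits normalized hydrolysis rates, forms the ratio
r = k_asym / k_sym per pair, computes the differential activation work
DeltaW from the allosteric model, and either fits DeltaG0 or flags the pair
as non-conforming with the signed shift that would be required.  Reports
are written as JSON and TSV with fixed ordering and 9-significant-digit
floats, so re-running an identical configuration yields byte-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import allosteric, kinetics
from .allosteric import (
    DEFAULT_DG0_BAND,
    ShapeChange,
    NonConformingError,
    UnidentifiableError,
    conformance,
    differential_work,
)
from .composition import BilayerComposition, make_bilayer
from .curvature import CurvatureTable, read_curvature_table, write_curvature_table
from .kinetics import (
    DEFAULT_PLATEAU_POINTS,
    DEFAULT_R2_THRESHOLD,
    NormalizationRecord,
    RateFit,
    fit_rate,
    normalize_rate,
    rate_ratio,
    read_timecourse_csv,
    write_timecourse_csv,
)
from .synthetic import StudyBundle, simulate_timecourse

__all__ = [
    "RunConfig",
    "PipelineError",
    "run_pipeline",
    "write_study_inputs",
    "REPORT_SCHEMA_VERSION",
]

logger = logging.getLogger("lipasym")

REPORT_SCHEMA_VERSION = "1"


class PipelineError(ValueError):
    """Raised on configuration or pairing problems."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    sample_sheet: Path
    curvature_csv: Path
    output_dir: Path
    kappa_csv: Path | None = None
    timecourse_dir: Path | None = None  # default: sample-sheet directory
    r2_threshold: float = DEFAULT_R2_THRESHOLD
    plateau_points: int = DEFAULT_PLATEAU_POINTS
    time_unit: str | None = None
    dG0_band_kBT: tuple[float, float] = DEFAULT_DG0_BAND
    shape: ShapeChange = field(default_factory=ShapeChange)
    electrostatic_shift_kBT: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r2_threshold <= 1.0):
            raise PipelineError("r2_threshold must be in (0, 1]")
        for name in ("sample_sheet", "curvature_csv", "output_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.kappa_csv is not None:
            self.kappa_csv = Path(self.kappa_csv)
        if self.timecourse_dir is None:
            self.timecourse_dir = self.sample_sheet.parent
        self.timecourse_dir = Path(self.timecourse_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        shape = raw.pop("shape", None)
        if shape is not None:
            raw["shape"] = ShapeChange(
                slope_inner_A=float(shape.get("s_inner_A", -5.0)),
                slope_outer_A=float(shape.get("s_outer_A", 5.0)),
            )
        band = raw.pop("dG0_band_kBT", None)
        if band is not None:
            raw["dG0_band_kBT"] = (float(band[0]), float(band[1]))
        return cls(**raw)


def _round9(x: float | None) -> float | None:
    """9-significant-digit float for stable report serialization."""
    return None if x is None else float(f"{float(x):.9g}")


def _load_samples(config: RunConfig) -> tuple[dict[str, dict], list[dict], dict]:
    sheet = yaml.safe_load(config.sample_sheet.read_text())
    if not isinstance(sheet, Mapping) or "samples" not in sheet:
        raise PipelineError("sample sheet must be a mapping with a 'samples' list")
    samples = {s["label"]: s for s in sheet["samples"]}
    pairs = sheet.get("pairs", [])
    reference = sheet.get(
        "reference", {"lipid_concentration_mM": 1.0, "protein_copies": 1.0}
    )
    if not pairs:
        raise PipelineError("sample sheet declares no asym/sym pairs")
    for pair in pairs:
        for role in ("asym", "sym"):
            if pair.get(role) not in samples:
                raise PipelineError(
                    f"unmatched pair: sample {pair.get(role)!r} ({role}) is not "
                    f"in the sheet"
                )
    return samples, pairs, reference


def _fit_sample(
    sample: Mapping[str, Any], config: RunConfig, reference: Mapping[str, float]
) -> RateFit:
    tc_path = config.timecourse_dir / sample["timecourse"]
    tc = read_timecourse_csv(
        str(tc_path),
        label=sample["label"],
        ion=sample.get("ion", "none"),
        concentration_mM=float(sample.get("concentration_mM", 0.0)),
        time_unit=config.time_unit,
    )
    fit = fit_rate(
        tc,
        x0=sample.get("x0"),
        x_inf=sample.get("x_inf"),
        r2_threshold=config.r2_threshold,
        plateau_points=config.plateau_points,
    )
    norm = NormalizationRecord(
        lipid_concentration_mM=float(sample.get("lipid_concentration_mM", 1.0)),
        protein_copies=float(sample.get("protein_copies", 1.0)),
        reference_lipid_concentration_mM=float(
            reference.get("lipid_concentration_mM", 1.0)
        ),
        reference_protein_copies=float(reference.get("protein_copies", 1.0)),
    )
    logger.info(
        "fitted %s: k=%.6g 1/s (window %s, R^2=%.4f)",
        sample["label"],
        fit.k,
        fit.window,
        fit.r_squared,
    )
    return normalize_rate(fit, norm)


def _bilayer_of(sample: Mapping[str, Any]) -> BilayerComposition:
    return make_bilayer(sample["inner"], sample["outer"], label=sample["label"])


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write report.json / report.tsv.

    Every reported number is produced by the composition, curvature,
    kinetics or allosteric modules; this layer only routes data.
    """
    samples, pairs, reference = _load_samples(config)
    table = read_curvature_table(
        str(config.curvature_csv),
        str(config.kappa_csv) if config.kappa_csv else None,
    )
    results = []
    for pair in pairs:
        asym_s, sym_s = samples[pair["asym"]], samples[pair["sym"]]
        asym_fit = _fit_sample(asym_s, config, reference)
        sym_fit = _fit_sample(sym_s, config, reference)
        bilayer = _bilayer_of(asym_s)
        work = differential_work(
            bilayer,
            config.shape,
            table,
            ion=asym_s.get("ion", "none"),
            concentration_mM=float(asym_s.get("concentration_mM", 0.0)),
        )
        entry: dict[str, Any] = {
            "pair": f"{pair['asym']} / {pair['sym']}",
            "asym_label": pair["asym"],
            "sym_label": pair["sym"],
            "ion": asym_s.get("ion", "none"),
            "concentration_mM": _round9(float(asym_s.get("concentration_mM", 0.0))),
            "k_asym_per_s": _round9(asym_fit.k),
            "k_asym_stderr": _round9(asym_fit.stderr_k),
            "k_sym_per_s": _round9(sym_fit.k),
            "k_sym_stderr": _round9(sym_fit.stderr_k),
            "delta_W_kBT": _round9(work.delta_W),
        }
        if sym_fit.k <= 0:
            entry.update(r=None, r_stderr=None, status="undefined-ratio")
            results.append(entry)
            continue
        r, r_err = rate_ratio(asym_fit, sym_fit)
        entry["r"] = _round9(r)
        entry["r_stderr"] = _round9(r_err)
        report = conformance(r, work.delta_W, config.dG0_band_kBT)
        entry["attainable_r_interval"] = [
            _round9(report.attainable[0]),
            _round9(report.attainable[1]),
        ]
        entry["band_conforming"] = report.conforming
        entry["required_shift_kBT"] = _round9(report.required_shift_kBT)
        if work.delta_W == 0.0:
            # r is pinned to 1 for every DeltaG0; nothing to fit
            entry["status"] = "unidentifiable"
            entry["dG0_fit_kBT"] = None
        else:
            try:
                entry["dG0_fit_kBT"] = _round9(
                    allosteric.fit_dG0(r, work.delta_W)
                )
                entry["status"] = "conforming"
            except NonConformingError:
                # e.g. observed r > 1 while DeltaW > 0: outside the model
                entry["dG0_fit_kBT"] = None
                entry["status"] = "non-conforming"
        results.append(entry)

    report_obj = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "dG0_band_kBT": [_round9(config.dG0_band_kBT[0]), _round9(config.dG0_band_kBT[1])],
        "shape": {
            "s_inner_A": _round9(config.shape.slope_inner_A),
            "s_outer_A": _round9(config.shape.slope_outer_A),
        },
        "r2_threshold": _round9(config.r2_threshold),
        "electrostatic_shift_kBT": _round9(config.electrostatic_shift_kBT),
        "pairs": results,
    }
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out_json = config.output_dir / "report.json"
    out_json.write_text(
        json.dumps(report_obj, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
    tsv_cols = [
        "asym_label",
        "sym_label",
        "ion",
        "concentration_mM",
        "k_asym_per_s",
        "k_sym_per_s",
        "r",
        "r_stderr",
        "delta_W_kBT",
        "dG0_fit_kBT",
        "required_shift_kBT",
        "status",
    ]
    pd.DataFrame(results).reindex(columns=tsv_cols).to_csv(
        config.output_dir / "report.tsv", sep="\t", index=False
    )
    logger.info("wrote %s", out_json)
    return report_obj


def write_study_inputs(bundle: StudyBundle, outdir: str | Path) -> RunConfig:
    """Materialize a synthetic study as pipeline-ready files.

    Writes one time-course CSV per sample, the curvature table CSV, a
    sample sheet pairing each asymmetric sample with its symmetric
    counterpart, and a ground-truth ledger (truth.json) for validation.
    Returns a RunConfig pointing at the files.
    """
    outdir = Path(outdir)
    tc_dir = outdir / "timecourses"
    tc_dir.mkdir(parents=True, exist_ok=True)

    def _slug(label: str) -> str:
        return label.replace("/", "-").replace("|", "_").replace(" ", "")

    sheet: dict[str, Any] = {
        "samples": [],
        "pairs": [],
        "reference": {"lipid_concentration_mM": 1.0, "protein_copies": 1.0},
    }
    for pair in bundle.pairs:
        for role, spec in (("asym", pair.asym), ("sym", pair.sym)):
            tc = simulate_timecourse(spec)
            fname = f"{_slug(spec.label)}.csv"
            write_timecourse_csv(tc, str(tc_dir / fname))
            sheet["samples"].append(
                {
                    "label": spec.label,
                    "timecourse": f"timecourses/{fname}",
                    "inner": {k: float(v) for k, v in spec.bilayer.inner.items()},
                    "outer": {k: float(v) for k, v in spec.bilayer.outer.items()},
                    "ion": spec.ion,
                    "concentration_mM": float(spec.concentration_mM),
                    "lipid_concentration_mM": 1.0,
                    "protein_copies": 1.0,
                    "x_inf": float(spec.x_inf),
                }
            )
        sheet["pairs"].append({"asym": pair.asym.label, "sym": pair.sym.label})

    sheet_path = outdir / "samples.yaml"
    sheet_path.write_text(yaml.safe_dump(sheet, sort_keys=False))
    curv_path = outdir / "curvature.csv"
    write_curvature_table(bundle.curvature_table, str(curv_path))
    truth = bundle.ledger().to_dict(orient="records")
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return RunConfig(
        sample_sheet=sheet_path,
        curvature_csv=curv_path,
        output_dir=outdir / "report",
        timecourse_dir=outdir,
        shape=bundle.shape,
        seed=bundle.seed,
    )
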