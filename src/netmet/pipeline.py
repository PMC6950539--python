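"""End-to-end orchestration: simulate -> preprocess -> quantify -> model.

A single YAML config (seed mandatory) drives every stage; all stage RNGs are
derived from the master seed by stable sub-seeding so one number reproduces
the whole run.  Outputs are plain text (CSV/TSV/JSON) plus a run summary
recording the config hash, per-stage status and the file inventory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adema import run_adema
from .cohort import (CohortConfig, SynthesisParams, generate_cohort,
                     simulate_cohort_spectra)
from .multivariate import run_model_suite
from .panel import MetabolitePanel, default_network, default_panel, load_network
from .quantify import (ReferenceCalibration, build_quant_table,
                       reference_calibration_from_template)
from .spectra import (AcquisitionParams, Spectrum, build_bucket_table,
                      normalize_by_weight, read_spectrum,
                      reference_to_lactate, scale_unit_variance,
                      write_spectrum)
from .univariate import screen_metabolites

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunSummary", "cmd_simulate", "cmd_run_all",
           "configure_logging"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def configure_logging(verbose: bool = False, json_path: Path | None = None):
    """Human-readable log lines, plus an optional JSON event stream."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if json_path is not None:
        class _JsonHandler(logging.FileHandler):
            def emit(self, record):
                payload = {"t": record.created, "level": record.levelname,
                           "logger": record.name, "msg": record.getMessage()}
                self.stream.write(json.dumps(payload) + "\n")
        handlers.append(_JsonHandler(json_path, mode="a"))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers, force=True,
    )


@dataclass
class RunConfig:
    """Everything a pipeline run needs; seed is mandatory."""

    seed: int
    outdir: Path = Path("netmet_run")
    cohort: CohortConfig | None = None
    synthesis: SynthesisParams | None = None
    acquisition: AcquisitionParams | None = None
    panel_path: Path | None = None  # None -> builtin panel
    network_path: Path | None = None  # None -> builtin network
    ref_nmol: float = 19.3
    ref_integral: float | None = None  # None -> simulated reference scan
    bucket_range: tuple[float, float] = (0.70, 7.50)
    bucket_width: float = 0.01
    exclude_water: tuple[float, float] | None = (4.5, 5.1)
    n_folds: int = 7
    adema_epsilon: float = 0.05
    adema_min_z: float = 1.75
    univariate_field: str = "grade"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.outdir = Path(self.outdir)
        for p in (self.panel_path, self.network_path):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"referenced path does not exist: {p}")
        if self.cohort is None:
            self.cohort = CohortConfig(seed=_subseed(self.seed, 0))
        if self.synthesis is None:
            self.synthesis = SynthesisParams()
        if self.acquisition is None:
            self.acquisition = AcquisitionParams()

    @classmethod
    def from_yaml(cls, path, seed: int | None = None,
                  outdir: Path | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if seed is not None:
            raw["seed"] = seed
        if "seed" not in raw:
            raise ConfigError("config must provide a seed")
        if outdir is not None:
            raw["outdir"] = outdir
        cohort_kw = raw.pop("cohort", {})
        synth_kw = raw.pop("synthesis", {})
        acq_kw = raw.pop("acquisition", {})
        cfg = cls(**raw)
        if cohort_kw:
            cohort_kw.setdefault("seed", _subseed(cfg.seed, 0))
            cfg.cohort = CohortConfig(**cohort_kw)
        if synth_kw:
            cfg.synthesis = SynthesisParams(**synth_kw)
        if acq_kw:
            cfg.acquisition = AcquisitionParams(**acq_kw)
        return cfg

    def panel(self) -> MetabolitePanel:
        if self.panel_path is not None:
            return MetabolitePanel.from_csv(self.panel_path)
        return default_panel()

    def network(self):
        if self.network_path is not None:
            return load_network(self.network_path, self.panel().names)
        return default_network()

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _subseed(master: int, stage: int) -> int:
    return int(np.random.SeedSequence([master, stage]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class RunSummary:
    version: str
    config_hash: str
    stages: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def cmd_simulate(config: RunConfig) -> dict[str, Path]:
    """Write manifest, ground truth and one spectrum file per sample."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest, truth = generate_cohort(config.cohort)
    manifest.to_csv(out / "manifest.csv", index=False)
    truth.to_csv(out / "ground_truth.csv")
    spec_dir = out / "spectra"
    spec_dir.mkdir(exist_ok=True)
    spectra = simulate_cohort_spectra(
        manifest, truth, acq=config.acquisition, synth=config.synthesis,
        seed=_subseed(config.seed, 1),
    )
    for s in spectra:
        write_spectrum(s, spec_dir / f"{s.sample_id}.txt")
    log.info("simulate: %d samples -> %s", len(manifest), out)
    return {"manifest": out / "manifest.csv",
            "ground_truth": out / "ground_truth.csv",
            "spectra_dir": spec_dir}


def _load_spectra(spec_dir: Path) -> list[Spectrum]:
    return [read_spectrum(p) for p in sorted(spec_dir.glob("*.txt"))]


def cmd_run_all(config: RunConfig) -> RunSummary:
    """Execute the full pipeline; failures abort downstream stages but the
    summary is always written."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(version=__version__, config_hash=config.config_hash())
    panel = config.panel()
    t0 = time.time()

    def _stage(name, fn):
        if any(v.startswith("failed") for v in summary.stages.values()):
            summary.stages[name] = "skipped"
            return None
        try:
            result = fn()
            summary.stages[name] = "ok"
            return result
        except Exception as exc:  # noqa: BLE001 - summary must still be written
            log.exception("stage %s failed", name)
            summary.stages[name] = f"failed: {exc}"
            return None

    files = _stage("simulate", lambda: cmd_simulate(config))
    state: dict = {}

    def _preprocess():
        spectra = _load_spectra(files["spectra_dir"])
        referenced = [reference_to_lactate(s) for s in spectra]
        state["referenced"] = referenced
        normalized = [normalize_by_weight(s) for s in referenced]
        lo, hi = config.bucket_range
        table = build_bucket_table(normalized, lo, hi, config.bucket_width,
                                   exclude_water=config.exclude_water)
        table = scale_unit_variance(table)
        table.to_tsv(out / "buckets.tsv")
        state["buckets"] = table
        return table

    _stage("preprocess", _preprocess)

    def _quantify():
        from .panel import default_templates
        cal = (
            ReferenceCalibration(config.ref_nmol, config.ref_integral)
            if config.ref_integral is not None
            else reference_calibration_from_template(
                default_templates()["lactate"], panel.window("lactate"),
                config.ref_nmol, grid=config.synthesis.grid,
            )
        )
        qt = build_quant_table(state["referenced"], panel, cal)
        qt.to_csv(out / "quant_table.csv")
        state["quant"] = qt
        return qt

    _stage("quantify", _quantify)

    manifest = pd.read_csv(out / "manifest.csv") if files else None

    def _multivariate():
        table = state["buckets"].to_frame()
        suite = run_model_suite(table, manifest, n_folds=config.n_folds,
                                seed=_subseed(config.seed, 2))
        report = {
            name: {k: entry[k] for k in ("r2y", "q2", "n_components", "classes")}
            | {"n_vip_selected": len(entry["vip_selected"])}
            for name, entry in suite.items()
        }
        (out / "plsda_report.json").write_text(json.dumps(report, indent=2))
        for name, entry in suite.items():
            m = entry["model"]
            pd.DataFrame(m.x_scores,
                         index=None).to_csv(out / f"scores_{name}.csv",
                                            index=False)
        summary.metrics["plsda"] = report
        return suite

    _stage("multivariate", _multivariate)

    def _univariate():
        primaries = manifest[manifest.tissue_class == "primary_tumor"]
        screen = screen_metabolites(
            state["quant"].loc[
                state["quant"].index.isin(primaries.sample_id)
            ],
            primaries, config.univariate_field,
        )
        screen.to_csv(out / "univariate_grade.csv")
        summary.metrics["univariate_significant"] = (
            screen.index[screen.significant].tolist()
        )
        return screen

    _stage("univariate", _univariate)

    def _adema():
        dm = run_adema(state["quant"], manifest, net=config.network(),
                       epsilon=config.adema_epsilon,
                       min_z=config.adema_min_z)
        dm.to_csv(out / "direction_matrix.csv")
        dm.dump_evidence(out / "adema_evidence.json")
        summary.metrics["direction_matrix_shape"] = list(dm.calls.shape)
        return dm

    _stage("adema", _adema)

    for p in sorted(out.glob("*")):
        if p.is_file():
            summary.outputs[p.name] = str(p)
    summary.metrics["wall_s"] = round(time.time() - t0, 2)
    summary.write(out / "run_summary.json")
    return summary
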