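"""End-to-end orchestration: simulate/load -> pretreat -> split -> GFA ->
fit -> validate -> Y-randomize -> applicability domain -> screen.

A :class:`PipelineConfig` is the single reproducibility contract: one
declarative document (YAML or dict) carrying every stage's parameters
plus a global seed.  ``run_pipeline`` executes the chain, writes each
stage's artefact under the output directory and returns a manifest;
every output embeds a provenance block (config hash, seed, package
version).  Deterministic stages are bit-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import QSARDataset, QSARError
from .design import screen
from .domain import williams
from .gfa import GFAConfig, gfa_search
from .io import load_activity, load_descriptor_table, save_model
from .kennard_stone import ks_split
from .mlr import fit_ols
from .pretreat import pretreat
from .synthetic import SyntheticSpec, generate
from .validation import validate_model
from .yrand import y_randomize

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(QSARError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    # data source: either synthetic generation or a pair of CSV paths
    descriptor_csv: str | None = None
    activity_csv: str | None = None
    synthetic: dict = field(default_factory=dict)
    # stage parameters
    correlation_cutoff: float = 0.7
    variance_tol: float = 1e-8
    train_fraction: float = 0.7
    gfa: dict = field(default_factory=dict)
    n_permutations: int = 10
    benchmarks: dict = field(default_factory=dict)
    ic50_max_uM: float | None = None

    def validate(self) -> tuple["SyntheticSpec | None", GFAConfig]:
        """Resolve and type-check every stage's parameters up front."""
        if (self.descriptor_csv is None) != (self.activity_csv is None):
            raise PipelineError("config: descriptor_csv and activity_csv must be given together")
        spec = None
        if self.descriptor_csv is None:
            spec = SyntheticSpec(**{"seed": self.seed, **self.synthetic})
        gfa_cfg = GFAConfig(**{"seed": self.seed, **self.gfa})
        if not (0 < self.train_fraction < 1):
            raise PipelineError("config: train_fraction must lie in (0, 1)")
        return spec, gfa_cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        return cls(**doc)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed, "version": __version__}


def _write_csv(frame: pd.DataFrame, path: Path, prov: dict, extra: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# provenance: {json.dumps(prov, sort_keys=True)}\n")
        if extra:
            fh.write(f"# {extra}\n")
        frame.to_csv(fh)


def _write_json(obj: dict, path: Path, prov: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"_provenance": prov, **obj}, fh, indent=2)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns a manifest with file paths and a summary."""
    spec, gfa_cfg = config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    manifest: dict[str, str] = {}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except QSARError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    # -- data ------------------------------------------------------------
    if spec is not None:
        dataset, truth = stage("simulate")(generate, spec)
        _write_json(
            {
                "informative": list(truth.informative),
                "coefficients": list(truth.coefficients),
                "intercept": truth.intercept,
                "noise_sd": truth.noise_sd,
            },
            outdir / "ground_truth.json",
            prov,
        )
        manifest["ground_truth"] = str(outdir / "ground_truth.json")
    else:
        table = stage("load")(load_descriptor_table, config.descriptor_csv)
        activity = stage("load")(load_activity, config.activity_csv)
        dataset = QSARDataset(table, activity)

    # -- pretreat --------------------------------------------------------
    pretreated, report = stage("pretreat")(
        pretreat, dataset.table, config.correlation_cutoff, config.variance_tol
    )
    _write_csv(report.to_frame().set_index("descriptor"), outdir / "pretreat_report.csv", prov)
    manifest["pretreat_report"] = str(outdir / "pretreat_report.csv")
    dataset = QSARDataset(pretreated, dataset.activity)

    # -- split -----------------------------------------------------------
    split = stage("split")(ks_split, dataset.table, config.train_fraction)
    dataset = dataset.with_membership(split.train_ids, split.test_ids)
    _write_csv(dataset.membership.to_frame(), outdir / "membership.csv", prov)
    manifest["membership"] = str(outdir / "membership.csv")

    X_train, y_train = dataset.train()
    X_test, y_test = dataset.test()

    # -- GFA + fit -------------------------------------------------------
    result = stage("gfa")(gfa_search, X_train, y_train, gfa_cfg)
    _write_csv(result.to_frame().set_index("descriptors"), outdir / "gfa_ranking.csv", prov)
    manifest["gfa_ranking"] = str(outdir / "gfa_ranking.csv")
    model = stage("fit")(fit_ols, X_train.select(result.best.descriptors), y_train)
    model = dataclasses.replace(model, metadata=prov)
    save_model(model, outdir / "model.json")
    manifest["model"] = str(outdir / "model.json")

    # -- validation ------------------------------------------------------
    report_v = stage("validate")(
        validate_model, model, X_train, y_train, X_test, y_test, config.benchmarks
    )
    _write_csv(report_v["anova"].to_frame(), outdir / "anova.csv", prov)
    _write_csv(report_v["diagnostics"], outdir / "descriptor_diagnostics.csv", prov)
    verdict = report_v["verdict"]
    _write_json(
        {
            "metrics": report_v["metrics"],
            "criteria": verdict.to_frame().to_dict(orient="records"),
            "passed": verdict.passed,
        },
        outdir / "verdict.json",
        prov,
    )
    manifest.update(
        anova=str(outdir / "anova.csv"),
        diagnostics=str(outdir / "descriptor_diagnostics.csv"),
        verdict=str(outdir / "verdict.json"),
    )

    # -- Y-randomization -------------------------------------------------
    Xm = X_train.select(model.descriptor_names)
    yr = stage("yrand")(y_randomize, Xm, y_train, config.n_permutations, config.seed)
    _write_csv(yr.to_frame(), outdir / "y_randomization.csv", prov, extra=f"cRp2: {yr.c_rp2}")
    manifest["y_randomization"] = str(outdir / "y_randomization.csv")

    # -- applicability domain -------------------------------------------
    ad = stage("ad")(williams, model, (X_train, y_train), (X_test, y_test))
    _write_csv(ad.records, outdir / "applicability.csv", prov, extra=f"h_star: {ad.h_star}")
    manifest["applicability"] = str(outdir / "applicability.csv")

    # -- screening: test compounds vs the most potent training compound --
    template = float(y_train.values.max())
    screened = stage("screen")(screen, model, X_test, template)
    _write_csv(screened, outdir / "screen.csv", prov, extra=f"template_pic50: {template}")
    manifest["screen"] = str(outdir / "screen.csv")

    summary = {
        "metrics": report_v["metrics"],
        "benchmark_passed": verdict.passed,
        "c_rp2": yr.c_rp2,
        "n_train": len(split.train_ids),
        "n_test": len(split.test_ids),
        "n_descriptors_after_pretreat": pretreated.shape[1],
        "selected_descriptors": list(model.descriptor_names),
        "h_star": ad.h_star,
        "manifest": manifest,
    }
    _write_json(summary, outdir / "summary.json", prov)
    manifest["summary"] = str(outdir / "summary.json")
    return summary
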