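"""End-to-end orchestration: synthesize, blind, quantify, test, report.

A :class:`RunConfig` fixes the cohort layout, the threshold multiplier k,
the test level alpha, the log base and one master seed.  Stage seeds
(cohort generation, blinding) are derived from the master seed through
``numpy.random.SeedSequence.spawn`` in a fixed order, so each stage is
independently reproducible and the whole artifact chain — images, ROI
geometry, blind presentation order with its sealed key, per-ROI and pooled
measurement CSVs, the activation report, and a provenance manifest — is
byte-identical across re-runs of the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .quantify import DEFAULT_K, blind_order, measure_records
from .stats import ActivationReport, build_report
from .synthetic import Cohort, CohortSpec, StainFieldSpec, generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    k: float = DEFAULT_K
    alpha: float = 0.05
    log_base: float = 10.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuple-keyed multiplier map -> nested {group: {region: m}} for YAML/JSON
        mult: dict[str, dict[str, float]] = {}
        for (g, r), m in self.cohort.activation_multiplier.items():
            mult.setdefault(g, {})[r] = m
        d["cohort"]["activation_multiplier"] = mult
        d["cohort"]["regions"] = list(self.cohort.regions)
        d["cohort"]["groups"] = list(self.cohort.groups)
        d["cohort"]["base_field"]["image_shape"] = list(
            self.cohort.base_field.image_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cd = dict(d.pop("cohort", {}))
        mult = cd.pop("activation_multiplier", {}) or {}
        flat = {(g, r): float(m) for g, rs in mult.items()
                for r, m in rs.items()}
        fd = dict(cd.pop("base_field", {}))
        if "image_shape" in fd:
            fd["image_shape"] = tuple(fd["image_shape"])
        for key in ("regions", "groups"):
            if key in cd:
                cd[key] = tuple(cd[key])
        spec = CohortSpec(activation_multiplier=flat,
                          base_field=StainFieldSpec(**fd), **cd)
        return cls(cohort=spec, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class PipelineResult:
    report: ActivationReport
    manifest: dict
    out_dir: Path
    cohort: Cohort


def _stage_seeds(master: int) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(2)
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(("cohort", "blind"), children)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 overwrite: bool = False) -> PipelineResult:
    """Run the full chain and leave every artifact in ``out_dir``.

    Refuses a non-empty output directory unless ``overwrite`` is set, so a
    partial previous run is never silently mixed with a new one.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    seeds = _stage_seeds(config.seed)
    spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    cohort = generate_cohort(spec, out_dir=out / "cohort")

    presentation, key = blind_order(cohort.metadata(), seed=seeds["blind"])
    presentation.to_csv(out / "blind_order.csv", index=False)
    key.to_csv(out / "blinding_key.csv", index=False)

    roi_df, pooled = measure_records(cohort.records, k=config.k)
    roi_df.to_csv(out / "roi_measurements.csv", index=False)
    pooled.to_csv(out / "measurements.csv", index=False)

    report = build_report(pooled, control_group=spec.control_group,
                          alpha=config.alpha, log_base=config.log_base)
    report.to_csv(out / "report.csv")
    report.to_json(out / "report.json")

    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package": "ps6quant",
        "version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "n_rois": len(cohort.records),
        "outputs": {p.name: _sha256(out / p.name) for p in [
            out / "blind_order.csv", out / "blinding_key.csv",
            out / "roi_measurements.csv", out / "measurements.csv",
            out / "report.csv", out / "report.json"]},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return PipelineResult(report=report, manifest=manifest, out_dir=out,
                          cohort=cohort)
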