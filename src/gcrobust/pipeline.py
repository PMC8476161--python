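"""End-to-end orchestration of a robustness analysis run.

A run is described by a :class:`RunConfig` (loadable from a flat
``key = value`` file), executed by :func:`run_full_analysis`, and leaves
on disk: the persisted MS ensemble, the report TSVs, and a log recording
the seed, parameter digests and per-stage wall times.  Re-running with
the same config and seed is bit-identical.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

from .error_models import MistranslationParams
from .ms_engine import KNOWN_METRICS, MSEnsemble, compute_ms_ensemble
from .properties_io import PropertyTable, load_property_table
from .robustness_stats import RobustnessReport, build_report
from .synthetic_data import FakePropertySpec, generate_fake_properties

logger = logging.getLogger(__name__)

#: Built-in demo property table (the classic polar requirement scale,
#: transcribed from the literature), shipped as package data.
POLAR_REQUIREMENT_TSV = Path(__file__).parent / "data" / "polar_requirement.tsv"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the input."""


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full analysis run.

    ``properties`` is a path to a property table; alternatively
    ``fake_properties``/``fake_distribution`` request a synthetic table.
    ``metrics`` defaults to all five (MS1, MS2, MS3 and the mismatch-like
    / -unlike MS3 variants).
    """

    properties: str | None = None
    fake_properties: int | None = None
    fake_distribution: str = "uniform"
    params_path: str | None = None
    n_codes: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    band: tuple[float, float] = (0.8, 1.2)
    metrics: tuple[str, ...] = KNOWN_METRICS
    compute_n_counts: bool = False
    out_dir: str = "gcrobust_run"

    def __post_init__(self) -> None:
        if self.n_codes < 2:
            raise PipelineError(f"n_codes must be >= 2, got {self.n_codes}")
        if not 0 < self.alpha < 1:
            raise PipelineError(f"alpha must be in (0, 1), got {self.alpha}")
        unknown = [m for m in self.metrics if m not in KNOWN_METRICS]
        if unknown:
            raise PipelineError(f"unknown metrics {unknown}")
        if self.properties is None and self.fake_properties is None:
            raise PipelineError("config must set either 'properties' or 'fake_properties'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat key = value config file (``#`` starts a comment)."""
        kv: dict[str, str] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kwargs: dict[str, object] = {}
        if "properties" in kv:
            kwargs["properties"] = kv["properties"]
        if "fake_properties" in kv:
            kwargs["fake_properties"] = int(kv["fake_properties"])
        if "fake_distribution" in kv:
            kwargs["fake_distribution"] = kv["fake_distribution"]
        if "params" in kv:
            kwargs["params_path"] = kv["params"]
        for key, cast in (("n_codes", int), ("seed", int), ("alpha", float)):
            if key in kv:
                kwargs[key] = cast(kv[key])
        if "band" in kv:
            lo, hi = kv["band"].split(",")
            kwargs["band"] = (float(lo), float(hi))
        if "metrics" in kv:
            kwargs["metrics"] = tuple(m.strip() for m in kv["metrics"].split(","))
        if "compute_n_counts" in kv:
            kwargs["compute_n_counts"] = kv["compute_n_counts"].lower() in ("1", "true", "yes")
        if "out_dir" in kv:
            kwargs["out_dir"] = kv["out_dir"]
        return cls(**kwargs)  # type: ignore[arg-type]


def _load_properties(config: RunConfig) -> PropertyTable:
    if config.properties is not None:
        try:
            return load_property_table(config.properties)
        except Exception as exc:
            raise PipelineError(f"stage load-properties failed on {config.properties}: {exc}") from exc
    spec = FakePropertySpec(
        count=config.fake_properties or 564,
        distribution=config.fake_distribution,  # type: ignore[arg-type]
        seed=config.seed,
    )
    return generate_fake_properties(spec)


def run_full_analysis(config: RunConfig) -> RobustnessReport:
    """Execute the full pipeline and write all artifacts under ``out_dir``.

    Stages, in order: property loading, mistranslation-parameter loading,
    RGC ensemble generation with MS computation, empirical P + BH per
    metric, correlation profile, MS-matched controls for every property
    flagged frameshift-robust, and (optionally) per-code N counts with
    band controls.  Any stage failure raises :class:`PipelineError`
    naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    properties = _load_properties(config)
    logger.info(
        "loaded %d properties (provenance=%s) [%.2fs]",
        len(properties), properties.provenance, time.perf_counter() - t0,
    )

    params = MistranslationParams()
    if config.params_path is not None:
        try:
            params = MistranslationParams.from_file(config.params_path)
        except Exception as exc:
            raise PipelineError(
                f"stage load-params failed on {config.params_path}: {exc}"
            ) from exc

    t0 = time.perf_counter()
    try:
        ensemble = compute_ms_ensemble(
            properties,
            n_codes=config.n_codes,
            seed=config.seed,
            metrics=config.metrics,
            params=params,
        )
    except Exception as exc:
        raise PipelineError(f"stage ensemble failed (n={config.n_codes}): {exc}") from exc
    logger.info(
        "ensemble: %d codes x %d properties x %d metrics [%.2fs]",
        config.n_codes, len(properties), len(config.metrics), time.perf_counter() - t0,
    )
    ensemble.save(out_dir / "ensemble")

    t0 = time.perf_counter()
    try:
        report = build_report(
            ensemble,
            alpha=config.alpha,
            band=config.band,
            compute_n_counts=config.compute_n_counts,
        )
    except Exception as exc:
        raise PipelineError(f"stage report failed: {exc}") from exc
    logger.info(
        "report: SGC counts %s; %d control tests [%.2fs]",
        report.sgc_counts, len(report.controls), time.perf_counter() - t0,
    )
    skipped_controls = [
        m for m in ("MS1", "MS2") if m not in config.metrics
    ]
    if skipped_controls and "MS3" in config.metrics:
        logger.warning(
            "controls requiring %s skipped (metric not requested)", skipped_controls
        )

    report.metadata["properties_provenance"] = properties.provenance
    report.metadata["n_properties"] = len(properties)
    report.write(out_dir)
    return report
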