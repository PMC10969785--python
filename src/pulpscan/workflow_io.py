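"""End-to-end pipeline: image I/O, batch segmentation, reporting.

``run_pipeline`` segments each sample's pre/post section pair, computes
damage records and per-deformation summaries, fits the deformation
regressions (damage always, decay when a decay table is supplied) and
returns a :class:`RunReport` whose body is fully deterministic for a given
config and seed.  A failing sample is logged and excluded — batch CT
processing has to tolerate a bad slice — and the failure count is part of
the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image import GrayImage
from .segmentation import SegmentationConfig, extract_cavity_area
from .damage_metrics import DamageRecord, GroupDamageSummary, summarize_all
from .deformation_regression import LinearModel, RatePoint, fit_ols, fit_report
from . import phantom as phantom_mod

logger = logging.getLogger("pulpscan")

_DTYPE_RANGES = {
    np.dtype("uint8"): (0.0, 255.0),
    np.dtype("uint16"): (0.0, 65535.0),
    np.dtype("uint32"): (0.0, 4294967295.0),
    np.dtype("int16"): (-32768.0, 32767.0),
}


def load_slice(path, section_kind: str = "cross") -> GrayImage:
    """Read a single-slice grayscale TIFF (8/16/32-bit) as a GrayImage.

    Color or multi-sample images are rejected: the pipeline is defined on
    scalar intensities only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:
        raise ValueError(f"{path} is not a readable TIFF: {exc}") from exc
    if data.ndim != 2:
        raise ValueError(
            f"{path}: expected a single grayscale slice, got shape {data.shape} "
            "(multi-channel or multi-page input)"
        )
    if data.dtype in _DTYPE_RANGES:
        vr = _DTYPE_RANGES[data.dtype]
    else:  # float TIFF: range from the data itself
        lo = float(min(data.min(), 0.0))
        hi = float(data.max())
        vr = (lo, hi if hi > lo else lo + 1.0)
    return GrayImage(data, vr, section_kind)


def save_slice(image: GrayImage, path, dtype: str = "float32") -> None:
    """Write a GrayImage as a single-slice TIFF (float32 or uint8)."""
    path = Path(path)
    px = image.pixels
    if dtype == "uint8":
        lo, hi = image.value_range
        px = np.clip((px - lo) / (hi - lo) * 255.0, 0, 255).astype(np.uint8)
    elif dtype == "float32":
        px = px.astype(np.float32)
    else:
        raise ValueError(f"unsupported output dtype {dtype!r}")
    tifffile.imwrite(path, px)


@dataclass(frozen=True)
class SamplePair:
    """One fruit's pre/post section images (paths or in-memory GrayImages)."""

    sample_id: str
    deformation_mm: float
    pre: object  # path or GrayImage
    post: object


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one batch run."""

    pairs: tuple = ()  # SamplePair instances
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    decay_points: tuple = ()  # (deformation_mm, decay_rate_pct) pairs, optional
    out_dir: str | None = None
    seed: int = 0
    verbosity: str = "INFO"


@dataclass(frozen=True)
class RunReport:
    """All pipeline outputs plus provenance for one run."""

    records: tuple  # DamageRecord
    summaries: tuple  # GroupDamageSummary
    damage_model: LinearModel | None
    decay_model: LinearModel | None
    failures: tuple  # (sample_id, stage/error message)
    provenance: dict

    @property
    def n_failed(self) -> int:
        return len(self.failures)

    def body_dict(self) -> dict:
        """Deterministic report body (timestamps excluded)."""
        prov = {k: v for k, v in self.provenance.items() if k != "timestamp"}

        def model_dict(m):
            if m is None:
                return None
            return {
                "slope": m.slope,
                "intercept": m.intercept,
                "r_squared": m.r_squared,
                "slope_p_value": m.slope_p_value,
                "n": m.n,
                "equation": m.equation(),
            }

        return {
            "records": [asdict(r) for r in self.records],
            "summaries": [asdict(s) for s in self.summaries],
            "damage_model": model_dict(self.damage_model),
            "decay_model": model_dict(self.decay_model),
            "failures": list(self.failures),
            "provenance": prov,
        }

    def to_json(self) -> str:
        body = self.body_dict()
        body["provenance"]["timestamp"] = self.provenance.get("timestamp")
        return json.dumps(body, indent=2, sort_keys=True)


def _config_hash(config: RunConfig) -> str:
    seg = asdict(config.segmentation)
    payload = {
        "segmentation": seg,
        "decay_points": list(map(list, config.decay_points)),
        "seed": config.seed,
        "samples": [
            [p.sample_id, p.deformation_mm,
             str(p.pre) if not isinstance(p.pre, GrayImage) else "<in-memory>",
             str(p.post) if not isinstance(p.post, GrayImage) else "<in-memory>"]
            for p in config.pairs
        ],
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _as_image(obj, section_kind: str = "cross") -> GrayImage:
    if isinstance(obj, GrayImage):
        return obj
    return load_slice(obj, section_kind)


def run_pipeline(config: RunConfig) -> RunReport:
    """Segment every pair, compute damage statistics and fit the regressions.

    Every configured sample appears in the report, either as a DamageRecord
    or in the failure list; nothing is dropped silently.
    """
    from . import __version__

    if not config.pairs:
        raise ValueError("no sample pairs configured")
    logger.setLevel(config.verbosity)

    records: list[DamageRecord] = []
    failures: list[tuple[str, str]] = []
    for pair in config.pairs:
        try:
            pre = _as_image(pair.pre)
            post = _as_image(pair.post)
            s1 = extract_cavity_area(pre, config.segmentation).area_px
            s2 = extract_cavity_area(post, config.segmentation).area_px
            records.append(
                DamageRecord.from_areas(pair.sample_id, pair.deformation_mm, s1, s2)
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-sample failures
            logger.warning("sample %s failed: %s", pair.sample_id, exc)
            failures.append((str(pair.sample_id), str(exc)))

    summaries = summarize_all(records) if records else []

    damage_model = None
    if len({r.deformation_mm for r in records}) >= 2:
        damage_model = fit_ols(
            [RatePoint(r.deformation_mm, r.A, "damage") for r in records],
            response="Y1",
        )
    decay_model = None
    if len(config.decay_points) >= 2:
        decay_model = fit_ols(
            [RatePoint(x, y, "decay") for x, y in config.decay_points],
            response="Y2",
        )

    report = RunReport(
        records=tuple(records),
        summaries=tuple(summaries),
        damage_model=damage_model,
        decay_model=decay_model,
        failures=tuple(failures),
        provenance={
            "config_hash": _config_hash(config),
            "version": __version__,
            "seed": config.seed,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
    )
    if config.out_dir:
        write_report(report, config.out_dir)
    return report


def write_report(report: RunReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json())
    pd.DataFrame([asdict(r) for r in report.records]).to_csv(
        out / "damage_records.csv", index=False
    )
    pd.DataFrame([asdict(s) for s in report.summaries]).to_csv(
        out / "group_summaries.csv", index=False
    )
    (out / "report.txt").write_text(render_report(report))


def render_report(report: RunReport) -> str:
    """Human-readable summary: group table plus fitted equations."""
    lines = ["Deformation (mm)\tDamage Rate (%)\tn"]
    for s in report.summaries:
        lines.append(s.table_row())
    if report.n_failed:
        lines.append(f"failed samples: {report.n_failed}")
    for model in (report.damage_model, report.decay_model):
        if model is not None:
            lines.append(
                f"{model.equation()}   (R² = {model.r_squared:.2f}, "
                f"slope p = {model.slope_p_value:.3f}, n = {model.n})"
            )
    return "\n".join(lines) + "\n"


def phantom_run_config(
    n_pairs_per_level: int,
    deformations=(4.0, 8.0, 12.0, 16.0),
    seed: int = 0,
    image_size: int = 512,
    noise_sd: float = 0.0,
    segmentation: SegmentationConfig | None = None,
    decay_points: tuple = (),
) -> tuple[RunConfig, dict]:
    """Build a RunConfig of seeded phantom pairs, plus the true rates.

    Returns ``(config, truths)`` where ``truths`` maps sample_id to the
    pair's exact damage rate, for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    truths: dict[str, float] = {}
    for d in deformations:
        for i in range(n_pairs_per_level):
            spec = phantom_mod.random_spec(
                int(rng.integers(0, 2**31 - 1)), image_size=image_size, noise_sd=noise_sd
            )
            p = phantom_mod.generate_pair(spec, d)
            sid = f"d{d:g}_{i:03d}"
            pairs.append(SamplePair(sid, d, p.pre_image, p.post_image))
            truths[sid] = p.true_damage_rate
    cfg = RunConfig(
        pairs=tuple(pairs),
        segmentation=segmentation or SegmentationConfig(),
        decay_points=tuple(decay_points),
        seed=seed,
    )
    return cfg, truths
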