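"""Configured end-to-end pipeline and per-culture aggregation.

Ties the stages together: a manifest lists input files (spike tables,
voltage recordings, image pairs, SWC tracings, point tables) tagged with
culture metadata; the pipeline runs the stage appropriate to each input
and writes tidy per-electrode, per-burst, per-cell and per-culture CSV
tables plus a JSON run summary.  Aggregation supports the two analysis
modes used for grouped cultures: culture-based (average within each
culture, then summarize across culture means) and cell-based (pool all
individual values).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .bursts import BurstParams, burst_metrics, detect_bursts
from .coloc import ColocParams, ImagePair, colocalize
from .ephys import RateParams, SpikeDetectionParams, detect_spikes, rate_metrics
from .io import read_image, read_points_csv, read_spike_csv, read_voltage
from .morpho import (
    MorphometryParams,
    ShollParams,
    ZoneSpec,
    branch_morphometrics,
    read_swc,
    sholl_profile,
    zone_density,
)

__all__ = [
    "CultureRecord",
    "PipelineConfig",
    "PipelineError",
    "AggregateResult",
    "aggregate_metrics",
    "run_pipeline",
]

logger = logging.getLogger("neuroagg")

CONDITIONS = ("dissociated_2D", "aggregated_3D")

# versioned CSV headers; golden-file tests guard these
SCHEMAS: Dict[str, List[str]] = {
    "electrode_metrics": [
        "culture_id", "condition", "div", "electrode_id", "n_spikes",
        "spikes_per_minute", "mean_isi", "mean_firing_rate", "mean_amplitude",
        "is_active", "n_bursts", "bursts_per_minute", "mean_spikes_per_burst",
        "mean_burst_duration", "mean_interburst_interval", "burstiness",
    ],
    "bursts": ["culture_id", "electrode_id", "t_start", "t_end", "n_spikes"],
    "cell_metrics": [
        "culture_id", "condition", "div", "cell_id", "n_main_branches",
        "longest_main_branch", "total_process_length", "n_junctions",
    ],
    "coloc": [
        "culture_id", "condition", "div", "M1", "M2", "PCC", "TOS",
        "n_pixels_a", "n_pixels_b", "n_overlap",
    ],
    "zones": [
        "culture_id", "inner_um", "outer_um", "count", "area_mm2", "density_per_mm2",
    ],
    "sholl": ["culture_id", "cell_id", "radius_um", "crossings"],
}
SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """Raised at the end of a run when one or more inputs failed."""


@dataclass
class CultureRecord:
    """All per-culture measurements used by the aggregation modes."""

    culture_id: str
    condition: str
    div: int
    electrode_metrics: List[Dict[str, Any]] = field(default_factory=list)
    cell_metrics: List[Dict[str, Any]] = field(default_factory=list)
    coloc: Optional[Dict[str, Any]] = None

    def __post_init__(self) -> None:
        if self.div <= 0:
            raise ValueError("div must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


# metrics that only make sense over active electrodes
_EPHYS_METRICS = {
    "spikes_per_minute", "mean_isi", "mean_firing_rate", "mean_amplitude",
    "n_bursts", "bursts_per_minute", "mean_spikes_per_burst",
    "mean_burst_duration", "mean_interburst_interval", "burstiness",
}


@dataclass
class AggregateResult:
    metric: str
    mode: str
    per_culture: pd.DataFrame  # culture_id, n, mean
    mean: float
    sd: float
    n: int  # cultures (culture_based) or pooled values (cell_based)


def _record_values(record: CultureRecord, metric: str) -> List[float]:
    vals: List[float] = []
    for m in record.electrode_metrics:
        if metric in m:
            if metric in _EPHYS_METRICS and not m.get("is_active", True):
                continue
            vals.append(float(m[metric]))
    for c in record.cell_metrics:
        if metric in c:
            vals.append(float(c[metric]))
    if record.coloc and metric in record.coloc:
        vals.append(float(record.coloc[metric]))
    return [v for v in vals if np.isfinite(v)]


def _available_metrics(records: Sequence[CultureRecord]) -> List[str]:
    names: set = set()
    for r in records:
        for m in r.electrode_metrics:
            names.update(m)
        for c in r.cell_metrics:
            names.update(c)
        if r.coloc:
            names.update(r.coloc)
    return sorted(n for n in names if n not in ("electrode_id", "is_active", "cell_id"))


def aggregate_metrics(
    records: Sequence[CultureRecord], metric: str, mode: str = "culture_based"
) -> AggregateResult:
    """Summarize one metric across cultures in either analysis mode.

    ``culture_based`` averages within each culture first and then
    summarizes the culture means (n = number of contributing cultures);
    ``cell_based`` pools every individual value (n = pooled count).
    Cultures contributing no values are excluded from culture-based
    analysis with a logged warning.  Ephys metrics draw only on active
    electrodes.
    """
    if mode not in ("culture_based", "cell_based"):
        raise ValueError("mode must be 'culture_based' or 'cell_based'")
    per_rows = []
    pooled: List[float] = []
    for r in records:
        vals = _record_values(r, metric)
        if not vals:
            logger.warning("culture %s contributes no values for %r", r.culture_id, metric)
            continue
        per_rows.append({"culture_id": r.culture_id, "n": len(vals), "mean": float(np.mean(vals))})
        pooled.extend(vals)
    if not pooled:
        avail = _available_metrics(records)
        raise KeyError(f"metric {metric!r} not found; available: {avail}")
    per_culture = pd.DataFrame(per_rows, columns=["culture_id", "n", "mean"])
    if mode == "culture_based":
        means = per_culture["mean"].to_numpy()
        return AggregateResult(
            metric, mode, per_culture,
            mean=float(np.mean(means)),
            sd=float(np.std(means, ddof=1)) if means.size > 1 else float("nan"),
            n=int(means.size),
        )
    arr = np.asarray(pooled)
    return AggregateResult(
        metric, mode, per_culture,
        mean=float(np.mean(arr)),
        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan"),
        n=int(arr.size),
    )


@dataclass
class PipelineConfig:
    """Every stage's parameter block; defaults reproduce the standard
    acquisition settings (200-3000 Hz band, 6x RMS threshold, 100/250 ms
    burst rules, 25-px rolling ball, top-10% TOS, 5 um junction filter)."""

    detection: SpikeDetectionParams = field(default_factory=SpikeDetectionParams)
    rate: RateParams = field(default_factory=RateParams)
    burst: BurstParams = field(default_factory=BurstParams)
    coloc: ColocParams = field(default_factory=ColocParams)
    sholl: ShollParams = field(default_factory=ShollParams)
    morpho: MorphometryParams = field(default_factory=MorphometryParams)
    zones: ZoneSpec = field(default_factory=ZoneSpec)
    seed: int = 0
    output_dir: str = "neuroagg_out"

    _BLOCKS = {
        "detection": SpikeDetectionParams,
        "rate": RateParams,
        "burst": BurstParams,
        "coloc": ColocParams,
        "sholl": ShollParams,
        "morpho": MorphometryParams,
        "zones": ZoneSpec,
    }

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        kwargs: Dict[str, Any] = {}
        for key, value in (data or {}).items():
            if key in cls._BLOCKS:
                block = dict(value or {})
                if key == "zones" and "bands" in block:
                    block["bands"] = [tuple(b) for b in block["bands"]]
                if key == "zones" and "aggregate_center" in block:
                    block["aggregate_center"] = tuple(block["aggregate_center"])
                kwargs[key] = cls._BLOCKS[key](**block)
            elif key in ("seed", "output_dir"):
                kwargs[key] = value
            else:
                raise ValueError(f"unknown config block {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def canonical_json(self) -> str:
        # output_dir is bookkeeping, not an analysis parameter: two runs
        # into different directories are the same configuration
        d = dataclasses.asdict(self)
        d.pop("output_dir", None)
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _load_manifest(manifest) -> List[Dict[str, Any]]:
    if isinstance(manifest, (str, Path)):
        text = Path(manifest).read_text()
        data = yaml.safe_load(text)
        if data is None:
            return []
        return list(data)
    return list(manifest)


def run_pipeline(config: PipelineConfig, manifest) -> Dict[str, Any]:
    """Run every stage named by the manifest and write the report bundle.

    ``manifest`` is a list (or YAML file) of entries, each a mapping with
    a ``kind`` in {spikes, voltage, image_pair, arbor, points} plus the
    paths and culture metadata that stage needs.  Independent inputs are
    processed even when others fail; a failed run raises
    :class:`PipelineError` at the end, after all outputs are written.
    Outputs are deterministic: rerunning the same config and manifest
    yields byte-identical files.
    """
    entries = _load_manifest(manifest)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tables: Dict[str, List[Dict[str, Any]]] = {name: [] for name in SCHEMAS}
    errors: List[Dict[str, str]] = []

    for entry in entries:
        kind = entry.get("kind")
        culture = str(entry.get("culture_id", "culture0"))
        condition = entry.get("condition", "dissociated_2D")
        div = int(entry.get("div", 1))
        try:
            if kind == "spikes":
                trains = read_spike_csv(entry["path"], duration=entry.get("duration"))
            elif kind == "voltage":
                trace = read_voltage(entry["path"])
                trains = [detect_spikes(trace, config.detection)]
            elif kind == "image_pair":
                pair = ImagePair(read_image(entry["path_a"]), read_image(entry["path_b"]))
                res = colocalize(pair, config.coloc)
                tables["coloc"].append(
                    {"culture_id": culture, "condition": condition, "div": div,
                     **dataclasses.asdict(res)}
                )
                continue
            elif kind == "arbor":
                arbor = read_swc(entry["path"])
                cell_id = str(entry.get("cell_id", Path(entry["path"]).stem))
                morph = branch_morphometrics(arbor, config.morpho)
                tables["cell_metrics"].append(
                    {"culture_id": culture, "condition": condition, "div": div,
                     "cell_id": cell_id, **dataclasses.asdict(morph)}
                )
                profile = sholl_profile(arbor, config.sholl)
                for r, x in zip(profile.radii, profile.crossings):
                    tables["sholl"].append(
                        {"culture_id": culture, "cell_id": cell_id,
                         "radius_um": float(r), "crossings": int(x)}
                    )
                continue
            elif kind == "points":
                pts = read_points_csv(entry["path"])
                zspec = config.zones
                if "aggregate_center" in entry or "aggregate_radius" in entry:
                    zspec = ZoneSpec(
                        aggregate_center=tuple(entry.get("aggregate_center", zspec.aggregate_center)),
                        aggregate_radius=float(entry.get("aggregate_radius", zspec.aggregate_radius)),
                        bands=zspec.bands,
                    )
                zres = zone_density(pts, zspec)
                for row in zres.table.to_dict("records"):
                    tables["zones"].append({"culture_id": culture, **row})
                continue
            else:
                raise ValueError(f"unknown manifest kind {kind!r}")

            # shared spike-train path (kinds: spikes, voltage)
            for train in trains:
                rm = rate_metrics(train, config.rate)
                bursts = detect_bursts(train, config.burst)
                if train.n_spikes:
                    bm = dataclasses.asdict(burst_metrics(train, bursts))
                else:
                    bm = {k: float("nan") for k in (
                        "bursts_per_minute", "mean_spikes_per_burst",
                        "mean_burst_duration", "mean_interburst_interval",
                        "burstiness")}
                    bm["n_bursts"] = 0
                tables["electrode_metrics"].append(
                    {"culture_id": culture, "condition": condition, "div": div,
                     **dataclasses.asdict(rm), **bm}
                )
                for b in bursts:
                    tables["bursts"].append(
                        {"culture_id": culture, "electrode_id": train.electrode_id,
                         "t_start": b.t_start, "t_end": b.t_end, "n_spikes": b.n_spikes}
                    )
        except Exception as exc:  # keep independent inputs running
            logger.error("entry %s (%s) failed: %s", entry.get("path", "?"), kind, exc)
            errors.append({"entry": str(entry.get("path", entry)), "kind": str(kind),
                           "error": f"{type(exc).__name__}: {exc}"})

    written: Dict[str, str] = {}
    for name, cols in SCHEMAS.items():
        df = pd.DataFrame(tables[name], columns=cols)
        fname = f"{name}.csv"
        df.to_csv(out_dir / fname, index=False, float_format="%.9g")
        written[name] = fname

    summary = {
        "schema_version": SCHEMA_VERSION,
        "package_version": _pkg_version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_entries": len(entries),
        "n_failed": len(errors),
        "errors": errors,
        "tables": written,
    }
    (out_dir / "run_summary.json").write_text(json.dumps(summary, sort_keys=True, indent=1))

    if errors:
        raise PipelineError(f"{len(errors)} of {len(entries)} inputs failed; see run_summary.json")
    return summary
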