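"""File formats, run configuration, reports and provenance.

Traces and correlation curves travel as delimited text with a
``# key = value`` header block, written at full precision so a
write/read round trip is bit-exact.  Photon timestamp lists are binned
on read (0.2 us base by default).  Reports mirror the per-construct
summary-table layout of the field: mean +/- SD per parameter across
cells, a bleach +/- column, and n.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlate import SIGMA_FLOOR, CorrelationCurve
from .models import FitResult, params_as_dict
from .selection import ComparisonReport
from .traces import BleachFit, IntensityTrace

logger = logging.getLogger("fcskit")

#: Native binning period (s) applied to photon-timestamp input.
TIMESTAMP_BIN_WIDTH = 0.2e-6

#: Cell-context presets: photobleach excision window and segment length.
PRESETS = {
    "psg": {"excision_window": 20.0, "segment_length": 10.0},
    "hela": {"excision_window": 10.0, "segment_length": 10.0},
}


@dataclass
class RunConfig:
    """Structured configuration of a pipeline run."""

    preset: str = "custom"
    excision_window: float = 0.0
    segment_length: float = 10.0
    max_components: int = 3
    structure_parameter: float = 5.0
    fit_range: tuple = (50e-6, 3.4)
    tau_reference: float | None = None  # reference dye transit time (s)
    rng_seed: int = 0
    output_dir: str = "."
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        preset = raw.get("preset", "custom")
        cfg = cls(preset=preset, raw=dict(raw))
        if preset != "custom":
            if preset not in PRESETS:
                raise ValueError(f"unknown preset: {preset!r}")
            cfg.excision_window = PRESETS[preset]["excision_window"]
            cfg.segment_length = PRESETS[preset]["segment_length"]
        for key in (
            "excision_window", "segment_length", "max_components",
            "structure_parameter", "rng_seed", "output_dir", "tau_reference",
        ):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "fit_range" in raw:
            cfg.fit_range = tuple(raw["fit_range"])
        return cfg

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _parse_header(path) -> tuple[dict, int]:
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta, n_header


def _read_columns(path, n_cols, skip) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= skip or not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return np.asarray(rows, dtype=float)


def read_trace(
    path,
    format: str = "delimited",
    bin_width: float | None = None,
) -> IntensityTrace:
    """Read a trace from delimited text or a photon-timestamp list.

    Delimited format: optional ``# key = value`` header then two columns
    (time_s, counts).  Timestamp format: one monotone arrival time per
    line, binned at ``bin_width`` (default 0.2 us).  A ``bin_width``
    argument conflicting with the file header is an error.
    """
    meta, skip = _parse_header(path)
    if format == "delimited":
        data = _read_columns(path, 2, skip)
        if data.size == 0:
            raise ValueError(f"{path}: no data rows")
        times, counts = data[:, 0], data[:, 1]
        header_bw = float(meta["bin_width"]) if "bin_width" in meta else None
        file_bw = float(np.median(np.diff(times))) if times.size > 1 else header_bw
        bw = header_bw if header_bw is not None else file_bw
        if bw is None:
            raise ValueError(f"{path}: cannot determine bin width")
        if bin_width is not None and abs(bin_width - bw) > 1e-12 * max(bw, 1e-12):
            raise ValueError(
                f"{path}: bin_width {bin_width:g} conflicts with file value {bw:g}"
            )
        return IntensityTrace(
            counts, bin_width=bw, start_time=float(times[0]),
            metadata={**meta, "source": "file"},
        )
    if format == "photon_timestamps":
        data = _read_columns(path, 1, skip)
        if data.size == 0:
            raise ValueError(f"{path}: no timestamps")
        ts = data[:, 0]
        bad = np.nonzero(np.diff(ts) < 0)[0]
        if bad.size:
            raise ValueError(
                f"{path}:{skip + int(bad[0]) + 2}: non-monotone timestamp"
            )
        bw = bin_width or TIMESTAMP_BIN_WIDTH
        # right-closed bins: an arrival at exactly i*bw falls in bin i-1
        idx = np.ceil(ts / bw - 1e-9).astype(int) - 1
        idx = np.clip(idx, 0, None)
        counts = np.bincount(idx, minlength=int(idx.max()) + 1)
        return IntensityTrace(
            counts.astype(float), bin_width=bw, start_time=0.0,
            metadata={**meta, "source": "file"},
        )
    raise ValueError(f"unknown trace format: {format!r}")


def write_trace(trace: IntensityTrace, path) -> None:
    """Write a trace as two-column text with a key=value header block."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# bin_width = {float(trace.bin_width)!r}\n")
        fh.write(f"# start_time = {float(trace.start_time)!r}\n")
        for key, val in trace.metadata.items():
            fh.write(f"# {key} = {val}\n")
        for i, c in enumerate(trace.counts):
            t = trace.start_time + i * trace.bin_width
            fh.write(f"{float(t)!r} {float(c)!r}\n")


def write_curve(curve: CorrelationCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_segments = {curve.n_segments}\n")
        fh.write(f"# mean_intensity = {float(curve.mean_intensity)!r}\n")
        for l, g, s in zip(curve.lags, curve.G, curve.sigma):
            fh.write(f"{float(l)!r} {float(g)!r} {float(s)!r}\n")


def read_curve(path) -> CorrelationCurve:
    meta, skip = _parse_header(path)
    data = _read_columns(path, 3, skip)
    if data.size == 0:
        raise ValueError(f"{path}: no data rows")
    return CorrelationCurve(
        lags=data[:, 0],
        G=data[:, 1],
        sigma=np.maximum(data[:, 2], SIGMA_FLOOR),
        n_segments=int(meta.get("n_segments", 1)),
        mean_intensity=float(meta.get("mean_intensity", 0.0)),
        metadata={"source": "file"},
    )


def write_ground_truth(truth, path) -> None:
    """Sidecar manifest of generating parameters, as key=value text."""
    with open(path, "w") as fh:
        fh.write("# ground truth manifest\n")
        for i, (D, frac) in enumerate(truth.components, 1):
            fh.write(f"component{i}_D = {float(D)!r}\n")
            fh.write(f"component{i}_fraction = {float(frac)!r}\n")
        for key in ("immobile_fraction", "bleach_A", "bleach_k", "bleach_y0"):
            fh.write(f"{key} = {float(getattr(truth, key))!r}\n")
        fh.write(f"rng_seed = {truth.rng_seed}\n")


def provenance_block(config: RunConfig) -> dict:
    return {
        "package": "fcskit",
        "version": __version__,
        "rng_seed": config.rng_seed,
        "config_hash": config.config_hash(),
        "preset": config.preset,
    }


def write_report(results: list[dict], out_dir, config: RunConfig | None = None):
    """Write the per-construct summary table plus per-curve detail.

    ``results`` entries are dicts with keys ``label`` (construct name),
    ``fit`` (FitResult of the selected model), and optionally ``bleach``
    (BleachFit) and ``report`` (ComparisonReport).  Produces
    ``summary.tsv`` (one row per construct: mean +/- SD per parameter,
    bleach +/-, n), ``details.json`` and ``provenance.json``.
    """
    if not results:
        raise ValueError("write_report requires at least one result")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for label in dict.fromkeys(r["label"] for r in results):
        group = [r for r in results if r["label"] == label]
        tables = [params_as_dict(r["fit"].params) for r in group]
        frame = pd.DataFrame(tables)
        row = {"construct": label, "n": len(group)}
        m = group[0]["fit"].params.n_components
        for i in range(1, m + 1):
            for base, scale in ((f"F{i}", 100.0), (f"tau{i}", 1.0)):
                vals = frame[base] * scale
                row[f"{base}_mean"] = vals.mean()
                row[f"{base}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        flags = [r.get("bleach") for r in group if r.get("bleach") is not None]
        if flags:
            frac = np.mean([b.bleach_flag for b in flags])
            row["bleach"] = "+" if frac >= 0.5 else "-"
        rows.append(row)
    summary = pd.DataFrame(rows)
    summary_path = out / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False, float_format="%.6g")

    details = []
    for r in results:
        fit: FitResult = r["fit"]
        entry = {
            "label": r["label"],
            "model": {
                "n_components": fit.spec.n_components,
                "triplet": fit.spec.triplet,
                "fit_range": list(fit.spec.fit_range),
            },
            "params": {k: float(v) for k, v in params_as_dict(fit.params).items()},
            "uncertainties": {
                k: float(v) for k, v in fit.param_uncertainties.items()
            },
            "chi2": fit.chi2,
            "n_points": fit.n_points,
            "dof": fit.dof,
            "converged": fit.converged,
        }
        bleach: BleachFit | None = r.get("bleach")
        if bleach is not None:
            entry["bleach"] = {
                "A": bleach.A, "k": bleach.k, "y0": bleach.y0,
                "flag": bleach.bleach_flag,
            }
        report: ComparisonReport | None = r.get("report")
        if report is not None:
            entry["selection"] = {
                "selected_components": report.selected.n_components,
                "aicc": {
                    f"M={s.n_components}": v for s, v in report.aicc.items()
                },
                "rationale": report.rationale,
            }
        details.append(entry)
    with open(out / "details.json", "w") as fh:
        json.dump(details, fh, indent=1)

    if config is not None:
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance_block(config), fh, indent=1)
    return summary_path
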