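"""File formats and run configuration.

Images travel as multi-page grayscale TIFF (the field's lingua franca),
transforms / ground truth / annotations / logs as JSON, tabular output as
CSV, and run configuration as YAML. A run's resolved configuration is
written next to its outputs so it can be reproduced bit-identically from
the snapshot alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .imaging_core import WidefieldTimelapse
from .controller import EventBundle, ExperimentRecord

__all__ = [
    "read_timelapse",
    "write_timelapse",
    "write_event_bundle",
    "RunConfig",
    "read_annotations",
    "write_annotations",
]


def read_timelapse(
    path: str | Path,
    pixel_size_nm: float = 100.0,
    frame_period_ms: float = 50.0,
) -> WidefieldTimelapse:
    """Read a multi-page grayscale TIFF as a timelapse.

    Pixel size and frame period are not encoded in plain TIFF; they come
    from a sidecar config or these arguments. Pages must be single-channel
    and share one shape; a single page yields a length-1 timelapse.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"{path}: empty TIFF")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise ValueError(f"{path}: TIFF pages have mismatched shapes {sorted(shapes)}")
    if pages[0].ndim != 2:
        raise ValueError(f"{path}: expected grayscale pages, got shape {pages[0].shape}")
    return WidefieldTimelapse(np.stack(pages), pixel_size_nm, frame_period_ms)


def write_timelapse(stack: WidefieldTimelapse | np.ndarray, path: str | Path) -> Path:
    """Write a (T, H, W) stack as an uncompressed little-endian TIFF."""
    data = stack.frames if isinstance(stack, WidefieldTimelapse) else np.asarray(stack)
    if data.ndim == 2:
        data = data[None]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), data, byteorder="<", photometric="minisblack")
    return path


def write_event_bundle(
    bundle: EventBundle,
    directory: str | Path,
    run_id: str,
    event_index: int,
    overwrite: bool = False,
) -> dict[str, Path]:
    """Write one event's evidence: widefield buffer TIFF, scan TIFF, log line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{run_id}_event{event_index:03d}"
    paths: dict[str, Path] = {}

    wf_path = directory / f"{stem}_widefield.tif"
    targets = [wf_path]
    scan_path = directory / f"{stem}_scan.tif"
    if bundle.scan_stack is not None:
        targets.append(scan_path)
    for t in targets:
        if t.exists() and not overwrite:
            raise FileExistsError(f"{t} exists; pass overwrite to replace")

    write_timelapse(bundle.widefield_buffer, wf_path)
    paths["widefield"] = wf_path
    if bundle.scan_stack is not None:
        write_timelapse(bundle.scan_stack, scan_path)
        paths["scan"] = scan_path

    log_path = directory / f"{run_id}_events.jsonl"
    with log_path.open("a") as fh:
        fh.write(
            json.dumps(
                {
                    "type": "event",
                    "event_index": event_index,
                    "pipeline": bundle.event.pipeline,
                    "frame_index": bundle.event.frame_index,
                    "widefield_xy": [bundle.event.x, bundle.event.y],
                    "scan_xy": list(bundle.scan_xy),
                    "salience": bundle.event.salience,
                    "widefield_path": wf_path.name,
                    "scan_path": scan_path.name if bundle.scan_stack is not None else None,
                }
            )
            + "\n"
        )
    paths["log"] = log_path
    return paths


@dataclass
class RunConfig:
    """Resolved configuration of one run; round-trips losslessly via YAML."""

    pipeline: str = "rapid_signal_spikes"
    pipeline_params: dict = field(default_factory=dict)
    mode: str = "endless"
    seed: int = 0
    scene: dict | None = None
    input_path: str | None = None
    transform_path: str | None = None
    output_dir: str = "."
    buffer_length: int = 10
    scan_size_um: float = 3.0
    scan_pixel_nm: float = 25.0
    scan_frames: int = 5
    mask_threshold: float | None = None
    pixel_size_nm: float = 100.0
    frame_period_ms: float = 50.0

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def read_annotations(path: str | Path) -> list[dict]:
    """Read manual event annotations: a JSON list of {frame_index, x, y}."""
    doc = json.loads(Path(path).read_text())
    if not isinstance(doc, list):
        raise ValueError("annotation file must contain a JSON list")
    out = []
    for item in doc:
        out.append(
            {"frame_index": int(item["frame_index"]), "x": float(item["x"]), "y": float(item["y"])}
        )
    return out


def write_annotations(events, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in events:
        if hasattr(e, "to_dict"):
            d = e.to_dict()
        elif isinstance(e, dict):
            d = e
        else:
            f, x, y = e
            d = {"frame_index": int(f), "x": float(x), "y": float(y)}
        rows.append({k: d[k] for k in d})
    path.write_text(json.dumps(rows, indent=2))
    return path
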