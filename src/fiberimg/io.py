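"""Trace, image and dataset interchange formats.

Traces travel either as a documented little-endian binary container with a
JSON header (bit-exact round-trip) or as two-column CSV (t_ps, value).
Datasets are directories of 8-bit grayscale PNG images and binary traces
tied together by a JSON manifest that records seeds and the config digest.
An IDX reader accepts user-supplied MNIST-format digit files.
"""

from __future__ import annotations

import csv
import json
import logging
import struct
from pathlib import Path

import numpy as np
from PIL import Image

from .encoder import Waveform
from .patterns import ImagePattern

__all__ = [
    "write_trace",
    "read_trace",
    "write_trace_csv",
    "read_trace_csv",
    "write_png",
    "read_png",
    "read_idx_images",
    "save_dataset",
    "load_dataset",
    "FormatError",
]

log = logging.getLogger(__name__)

_TRACE_MAGIC = b"FIMGTRC1\n"
TRACE_VERSION = 1


class FormatError(ValueError):
    """Raised on malformed container/IDX input."""


def write_trace(w: Waveform, path: str | Path) -> None:
    """Binary trace container: magic, length-prefixed JSON header, float64 LE."""
    header = {
        "version": TRACE_VERSION,
        "dt_ps": w.dt_ps,
        "t0_ps": w.t0_ps,
        "length": len(w.samples),
        "meta": w.meta,
    }
    hb = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_TRACE_MAGIC)
        fh.write(len(hb).to_bytes(8, "little"))
        fh.write(hb)
        fh.write(np.ascontiguousarray(w.samples, dtype="<f8").tobytes())


def read_trace(path: str | Path) -> Waveform:
    with open(path, "rb") as fh:
        if fh.read(len(_TRACE_MAGIC)) != _TRACE_MAGIC:
            raise FormatError(f"{path}: bad trace magic")
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        payload = fh.read()
    expected = header["length"] * 8
    if len(payload) != expected:
        raise FormatError(
            f"{path}: payload length {len(payload)} != header length {expected}"
        )
    samples = np.frombuffer(payload, dtype="<f8").copy()
    meta = dict(header.get("meta", {}))
    meta.setdefault("version", header["version"])
    return Waveform(samples=samples, dt_ps=header["dt_ps"], t0_ps=header["t0_ps"], meta=meta)


def write_trace_csv(w: Waveform, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t_ps", "value"])
        for t, v in zip(w.t_ps, w.samples):
            writer.writerow([f"{t:.9f}", f"{v:.12g}"])


def read_trace_csv(path: str | Path) -> Waveform:
    t, v = [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for row in reader:
            t.append(float(row[0]))
            v.append(float(row[1]))
    t = np.asarray(t)
    dt = float(np.mean(np.diff(t))) if len(t) > 1 else 1.0
    return Waveform(samples=np.asarray(v), dt_ps=dt, t0_ps=float(t[0]) if len(t) else 0.0)


def write_png(img: ImagePattern | np.ndarray, path: str | Path) -> None:
    arr = img.intensities if isinstance(img, ImagePattern) else np.asarray(img, float)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def read_png(path: str | Path, pixel_pitch_um: float = 7.56, kind: str = "glyph") -> ImagePattern:
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    return ImagePattern(arr, pixel_pitch_um=pixel_pitch_um, kind=kind)


# --------------------------------------------------------------------------
# IDX (MNIST-compatible) reader


def read_idx_images(path: str | Path, pixel_pitch_um: float = 7.56) -> list[ImagePattern]:
    """Read an IDX3 unsigned-byte image file; intensities scaled to [0, 1]."""
    data = Path(path).read_bytes()
    if len(data) < 16:
        raise FormatError(f"{path}: truncated IDX header")
    magic, count, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != 0x00000803:
        raise FormatError(f"{path}: bad IDX magic 0x{magic:08x}")
    if count == 0:
        log.warning("%s: IDX file declares zero images", path)
        return []
    expected = 16 + count * rows * cols
    if len(data) < expected:
        raise FormatError(f"{path}: truncated IDX payload ({len(data)} < {expected} bytes)")
    arr = np.frombuffer(data[16:expected], dtype=np.uint8).reshape(count, rows, cols)
    return [
        ImagePattern(a / 255.0, pixel_pitch_um=pixel_pitch_um, kind="glyph") for a in arr
    ]


# --------------------------------------------------------------------------
# dataset directories


def save_dataset(
    path: str | Path,
    images: list[ImagePattern],
    waveforms: list[Waveform],
    seed: int | None = None,
    config_digest: str | None = None,
) -> None:
    """One directory per dataset: PNG images, binary traces, JSON manifest."""
    if len(images) != len(waveforms):
        raise ValueError("images and waveforms must pair up")
    root = Path(path)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "traces").mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (img, wf) in enumerate(zip(images, waveforms)):
        img_name = f"images/{i:06d}.png"
        trc_name = f"traces/{i:06d}.trc"
        write_png(img, root / img_name)
        write_trace(wf, root / trc_name)
        entries.append(
            {"id": i, "image": img_name, "trace": trc_name, "label": img.label, "kind": img.kind}
        )
    manifest = {
        "n": len(entries),
        "seed": seed,
        "config_digest": config_digest,
        "pixel_pitch_um": images[0].pixel_pitch_um if images else None,
        "entries": entries,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(path: str | Path) -> tuple[list[ImagePattern], list[Waveform], dict]:
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    images, waveforms = [], []
    for e in manifest["entries"]:
        img = read_png(root / e["image"], pixel_pitch_um=manifest.get("pixel_pitch_um") or 7.56,
                       kind=e.get("kind", "glyph"))
        img.label = e.get("label")
        images.append(img)
        waveforms.append(read_trace(root / e["trace"]))
    return images, waveforms, manifest
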