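"""Readers and writers for Mueller-image containers and realizability masks.

Three interchange formats carry a rows x cols image of 4x4 Mueller
matrices:

``bin``
    Raw little-endian float64 payload, pixels row-major, 16 values per
    pixel in ``m00..m33`` order, with a JSON sidecar header at
    ``<path>.json`` recording shape and layout.  Payload length must equal
    ``rows * cols * 16 * 8`` bytes exactly.
``csv``
    One pixel per line, header ``row,col,m00,...,m33``; every pixel must
    appear exactly once.
``tiff``
    16-page TIFF stack; page k holds element ``m[k // 4][k % 4]`` as a
    rows x cols float image.

Masks are written as binary PGM (P5; 255 = physical, 0 = nonphysical) or
CSV, always with a JSON summary sidecar recording the method, criterion,
tolerance and counts needed to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .checks import Tolerance
from .filter import MuellerImage, RealizabilityMask

__all__ = [
    "ELEMENT_ORDER",
    "read_mueller_image",
    "write_mueller_image",
    "write_mask",
    "read_mask",
]

log = logging.getLogger("muellercheck")

ELEMENT_ORDER = [f"m{i}{j}" for i in range(4) for j in range(4)]
IMAGE_FORMATS = ("bin", "csv", "tiff")
MASK_FORMATS = ("pgm", "csv")


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_mueller_image(img: MuellerImage, path, format: str) -> Path:
    """Write an image in one of the supported container formats."""
    path = Path(path)
    data = img.data.copy()
    data[img.invalid_mask] = np.nan  # invalid pixels round-trip as NaN
    if format == "bin":
        payload = np.ascontiguousarray(data, dtype="<f8")
        path.write_bytes(payload.tobytes())
        header = {
            "rows": img.rows,
            "cols": img.cols,
            "element_order": ",".join(ELEMENT_ORDER),
            "value_type": "<f8",
            "layout": "pixels row-major, 16 values per pixel",
        }
        _sidecar(path).write_text(json.dumps(header, indent=1))
    elif format == "csv":
        rr, cc = np.meshgrid(np.arange(img.rows), np.arange(img.cols), indexing="ij")
        frame = pd.DataFrame(data.reshape(-1, 16), columns=ELEMENT_ORDER)
        frame.insert(0, "col", cc.ravel())
        frame.insert(0, "row", rr.ravel())
        frame.to_csv(path, index=False)
    elif format == "tiff":
        import tifffile

        pages = np.ascontiguousarray(
            data.reshape(img.rows, img.cols, 16).transpose(2, 0, 1)
        )
        tifffile.imwrite(path, pages, photometric="minisblack")
    else:
        raise ValueError(f"unknown image format {format!r}; valid: {IMAGE_FORMATS}")
    return path


def read_mueller_image(path, format: str) -> MuellerImage:
    """Read a Mueller image; non-finite values set the invalid mask."""
    path = Path(path)
    if format == "bin":
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(f"missing sidecar header {side}")
        header = json.loads(side.read_text())
        rows, cols = int(header["rows"]), int(header["cols"])
        expected = rows * cols * 16 * 8
        raw = path.read_bytes()
        if len(raw) != expected:
            raise ValueError(
                f"payload size mismatch for {rows}x{cols} image: "
                f"expected {expected} bytes, found {len(raw)}"
            )
        data = np.frombuffer(raw, dtype="<f8").reshape(rows, cols, 4, 4)
    elif format == "csv":
        frame = pd.read_csv(path, float_precision="round_trip")
        missing_cols = [c for c in ["row", "col", *ELEMENT_ORDER] if c not in frame]
        if missing_cols:
            raise ValueError(f"CSV missing columns: {missing_cols}")
        rows = int(frame["row"].max()) + 1
        cols = int(frame["col"].max()) + 1
        if frame.duplicated(subset=["row", "col"]).any():
            dup = frame[frame.duplicated(subset=["row", "col"])].iloc[0]
            raise ValueError(f"duplicate pixel ({int(dup.row)}, {int(dup.col)})")
        if len(frame) != rows * cols:
            seen = set(zip(frame["row"].astype(int), frame["col"].astype(int)))
            for r in range(rows):
                for c in range(cols):
                    if (r, c) not in seen:
                        raise ValueError(f"missing pixel ({r}, {c})")
            raise ValueError("pixel grid is not dense")
        frame = frame.sort_values(["row", "col"])
        data = frame[ELEMENT_ORDER].to_numpy(dtype=np.float64).reshape(rows, cols, 4, 4)
    elif format == "tiff":
        import tifffile

        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] != 16:
            raise ValueError(
                f"expected a 16-page TIFF stack, found shape {pages.shape}"
            )
        data = np.asarray(pages, dtype=np.float64).transpose(1, 2, 0)
        data = data.reshape(data.shape[0], data.shape[1], 4, 4)
    else:
        raise ValueError(f"unknown image format {format!r}; valid: {IMAGE_FORMATS}")
    return MuellerImage.from_array(data)


def write_mask(mask: RealizabilityMask, path, format: str = "pgm") -> Path:
    """Write a realizability mask plus its JSON summary sidecar."""
    path = Path(path)
    if format == "pgm":
        header = f"P5\n{mask.cols} {mask.rows}\n255\n".encode("ascii")
        body = np.where(mask.physical, 255, 0).astype(np.uint8).tobytes()
        path.write_bytes(header + body)
    elif format == "csv":
        rr, cc = np.meshgrid(np.arange(mask.rows), np.arange(mask.cols), indexing="ij")
        frame = pd.DataFrame(
            {
                "row": rr.ravel(),
                "col": cc.ravel(),
                "physical": mask.physical.ravel().astype(int),
            }
        )
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown mask format {format!r}; valid: {MASK_FORMATS}")
    summary_path = path.with_suffix(path.suffix + ".summary.json")
    summary_path.write_text(json.dumps(mask.summary(), indent=1))
    return path


def read_mask(path, format: str = "pgm") -> RealizabilityMask:
    """Read a mask written by :func:`write_mask` (summary sidecar required)."""
    path = Path(path)
    summary_path = path.with_suffix(path.suffix + ".summary.json")
    summary = json.loads(summary_path.read_text())
    if format == "pgm":
        raw = path.read_bytes()
        if not raw.startswith(b"P5"):
            raise ValueError("not a binary PGM (P5) file")
        # header: magic, dims, maxval, single whitespace, then payload
        parts = raw.split(b"\n", 3)
        cols, rows = (int(x) for x in parts[1].split())
        body = np.frombuffer(parts[3], dtype=np.uint8, count=rows * cols)
        physical = (body == 255).reshape(rows, cols)
    elif format == "csv":
        frame = pd.read_csv(path).sort_values(["row", "col"])
        rows = int(frame["row"].max()) + 1
        cols = int(frame["col"].max()) + 1
        physical = frame["physical"].to_numpy(dtype=bool).reshape(rows, cols)
    else:
        raise ValueError(f"unknown mask format {format!r}; valid: {MASK_FORMATS}")
    return RealizabilityMask(
        physical=physical,
        method=summary["method"],
        criterion=summary["criterion"],
        tolerance=Tolerance(summary["abs_tol"], summary["rel_tol"]),
        n_invalid=summary.get("n_invalid", 0),
        invalid_policy=summary.get("invalid_policy", "count_as_nonphysical"),
    )
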