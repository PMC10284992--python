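"""Readers/writers for the small image-domain formats the pipeline exchanges.

Middlebury ``.flo`` optical flow, PFM disparity, PNG masks, and the YAML
stereo calibration file.  All arrays are row-major with row 0 at the top of
the image (PFM files store rows bottom-up and are flipped on read/write).
"""

from __future__ import annotations

import re
import struct

import numpy as np
import yaml

FLO_MAGIC = 202021.25  # sanity check value from the Middlebury spec


def read_flo(path) -> np.ndarray:
    """Read a Middlebury .flo file -> (H, W, 2) float32 flow (u, v)."""
    with open(path, "rb") as fh:
        magic = struct.unpack("<f", fh.read(4))[0]
        if abs(magic - FLO_MAGIC) > 1e-3:
            raise IOError(f"{path}: bad .flo magic {magic!r}")
        w, h = struct.unpack("<ii", fh.read(8))
        data = np.frombuffer(fh.read(w * h * 8), dtype="<f4")
        if data.size != w * h * 2:
            raise IOError(f"{path}: truncated .flo payload")
    return data.reshape(h, w, 2).copy()


def write_flo(flow: np.ndarray, path) -> None:
    flow = np.asarray(flow, dtype="<f4")
    if flow.ndim != 3 or flow.shape[2] != 2:
        raise ValueError(f"flow must be (H, W, 2), got {flow.shape}")
    h, w = flow.shape[:2]
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", FLO_MAGIC))
        fh.write(struct.pack("<ii", w, h))
        fh.write(np.ascontiguousarray(flow).tobytes())


def read_pfm(path) -> np.ndarray:
    """Read a grayscale PFM file -> (H, W) float32, row 0 at image top."""
    with open(path, "rb") as fh:
        header = fh.readline().decode("ascii").strip()
        if header not in ("Pf", "PF"):
            raise IOError(f"{path}: not a PFM file (header {header!r})")
        channels = 3 if header == "PF" else 1
        dims = fh.readline().decode("ascii")
        m = re.match(r"^(\d+)\s+(\d+)\s*$", dims)
        if not m:
            raise IOError(f"{path}: malformed PFM dimensions {dims!r}")
        w, h = int(m.group(1)), int(m.group(2))
        scale = float(fh.readline().decode("ascii").strip())
        endian = "<" if scale < 0 else ">"
        data = np.frombuffer(fh.read(w * h * channels * 4), dtype=endian + "f4")
        if data.size != w * h * channels:
            raise IOError(f"{path}: truncated PFM payload")
    img = data.reshape(h, w) if channels == 1 else data.reshape(h, w, 3)
    return np.flipud(img).copy()  # PFM rows are stored bottom-up


def write_pfm(img: np.ndarray, path) -> None:
    img = np.asarray(img, dtype="<f4")
    if img.ndim != 2:
        raise ValueError("only grayscale PFM supported")
    h, w = img.shape
    with open(path, "wb") as fh:
        fh.write(b"Pf\n")
        fh.write(f"{w} {h}\n".encode("ascii"))
        fh.write(b"-1.0\n")
        fh.write(np.ascontiguousarray(np.flipud(img)).tobytes())


def read_mask(path) -> np.ndarray:
    """Read a binary PNG mask -> (H, W) bool (non-zero = True)."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_mask(mask: np.ndarray, path) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_calibration_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    missing = {"f", "cx", "cy", "b"} - set(data)
    if missing:
        raise IOError(f"{path}: calibration missing keys {sorted(missing)}")
    return data


def write_calibration_yaml(calib, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"f": float(calib.f), "cx": float(calib.cx),
             "cy": float(calib.cy), "b": float(calib.b)},
            fh,
        )
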