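"""Image I/O and the reproducible pipeline runner.

Internal convention: pixel value 0 is black (Def.-style sublevel sets are
black sets), binary images live in {0, 1}.  At the file boundary, binary
data stored as {0, 255} is normalised to {0, 1} on read, and binary images
are exported with 0 -> 0 (black) and 1 -> 255 (white).  Supported formats
are 8-bit PNG, TIFF and PGM for single-channel data and PNG/TIFF for RGB.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import __version__
from .denoise import DenoiseParams, denoise_binary, denoise_grayscale, denoise_rgb
from .metrics import ScoreReport
from .morphology import square_se_sequence
from .persistence import diagram_to_dataframe

__all__ = ["read_image", "write_image", "RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)

_FORMATS = {".png", ".tif", ".tiff", ".pgm"}


def read_image(path, mode: str = "auto") -> np.ndarray:
    """Read an image as a 2-D array (or (H, W, 3) for RGB).

    mode "auto" detects binary data ({0, 1} or {0, 255}) on single-channel
    input and normalises it to {0, 1}; "gray" keeps raw 8-bit values;
    "binary" insists on binary data; "rgb" insists on three channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    arr = np.asarray(iio.imread(path))
    if arr.dtype not in (np.uint8, np.bool_):
        raise ValueError(f"unsupported bit depth {arr.dtype} in {path}")
    arr = arr.astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if mode == "rgb":
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(f"{path} is not an RGB image")
        return arr
    if arr.ndim == 3:
        if mode == "auto":
            return arr
        raise ValueError(f"{path} has 3 channels; expected single-channel")
    values = np.unique(arr)
    binaryish = np.isin(values, (0, 1)).all() or np.isin(values, (0, 255)).all()
    if mode == "binary" and not binaryish:
        raise ValueError(f"{path} is not a binary image")
    if mode in ("auto", "binary") and binaryish:
        return (arr > 0).astype(np.uint8)
    return arr


def write_image(img, path) -> None:
    """Write an image; binary {0, 1} data is exported as {0, 255}."""
    path = Path(path)
    if path.suffix.lower() not in _FORMATS:
        raise ValueError(f"unsupported image format: {path.suffix!r}")
    arr = np.asarray(img)
    if arr.max(initial=0) <= 1 and np.isin(np.unique(arr), (0, 1)).all():
        arr = (arr * 255).astype(np.uint8)
    if arr.max(initial=0) > 255:
        raise ValueError("only 8-bit data can be written")
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, arr.astype(np.uint8))


@dataclass
class RunConfig:
    """Configuration of one reproducible denoising run."""

    input: str = ""
    output: str = ""
    mode: str = "binary"  # binary | gray | rgb
    size_tol: int = 5
    max_iter: int = 10
    se_step: int = 1
    seed: int = 0
    trace: str = ""
    diagrams_dir: str = ""
    reference: str = ""
    score: str = ""
    dry_run: bool = False

    def params(self) -> DenoiseParams:
        seq = square_se_sequence(self.size_tol * self.se_step).subsequence(self.se_step)
        return DenoiseParams(
            size_tol=self.size_tol, max_iter=self.max_iter, se_sequence=seq
        )

    def validate(self) -> None:
        if self.mode not in ("binary", "gray", "rgb"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.se_step not in (1, 2):
            raise ValueError("se_step must be 1 or 2")
        self.params()  # raises on bad size_tol / max_iter
        if not self.dry_run and not self.input:
            raise ValueError("an input image is required")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Run a denoising job end to end and write its artifacts.

    Returns a manifest of what was produced.  The run is a deterministic
    function of the configuration (the seed only matters for callers that
    generate inputs with it).
    """
    config.validate()
    manifest = {
        "version": __version__,
        "config": dict(config.__dict__),
        "config_hash": config.digest(),
    }
    log.info("run %s: mode=%s seed=%d", config.digest(), config.mode, config.seed)
    if config.dry_run:
        manifest["dry_run"] = True
        return manifest
    params = config.params()
    if config.mode == "binary":
        img = read_image(config.input, mode="binary")
        out, trace = denoise_binary(img, params)
        if config.trace:
            Path(config.trace).parent.mkdir(parents=True, exist_ok=True)
            Path(config.trace).write_text(json.dumps(trace.to_json(), indent=1))
            manifest["trace"] = config.trace
        if config.diagrams_dir:
            d = Path(config.diagrams_dir)
            d.mkdir(parents=True, exist_ok=True)
            for i, diag in enumerate(trace.diagrams):
                p = d / f"diagram_{i:03d}.csv"
                diagram_to_dataframe(diag).to_csv(p, index=False)
            manifest["diagrams"] = [
                str(d / f"diagram_{i:03d}.csv") for i in range(len(trace.diagrams))
            ]
    elif config.mode == "gray":
        img = read_image(config.input, mode="gray")
        out = denoise_grayscale(img, params)
    else:
        img = read_image(config.input, mode="rgb")
        out = denoise_rgb(img, params)
    write_image(out, config.output)
    manifest["output"] = config.output
    if config.reference:
        ref = read_image(config.reference)
        report = ScoreReport.compute(ref, out if out.ndim == 2 else out[:, :, 0])
        if config.score:
            Path(config.score).parent.mkdir(parents=True, exist_ok=True)
            Path(config.score).write_text(json.dumps(report.to_dict(), indent=1))
            manifest["score"] = config.score
        manifest["scores"] = report.to_dict()
    return manifest
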