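"""Recording and image persistence.

Two interchangeable on-disk recording formats, selected by extension:

* text (``.tsv``/``.txt``/``.csv``): ``#``-prefixed header lines followed by
  one tab-separated row per channel — human-inspectable and diff-friendly;
* binary (``.npz``): a numpy archive with the same fields.

Both round-trip bit-identically (the text writer prints full ``%.17g``
precision).  Encoded image batches are stored as an ``.npz`` container plus
a delimited-text manifest.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .encode import EncodedImage
from .exceptions import IntegrityError, ParameterError, ParseError
from .simulate import Recording

__all__ = [
    "read_recording",
    "write_recording",
    "write_images",
    "read_images",
    "config_hash",
]

SCHEMA_VERSION = 1
_TEXT_EXT = {".tsv", ".txt", ".csv"}
_INT_FIELDS = ("n_channels", "n_samples", "gesture_id", "subject_id",
               "repetition", "schema_version")


def _header(rec: Recording) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "gesture_id": rec.gesture_id,
        "subject_id": rec.subject_id,
        "repetition": rec.repetition,
    }


def write_recording(rec: Recording, path) -> Path:
    """Write a recording; the extension picks the dialect."""
    path = Path(path)
    header = _header(rec)
    if path.suffix == ".npz":
        np.savez(path, samples=rec.samples,
                 **{k: np.asarray(v) for k, v in header.items()})
    elif path.suffix in _TEXT_EXT:
        with open(path, "w") as fh:
            fh.write("# emgpix-recording\n")
            for key, value in header.items():
                fh.write(f"# {key}={value}\n")
            np.savetxt(fh, rec.samples, fmt="%.17g", delimiter="\t")
    else:
        raise ParameterError(
            f"unknown recording extension {path.suffix!r} "
            f"(use .npz or one of {sorted(_TEXT_EXT)})"
        )
    return path


def _parse_text(path: Path) -> tuple[dict, np.ndarray]:
    header: dict = {}
    data_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped.startswith("#"):
            data_start = lineno - 1
            break
        body = stripped.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            key = key.strip()
            try:
                header[key] = (int(value) if key in _INT_FIELDS else float(value))
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: bad header value {value!r}") from err
    else:
        raise ParseError(f"{path}: no sample rows found")
    try:
        samples = np.loadtxt(lines[data_start:], delimiter="\t", ndmin=2)
    except ValueError as err:
        raise ParseError(f"{path}: malformed sample row ({err})") from err
    return header, samples


def read_recording(path) -> Recording:
    """Read either recording dialect; validates header against payload."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        if path.stat().st_size == 0:
            raise ParseError(f"{path}: empty file")
        try:
            with np.load(path, allow_pickle=False) as data:
                header = {k: data[k].item() for k in data.files if k != "samples"}
                samples = np.atleast_2d(data["samples"])
        except (OSError, KeyError, ValueError) as err:
            raise ParseError(f"{path}: not a readable recording archive ({err})") from err
    elif path.suffix in _TEXT_EXT:
        header, samples = _parse_text(path)
    else:
        raise ParameterError(f"unknown recording extension {path.suffix!r}")

    missing = [k for k in ("fs", "n_channels", "n_samples", "gesture_id") if k not in header]
    if missing:
        raise ParseError(f"{path}: header missing fields {missing}")
    if samples.shape[0] != header["n_channels"]:
        raise IntegrityError(
            f"{path}: header declares {header['n_channels']} channels, "
            f"payload has {samples.shape[0]} rows"
        )
    if samples.shape[1] != header["n_samples"]:
        raise IntegrityError(
            f"{path}: header declares {header['n_samples']} samples, "
            f"payload has {samples.shape[1]} columns"
        )
    return Recording(
        samples=samples,
        fs=float(header["fs"]),
        gesture_id=int(header["gesture_id"]),
        subject_id=int(header.get("subject_id", 0)),
        repetition=int(header.get("repetition", 0)),
    )


def write_images(images: list[EncodedImage], directory, stem: str = "images") -> tuple[Path, Path]:
    """Store an image batch: ``<stem>.npz`` pixels + ``<stem>_manifest.tsv``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {f"image_{i:06d}": im.pixels for i, im in enumerate(images)}
    npz_path = directory / f"{stem}.npz"
    np.savez(npz_path, **arrays)
    manifest = pd.DataFrame(
        {
            "image": list(arrays),
            "encoder": [im.encoder for im in images],
            "n_channels_source": [im.n_channels_source for im in images],
            "label": [im.label for im in images],
            "subject_id": [im.subject_id for im in images],
            "repetition": [im.repetition for im in images],
            "segment_index": [im.segment_index for im in images],
        }
    )
    manifest_path = directory / f"{stem}_manifest.tsv"
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return npz_path, manifest_path


def read_images(npz_path, manifest_path) -> list[EncodedImage]:
    manifest = pd.read_csv(manifest_path, sep="\t")
    out = []
    with np.load(npz_path, allow_pickle=False) as data:
        for row in manifest.itertuples(index=False):
            out.append(
                EncodedImage(
                    pixels=data[row.image],
                    encoder=row.encoder,
                    n_channels_source=int(row.n_channels_source),
                    label=int(row.label),
                    subject_id=int(row.subject_id),
                    repetition=int(row.repetition),
                    segment_index=int(row.segment_index),
                )
            )
    return out


def config_hash(config: dict) -> str:
    """Short stable digest of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
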