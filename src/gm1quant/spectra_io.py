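"""Containers and file I/O for imaging mass-spectrometry data.

Spectra travel as imzML 1.1 (via pyimzml); ROI definitions and ground truth
travel as versioned JSON sidecars (imzML itself has no ROI standard). Pixel
coordinates are 0-based internally, x = column, y = row, origin top-left;
imzML's 1-based convention is converted on read/write.
"""

from __future__ import annotations

import hashlib
import json
import uuid as _uuid
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MassSpectrum",
    "IMSDataset",
    "ROI",
    "ParseError",
    "write_dataset",
    "read_dataset",
    "write_rois",
    "read_rois",
]

ROI_SCHEMA_VERSION = 1


class ParseError(ValueError):
    """A dataset or ROI file could not be parsed/validated."""


@dataclass(frozen=True)
class MassSpectrum:
    """One m/z axis + intensity vector (a pixel, or an ROI average)."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        mz = np.asarray(self.mz, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if mz.ndim != 1 or it.ndim != 1 or mz.shape != it.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be nonnegative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)

    def __len__(self) -> int:
        return self.mz.size

    def slice(self, lo: float, hi: float) -> "MassSpectrum":
        """Sub-spectrum with lo <= m/z <= hi."""
        i0, i1 = np.searchsorted(self.mz, [lo, hi], side="left")
        if self.mz[min(i1, len(self.mz) - 1)] == hi:
            i1 += 1
        return MassSpectrum(self.mz[i0:i1], self.intensity[i0:i1])


@dataclass
class IMSDataset:
    """Pixel grid with spectra on a shared (continuous-mode) m/z axis.

    ``coordinates`` is an (N, 2) int array of (x, y); ``intensities`` is
    (N, B) aligned with ``mz`` (B bins). Processed-mode files whose axes
    differ per pixel are resampled onto a common axis on read, so the
    in-memory representation is always continuous.
    """

    coordinates: np.ndarray
    mz: np.ndarray
    intensities: np.ndarray
    pixel_pitch: float = 70.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be an (N, 2) array")
        n = self.coordinates.shape[0]
        if self.intensities.shape != (n, self.mz.size):
            raise ValueError("intensities must be (n_pixels, n_bins)")
        uniq = {tuple(c) for c in self.coordinates}
        if len(uniq) != n:
            raise ValueError("pixel coordinates must be unique")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")

    @property
    def n_pixels(self) -> int:
        return self.coordinates.shape[0]

    def spectrum(self, i: int) -> MassSpectrum:
        return MassSpectrum(self.mz, self.intensities[i])


@dataclass(frozen=True)
class ROI:
    """A set of pixel indices into one dataset, with full provenance."""

    pixel_indices: tuple[int, ...]
    region: str
    hemisphere: str
    section_id: str
    animal_id: str

    def __post_init__(self):
        idx = tuple(int(i) for i in self.pixel_indices)
        if not idx:
            raise ValueError("ROI pixel list must be non-empty")
        if any(i < 0 for i in idx):
            raise ValueError("ROI pixel indices must be nonnegative")
        for f in ("region", "hemisphere", "section_id", "animal_id"):
            if not getattr(self, f):
                raise ValueError(f"ROI field {f!r} must be non-empty")
        object.__setattr__(self, "pixel_indices", idx)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.animal_id, self.section_id, self.hemisphere, self.region)


def _deterministic_uuid(dataset: IMSDataset) -> _uuid.UUID:
    h = hashlib.sha1()
    h.update(dataset.coordinates.tobytes())
    h.update(np.ascontiguousarray(dataset.mz).tobytes())
    h.update(np.ascontiguousarray(dataset.intensities[:4]).tobytes())
    h.update(json.dumps(dataset.metadata, sort_keys=True, default=str).encode())
    return _uuid.UUID(bytes=h.digest()[:16])


def write_dataset(dataset: IMSDataset, path: str | Path) -> None:
    """Write a dataset as continuous-mode imzML (``path`` + sibling .ibd).

    The file UUID is derived from the content so reruns at a fixed seed
    produce byte-identical files.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    path = Path(path)
    det_uuid = _deterministic_uuid(dataset)
    orig_uuid4 = _uuid.uuid4
    _uuid.uuid4 = lambda: det_uuid  # pyimzml draws its file UUID from uuid4
    try:
        with ImzMLWriter(str(path), mode="continuous", polarity="negative") as w:
            for (x, y), it in zip(dataset.coordinates, dataset.intensities):
                w.addSpectrum(dataset.mz, it, (int(x) + 1, int(y) + 1, 1))
    finally:
        _uuid.uuid4 = orig_uuid4
    # pyimzml embeds the absolute output path as the run id; normalize it so
    # identical data written anywhere yields byte-identical files
    text = path.read_text()
    run_id = str(path.with_suffix(""))
    path.write_text(text.replace(f'<run defaultInstrumentConfigurationRef="IC1" id="{run_id}">',
                                 f'<run defaultInstrumentConfigurationRef="IC1" id="{path.stem}">'))


def read_dataset(
    path: str | Path, pixel_pitch: float = 70.0, metadata: dict | None = None
) -> IMSDataset:
    """Read an imzML file (continuous or processed) into an IMSDataset.

    Processed-mode pixels with differing axes are linearly resampled onto
    the first pixel's axis.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        parser = ImzMLParser(str(path))
        coords = np.array([(x - 1, y - 1) for x, y, *_ in parser.coordinates], dtype=int)
        if coords.size == 0:
            raise ParseError(f"{path}: no spectra found")
        mz0, it0 = parser.getspectrum(0)
        mz0 = np.asarray(mz0, dtype=float)
        intensities = np.empty((len(coords), mz0.size))
        intensities[0] = it0
        for i in range(1, len(coords)):
            mz, it = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=float)
            if mz.size == mz0.size and np.array_equal(mz, mz0):
                intensities[i] = it
            else:  # processed mode with per-pixel axes
                intensities[i] = np.interp(mz0, mz, np.asarray(it, dtype=float))
    except ParseError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap lxml/struct/etc. errors
        raise ParseError(f"failed to parse imzML file {path}: {exc}") from exc
    return IMSDataset(
        coordinates=coords,
        mz=mz0,
        intensities=np.clip(intensities, 0.0, None),
        pixel_pitch=pixel_pitch,
        metadata=dict(metadata or {}),
    )


def write_rois(rois: Sequence[ROI], path: str | Path) -> None:
    payload = {
        "schema_version": ROI_SCHEMA_VERSION,
        "rois": [
            {
                "animal_id": r.animal_id,
                "section_id": r.section_id,
                "hemisphere": r.hemisphere,
                "region": r.region,
                "pixels": list(r.pixel_indices),
            }
            for r in rois
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_rois(path: str | Path) -> list[ROI]:
    """Read and validate an ROI JSON sidecar.

    Duplicate (animal, section, hemisphere, region) tuples are rejected —
    each measurement must be unique.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"failed to read ROI file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "rois" not in payload:
        raise ParseError(f"{path}: missing 'rois' key")
    version = payload.get("schema_version")
    if version != ROI_SCHEMA_VERSION:
        raise ParseError(f"{path}: unsupported ROI schema version {version!r}")
    rois: list[ROI] = []
    seen: set[tuple] = set()
    for i, entry in enumerate(payload["rois"]):
        try:
            roi = ROI(
                pixel_indices=tuple(entry["pixels"]),
                region=entry["region"],
                hemisphere=entry["hemisphere"],
                section_id=entry["section_id"],
                animal_id=entry["animal_id"],
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: ROI #{i} invalid: {exc}") from exc
        if roi.key in seen:
            raise ParseError(f"{path}: duplicate ROI {roi.key}")
        seen.add(roi.key)
        rois.append(roi)
    return rois
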