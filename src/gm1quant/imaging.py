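"""Per-species ion images and two-channel composites.

Each pixel's value is the baseline-corrected highest-peak AUC of the target
species; the image is normalized to its own maximum, so intensities are
comparable within an image but never across images (images are optimized
for visualization of expression, not absolute signal). Pixels where the
peak is not detected get 0 (low-signal context), off-tissue pixels are
missing (NaN), not zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chem import SpeciesTarget
from .preprocessing import DEFAULT_FLANK_WIDTH
from .quantify import DETECTION_SNR, PeakNotFoundError, quantify_target
from .spectra_io import IMSDataset, MassSpectrum

__all__ = ["IonImage", "render_ion_image", "composite"]


@dataclass(frozen=True)
class IonImage:
    """Max-normalized 2-D intensity grid aligned to pixel coordinates."""

    values: np.ndarray  # in [0, 1]; NaN = off-tissue
    species: str
    scale: float  # the pre-normalization maximum: raw = values * scale
    pixel_pitch: float = 70.0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("normalized image values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    @property
    def raw(self) -> np.ndarray:
        return self.values * self.scale


def render_ion_image(
    dataset: IMSDataset,
    target: SpeciesTarget,
    flank_width: float = DEFAULT_FLANK_WIDTH,
    baseline_method: str = "linear_median",
    detection_snr: float = DETECTION_SNR,
) -> IonImage:
    """Per-pixel baseline-corrected highest-peak AUC, divided by the image
    maximum. An all-zero image is returned as-is with a warning."""
    if dataset.n_pixels == 0:
        raise ValueError("dataset has no pixels")
    xs, ys = dataset.coordinates[:, 0], dataset.coordinates[:, 1]
    grid = np.full((ys.max() - ys.min() + 1, xs.max() - xs.min() + 1), np.nan)
    for i in range(dataset.n_pixels):
        spec = MassSpectrum(dataset.mz, dataset.intensities[i])
        try:
            q = quantify_target(
                spec, target,
                flank_width=flank_width,
                baseline_method=baseline_method,
                detection_snr=detection_snr,
            )
            auc = q.auc
        except PeakNotFoundError:
            auc = 0.0
        grid[ys[i] - ys.min(), xs[i] - xs.min()] = auc
    vmax = np.nanmax(grid)
    if vmax <= 0:
        warnings.warn(f"ion image for {target.name} is all zero; not normalizing")
        return IonImage(grid, target.name, scale=0.0, pixel_pitch=dataset.pixel_pitch)
    return IonImage(grid / vmax, target.name, scale=float(vmax),
                    pixel_pitch=dataset.pixel_pitch)


def composite(
    green: IonImage,
    red: IonImage,
    path: str | Path | None = None,
    scalebar_um: float = 1000.0,
) -> np.ndarray:
    """Two-channel overlay (green/red) as an (H, W, 3) RGB array in [0, 1].

    Off-tissue pixels render black. If ``path`` is given, a PNG with a
    scale bar derived from the pixel pitch is written there.
    """
    if green.values.shape != red.values.shape:
        raise ValueError(
            f"channel grids differ: {green.values.shape} vs {red.values.shape}"
        )
    g = np.nan_to_num(green.values, nan=0.0)
    r = np.nan_to_num(red.values, nan=0.0)
    rgb = np.stack([r, g, np.zeros_like(g)], axis=-1)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6 * rgb.shape[0] / max(rgb.shape[1], 1)))
        ax.imshow(rgb, interpolation="nearest")
        ax.set_axis_off()
        bar_px = scalebar_um / green.pixel_pitch
        if bar_px < rgb.shape[1]:
            y = rgb.shape[0] - max(1.0, rgb.shape[0] * 0.05)
            x0 = rgb.shape[1] * 0.05
            ax.plot([x0, x0 + bar_px], [y, y], color="white", linewidth=3)
            ax.text(
                x0, y - rgb.shape[0] * 0.03,
                f"{scalebar_um / 1000:g} mm", color="white", fontsize=9,
            )
        fig.savefig(path, dpi=200, bbox_inches="tight", pad_inches=0.02)
        plt.close(fig)
    return rgb
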