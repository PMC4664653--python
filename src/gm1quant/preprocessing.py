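"""Local baseline removal around a targeted peak.

The baseline under each species' peak cluster is estimated from two flanking
sub-windows just outside the correction window: a straight line is drawn
through one anchor point per flank and subtracted; negative residuals are
clipped to zero. Because any order statistic of a straight-line segment lies
on the line, both anchor choices remove constant and linear baselines
exactly on noise-free data. They differ under noise:

* ``median`` (default): the flank median is unbiased under symmetric noise.
  Heavier-isotope peaks of the species fall inside the high-m/z flank and
  raise its median in proportion to the peak amplitude — that component is
  common-mode between the two species and cancels in their AUC ratio
  (verified to <1% on realistic envelopes).
* ``min``: anchors at the minimum-intensity point of each flank, the way
  interactive baseline tools behave and exactly idempotent — but the
  minimum of a noisy flank is an extreme statistic biased low by ~2.3
  noise-SD, which inflates both AUCs and drags low-signal ratios toward 1
  (about -8% on white-matter-level spectra at default noise). Use it for
  noise-free or strongly averaged data.

A top-hat (morphological opening) estimator is also available for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import SpeciesTarget
from .spectra_io import MassSpectrum

__all__ = ["remove_local_baseline", "local_baseline", "BaselineFit", "DEFAULT_FLANK_WIDTH"]

DEFAULT_FLANK_WIDTH = 1.0  # Da


@dataclass(frozen=True)
class BaselineFit:
    """Window + fitted baseline, before clipping.

    ``mz``/``intensity`` span the correction window plus both flanks;
    ``baseline`` is the fitted line (or top-hat floor) on that axis;
    ``window`` the inner (search + integration) m/z bounds.
    """

    mz: np.ndarray
    intensity: np.ndarray
    baseline: np.ndarray
    window: tuple[float, float]

    @property
    def residual(self) -> np.ndarray:
        """Unclipped corrected intensities (may be negative)."""
        return self.intensity - self.baseline

    def corrected(self) -> MassSpectrum:
        return MassSpectrum(self.mz, np.clip(self.residual, 0.0, None))

    def left_flank_residual(self) -> np.ndarray:
        """Unclipped residuals below the window — the peak-free side, used
        as the noise reference for detection."""
        return self.residual[self.mz < self.window[0]]


def _anchor(xs: np.ndarray, vals: np.ndarray, stat: str) -> tuple[float, float]:
    if stat == "min":
        k = int(np.argmin(vals))
        return float(xs[k]), float(vals[k])
    if stat == "median":
        # on a uniform grid the median of a linear segment equals the line's
        # value at the mean abscissa, so linear baselines are removed exactly
        return float(xs.mean()), float(np.median(vals))
    raise ValueError(f"unknown baseline anchor {stat!r}")


def local_baseline(
    spectrum: MassSpectrum,
    target: SpeciesTarget,
    flank_width: float = DEFAULT_FLANK_WIDTH,
    method: str = "linear_median",
) -> BaselineFit:
    """Fit (do not subtract) the local baseline around ``target``.

    ``method``: ``linear_median`` (default), ``linear_minima``, ``tophat``.
    """
    if flank_width <= 0:
        raise ValueError("flank_width must be > 0")
    mz, it = spectrum.mz, spectrum.intensity
    lo, hi = target.window_bounds()
    flo, fhi = lo - flank_width, hi + flank_width
    if flo < mz[0] or fhi > mz[-1]:
        raise ValueError(
            f"target window [{flo:.3f}, {fhi:.3f}] (incl. flanks) exceeds "
            f"spectrum range [{mz[0]:.3f}, {mz[-1]:.3f}]"
        )
    i0 = int(np.searchsorted(mz, flo, side="left"))
    i1 = int(np.searchsorted(mz, fhi, side="right"))
    wmz = mz[i0:i1]
    wit = it[i0:i1].copy()

    if method in ("linear_median", "linear_minima"):
        stat = "median" if method == "linear_median" else "min"
        left = wmz < lo
        right = wmz > hi
        if not left.any() or not right.any():
            raise ValueError("flanking windows are empty at this m/z binning")
        x0, y0 = _anchor(wmz[left], wit[left], stat)
        x1, y1 = _anchor(wmz[right], wit[right], stat)
        baseline = y0 + (y1 - y0) * (wmz - x0) / (x1 - x0)
    elif method == "tophat":
        from scipy.ndimage import grey_opening

        bin_width = float(np.median(np.diff(wmz)))
        size = max(3, int(round(4 * target.integration_halfwidth / bin_width)) | 1)
        baseline = grey_opening(wit, size=size)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    return BaselineFit(wmz, wit, baseline, (lo, hi))


def remove_local_baseline(
    spectrum: MassSpectrum,
    target: SpeciesTarget,
    flank_width: float = DEFAULT_FLANK_WIDTH,
    method: str = "linear_median",
) -> MassSpectrum:
    """Baseline-corrected sub-spectrum around ``target``.

    The returned spectrum spans the correction window *plus* both flanks
    (downstream peak detection uses the corrected flanks as its noise
    reference); negative residuals are clipped to 0; the input spectrum is
    untouched.
    """
    return local_baseline(spectrum, target, flank_width, method).corrected()
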