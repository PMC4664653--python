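"""Targeted highest-peak AUC quantification and the d18:1/d20:1 ratio.

For each species the apex is the maximum-intensity local maximum within
``predicted_mz ± search_halfwidth`` of the baseline-corrected window; the
AUC is the trapezoidal integral over ``apex ± integration_halfwidth``.
Only the highest (monoisotopic) peak is integrated — its AUC is taken as
indicative of the species' total signal, and the per-ROI measurand is
AUC(d18:1) / AUC(d20:1). Because both AUCs share every multiplicative
factor of the pixel spectra, the ratio is exactly invariant under global
intensity gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chem import SpeciesTarget, default_targets
from .preprocessing import DEFAULT_FLANK_WIDTH, local_baseline
from .spectra_io import IMSDataset, MassSpectrum, ROI

__all__ = [
    "PeakNotFoundError",
    "PeakQuantification",
    "RatioRecord",
    "find_highest_peak",
    "integrate_auc",
    "quantify_target",
    "roi_ratio",
    "records_to_frame",
]

log = logging.getLogger(__name__)

#: apex must exceed ``DETECTION_SNR`` robust noise sd (1.4826*MAD of the
#: corrected flanks) to count as detected.
DETECTION_SNR = 3.0


class PeakNotFoundError(ValueError):
    """No local maximum above the detection floor in the search window."""

    def __init__(self, target: SpeciesTarget, lo: float, hi: float, floor: float):
        super().__init__(
            f"no peak for {target.name} above detection floor {floor:.4g} "
            f"in window [{lo:.3f}, {hi:.3f}]"
        )
        self.target, self.window, self.floor = target, (lo, hi), floor


@dataclass(frozen=True)
class PeakQuantification:
    species: str
    apex_mz: float
    apex_intensity: float
    auc: float
    bounds: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.bounds
        if not lo < self.apex_mz < hi:
            raise ValueError("apex must lie strictly inside the integration bounds")
        if self.auc < 0:
            raise ValueError("AUC must be nonnegative")


@dataclass(frozen=True)
class RatioRecord:
    """One ROI's d18:1/d20:1 AUC ratio with full provenance.

    Invalid measurements (a missing peak, a zero denominator) are kept as
    flagged records with ``valid=False`` and excluded downstream, never
    silently dropped.
    """

    animal_id: str
    section_id: str
    hemisphere: str
    region: str
    ratio: float
    numerator: PeakQuantification | None = None
    denominator: PeakQuantification | None = None
    valid: bool = True
    reason: str | None = None

    def __post_init__(self):
        if self.valid and not self.ratio > 0:
            raise ValueError("a valid RatioRecord must have ratio > 0")
        for f in ("animal_id", "section_id", "hemisphere", "region"):
            if not getattr(self, f):
                raise ValueError(f"RatioRecord field {f!r} must be non-empty")


def _noise_floor(fit, snr: float) -> float:
    """Detection floor: ``snr`` robust noise SDs (1.4826*MAD of the
    unclipped low-m/z flank residuals — the peak-free side)."""
    resid = fit.left_flank_residual()
    if resid.size == 0:
        return 0.0
    mad = np.median(np.abs(resid - np.median(resid)))
    return snr * 1.4826 * float(mad)


def find_highest_peak(
    corrected: MassSpectrum,
    target: SpeciesTarget,
    detection_floor: float = 0.0,
) -> tuple[float, float]:
    """Apex (m/z, intensity) of the highest local maximum near predicted m/z.

    Ties are broken toward the candidate closest to the predicted m/z, and
    an exactly equidistant tie toward the lower m/z.
    """
    mz, it = corrected.mz, corrected.intensity
    lo = target.predicted_mz - target.search_halfwidth
    hi = target.predicted_mz + target.search_halfwidth
    sel = (mz >= lo) & (mz <= hi)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise PeakNotFoundError(target, lo, hi, detection_floor)
    i0, i1 = idx[0], idx[-1]
    # local maxima within the search window (window-edge points excluded
    # unless they are also spectrum edges)
    prev = it[np.maximum(idx - 1, 0)]
    nxt = it[np.minimum(idx + 1, it.size - 1)]
    cand = idx[(it[idx] >= prev) & (it[idx] >= nxt) & (it[idx] > detection_floor) & (it[idx] > 0)]
    if cand.size == 0:
        raise PeakNotFoundError(target, lo, hi, detection_floor)
    best = it[cand] == it[cand].max()
    cand = cand[best]
    dist = np.abs(mz[cand] - target.predicted_mz)
    cand = cand[dist == dist.min()]
    i = int(cand.min())  # equidistant tie -> lower m/z
    return float(mz[i]), float(it[i])


def integrate_auc(
    corrected: MassSpectrum, apex_mz: float, target: SpeciesTarget
) -> tuple[float, tuple[float, float]]:
    """Trapezoidal AUC over ``apex ± integration_halfwidth``."""
    lo = apex_mz - target.integration_halfwidth
    hi = apex_mz + target.integration_halfwidth
    if lo < corrected.mz[0] - 1e-9 or hi > corrected.mz[-1] + 1e-9:
        raise ValueError(
            f"integration bounds [{lo:.3f}, {hi:.3f}] exceed the corrected window"
        )
    # small tolerance so bounds landing exactly on a grid point are included
    # regardless of floating-point rounding of apex +/- halfwidth
    sel = (corrected.mz >= lo - 1e-9) & (corrected.mz <= hi + 1e-9)
    auc = float(np.trapezoid(corrected.intensity[sel], corrected.mz[sel]))
    return auc, (lo, hi)


def quantify_target(
    spectrum: MassSpectrum,
    target: SpeciesTarget,
    flank_width: float = DEFAULT_FLANK_WIDTH,
    baseline_method: str = "linear_median",
    detection_snr: float = DETECTION_SNR,
) -> PeakQuantification:
    """Baseline-correct, locate and integrate one species' highest peak."""
    fit = local_baseline(spectrum, target, flank_width=flank_width, method=baseline_method)
    corrected = fit.corrected()
    floor = _noise_floor(fit, detection_snr)
    apex_mz, apex_it = find_highest_peak(corrected, target, detection_floor=floor)
    auc, bounds = integrate_auc(corrected, apex_mz, target)
    return PeakQuantification(target.name, apex_mz, apex_it, auc, bounds)


def roi_ratio(
    dataset: IMSDataset,
    roi: ROI,
    targets: Sequence[SpeciesTarget] | None = None,
    flank_width: float = DEFAULT_FLANK_WIDTH,
    baseline_method: str = "linear_median",
    detection_snr: float = DETECTION_SNR,
) -> RatioRecord:
    """Quantify one ROI: mean spectrum -> per-target baseline removal ->
    highest-peak AUCs -> AUC(d18:1)/AUC(d20:1)."""
    from .roi_analysis import roi_mean_spectrum

    num_t, den_t = targets if targets is not None else default_targets()
    mean_spec = roi_mean_spectrum(dataset, roi)
    quants: dict[str, PeakQuantification | None] = {}
    for t in (num_t, den_t):
        try:
            quants[t.name] = quantify_target(
                mean_spec, t,
                flank_width=flank_width,
                baseline_method=baseline_method,
                detection_snr=detection_snr,
            )
        except PeakNotFoundError as exc:
            log.warning("ROI %s: %s", roi.key, exc)
            quants[t.name] = None
    num, den = quants[num_t.name], quants[den_t.name]
    meta = dict(
        animal_id=roi.animal_id, section_id=roi.section_id,
        hemisphere=roi.hemisphere, region=roi.region,
    )
    if num is None or den is None:
        missing = [t.name for t in (num_t, den_t) if quants[t.name] is None]
        return RatioRecord(
            **meta, ratio=float("nan"), numerator=num, denominator=den,
            valid=False, reason=f"peak not found: {', '.join(missing)}",
        )
    if den.auc <= 0:
        log.warning("ROI %s: zero denominator AUC for %s", roi.key, den_t.name)
        return RatioRecord(
            **meta, ratio=float("nan"), numerator=num, denominator=den,
            valid=False, reason=f"zero AUC for {den_t.name}",
        )
    return RatioRecord(**meta, ratio=num.auc / den.auc, numerator=num, denominator=den)


def records_to_frame(records: Sequence[RatioRecord]):
    """Tidy per-ROI table (one row per ROI measurement)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "section_id": r.section_id,
                "hemisphere": r.hemisphere,
                "region": r.region,
                "ratio": r.ratio,
                "valid": r.valid,
                "reason": r.reason,
                "auc_num": r.numerator.auc if r.numerator else np.nan,
                "auc_den": r.denominator.auc if r.denominator else np.nan,
                "apex_mz_num": r.numerator.apex_mz if r.numerator else np.nan,
                "apex_mz_den": r.denominator.apex_mz if r.denominator else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "section_id", "hemisphere", "region", "ratio",
            "valid", "reason", "auc_num", "auc_den", "apex_mz_num", "apex_mz_den",
        ],
    )
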