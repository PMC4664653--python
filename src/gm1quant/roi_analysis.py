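"""ROI mean spectra, per-animal averaging with exclusion, region summaries.

The unit of statistical analysis is the animal: per-ROI ratios are averaged
within each (animal, region) group — typically four measurements per animal
(both hemispheres in two sections; eight for regions sampled in four
sections) — and groups with fewer than two valid measurements are excluded.
Region summaries report mean ± SEM over the per-animal means, with the SEM
based on the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .quantify import RatioRecord
from .spectra_io import IMSDataset, MassSpectrum, ROI

__all__ = [
    "AnimalRegionMean",
    "RegionSummary",
    "roi_mean_spectrum",
    "animal_averages",
    "region_summaries",
    "means_to_frame",
    "summaries_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnimalRegionMean:
    animal_id: str
    region: str
    mean_ratio: float
    n_measurements: int

    def __post_init__(self):
        # under the default exclusion rule (min_measurements = 2) records
        # with a single measurement are never created by animal_averages
        if self.n_measurements < 1:
            raise ValueError("an AnimalRegionMean requires at least one measurement")


@dataclass(frozen=True)
class RegionSummary:
    region: str
    mean: float
    sem: float
    n_animals: int

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def roi_mean_spectrum(dataset: IMSDataset, roi: ROI) -> MassSpectrum:
    """Unweighted per-bin mean over the ROI's member pixels."""
    idx = np.asarray(roi.pixel_indices)
    if idx.size == 0:
        raise ValueError("empty ROI")
    if idx.max() >= dataset.n_pixels:
        raise IndexError(
            f"ROI {roi.key} references pixel {idx.max()} but dataset has "
            f"{dataset.n_pixels} pixels"
        )
    return MassSpectrum(dataset.mz, dataset.intensities[idx].mean(axis=0))


def animal_averages(
    records: Sequence[RatioRecord], min_measurements: int = 2
) -> list[AnimalRegionMean]:
    """Group valid ratios by (animal, region) and average.

    Groups with fewer than ``min_measurements`` valid measurements are
    excluded with a log entry (exclusion is part of the contract, not an
    error). Ordering of the input never affects the result.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if not r.valid:
            log.info("excluding invalid measurement %s: %s",
                     (r.animal_id, r.section_id, r.hemisphere, r.region), r.reason)
            continue
        groups.setdefault((r.animal_id, r.region), []).append(r.ratio)
    out: list[AnimalRegionMean] = []
    for (animal, region) in sorted(groups):
        vals = groups[(animal, region)]
        if len(vals) < min_measurements:
            log.info(
                "excluding animal %s region %s: %d < %d valid measurements",
                animal, region, len(vals), min_measurements,
            )
            continue
        # sort before summing so the mean is exactly permutation-invariant
        out.append(AnimalRegionMean(animal, region, float(np.mean(np.sort(vals))), len(vals)))
    return out


def region_summaries(means: Sequence[AnimalRegionMean]) -> list[RegionSummary]:
    """Per-region mean ± SEM over per-animal means.

    SEM = sample sd / sqrt(n_animals); a single-animal region gets sem = 0
    by convention and is flagged by its n.
    """
    groups: dict[str, list[float]] = {}
    for m in means:
        groups.setdefault(m.region, []).append(m.mean_ratio)
    out: list[RegionSummary] = []
    for region in sorted(groups):
        vals = np.sort(np.asarray(groups[region]))  # permutation-invariant sums
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out.append(RegionSummary(region, float(vals.mean()), sem, int(vals.size)))
    return out


def means_to_frame(means: Sequence[AnimalRegionMean]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"animal_id": m.animal_id, "region": m.region,
             "mean_ratio": m.mean_ratio, "n_measurements": m.n_measurements}
            for m in means
        ],
        columns=["animal_id", "region", "mean_ratio", "n_measurements"],
    )


def summaries_to_frame(summaries: Sequence[RegionSummary]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"region": s.region, "mean": s.mean, "sem": s.sem, "n_animals": s.n_animals}
            for s in summaries
        ],
        columns=["region", "mean", "sem", "n_animals"],
    )
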