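"""Seeded, ground-truth-known IMS study simulator.

Emulates the anatomical study design this package analyzes: multi-region
brain phantoms sampled at a 70 µm pixel pitch, each region expressing the
two GM1 species at a region-specific d18:1/d20:1 ratio, acquired over
multiple sections and hemispheres for a cohort of animals.

Per-pixel spectra are built as

    intensity(m/z) = gain * sum_s ab_s * sum_k frac_{s,k} * N(m/z; mu_{s,k}, sigma)
                     + baseline(m/z) + noise,   clipped at 0

where the peak positions are the species' [M-H]- isotope-envelope masses,
``frac`` the envelope abundances, ``gain`` a per-pixel lognormal factor
(matrix/detector variability; cancels in the ratio), the baseline a
constant + slope + broad Gaussian bump, and the noise additive Gaussian.

Species abundances are parameterized from the *highest-peak AUC ratio* —
the pipeline's measurand — not the total-envelope ratio: with ``rho =
true_ratio * f2 / f1`` (f = monoisotopic fraction of each envelope),
``ab1 = total * rho / (1 + rho)`` and ``ab2 = total / (1 + rho)``, so the
expected recovered ratio equals ``true_ratio`` exactly.

Biological variability: real animals do not share one exact ratio — the
between-animal spreads reported for this kind of study imply relative SDs
of roughly 5-25% per region. The generator therefore draws a mean-centred
lognormal animal effect and ROI effect on the local true ratio
(``ratio_animal_cv``, ``ratio_roi_cv``, default 0.08 each). Set both to 0
for purely technical-noise simulations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .chem import SpeciesTarget, default_targets
from .spectra_io import IMSDataset, MassSpectrum, ROI

__all__ = [
    "RegionMap",
    "RegionParams",
    "BaselineParams",
    "SimulationConfig",
    "GroundTruth",
    "build_phantom",
    "simulate_pixel_spectrum",
    "iter_sections",
    "simulate_study",
    "write_study",
]

PHANTOM_LAYOUTS = ("single", "pair", "cortex3", "hippo6")

_LAYOUT_LABELS = {
    "single": ("region",),
    "pair": ("A", "B"),
    "cortex3": ("superficial", "intermediate", "deep"),
    "hippo6": ("DG_gc", "DG_ml", "CA1_pc", "CA1_rad", "CA3_pc", "CA3_rad"),
}


@dataclass(frozen=True)
class RegionMap:
    """2-D grid of region labels (None = off-tissue) at a pixel pitch in µm."""

    grid: np.ndarray
    pixel_pitch: float = 70.0

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=object)
        if grid.ndim != 2:
            raise ValueError("phantom grid must be 2-D")
        if not any(lbl is not None for lbl in grid.ravel()):
            raise ValueError("phantom must contain at least one on-tissue region")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        object.__setattr__(self, "grid", grid)

    @property
    def labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lbl in self.grid.ravel():
            if lbl is not None:
                seen.setdefault(lbl)
        return tuple(seen)


def build_phantom(
    layout: str,
    dims: tuple[int, int],
    pixel_pitch: float = 70.0,
    labels: Sequence[str] | None = None,
) -> RegionMap:
    """Deterministic label grid for a named layout.

    ``dims`` = (rows, cols), at least 8x8. Layouts: ``single`` (one label),
    ``pair`` (two horizontal blocks), ``cortex3`` (three equal-depth
    horizontal bands, superficial at the top), ``hippo6`` (six vertical
    stripes).
    """
    rows, cols = dims
    if rows < 8 or cols < 8:
        raise ValueError("phantom dims must be at least 8x8")
    if layout not in PHANTOM_LAYOUTS:
        raise ValueError(f"unknown phantom layout {layout!r}; known: {PHANTOM_LAYOUTS}")
    names = tuple(labels) if labels is not None else _LAYOUT_LABELS[layout]
    if len(names) != len(_LAYOUT_LABELS[layout]):
        raise ValueError(
            f"layout {layout!r} needs {len(_LAYOUT_LABELS[layout])} labels"
        )
    grid = np.empty((rows, cols), dtype=object)
    if layout == "single":
        grid[:] = names[0]
    elif layout in ("pair", "cortex3"):
        bands = np.array_split(np.arange(rows), len(names))
        for name, band in zip(names, bands):
            grid[band] = name
    else:  # hippo6: vertical stripes
        stripes = np.array_split(np.arange(cols), len(names))
        for name, stripe in zip(names, stripes):
            grid[:, stripe] = name
    return RegionMap(grid, pixel_pitch)


@dataclass(frozen=True)
class RegionParams:
    """Generating parameters of one region: the expected highest-peak AUC
    ratio and the total GM1 signal level (arbitrary units)."""

    true_ratio: float
    total_intensity: float = 100.0

    def __post_init__(self):
        if self.true_ratio <= 0:
            raise ValueError("true_ratio must be > 0")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")


@dataclass(frozen=True)
class BaselineParams:
    """Additive chemical background: constant + linear slope + broad bump."""

    constant: float = 2.0
    slope: float = -0.002  # per Da, anchored at the low edge of the axis
    bump_amplitude: float = 5.0
    bump_center: float = 1500.0
    bump_sigma: float = 120.0


@dataclass
class SimulationConfig:
    """Everything needed to regenerate a study bit-identically from a seed."""

    regions: Mapping[str, RegionParams]
    mz_range: tuple[float, float] = (1000.0, 2000.0)
    mz_bin: float = 0.02
    peak_sigma: float = 0.15
    baseline: BaselineParams = field(default_factory=BaselineParams)
    gain_sigma: float = 0.3
    noise_sigma: float = 1.0
    ratio_animal_cv: float = 0.08
    ratio_roi_cv: float = 0.08
    n_animals: int = 1
    sections_per_animal: int = 2
    hemispheres: tuple[str, ...] = ("left", "right")
    roi_drop_rate: float | Mapping[str, float] = 0.0
    roi_max_pixels: int | None = None
    rng_seed: int = 0
    envelope_peaks: int = 8
    targets: tuple[SpeciesTarget, SpeciesTarget] = field(default_factory=default_targets)

    def __post_init__(self):
        self.regions = {k: v for k, v in self.regions.items()}
        if not self.regions:
            raise ValueError("at least one region must be declared")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must be (low, high) with low < high")
        if self.mz_bin <= 0 or self.peak_sigma <= 0:
            raise ValueError("mz_bin and peak_sigma must be > 0")
        if self.n_animals < 1 or self.sections_per_animal < 1:
            raise ValueError("n_animals and sections_per_animal must be >= 1")
        if self.noise_sigma < 0 or self.gain_sigma < 0:
            raise ValueError("noise/gain sigmas must be >= 0")
        if self.ratio_animal_cv < 0 or self.ratio_roi_cv < 0:
            raise ValueError("ratio CVs must be >= 0")
        for t in self.targets:
            masses = t.ion_peak_masses(self.envelope_peaks)
            wlo, whi = t.window_bounds()
            if wlo - 1.5 < lo or max(whi + 1.5, masses.max()) > hi:
                raise ValueError(
                    f"mz_range {self.mz_range} does not contain the envelope and "
                    f"correction window of {t.name}"
                )

    @property
    def mz_axis(self) -> np.ndarray:
        lo, hi = self.mz_range
        n = int(round((hi - lo) / self.mz_bin)) + 1
        return lo + self.mz_bin * np.arange(n)

    def species_abundances(self, region: str, local_ratio: float | None = None) -> tuple[float, float]:
        """(ab_num, ab_den) giving an expected highest-peak AUC ratio equal
        to the region's true ratio (or ``local_ratio`` if given)."""
        params = self.regions[region]
        r = params.true_ratio if local_ratio is None else local_ratio
        t1, t2 = self.targets
        f1 = t1.envelope(self.envelope_peaks).monoisotopic_fraction()
        f2 = t2.envelope(self.envelope_peaks).monoisotopic_fraction()
        rho = r * f2 / f1
        total = params.total_intensity
        return total * rho / (1.0 + rho), total / (1.0 + rho)

    def baseline_values(self, mz: np.ndarray) -> np.ndarray:
        b = self.baseline
        return (
            b.constant
            + b.slope * (mz - self.mz_range[0])
            + b.bump_amplitude * np.exp(-0.5 * ((mz - b.bump_center) / b.bump_sigma) ** 2)
        )

    def signal_profile(self, region: str, local_ratio: float | None = None) -> np.ndarray:
        """Noise-free, gain-free signal vector on the shared axis."""
        mz = self.mz_axis
        out = np.zeros_like(mz)
        abunds = self.species_abundances(region, local_ratio)
        norm = 1.0 / (self.peak_sigma * np.sqrt(2.0 * np.pi))
        for ab, target in zip(abunds, self.targets):
            env = target.envelope(self.envelope_peaks)
            fracs = env.abundances / env.abundances.sum()
            for mu, frac in zip(target.ion_peak_masses(self.envelope_peaks), fracs):
                i0, i1 = np.searchsorted(mz, [mu - 6 * self.peak_sigma, mu + 6 * self.peak_sigma])
                d = mz[i0:i1] - mu
                out[i0:i1] += ab * frac * norm * np.exp(-0.5 * (d / self.peak_sigma) ** 2)
        return out

    def _drop_rate(self, animal_id: str) -> float:
        if isinstance(self.roi_drop_rate, Mapping):
            return float(self.roi_drop_rate.get(animal_id, 0.0))
        return float(self.roi_drop_rate)


@dataclass
class GroundTruth:
    """Generating values stored alongside every simulated study."""

    seed: int
    true_ratios: dict[str, float]
    rois: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(seed=d["seed"], true_ratios=d["true_ratios"], rois=d["rois"])


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _lognormal_effect(rng: np.random.Generator, cv: float, size=None):
    """exp(N(-cv^2/2, cv)): multiplicative, mean exactly 1."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    return np.exp(rng.normal(-0.5 * cv * cv, cv, size=size))


def simulate_pixel_spectrum(
    config: SimulationConfig,
    region: str,
    rng: np.random.Generator,
    local_ratio: float | None = None,
) -> MassSpectrum:
    """One pixel's spectrum: gain x signal + baseline + noise, clipped at 0."""
    if region not in config.regions:
        raise ValueError(f"region {region!r} not declared in config")
    mz = config.mz_axis
    gain = float(_lognormal_effect(rng, config.gain_sigma))
    it = gain * config.signal_profile(region, local_ratio) + config.baseline_values(mz)
    if config.noise_sigma > 0:
        it = it + rng.normal(0.0, config.noise_sigma, size=mz.size)
    return MassSpectrum(mz, np.clip(it, 0.0, None))


def _mirrored_grid(phantom: RegionMap, hemispheres: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Full-section grid (left = phantom, right = mirror image) plus a
    same-shape hemisphere-label grid."""
    g = phantom.grid
    if len(hemispheres) == 2:
        grid = np.concatenate([g, g[:, ::-1]], axis=1)
        hemi = np.empty_like(grid)
        hemi[:, : g.shape[1]] = hemispheres[0]
        hemi[:, g.shape[1]:] = hemispheres[1]
    elif len(hemispheres) == 1:
        grid = g.copy()
        hemi = np.full_like(grid, hemispheres[0])
    else:
        raise ValueError("hemispheres must name one or two hemispheres")
    return grid, hemi


def iter_sections(
    config: SimulationConfig, phantom: RegionMap
) -> Iterator[tuple[IMSDataset, list[ROI], list[dict]]]:
    """Yield one (dataset, rois, roi_truth) triple per animal-section.

    Datasets are generated lazily so arbitrarily large cohorts can be
    quantified in a streaming fashion. Seeding is hierarchical (master seed
    -> animal -> section), so any subset is reproducible on its own.
    """
    for lbl in phantom.labels:
        if lbl not in config.regions:
            raise ValueError(f"phantom region {lbl!r} has no RegionParams in config")
    mz = config.mz_axis
    baseline = config.baseline_values(mz)
    grid, hemi_grid = _mirrored_grid(phantom, config.hemispheres)
    rows, cols = grid.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    on = np.array([lbl is not None for lbl in grid.ravel()])
    coords = np.column_stack([xx.ravel()[on], yy.ravel()[on]])
    labels_flat = grid.ravel()[on]
    hemis_flat = hemi_grid.ravel()[on]
    n_px = coords.shape[0]

    for a in range(config.n_animals):
        animal_id = f"A{a + 1:02d}"
        rng_a = _rng(config.rng_seed, a, 0)
        animal_eff = {
            region: float(_lognormal_effect(rng_a, config.ratio_animal_cv))
            for region in phantom.labels
        }
        drop_rate = config._drop_rate(animal_id)
        for s in range(config.sections_per_animal):
            section_id = f"S{s + 1}"
            rng = _rng(config.rng_seed, a, 1 + s)
            intensities = np.empty((n_px, mz.size))
            gains = _lognormal_effect(rng, config.gain_sigma, size=n_px)
            rois: list[ROI] = []
            truths: list[dict] = []
            for hemi in config.hemispheres:
                for region in phantom.labels:
                    sel = np.flatnonzero((labels_flat == region) & (hemis_flat == hemi))
                    roi_eff = float(_lognormal_effect(rng, config.ratio_roi_cv))
                    local_ratio = (
                        config.regions[region].true_ratio * animal_eff[region] * roi_eff
                    )
                    profile = config.signal_profile(region, local_ratio)
                    intensities[sel] = gains[sel, None] * profile[None, :]
                    dropped = bool(rng.random() < drop_rate)
                    idx = sel
                    if config.roi_max_pixels is not None:
                        idx = sel[: config.roi_max_pixels]
                    if not dropped:
                        rois.append(
                            ROI(
                                pixel_indices=tuple(int(i) for i in idx),
                                region=region,
                                hemisphere=hemi,
                                section_id=section_id,
                                animal_id=animal_id,
                            )
                        )
                    truths.append(
                        {
                            "animal_id": animal_id,
                            "section_id": section_id,
                            "hemisphere": hemi,
                            "region": region,
                            "local_ratio": local_ratio,
                            "mean_gain": float(gains[sel].mean()),
                            "dropped": dropped,
                        }
                    )
            intensities += baseline[None, :]
            if config.noise_sigma > 0:
                intensities += rng.normal(0.0, config.noise_sigma, size=intensities.shape)
            np.clip(intensities, 0.0, None, out=intensities)
            dataset = IMSDataset(
                coordinates=coords.copy(),
                mz=mz,
                intensities=intensities,
                pixel_pitch=phantom.pixel_pitch,
                metadata={
                    "animal_id": animal_id,
                    "section_id": section_id,
                    "rng_seed": config.rng_seed,
                },
            )
            yield dataset, rois, truths


def simulate_study(
    config: SimulationConfig, phantom: RegionMap
) -> tuple[list[IMSDataset], list[ROI], GroundTruth]:
    """Materialize the whole study: one dataset per animal-section, ROI
    masks mirroring the phantom regions per hemisphere, and the ground
    truth needed to predict any pipeline output."""
    datasets: list[IMSDataset] = []
    rois: list[ROI] = []
    truth = GroundTruth(
        seed=config.rng_seed,
        true_ratios={r: p.true_ratio for r, p in config.regions.items()},
    )
    for dataset, section_rois, truths in iter_sections(config, phantom):
        datasets.append(dataset)
        rois.extend(section_rois)
        truth.rois.extend(truths)
    return datasets, rois, truth


def write_study(
    config: SimulationConfig, phantom: RegionMap, outdir: str | Path
) -> list[Path]:
    """Simulate and write a study tree: one imzML per animal-section, a
    rois.json sidecar (ROI indices carry a dataset filename field via
    naming convention <animal>_<section>.imzML), and ground_truth.json."""
    from .spectra_io import write_dataset, write_rois

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    all_rois: list[ROI] = []
    truth = GroundTruth(
        seed=config.rng_seed,
        true_ratios={r: p.true_ratio for r, p in config.regions.items()},
    )
    for dataset, section_rois, truths in iter_sections(config, phantom):
        name = f"{dataset.metadata['animal_id']}_{dataset.metadata['section_id']}.imzML"
        write_dataset(dataset, outdir / name)
        paths.append(outdir / name)
        all_rois.extend(section_rois)
        truth.rois.extend(truths)
    write_rois(all_rois, outdir / "rois.json")
    truth.to_json(outdir / "ground_truth.json")
    return paths
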