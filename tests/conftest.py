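import numpy as np
import pytest

from gm1quant.chem import MolecularFormula, SpeciesTarget, default_targets


@pytest.fixture(scope="session")
def gm1_targets():
    return default_targets()


def make_target(
    mz0: float,
    name: str = "probe",
    search_halfwidth: float = 0.5,
    integration_halfwidth: float = 0.4,
) -> SpeciesTarget:
    """A quantification target at an arbitrary m/z (formula irrelevant)."""
    return SpeciesTarget(
        name=name,
        formula=MolecularFormula.parse("H2O"),
        predicted_mz=mz0,
        search_halfwidth=search_halfwidth,
        integration_halfwidth=integration_halfwidth,
    )


def gaussian_peak(mz: np.ndarray, mu: float, amplitude: float, sigma: float) -> np.ndarray:
    """Gaussian with apex height ``amplitude`` (not unit area)."""
    return amplitude * np.exp(-0.5 * ((mz - mu) / sigma) ** 2)


def mz_axis(lo: float = 1530.0, hi: float = 1590.0, bin_width: float = 0.02) -> np.ndarray:
    n = int(round((hi - lo) / bin_width)) + 1
    return lo + bin_width * np.arange(n)
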