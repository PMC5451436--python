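"""Lorentzian broadening of stick spectra and difference spectra.

Tabulated vertical excitation lines (energy in eV, oscillator strength) are
convolved with unit-peak Lorentzians,

    A(E) = sum_i f_i * gamma^2 / ((E - E_i)^2 + gamma^2),

to form broadened absorption spectra; NPQ-minus-Fm style signed difference
spectra report the positions of their positive/negative extrema, whose
ordering on the wavelength axis diagnoses a red- or blueshift. Energies
convert to wavelengths via lambda = hc / E.

The packaged fixture ``table2_qy.csv`` carries chlorophyll Qy excitation
energies for an isolated Chl-a and the chl-613/614 pair at different lumen
states; oscillator strengths are not available for those lines and default
to 1, so only peak positions and shift orderings (never relative
intensities) are meaningful for that fixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HC_EV_NM",
    "StickSpectrum",
    "BroadenedSpectrum",
    "broaden",
    "difference",
    "ev_to_nm",
    "nm_to_ev",
    "load_table2_qy",
]

#: h*c in eV nm (CODATA).
HC_EV_NM = 1239.841984


@dataclass
class StickSpectrum:
    """Discrete excitation lines: (energy eV, oscillator strength >= 0)."""

    energies: np.ndarray
    strengths: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.strengths = np.atleast_1d(np.asarray(self.strengths, dtype=float))
        if self.energies.size == 0:
            raise ValueError("a stick spectrum needs at least one line")
        if self.energies.shape != self.strengths.shape:
            raise ValueError("energies and strengths must align")
        if np.any(self.energies <= 0):
            raise ValueError("line energies must be > 0")
        if np.any(self.strengths < 0):
            raise ValueError("oscillator strengths must be >= 0")

    def __add__(self, other: "StickSpectrum") -> "StickSpectrum":
        return StickSpectrum(
            np.concatenate([self.energies, other.energies]),
            np.concatenate([self.strengths, other.strengths]),
            label=f"{self.label}+{other.label}",
        )


@dataclass
class BroadenedSpectrum:
    """Absorbance on a strictly increasing energy grid (eV), a.u."""

    energy: np.ndarray
    absorbance: np.ndarray
    gamma: float
    label: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def wavelength(self) -> np.ndarray:
        """nm axis corresponding to the energy grid (decreasing)."""
        return ev_to_nm(self.energy)

    def peak_energy(self) -> float:
        return float(self.energy[np.argmax(self.absorbance)])


def broaden(
    stick: StickSpectrum,
    gamma: float = 0.02,
    grid: np.ndarray | None = None,
    unit_area: bool = False,
) -> BroadenedSpectrum:
    """Convolve a stick spectrum with Lorentzians of HWHM ``gamma`` (eV).

    Unit-peak Lorentzians by default (each line contributes f_i at its
    center); ``unit_area=True`` switches to the normalized density
    f_i * (gamma/pi) / ((E-E_i)^2 + gamma^2). The grid defaults to the line
    range padded by 8 gamma; a supplied grid that does not cover every line
    +/- 5 gamma triggers a coverage warning.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if grid is None:
        lo = stick.energies.min() - 8 * gamma
        hi = stick.energies.max() + 8 * gamma
        grid = np.linspace(lo, hi, 4001)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() > stick.energies.min() - 5 * gamma or grid.max() < stick.energies.max() + 5 * gamma:
            warnings.warn(
                "grid does not cover all lines +/- 5 gamma; tails are truncated",
                stacklevel=2,
            )
    diff2 = (grid[:, None] - stick.energies[None, :]) ** 2
    lor = gamma**2 / (diff2 + gamma**2)
    if unit_area:
        lor /= np.pi * gamma
    a = lor @ stick.strengths
    return BroadenedSpectrum(grid, a, gamma, label=stick.label)


def difference(a: BroadenedSpectrum, b: BroadenedSpectrum) -> BroadenedSpectrum:
    """Signed pointwise difference a - b on a common grid.

    Metadata records the energy and wavelength of the most positive and most
    negative extrema; on the wavelength axis a positive extremum at longer
    wavelength than the negative one is the redshift signature.
    """
    if a.energy.shape != b.energy.shape or not np.allclose(a.energy, b.energy):
        raise ValueError("spectra are on different grids: regrid required")
    d = a.absorbance - b.absorbance
    i_pos = int(np.argmax(d))
    i_neg = int(np.argmin(d))
    return BroadenedSpectrum(
        a.energy,
        d,
        a.gamma,
        label=f"{a.label}-minus-{b.label}",
        metadata={
            "positive_extremum_ev": float(a.energy[i_pos]),
            "negative_extremum_ev": float(a.energy[i_neg]),
            "positive_extremum_nm": float(ev_to_nm(a.energy[i_pos])),
            "negative_extremum_nm": float(ev_to_nm(a.energy[i_neg])),
        },
    )


def ev_to_nm(energy_ev):
    """Photon energy (eV) to vacuum wavelength (nm); involutive with nm_to_ev."""
    e = np.asarray(energy_ev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("energy must be > 0")
    out = HC_EV_NM / e
    return float(out) if np.isscalar(energy_ev) else out


def nm_to_ev(wavelength_nm):
    """Vacuum wavelength (nm) to photon energy (eV)."""
    w = np.asarray(wavelength_nm, dtype=float)
    if np.any(w <= 0):
        raise ValueError("wavelength must be > 0")
    out = HC_EV_NM / w
    return float(out) if np.isscalar(wavelength_nm) else out


def load_table2_qy() -> dict[str, StickSpectrum]:
    """Packaged chlorophyll Qy excitation-line fixture, one stick per state.

    States: isolated Chl-a, the high-pH (Vio) pair, the low-pH (Vio) pair and
    the low-pH (Zea) pair. Equal unit strengths (none are tabulated).
    """
    with resources.files("lhcdyn.data").joinpath("table2_qy.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    out = {}
    for label, sub in df.groupby("label", sort=False):
        out[str(label)] = StickSpectrum(
            sub["energy_ev"].to_numpy(), sub["strength"].to_numpy(), label=str(label)
        )
    return out
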