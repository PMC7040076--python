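"""Spectra as first-class objects.

Spectral (photon or energy) irradiance on a strictly increasing wavelength
grid, with unit conversion, resampling, half-open waveband integration, and
absorbance-band summaries for leaf extracts.

Conventions
-----------
* Wavelengths in nm; photon spectral irradiance in µmol m⁻² s⁻¹ nm⁻¹;
  energy spectral irradiance in W m⁻² nm⁻¹.
* Wavebands are half-open ``[lower, upper)`` so that adjacent bands
  (UV-B | UV-A at 315 nm, UV-A | PAR at 400 nm) partition the spectrum
  without double counting.  For a continuous integrand the trapezoidal
  integral is unaffected by the open upper edge; the closure matters only
  for the partition property.
* Band integrals insert linearly interpolated virtual samples exactly at
  the band edges, so integrals over adjacent bands sum to the integral
  over their union.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import constants

logger = logging.getLogger(__name__)

#: J·m per mol of photons: h·c·N_A
_HC_NA = constants.h * constants.c * constants.Avogadro

PHOTON = "photon"
ENERGY = "energy"

#: Canonical analysis range (nm).
ANALYSIS_RANGE = (280.0, 900.0)


@dataclass(frozen=True)
class Waveband:
    """Half-open wavelength band ``[lower_nm, upper_nm)``."""

    name: str
    lower_nm: float
    upper_nm: float

    def __post_init__(self) -> None:
        if not self.lower_nm < self.upper_nm:
            raise ValueError(
                f"waveband {self.name!r}: lower ({self.lower_nm}) must be "
                f"< upper ({self.upper_nm})"
            )

    @property
    def width(self) -> float:
        return self.upper_nm - self.lower_nm


UVB = Waveband("UV-B", 280.0, 315.0)
UVA = Waveband("UV-A", 315.0, 400.0)
UV = Waveband("UV", 280.0, 400.0)
PAR = Waveband("PAR", 400.0, 700.0)
RED = Waveband("RED", 655.0, 665.0)
FAR_RED = Waveband("FAR_RED", 725.0, 735.0)

CANONICAL_BANDS = {b.name: b for b in (UVB, UVA, UV, PAR, RED, FAR_RED)}


@dataclass
class SpectralIrradiance:
    """A measured spectrum with metadata.

    Negative values are clipped to zero on construction (small negative
    UV-B excursions are routine instrument noise in calibrated field
    spectra); the number of clipped samples is kept in ``clip_count``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    unit: str = PHOTON
    meta: dict = field(default_factory=dict)
    clip_count: int = 0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D arrays of equal length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("non-monotone grid: wavelengths must be strictly increasing")
        if self.unit not in (PHOTON, ENERGY):
            raise ValueError(f"unknown unit flag {self.unit!r}")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectral values must be finite")
        neg = v < 0
        n_neg = int(neg.sum())
        if n_neg:
            v = np.where(neg, 0.0, v)
            logger.info("clipped %d negative spectral values to 0", n_neg)
        self.wavelengths_nm = wl
        self.values = v
        self.clip_count = self.clip_count + n_neg

    def covers(self, lower_nm: float, upper_nm: float) -> bool:
        return self.wavelengths_nm[0] <= lower_nm and self.wavelengths_nm[-1] >= upper_nm

    def _require_coverage(self, lower_nm: float, upper_nm: float, what: str) -> None:
        if not self.covers(lower_nm, upper_nm):
            raise ValueError(
                f"spectrum covers [{self.wavelengths_nm[0]:g}, "
                f"{self.wavelengths_nm[-1]:g}] nm which does not contain "
                f"{what} [{lower_nm:g}, {upper_nm:g}] nm"
            )


@dataclass
class AbsorbanceSpectrum:
    """Spectrophotometer absorbance of a leaf extract (dimensionless AU).

    ``dilution`` (≥ 1), ``volume_ml`` and ``fresh_weight_g`` are carried so
    band summaries can be normalised to AU·ml·g⁻¹.  Pre-normalisation
    absorbance above 2 AU triggers a warning (the extract should have been
    diluted), not an error.
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    dilution: float = 1.0
    volume_ml: float = 1.0
    fresh_weight_g: float = 1.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("non-monotone grid: wavelengths must be strictly increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance must be finite")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")
        if np.any(a > 2.0):
            logger.warning(
                "absorbance exceeds 2 AU at %d wavelengths; extract should be diluted",
                int((a > 2.0).sum()),
            )
        self.wavelengths_nm = wl
        self.absorbance = a


# ---------------------------------------------------------------------------
# I/O: CSV dialect with `# key=value` metadata lines
# ---------------------------------------------------------------------------

_META_KEYS = ("stand", "doy", "position", "point", "unit", "timestamp")


def write_spectrum(spectrum: SpectralIrradiance, path) -> None:
    """Write the spectrum CSV dialect: `# key=value` lines, then data."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit={spectrum.unit}\n")
        for key, val in spectrum.meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(spectrum.wavelengths_nm, spectrum.values):
            fh.write(f"{float(wl):.17g},{float(v):.17g}\n")


def read_spectrum(path, unit: str | None = None) -> SpectralIrradiance:
    """Read a spectrum CSV (leading ``# key=value`` metadata lines).

    ``unit`` overrides any unit recorded in the file; if neither is given
    photon units are assumed.
    """
    meta: dict = {}
    data_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            data_lines.append(line)
    if not data_lines:
        raise ValueError(f"{path}: no data rows")
    header = [h.strip() for h in data_lines[0].split(",")]
    if header[:2] != ["wavelength_nm", "value"]:
        raise ValueError(f"{path}: missing columns, expected header 'wavelength_nm,value'")
    arr = np.loadtxt(io.StringIO("\n".join(data_lines[1:])), delimiter=",", ndmin=2)
    file_unit = meta.pop("unit", None)
    resolved = unit or file_unit or PHOTON
    if "doy" in meta:
        meta["doy"] = int(meta["doy"])
    return SpectralIrradiance(arr[:, 0], arr[:, 1], unit=resolved, meta=meta)


# ---------------------------------------------------------------------------
# Unit conversion and resampling
# ---------------------------------------------------------------------------

def energy_to_photon(spectrum: SpectralIrradiance) -> SpectralIrradiance:
    """Convert W m⁻² nm⁻¹ to µmol m⁻² s⁻¹ nm⁻¹.

    N(λ) = E(λ)·λ/(h·c·N_A); 1 W at 400 nm is 3.344 µmol of photons per
    second.
    """
    if spectrum.unit != ENERGY:
        raise ValueError("energy_to_photon expects a spectrum in energy units")
    lam_m = spectrum.wavelengths_nm * 1e-9
    mol = spectrum.values * lam_m / _HC_NA  # mol m-2 s-1 nm-1
    return replace(spectrum, values=mol * 1e6, unit=PHOTON, clip_count=0)


def resample(spectrum: SpectralIrradiance, target_grid) -> SpectralIrradiance:
    """Linear interpolation onto ``target_grid``; never extrapolates."""
    grid = np.asarray(target_grid, dtype=float)
    spectrum._require_coverage(grid.min(), grid.max(), "target grid")
    vals = np.interp(grid, spectrum.wavelengths_nm, spectrum.values)
    return replace(spectrum, wavelengths_nm=grid, values=vals, clip_count=0)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _edge_grid(wl: np.ndarray, v: np.ndarray, lower: float, upper: float):
    """Samples inside [lower, upper] plus interpolated virtual edge samples."""
    inside = (wl > lower) & (wl < upper)
    xs = np.concatenate(([lower], wl[inside], [upper]))
    ys = np.concatenate(
        ([np.interp(lower, wl, v)], v[inside], [np.interp(upper, wl, v)])
    )
    return xs, ys


def integrate_band(spectrum: SpectralIrradiance, band: Waveband) -> float:
    """Trapezoidal photon irradiance over the band (µmol m⁻² s⁻¹).

    Virtual samples are interpolated exactly at the band edges so adjacent
    half-open bands partition the spectrum.
    """
    if spectrum.unit != PHOTON:
        raise ValueError(
            "integrate_band expects photon units; convert with energy_to_photon first"
        )
    spectrum._require_coverage(band.lower_nm, band.upper_nm, f"band {band.name!r}")
    xs, ys = _edge_grid(
        spectrum.wavelengths_nm, spectrum.values, band.lower_nm, band.upper_nm
    )
    return float(np.trapezoid(ys, xs))


def extract_band_summary(abs_spec: AbsorbanceSpectrum) -> dict:
    """Band summaries of a leaf-extract absorbance spectrum.

    Returns A375, mean absorbance over UV-B / UV-A / whole UV (integral ÷
    band width), and the same four quantities normalised for dilution,
    sample volume and leaf fresh weight (AU·ml·g⁻¹).
    """
    if abs_spec.fresh_weight_g <= 0:
        raise ValueError("leaf fresh weight must be > 0")
    wl, a = abs_spec.wavelengths_nm, abs_spec.absorbance
    if wl[0] > UVB.lower_nm or wl[-1] < UVA.upper_nm:
        raise ValueError("absorbance spectrum must cover 280-400 nm")

    def band_mean(band: Waveband) -> float:
        xs, ys = _edge_grid(wl, a, band.lower_nm, band.upper_nm)
        return float(np.trapezoid(ys, xs)) / band.width

    norm = abs_spec.dilution * abs_spec.volume_ml / abs_spec.fresh_weight_g
    out = {
        "A375": float(np.interp(375.0, wl, a)),
        "mean_UVB": band_mean(UVB),
        "mean_UVA": band_mean(UVA),
        "mean_UV": band_mean(UV),
    }
    out.update({f"{k}_normalized": v * norm for k, v in list(out.items())})
    return out
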