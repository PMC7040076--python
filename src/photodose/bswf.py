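"""Biological spectral weighting functions (BSWFs) and effective UV doses.

A BSWF assigns each wavelength a dimensionless biological effectiveness
w(λ); the effective dose of a spectrum is the weighted photon integral
∫ w(λ)·E(λ) dλ, here reported in weighted-photon units (µmol m⁻² s⁻¹).
All registered BSWFs are normalised so w = 1 at the normalisation
wavelength (300 nm by community convention) and vanish outside their
domain.

Built-in BSWFs:

* ``PG`` — plant-growth action spectrum (Flint & Caldwell closed form),
  spanning the UV-B and UV-A up to 390 nm.
* ``GEN_G`` — Green et al. mathematical formulation of the generalised
  plant action spectrum, nonzero only below 313.3 nm.
* ``FLAV`` — flavonoid-accumulation action spectrum, as a tabulated node
  table with linear interpolation.  The node table shipped with this
  package is a *synthetic stand-in* with the literature's qualitative
  shape (see ``data/flav_action_spectrum_synthetic.csv``).

The red:far-red photon ratio uses the conventional 10-nm bands
655–665 nm / 725–735 nm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .spectra import (
    FAR_RED,
    PHOTON,
    RED,
    SpectralIrradiance,
    Waveband,
    _edge_grid,
    integrate_band,
)

logger = logging.getLogger(__name__)

DEFAULT_NORMALIZATION_NM = 300.0


@dataclass
class WeightingFunction:
    """A BSWF with a domain, normalisation wavelength and raw evaluator."""

    name: str
    raw: callable  # unnormalised weight, vectorised over λ (nm)
    domain_nm: tuple[float, float]
    normalization_nm: float = DEFAULT_NORMALIZATION_NM
    form: str = "closed_form"
    _norm: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lo, hi = self.domain_nm
        if not lo < hi:
            raise ValueError("BSWF domain must have lower < upper")
        if not lo <= self.normalization_nm <= hi:
            raise ValueError("normalisation wavelength must lie inside the domain")
        norm = float(self.raw(np.asarray(self.normalization_nm)))
        if not norm > 0:
            raise ValueError("raw weight at the normalisation wavelength must be > 0")
        self._norm = norm

    def __call__(self, wavelengths_nm) -> np.ndarray:
        """Normalised weight; exactly 0 outside the domain."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = self.domain_nm
        inside = (lam >= lo) & (lam < hi)
        out = np.zeros_like(lam, dtype=float)
        if np.any(inside):
            out[inside] = np.asarray(self.raw(lam[inside]), dtype=float) / self._norm
        return out if lam.ndim else float(out)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def pg_raw(lam) -> np.ndarray:
    """Unnormalised plant-growth (PG) weight, λ ≤ 390 nm.

    exp{4.688272·exp[−exp(0.1703411·(λ−307.867)/1.15)]
        + (390−λ)/121.7557 − 4.183832}
    """
    lam = np.asarray(lam, dtype=float)
    inner = np.exp(0.1703411 * (lam - 307.867) / 1.15)
    return np.exp(
        4.688272 * np.exp(-inner) + (390.0 - lam) / 121.7557 - 4.183832
    )


def gen_g_raw(lam) -> np.ndarray:
    """Unnormalised generalised plant action spectrum GEN(G), λ < 313.3 nm.

    2.618·[1 − (λ/313.3)²]·exp(−(λ−300)/31.08)
    """
    lam = np.asarray(lam, dtype=float)
    return 2.618 * (1.0 - (lam / 313.3) ** 2) * np.exp(-(lam - 300.0) / 31.08)


def tabulated_weight(nodes_nm, nodes_w, lam) -> np.ndarray:
    """Linear interpolation between (λ, w) nodes; 0 outside the node range."""
    nodes_nm = np.asarray(nodes_nm, dtype=float)
    nodes_w = np.asarray(nodes_w, dtype=float)
    if np.any(np.diff(nodes_nm) <= 0):
        raise ValueError("BSWF nodes must be sorted with no duplicate wavelengths")
    if np.any(nodes_w < 0):
        raise ValueError("BSWF node weights must be >= 0")
    lam = np.asarray(lam, dtype=float)
    out = np.interp(lam, nodes_nm, nodes_w, left=0.0, right=0.0)
    out = np.where((lam < nodes_nm[0]) | (lam > nodes_nm[-1]), 0.0, out)
    return out


def _load_nodes(path) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha():
                continue  # blank, comment, or header line
            lam, w = line.split(",")
            rows.append((float(lam), float(w)))
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def make_tabulated(name: str, nodes_nm, nodes_w,
                   normalization_nm: float = DEFAULT_NORMALIZATION_NM) -> WeightingFunction:
    nodes_nm = np.asarray(nodes_nm, dtype=float)
    nodes_w = np.asarray(nodes_w, dtype=float)
    tabulated_weight(nodes_nm, nodes_w, nodes_nm)  # validates
    return WeightingFunction(
        name=name,
        raw=lambda lam, _n=nodes_nm, _w=nodes_w: tabulated_weight(_n, _w, lam),
        # upper edge just past the last node so the node itself is inside
        domain_nm=(float(nodes_nm[0]), float(nodes_nm[-1]) + 1e-9),
        normalization_nm=normalization_nm,
        form="tabulated",
    )


def default_registry() -> dict[str, WeightingFunction]:
    """The three BSWFs used throughout: PG, GEN_G, FLAV."""
    with resources.as_file(
        resources.files("photodose.data") / "flav_action_spectrum_synthetic.csv"
    ) as p:
        flav_nodes = _load_nodes(p)
    return {
        "PG": WeightingFunction("PG", pg_raw, domain_nm=(275.0, 390.0)),
        "GEN_G": WeightingFunction("GEN_G", gen_g_raw, domain_nm=(280.0, 313.3)),
        "FLAV": make_tabulated("FLAV", *flav_nodes),
    }


def load_registry(config: dict, base_dir: Path | None = None) -> dict[str, WeightingFunction]:
    """Build a registry from a config mapping (parsed YAML/JSON).

    Each entry: ``{form: closed_form|tabulated, ...}`` where closed forms
    reference a built-in (``builtin: PG``) and tabulated entries give a
    2-column CSV ``nodes`` path; ``normalization_nm`` optional.
    """
    builtins = {"PG": (pg_raw, (275.0, 390.0)), "GEN_G": (gen_g_raw, (280.0, 313.3))}
    registry: dict[str, WeightingFunction] = {}
    for name, entry in config.items():
        norm = float(entry.get("normalization_nm", DEFAULT_NORMALIZATION_NM))
        if entry.get("form", "closed_form") == "tabulated":
            path = Path(entry["nodes"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            registry[name] = make_tabulated(name, *_load_nodes(path), normalization_nm=norm)
        else:
            raw, domain = builtins[entry["builtin"]]
            registry[name] = WeightingFunction(
                name, raw, domain_nm=tuple(entry.get("domain_nm", domain)),
                normalization_nm=norm,
            )
    return registry


# ---------------------------------------------------------------------------
# Doses and ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResult:
    """An effective dose in weighted-photon units (µmol m⁻² s⁻¹)."""

    value: float
    bswf: str
    normalization_nm: float
    meta: dict = field(default_factory=dict)


def effective_dose(spectrum: SpectralIrradiance, bswf: WeightingFunction) -> DoseResult:
    """Trapezoidal ∫ w(λ)·E(λ) dλ over the BSWF domain ∩ spectrum range.

    The weight function is evaluated on the spectrum's own grid (the
    measured values are never resampled), with virtual samples inserted
    at the domain edges.
    """
    if spectrum.unit != PHOTON:
        raise ValueError(
            "effective_dose expects photon units; convert with energy_to_photon first"
        )
    lo = max(bswf.domain_nm[0], spectrum.wavelengths_nm[0])
    hi = min(bswf.domain_nm[1], spectrum.wavelengths_nm[-1])
    if hi <= lo:
        value = 0.0
    else:
        xs, ys = _edge_grid(spectrum.wavelengths_nm, spectrum.values, lo, hi)
        value = float(np.trapezoid(bswf(xs) * ys, xs))
    return DoseResult(
        value=value,
        bswf=bswf.name,
        normalization_nm=bswf.normalization_nm,
        meta=dict(spectrum.meta),
    )


def red_far_red_ratio(spectrum: SpectralIrradiance) -> float:
    """Photon integral 655–665 nm ÷ photon integral 725–735 nm."""
    red = integrate_band(spectrum, RED)
    far_red = integrate_band(spectrum, FAR_RED)
    if far_red <= 0:
        raise ValueError("undefined R:FR: far-red photon irradiance is zero")
    return red / far_red


def dose_table(spectra, registry: dict[str, WeightingFunction] | None = None):
    """Tidy per-spectrum table of band irradiances, doses and R:FR.

    Columns: stand, doy, position, point, PPFD, UVB, UVA, then one column
    per registered BSWF, then R_FR.
    """
    import pandas as pd

    from .spectra import PAR, UVA, UVB

    registry = default_registry() if registry is None else registry
    rows = []
    for spec in spectra:
        row = {
            "stand": spec.meta.get("stand"),
            "doy": spec.meta.get("doy"),
            "position": spec.meta.get("position"),
            "point": spec.meta.get("point"),
            "PPFD": integrate_band(spec, PAR),
            "UVB": integrate_band(spec, UVB),
            "UVA": integrate_band(spec, UVA),
        }
        for name, fn in registry.items():
            row[name] = effective_dose(spec, fn).value
        try:
            row["R_FR"] = red_far_red_ratio(spec)
        except ValueError:
            row["R_FR"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
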