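"""Synthetic emulation of the field campaign's five input streams.

Generates, from a scenario configuration and a seed, everything the
analysis consumes: open-field and understorey spectra (280–900 nm,
0.5 nm grid) for five canopy scenarios, a daily weather year with
snowpack, and a repeated leaf-trait survey of a multi-species
understorey community with known (planted) response parameters.

The solar template is parametric, not a radiative-transfer model: a
smooth photon-irradiance envelope times a logistic UV-B cut-on whose
midpoint shifts to longer wavelengths at low solar elevation, with the
amplitude calibrated so open-field band integrals have midsummer-noon
magnitudes typical of a boreal site (PPFD ≈ 1.4 mmol m⁻² s⁻¹, UV-B
roughly 0.09% of PPFD).  Canopy positions follow the sampling design:
*sunfleck* (direct beam, nearly neutral attenuation), *shade* (trunk
umbra: strong Beer–Lambert attenuation with mild UV enrichment and
far-red enrichment), and *leaf* (shade filtered through a leaf
transmittance spectrum: low UV and PAR, green bump, high beyond
700 nm).

The planted I_flav response is linear in the stand's shade UV-A dose
with a cold-temperature hinge and a point-level random effect:

    I_flav = β₀(species) + β_UVA·D_UVA_shade(stand, doy)
             + γ·max(0, T_cold − t_min(doy)) + b_point + ε

so every downstream statistic (CWM, correlation, compound-symmetry GLS)
has a known truth to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import PHOTON, UVA, SpectralIrradiance, integrate_band, write_spectrum

#: canonical analysis grid: 280–900 nm at 0.5 nm
GRID_NM = np.arange(280.0, 900.0 + 0.25, 0.5)

_REFERENCE_ELEVATION_DEG = 52.4  # midsummer noon at ~61° N
_REFERENCE_PPFD = 1390.0         # µmol m-2 s-1, open field, midsummer noon


def solar_elevation(doy: int, latitude_deg: float = 61.05) -> float:
    """Solar noon elevation (deg) from the day-of-year declination."""
    declination = 23.44 * np.sin(2.0 * np.pi * (doy - 81) / 365.0)
    return 90.0 - latitude_deg + declination


# ---------------------------------------------------------------------------
# Solar template
# ---------------------------------------------------------------------------

def _solar_shape(elevation_deg: float, diffuse_fraction: float) -> np.ndarray:
    lam = GRID_NM
    envelope = np.exp(-(((lam - 590.0) / 330.0) ** 2))
    # UV decline (Rayleigh + aerosol, in photon units): exponential in
    # (400−λ); calibrated so UV-A ≈ 7.8% of PPFD at the reference elevation
    u = np.clip((400.0 - lam) / 100.0, 0.0, None)
    uv_slope = np.exp(-2.6 * u)
    # ozone cut-on: logistic whose midpoint moves to longer λ as the sun
    # drops (longer slant path), steepening the UV-B cut
    airmass = 1.0 / max(np.sin(np.radians(elevation_deg)), 0.05)
    airmass_ref = 1.0 / np.sin(np.radians(_REFERENCE_ELEVATION_DEG))
    midpoint = 309.0 + 6.0 * (airmass - airmass_ref)
    cut_on = 1.0 / (1.0 + np.exp(-(lam - midpoint) / 3.0))
    # diffuse skylight slightly enriches the blue/UV end
    tilt = 1.0 + 0.25 * diffuse_fraction * np.clip((500.0 - lam) / 220.0, 0.0, 1.0)
    return envelope * uv_slope * cut_on * tilt


def gen_solar_spectrum(elevation_deg: float = _REFERENCE_ELEVATION_DEG,
                       diffuse_fraction: float = 0.15) -> SpectralIrradiance:
    """Open-field photon spectrum (µmol m⁻² s⁻¹ nm⁻¹) on the 0.5 nm grid."""
    if elevation_deg <= 0:
        raise ValueError("solar elevation must be > 0 degrees")
    shape = _solar_shape(elevation_deg, diffuse_fraction)
    spec = SpectralIrradiance(GRID_NM, shape, unit=PHOTON,
                              meta={"position": "open"})
    sin_ratio = (np.sin(np.radians(elevation_deg))
                 / np.sin(np.radians(_REFERENCE_ELEVATION_DEG)))
    target_ppfd = _REFERENCE_PPFD * sin_ratio ** 0.55
    from .spectra import PAR
    scale = target_ppfd / integrate_band(spec, PAR)
    return SpectralIrradiance(GRID_NM, shape * scale, unit=PHOTON,
                              meta={"position": "open",
                                    "elevation_deg": elevation_deg})


# ---------------------------------------------------------------------------
# Canopy filters
# ---------------------------------------------------------------------------

def _shade_extinction(lam: np.ndarray) -> np.ndarray:
    """Spectral Beer–Lambert extinction for diffuse shade light.

    Slightly lower in the UV (diffuse skylight is UV-rich relative to
    the direct beam) and markedly lower beyond 700 nm (foliage transmits
    far-red), so shade is UV-enriched and R:FR-depressed relative to
    open radiation.
    """
    k0 = 0.9
    uv_relief = 0.15 * np.clip((400.0 - lam) / 120.0, 0.0, 1.0)
    nir_relief = 0.35 * np.clip((lam - 690.0) / 40.0, 0.0, 1.0)
    return k0 * (1.0 - uv_relief - nir_relief)


def _leaf_transmittance(lam: np.ndarray) -> np.ndarray:
    """One-leaf transmittance: low UV/PAR, green bump, high beyond 700 nm."""
    green = 0.06 * np.exp(-(((lam - 550.0) / 40.0) ** 2))
    nir = 0.40 / (1.0 + np.exp(-(lam - 712.0) / 10.0))
    base = np.where(lam < 400.0, 0.01, 0.02)
    return base + green + nir


POSITIONS = ("sunfleck", "shade", "leaf")


def apply_canopy(spectrum: SpectralIrradiance, position: str,
                 pai: float) -> SpectralIrradiance:
    """Filter an open spectrum to an understorey sampling position.

    At PAI = 0 sunfleck and shade reduce to the open spectrum exactly;
    the leaf position always carries the one-leaf transmittance filter.
    """
    if pai < 0:
        raise ValueError("PAI must be >= 0")
    lam = spectrum.wavelengths_nm
    if position == "sunfleck":
        factor = np.exp(-0.06 * pai) * np.ones_like(lam)
    elif position == "shade":
        factor = np.exp(-_shade_extinction(lam) * pai)
    elif position == "leaf":
        factor = np.exp(-_shade_extinction(lam) * pai) * _leaf_transmittance(lam)
    else:
        raise ValueError(f"unknown position {position!r}; expected one of {POSITIONS}")
    meta = dict(spectrum.meta)
    meta["position"] = position
    return SpectralIrradiance(lam, spectrum.values * factor,
                              unit=spectrum.unit, meta=meta)


# ---------------------------------------------------------------------------
# Scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandSpec:
    stand_id: str
    canopy: str  # deciduous | evergreen
    pai_winter: float
    pai_summer: float
    leafout_doy: float = 135.0
    leafout_rate_days: float = 6.0

    def pai(self, doy: float) -> float:
        if self.canopy == "evergreen":
            return self.pai_summer
        frac = 1.0 / (1.0 + np.exp(-(doy - self.leafout_doy) / self.leafout_rate_days))
        return self.pai_winter + (self.pai_summer - self.pai_winter) * frac


def default_stands() -> tuple[StandSpec, ...]:
    return (
        StandSpec("betula_old", "deciduous", 0.9, 3.6, 135.0, 6.0),
        StandSpec("betula_young", "deciduous", 0.8, 3.2, 133.0, 5.0),
        StandSpec("betula_mixed", "deciduous", 1.2, 3.8, 136.0, 6.0),
        StandSpec("quercus", "deciduous", 0.9, 3.4, 150.0, 7.0),
        StandSpec("picea", "evergreen", 4.2, 4.2),
    )


@dataclass(frozen=True)
class WeatherParams:
    annual_mean_c: float = 3.5
    amplitude_c: float = 13.5
    peak_doy: float = 199.0
    ar1: float = 0.7
    noise_sd_c: float = 2.5
    half_range_low_c: float = 4.5
    half_range_high_c: float = 5.5
    initial_snow_cm: float = 30.0
    accumulation_cm_per_degday: float = 0.4
    melt_cm_per_degday: float = 2.0


@dataclass(frozen=True)
class ScenarioConfig:
    """The study conditions the generator emulates.

    Defaults mirror the measurement design: five stands (three birch, one
    oak, one spruce), four points per stand, four measurement DOYs over
    spring and summer, three understorey positions, and a 35-species
    community of which each stand hosts a subset.
    """

    stands: tuple = field(default_factory=default_stands)
    doys: tuple = (115, 144, 156, 202)
    n_points: int = 4
    positions: tuple = POSITIONS
    n_species: int = 35
    species_per_stand: int = 14
    n_plants: int = 4
    beta_uva: float = 0.02       # I_flav per µmol m-2 s-1 of shade UV-A
    gamma: float = 0.012         # I_flav per °C below the cold threshold
    t_cold: float = 5.0          # °C
    sigma_e: float = 0.08        # plant-level residual SD
    sigma_point: float = 0.06    # point random-effect SD
    diffuse_fraction: float = 0.15
    # multiplicative point-to-point irradiance spread (lognormal sigma);
    # sunflecks are far more variable than background shade
    jitter_sd: dict = field(default_factory=lambda: {
        "sunfleck": 0.45, "shade": 0.10, "leaf": 0.18})
    weather: WeatherParams = field(default_factory=WeatherParams)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_weather_year(params: WeatherParams = WeatherParams(), seed: int = 0,
                     year: int = 2015) -> pd.DataFrame:
    """Daily weather: sinusoidal mean + AR(1) noise, deterministic snowpack."""
    rng = np.random.default_rng(seed)
    doys = np.arange(1, 366)
    det = params.annual_mean_c + params.amplitude_c * np.cos(
        2.0 * np.pi * (doys - params.peak_doy) / 365.0
    )
    innovations = rng.normal(0.0, params.noise_sd_c * np.sqrt(1 - params.ar1 ** 2),
                             doys.size)
    noise = np.empty(doys.size)
    prev = rng.normal(0.0, params.noise_sd_c)
    for i, eps in enumerate(innovations):
        prev = params.ar1 * prev + eps
        noise[i] = prev
    t_mean = det + noise
    # snowpack follows the deterministic envelope: accumulate on sub-zero
    # days, melt proportionally to above-zero warmth
    snow = np.empty(doys.size)
    depth = params.initial_snow_cm
    for i, t in enumerate(det):
        if t < 0:
            depth += params.accumulation_cm_per_degday * (-t)
        else:
            depth -= params.melt_cm_per_degday * t
        depth = max(depth, 0.0)
        snow[i] = depth
    return pd.DataFrame({
        "doy": doys,
        "t_mean": t_mean,
        "t_min": t_mean - params.half_range_low_c,
        "t_max": t_mean + params.half_range_high_c,
        "snow_depth_cm": snow,
        "year": year,
    })


def gen_stand_spectra(config: ScenarioConfig, seed: int) -> list[SpectralIrradiance]:
    """Spectra for every stand × DOY × position × point, plus open references.

    Point-to-point variation is a neutral (wavelength-independent)
    lognormal factor, much larger for sunflecks than for shade, matching
    the campaign's observation that sunfleck irradiance varies with
    sunfleck size while its spectral shape persists.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    spectra = []
    for doy in config.doys:
        open_spec = gen_solar_spectrum(solar_elevation(doy), config.diffuse_fraction)
        open_spec.meta.update({"doy": int(doy), "stand": "open", "point": 0})
        spectra.append(open_spec)
        for stand in config.stands:
            pai = stand.pai(doy)
            for position in config.positions:
                base = apply_canopy(open_spec, position, pai)
                for point in range(1, config.n_points + 1):
                    jitter = float(np.exp(rng.normal(
                        0.0, config.jitter_sd[position])))
                    meta = dict(base.meta)
                    meta.update({"stand": stand.stand_id, "doy": int(doy),
                                 "point": point})
                    spectra.append(SpectralIrradiance(
                        base.wavelengths_nm, base.values * jitter,
                        unit=PHOTON, meta=meta))
    return spectra


def shade_uva_dose_table(spectra: list[SpectralIrradiance]) -> pd.DataFrame:
    """Stand × DOY mean shade UV-A photon irradiance (µmol m⁻² s⁻¹)."""
    rows = [
        {"stand": s.meta["stand"], "doy": s.meta["doy"],
         "uva_shade": integrate_band(s, UVA)}
        for s in spectra
        if s.meta.get("position") == "shade" and s.meta.get("stand") != "open"
    ]
    if not rows:
        raise ValueError("no shade spectra found")
    return (pd.DataFrame(rows).groupby(["stand", "doy"], as_index=False)
            .mean())


def gen_community_survey(config: ScenarioConfig, dose_table: pd.DataFrame,
                         weather: pd.DataFrame, seed: int,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Leaf-trait records and abundance table with planted parameters.

    Returns ``(records, abundances, truth)`` where ``truth`` holds every
    planted parameter for recovery tests.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    doses = dose_table.set_index(["stand", "doy"])["uva_shade"]
    missing = [
        (s.stand_id, d) for s in config.stands for d in config.doys
        if (s.stand_id, d) not in doses.index
    ]
    if missing:
        raise ValueError(f"dose table missing stand × DOY rows: {missing}")
    t_min = weather.set_index("doy")["t_min"]

    species = [f"sp{i:02d}" for i in range(1, config.n_species + 1)]
    beta0 = {sp: float(0.8 + 0.9 * rng.beta(2.0, 2.0)) for sp in species}

    ab_rows, rec_rows = [], []
    for stand in config.stands:
        pool = sorted(rng.choice(species, size=config.species_per_stand,
                                 replace=False))
        for point in range(1, config.n_points + 1):
            weights = rng.dirichlet(np.full(len(pool), 0.8))
            for sp, w in zip(pool, weights):
                ab_rows.append({"stand": stand.stand_id, "point": point,
                                "species": sp, "rel_abundance": float(w)})
            b_point = rng.normal(0.0, config.sigma_point)
            for doy in config.doys:
                dose = float(doses.loc[(stand.stand_id, doy)])
                cold = max(0.0, config.t_cold - float(t_min.loc[doy]))
                for sp in pool:
                    mu = (beta0[sp] + config.beta_uva * dose
                          + config.gamma * cold + b_point)
                    eps = rng.normal(0.0, config.sigma_e, config.n_plants)
                    for j in range(config.n_plants):
                        rec_rows.append({
                            "plant_id": f"{stand.stand_id}-p{point}-{sp}-{j + 1}",
                            "species": sp, "stand": stand.stand_id,
                            "point": point, "doy": int(doy), "year": 2015,
                            "leaf_side": "adaxial", "leaf_age": "mature",
                            "iflav": max(0.0, mu + eps[j]),
                        })
    records = pd.DataFrame(rec_rows)
    abundances = pd.DataFrame(ab_rows)
    truth = {
        "beta_uva": config.beta_uva, "gamma": config.gamma,
        "t_cold": config.t_cold, "sigma_e": config.sigma_e,
        "sigma_point": config.sigma_point, "beta0": beta0,
    }
    return records, abundances, truth


def simulate_scenario(config: ScenarioConfig = ScenarioConfig(), seed: int = 0,
                      outdir: str | Path | None = None) -> dict:
    """Run every generator; optionally write the full CSV bundle.

    Returns a dict with keys ``spectra`` (list of SpectralIrradiance),
    ``weather``, ``records``, ``abundances``, ``dose_table`` and
    ``truth``.  With ``outdir`` the bundle is written as spectra CSVs,
    weather/iflav/abundance CSVs and a truth.json.
    """
    weather = gen_weather_year(config.weather, seed=seed)
    spectra = gen_stand_spectra(config, seed=seed)
    dose_table = shade_uva_dose_table(spectra)
    records, abundances, truth = gen_community_survey(config, dose_table,
                                                      weather, seed=seed)
    bundle = {"spectra": spectra, "weather": weather, "records": records,
              "abundances": abundances, "dose_table": dose_table,
              "truth": truth, "seed": seed}
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "spectra").mkdir(parents=True, exist_ok=True)
        for i, spec in enumerate(spectra):
            m = spec.meta
            name = f"{m.get('stand', 'open')}_doy{m.get('doy')}_" \
                   f"{m.get('position')}_pt{m.get('point', 0)}_{i:04d}.csv"
            write_spectrum(spec, outdir / "spectra" / name)
        weather.to_csv(outdir / "weather.csv", index=False)
        records.to_csv(outdir / "iflav.csv", index=False)
        abundances.to_csv(outdir / "abundance.csv", index=False)
        dose_table.to_csv(outdir / "shade_uva_dose.csv", index=False)
        with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
    return bundle
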