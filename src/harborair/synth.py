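"""Synthetic water, meteorology and PUF-PAS datasets.

The generator emulates the statistical structure of the harbor study the
pipeline is designed for: 21 dissolved-phase water samples at 7 sites with
ΣPCB totals of 80-184 pg L-1 and a profile dominated by the silicone-rubber
byproduct peaks (PCBs 44+47+65, 45+51 and 68, ~48 % of mass); August-like
hourly meteorology (daily-mean air temperature 23 deg C, Weibull winds
calibrated so 3.60-8.80 m s-1 occurs about a third of hours); and 28
~40-day PUF-PAS deployments spiked with 25 ng of depuration compounds,
with 5 field blanks and surrogate recoveries of 88 +/- 13 %.

Everything is driven by one integer seed; the same seed reproduces the
same tables byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import properties as props_mod
from . import pufpas

SILICONE_PEAKS = ("PCB44+47+65", "PCB45+51", "PCB68")
SILICONE_SPLIT = (0.5, 0.3, 0.2)  # within-component split across the 3 peaks

#: depuration compounds: 13C-labelled congeners, property surrogates by number
DC_COMPOUNDS = {"13C-PCB28": "PCB20+28", "13C-PCB111": "PCB111",
                "13C-PCB178": "PCB178"}

WATER_SITES = (
    "Willamette River North", "NW Front Ave", "Kingsley Community Garden",
    "Swan Island", "Cathedral Park", "St Johns", "Upstream Reference",
)
FLOW_REGIMES = ("high", "low", "storm")


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generator."""

    seed: int = 0
    # water
    n_water_samples: int = 21
    n_sites: int = 7
    total_conc_range: tuple[float, float] = (80.0, 184.0)  # pg L-1
    silicone_fraction: float = 0.48
    water_noise_log_sd: float = 0.3  # natural-log sd of multiplicative noise
    # meteorology
    met_start: date = date(2022, 7, 8)
    met_end: date = date(2022, 8, 17)
    mean_daily_temp: float = 23.0  # deg C
    diurnal_amplitude: float = 5.0  # deg C
    wind_band: tuple[float, float] = (3.60, 8.80)  # m s-1
    band_frequency: float = 0.33
    prevailing_wind_dir: float = 340.0  # deg, direction wind blows from
    wind_dir_kappa: float = 2.0
    # PUF-PAS
    n_pufs: int = 28
    deployment_days: float = 40.0
    dc_spike_ng: float = 25.0
    v_puf: float = 2.1e-4  # m3
    puf_noise_log_sd: float = 0.2
    rs_range: tuple[float, float] = (1.4, 7.6)  # m3 d-1 across sites
    n_blanks: int = 5
    n_triplicate_sites: int = 2
    # measured-air structure (non-water urban source)
    air_geomean: float = 330.0  # pg m-3 ΣPCB
    air_gsd_log10: float = 0.20
    air_distance_exponent: float = 0.314  # power-law decay with distance

    def validate(self) -> "SyntheticConfig":
        lo, hi = self.total_conc_range
        if not lo < hi:
            raise ValueError("total_conc_range must be non-degenerate")
        if not 0.0 <= self.silicone_fraction <= 1.0:
            raise ValueError("silicone_fraction must lie in [0, 1]")
        if not 0.0 <= self.band_frequency <= 1.0:
            raise ValueError("band_frequency must lie in [0, 1]")
        if self.met_end <= self.met_start:
            raise ValueError("met_end must be after met_start")
        if self.wind_band[0] >= self.wind_band[1]:
            raise ValueError("wind_band must be non-degenerate")
        return self


# ---------------------------------------------------------------------------
# water samples

def generate_water_samples(cfg: SyntheticConfig,
                           table: pd.DataFrame) -> pd.DataFrame:
    """Synthetic dissolved-phase water samples, one row per sample.

    Each sample's congener profile is a mixture of a silicone-byproduct
    component (concentrated on PCBs 44+47+65, 45+51 and 68, expected mass
    share ``silicone_fraction``) and a light-Aroclor component, with
    per-peak lognormal multiplicative noise; totals are uniform over
    ``total_conc_range``.  The three highest-total samples are placed at
    the three named worst-case sites.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    peak_ids = list(table["peak_id"])
    missing = [p for p in SILICONE_PEAKS if p not in peak_ids]
    if missing:
        raise ValueError(f"silicone peaks missing from property table: {missing}")

    silicone = pd.Series(0.0, index=peak_ids)
    for pid, w in zip(SILICONE_PEAKS, SILICONE_SPLIT):
        silicone[pid] = w
    light = props_mod.load_aroclor_profile("Aroclor1242").reindex(peak_ids).fillna(0.0)
    light[list(SILICONE_PEAKS)] = 0.0  # keep the two components disjoint
    light /= light.sum()
    base = cfg.silicone_fraction * silicone + (1 - cfg.silicone_fraction) * light

    sites = list(WATER_SITES[:cfg.n_sites])
    slots = [(sites[i % len(sites)], FLOW_REGIMES[i % 3])
             for i in range(cfg.n_water_samples)]
    totals = rng.uniform(*cfg.total_conc_range, size=cfg.n_water_samples)
    order = np.argsort(totals)[::-1]
    # highest three totals at the named worst-case sites, rest shuffled
    ranked_slots = [(s, r) for s, r in slots if s in sites[:3]][:3]
    other_slots = [sr for sr in slots if sr not in ranked_slots]
    rng.shuffle(other_slots)
    assigned = ranked_slots + other_slots

    start = cfg.met_start
    rows = []
    for rank, (site, regime) in enumerate(assigned):
        total = totals[order[rank]]
        noise = np.exp(rng.normal(0.0, cfg.water_noise_log_sd, size=len(peak_ids)))
        frac = base.to_numpy() * noise
        frac /= frac.sum()
        conc = dict(zip(peak_ids, total * frac))
        rows.append({"site": site, "date": start + timedelta(days=rank),
                     "flow_regime": regime, **conc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meteorology

def _band_fraction(scale: float, band: tuple[float, float]) -> float:
    lo, hi = band
    return float(np.exp(-((lo / scale) ** 2)) - np.exp(-((hi / scale) ** 2)))


def weibull_scale_for_band(band: tuple[float, float], target: float) -> float:
    """Weibull (shape 2) scale whose band probability matches ``target``.

    Solved by bisection on the increasing branch (light-wind side).  The
    achievable maximum is attained at scale^2 = (hi^2-lo^2)/(2 ln(hi/lo));
    a target above it raises ValueError.
    """
    lo, hi = band
    peak = float(np.sqrt((hi ** 2 - lo ** 2) / (2.0 * np.log(hi / lo))))
    if target <= 0.0:
        return 1e-3 * lo
    if target > _band_fraction(peak, band):
        raise ValueError(
            f"band frequency {target} unreachable (max {_band_fraction(peak, band):.3f})")
    a, b = 1e-3 * lo, peak
    for _ in range(200):
        mid = 0.5 * (a + b)
        if _band_fraction(mid, band) < target:
            a = mid
        else:
            b = mid
    return 0.5 * (a + b)


def generate_met(cfg: SyntheticConfig) -> pd.DataFrame:
    """Hourly meteorology: u10, wind_dir, t_air, t_water, pressure.

    Sinusoidal diurnal air temperature around the configured daily mean,
    Weibull (Rayleigh-like) winds scaled to the band-frequency target, a
    von Mises wind direction about the prevailing direction, and water
    temperature as a 24-h trailing smoothing of air temperature.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    idx = pd.date_range(cfg.met_start, cfg.met_end, freq="h", inclusive="left")
    n = len(idx)
    if n == 0:
        raise ValueError("zero-length meteorology period")
    hours = idx.hour.to_numpy(float)
    day_offset = np.repeat(rng.normal(0.0, 1.0, size=(n + 23) // 24), 24)[:n]
    t_air = (cfg.mean_daily_temp
             + cfg.diurnal_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
             + day_offset + rng.normal(0.0, 0.5, size=n))
    t_water = pd.Series(t_air).rolling(24, min_periods=1).mean().to_numpy()

    scale = weibull_scale_for_band(cfg.wind_band, cfg.band_frequency)
    u10 = scale * rng.weibull(2.0, size=n)
    wind_dir = np.degrees(rng.vonmises(np.radians(cfg.prevailing_wind_dir),
                                       cfg.wind_dir_kappa, size=n)) % 360.0
    pressure = 101.325 + rng.normal(0.0, 0.3, size=n)
    return pd.DataFrame({"timestamp": idx, "u10": u10, "wind_dir": wind_dir,
                         "t_air": t_air, "t_water": t_water,
                         "pressure": pressure})


# ---------------------------------------------------------------------------
# PUF-PAS deployments

def generate_puf_sites(cfg: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Sampler sites scattered 30 m - 5 km from the river centreline (x=0).

    Coordinates are local projected metres (x east, y north along the
    river axis).  The first ``n_triplicate_sites`` locations carry three
    co-located samplers each, mirroring a triplicate QA design.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    n_locations = cfg.n_pufs - 2 * cfg.n_triplicate_sites
    dist = np.exp(rng.uniform(np.log(30.0), np.log(5000.0), size=n_locations))
    side = rng.choice([-1.0, 1.0], size=n_locations)
    y = rng.uniform(-12_000.0, 12_000.0, size=n_locations)
    rows = []
    k = 0
    for i in range(n_locations):
        reps = 3 if i < cfg.n_triplicate_sites else 1
        for r in range(reps):
            rows.append({
                "site_id": f"PH{i + 1:02d}" + (f"-{chr(97 + r)}" if reps > 1 else ""),
                "location": f"PH{i + 1:02d}",
                "x": side[i] * dist[i] + 283.0,  # river half-width offset
                "y": y[i],
                "height": 2.0,
                "distance_to_water": dist[i],
            })
            k += 1
    return pd.DataFrame(rows[:cfg.n_pufs])


def generate_true_air(cfg: SyntheticConfig, table: pd.DataFrame,
                      sites: pd.DataFrame, rng=None) -> pd.DataFrame:
    """ΣPCB truth for the non-water (urban Aroclor) air component, pg m-3.

    An Aroclor-1242-shaped profile whose total decays as a power law of
    distance to the water and is lognormal across sites with the
    configured geometric mean.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    profile = props_mod.load_aroclor_profile("Aroclor1242").reindex(
        table["peak_id"]).fillna(0.0)
    profile /= profile.sum()
    d = sites["distance_to_water"].to_numpy(float)
    shape = (d / np.exp(np.mean(np.log(d)))) ** (-cfg.air_distance_exponent)
    noise = np.exp(rng.normal(0.0, cfg.air_gsd_log10 * np.log(10.0), size=len(d)))
    totals = cfg.air_geomean * shape * noise
    # recentre so the geometric mean is exact for the drawn sites
    totals *= cfg.air_geomean / np.exp(np.mean(np.log(totals)))
    out = pd.DataFrame(np.outer(totals, profile.to_numpy()),
                       columns=list(table["peak_id"]), index=sites["site_id"])
    return out


def generate_puf_dataset(cfg: SyntheticConfig, true_air: pd.DataFrame,
                         rs_true: pd.Series, table: pd.DataFrame,
                         sites: pd.DataFrame | None = None,
                         noise: bool = True) -> dict:
    """Deployments, sorbed masses, DC masses, blanks and recoveries.

    Sorbed mass per peak is true concentration times the effective volume
    for the site's true sampling rate, with optional lognormal noise; DC
    final masses decay exponentially at the same sampling rate; blanks
    are drawn from a peak-specific lognormal floor; surrogate recoveries
    are Normal(0.88, 0.13) truncated to (0, 1.5].
    """
    cfg.validate()
    if (true_air.to_numpy(float) < 0).any():
        raise ValueError("true air concentrations must be nonnegative")
    if (rs_true.to_numpy(float) <= 0).any():
        raise ValueError("true sampling rates must be positive")
    rng = np.random.default_rng(cfg.seed + 4)
    if sites is None:
        sites = generate_puf_sites(cfg)
    t_avg_k = cfg.mean_daily_temp + 273.15
    t_days = cfg.deployment_days
    peak_ids = list(true_air.columns)

    deployments = sites.copy()
    deployments["t_start"] = cfg.met_start
    deployments["t_end"] = cfg.met_start + timedelta(days=round(t_days))
    deployments["v_puf"] = cfg.v_puf

    recs = {pid: props_mod.record_for(table, pid) for pid in peak_ids}
    veff = np.empty((len(sites), len(peak_ids)))
    for j, pid in enumerate(peak_ids):
        veff[:, j] = pufpas.effective_volume(
            recs[pid], rs_true.loc[sites["site_id"]].to_numpy(float),
            t_days, cfg.v_puf, t_avg_k)
    rec = rng.normal(0.88, 0.13, size=len(sites))
    for _ in range(100):
        bad = (rec <= 0) | (rec > 1.5)
        if not bad.any():
            break
        rec[bad] = rng.normal(0.88, 0.13, size=bad.sum())
    recoveries = pd.Series(rec, index=sites["site_id"], name="recovery")

    masses = true_air.loc[sites["site_id"], peak_ids].to_numpy(float) * veff
    if noise:
        # reported masses carry the extraction loss that the surrogate
        # recovery correction later undoes
        masses = masses * np.exp(
            rng.normal(0.0, cfg.puf_noise_log_sd, size=masses.shape))
        masses = masses * np.minimum(rec, 1.0)[:, None]
    masses_df = pd.DataFrame(masses, columns=peak_ids, index=sites["site_id"])

    spike_pg = cfg.dc_spike_ng * 1000.0
    dc_rows = []
    for sid in sites["site_id"]:
        rs = float(rs_true.loc[sid])
        for dc_name, surrogate_peak in DC_COMPOUNDS.items():
            kvp = pufpas.puf_capacity(recs[surrogate_peak], t_avg_k) * cfg.v_puf
            final = spike_pg * np.exp(-rs * t_days / kvp)
            if noise:
                final *= np.exp(rng.normal(0.0, 0.05))
            dc_rows.append({"site_id": sid, "compound": dc_name,
                            "surrogate_peak": surrogate_peak,
                            "initial_pg": spike_pg,
                            "final_pg": min(final, spike_pg)})
    dc_df = pd.DataFrame(dc_rows)

    floor = np.exp(rng.normal(np.log(0.6), 0.6 * np.log(10.0), size=len(peak_ids)))
    blank_rows = {}
    for b in range(cfg.n_blanks):
        blank_rows[f"blank{b + 1}"] = floor * np.exp(
            rng.normal(0.0, 0.25 * np.log(10.0), size=len(peak_ids)))
    blanks_df = pd.DataFrame(blank_rows, index=peak_ids).T

    return {"deployments": deployments, "masses": masses_df, "dc": dc_df,
            "blanks": blanks_df, "recoveries": recoveries}
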