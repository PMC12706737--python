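"""Steady-state Gaussian-plume dispersion from a water-surface area source.

The emitting water surface is discretized into ground-level cells; each
cell of emission rate Q (ng s-1) contributes the reflected ground-source
kernel

    C = Q / (pi * sigma_y * sigma_z * u) * exp(-y^2 / (2 sigma_y^2))
                                         * exp(-z^2 / (2 sigma_z^2))

at a receptor x metres downwind, y crosswind, z above ground.  Dispersion
coefficients sigma_y, sigma_z follow the Briggs interpolation formulas
(urban by default, matching built-up study areas) for a Pasquill stability
class assigned from wind speed and a day/night insolation proxy
(Turner-style lookup).  Hourly fields are averaged over all non-calm
hours of the analysis window; hours below the calm threshold are excluded
and counted.

This is a desk-scale, fully specifiable stand-in for a regulatory
boundary-layer model: flat terrain, no downwash, no deposition or decay,
order-of-magnitude fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

CALM_THRESHOLD = 0.5  # m s-1

STABILITY_CLASSES = "ABCDEF"

#: Briggs urban sigma coefficients: class -> (a, b, exponent) with
#: sigma = a * x * (1 + b * x)^exponent
_BRIGGS_URBAN_Y = {
    "A": (0.32, 0.0004, -0.5), "B": (0.32, 0.0004, -0.5),
    "C": (0.22, 0.0004, -0.5), "D": (0.16, 0.0004, -0.5),
    "E": (0.11, 0.0004, -0.5), "F": (0.11, 0.0004, -0.5),
}
_BRIGGS_URBAN_Z = {
    "A": (0.24, 0.001, 0.5), "B": (0.24, 0.001, 0.5),
    "C": (0.20, 0.0, 0.0), "D": (0.14, 0.0003, -0.5),
    "E": (0.08, 0.00015, -0.5), "F": (0.08, 0.00015, -0.5),
}
_BRIGGS_RURAL_Y = {
    "A": (0.22, 0.0001, -0.5), "B": (0.16, 0.0001, -0.5),
    "C": (0.11, 0.0001, -0.5), "D": (0.08, 0.0001, -0.5),
    "E": (0.06, 0.0001, -0.5), "F": (0.04, 0.0001, -0.5),
}
_BRIGGS_RURAL_Z = {
    "A": (0.20, 0.0, 0.0), "B": (0.12, 0.0, 0.0),
    "C": (0.08, 0.0002, -0.5), "D": (0.06, 0.0015, -0.5),
    "E": (0.03, 0.0003, -1.0), "F": (0.016, 0.0003, -1.0),
}


@dataclass
class AreaSource:
    """Planar polygon source (projected metres) with per-peak emission flux.

    ``emission_flux`` is a Series of ng m-2 d-1 indexed by peak_id;
    release height is the water surface (0 m).
    """

    polygon: Polygon
    emission_flux: pd.Series
    release_height: float = 0.0

    def __post_init__(self):
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError("source polygon must be simple, closed, nonempty")
        if (np.asarray(self.emission_flux, dtype=float) < 0).any():
            raise ValueError("emission flux must be nonnegative")


def default_source_polygon(length_m: float = 26_500.0,
                           area_m2: float = 1.5e7) -> Polygon:
    """River-stretch rectangle along the y axis with the study water area."""
    half_w = area_m2 / length_m / 2.0
    half_l = length_m / 2.0
    return Polygon([(-half_w, -half_l), (half_w, -half_l),
                    (half_w, half_l), (-half_w, half_l)])


def stability_class(u10: float, is_day: bool,
                    insolation: str = "moderate") -> str:
    """Pasquill stability class from a Turner-style lookup.

    ``insolation`` is "strong", "moderate" or "slight" by day; by night it
    encodes cloud cover, "clear" (<= 3/8) or "cloudy" (>= 4/8).
    "overcast" forces neutral (D) at any hour.
    """
    if u10 < 0:
        raise ValueError("wind speed must be nonnegative")
    if insolation == "overcast":
        return "D"
    bins = [2.0, 3.0, 5.0, 6.0]
    i = int(np.searchsorted(bins, u10, side="right"))
    if is_day:
        day_table = {
            "strong": "AABCC", "moderate": "BBBCD", "slight": "BCCDD",
        }
        return day_table[insolation][i]
    night_table = {"clear": "FFEDD", "cloudy": "FEDDD"}
    return night_table.get(insolation, night_table["clear"])[i]


def sigma_yz(pclass: str, downwind_distance, urban: bool = True):
    """Briggs dispersion coefficients (sigma_y, sigma_z) in metres."""
    x = np.asarray(downwind_distance, dtype=float)
    if np.any(x <= 0):
        raise ValueError("downwind distance must be positive")
    ytab = _BRIGGS_URBAN_Y if urban else _BRIGGS_RURAL_Y
    ztab = _BRIGGS_URBAN_Z if urban else _BRIGGS_RURAL_Z
    ay, by, ey = ytab[pclass]
    az, bz, ez = ztab[pclass]
    sy = ay * x * (1.0 + by * x) ** ey
    sz = az * x * (1.0 + bz * x) ** ez
    if np.ndim(x) == 0:
        return float(sy), float(sz)
    return sy, sz


def discretize_source(polygon: Polygon, cell_size: float = 250.0):
    """Centres and areas of grid cells covering the polygon interior."""
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx + cell_size / 2.0, maxx, cell_size)
    ys = np.arange(miny + cell_size / 2.0, maxy, cell_size)
    if len(xs) == 0:
        xs = np.array([(minx + maxx) / 2.0])
    if len(ys) == 0:
        ys = np.array([(miny + maxy) / 2.0])
    gx, gy = np.meshgrid(xs, ys)
    centres = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.array([polygon.intersects(Point(p)) for p in centres])
    centres = centres[inside]
    if len(centres) == 0:
        raise ValueError("no source cells inside polygon at this cell size")
    cell_area = min(cell_size, maxx - minx) * min(cell_size, maxy - miny)
    return centres, cell_area


def _unit_concentration(cells: np.ndarray, receptor_xyz, u10: float,
                        wind_dir_deg: float, pclass: str, urban: bool,
                        cell_size: float) -> float:
    """Concentration (ng m-3) per unit area flux of 1 ng m-2 s-1."""
    rx, ry, rz = receptor_xyz
    # meteorological convention: direction the wind blows FROM; transport
    # is toward dir+180
    theta = np.radians(270.0 - wind_dir_deg)
    ux, uy = np.cos(theta), np.sin(theta)
    dx = rx - cells[:, 0]
    dy = ry - cells[:, 1]
    x = dx * ux + dy * uy          # downwind
    y = -dx * uy + dy * ux         # crosswind
    mask = x >= cell_size / 2.0    # exclude self/upwind cells
    if not mask.any():
        return 0.0
    sy, sz = sigma_yz(pclass, x[mask], urban)
    kern = (1.0 / (np.pi * sy * sz * u10)
            * np.exp(-y[mask] ** 2 / (2.0 * sy ** 2))
            * np.exp(-rz ** 2 / (2.0 * sz ** 2)))
    return float(kern.sum())


def area_source_concentration(src: AreaSource, receptors: pd.DataFrame,
                              u10: float, wind_dir_deg: float, pclass: str,
                              urban: bool = True,
                              cell_size: float = 250.0) -> pd.DataFrame:
    """Per-receptor, per-peak concentrations (ng m-3) for one met hour.

    ``receptors`` needs columns site_id, x, y and optionally z (default
    sampler height 2 m).  Linear in the source emission flux.
    """
    if u10 < CALM_THRESHOLD:
        raise ValueError(f"wind speed {u10} below calm threshold {CALM_THRESHOLD}")
    cells, cell_area = discretize_source(src.polygon, cell_size)
    q_per_flux = cell_area / 86_400.0  # (ng s-1 per cell) per (ng m-2 d-1)
    factors = np.array([
        _unit_concentration(
            cells, (r.x, r.y, getattr(r, "z", 2.0)), u10, wind_dir_deg,
            pclass, urban, cell_size) * q_per_flux
        for r in receptors.itertuples()])
    out = pd.DataFrame(np.outer(factors, src.emission_flux.to_numpy(float)),
                       index=receptors["site_id"],
                       columns=src.emission_flux.index)
    return out


def hourly_stability(met: pd.DataFrame) -> pd.Series:
    """Assign a Pasquill class to every met hour (day = 07-18 local)."""
    classes = []
    for row in met.itertuples():
        hour = row.timestamp.hour
        is_day = 7 <= hour <= 18
        insol = "moderate" if is_day else "clear"
        classes.append(stability_class(row.u10, is_day, insol))
    return pd.Series(classes, index=met.index, name="pclass")


def period_average(src: AreaSource, receptors: pd.DataFrame,
                   met: pd.DataFrame, urban: bool = True,
                   cell_size: float = 250.0) -> dict:
    """Period-mean per-receptor, per-peak concentrations over non-calm hours.

    Returns a dict with "concentrations" (pg m-3 DataFrame), "n_calm" and
    "n_hours".  Hours with u10 below the calm threshold are excluded from
    the average (the plume kernel diverges as u -> 0).
    """
    ok = met["u10"] >= CALM_THRESHOLD
    n_calm = int((~ok).sum())
    active = met[ok]
    if len(active) == 0:
        raise ValueError("all hours calm: no plume transport to average")
    cells, cell_area = discretize_source(src.polygon, cell_size)
    pcls = hourly_stability(active)

    xyz = [(r.x, r.y, getattr(r, "z", 2.0)) for r in receptors.itertuples()]
    acc = np.zeros(len(xyz))
    for (_, row), pc in zip(active.iterrows(), pcls):
        for i, rxyz in enumerate(xyz):
            acc[i] += _unit_concentration(cells, rxyz, row["u10"],
                                          row["wind_dir"], pc, urban, cell_size)
    factors = acc / len(active) * cell_area / 86_400.0
    conc_ng = np.outer(factors, src.emission_flux.to_numpy(float))
    conc = pd.DataFrame(conc_ng * 1000.0,  # ng m-3 -> pg m-3
                        index=receptors["site_id"],
                        columns=src.emission_flux.index)
    conc.attrs["sigma_pcb"] = conc.sum(axis=1)
    return {"concentrations": conc, "n_calm": n_calm, "n_hours": int(len(met))}
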