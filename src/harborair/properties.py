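"""Physicochemical properties of PCB congeners and coeluting peaks.

All 209 IUPAC congeners are organized into 173 chromatographic peaks, the
resolution at which GC-MS/MS congener analysis on an octyl-type column
quantifies them; coeluting congeners share a single peak and are assigned
the property values of the lowest-numbered member (a deterministic,
documented convention).  Every downstream module reads Henry's law
constants, internal energies of air-water transfer, octanol-air partition
coefficients and molar volumes exclusively through this module, so a
user-supplied property table replaces the defaults everywhere at once.

The default table is a synthetic stand-in built from homolog-based
correlations anchored to published measurement scales (Henry's law on the
experimental scale of roughly 20-50 Pa m3 mol-1 for light congeners); it
is not a transcription of any single published compilation and carries a
``provenance`` column saying so.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

R_GAS = 8.314  # Pa m3 mol-1 K-1
T_REF = 298.15  # K

#: inclusive IUPAC number ranges per homolog (chlorine count 1..10)
HOMOLOG_RANGES: list[tuple[int, int, int]] = [
    (1, 3, 1), (4, 15, 2), (16, 39, 3), (40, 81, 4), (82, 127, 5),
    (128, 169, 6), (170, 193, 7), (194, 205, 8), (206, 208, 9), (209, 209, 10),
]

#: coeluting congener groups (deterministic scheme; 209 congeners -> 173 peaks)
COELUTIONS: list[tuple[int, ...]] = [
    (18, 30), (20, 28), (40, 41, 71), (44, 47, 65), (45, 51), (50, 53),
    (61, 70, 74, 76), (83, 99), (86, 87, 97, 109, 119, 125), (90, 101, 113),
    (93, 95, 98, 100, 102), (107, 124), (110, 115), (128, 166),
    (129, 138, 163), (135, 151), (147, 149), (153, 168), (156, 157),
    (180, 193), (183, 185), (197, 200), (198, 199),
]

REQUIRED_COLUMNS = (
    "peak_id", "iupac_numbers", "mw", "h298", "du_aw",
    "log_koa_298", "molar_volume", "homolog",
)


class PropertyTableError(ValueError):
    """Raised when a congener property table fails validation."""


@dataclass(frozen=True)
class CongenerRecord:
    """Properties of one chromatographic peak (one or more congeners).

    h298 is the Henry's law constant at 298.15 K in Pa m3 mol-1; du_aw the
    internal energy of air-water phase transfer in J mol-1; log_koa_298
    the decadic log of the dimensionless octanol-air partition
    coefficient; molar_volume the LeBas molar volume in cm3 mol-1.
    """

    peak_id: str
    iupac_numbers: tuple[int, ...]
    mw: float
    h298: float
    du_aw: float
    log_koa_298: float
    molar_volume: float
    homolog: int


def homolog_of(iupac: int) -> int:
    """Chlorine count for an IUPAC congener number (1-209)."""
    for lo, hi, ncl in HOMOLOG_RANGES:
        if lo <= iupac <= hi:
            return ncl
    raise ValueError(f"IUPAC number {iupac} outside 1-209")


def peak_id_for(members: tuple[int, ...]) -> str:
    return "PCB" + "+".join(str(m) for m in members)


def _peak_membership() -> list[tuple[int, ...]]:
    grouped = {m for grp in COELUTIONS for m in grp}
    peaks: list[tuple[int, ...]] = [tuple(sorted(g)) for g in COELUTIONS]
    peaks.extend((n,) for n in range(1, 210) if n not in grouped)
    peaks.sort(key=lambda g: g[0])
    return peaks


def _properties_for(iupac: int) -> dict[str, float]:
    # Homolog-based correlations with a small deterministic within-homolog
    # spread; anchored so that tri/tetra congeners carry H ~ 35-40
    # Pa m3 mol-1 and log KOA ~ 7.9-8.5, the ranges the mass-transfer and
    # sampler models are most sensitive to.
    ncl = homolog_of(iupac)
    lo, hi, _ = next(r for r in HOMOLOG_RANGES if r[0] <= iupac <= r[1])
    frac = 0.0 if hi == lo else (iupac - lo) / (hi - lo) - 0.5
    return {
        "mw": 188.7 + 34.444 * (ncl - 1),
        "h298": 10.0 ** (1.80 - 0.045 * ncl + 0.08 * frac),
        "du_aw": 47_000.0 + 1_800.0 * ncl,
        "log_koa_298": 6.35 + 0.53 * ncl + 0.15 * frac,
        "molar_volume": 184.6 + 20.9 * ncl,
        "homolog": ncl,
    }


def default_table() -> pd.DataFrame:
    """Build the default 173-peak property table (209 congeners).

    Coeluting peaks carry the property values of their lowest-numbered
    member congener.
    """
    rows = []
    for members in _peak_membership():
        props = _properties_for(members[0])
        rows.append({
            "peak_id": peak_id_for(members),
            "iupac_numbers": "+".join(str(m) for m in members),
            **props,
            "provenance": "synthetic homolog correlation",
        })
    table = pd.DataFrame(rows)
    return validate_table(table)


def parse_iupac_numbers(value) -> tuple[int, ...]:
    if isinstance(value, (tuple, list)):
        return tuple(int(v) for v in value)
    return tuple(int(tok) for tok in str(value).replace("PCB", "").split("+"))


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) == 0:
        raise PropertyTableError("no records in congener property table")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise PropertyTableError(f"missing required column(s): {missing}")

    seen: dict[int, str] = {}
    for idx, row in table.iterrows():
        members = parse_iupac_numbers(row["iupac_numbers"])
        if not members:
            raise PropertyTableError(f"row {idx} ({row['peak_id']}): empty congener list")
        for m in members:
            if not 1 <= m <= 209:
                raise PropertyTableError(
                    f"row {idx} ({row['peak_id']}): IUPAC number {m} outside 1-209")
            if m in seen:
                raise PropertyTableError(
                    f"row {idx} ({row['peak_id']}): duplicate congener PCB{m} "
                    f"(already in {seen[m]})")
            seen[m] = str(row["peak_id"])
        if not row["h298"] > 0:
            raise PropertyTableError(
                f"row {idx} ({row['peak_id']}): non-positive h298 {row['h298']}")
        if not 188.0 <= row["mw"] <= 499.0:
            raise PropertyTableError(
                f"row {idx} ({row['peak_id']}): mw {row['mw']} outside PCB range")
        if int(row["homolog"]) != homolog_of(members[0]):
            raise PropertyTableError(
                f"row {idx} ({row['peak_id']}): homolog {row['homolog']} inconsistent "
                f"with IUPAC number {members[0]}")
    out = table.reset_index(drop=True).copy()
    out.attrs["n_congeners"] = len(seen)
    return out


def load_congener_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a congener property table CSV (one row per peak)."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise PropertyTableError("no records in congener property table") from exc
    return validate_table(table)


def write_congener_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def records_from_table(table: pd.DataFrame) -> list[CongenerRecord]:
    return [
        CongenerRecord(
            peak_id=row["peak_id"],
            iupac_numbers=parse_iupac_numbers(row["iupac_numbers"]),
            mw=float(row["mw"]),
            h298=float(row["h298"]),
            du_aw=float(row["du_aw"]),
            log_koa_298=float(row["log_koa_298"]),
            molar_volume=float(row["molar_volume"]),
            homolog=int(row["homolog"]),
        )
        for _, row in table.iterrows()
    ]


def record_for(table: pd.DataFrame, peak_id: str) -> CongenerRecord:
    match = table[table["peak_id"] == peak_id]
    if len(match) == 0:
        raise KeyError(f"peak {peak_id!r} not in property table")
    return records_from_table(match)[0]


# ---------------------------------------------------------------------------
# temperature adjustment

def henry_at_temperature(h298, du_aw, t_water):
    """Henry's law constant at water temperature t_water (K), Pa m3 mol-1.

    Van 't Hoff form: H(T) = H298 * exp((dU_aw/R) * (1/298.15 - 1/T)).
    Monotone increasing in T for du_aw > 0.
    """
    t = np.asarray(t_water, dtype=float)
    if np.any(t <= 270.0) or np.any(t >= 320.0):
        raise ValueError(f"water temperature {t_water} K outside 270-320 K")
    out = np.asarray(h298, dtype=float) * np.exp(
        (np.asarray(du_aw, dtype=float) / R_GAS) * (1.0 / T_REF - 1.0 / t))
    return float(out) if out.ndim == 0 else out


def dimensionless_henry(h_t, t_water):
    """Dimensionless Henry's law constant H' = H(T) / (R * T)."""
    h = np.asarray(h_t, dtype=float)
    if np.any(h <= 0):
        raise ValueError("Henry's law constant must be positive")
    out = h / (R_GAS * np.asarray(t_water, dtype=float))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Aroclor reference profiles

_DATA_DIR = Path(__file__).parent / "data"
AROCLOR_FILES = {
    "Aroclor1016": "aroclor1016_synthetic.csv",
    "Aroclor1242": "aroclor1242_synthetic.csv",
}


def load_aroclor_profile(name_or_path: str | Path) -> pd.Series:
    """Load an Aroclor mass-fraction profile as a Series indexed by peak_id.

    ``name_or_path`` is either a shipped mixture name ("Aroclor1016",
    "Aroclor1242") or a path to a two-column CSV (peak_id, fraction).
    Fractions are renormalized to sum to one.
    """
    path = _DATA_DIR / AROCLOR_FILES[str(name_or_path)] \
        if str(name_or_path) in AROCLOR_FILES else Path(name_or_path)
    df = pd.read_csv(path)
    frac = pd.Series(df["fraction"].to_numpy(float), index=df["peak_id"])
    if (frac < 0).any():
        raise ValueError("Aroclor profile has negative fractions")
    total = frac.sum()
    if total <= 0:
        raise ValueError("Aroclor profile sums to zero")
    return frac / total


def subset_profile(profile: pd.Series, peak_ids) -> pd.Series:
    """Restrict a profile to a peak set and renormalize to sum to one."""
    sub = profile.reindex(peak_ids).fillna(0.0)
    total = sub.sum()
    if total <= 0:
        raise ValueError("profile has no mass on the requested peak set")
    return sub / total
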