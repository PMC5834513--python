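"""CSV input/output, configuration and table-level pipelines.

CSV dialect: comma-separated, UTF-8, header row, empty string = missing.
Headers are matched case-insensitively.  Isotopic composition columns come
in exactly one of two unit-tagged spellings per quantity —
``<base>_atom_percent`` or ``<base>_delta_permil`` — and are converted to
atom fraction at the boundary.  Depths are meters, positive downward.

Outputs are written atomically (temp file, then rename) and input files
are never mutated.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .isotopes import (
    AIR,
    IsotopeReference,
    NPool,
    atom_percent_to_fraction,
    delta_to_atom_fraction,
)
from .kinetics import MichaelisMentenModel
from .profiles import StationProfile, detect_features
from .rates import (
    IncubationRecord,
    detection_limit,
    integrate_daily,
    rate_bulk,
    rate_in_situ,
    rate_r14,
    rate_r15,
)

__all__ = [
    "RunConfig",
    "SchemaError",
    "read_incubations",
    "read_kinetics",
    "read_profiles",
    "compute_rates_table",
    "compute_daily_table",
    "fit_kinetics_table",
    "profile_features_table",
    "write_csv_atomic",
]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


@dataclass
class RunConfig:
    """Run-level constants for the rate pipeline.

    Defaults are the framework's standard constants: atmospheric-N₂
    reference ratio, 98 at-% tracer, 12 h/12 h oxidation and ×16 uptake
    daily integration, 3σ of the ±0.2‰ δ¹⁵N accuracy as the detection
    threshold, the 0.8 °C mixed-layer criterion, the 90% nitracline
    contiguity rule and the 0.1% sPAR euphotic fraction.
    """

    r15_standard: float = 0.0036765
    tracer_atom_frac: float = 0.98
    light_hours: float = 12.0
    dark_hours: float = 12.0
    uptake_hours: float = 16.0
    delta_sd_permil: float = 0.2
    k_sigma: float = 3.0
    mld_delta_t: float = 0.8
    nitracline_contiguity: float = 0.9
    nitracline_floor: float = 0.01
    euphotic_fraction: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r15_standard < 1:
            raise ValueError("r15_standard must lie in (0, 1)")
        if not 0 < self.tracer_atom_frac < 1:
            raise ValueError("tracer_atom_frac must lie in (0, 1)")
        if self.delta_sd_permil <= 0 or self.k_sigma <= 0:
            raise ValueError("detection-limit parameters must be positive")
        if not 0 < self.euphotic_fraction <= 1:
            raise ValueError("euphotic_fraction must lie in (0, 1]")
        if not 0 < self.nitracline_contiguity <= 1:
            raise ValueError("nitracline_contiguity must lie in (0, 1]")

    @property
    def reference(self) -> IsotopeReference:
        return IsotopeReference(self.r15_standard)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def write_csv_atomic(df: pd.DataFrame, path) -> None:
    """Write a DataFrame to CSV atomically (temp file then rename)."""
    path = os.fspath(path)
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return df


def _isotope_column(df: pd.DataFrame, base: str, row, ref: IsotopeReference,
                    required: bool = True) -> float | None:
    """Read one isotopic-composition value with its unit tag resolved."""
    pct_col = f"{base}_atom_percent"
    delta_col = f"{base}_delta_permil"
    has_pct = pct_col in df.columns
    has_delta = delta_col in df.columns
    if has_pct and has_delta:
        pct_val, delta_val = row.get(pct_col), row.get(delta_col)
        if pd.notna(pct_val) and pd.notna(delta_val):
            raise SchemaError(
                f"both {pct_col} and {delta_col} given for one row: ambiguous"
            )
    if has_pct and pd.notna(row.get(pct_col)):
        return atom_percent_to_fraction(float(row[pct_col]))
    if has_delta and pd.notna(row.get(delta_col)):
        return delta_to_atom_fraction(float(row[delta_col]), ref)
    if required:
        raise SchemaError(f"no value for {base} (need {pct_col} or {delta_col})")
    return None


INCUBATION_REQUIRED = ("depth_m", "light", "t_h", "c0_product", "ct_product",
                       "ci_substrate", "ct_tracer")

_LIGHT_CODES = {"l": "light", "light": "light", "d": "dark", "dark": "dark"}


def read_incubations(path, config: RunConfig | None = None,
                     ) -> tuple[list[IncubationRecord], list[tuple[int, str]]]:
    """Read an incubation table into validated records.

    Malformed rows are rejected individually and collected as
    ``(line_number, message)`` pairs (line 1 is the header); the valid
    remainder is returned.  When no substrate-labelling column is present,
    f15 is computed from Ci, the tracer concentration and the configured
    tracer purity by mass balance.
    """
    config = config or RunConfig()
    ref = config.reference
    df = _read_table(path, INCUBATION_REQUIRED)
    records: list[IncubationRecord] = []
    errors: list[tuple[int, str]] = []
    natural = delta_to_atom_fraction(0.0, ref)
    for idx, row in df.iterrows():
        line = int(idx) + 2
        try:
            light = _LIGHT_CODES.get(str(row["light"]).strip().lower())
            if light is None:
                raise SchemaError(f"light must be L or D, got {row['light']!r}")
            n0 = _isotope_column(df, "n0_product", row, ref)
            nt = _isotope_column(df, "nt_product", row, ref)
            f15 = _isotope_column(df, "n_substrate", row, ref, required=False)
            ci = float(row["ci_substrate"])
            ct = float(row["ct_tracer"])
            if f15 is None:
                if ci + ct <= 0:
                    raise SchemaError("cannot infer f15 with no substrate")
                f15 = (ci * natural + ct * config.tracer_atom_frac) / (ci + ct)
            rec = IncubationRecord(
                product_t0=NPool(conc=float(row["c0_product"]), atom_frac=n0,
                                 label="product"),
                product_t1=NPool(conc=float(row["ct_product"]), atom_frac=nt,
                                 label="product"),
                substrate_ambient_conc=ci,
                tracer_conc=ct,
                substrate_atom_frac=f15,
                duration_h=float(row["t_h"]),
                light=light,
                depth_m=float(row["depth_m"]),
                replicate_id=(str(row["replicate"])
                              if "replicate" in df.columns
                              and pd.notna(row.get("replicate")) else None),
                station=(str(row["station"]) if "station" in df.columns
                         and pd.notna(row.get("station")) else None),
            )
            records.append(rec)
        except (ValueError, KeyError) as exc:
            errors.append((line, str(exc)))
    return records, errors


def compute_rates_table(records: list[IncubationRecord],
                        config: RunConfig | None = None) -> pd.DataFrame:
    """Tidy table of rate estimates (bulk, r15, r14, in_situ) per record,
    with per-sample detection limits and below-DL flags."""
    config = config or RunConfig()
    rows = []
    for rec in records:
        dl = detection_limit(rec.product_t0.conc, rec.substrate_atom_frac,
                             rec.duration_h, delta_sd=config.delta_sd_permil,
                             k_sigma=config.k_sigma, ref=config.reference)
        r15 = rate_r15(rec)
        r14 = rate_r14(r15, rec.substrate_atom_frac)
        estimates = [rate_bulk(rec, detection_limit_value=dl), r15, r14,
                     rate_in_situ(rec, detection_limit_value=dl)]
        for est in estimates:
            rows.append({
                "station": rec.station,
                "depth_m": rec.depth_m,
                "light": rec.light,
                "replicate": rec.replicate_id,
                "method": est.method,
                "value": est.value,
                "units": est.units,
                "detection_limit": est.detection_limit,
                "below_dl": est.below_dl,
            })
    return pd.DataFrame(rows)


def compute_daily_table(rates_df: pd.DataFrame, process: str = "oxidation",
                        config: RunConfig | None = None) -> pd.DataFrame:
    """Integrate in-situ hourly rates to daily rates per station/depth.

    Light/dark replicate rates are averaged within condition first;
    oxidation requires both conditions at a depth.
    """
    from .rates import RateEstimate

    config = config or RunConfig()
    sub = rates_df[rates_df["method"] == "in_situ"]
    rows = []
    for (station, depth), grp in sub.groupby(["station", "depth_m"],
                                             dropna=False):
        by_light = {light: g["value"].mean()
                    for light, g in grp.groupby("light")}
        dls = {light: g["detection_limit"].mean()
               for light, g in grp.groupby("light")}
        light_est = RateEstimate(value=by_light.get("light", np.nan),
                                 method="in_situ",
                                 detection_limit=dls.get("light"))
        dark_est = (RateEstimate(value=by_light["dark"], method="in_situ",
                                 detection_limit=dls.get("dark"))
                    if "dark" in by_light else None)
        if process == "oxidation" and dark_est is None:
            continue
        daily = integrate_daily(light_est, dark_est, process=process,
                                light_hours=config.light_hours,
                                dark_hours=config.dark_hours,
                                uptake_hours=config.uptake_hours)
        rows.append({"station": station, "depth_m": depth,
                     "value": daily.value, "units": daily.units,
                     "detection_limit": daily.detection_limit,
                     "below_dl": daily.below_dl})
    return pd.DataFrame(rows)


KINETIC_REQUIRED = ("depth_m", "process", "s_total_nmol_l", "rate_nmol_l_h")


def read_kinetics(path) -> pd.DataFrame:
    """Read a kinetic table (depth_m, process, s_total_nmol_L,
    rate_nmol_L_h, replicate)."""
    return _read_table(path, KINETIC_REQUIRED)


def fit_kinetics_table(df: pd.DataFrame) -> pd.DataFrame:
    """Fit a Michaelis–Menten curve per (process, depth) group; returns a
    table of Vmax, Ks, α, standard errors and convergence flags."""
    rows = []
    for (process, depth), grp in df.groupby(["process", "depth_m"]):
        fit = MichaelisMentenModel(
            grp["s_total_nmol_l"].to_numpy(dtype=float),
            grp["rate_nmol_l_h"].to_numpy(dtype=float),
            process=process, depth_m=depth).fit()
        rows.append({
            "process": process, "depth_m": depth,
            "vmax": fit.vmax, "vmax_se": fit.vmax_se,
            "ks": fit.ks, "ks_se": fit.ks_se,
            "alpha": fit.alpha, "alpha_se": fit.alpha_se,
            "converged": fit.converged, "residual_norm": fit.residual_norm,
            "n_points": fit.nobs,
        })
    return pd.DataFrame(rows)


PROFILE_REQUIRED = ("station", "depth_m")


def read_profiles(path) -> dict[str, StationProfile]:
    """Read a bottle/CTD table into one :class:`StationProfile` per
    station."""
    df = _read_table(path, PROFILE_REQUIRED)
    return {str(station): StationProfile.from_dataframe(grp)
            for station, grp in df.groupby("station")}


def profile_features_table(profiles: dict[str, StationProfile],
                           config: RunConfig | None = None) -> pd.DataFrame:
    """One-row-per-station table of detected water-column features."""
    config = config or RunConfig()
    rows = []
    for station, profile in sorted(profiles.items()):
        features = detect_features(
            profile,
            mld_delta_t=config.mld_delta_t,
            nitracline_contiguity=config.nitracline_contiguity,
            nitracline_floor=config.nitracline_floor,
            euphotic_fraction=config.euphotic_fraction,
        )
        row = {"station": station}
        row.update(features.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
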