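"""Water-column feature detection for stratified station profiles.

Detects the hydrographic and biogeochemical features used to interpret
vertical rate structure in the upper ocean:

* mixed-layer depth (MLD) — temperature-threshold criterion: shallowest
  depth where T falls a fixed offset (default 0.8 °C) below the surface
  value, linearly interpolated between bottles;
* nitracline — the depth range with the steepest vertical NO₃⁻ gradient
  and its midpoint (the nitracline depth);
* euphotic depth — the depth receiving a stated fraction (default 0.1%)
  of surface photosynthetically active radiation (sPAR), from an
  exponential attenuation fit PAR(z) = sPAR·exp(−k z);
* subsurface extrema — primary nitrite maximum (PNM), deep chlorophyll
  maximum (DCM) and the NO₃⁻/SiO₄ ratio maximum;
* the uptake→nitrification transition depth — the shallowest persistent
  crossover where nitrification exceeds NH₄⁺ uptake.

Depth convention: meters, positive downward, shallowest sample first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StationProfile",
    "ProfileFeatures",
    "NitraclineResult",
    "ExtremumLayers",
    "TransitionResult",
    "LightDarkTest",
    "InvalidOpticsError",
    "InsufficientOverlapError",
    "mixed_layer_depth",
    "nitracline",
    "attenuation_coefficient",
    "euphotic_depth",
    "extremum_layers",
    "transition_depth",
    "paired_light_dark_test",
    "ols_r2",
    "detect_features",
]


class InvalidOpticsError(ValueError):
    """PAR does not decrease with depth: attenuation fit impossible."""


class InsufficientOverlapError(ValueError):
    """Fewer than two common depths between two rate profiles."""


@dataclass
class StationProfile:
    """Depth-indexed environmental and rate series for one station.

    Depths must be strictly increasing (positive downward); every series
    is aligned to the depth grid, with NaN allowed for missing samples.
    ``rates`` maps series names (e.g. ``"nh4_uptake"``,
    ``"nh4_oxidation"``) to arrays on the same grid.
    """

    depth_m: np.ndarray
    temperature_C: np.ndarray | None = None
    par: np.ndarray | None = None
    no3: np.ndarray | None = None
    no2: np.ndarray | None = None
    nh4: np.ndarray | None = None
    sio4: np.ndarray | None = None
    chl_fluor: np.ndarray | None = None
    rates: dict = field(default_factory=dict)
    station: str | None = None

    def __post_init__(self) -> None:
        self.depth_m = np.asarray(self.depth_m, dtype=float)
        if self.depth_m.ndim != 1 or self.depth_m.size < 2:
            raise ValueError("need a 1-D depth grid with >= 2 samples")
        if np.any(np.isnan(self.depth_m)):
            raise ValueError("NaN in depth grid")
        if np.any(np.diff(self.depth_m) <= 0):
            raise ValueError("depths must be strictly increasing")
        for name in ("temperature_C", "par", "no3", "no2", "nh4", "sio4",
                     "chl_fluor"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.depth_m.shape:
                    raise ValueError(f"{name} not aligned to the depth grid")
                setattr(self, name, arr)
        self.rates = {k: np.asarray(v, dtype=float)
                      for k, v in self.rates.items()}
        for k, v in self.rates.items():
            if v.shape != self.depth_m.shape:
                raise ValueError(f"rate series {k!r} not aligned to depth grid")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       rate_columns: tuple = ("nh4_uptake", "nh4_oxidation",
                                              "no3_uptake")) -> "StationProfile":
        """Build from a bottle table with a ``depth_m`` column."""
        df = df.sort_values("depth_m")
        colmap = {"temp_C": "temperature_C", "par_pct_surface": "par",
                  "par_abs": "par", "no3": "no3", "no2": "no2", "nh4": "nh4",
                  "sio4": "sio4", "chl_fluor": "chl_fluor"}
        kwargs = {}
        for col, attr in colmap.items():
            if col in df.columns and attr not in kwargs:
                kwargs[attr] = df[col].to_numpy(dtype=float)
        rates = {c: df[c].to_numpy(dtype=float)
                 for c in rate_columns if c in df.columns}
        station = df["station"].iloc[0] if "station" in df.columns else None
        return cls(depth_m=df["depth_m"].to_numpy(dtype=float),
                   rates=rates, station=station, **kwargs)


def _clean(depth: np.ndarray, y: np.ndarray):
    ok = np.isfinite(y)
    return depth[ok], y[ok]


def mixed_layer_depth(depth, temperature, delta_t: float = 0.8) -> float | None:
    """Temperature-threshold mixed-layer depth.

    Shallowest depth at which the temperature equals the surface
    (shallowest-sample) value minus ``delta_t``, linearly interpolated
    between the bracketing bottles.  Returns ``None`` when the threshold
    is never crossed (e.g. an isothermal profile) — a distinct no-MLD
    outcome, not an error.
    """
    depth, temperature = _clean(np.asarray(depth, float),
                                np.asarray(temperature, float))
    if depth.size < 2:
        raise ValueError("need >= 2 temperature samples")
    target = temperature[0] - delta_t
    for i in range(1, depth.size):
        if temperature[i] <= target:
            if temperature[i] == target:
                return float(depth[i])
            t_hi, t_lo = temperature[i - 1], temperature[i]
            frac = (t_hi - target) / (t_hi - t_lo)
            return float(depth[i - 1] + frac * (depth[i] - depth[i - 1]))
    return None


@dataclass(frozen=True)
class NitraclineResult:
    """Steepest-NO₃⁻-gradient depth range and its midpoint."""

    top_m: float
    bottom_m: float

    @property
    def midpoint_m(self) -> float:
        return 0.5 * (self.top_m + self.bottom_m)


def nitracline(depth, no3, contiguity_frac: float = 0.9,
               flatness_floor: float = 0.01) -> NitraclineResult | None:
    """Locate the nitracline: the depth range with the steepest NO₃⁻
    gradient, and its midpoint.

    Finite-difference gradients are taken on raw adjacent bottle pairs
    (no smoothing).  The "steepest range" is the contiguous run of pairs,
    containing the maximum, whose gradients reach at least
    ``contiguity_frac`` (default 90%) of the maximum gradient.  Returns
    ``None`` when the maximum gradient does not exceed ``flatness_floor``
    (concentration units per meter) — the no-nitracline case typical of
    well-mixed eutrophic coastal water.
    """
    depth, no3 = _clean(np.asarray(depth, float), np.asarray(no3, float))
    if depth.size < 3:
        raise ValueError("need >= 3 NO3 samples")
    grad = np.diff(no3) / np.diff(depth)
    gmax = float(np.max(grad))
    if gmax <= flatness_floor:
        return None
    imax = int(np.argmax(grad))
    mask = grad >= contiguity_frac * gmax
    lo = imax
    while lo > 0 and mask[lo - 1]:
        lo -= 1
    hi = imax
    while hi < mask.size - 1 and mask[hi + 1]:
        hi += 1
    return NitraclineResult(top_m=float(depth[lo]), bottom_m=float(depth[hi + 1]))


def attenuation_coefficient(depth, par, par_floor: float = 0.0) -> float:
    """Diffuse PAR attenuation coefficient k (m⁻¹) from the least-squares
    slope of ln(PAR) against depth over samples above ``par_floor``."""
    depth = np.asarray(depth, float)
    par = np.asarray(par, float)
    ok = np.isfinite(par) & (par > max(par_floor, 0.0))
    depth, par = depth[ok], par[ok]
    if depth.size < 2:
        raise InvalidOpticsError("need >= 2 positive PAR samples")
    slope = stats.linregress(depth, np.log(par)).slope
    if slope >= 0:
        raise InvalidOpticsError("PAR does not decrease with depth")
    return float(-slope)


def euphotic_depth(k: float | None = None, depth=None, par=None,
                   fraction: float = 0.001,
                   par_floor: float = 0.0) -> tuple[float, float]:
    """Euphotic depth: where PAR falls to ``fraction`` of the surface value.

    Under exponential attenuation PAR(z) = sPAR·e^{−kz}, the depth solving
    PAR(z) = fraction × sPAR is z = ln(1/fraction)/k.  Supply ``k``
    directly or a (depth, PAR) profile to fit it.  Returns ``(k, depth)``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if k is None:
        if depth is None or par is None:
            raise ValueError("supply either k or a (depth, par) profile")
        k = attenuation_coefficient(depth, par, par_floor=par_floor)
    if k <= 0:
        raise InvalidOpticsError("attenuation coefficient must be positive")
    return float(k), float(np.log(1.0 / fraction) / k)


def _series_max_depth(depth: np.ndarray, y: np.ndarray):
    """Depth of the global maximum; ties broken shallow; flags boundary
    extrema; None for flat series."""
    d, v = _clean(depth, y)
    if d.size == 0 or np.ptp(v) == 0:
        return None, False
    i = int(np.argmax(v))  # first occurrence = shallowest on a sorted grid
    return float(d[i]), bool(i in (0, d.size - 1))


@dataclass(frozen=True)
class ExtremumLayers:
    """Depths of subsurface extrema: PNM, DCM, and the NO₃⁻/SiO₄ ratio
    maximum; *_boundary flags mark maxima at the profile's endpoints."""

    pnm_depth_m: float | None = None
    pnm_boundary: bool = False
    dcm_depth_m: float | None = None
    dcm_boundary: bool = False
    no3_si_ratio_max_depth_m: float | None = None
    no3_si_ratio_boundary: bool = False


def extremum_layers(profile: StationProfile) -> ExtremumLayers:
    """Locate the PNM (NO₂⁻ maximum), DCM (fluorescence maximum) and the
    NO₃⁻/SiO₄ ratio maximum (ratio computed only where SiO₄ > 0)."""
    pnm = dcm = ratio = (None, False)
    if profile.no2 is not None:
        pnm = _series_max_depth(profile.depth_m, profile.no2)
    if profile.chl_fluor is not None:
        dcm = _series_max_depth(profile.depth_m, profile.chl_fluor)
    if profile.no3 is not None and profile.sio4 is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(profile.sio4 > 0, profile.no3 / profile.sio4, np.nan)
        ratio = _series_max_depth(profile.depth_m, r)
    return ExtremumLayers(
        pnm_depth_m=pnm[0], pnm_boundary=pnm[1],
        dcm_depth_m=dcm[0], dcm_boundary=dcm[1],
        no3_si_ratio_max_depth_m=ratio[0], no3_si_ratio_boundary=ratio[1],
    )


@dataclass(frozen=True)
class TransitionResult:
    """Uptake→nitrification crossover: depth if present, else a status of
    ``surface_dominated`` (nitrification exceeds uptake from the top) or
    ``no_crossover`` (no persistent crossover, the co-occurrence case)."""

    depth_m: float | None
    status: str  # "crossover" | "surface_dominated" | "no_crossover"


def transition_depth(uptake_depth, uptake, nitrif_depth, nitrif,
                     persistence: int = 2) -> TransitionResult:
    """Shallowest persistent crossover from NH₄⁺-uptake dominance to
    nitrification dominance.

    The coarser series is linearly interpolated onto the finer grid over
    the overlapping depth span.  A crossover is accepted where the
    nitrification−uptake difference turns positive and stays positive for
    at least ``persistence`` consecutive samples; the crossing depth is
    linearly interpolated.  Transient sign flips (co-occurring comparable
    rates) yield no crossover.
    """
    du = np.asarray(uptake_depth, float)
    dn = np.asarray(nitrif_depth, float)
    u = np.asarray(uptake, float)
    n = np.asarray(nitrif, float)
    du, u = _clean(du, u)
    dn, n = _clean(dn, n)
    lo, hi = max(du.min(), dn.min()), min(du.max(), dn.max())
    grid = np.union1d(du[(du >= lo) & (du <= hi)], dn[(dn >= lo) & (dn <= hi)])
    if grid.size < 2:
        raise InsufficientOverlapError(
            "fewer than 2 common depths between the rate profiles"
        )
    ui = np.interp(grid, du, u)
    ni = np.interp(grid, dn, n)
    diff = ni - ui
    if np.all(diff > 0):
        return TransitionResult(depth_m=None, status="surface_dominated")
    for i in range(1, diff.size):
        if diff[i - 1] <= 0 and diff[i] > 0:
            run = diff[i:i + persistence]
            if run.size >= persistence and np.all(run > 0):
                if diff[i - 1] == 0:
                    z = grid[i - 1]
                else:
                    frac = -diff[i - 1] / (diff[i] - diff[i - 1])
                    z = grid[i - 1] + frac * (grid[i] - grid[i - 1])
                return TransitionResult(depth_m=float(z), status="crossover")
    return TransitionResult(depth_m=None, status="no_crossover")


@dataclass(frozen=True)
class LightDarkTest:
    """Student's t comparison of light vs. dark incubation rates."""

    t: float
    p: float
    mean_difference: float
    paired: bool


def paired_light_dark_test(light_reps, dark_reps,
                           paired: bool | None = None) -> LightDarkTest:
    """Student's t test of light vs. dark rates.

    Paired across depths when the replicates are depth-matched (equal
    length; the default when ``paired`` is None), otherwise a two-sample
    test.  Degenerate identical groups return t = 0, p = 1.
    """
    light = np.asarray(light_reps, float)
    dark = np.asarray(dark_reps, float)
    if light.size < 2 or dark.size < 2:
        raise ValueError("need >= 2 replicates per condition")
    if paired is None:
        paired = light.size == dark.size
    if paired and light.size != dark.size:
        raise ValueError("paired test needs equal-length groups")
    mean_diff = float(np.mean(light) - np.mean(dark))
    if paired:
        if np.ptp(light - dark) == 0 and mean_diff == 0:
            return LightDarkTest(t=0.0, p=1.0, mean_difference=0.0, paired=True)
        res = stats.ttest_rel(light, dark)
    else:
        if np.ptp(light) == 0 and np.ptp(dark) == 0 and mean_diff == 0:
            return LightDarkTest(t=0.0, p=1.0, mean_difference=0.0, paired=False)
        res = stats.ttest_ind(light, dark)
    return LightDarkTest(t=float(res.statistic), p=float(res.pvalue),
                         mean_difference=mean_diff, paired=bool(paired))


def ols_r2(x, y):
    """Ordinary least-squares diagnostic for rate–covariate relationships:
    returns (slope, intercept, r², p)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    res = stats.linregress(x[ok], y[ok])
    return res.slope, res.intercept, res.rvalue**2, res.pvalue


@dataclass(frozen=True)
class ProfileFeatures:
    """Derived water-column features for one station."""

    mld_m: float | None = None
    nitracline: NitraclineResult | None = None
    attenuation_k: float | None = None
    euphotic_depth_m: float | None = None
    extrema: ExtremumLayers | None = None
    transition: TransitionResult | None = None

    @property
    def nitracline_depth_m(self) -> float | None:
        return None if self.nitracline is None else self.nitracline.midpoint_m

    def to_dict(self) -> dict:
        d = {
            "mld_m": self.mld_m,
            "nitracline_top_m": None,
            "nitracline_bottom_m": None,
            "nitracline_depth_m": None,
            "attenuation_k_per_m": self.attenuation_k,
            "euphotic_depth_m": self.euphotic_depth_m,
            "pnm_depth_m": None,
            "dcm_depth_m": None,
            "no3_si_ratio_max_depth_m": None,
            "transition_depth_m": None,
            "transition_status": None,
        }
        if self.nitracline is not None:
            d["nitracline_top_m"] = self.nitracline.top_m
            d["nitracline_bottom_m"] = self.nitracline.bottom_m
            d["nitracline_depth_m"] = self.nitracline.midpoint_m
        if self.extrema is not None:
            d["pnm_depth_m"] = self.extrema.pnm_depth_m
            d["dcm_depth_m"] = self.extrema.dcm_depth_m
            d["no3_si_ratio_max_depth_m"] = self.extrema.no3_si_ratio_max_depth_m
        if self.transition is not None:
            d["transition_depth_m"] = self.transition.depth_m
            d["transition_status"] = self.transition.status
        return d


def detect_features(profile: StationProfile,
                    mld_delta_t: float = 0.8,
                    nitracline_contiguity: float = 0.9,
                    nitracline_floor: float = 0.01,
                    euphotic_fraction: float = 0.001,
                    par_floor: float = 0.0,
                    uptake_key: str = "nh4_uptake",
                    oxidation_key: str = "nh4_oxidation") -> ProfileFeatures:
    """Run every available feature detector on a station profile."""
    mld = (mixed_layer_depth(profile.depth_m, profile.temperature_C,
                             delta_t=mld_delta_t)
           if profile.temperature_C is not None else None)
    ncl = (nitracline(profile.depth_m, profile.no3,
                      contiguity_frac=nitracline_contiguity,
                      flatness_floor=nitracline_floor)
           if profile.no3 is not None else None)
    k = zeu = None
    if profile.par is not None:
        k, zeu = euphotic_depth(depth=profile.depth_m, par=profile.par,
                                fraction=euphotic_fraction,
                                par_floor=par_floor)
    extrema = extremum_layers(profile)
    transition = None
    if uptake_key in profile.rates and oxidation_key in profile.rates:
        transition = transition_depth(profile.depth_m, profile.rates[uptake_key],
                                      profile.depth_m,
                                      profile.rates[oxidation_key])
    return ProfileFeatures(mld_m=mld, nitracline=ncl, attenuation_k=k,
                           euphotic_depth_m=zeu, extrema=extrema,
                           transition=transition)
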