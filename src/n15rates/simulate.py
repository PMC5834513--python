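"""Synthetic incubation experiments and station profiles with known truth.

The generators emulate the measurement design the rate framework is built
for — ¹⁵N tracer spikes of 10–20 nmol L⁻¹ into nmol-level ambient NH₄⁺,
four-level kinetic enrichments spanning 10–2000 nmol L⁻¹, 3–12 h
incubations, and stratified stations with an exponential light field, a
sigmoidal nitracline and unimodal subsurface rate maxima — so that every
pipeline stage can be exercised against ground truth.

Within an incubation the transformation rate is held constant (the
substrate pool is effectively undepleted over 3–12 h and the substrate
labelling f15 constant; no regeneration/dilution), and the product pool's
¹⁵N accumulation follows from exact mass balance.  Analytical noise:
multiplicative CV 3.5% on concentrations and additive SD 0.2‰ on δ¹⁵N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .isotopes import (
    NATURAL_ABUNDANCE,
    TRACER_ATOM_FRACTION,
    NPool,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
)
from .kinetics import DEFAULT_KINETIC_LEVELS, KineticSeries, mm_rate
from .profiles import StationProfile
from .rates import IncubationRecord

__all__ = [
    "IncubationTruth",
    "IncubationGroundTruth",
    "StationTruth",
    "simulate_incubation",
    "simulate_kinetic_experiment",
    "simulate_station",
]


@dataclass
class IncubationTruth:
    """Ground-truth configuration for a simulated tracer incubation.

    Defaults describe an ammonium-oxidation experiment: Michaelis–Menten
    kinetics with Vmax = 22 nmol N L⁻¹ h⁻¹ and Ks = 300 nmol N L⁻¹,
    ambient NH₄⁺ of 20 nmol L⁻¹ (within the observed 1–74 nmol L⁻¹ span)
    and a large natural-abundance NOx product pool.  For nitrification the
    light incubation runs at ``light_inhibition_factor`` times the dark
    rate (photoinhibition of ammonia oxidizers); uptake is not inhibited.
    """

    process: str = "nh4_oxidation"
    vmax: float = 22.0                      # nmol N L-1 h-1
    ks: float = 300.0                       # nmol N L-1
    ambient_substrate_conc: float = 20.0    # nmol N L-1
    ambient_product_conc: float = 30000.0   # nmol N L-1 (NOx ~ 30 umol/L)
    ambient_product_delta: float = 0.0      # permil
    light_inhibition_factor: float = 0.5    # light/dark rate ratio
    tracer_atom_frac: float = TRACER_ATOM_FRACTION
    conc_cv: float = 0.035                  # NH4 analysis precision +-3.5%
    delta_sd: float = 0.2                   # permil

    def __post_init__(self) -> None:
        if not 0.0 <= self.light_inhibition_factor <= 1.0:
            raise ValueError("light inhibition factor must lie in [0, 1]")
        if min(self.vmax, self.ks) <= 0:
            raise ValueError("vmax and ks must be positive")
        if min(self.ambient_substrate_conc, self.ambient_product_conc) < 0:
            raise ValueError("concentrations must be >= 0")

    def substrate_atom_frac(self, spike_conc: float) -> float:
        """f15 of the substrate pool after a tracer spike, by mass balance."""
        ci = self.ambient_substrate_conc
        if ci + spike_conc <= 0:
            raise ValueError("no substrate")
        return ((ci * NATURAL_ABUNDANCE + spike_conc * self.tracer_atom_frac)
                / (ci + spike_conc))

    def light_factor(self, light: str) -> float:
        if light == "light" and self.process == "nh4_oxidation":
            return self.light_inhibition_factor
        return 1.0

    def true_rate_total(self, spike_conc: float, light: str = "dark") -> float:
        """True transformation rate at the bulk (ambient+spike) substrate."""
        s = self.ambient_substrate_conc + spike_conc
        return mm_rate(self.vmax, self.ks, s) * self.light_factor(light)

    def true_rate_ambient(self, light: str = "dark") -> float:
        """True in-situ rate at the unperturbed ambient concentration."""
        return (mm_rate(self.vmax, self.ks, self.ambient_substrate_conc)
                * self.light_factor(light))


@dataclass(frozen=True)
class IncubationGroundTruth:
    """True quantities behind a batch of simulated incubation records."""

    rate_total: float
    rate_ambient: float
    f15: float
    spike_conc: float
    duration_h: float
    light: str


def simulate_incubation(truth: IncubationTruth,
                        spike_conc: float = 20.0,
                        duration_h: float = 12.0,
                        replicates: int = 2,
                        light: str = "dark",
                        noise: bool = True,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[list[IncubationRecord], IncubationGroundTruth]:
    """Simulate replicate tracer incubations and return records plus truth.

    The product pool gains A = R·t nmol L⁻¹ of nitrogen carrying the
    substrate's post-spike atom fraction f15:
    C_t = C0 + A and n_t = (C0·n0 + A·f15)/C_t (exact mass balance).
    With ``noise`` on, measured concentrations receive multiplicative
    Gaussian noise (CV ``truth.conc_cv``) and measured δ¹⁵N additive
    Gaussian noise (SD ``truth.delta_sd``).  Deterministic for a fixed
    seed.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    f15 = (truth.substrate_atom_frac(spike_conc) if spike_conc > 0
           else NATURAL_ABUNDANCE)
    rate_total = truth.true_rate_total(spike_conc, light)
    c0 = truth.ambient_product_conc
    n0 = delta_to_atom_fraction(truth.ambient_product_delta)
    accumulated = rate_total * duration_h
    c1 = c0 + accumulated
    n1 = (c0 * n0 + accumulated * f15) / c1

    records = []
    for rep in range(replicates):
        c0_m, c1_m, n0_m, n1_m = c0, c1, n0, n1
        if noise:
            c0_m = c0 * (1.0 + rng.normal(0.0, truth.conc_cv))
            c1_m = c1 * (1.0 + rng.normal(0.0, truth.conc_cv))
            n0_m = delta_to_atom_fraction(
                atom_fraction_to_delta(n0) + rng.normal(0.0, truth.delta_sd))
            n1_m = delta_to_atom_fraction(
                atom_fraction_to_delta(n1) + rng.normal(0.0, truth.delta_sd))
        records.append(IncubationRecord(
            product_t0=NPool(conc=max(c0_m, 0.0), atom_frac=n0_m,
                             label="product"),
            product_t1=NPool(conc=max(c1_m, 0.0), atom_frac=n1_m,
                             label="product"),
            substrate_ambient_conc=truth.ambient_substrate_conc,
            tracer_conc=spike_conc,
            substrate_atom_frac=f15,
            duration_h=duration_h,
            light=light,
            replicate_id=str(rep + 1),
        ))
    ground = IncubationGroundTruth(
        rate_total=rate_total,
        rate_ambient=truth.true_rate_ambient(light),
        f15=f15, spike_conc=spike_conc, duration_h=duration_h, light=light,
    )
    return records, ground


def simulate_kinetic_experiment(truth: IncubationTruth,
                                levels=DEFAULT_KINETIC_LEVELS,
                                replicates: int = 2,
                                duration_h: float = 12.0,
                                light: str = "dark",
                                noise: bool = True,
                                rate_cv: float | None = None,
                                seed: int | None = None,
                                ) -> tuple[KineticSeries, IncubationTruth]:
    """Simulate a multi-level tracer-addition kinetic experiment.

    One batch of replicate incubations per enrichment level (default four
    levels, 10–2000 nmol L⁻¹, duplicates); each incubation's bulk rate is
    recovered through the exact ¹⁵N/¹⁴N accumulation chain and assembled
    into a :class:`KineticSeries` against total substrate (ambient +
    spike).

    Noise models: with ``rate_cv`` set, incubations are generated
    noise-free and multiplicative Gaussian noise of that CV is applied to
    the assembled rates (the canonical recovery-study condition);
    otherwise ``noise`` toggles the analytical concentration/δ noise of
    :func:`simulate_incubation`.
    """
    levels = tuple(float(x) for x in levels)
    if len(levels) < 3:
        raise ValueError("need >= 3 enrichment levels for a kinetic design")
    rng = np.random.default_rng(seed)
    from .rates import rate_r14, rate_r15

    incubation_noise = noise and rate_cv is None
    s_total, rate, rep_id = [], [], []
    for level in levels:
        records, _ = simulate_incubation(
            truth, spike_conc=level, duration_h=duration_h,
            replicates=replicates, light=light, noise=incubation_noise,
            rng=rng)
        for rec in records:
            r15 = rate_r15(rec)
            bulk = r15.value + rate_r14(r15, rec.substrate_atom_frac).value
            s_total.append(rec.total_substrate_conc)
            rate.append(bulk)
            rep_id.append(rec.replicate_id)
    rate = np.array(rate)
    if noise and rate_cv is not None:
        rate = rate * (1.0 + rng.normal(0.0, rate_cv, rate.size))
    series = KineticSeries(s_total=np.array(s_total), rate=rate,
                           process=truth.process,
                           replicate=np.array(rep_id))
    return series, truth


@dataclass
class StationTruth:
    """Ground truth for a stratified synthetic station.

    The noise-free profile is analytic, so every feature depth is known in
    closed form (the crossover is solved numerically from the noise-free
    rate curves):

    * temperature: surface mixed layer above ``thermocline_top``, then an
      exponentially saturating decline; the 0.8 °C-threshold MLD follows
      analytically;
    * PAR: sPAR·exp(−k z);
    * NO₃⁻: logistic with inflection (steepest gradient) at
      ``nitracline_center``;
    * NO₂⁻ and fluorescence: Gaussian PNM and DCM;
    * NH₄⁺: low, patchy, in the 1–74 nmol L⁻¹ span;
    * rates (daily units): Gaussian uptake peak shallow, Gaussian
      nitrification peak deep, crossing between the two maxima.
    """

    grid_m: float = 5.0
    z_max_m: float = 200.0
    surface_temp_C: float = 28.0
    thermocline_top_m: float = 30.0
    thermocline_total_drop_C: float = 12.0
    thermocline_scale_m: float = 60.0
    mld_delta_t: float = 0.8
    no3_surface_uM: float = 0.05
    no3_deep_uM: float = 6.0
    nitracline_center_m: float = 70.0
    nitracline_width_m: float = 8.0
    k_par: float = 0.06
    spar: float = 100.0
    euphotic_fraction: float = 0.001
    dcm_center_m: float = 75.0
    dcm_width_m: float = 15.0
    dcm_amp: float = 1.0
    chl_background: float = 0.05
    pnm_center_m: float = 85.0
    pnm_width_m: float = 10.0
    pnm_amp_nM: float = 220.0
    no2_background_nM: float = 5.0
    nh4_background_nM: float = 25.0
    sio4_ratio_peak_m: float = 95.0
    uptake_amp: float = 25.0      # nmol N L-1 d-1
    uptake_center_m: float = 25.0
    uptake_width_m: float = 35.0
    nitrif_amp: float = 18.0
    nitrif_center_m: float = 90.0
    nitrif_width_m: float = 35.0
    temp_sd_C: float = 0.01
    par_cv: float = 0.02
    no3_cv: float = 0.01
    no2_cv: float = 0.035
    nh4_cv: float = 0.035
    chl_cv: float = 0.03
    rate_cv: float = 0.05

    def __post_init__(self) -> None:
        for name in ("grid_m", "nitracline_width_m", "dcm_width_m",
                     "pnm_width_m", "uptake_width_m", "nitrif_width_m",
                     "thermocline_scale_m", "k_par"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # --- analytic noise-free fields -------------------------------------
    def depth_grid(self) -> np.ndarray:
        return np.arange(0.0, self.z_max_m + 0.5 * self.grid_m, self.grid_m)

    def temperature(self, z):
        z = np.asarray(z, float)
        below = np.clip(z - self.thermocline_top_m, 0.0, None)
        drop = self.thermocline_total_drop_C * (
            1.0 - np.exp(-below / self.thermocline_scale_m))
        return self.surface_temp_C - drop

    def no3(self, z):
        z = np.asarray(z, float)
        return self.no3_surface_uM + (self.no3_deep_uM - self.no3_surface_uM) / (
            1.0 + np.exp(-(z - self.nitracline_center_m) / self.nitracline_width_m))

    def par(self, z):
        return self.spar * np.exp(-self.k_par * np.asarray(z, float))

    def chl(self, z):
        z = np.asarray(z, float)
        return self.chl_background + self.dcm_amp * np.exp(
            -((z - self.dcm_center_m) / self.dcm_width_m) ** 2)

    def no2(self, z):
        z = np.asarray(z, float)
        return self.no2_background_nM + self.pnm_amp_nM * np.exp(
            -((z - self.pnm_center_m) / self.pnm_width_m) ** 2)

    def sio4(self, z):
        # shaped so that NO3/SiO4 peaks near sio4_ratio_peak_m at ~1.15
        z = np.asarray(z, float)
        ratio = 0.3 + 0.85 * np.exp(-((z - self.sio4_ratio_peak_m) / 20.0) ** 2)
        return np.maximum(self.no3(z), 0.05) / ratio

    def uptake(self, z):
        z = np.asarray(z, float)
        return self.uptake_amp * np.exp(
            -((z - self.uptake_center_m) / self.uptake_width_m) ** 2)

    def nitrification(self, z):
        z = np.asarray(z, float)
        return self.nitrif_amp * np.exp(
            -((z - self.nitrif_center_m) / self.nitrif_width_m) ** 2)

    # --- true feature depths --------------------------------------------
    @property
    def true_mld_m(self) -> float:
        """Depth where T = surface − ΔT on the analytic profile."""
        frac = self.mld_delta_t / self.thermocline_total_drop_C
        return self.thermocline_top_m - self.thermocline_scale_m * np.log1p(-frac)

    @property
    def true_nitracline_m(self) -> float:
        return self.nitracline_center_m

    @property
    def true_euphotic_m(self) -> float:
        return float(np.log(1.0 / self.euphotic_fraction) / self.k_par)

    @property
    def true_dcm_m(self) -> float:
        return self.dcm_center_m

    @property
    def true_pnm_m(self) -> float:
        return self.pnm_center_m

    @property
    def true_crossover_m(self) -> float:
        """Root of nitrification − uptake between the two rate maxima."""
        f = lambda z: self.nitrification(z) - self.uptake(z)
        return float(brentq(f, self.uptake_center_m, self.nitrif_center_m))


def simulate_station(truth: StationTruth, seed: int | None = None,
                     noise: bool = True) -> tuple[StationProfile, StationTruth]:
    """Simulate one station profile (CTD + bottle + rate series).

    Returns the profile and the truth object whose ``true_*`` properties
    give the generating feature depths.  Construction guarantees strictly
    increasing depths and strictly decreasing noise-free PAR.
    """
    rng = np.random.default_rng(seed)
    z = truth.depth_grid()
    temp = truth.temperature(z)
    par = truth.par(z)
    no3 = truth.no3(z)
    no2 = truth.no2(z)
    chl = truth.chl(z)
    sio4 = truth.sio4(z)
    # patchy ambient NH4 within the observed 1-74 nmol/L span
    nh4 = np.clip(
        truth.nh4_background_nM
        * np.exp(rng.normal(0.0, 0.5, z.size) if noise else np.zeros(z.size)),
        1.0, 74.0)
    uptake = truth.uptake(z)
    nitrif = truth.nitrification(z)
    if noise:
        temp = temp + rng.normal(0.0, truth.temp_sd_C, z.size)
        par = par * (1.0 + rng.normal(0.0, truth.par_cv, z.size))
        no3 = no3 * (1.0 + rng.normal(0.0, truth.no3_cv, z.size))
        no2 = no2 * (1.0 + rng.normal(0.0, truth.no2_cv, z.size))
        chl = chl * (1.0 + rng.normal(0.0, truth.chl_cv, z.size))
        sio4 = sio4 * (1.0 + rng.normal(0.0, 0.02, z.size))
        uptake = uptake * (1.0 + rng.normal(0.0, truth.rate_cv, z.size))
        nitrif = nitrif * (1.0 + rng.normal(0.0, truth.rate_cv, z.size))
        par = np.maximum(par, 1e-12)
    profile = StationProfile(
        depth_m=z, temperature_C=temp, par=par, no3=no3, no2=no2, nh4=nh4,
        sio4=sio4, chl_fluor=chl,
        rates={"nh4_uptake": uptake, "nh4_oxidation": nitrif},
        station="synthetic",
    )
    return profile, truth
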