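"""Isotope notation conversions and nitrogen mass-balance bookkeeping.

All isotope arithmetic is performed in (amount, atom fraction) space: the
linear δ-mixing approximation breaks down at the ~98 at-% enrichment of the
tracer, whereas ¹⁵N-content mass balance is exact at any enrichment.  δ¹⁵N
values (per-mil vs. atmospheric N₂) appear only at the interfaces.

Internal units: nmol N L⁻¹ for concentrations, nmol N for amounts, atom
fraction on [0, 1] for isotopic composition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "R15_AIR",
    "TRACER_ATOM_FRACTION",
    "NATURAL_ABUNDANCE",
    "IsotopeReference",
    "AIR",
    "NPool",
    "BlankCorrection",
    "IsotopeError",
    "InvalidIsotopeValueError",
    "DegenerateMixtureError",
    "UnmixingInfeasibleError",
    "BlankExceedsSampleError",
    "BlankFractionWarning",
    "delta_to_atom_fraction",
    "atom_fraction_to_delta",
    "atom_percent_to_fraction",
    "atom_fraction_to_percent",
    "mix_pools",
    "unmix_carrier",
    "correct_blanks",
]

#: ¹⁵N/¹⁴N ratio of atmospheric N₂.  With this reference, δ¹⁵N = 0‰
#: corresponds to 0.3663 atom-% ¹⁵N.
R15_AIR = 0.0036765

#: Default atom fraction of a commercial ¹⁵N tracer salt (98 at-%).
TRACER_ATOM_FRACTION = 0.98


class IsotopeError(ValueError):
    """Base class for isotope bookkeeping errors."""


class InvalidIsotopeValueError(IsotopeError):
    """A δ or atom-fraction value outside its physical domain."""


class DegenerateMixtureError(IsotopeError):
    """Mixture with zero total nitrogen: composition undefined."""


class UnmixingInfeasibleError(IsotopeError):
    """Carrier removal yields a non-physical sample (blank-dominated)."""


class BlankExceedsSampleError(IsotopeError):
    """Blank nitrogen meets or exceeds the measured nitrogen."""


class BlankFractionWarning(UserWarning):
    """Blank contribution above the declared acceptable fraction."""


@dataclass(frozen=True)
class IsotopeReference:
    """¹⁵N/¹⁴N isotope reference scale (atmospheric N₂ by default)."""

    r15_standard: float = R15_AIR

    def __post_init__(self) -> None:
        if not self.r15_standard > 0:
            raise InvalidIsotopeValueError(
                f"reference ratio must be positive, got {self.r15_standard}"
            )


#: The default atmospheric-N₂ reference.
AIR = IsotopeReference()


def _maybe_scalar(x: np.ndarray):
    return float(x) if np.ndim(x) == 0 else x


def delta_to_atom_fraction(delta, ref: IsotopeReference = AIR):
    """Convert δ¹⁵N (‰ vs. the reference) to ¹⁵N atom fraction.

    n = R / (1 + R) with R = r_std × (1 + δ/1000).  Strictly increasing in
    δ and bounded in (0, 1).

    Parameters
    ----------
    delta : float or array_like
        δ¹⁵N in per mil; must be > −1000 (R > 0).
    ref : IsotopeReference
        Reference scale; atmospheric N₂ by default.
    """
    d = np.asarray(delta, dtype=float)
    if np.any(d <= -1000.0):
        raise InvalidIsotopeValueError("delta must be > -1000 permil")
    r = ref.r15_standard * (1.0 + d / 1000.0)
    return _maybe_scalar(r / (1.0 + r))


def atom_fraction_to_delta(n, ref: IsotopeReference = AIR):
    """Convert ¹⁵N atom fraction (0, 1) to δ¹⁵N in ‰; inverse of
    :func:`delta_to_atom_fraction`."""
    a = np.asarray(n, dtype=float)
    if np.any((a <= 0.0) | (a >= 1.0)):
        raise InvalidIsotopeValueError("atom fraction must lie in (0, 1)")
    return _maybe_scalar(1000.0 * (a / (1.0 - a) / ref.r15_standard - 1.0))


def atom_percent_to_fraction(at_pct):
    """Atom-% (0–100) to atom fraction (0–1)."""
    a = np.asarray(at_pct, dtype=float)
    if np.any((a <= 0.0) | (a >= 100.0)):
        raise InvalidIsotopeValueError("atom percent must lie in (0, 100)")
    return _maybe_scalar(a / 100.0)


def atom_fraction_to_percent(n):
    """Atom fraction (0–1) to atom-% (0–100)."""
    a = np.asarray(n, dtype=float)
    if np.any((a <= 0.0) | (a >= 1.0)):
        raise InvalidIsotopeValueError("atom fraction must lie in (0, 1)")
    return _maybe_scalar(100.0 * a)


#: ¹⁵N atom fraction at natural abundance (δ¹⁵N = 0‰ on the AIR scale);
#: 0.3663 atom-% to four significant digits.
NATURAL_ABUNDANCE = delta_to_atom_fraction(0.0)


@dataclass
class NPool:
    """A nitrogen pool: concentration (or amount) plus ¹⁵N atom fraction.

    Parameters
    ----------
    conc : float
        Amount concentration in nmol N L⁻¹.  When ``volume_mL`` is absent
        the value doubles as an amount in nmol (nominal 1 L).
    atom_frac : float
        ¹⁵N atom fraction in (0, 1).
    label : str
        Free-text role: substrate | product | tracer | carrier | blank.
    volume_mL : float, optional
        Sample volume; enables amount-based operations on real volumes.
    """

    conc: float
    atom_frac: float
    label: str = ""
    volume_mL: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.conc < 0:
            raise IsotopeError(f"concentration must be >= 0, got {self.conc}")
        if not 0.0 < self.atom_frac < 1.0:
            raise InvalidIsotopeValueError(
                f"atom fraction must lie in (0, 1), got {self.atom_frac}"
            )
        if self.volume_mL is not None and self.volume_mL <= 0:
            raise IsotopeError("volume must be positive when given")

    @property
    def amount_nmol(self) -> float:
        """Amount of N in nmol (conc × volume; conc itself for 1 L nominal)."""
        if self.volume_mL is None:
            return self.conc
        return self.conc * self.volume_mL / 1000.0

    @property
    def n15_nmol(self) -> float:
        """¹⁵N content in nmol."""
        return self.amount_nmol * self.atom_frac

    @property
    def n14_nmol(self) -> float:
        """¹⁴N content in nmol."""
        return self.amount_nmol * (1.0 - self.atom_frac)

    def delta(self, ref: IsotopeReference = AIR) -> float:
        """δ¹⁵N of the pool in ‰."""
        return atom_fraction_to_delta(self.atom_frac, ref)


def mix_pools(pools: list[NPool]) -> NPool:
    """Mix nitrogen pools conserving ¹⁵N and ¹⁴N content exactly.

    When every pool carries a volume the mixture is formed in amount space
    and the result carries the summed volume.  Otherwise concentrations add
    (co-dissolution: e.g. a tracer spike quoted as final concentration in
    the incubation bottle).
    """
    if not pools:
        raise DegenerateMixtureError("no pools to mix")
    with_volumes = all(p.volume_mL is not None for p in pools)
    amounts = np.array([p.amount_nmol for p in pools])
    total = amounts.sum()
    if total <= 0:
        raise DegenerateMixtureError("all pool amounts are zero")
    n15 = sum(p.n15_nmol for p in pools)
    n = n15 / total
    if with_volumes:
        vol = sum(p.volume_mL for p in pools)
        return NPool(conc=total / (vol / 1000.0), atom_frac=n,
                     label="mixture", volume_mL=vol)
    return NPool(conc=total, atom_frac=n, label="mixture")


def unmix_carrier(mixture: NPool, carrier: NPool,
                  sample_amount: float | None = None) -> NPool:
    """Recover a sample's composition after a carrier addition.

    Inverts the carrier mass balance: a known amount of carrier (e.g. an
    in-house NO₃⁻ standard added to low-concentration samples before
    isotopic analysis) is subtracted from the measured mixture in
    (amount × atom fraction) space.

    Raises
    ------
    UnmixingInfeasibleError
        If the implied sample amount or ¹⁵N content is non-physical
        (signals a blank/carrier-dominated sample).
    """
    n_mix = mixture.amount_nmol
    n_car = carrier.amount_nmol
    n_sam = n_mix - n_car
    if sample_amount is not None:
        if not np.isclose(sample_amount, n_sam, rtol=1e-6, atol=1e-9):
            raise UnmixingInfeasibleError(
                f"stated sample amount {sample_amount} inconsistent with "
                f"mixture - carrier = {n_sam}"
            )
        n_sam = sample_amount
    if n_sam <= 0:
        raise UnmixingInfeasibleError("sample amount <= 0 after carrier removal")
    n15_sam = mixture.n15_nmol - carrier.n15_nmol
    frac = n15_sam / n_sam
    if not 0.0 < frac < 1.0:
        raise UnmixingInfeasibleError(
            f"implied sample atom fraction {frac} outside (0, 1)"
        )
    if mixture.volume_mL is not None and carrier.volume_mL is not None:
        vol = mixture.volume_mL - carrier.volume_mL
        if vol <= 0:
            raise UnmixingInfeasibleError("sample volume <= 0")
        return NPool(conc=n_sam / (vol / 1000.0), atom_frac=frac,
                     label="sample", volume_mL=vol)
    return NPool(conc=n_sam, atom_frac=frac, label="sample")


@dataclass(frozen=True)
class BlankCorrection:
    """Result of a blank subtraction: the corrected pool plus diagnostics."""

    pool: NPool
    blank_amount_nmol: float
    blank_fraction: float


def correct_blanks(measured: NPool, blanks: list[NPool],
                   warn_fraction: float = 0.03) -> BlankCorrection:
    """Subtract procedural blanks (e.g. oxidizing-reagent and filter blanks)
    from a measured pool by exact mass balance.

    Identity when the blank list is empty or all blanks carry zero N.
    Warns (:class:`BlankFractionWarning`) when the blanks exceed
    ``warn_fraction`` of the measured nitrogen, and raises
    :class:`BlankExceedsSampleError` when they meet or exceed it entirely.
    """
    n_meas = measured.amount_nmol
    n_blank = sum(b.amount_nmol for b in blanks)
    if n_blank >= n_meas:
        raise BlankExceedsSampleError(
            f"blank N ({n_blank} nmol) >= measured N ({n_meas} nmol)"
        )
    if n_blank == 0:
        return BlankCorrection(pool=replace(measured), blank_amount_nmol=0.0,
                               blank_fraction=0.0)
    n15 = measured.n15_nmol - sum(b.n15_nmol for b in blanks)
    n_corr = n_meas - n_blank
    frac = n15 / n_corr
    if not 0.0 < frac < 1.0:
        raise BlankExceedsSampleError(
            f"blank-corrected atom fraction {frac} outside (0, 1)"
        )
    blank_fraction = n_blank / n_meas
    if blank_fraction > warn_fraction:
        warnings.warn(
            f"blanks are {100 * blank_fraction:.1f}% of measured N "
            f"(> {100 * warn_fraction:.0f}%)",
            BlankFractionWarning,
            stacklevel=2,
        )
    if measured.volume_mL is not None:
        pool = NPool(conc=n_corr / (measured.volume_mL / 1000.0),
                     atom_frac=frac, label=measured.label or "corrected",
                     volume_mL=measured.volume_mL)
    else:
        pool = NPool(conc=n_corr, atom_frac=frac,
                     label=measured.label or "corrected")
    return BlankCorrection(pool=pool, blank_amount_nmol=n_blank,
                           blank_fraction=blank_fraction)
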