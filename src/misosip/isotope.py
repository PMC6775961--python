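"""Isotope arithmetic for carbon stable-isotope probing.

Converts between the three equivalent descriptions of a carbon pool's
isotopic state -- delta notation (per mil vs VPDB), the 13C/12C amount
ratio R, and the fractional abundance F = R/(1+R) -- and implements the
two-end-member source apportionment used to split methane (or any product
pool) between a methyl donor and dissolved inorganic carbon (DIC), the
label incorporation ratios for single-labeling experiments, and
mass-balance mixing of pools.

All fractional abundances are dimensionless in [0, 1); concentrations are
mmol per liter of slurry. Percent appears only at report boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateEndmemberError,
    DegenerateLabelError,
    EmptyPoolError,
    InconsistentMeasurementError,
    InvalidIsotopeError,
    NoEnrichmentError,
)

#: 13C/12C amount ratio of the VPDB standard, as conventionally rounded.
R_VPDB = 0.011180

#: Default delta-13C of unlabeled (natural abundance) pools, per mil vs VPDB.
#: Typical of biogenic organic matter; every estimator accepts explicit
#: backgrounds, so this only drives convenience defaults.
NATURAL_DELTA_PERMIL = -30.0

#: Endmembers closer than this (in F units) cannot be apportioned between;
#: the gap is below GC-IRMS precision.
ENDMEMBER_EPSILON = 1e-6


def delta_to_ratio(delta):
    """13C/12C amount ratio R from delta-13C (per mil vs VPDB).

    R = (delta/1000 + 1) * R_VPDB.  Raises for delta < -1000 per mil, which
    would imply a negative ratio.
    """
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < -1000.0):
        raise InvalidIsotopeError(
            f"delta-13C must be >= -1000 per mil, got {delta!r}"
        )
    out = (delta / 1000.0 + 1.0) * R_VPDB
    return out if out.ndim else float(out)


def ratio_to_delta(ratio):
    """delta-13C (per mil vs VPDB) from the 13C/12C amount ratio."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0.0):
        raise InvalidIsotopeError(f"isotope ratio must be >= 0, got {ratio!r}")
    out = (ratio / R_VPDB - 1.0) * 1000.0
    return out if out.ndim else float(out)


def ratio_to_fraction(ratio):
    """Fractional 13C abundance F = R/(1+R)."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio < 0.0):
        raise InvalidIsotopeError(f"isotope ratio must be >= 0, got {ratio!r}")
    out = ratio / (1.0 + ratio)
    return out if out.ndim else float(out)


def fraction_to_ratio(f):
    """13C/12C amount ratio from fractional abundance, R = F/(1-F)."""
    f = np.asarray(f, dtype=float)
    if np.any((f < 0.0) | (f >= 1.0)):
        raise InvalidIsotopeError(f"fraction-13C must lie in [0, 1), got {f!r}")
    out = f / (1.0 - f)
    return out if out.ndim else float(out)


def delta_to_fraction(delta):
    """Fractional 13C abundance from delta-13C (per mil vs VPDB)."""
    return ratio_to_fraction(delta_to_ratio(delta))


def fraction_to_delta(f):
    """delta-13C (per mil vs VPDB) from fractional 13C abundance."""
    return ratio_to_delta(fraction_to_ratio(f))


NATURAL_FRACTION_13C = delta_to_fraction(NATURAL_DELTA_PERMIL)


@dataclass(frozen=True)
class IsotopeValue:
    """Isotopic state of one carbon pool, stored as fractional abundance.

    Construct from whichever representation was measured::

        IsotopeValue.from_delta(-30.0)
        IsotopeValue.from_fraction(0.836)
        IsotopeValue.from_ratio(0.011180)
    """

    fraction_13c: float

    def __post_init__(self):
        if not (0.0 <= self.fraction_13c < 1.0):
            raise InvalidIsotopeError(
                f"fraction-13C must lie in [0, 1), got {self.fraction_13c}"
            )

    @classmethod
    def from_delta(cls, delta: float) -> "IsotopeValue":
        return cls(delta_to_fraction(delta))

    @classmethod
    def from_fraction(cls, f: float) -> "IsotopeValue":
        return cls(float(f))

    @classmethod
    def from_ratio(cls, ratio: float) -> "IsotopeValue":
        return cls(ratio_to_fraction(ratio))

    @property
    def delta_c13(self) -> float:
        return fraction_to_delta(self.fraction_13c)

    @property
    def ratio(self) -> float:
        return fraction_to_ratio(self.fraction_13c)


@dataclass(frozen=True)
class CarbonPool:
    """A named carbon pool with optional concentration (mmol/L slurry)."""

    name: str
    isotope: IsotopeValue
    concentration: float | None = None

    def __post_init__(self):
        if self.concentration is not None and self.concentration < 0.0:
            raise InvalidIsotopeError(
                f"pool {self.name!r}: concentration must be >= 0"
            )

    @property
    def c13_mM(self) -> float:
        """Amount of 13C in the pool (mmol/L)."""
        if self.concentration is None:
            raise ValueError(f"pool {self.name!r} has no concentration")
        return self.concentration * self.isotope.fraction_13c


@dataclass(frozen=True)
class MixingEstimate:
    """A two-end-member source fraction with its uncertainty.

    ``f_source`` is the clamped-to-[0,1] value used downstream;
    ``f_raw`` preserves the unclamped estimate (measurement noise can push
    it slightly outside the unit interval), and ``clamped`` flags when the
    two differ.
    """

    f_source: float
    f_raw: float
    sd: float | None = None
    n_mc: int = 0
    ci_low: float | None = None
    ci_high: float | None = None
    #: across-replicate spread of per-replicate estimates (distinct from the
    #: propagated measurement-noise sd above)
    sd_replicate: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.f_source <= 1.0):
            raise ValueError("clamped fraction must lie in [0, 1]")
        if self.sd is not None and self.sd < 0.0:
            raise ValueError("sd must be >= 0")

    @property
    def clamped(self) -> bool:
        return self.f_raw != self.f_source

    @classmethod
    def from_raw(cls, raw: float, sd: float | None = None, n_mc: int = 0,
                 ci_low: float | None = None, ci_high: float | None = None,
                 sd_replicate: float | None = None):
        return cls(float(min(1.0, max(0.0, raw))), float(raw), sd, n_mc,
                   ci_low, ci_high, sd_replicate)


@dataclass(frozen=True)
class IncorporationRatio:
    """13C incorporation ratio X for one label (enrichment / label strength)."""

    x: float
    source: str  # "MEOH" or "DIC"
    x_raw: float | None = None

    def __post_init__(self):
        if self.x < 0.0:
            raise ValueError("incorporation ratio must be >= 0 after clamping")

    @classmethod
    def from_raw(cls, raw: float, source: str) -> "IncorporationRatio":
        return cls(float(max(0.0, raw)), source, float(raw))


def two_pool_source_fraction(f_target, f_source, f_background,
                             epsilon: float = ENDMEMBER_EPSILON) -> MixingEstimate:
    """Apportion a measured pool between two isotopic endmembers.

    Solves the linear mixing model
    ``f * F_source + (1 - f) * F_background = F_target`` for f, i.e.

        f = (F_target - F_background) / (F_source - F_background)

    For methane this is f_DIC/CH4 with F_source the harvest-time DIC
    fractional abundance and F_background the methanol fractional abundance
    at the start.
    """
    for name, v in (("f_target", f_target), ("f_source", f_source),
                    ("f_background", f_background)):
        if not (0.0 <= v < 1.0):
            raise InvalidIsotopeError(f"{name} must lie in [0, 1), got {v}")
    span = f_source - f_background
    if abs(span) < epsilon:
        raise DegenerateEndmemberError(
            f"endmembers differ by {span:.2e} < {epsilon:.1e} in F; "
            "source apportionment is undefined"
        )
    return MixingEstimate.from_raw((f_target - f_background) / span)


def incorporation_ratio(f_end, f_start, f_label, source: str = "MEOH") -> IncorporationRatio:
    """13C incorporation ratio X = (F_end - F_start) / F_label.

    F_end and F_start are the lipid (or other biomarker) fractional
    abundances at harvest and time zero; F_label is the fractional
    abundance of the labeled substrate pool.
    """
    if f_label <= 0.0:
        raise DegenerateLabelError(
            f"label strength must be > 0, got {f_label}"
        )
    return IncorporationRatio.from_raw((f_end - f_start) / f_label, source)


def dic_lipid_fraction(x_dic: IncorporationRatio, x_meoh: IncorporationRatio) -> MixingEstimate:
    """Fraction of biomarker carbon from DIC: X_DIC / (X_DIC + X_MeOH).

    Valid when the two single-labeling incubations used identical
    amendments, so the two ratios are commensurable.
    """
    total = x_dic.x + x_meoh.x
    if total <= 0.0:
        raise NoEnrichmentError(
            "both incorporation ratios are zero; sample looks unlabeled"
        )
    return MixingEstimate.from_raw(x_dic.x / total)


def mix_pools(pools: list[CarbonPool], name: str = "mixture") -> CarbonPool:
    """Mass-weighted isotopic mixture of pools; conserves total 13C.

    Models label dilution, e.g. amended 13C-bicarbonate equilibrating into
    the sediment's endogenous DIC pool.
    """
    if not pools:
        raise EmptyPoolError("no pools to mix")
    for p in pools:
        if p.concentration is None:
            raise EmptyPoolError(f"pool {p.name!r} has no concentration")
    total = sum(p.concentration for p in pools)
    if total <= 0.0:
        raise EmptyPoolError("all pool concentrations are zero")
    total_13c = sum(p.c13_mM for p in pools)
    return CarbonPool(name, IsotopeValue.from_fraction(total_13c / total), total)


def infer_ambient_pool(amended_conc, f_label, f_measured, f_ambient) -> float:
    """Size (mM) of an unlabeled ambient pool from the observed label dilution.

    Inverse of :func:`mix_pools` for two pools: an amendment of known
    concentration and label strength mixed into an ambient pool of unknown
    size whose isotopic state is f_ambient.  Requires
    f_ambient < f_measured <= f_label.
    """
    if not (f_ambient < f_measured <= f_label):
        raise InconsistentMeasurementError(
            "expected f_ambient < f_measured <= f_label, got "
            f"{f_ambient}, {f_measured}, {f_label}"
        )
    return amended_conc * (f_label - f_measured) / (f_measured - f_ambient)
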