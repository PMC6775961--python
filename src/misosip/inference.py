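"""Statistical stage: estimators on replicate tables, uncertainty, correlation.

Applies the two-end-member methane apportionment and the single-labeling
lipid incorporation estimators to replicate measurement sets, propagates
measurement uncertainty by a seeded parametric bootstrap, computes the
methanogenesis-rate vs CO2-derived-methane correlation, and classifies
buoyant densities into the heavy/light gradient windows used for RNA-SIP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateCorrelationError, InvalidDensityError, SchemaError
from .isotope import (
    IncorporationRatio,
    IsotopeValue,
    MixingEstimate,
    dic_lipid_fraction,
    incorporation_ratio,
    two_pool_source_fraction,
)
from .tables import ReplicateSet


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation with two-sided p and Fisher-z 95% CI."""

    r: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self):
        if not (self.ci_low <= self.r <= self.ci_high):
            raise ValueError("CI must bracket r")
        if self.n < 3:
            raise ValueError("need at least 3 pairs")


@dataclass(frozen=True)
class GradientWindow:
    """A buoyant-density window (g/mL) of the CsTFA gradient."""

    label: str
    low: float
    high: float

    def __contains__(self, density: float) -> bool:
        return self.low <= density <= self.high


#: Density windows defined from the fully-labeled/unlabeled E. coli RNA
#: standard: heavy = gradient fractions 3-5, light = fraction 11.
HEAVY_WINDOW = GradientWindow("heavy", 1.803, 1.823)
LIGHT_WINDOW = GradientWindow("light", 1.777, 1.780)


def classify_density(density: float) -> str:
    """Label a buoyant density heavy / light / intermediate (inclusive bounds)."""
    if not (1.70 < density < 1.90):
        raise InvalidDensityError(
            f"density {density} g/mL outside plausible gradient range (1.70, 1.90)"
        )
    if density in HEAVY_WINDOW:
        return "heavy"
    if density in LIGHT_WINDOW:
        return "light"
    return "intermediate"


def _mc_means(rng: np.random.Generator, table: ReplicateSet, pool: str,
              n_mc: int) -> np.ndarray:
    """Monte-Carlo draws of a pool's replicate-mean atom fraction.

    When the table reports per-measurement precision (sd column, per mil),
    each replicate's delta value is perturbed by N(0, sd) in delta space --
    the space in which IRMS noise is Gaussian -- and re-converted.
    Otherwise falls back to a parametric bootstrap of the observed
    replicate scatter in F space.
    """
    from .isotope import delta_to_fraction, fraction_to_delta

    values = table.require(pool)
    sd_delta = table.sd_delta(pool)
    if sd_delta is not None:
        deltas = np.array([fraction_to_delta(v) for v in values])
        draws = deltas + rng.normal(0.0, 1.0, size=(n_mc, values.size)) * sd_delta
        draws = np.clip(draws, -1000.0, None)
        return delta_to_fraction(draws).mean(axis=1)
    mean = values.mean()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return rng.normal(mean, sd, size=(n_mc, values.size)).mean(axis=1)


def estimate_methane_sources(table: ReplicateSet, background: IsotopeValue,
                             n_mc: int = 10_000,
                             seed: int | None = None) -> MixingEstimate:
    """f_DIC/CH4 from a replicate set with CH4 and DIC pools.

    The point estimate apportions the replicate-mean methane F between the
    harvest-time DIC pool (source) and the methanol pool at the start
    (background).  With ``n_mc > 0`` seeded Monte-Carlo draws (see
    :func:`_mc_means`) yield a propagated SD and a 2.5-97.5 percentile CI.
    The across-replicate spread of per-replicate estimates is reported
    separately as ``sd_replicate`` -- the two answer different questions
    (measurement precision vs replicate variability).
    """
    f_ch4 = table.require("CH4")
    f_dic = table.require("DIC")
    f_bg = background.fraction_13c
    point = two_pool_source_fraction(f_ch4.mean(), f_dic.mean(), f_bg)
    if f_ch4.size > 1 and f_ch4.size == f_dic.size:
        per_rep = (f_ch4 - f_bg) / (f_dic - f_bg)
        sd_rep = float(per_rep.std(ddof=1))
    else:
        sd_rep = None
    if n_mc <= 0:
        return MixingEstimate.from_raw(point.f_raw, sd=sd_rep, n_mc=0,
                                       sd_replicate=sd_rep)
    rng = np.random.default_rng(seed)
    ch4_means = _mc_means(rng, table, "CH4", n_mc)
    dic_means = _mc_means(rng, table, "DIC", n_mc)
    draws = (ch4_means - f_bg) / (dic_means - f_bg)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return MixingEstimate.from_raw(
        point.f_raw, sd=float(draws.std(ddof=1)), n_mc=int(n_mc),
        ci_low=float(lo), ci_high=float(hi), sd_replicate=sd_rep,
    )


def estimate_lipid_assimilation(
    table_meoh_label: ReplicateSet,
    table_dic_label: ReplicateSet,
    t0: IsotopeValue,
) -> dict[str, tuple[IncorporationRatio, IncorporationRatio, MixingEstimate]]:
    """Per-moiety lipid carbon apportionment from parallel single-label runs.

    The two tables must come from incubations with identical amendments,
    one with labeled methanol and one with labeled DIC (the validity
    condition for comparing the two incorporation ratios).  Label strengths
    are taken from each table's own labeled pool: methanol F from the
    methanol-labeled run, harvest-time DIC F from the DIC-labeled run.
    Returns ``{moiety: (X_MeOH, X_DIC, f_DIC/lipid)}``.
    """
    moieties_a = table_meoh_label.lipid_moieties
    moieties_b = table_dic_label.lipid_moieties
    if moieties_a != moieties_b:
        raise SchemaError(
            f"lipid moiety sets differ between labelings: {moieties_a} vs {moieties_b}"
        )
    if not moieties_a:
        raise SchemaError("no LIPID:<moiety> pools in the tables")
    f_label_meoh = table_meoh_label.mean("MEOH")
    f_label_dic = table_dic_label.mean("DIC")
    out = {}
    for moiety in moieties_a:
        pool = f"LIPID:{moiety}"
        x_me = incorporation_ratio(
            table_meoh_label.mean(pool), t0.fraction_13c, f_label_meoh, "MEOH"
        )
        x_dic = incorporation_ratio(
            table_dic_label.mean(pool), t0.fraction_13c, f_label_dic, "DIC"
        )
        out[moiety] = (x_me, x_dic, dic_lipid_fraction(x_dic, x_me))
    return out


def rate_fraction_correlation(pairs) -> CorrelationReport:
    """Pearson correlation between methanogenesis rate and f_DIC/CH4.

    ``pairs`` is a sequence of (rate in umol CH4 / L / d, f_DIC fraction).
    Two-sided p from the t distribution; 95% CI by Fisher z-transform.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise SchemaError("pairs must be a sequence of (rate, fraction)")
    if not np.all(np.isfinite(arr)):
        raise SchemaError("pairs contain non-finite values")
    n = arr.shape[0]
    if n < 3:
        raise DegenerateCorrelationError(f"need >= 3 pairs, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateCorrelationError("zero variance in one variable")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0 or n <= 3:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationReport(r, float(res.pvalue), float(lo), float(hi), n)
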