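"""Forward simulator of mixotrophic methylotrophic SIP incubations.

Simulates anoxic slurry or pure-culture incubations amended with methanol
and bicarbonate, one substrate 13C-labeled, with full carbon and 13C mass
balance: methanol is consumed by first-order kinetics and disproportionated
(4 CH3OH -> 3 CH4 + CO2) for the methyl-derived share of methane, while a
mixotrophic fraction f_mix of methane carbon is drawn from the DIC pool at
its current fractional abundance; CO2 produced from methanol enters the DIC
pool and dilutes its label by mass balance; biomass markers (lipid, RNA)
accrue with the source split predicted by the bundled pathway-provenance
networks; Gaussian measurement noise on delta-13C is applied only at export.

The simulator exists so every estimator can be validated by parameter
recovery without external data: simulate with a known f_mix, export the
measurement tables, run the estimators, compare.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .errors import InfeasibleConfigError, SchemaError
from .isotope import (
    CarbonPool,
    IsotopeValue,
    delta_to_fraction,
    fraction_to_delta,
    mix_pools,
)
from .inference import estimate_methane_sources
from .provenance import (
    aggregate_macromolecule,
    compound_source_fraction,
    load_pathway,
    propagate,
)
from .tables import ReplicateSet, frame_from_fractions

#: Mean ribonucleotide used for bulk RNA provenance: one ribose and an
#: equimolar purine/pyrimidine mix, doubled to keep integer counts.
RNA_COMPOSITION = [("ribose-5-phosphate", 2), ("purine-base", 1),
                   ("pyrimidine-base", 1)]


@functools.cache
def _biomass_provenance() -> tuple[float, float]:
    """(p_MEOH of the phytanyl lipid chain, p_MEOH of bulk RNA)."""
    lipid = propagate(load_pathway("lipid_biosynthesis"))
    nucl = propagate(load_pathway("nucleotide_biosynthesis"))
    p_lipid = compound_source_fraction(lipid, "phytanyl", "MEOH")
    p_rna = aggregate_macromolecule(nucl, RNA_COMPOSITION, "MEOH")
    return p_lipid, p_rna


@dataclass
class IncubationConfig:
    """Parameters of one simulated SIP incubation.

    Defaults are the sediment-slurry amendment scheme: 1 mM methanol plus
    10 mM amended bicarbonate over a ~2 mM endogenous DIC pool, one
    substrate labeled at 99 atom-% 13C, triplicates, harvest when methanol
    is effectively exhausted.
    """

    name: str = "incubation"
    meoh_mM: float = 1.0
    dic_amended_mM: float = 10.0
    dic_ambient_mM: float = 2.0
    label: str = "DIC"              # MEOH | DIC | BOTH | NONE
    label_fraction_13c: float = 0.99
    natural_delta: float = -30.0    # delta-13C of unlabeled pools, per mil
    f_mix: float = 0.103            # fraction of CH4 carbon drawn from DIC
    f_mix_mode: str = "constant"    # constant | rate_dependent
    f_mix_max: float = 0.12         # cap of the rate-dependent mode
    rate_scale_umol: float = 1000.0  # e-folding rate (umol CH4/L/d) of f_mix(rate)
    k_per_day: float | None = None  # first-order methanol consumption; default
                                    # set so 99% is consumed by duration_days
    assimilation_fraction: float = 0.05  # consumed methyl carbon to biosynthesis
    lipid_share: float = 0.3        # split of tracked biomass C: lipid vs RNA
    lipid_background_mM: float = 0.02   # pre-existing lipid C at natural abundance
    rna_background_mM: float = 0.05     # pre-existing RNA C at natural abundance
    noise_sd_delta: float = 0.5     # GC-IRMS noise on exported delta, per mil
    n_replicates: int = 3
    seed: int = 0
    duration_days: float = 43.0
    sampling_days: tuple[float, ...] | None = None
    dt_days: float = 0.02
    infinite_dic: bool = False      # idealized constant-F_DIC reservoir

    def __post_init__(self):
        if self.label not in {"MEOH", "DIC", "BOTH", "NONE"}:
            raise SchemaError(f"label must be MEOH|DIC|BOTH|NONE, got {self.label!r}")
        if not (0.0 <= self.f_mix <= 1.0) or not (0.0 <= self.f_mix_max < 1.0):
            raise SchemaError("f_mix and f_mix_max must lie in [0, 1]")
        if self.f_mix_mode not in {"constant", "rate_dependent"}:
            raise SchemaError(f"unknown f_mix_mode {self.f_mix_mode!r}")
        for key in ("meoh_mM", "dic_amended_mM", "dic_ambient_mM",
                    "noise_sd_delta", "lipid_background_mM", "rna_background_mM"):
            if getattr(self, key) < 0:
                raise SchemaError(f"{key} must be >= 0")
        if not (0.0 <= self.assimilation_fraction < 1.0):
            raise SchemaError("assimilation_fraction must lie in [0, 1)")
        if self.n_replicates < 1:
            raise SchemaError("n_replicates must be >= 1")
        if self.duration_days <= 0 or self.dt_days <= 0:
            raise SchemaError("duration_days and dt_days must be > 0")

    @property
    def k(self) -> float:
        if self.k_per_day is not None:
            return self.k_per_day
        return math.log(100.0) / self.duration_days

    @property
    def f_natural(self) -> float:
        return delta_to_fraction(self.natural_delta)

    @property
    def f_meoh(self) -> float:
        return self.label_fraction_13c if self.label in {"MEOH", "BOTH"} \
            else self.f_natural

    @property
    def f_dic_amended(self) -> float:
        return self.label_fraction_13c if self.label in {"DIC", "BOTH"} \
            else self.f_natural

    def initial_dic(self) -> CarbonPool:
        """Amended bicarbonate diluted into the endogenous DIC pool."""
        pools = [CarbonPool("amended",
                            IsotopeValue.from_fraction(self.f_dic_amended),
                            self.dic_amended_mM)]
        if self.dic_ambient_mM > 0:
            pools.append(CarbonPool("ambient",
                                    IsotopeValue.from_fraction(self.f_natural),
                                    self.dic_ambient_mM))
        return mix_pools(pools, "DIC")

    def sampling(self) -> tuple[float, ...]:
        if self.sampling_days is not None:
            return tuple(self.sampling_days)
        step = max(1.0, round(self.duration_days / 6))
        days = list(np.arange(0.0, self.duration_days, step))
        if days[-1] != self.duration_days:
            days.append(self.duration_days)
        return tuple(days)


@dataclass
class IncubationRun:
    """Time series of pool amounts (mM carbon) and atom fractions.

    ``series[pool]`` is a (times, amounts, fractions) triple of arrays;
    ``summary`` is the harvest row: DIC atom fraction, true cumulative
    f_DIC/CH4, and incubation time.
    """

    config: IncubationConfig
    times: np.ndarray
    series: dict[str, tuple[np.ndarray, np.ndarray]]
    summary: dict

    def at(self, pool: str, day: float) -> tuple[float, float]:
        """(amount_mM, fraction_13c) of a pool at a sampled day."""
        idx = int(np.argmin(np.abs(self.times - day)))
        amount, frac = self.series[pool]
        return float(amount[idx]), float(frac[idx])

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Total carbon and total 13C over time (closed pools only)."""
        c = np.zeros_like(self.times)
        c13 = np.zeros_like(self.times)
        for pool, (amount, frac) in self.series.items():
            c += amount
            c13 += amount * frac
        return c, c13


def _f_mix_at(config: IncubationConfig, rate_umol: float) -> float:
    if config.f_mix_mode == "constant":
        return config.f_mix
    return config.f_mix_max * math.exp(-rate_umol / config.rate_scale_umol)


def simulate(config: IncubationConfig) -> IncubationRun:
    """Forward-simulate one incubation (noise-free; noise is an export step).

    Per time step the consumed methanol splits into an assimilated share
    (biosynthesis, with DIC co-assimilation per pathway provenance) and a
    catabolized share (disproportionation, with a mixotrophic DIC-derived
    share of methane).  Carbon and 13C are conserved exactly unless
    ``infinite_dic`` clamps the DIC reservoir.
    """
    p_lipid, p_rna = _biomass_provenance()
    f_me = config.f_meoh
    dic0 = config.initial_dic()

    meoh = config.meoh_mM
    dic, f_dic = dic0.concentration, dic0.isotope.fraction_13c
    dic13 = dic * f_dic
    ch4 = ch4_13 = 0.0
    lipid = config.lipid_background_mM
    lipid13 = lipid * config.f_natural
    rna = config.rna_background_mM
    rna13 = rna * config.f_natural
    ch4_from_dic = 0.0

    n_steps = int(round(config.duration_days / config.dt_days))
    sample_days = config.sampling()
    times, recs = [], {p: ([], []) for p in
                       ("MEOH", "DIC", "CH4", "LIPID", "RNA")}

    def record(t):
        times.append(t)
        for pool, amt, f in (
            ("MEOH", meoh, f_me),
            ("DIC", dic, dic13 / dic if dic > 0 else f_dic),
            ("CH4", ch4, ch4_13 / ch4 if ch4 > 0 else f_me),
            ("LIPID", lipid, lipid13 / lipid if lipid > 0 else config.f_natural),
            ("RNA", rna, rna13 / rna if rna > 0 else config.f_natural),
        ):
            recs[pool][0].append(amt)
            recs[pool][1].append(f)

    next_sample = 0
    decay = 1.0 - math.exp(-config.k * config.dt_days)
    for step in range(n_steps + 1):
        t = step * config.dt_days
        while (next_sample < len(sample_days)
               and sample_days[next_sample] <= t + 1e-9):
            record(sample_days[next_sample])
            next_sample += 1
        if step == n_steps:
            break

        consumed = meoh * decay
        meoh -= consumed
        assim_me = config.assimilation_fraction * consumed
        catab = consumed - assim_me

        # disproportionation of the catabolized methyl carbon
        ch4_me = 0.75 * catab
        co2_me = 0.25 * catab
        rate_umol = ch4_me / config.dt_days * 1000.0
        f = _f_mix_at(config, rate_umol)
        if f >= 1.0:
            raise InfeasibleConfigError(
                f"f_mix = 1 leaves no methyl-derived methane (step {step})"
            )
        ch4_dic = ch4_me * f / (1.0 - f)

        # biomass: methyl-derived carbon enters at the pathway MEOH share,
        # pulling the complementary DIC-derived carbon from the DIC pool
        b_me_lip = assim_me * config.lipid_share
        b_me_rna = assim_me - b_me_lip
        lip_new = b_me_lip / p_lipid
        rna_new = b_me_rna / p_rna
        dic_lip = lip_new - b_me_lip
        dic_rna = rna_new - b_me_rna

        f_dic_now = dic13 / dic if dic > 0 else 0.0
        dic_out = ch4_dic + dic_lip + dic_rna
        if dic + co2_me - dic_out < 0:
            raise InfeasibleConfigError(
                f"DIC pool driven negative at day {t + config.dt_days:.2f} "
                f"(step {step})"
            )

        ch4 += ch4_me + ch4_dic
        ch4_13 += ch4_me * f_me + ch4_dic * f_dic_now
        ch4_from_dic += ch4_dic
        lipid += lip_new
        lipid13 += b_me_lip * f_me + dic_lip * f_dic_now
        rna += rna_new
        rna13 += b_me_rna * f_me + dic_rna * f_dic_now
        if config.infinite_dic:
            # idealized reservoir: composition and size held fixed
            pass
        else:
            dic += co2_me - dic_out
            dic13 += co2_me * f_me - dic_out * f_dic_now

    summary = {
        "f_dic": dic13 / dic,
        "f_ch4": ch4_13 / ch4 if ch4 > 0 else f_me,
        "f_dic_ch4_true": ch4_from_dic / ch4 if ch4 > 0 else 0.0,
        "incubation_days": config.duration_days,
        "f_lipid": lipid13 / lipid,
        "f_rna": rna13 / rna,
        "p_meoh_lipid": p_lipid,
        "p_meoh_rna": p_rna,
    }
    series = {p: (np.asarray(a), np.asarray(f)) for p, (a, f) in recs.items()}
    return IncubationRun(config, np.asarray(times), series, summary)


def simulate_replicates(config: IncubationConfig) -> tuple[list[IncubationRun], pd.DataFrame]:
    """Simulate replicate incubations and export a measurement table.

    Replicates share the deterministic trajectory; replicate-specific
    Gaussian noise (sd ``noise_sd_delta`` per mil, applied in delta space)
    is added at export via per-replicate substreams of the seed.  The
    exported frame is valid input to the inference stage.
    """
    run = simulate(config)
    runs = [run] * config.n_replicates
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    rows = []
    moiety_pool = {"LIPID": "LIPID:phytanyl", "RNA": "RNA"}
    for rep, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        for day in config.sampling():
            for pool in ("MEOH", "DIC", "CH4", "LIPID", "RNA"):
                amount, frac = run.at(pool, day)
                if pool == "CH4" and amount == 0.0:
                    continue
                delta = fraction_to_delta(frac)
                if config.noise_sd_delta > 0:
                    delta += rng.normal(0.0, config.noise_sd_delta)
                rows.append({
                    "sample_id": config.name,
                    "pool": moiety_pool.get(pool, pool),
                    "replicate": rep,
                    "time_days": day,
                    "fraction_13c": delta_to_fraction(delta),
                    "sd": config.noise_sd_delta,
                })
    frame = frame_from_fractions(config.name, rows)
    return runs, frame


def rna_density(f_rna_13c: float, f_natural: float | None = None,
                bd_unlabeled: float = 1.7785,
                k_shift: float = 0.035) -> float:
    """Buoyant density (g/mL) of RNA from its 13C fractional abundance.

    Linear shift model anchored at the light-window midpoint for unlabeled
    RNA; the default slope puts fully labeled RNA inside the heavy window.
    RNA-SIP needs roughly >10% 13C for separation, i.e. a shift of a few
    thousandths of a g/mL.
    """
    from .errors import InvalidIsotopeError
    if not (0.0 <= f_rna_13c < 1.0):
        raise InvalidIsotopeError(f"RNA fraction-13C must lie in [0,1), got {f_rna_13c}")
    if f_natural is None:
        f_natural = delta_to_fraction(-30.0)
    return bd_unlabeled + k_shift * (f_rna_13c - f_natural)


@dataclass(frozen=True)
class RecoveryReport:
    """Closed-loop check: simulate with known f_mix, re-estimate, compare."""

    true_f_mix: float
    estimate: float
    bias: float
    sd: float | None
    n_mc: int


def recovery_experiment(config: IncubationConfig, n_mc: int = 10_000,
                        seed: int | None = None) -> RecoveryReport:
    """Simulate replicates, export tables, run the methane estimator.

    Requires a design that labels DIC (the estimable design: labeling only
    methanol cannot resolve the DIC-derived share of methane).  The truth
    is the simulator's cumulative fraction of methane carbon drawn from the
    DIC pool.
    """
    if config.label not in {"DIC", "BOTH"}:
        raise SchemaError(
            "recovery requires a 13C-DIC labeled design; "
            f"config labels {config.label!r}"
        )
    runs, frame = simulate_replicates(config)
    table = ReplicateSet.from_frame(frame, time_days=config.duration_days)
    background = IsotopeValue.from_fraction(config.f_meoh)
    est = estimate_methane_sources(table, background, n_mc=n_mc, seed=seed)
    truth = runs[0].summary["f_dic_ch4_true"]
    return RecoveryReport(truth, est.f_raw, est.f_raw - truth, est.sd, est.n_mc)


# ---------------------------------------------------------------------------
# Presets mirroring the study's incubation setups
# ---------------------------------------------------------------------------

def preset(name: str, seed: int = 0) -> IncubationConfig:
    """Named incubation presets.

    ``sediment-SRZ`` / ``sediment-MZ``: 1 mM methanol + 10 mM bicarbonate
    slurries from the sulfate-reduction and methanogenic zones (13C-DIC
    labeling, harvest at 43 / 19 days).  ``pure-culture``: 30 mM methanol +
    50 mM bicarbonate, 5% label, defined medium.  ``autoclaved-slurry``:
    20 mM methanol with ~10% labeled DIC and rate-dependent mixotrophy.
    """
    presets = {
        "sediment-SRZ": dict(
            name="sediment-SRZ", meoh_mM=1.0, dic_amended_mM=10.0,
            dic_ambient_mM=1.9, label="DIC", f_mix=0.103,
            duration_days=43.0,
        ),
        "sediment-MZ": dict(
            name="sediment-MZ", meoh_mM=1.0, dic_amended_mM=10.0,
            dic_ambient_mM=4.3, label="DIC", f_mix=0.034,
            duration_days=19.0,
        ),
        "pure-culture": dict(
            name="pure-culture", meoh_mM=30.0, dic_amended_mM=50.0,
            dic_ambient_mM=0.0, label="DIC", label_fraction_13c=0.05,
            f_mix=0.025, duration_days=10.0,
            lipid_background_mM=0.01, rna_background_mM=0.02,
        ),
        "autoclaved-slurry": dict(
            name="autoclaved-slurry", meoh_mM=20.0, dic_amended_mM=1.0,
            dic_ambient_mM=9.0, label="DIC", f_mix_mode="rate_dependent",
            duration_days=10.0,
        ),
    }
    if name not in presets:
        raise SchemaError(f"unknown preset {name!r}; have {sorted(presets)}")
    return IncubationConfig(seed=seed, **presets[name])
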