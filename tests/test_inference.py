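"""Replicate-table estimators, uncertainty propagation, correlation, density."""

import numpy as np
import pytest

from misosip.errors import (
    DegenerateCorrelationError,
    InvalidDensityError,
    NoEnrichmentError,
    SchemaError,
)
from misosip.inference import (
    classify_density,
    estimate_lipid_assimilation,
    estimate_methane_sources,
    rate_fraction_correlation,
)
from misosip.isotope import IsotopeValue
from misosip.simulator import IncubationConfig, preset, simulate_replicates
from misosip.tables import ReplicateSet

NAT = IsotopeValue.from_delta(-30.0)


def _set(pools, sd=None, t=10.0):
    pools = {k: np.asarray(v, dtype=float) for k, v in pools.items()}
    return ReplicateSet("t", pools, t, sd)


class TestMethaneSources:
    def test_noiseless_forward_model_recovered_exactly(self):
        f_src, f_bg, f = 0.7, NAT.fraction_13c, 0.25
        f_target = f * f_src + (1 - f) * f_bg
        rs = _set({"CH4": [f_target] * 3, "DIC": [f_src] * 3})
        est = estimate_methane_sources(rs, NAT, n_mc=0)
        assert est.f_source == pytest.approx(f, abs=1e-14)

    def test_srz_like_table(self, srz_like_frame):
        rs = ReplicateSet.from_frame(srz_like_frame)
        est = estimate_methane_sources(
            rs, IsotopeValue.from_fraction(0.0110564), n_mc=0)
        assert est.f_source == pytest.approx(0.103, abs=2e-3)

    def test_mc_agrees_with_point_estimate(self, srz_like_frame):
        rs = ReplicateSet.from_frame(srz_like_frame)
        a = estimate_methane_sources(rs, NAT, n_mc=0)
        b = estimate_methane_sources(rs, NAT, n_mc=10_000, seed=1)
        assert a.f_source == b.f_source
        assert b.sd is not None and b.sd > 0
        assert b.ci_low < b.f_source < b.ci_high

    def test_mc_reproducible_under_seed(self, srz_like_frame):
        rs = ReplicateSet.from_frame(srz_like_frame)
        a = estimate_methane_sources(rs, NAT, n_mc=2000, seed=7)
        b = estimate_methane_sources(rs, NAT, n_mc=2000, seed=7)
        assert a.sd == b.sd and a.ci_low == b.ci_low

    def test_mc_sd_vanishes_with_measurement_precision(self):
        rs = _set({"CH4": [0.096] * 3, "DIC": [0.836] * 3},
                  sd={"CH4": np.full(3, 1e-6), "DIC": np.full(3, 1e-6)})
        est = estimate_methane_sources(rs, NAT, n_mc=4000, seed=2)
        assert est.sd < 1e-7
        assert abs(est.f_raw - est.f_source) < 1e-12

    def test_missing_pool(self):
        with pytest.raises(SchemaError):
            estimate_methane_sources(_set({"CH4": [0.1]}), NAT, n_mc=0)


class TestLipidAssimilation:
    def _tables(self, f_lip_me, f_lip_dic, f_label_me=0.99, f_label_dic=0.99):
        a = _set({"MEOH": [f_label_me] * 3, "DIC": [NAT.fraction_13c] * 3,
                  "LIPID:phytanyl": [f_lip_me] * 3})
        b = _set({"MEOH": [NAT.fraction_13c] * 3, "DIC": [f_label_dic] * 3,
                  "LIPID:phytanyl": [f_lip_dic] * 3})
        return a, b

    def test_symmetric_enrichment_gives_half(self):
        t0 = NAT
        a, b = self._tables(t0.fraction_13c + 0.02, t0.fraction_13c + 0.02)
        res = estimate_lipid_assimilation(a, b, t0)
        _, _, f = res["phytanyl"]
        assert f.f_source == pytest.approx(0.5, rel=1e-9)

    def test_simulated_phytanyl_provenance_recovered(self):
        # identical amendments, one label each; lipid truly 60% methanol
        cfgs = {}
        for label in ("MEOH", "DIC"):
            cfgs[label] = IncubationConfig(
                name=f"pc-{label}", meoh_mM=30.0, dic_amended_mM=50.0,
                dic_ambient_mM=0.0, label=label, label_fraction_13c=0.05,
                f_mix=0.0, duration_days=10.0, noise_sd_delta=0.0,
                lipid_background_mM=0.0, rna_background_mM=0.0,
                infinite_dic=True, dt_days=0.05, n_replicates=3)
        tables = {}
        for label, cfg in cfgs.items():
            _, frame = simulate_replicates(cfg)
            tables[label] = ReplicateSet.from_frame(frame, time_days=10.0)
        res = estimate_lipid_assimilation(tables["MEOH"], tables["DIC"], NAT)
        _, _, f = res["phytanyl"]
        assert f.f_source == pytest.approx(0.40, abs=0.02)

    def test_zero_enrichment(self):
        a, b = self._tables(NAT.fraction_13c, NAT.fraction_13c)
        with pytest.raises(NoEnrichmentError):
            estimate_lipid_assimilation(a, b, NAT)

    def test_mismatched_moieties(self):
        a = _set({"MEOH": [0.99], "LIPID:phytanyl": [0.02]})
        b = _set({"DIC": [0.99], "LIPID:biphytane": [0.02]})
        with pytest.raises(SchemaError, match="moiety"):
            estimate_lipid_assimilation(a, b, NAT)


class TestCorrelation:
    def test_perfect_anticorrelation(self):
        pairs = [(r, 0.2 - 0.01 * r) for r in range(1, 8)]
        rep = rate_fraction_correlation(pairs)
        assert rep.r == pytest.approx(-1.0)
        assert rep.p_value < 1e-6

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=12)
        y = -x + rng.normal(scale=0.2, size=12)
        base = rate_fraction_correlation(np.column_stack([x, y]))
        scaled = rate_fraction_correlation(np.column_stack([3 * x + 7, 0.5 * y - 1]))
        assert scaled.r == pytest.approx(base.r, rel=1e-12)
        assert scaled.ci_low == pytest.approx(base.ci_low, rel=1e-9)

    def test_ci_brackets_r(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=20)
        y = -0.7 * x + rng.normal(size=20)
        rep = rate_fraction_correlation(np.column_stack([x, y]))
        assert rep.ci_low <= rep.r <= rep.ci_high
        assert -1.0 <= rep.ci_low and rep.ci_high <= 1.0

    def test_constant_fraction_degenerate(self):
        with pytest.raises(DegenerateCorrelationError):
            rate_fraction_correlation([(1, 0.1), (2, 0.1), (3, 0.1)])

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateCorrelationError):
            rate_fraction_correlation([(1, 0.1), (2, 0.2)])

    def test_rate_dependent_simulator_sweep_is_negative(self):
        # six treatments differing in methanol-consumption rate, triplicates;
        # the rate-dependent mixotrophy mode must yield a clearly negative
        # rate vs f_DIC/CH4 relationship
        nat = NAT
        pairs = []
        for i, k in enumerate(np.linspace(0.05, 0.6, 6)):
            cfg = preset("autoclaved-slurry", seed=100 + i)
            cfg.k_per_day = float(k)
            cfg.sampling_days = (0.0, 2.0, 3.0, cfg.duration_days)
            cfg.dt_days = 0.05
            runs, frame = simulate_replicates(cfg)
            rs = ReplicateSet.from_frame(frame, time_days=3.0)
            f_bg = nat.fraction_13c
            a2, _ = runs[0].at("CH4", 2.0)
            a3, _ = runs[0].at("CH4", 3.0)
            rate = (a3 - a2) * 1000.0  # umol CH4 / L / d
            for f_ch4, f_dic in zip(rs.pools["CH4"], rs.pools["DIC"]):
                pairs.append((rate, (f_ch4 - f_bg) / (f_dic - f_bg)))
        rep = rate_fraction_correlation(pairs)
        assert rep.r < -0.6
        assert rep.p_value < 0.05


class TestDensityWindows:
    @pytest.mark.parametrize("density, label", [
        (1.808, "heavy"),      # the small RNA peak seen with methanol label
        (1.778, "light"),
        (1.790, "intermediate"),
        (1.803, "heavy"),      # boundaries inclusive
        (1.823, "heavy"),
        (1.777, "light"),
        (1.780, "light"),
    ])
    def test_classification(self, density, label):
        assert classify_density(density) == label

    @pytest.mark.parametrize("density", [1.60, 1.95])
    def test_out_of_range(self, density):
        with pytest.raises(InvalidDensityError):
            classify_density(density)
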