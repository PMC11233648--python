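import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import spikenet as sn
from spikenet.synth import (
    CouplingConfig,
    GroundTruthCouplings,
    ModulationConfig,
    PopulationConfig,
    draw_couplings,
    evaluate_recovery,
    make_ground_truth,
    simulate_session,
)


class TestGroundTruth:
    def test_zero_couplings_keeps_population(self):
        truth = make_ground_truth(
            PopulationConfig(areas={"A": 7}), CouplingConfig(n_couplings=0), seed=0
        )
        assert len(truth.couplings) == 0
        assert len(truth.units) == 7

    def test_deterministic_for_fixed_seed(self):
        a = make_ground_truth(seed=5)
        b = make_ground_truth(seed=5)
        pd.testing.assert_frame_equal(a.couplings, b.couplings)
        pd.testing.assert_frame_equal(a.units, b.units)

    def test_requested_couplings_are_distinct_ordered_pairs(self):
        truth = make_ground_truth(
            PopulationConfig(areas={"A": 20}),
            CouplingConfig(n_couplings=10),
            seed=2,
        )
        pairs = list(zip(truth.couplings["source"], truth.couplings["target"]))
        assert len(pairs) == 10
        assert len(set(pairs)) == 10
        assert all(s != t for s, t in pairs)
        assert truth.couplings["lag"].between(1, 12).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            make_ground_truth(PopulationConfig(areas={}), CouplingConfig(0))
        with pytest.raises(ValueError):
            make_ground_truth(
                PopulationConfig(areas={"A": 5}),
                CouplingConfig(n_couplings=2, lag_range=(1, 30)),
            )
        with pytest.raises(ValueError):
            make_ground_truth(
                PopulationConfig(areas={"A": 5}, rate_hz=-1.0), CouplingConfig(0)
            )
        with pytest.raises(ValueError):
            make_ground_truth(
                PopulationConfig(areas={"A": 3}), CouplingConfig(n_couplings=10)
            )

    def test_area_labels_and_positions(self):
        truth = make_ground_truth(
            PopulationConfig(areas={"V1": 3, "LM": 2}), CouplingConfig(0), seed=1
        )
        assert list(truth.units["area"]) == ["V1"] * 3 + ["LM"] * 2
        assert {"x", "y", "z"}.issubset(truth.units.columns)


class TestSimulateSession:
    def test_deterministic(self):
        truth = make_ground_truth(seed=3)
        a = simulate_session(truth, n_trials=5, n_bins=300, seed=9)
        b = simulate_session(truth, n_trials=5, n_bins=300, seed=9)
        assert np.array_equal(a.spikes, b.spikes)

    def test_silent_source_changes_nothing(self):
        units = pd.DataFrame(
            {"area": ["A", "A"], "rate_hz": [1e-9, 20.0],
             "x": [0, 0], "y": [0, 0], "z": [0, 0]},
            index=pd.Index([0, 1], name="unit"),
        )
        c = pd.DataFrame(
            [{"source": 0, "target": 1, "sign": 1, "lag": 3, "duration": 1,
              "transmission": 1.0}]
        )
        truth = GroundTruthCouplings(couplings=c, units=units)
        with_c = simulate_session(truth, n_trials=4, n_bins=400, seed=7)
        truth_none = GroundTruthCouplings(
            couplings=c.iloc[:0], units=units
        )
        without = simulate_session(truth_none, n_trials=4, n_bins=400, seed=7)
        assert np.array_equal(with_c.spikes[:, :, 1], without.spikes[:, :, 1])

    def test_positive_coupling_concentrates_coincidences_at_lag(self):
        units = pd.DataFrame(
            {"area": ["A", "A"], "rate_hz": [20.0, 20.0],
             "x": [0, 0], "y": [0, 0], "z": [0, 0]},
            index=pd.Index([0, 1], name="unit"),
        )
        c = pd.DataFrame(
            [{"source": 0, "target": 1, "sign": 1, "lag": 2, "duration": 1,
              "transmission": 0.5}]
        )
        truth = GroundTruthCouplings(couplings=c, units=units)
        data = simulate_session(truth, n_trials=100, n_bins=2000, seed=11)
        a, b = data.spikes[:, :, 0], data.spikes[:, :, 1]
        tallies = [
            int(np.sum(a[:, : 2000 - tau] * b[:, tau:])) for tau in range(13)
        ]
        assert np.argmax(tallies) == 2
        assert tallies[2] > max(t for i, t in enumerate(tallies) if i != 2)

    def test_negative_coupling_depletes_window(self):
        units = pd.DataFrame(
            {"area": ["A", "A"], "rate_hz": [30.0, 30.0],
             "x": [0, 0], "y": [0, 0], "z": [0, 0]},
            index=pd.Index([0, 1], name="unit"),
        )
        c = pd.DataFrame(
            [{"source": 0, "target": 1, "sign": -1, "lag": 2, "duration": 2,
              "transmission": 1.0}]
        )
        truth = GroundTruthCouplings(couplings=c, units=units)
        data = simulate_session(truth, n_trials=100, n_bins=2000, seed=13)
        a, b = data.spikes[:, :, 0], data.spikes[:, :, 1]
        tallies = [
            int(np.sum(a[:, : 2000 - tau] * b[:, tau:])) for tau in range(13)
        ]
        assert tallies[2] == 0 and tallies[3] == 0
        assert min(t for i, t in enumerate(tallies) if i not in (2, 3)) > 0

    def test_rate_fidelity_within_five_percent(self):
        truth = make_ground_truth(
            PopulationConfig(areas={"A": 5}, rate_hz=20.0), CouplingConfig(0),
            seed=4,
        )
        data = simulate_session(truth, n_trials=100, n_bins=1000, seed=5)
        rates = data.rates_hz()
        assert np.all(np.abs(rates - 20.0) / 20.0 < 0.05)

    def test_rate_fidelity_with_modulation(self):
        # the sinusoidal envelope is mean-one, so rates are unchanged
        truth = make_ground_truth(
            PopulationConfig(areas={"A": 5}, rate_hz=20.0), CouplingConfig(0),
            modulation=ModulationConfig(), seed=4,
        )
        data = simulate_session(truth, n_trials=100, n_bins=1000, seed=5)
        assert np.all(np.abs(data.rates_hz() - 20.0) / 20.0 < 0.05)

    def test_rate_too_high_for_bin_width_rejected(self):
        truth = make_ground_truth(
            PopulationConfig(areas={"A": 2}, rate_hz=900.0),
            CouplingConfig(0),
            modulation=ModulationConfig(amplitude=0.5),
            seed=0,
        )
        with pytest.raises(ValueError, match="probability"):
            simulate_session(truth, n_trials=2, n_bins=100, seed=0)

    def test_uncoupled_pairs_pass_independence_chi_square(self):
        """Coincidence counts across lags match the independence expectation
        for >= 95% of (seed, pair) combinations at the 0.001 level."""
        ok = total = 0
        for seed in range(50):
            truth = make_ground_truth(
                PopulationConfig(areas={"A": 4}, rate_hz=25.0),
                CouplingConfig(0), seed=seed,
            )
            data = simulate_session(truth, n_trials=20, n_bins=500, seed=seed)
            s = data.spikes
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    obs = np.array(
                        [
                            np.sum(s[:, : 500 - tau, i] * s[:, tau:, j])
                            for tau in range(13)
                        ],
                        dtype=float,
                    )
                    lam_i = s[:, :, i].mean()
                    lam_j = s[:, :, j].mean()
                    exp = lam_i * lam_j * 20 * (500 - np.arange(13))
                    if exp.min() < 5:
                        continue
                    stat = np.sum((obs - exp) ** 2 / exp)
                    p = sps.chi2.sf(stat, df=12)
                    ok += p > 0.001
                    total += 1
        assert total > 100
        assert ok / total >= 0.95


class TestRecovery:
    def _truth(self):
        truth = make_ground_truth(
            PopulationConfig(areas={"A": 10}),
            CouplingConfig(n_couplings=10, frac_positive=1.0),
            seed=6,
        )
        return truth

    def _net_from(self, rows):
        g = nx.DiGraph()
        g.add_nodes_from(range(10))
        for s, t, sign, lag in rows:
            g.add_edge(s, t, sign=sign, weight=float(sign), lag=lag, duration=1,
                       significance=5.0)
        return g

    def test_exact_recovery(self):
        truth = self._truth()
        rows = [
            (r.source, r.target, r.sign, r.lag)
            for r in truth.couplings.itertuples()
        ]
        rep = evaluate_recovery(truth, self._net_from(rows))
        assert rep.sensitivity == 1.0 and rep.precision == 1.0
        assert rep.sign_accuracy == 1.0

    def test_empty_detection(self):
        truth = self._truth()
        rep = evaluate_recovery(truth, self._net_from([]))
        assert rep.sensitivity == 0.0
        assert rep.precision is None and rep.sign_accuracy is None

    def test_partial_recovery_arithmetic(self):
        truth = self._truth()
        rows = [
            (r.source, r.target, r.sign, r.lag)
            for r in truth.couplings.head(8).itertuples()
        ]
        # two spurious detections on unplanted pairs
        planted = set(zip(truth.couplings["source"], truth.couplings["target"]))
        extra = [(u, v) for u in range(10) for v in range(10)
                 if u != v and (u, v) not in planted][:2]
        rows += [(u, v, 1, 5) for u, v in extra]
        rep = evaluate_recovery(truth, self._net_from(rows))
        assert rep.sensitivity == pytest.approx(0.8)
        assert rep.precision == pytest.approx(0.8)

    def test_wrong_sign_not_a_match(self):
        truth = self._truth()
        r = truth.couplings.iloc[0]
        rep = evaluate_recovery(
            truth, self._net_from([(r["source"], r["target"], -1, r["lag"])])
        )
        assert rep.n_true == 0 and rep.sign_accuracy == 0.0

    def test_unknown_nodes_rejected(self):
        truth = self._truth()
        g = nx.DiGraph()
        g.add_node(99)
        with pytest.raises(ValueError):
            evaluate_recovery(truth, g)


class TestDetectionMonotonicity:
    def test_sensitivity_nondecreasing_in_transmission(self):
        sens = []
        for p in (0.05, 0.4, 1.0):
            truth = make_ground_truth(
                PopulationConfig(areas={"A": 8}, rate_hz=20.0),
                CouplingConfig(
                    n_couplings=6, frac_positive=1.0, lag_range=(2, 4),
                    duration_range=(1, 2), transmission=p,
                ),
                seed=8,
            )
            data = simulate_session(truth, n_trials=50, n_bins=1000, seed=9)
            net = sn.build_network(data)
            sens.append(evaluate_recovery(truth, net).sensitivity)
        assert sens[0] <= sens[1] <= sens[2]


class TestDrawCouplings:
    def test_respects_unit_ids(self):
        units = make_ground_truth(seed=0).units.iloc[10:30]
        c = draw_couplings(units, CouplingConfig(n_couplings=8), 3)
        assert set(c["source"]).issubset(set(units.index))
        assert set(c["target"]).issubset(set(units.index))
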