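import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pifomics import (
    activation_z,
    bh_adjust,
    classify_regulator,
    hypergeom_enrichment,
    overlap_p,
    regulator_predictions,
)


def _hyper_upper_tail(N, K, n, k):
    """Oracle: exact upper-tail hypergeometric via binomial coefficients."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def _net(edges):
    return pd.DataFrame(edges, columns=["regulator", "target", "direction"])


class TestHypergeomEnrichment:
    def test_extreme_overlap_closed_form(self):
        bg = {f"g{i}" for i in range(20)}
        target = {f"g{i}" for i in range(5)}
        res = hypergeom_enrichment(target, bg, {"T": set(target)})
        assert res.loc["T", "p_hyper"] == pytest.approx(1 / math.comb(20, 5),
                                                        rel=1e-9)

    def test_zero_overlap_gives_one(self):
        bg = {f"g{i}" for i in range(10)}
        res = hypergeom_enrichment({"g0", "g1"}, bg, {"T": {"g8", "g9"}})
        assert res.loc["T", "p_hyper"] == pytest.approx(1.0)

    def test_counted_draw_example(self):
        bg = {f"g{i}" for i in range(10)}
        target = {"g0", "g1", "g2", "g3"}
        term = {"g0", "g1", "g2", "g3", "g4"}
        res = hypergeom_enrichment(target, bg, {"T": term})
        assert res.loc["T", "p_hyper"] == pytest.approx(5 / 210, rel=1e-9)

    def test_matches_enumeration_oracle(self):
        for N in range(2, 11):
            bg = {f"g{i}" for i in range(N)}
            for n, K in itertools.product(range(1, N + 1), repeat=2):
                target = {f"g{i}" for i in range(n)}
                term = {f"g{i}" for i in range(N - K, N)}
                res = hypergeom_enrichment(target, bg, {"T": term})
                k = len(target & term)
                assert res.loc["T", "p_hyper"] == pytest.approx(
                    _hyper_upper_tail(N, K, n, k), rel=1e-9
                )

    def test_term_outside_background_skipped(self):
        bg = {"a", "b", "c"}
        res = hypergeom_enrichment({"a"}, bg, {"T": {"x", "y"}})
        assert len(res) == 0

    def test_target_outside_background_errors(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_enrichment({"z"}, {"a", "b"}, {})


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestActivationZ:
    def test_fifteen_inhibition_consistent(self):
        net = _net([("RICTOR", f"T{i}", 1) for i in range(15)])
        observed = pd.Series(-1, index=[f"T{i}" for i in range(15)])
        z = activation_z(net, observed).loc["RICTOR"]
        assert z["z"] == pytest.approx(-math.sqrt(15))
        assert round(z["z"], 3) == -3.873
        assert z["N_informative"] == 15

    def test_four_inhibition_consistent(self):
        net = _net([("MAP4K4", f"T{i}", 1) for i in range(4)])
        observed = pd.Series(-1, index=[f"T{i}" for i in range(4)])
        assert activation_z(net, observed).loc["MAP4K4", "z"] == pytest.approx(
            -2.0
        )

    def test_mixed_signs_arithmetic(self):
        # 3 activation-consistent, 1 inhibition-consistent: z = 2/2 = 1
        net = _net([("R", f"T{i}", 1) for i in range(4)])
        observed = pd.Series([1, 1, 1, -1], index=[f"T{i}" for i in range(4)])
        assert activation_z(net, observed).loc["R", "z"] == pytest.approx(1.0)

    def test_repression_edges_count_toward_activation(self):
        # regulator represses a target that goes down: consistent with
        # activation
        net = _net([("R", "T0", -1)])
        observed = pd.Series([-1], index=["T0"])
        assert activation_z(net, observed).loc["R", "z"] == pytest.approx(1.0)

    def test_flipping_observations_negates_z(self):
        rng = np.random.default_rng(13)
        net = _net([("R", f"T{i}", int(d)) for i, d in
                    enumerate(rng.choice([1, -1], 9))])
        observed = pd.Series(rng.choice([1, -1], 9),
                             index=[f"T{i}" for i in range(9)])
        z1 = activation_z(net, observed).loc["R", "z"]
        z2 = activation_z(net, -observed).loc["R", "z"]
        assert z2 == pytest.approx(-z1)

    def test_uninformative_targets_excluded(self):
        net = _net([("R", "T0", 1), ("R", "ABSENT", 1)])
        observed = pd.Series([1], index=["T0"])
        row = activation_z(net, observed).loc["R"]
        assert row["N_informative"] == 1
        assert row["z"] == pytest.approx(1.0)

    def test_no_informative_targets_reports_missing(self):
        net = _net([("R", "ABSENT", 1)])
        observed = pd.Series([1], index=["T0"])
        row = activation_z(net, observed).loc["R"]
        assert row["N_informative"] == 0
        assert np.isnan(row["z"])

    def test_z_bounded_by_sqrt_n(self):
        rng = np.random.default_rng(14)
        for trial in range(20):
            n = rng.integers(1, 12)
            net = _net([("R", f"T{i}", int(d)) for i, d in
                        enumerate(rng.choice([1, -1], n))])
            observed = pd.Series(rng.choice([1, -1], n),
                                 index=[f"T{i}" for i in range(n)])
            z = activation_z(net, observed).loc["R", "z"]
            assert abs(z) <= math.sqrt(n) + 1e-12


class TestOverlapP:
    def test_equals_hypergeometric_upper_tail_exhaustive(self):
        # Fisher one-sided p must equal the hypergeometric upper tail on
        # every 2x2 table with margins <= 12
        for N in range(2, 13):
            bg = {f"g{i}" for i in range(N)}
            for n_t, n_d in itertools.product(range(N + 1), repeat=2):
                targets = {f"g{i}" for i in range(n_t)}
                de = {f"g{i}" for i in range(N - n_d, N)}
                k = len(targets & de)
                assert overlap_p(targets, de, bg) == pytest.approx(
                    _hyper_upper_tail(N, n_t, n_d, k), rel=1e-9, abs=1e-12
                )

    def test_expected_overlap_not_significant(self):
        bg = {f"g{i}" for i in range(20)}
        targets = {f"g{i}" for i in range(10)}
        de = {f"g{i}" for i in range(5, 15)}  # overlap 5 = expectation
        assert overlap_p(targets, de, bg) > 0.05

    def test_degenerate_full_sets(self):
        bg = {"a", "b"}
        assert overlap_p(bg, bg, bg) == pytest.approx(1.0)

    def test_empty_background_errors(self):
        with pytest.raises(ValueError):
            overlap_p({"a"}, {"a"}, set())


class TestClassification:
    @pytest.mark.parametrize(
        "z,p,state,label",
        [
            (-3.873, 7.58e-11, "inhibited", "Inhibited"),
            (2.425, 4.29e-5, "activated", "Activated"),
            (1.954, 4.55e-2, "strong", "+++"),
            (-1.961, 1.49e-3, "strong", "---"),
            (1.531, 4.37e-5, "moderate", "++"),
            (1.2, 0.01, "weak", "+"),
            (0.5, 0.001, "none", "none"),
            (2.0, 0.001, "strong", "+++"),   # boundary: exactly 2.0
            (3.0, 0.2, "none", "none"),      # overlap p gates every call
            (float("nan"), 0.001, "none", "none"),
        ],
    )
    def test_bands(self, z, p, state, label):
        st = classify_regulator(z, p)
        assert (st.state, st.label) == (state, label)

    def test_bad_bands_rejected(self):
        with pytest.raises(ValueError):
            classify_regulator(1.0, 0.01, qualified_bands=(1.0, 1.5, 1.7))


def test_regulator_predictions_end_to_end():
    bg = {f"G{i}" for i in range(40)}
    de = {f"G{i}" for i in range(10)}
    observed = pd.Series(-1, index=sorted(de))
    net = _net([("RICTOR", f"G{i}", 1) for i in range(10)])
    table = regulator_predictions(net, observed, de, bg)
    row = table.loc["RICTOR"]
    assert row["z"] == pytest.approx(-math.sqrt(10))
    assert row["p_overlap"] == pytest.approx(1 / math.comb(40, 10), rel=1e-9)
    assert row["state"] == "inhibited"
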