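"""Frontier estimators: VRS/CRS DEA, FDH, super-efficiency, diagnostics, bins."""

import numpy as np
import pandas as pd
import pytest

from hospeff import (
    ProductionSet,
    bin_scores,
    dea_input_crs,
    dea_input_vrs,
    dimensionality_diagnostics,
    fdh_input,
    super_efficiency,
)
from hospeff.errors import InvalidArgumentError

from .oracles import dea_crs_dual, dea_vrs_dual, fdh_enumerate


def make_ps(X, Y):
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    return ProductionSet(dmu=[f"d{i}" for i in range(len(X))], X=X, Y=Y)


def random_ps(n, p, q, seed):
    rng = np.random.default_rng(seed)
    return make_ps(
        rng.uniform(0.5, 10.0, size=(n, p)), rng.uniform(0.5, 10.0, size=(n, q))
    )


class TestVRS:
    def test_single_dmu_is_efficient(self):
        ps = make_ps([[2.0, 3.0]], [[1.0]])
        assert dea_input_vrs(ps).iloc[0] == pytest.approx(1.0)

    def test_three_dmu_hand_instance(self):
        # (x, y): (2,1), (4,1), (3,3); DMU2 is dominated by DMU1
        ps = make_ps([[2.0], [4.0], [3.0]], [[1.0], [1.0], [3.0]])
        theta = dea_input_vrs(ps)
        assert theta.iloc[0] == pytest.approx(1.0)
        assert theta.iloc[1] == pytest.approx(0.5)
        assert theta.iloc[2] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dual_form_oracle(self, seed):
        ps = random_ps(30, 3, 2, seed)
        theta = dea_input_vrs(ps).to_numpy()
        oracle = np.array(
            [dea_vrs_dual(ps.X, ps.Y, o) for o in range(ps.n)]
        )
        assert np.allclose(theta, np.minimum(oracle, 1.0), atol=1e-7)

    def test_units_invariance(self):
        ps = random_ps(25, 4, 2, seed=5)
        theta = dea_input_vrs(ps).to_numpy()
        X2 = ps.X * np.array([3.0, 0.01, 250.0, 1.0])
        Y2 = ps.Y * np.array([1000.0, 0.5])
        theta2 = dea_input_vrs(make_ps(X2, Y2)).to_numpy()
        assert np.allclose(theta, theta2, atol=1e-9)

    def test_adding_dmu_weakly_decreases_scores(self):
        ps = random_ps(20, 2, 2, seed=9)
        theta = dea_input_vrs(ps).to_numpy()
        extra = make_ps(
            np.vstack([ps.X, [[0.6, 0.6]]]), np.vstack([ps.Y, [[9.5, 9.5]]])
        )
        theta2 = dea_input_vrs(extra).to_numpy()[:-1]
        assert np.all(theta2 <= theta + 1e-9)

    def test_free_disposability_stability(self):
        """A DMU with weakly more input / less output than an existing one
        leaves every other score unchanged."""
        ps = random_ps(15, 2, 2, seed=11)
        theta = dea_input_vrs(ps).to_numpy()
        worse_x = ps.X[3] * 1.5
        worse_y = ps.Y[3] * 0.7
        bigger = make_ps(
            np.vstack([ps.X, worse_x]), np.vstack([ps.Y, worse_y])
        )
        theta2 = dea_input_vrs(bigger).to_numpy()[:-1]
        assert np.allclose(theta, theta2, atol=1e-9)


class TestFDH:
    def test_mutually_nondominated_all_efficient(self):
        ps = make_ps([[1.0], [2.0], [3.0]], [[1.0], [2.0], [3.0]])
        assert np.allclose(fdh_input(ps).to_numpy(), 1.0)

    def test_doubled_inputs_halve_score(self):
        ps = make_ps([[2.0, 4.0], [4.0, 8.0]], [[1.0], [1.0]])
        theta = fdh_input(ps)
        assert theta.iloc[0] == pytest.approx(1.0)
        assert theta.iloc[1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_enumeration_oracle(self, seed):
        ps = random_ps(20, 3, 2, seed)
        theta = fdh_input(ps).to_numpy()
        oracle = np.array(
            [fdh_enumerate(ps.X, ps.Y, o) for o in range(ps.n)]
        )
        assert np.allclose(theta, oracle, atol=0)


class TestNesting:
    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_crs_below_vrs_below_fdh(self, seed):
        ps = random_ps(25, 2, 2, seed)
        crs = dea_input_crs(ps).to_numpy()
        vrs = dea_input_vrs(ps).to_numpy()
        fdh = fdh_input(ps).to_numpy()
        assert np.all(crs <= vrs + 1e-8)
        assert np.all(vrs <= fdh + 1e-8)

    def test_crs_matches_dual_oracle(self):
        ps = random_ps(15, 2, 1, seed=13)
        crs = dea_input_crs(ps).to_numpy()
        oracle = np.array(
            [dea_crs_dual(ps.X, ps.Y, o) for o in range(ps.n)]
        )
        assert np.allclose(crs, np.minimum(oracle, 1.0), atol=1e-7)


class TestSuperEfficiency:
    def test_dominated_dmu_keeps_ordinary_score(self):
        ps = make_ps([[2.0], [4.0], [3.0]], [[1.0], [1.0], [3.0]])
        se = super_efficiency(ps)
        theta = dea_input_vrs(ps)
        assert se["superefficiency"].iloc[1] == pytest.approx(
            theta.iloc[1], abs=1e-9
        )

    def test_two_dmu_hand_instance(self):
        ps = make_ps([[2.0], [4.0]], [[1.0], [1.0]])
        se = super_efficiency(ps)
        assert se["superefficiency"].iloc[0] == pytest.approx(2.0)

    def test_infeasible_reported_not_raised(self):
        # unique maximal-output DMU under VRS has no feasible reference
        ps = make_ps([[1.0], [1.0]], [[5.0], [1.0]])
        se = super_efficiency(ps)
        assert se["status"].iloc[0] == "infeasible"
        assert np.isnan(se["superefficiency"].iloc[0])

    def test_needs_two_dmus(self):
        with pytest.raises(InvalidArgumentError):
            super_efficiency(make_ps([[1.0]], [[1.0]]))


class TestDiagnostics:
    def test_two_nondominated_dmus_warn(self):
        ps = make_ps([[1.0], [2.0]], [[1.0], [2.0]])
        rep = dimensionality_diagnostics(ps)
        assert rep.fdh_efficient_share == pytest.approx(1.0)
        assert rep.flag == "warn"

    def test_reports_sample_dimensions(self):
        ps = random_ps(50, 4, 2, seed=2)
        rep = dimensionality_diagnostics(ps)
        assert rep.n == 50 and rep.dims == 6
        assert rep.effective_sample_size == pytest.approx(50 ** (2 / 7))


class TestBins:
    def test_all_efficient(self):
        s = bin_scores(np.ones(10))
        assert s["1.00"] == pytest.approx(1.0)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)

    def test_edge_handling(self):
        s = bin_scores([0.99, 0.80, 0.79])
        assert s["0.80-0.99"] == pytest.approx(2 / 3)
        assert s["0.60-0.79"] == pytest.approx(1 / 3)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)

    def test_scores_above_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            bin_scores([1.2])

    def test_synthetic_shares_sum_to_one(self):
        rng = np.random.default_rng(0)
        s = bin_scores(rng.uniform(0.05, 1.0, size=500))
        assert s.sum() == pytest.approx(1.0, abs=1e-12)


class TestProductionSetValidation:
    def test_rejects_zero_inputs(self):
        with pytest.raises(InvalidArgumentError):
            make_ps([[0.0, 1.0]], [[1.0]])

    def test_rejects_all_zero_output_rows(self):
        with pytest.raises(InvalidArgumentError):
            make_ps([[1.0]], [[0.0]])

    def test_from_panel_floors_scattered_zero_ftes(self, panel201):
        panel, _ = panel201
        t = panel.table.copy()
        t.loc[t.index[:3], "fte_na"] = 0.0
        from hospeff import HospitalPanel, urgency_measures

        p2 = HospitalPanel(t, panel.catalogue)
        m = urgency_measures(p2)
        ps = ProductionSet.from_panel(p2, m["adjusted_inpatients"])
        col = ps.input_names.index("fte_na")
        assert ps.X[:3, col].min() > 0
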