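"""Case-mix weights, adjusted inpatient volume, UrS and UrD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hospeff import (
    adjusted_inpatients,
    casemix_weights,
    generate_catalogue,
    urgency_dispersion,
    urgency_measures,
    urgency_score,
)
from hospeff.errors import InvalidArgumentError
from hospeff.measures import classify_urgency

from .conftest import make_catalogue, make_panel
from .oracles import urs_urd_by_expansion


class TestCaseMixWeights:
    def test_equal_los_gives_unit_weights(self):
        cat = make_catalogue(
            [(f"c{g}", 0.5, g, 1, 5.0) for g in range(1, 11)]
        )
        w = casemix_weights(cat)
        assert w.G == 10
        assert np.allclose(w.weights.to_numpy(), 1.0)

    def test_two_group_ratio(self, tiny_catalogue):
        w = casemix_weights(tiny_catalogue)
        # group LOS {2, 6}: grand mean 4 -> weights 0.5 and 1.5
        assert w.weights[1] == pytest.approx(0.5)
        assert w.weights[2] == pytest.approx(1.5)

    def test_mean_weight_is_one_for_random_catalogue(self):
        cat = generate_catalogue(241, 241, 22, seed=3)
        w = casemix_weights(cat)
        assert w.weights.mean() == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_mean_weight_is_one_property(self, seed):
        cat = generate_catalogue(40, 17, 5, seed=seed)
        assert casemix_weights(cat).weights.mean() == pytest.approx(
            1.0, abs=1e-12
        )


class TestAdjustedInpatients:
    def test_unit_weight_group_passes_through(self):
        cat = make_catalogue([("A", 0.5, 1, 1, 4.0), ("B", 0.5, 2, 1, 4.0)])
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 100}}], cat
        )
        adj = adjusted_inpatients(panel, casemix_weights(cat))
        assert adj.iloc[0] == pytest.approx(100.0)

    def test_weight_balance(self, tiny_catalogue):
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 50, "B": 50}}], tiny_catalogue
        )
        adj = adjusted_inpatients(panel, casemix_weights(tiny_catalogue))
        assert adj.iloc[0] == pytest.approx(0.5 * 50 + 1.5 * 50)

    def test_matches_bruteforce_recomputation(self, panel201):
        panel, _ = panel201
        cat = panel.catalogue
        w = casemix_weights(cat)
        adj = adjusted_inpatients(panel, w)
        counts = panel.counts()
        groups = cat.group_by_code()
        expected = np.zeros(len(counts))
        for j, code in enumerate(counts.columns):
            expected += counts[code].to_numpy() * w.weights[groups[code]]
        assert np.allclose(adj.to_numpy(), expected, rtol=1e-12)

    def test_linearity_in_counts(self, tiny_catalogue):
        w = casemix_weights(tiny_catalogue)
        a = make_panel(
            [{"hospital": "h1", "diag": {"A": 10, "B": 5}}], tiny_catalogue
        )
        b = make_panel(
            [{"hospital": "h1", "diag": {"A": 3, "C": 7}}], tiny_catalogue
        )
        ab = make_panel(
            [{"hospital": "h1", "diag": {"A": 13, "B": 5, "C": 7}}],
            tiny_catalogue,
        )
        assert adjusted_inpatients(ab, w).iloc[0] == pytest.approx(
            adjusted_inpatients(a, w).iloc[0]
            + adjusted_inpatients(b, w).iloc[0]
        )


class TestUrgencyScore:
    def test_mean_of_two_cases_and_boundary_rule(self, tiny_catalogue):
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 1, "B": 1}}], tiny_catalogue
        )
        res = urgency_score(panel)
        assert res["urs"].iloc[0] == pytest.approx(0.5)
        # 0.5 sits on the emergency side of the boundary
        assert res["dominance"].iloc[0] == "emergency-dominated"
        assert classify_urgency(0.49999) == "elective-dominated"

    def test_single_diagnosis(self, tiny_catalogue):
        panel = make_panel(
            [{"hospital": "h1", "diag": {"C": 12}}], tiny_catalogue
        )
        assert urgency_score(panel)["urs"].iloc[0] == pytest.approx(0.37)

    def test_within_treated_u_range(self, panel201):
        panel, _ = panel201
        res = urgency_score(panel)
        u = panel.catalogue.u_by_code()
        counts = panel.counts()
        for i in range(0, len(counts), 37):
            treated = counts.iloc[i] > 0
            us = u[counts.columns[treated]]
            assert us.min() - 1e-12 <= res["urs"].iloc[i] <= us.max() + 1e-12


class TestUrgencyDispersion:
    def test_hand_computed_two_case_sd(self, tiny_catalogue):
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 1, "B": 1}}], tiny_catalogue
        )
        res = urgency_dispersion(panel)
        assert res["urd"].iloc[0] == pytest.approx(np.sqrt(0.18))

    def test_identical_diagnoses_have_zero_dispersion(self, tiny_catalogue):
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 500}}], tiny_catalogue
        )
        assert urgency_dispersion(panel)["urd"].iloc[0] == pytest.approx(0.0)

    def test_single_case_is_an_error(self, tiny_catalogue):
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 1}}], tiny_catalogue
        )
        with pytest.raises(InvalidArgumentError):
            urgency_dispersion(panel)

    def test_matches_case_expansion_oracle(self, tiny_catalogue):
        diag = {"A": 4, "B": 7, "C": 2}
        panel = make_panel([{"hospital": "h1", "diag": diag}], tiny_catalogue)
        urs_o, urd_o = urs_urd_by_expansion(
            diag, tiny_catalogue.u_by_code()
        )
        assert urgency_score(panel)["urs"].iloc[0] == pytest.approx(urs_o)
        assert urgency_dispersion(panel)["urd"].iloc[0] == pytest.approx(urd_o)

    @given(
        st.integers(1, 50), st.integers(1, 50), st.integers(0, 50),
        st.integers(2, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_count_scaling_invariance(self, a, b, c, k):
        """Multiplying every count by k leaves UrS unchanged exactly, and
        UrD matches the case-expansion oracle at the scaled counts."""
        cat = make_catalogue(
            [("A", 0.2, 1, 1, 2.0), ("B", 0.8, 2, 1, 6.0), ("C", 0.37, 1, 2, 2.0)]
        )
        diag = {"A": a, "B": b, "C": c}
        scaled = {kk: k * v for kk, v in diag.items()}
        p1 = make_panel([{"hospital": "h1", "diag": diag}], cat)
        pk = make_panel([{"hospital": "h1", "diag": scaled}], cat)
        assert urgency_score(pk)["urs"].iloc[0] == pytest.approx(
            urgency_score(p1)["urs"].iloc[0], abs=1e-14
        )
        _, urd_o = urs_urd_by_expansion(scaled, cat.u_by_code())
        assert urgency_dispersion(pk)["urd"].iloc[0] == pytest.approx(urd_o)


class TestMissingUrgencyValues:
    def test_nan_u_codes_excluded_from_urs_denominator(self):
        cat = make_catalogue(
            [("A", 0.2, 1, 1, 2.0), ("N", np.nan, 2, 1, 3.0)]
        )
        panel = make_panel(
            [{"hospital": "h1", "diag": {"A": 10, "N": 90}}], cat
        )
        assert urgency_score(panel)["urs"].iloc[0] == pytest.approx(0.2)
        # but they still count toward adjusted volume
        adj = adjusted_inpatients(panel, casemix_weights(cat))
        assert adj.iloc[0] > 10


def test_measures_table_row_order_is_deterministic(panel201):
    panel, _ = panel201
    m = urgency_measures(panel)
    assert list(m.index) == sorted(m.index)
    assert set(m.columns) >= {"urs", "urd", "n_cases", "adjusted_inpatients"}
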