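"""Catchment areas and chapter-weighted market concentration."""

import numpy as np
import pytest

from hospeff import catchment, hhi_table, weighted_hhi
from hospeff.market import EARTH_RADIUS_KM, haversine_km

from .conftest import make_catalogue, make_panel
from .oracles import weighted_hhi_enumerate


@pytest.fixture(scope="module")
def chapter_catalogue():
    # one code per chapter, three chapters
    return make_catalogue(
        [
            ("A", 0.3, 1, 1, 3.0),
            ("B", 0.6, 2, 2, 4.0),
            ("C", 0.9, 3, 3, 5.0),
        ]
    )


def lon_offset_for_km(lat, km):
    """Longitude offset whose haversine distance at given latitude is km."""
    dlon = km / (EARTH_RADIUS_KM * np.cos(np.radians(lat)))
    return np.degrees(dlon)


class TestCatchment:
    def test_colocated_hospitals_are_mutual(self, chapter_catalogue):
        panel = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 10}},
                {"hospital": "h2", "diag": {"A": 10}},
            ],
            chapter_catalogue,
        )
        assert set(catchment(panel, "h1", 2016)) == {"h1", "h2"}
        assert set(catchment(panel, "h2", 2016)) == {"h1", "h2"}

    def test_hospital_beyond_radius_excluded(self, chapter_catalogue):
        off = lon_offset_for_km(52.0, 40.0)
        panel = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 10}, "lat": 52.0, "lon": 13.0},
                {"hospital": "h2", "diag": {"A": 10}, "lat": 52.0,
                 "lon": 13.0 + off},
            ],
            chapter_catalogue,
        )
        d = haversine_km([[52.0, 13.0]], [[52.0, 13.0 + off]])[0, 0]
        assert d == pytest.approx(40.0, abs=0.01)
        assert catchment(panel, "h1", 2016) == ["h1"]
        # ... but a 32 km threshold is inclusive
        off32 = lon_offset_for_km(52.0, 32.0)
        panel2 = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 10}, "lat": 52.0, "lon": 13.0},
                {"hospital": "h2", "diag": {"A": 10}, "lat": 52.0,
                 "lon": 13.0 + off32},
            ],
            chapter_catalogue,
        )
        assert set(catchment(panel2, "h1", 2016)) == {"h1", "h2"}

    def test_isolated_hospital_is_alone(self, chapter_catalogue):
        panel = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 5}, "lat": 48.0, "lon": 8.0},
                {"hospital": "h2", "diag": {"A": 5}, "lat": 54.0, "lon": 14.0},
            ],
            chapter_catalogue,
        )
        assert catchment(panel, "h1", 2016) == ["h1"]


class TestWeightedHHI:
    def test_monopoly_in_every_chapter(self, chapter_catalogue):
        panel = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 5, "B": 3}, "lat": 48.0,
                 "lon": 8.0},
                {"hospital": "h2", "diag": {"A": 5}, "lat": 54.0, "lon": 14.0},
            ],
            chapter_catalogue,
        )
        res = weighted_hhi(panel, focal="h1", year=2016)
        assert res.hhi == pytest.approx(1.0)
        assert res.n_competitors == 0

    def test_two_equal_colocated_single_chapter(self, chapter_catalogue):
        panel = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 100}},
                {"hospital": "h2", "diag": {"A": 100}},
            ],
            chapter_catalogue,
        )
        res = weighted_hhi(panel, focal="h1", year=2016)
        assert res.hhi == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [2, 3, 5, 8])
    def test_n_equal_hospitals_give_one_over_n(self, n, chapter_catalogue):
        panel = make_panel(
            [
                {"hospital": f"h{i}", "diag": {"B": 40}}
                for i in range(n)
            ],
            chapter_catalogue,
        )
        res = weighted_hhi(panel, focal="h0", year=2016)
        assert res.hhi == pytest.approx(1.0 / n)

    def test_five_hospital_three_chapter_enumeration_oracle(
        self, chapter_catalogue
    ):
        diag = {
            "h1": {"A": 10, "B": 5, "C": 1},
            "h2": {"A": 3, "C": 9},
            "h3": {"B": 20},
            "h4": {"A": 1, "B": 1, "C": 1},
            "h5": {"C": 14},
        }
        panel = make_panel(
            [{"hospital": h, "diag": d} for h, d in diag.items()],
            chapter_catalogue,
        )
        chap_of = {"A": 1, "B": 2, "C": 3}
        hospitals = {
            h: {
                "chapters": {
                    chap_of[c]: cnt for c, cnt in d.items()
                }
            }
            for h, d in diag.items()
        }
        for focal in diag:
            expected = weighted_hhi_enumerate(hospitals, focal)
            got = weighted_hhi(panel, focal=focal, year=2016).hhi
            assert got == pytest.approx(expected, abs=1e-12)

    def test_hhi_is_convex_combination_of_chapter_hhis(
        self, chapter_catalogue
    ):
        panel = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 10, "B": 30, "C": 60}},
                {"hospital": "h2", "diag": {"A": 25, "C": 5}},
            ],
            chapter_catalogue,
        )
        res = weighted_hhi(panel, focal="h1", year=2016)
        lo, hi = res.chapter_hhi.min(), res.chapter_hhi.max()
        assert lo - 1e-12 <= res.hhi <= hi + 1e-12

    def test_zero_volume_competitor_changes_nothing(self, chapter_catalogue):
        base = [
            {"hospital": "h1", "diag": {"A": 10, "B": 4}},
            {"hospital": "h2", "diag": {"A": 6}},
        ]
        panel = make_panel(base, chapter_catalogue)
        # "zero volume" in the chapters h1 serves: h3 only treats chapter 3
        panel2 = make_panel(
            base + [{"hospital": "h3", "diag": {"C": 50}}], chapter_catalogue
        )
        a = weighted_hhi(panel, focal="h1", year=2016).hhi
        b = weighted_hhi(panel2, focal="h1", year=2016).hhi
        assert a == pytest.approx(b, abs=1e-12)

    def test_splitting_a_competitor_weakly_decreases_hhi(
        self, chapter_catalogue
    ):
        merged = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 10}},
                {"hospital": "h2", "diag": {"A": 40}},
            ],
            chapter_catalogue,
        )
        split = make_panel(
            [
                {"hospital": "h1", "diag": {"A": 10}},
                {"hospital": "h2a", "diag": {"A": 20}},
                {"hospital": "h2b", "diag": {"A": 20}},
            ],
            chapter_catalogue,
        )
        a = weighted_hhi(merged, focal="h1", year=2016).hhi
        b = weighted_hhi(split, focal="h1", year=2016).hhi
        assert b <= a + 1e-12


def test_hhi_table_bounds_and_alignment(panel201):
    panel, _ = panel201
    table = hhi_table(panel)
    assert (table["hhi"] > 0).all() and (table["hhi"] <= 1 + 1e-12).all()
    assert list(table.index) == list(panel.dmu_index())
    solo = table[table["n_competitors"] == 0]
    assert np.allclose(solo["hhi"], 1.0)
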