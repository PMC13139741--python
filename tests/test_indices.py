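"""SI/DSI coefficients, matrix origin and quadrant assignment."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kanokit as kk
from kanokit import ItemFrequencies, MatrixOrigin, Quadrant, UndefinedIndexError

from conftest import EXPECTED_MEMBERSHIP, EXPECTED_TABLE

counts_strategy = st.fixed_dictionaries(
    {tag: st.integers(0, 1000) for tag in "MOAIRQ"}
)


class TestIndices:
    @pytest.mark.parametrize(
        "counts, si, dsi",
        [
            (dict(M=282, O=235, A=725, I=322), 960 / 1564, -517 / 1564),
            (dict(M=148, O=534, A=433, I=454), 967 / 1569, -682 / 1569),
            (dict(M=699, O=272, A=291, I=301), 563 / 1563, -971 / 1563),
            (dict(M=131, O=102, A=714, I=608), 816 / 1555, -233 / 1555),
            (dict(A=10), 1.0, 0.0),           # all-attractive limit
            (dict(A=5, I=5), 0.5, 0.0),       # no O/M mass: DSI = 0
            (dict(M=7), 0.0, -1.0),           # all-must-be limit
        ],
    )
    def test_closed_form(self, counts, si, dsi):
        freqs = ItemFrequencies.from_counts("it", **counts)
        assert kk.satisfaction_index(freqs) == pytest.approx(si)
        assert kk.importance_index(freqs) == pytest.approx(dsi)

    def test_r_and_q_are_ignored(self):
        base = ItemFrequencies.from_counts("a", M=3, O=4, A=5, I=6)
        noisy = ItemFrequencies.from_counts("b", M=3, O=4, A=5, I=6, R=99, Q=42)
        assert kk.satisfaction_index(base) == kk.satisfaction_index(noisy)
        assert kk.importance_index(base) == kk.importance_index(noisy)

    def test_undefined_when_no_classifiable_mass(self):
        freqs = ItemFrequencies.from_counts("it", R=5, Q=5)
        with pytest.raises(UndefinedIndexError):
            kk.satisfaction_index(freqs)
        with pytest.raises(UndefinedIndexError):
            kk.importance_index(freqs)

    @settings(max_examples=60, derandomize=True)
    @given(counts=counts_strategy)
    def test_ranges(self, counts):
        freqs = ItemFrequencies.from_counts("it", **counts)
        if sum(counts[t] for t in "MOAI") == 0:
            with pytest.raises(UndefinedIndexError):
                kk.satisfaction_index(freqs)
            return
        assert 0.0 <= kk.satisfaction_index(freqs) <= 1.0
        assert -1.0 <= kk.importance_index(freqs) <= 0.0

    @settings(max_examples=40, derandomize=True)
    @given(counts=counts_strategy)
    def test_adding_one_o_response_is_monotone(self, counts):
        if sum(counts[t] for t in "MOAI") == 0:
            counts = dict(counts, I=1)
        before = ItemFrequencies.from_counts("it", **counts)
        after = ItemFrequencies.from_counts("it", **{**counts, "O": counts["O"] + 1})
        assert kk.satisfaction_index(after) >= kk.satisfaction_index(before) - 1e-12
        assert kk.importance_index(after) <= kk.importance_index(before) + 1e-12


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.615, 0.62), (-0.615, -0.62), (0.614, 0.61), (0.5, 0.5), (-0.125, -0.13)],
    )
    def test_round_half_away_from_zero(self, x, expected):
        assert kk.round_display(x) == expected

    def test_bundled_survey_matches_all_printed_values(self, nurse_freqs):
        for f in nurse_freqs:
            _, dsi_exp, si_exp = EXPECTED_TABLE[f.item_id]
            assert kk.round_display(kk.satisfaction_index(f)) == si_exp
            assert kk.round_display(kk.importance_index(f)) == dsi_exp


class TestOriginAndQuadrants:
    def test_origin_is_per_axis_mean(self, nurse_freqs):
        results = kk.item_results(nurse_freqs)
        origin = kk.compute_origin(results)
        assert origin.x0 == pytest.approx(
            sum(abs(r.dsi) for r in results) / len(results)
        )
        assert origin.y0 == pytest.approx(sum(r.si for r in results) / len(results))
        assert origin.x0 == pytest.approx(0.43, abs=0.005)
        assert origin.y0 == pytest.approx(0.49, abs=0.005)

    def test_origin_of_single_item(self):
        [r] = kk.item_results([ItemFrequencies.from_counts("it", M=1, O=1, A=2)])
        origin = kk.compute_origin([r])
        assert (origin.x0, origin.y0) == (abs(r.dsi), r.si)

    def test_origin_of_identical_items_degenerates(self):
        rows = [ItemFrequencies.from_counts(str(i), M=2, O=3, A=4, I=1)
                for i in range(5)]
        results = kk.item_results(rows)
        origin = kk.compute_origin(results)
        assert (origin.x0, origin.y0) == (abs(results[0].dsi), results[0].si)

    @settings(max_examples=50, derandomize=True)
    @given(
        si=st.floats(0, 1), dsi=st.floats(-1, 0),
        x0=st.floats(0, 1), y0=st.floats(0, 1),
    )
    def test_quadrant_partition_exhaustive_exclusive(self, si, dsi, x0, y0):
        q = kk.assign_quadrant(si, dsi, MatrixOrigin(x0, y0))
        assert q in list(Quadrant)

    def test_boundary_goes_to_predominance(self):
        origin = MatrixOrigin(0.4, 0.5)
        assert kk.assign_quadrant(0.5, -0.4, origin) is Quadrant.I

    def test_strategy_names(self):
        assert [q.strategy_name for q in Quadrant] == [
            "predominance", "improving", "secondary improving", "reserving",
        ]

    def test_bundled_survey_memberships_full_precision(self, nurse_freqs):
        results = kk.item_results(nurse_freqs)
        _, _, membership = kk.build_matrix(results)
        assert {q.name: ids for q, ids in membership.items()} == EXPECTED_MEMBERSHIP

    def test_bundled_survey_memberships_from_rounded_values(self, nurse_freqs):
        """Recomputing from the 2-dp printed indices places items identically."""
        results = kk.item_results(nurse_freqs)
        rounded = [
            kk.ItemResult(
                item_id=r.item_id, frequencies=r.frequencies,
                classification=r.classification,
                si=kk.round_display(r.si), dsi=kk.round_display(r.dsi),
            )
            for r in results
        ]
        _, _, membership = kk.build_matrix(
            rounded, kk.compute_origin(rounded, from_rounded=True)
        )
        assert {q.name: ids for q, ids in membership.items()} == EXPECTED_MEMBERSHIP

    def test_every_item_in_exactly_one_quadrant(self, nurse_report):
        all_ids = [i for ids in nurse_report.quadrant_membership.values() for i in ids]
        assert sorted(all_ids, key=int) == [str(i) for i in range(1, 27)]
        assert len(set(all_ids)) == len(all_ids)
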