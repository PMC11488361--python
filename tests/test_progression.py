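"""Feature-vector distances, risk bands, boundary line and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from cognet import (
    CommunityPartition,
    Diagnosis,
    DistanceRecord,
    GeneratorConfig,
    RiskBand,
    band_outcome_rates,
    boundary_line,
    community_distances,
    find_community,
    generate_cohort,
    match_communities,
    risk_band,
    select_study_sample,
    sex_stratified_summary,
)
from conftest import CU, DEM, MCI, make_cohort

COGNITIVE = frozenset(["CDRSum", "CDRGlob", "FAQ"])


def cognitive_partition():
    return CommunityPartition(
        communities=(COGNITIVE,), method="cnm", modularity=None
    )


def record(pid="P1", cid=0, tj=2, lapse=1.0, dist=5.0, dx=Diagnosis.MCI,
           sex="F"):
    return DistanceRecord(
        participant_id=pid, community_id=cid, visit_index_i=1,
        visit_index_j=tj, time_lapse_years=lapse, distance=dist,
        diagnosis_at_tj=dx, sex=sex,
    )


class TestCommunityDistances:
    def test_identical_vectors_give_zero(self):
        cohort = make_cohort(
            {"P1": [CU, MCI, DEM]},
            values_fn=lambda p, t: {"CDRSum": 1.0, "CDRGlob": 0.5, "FAQ": 3.0},
        )
        recs = community_distances(cohort, cognitive_partition())
        assert all(r.distance == 0.0 for r in recs)

    def test_raw_scale_euclidean_norm(self):
        values = {
            1: {"CDRGlob": 0.5, "CDRSum": 1.0, "FAQ": 3.0},
            2: {"CDRGlob": 1.0, "CDRSum": 5.0, "FAQ": 15.0},
        }
        cohort = make_cohort(
            {"P1": [CU, MCI, DEM]},
            values_fn=lambda p, t: values.get(t, {"CDRGlob": 0.5,
                                                  "CDRSum": 1.0, "FAQ": 3.0}),
        )
        recs = community_distances(cohort, cognitive_partition())
        assert recs[-1].distance == pytest.approx(
            np.sqrt(0.25 + 16 + 144), abs=1e-9
        )
        assert recs[-1].distance == pytest.approx(12.659, abs=1e-3)

    def test_three_four_five(self):
        values = {1: {"CDRSum": 0.0, "FAQ": 0.0}, 2: {"CDRSum": 3.0, "FAQ": 4.0}}
        cohort = make_cohort(
            {"P1": [CU, MCI, DEM]}, values_fn=lambda p, t: values.get(t, {})
        )
        recs = community_distances(cohort, cognitive_partition())
        assert recs[0].distance == pytest.approx(5.0)

    def test_missing_components_dropped_pairwise(self):
        values = {1: {"CDRSum": 1.0, "FAQ": 2.0}, 2: {"CDRSum": 4.0}}
        cohort = make_cohort(
            {"P1": [CU, MCI, DEM]}, values_fn=lambda p, t: values.get(t, {})
        )
        recs = community_distances(cohort, cognitive_partition())
        assert recs[0].distance == pytest.approx(3.0)

    def test_no_overlap_skips_with_warning(self):
        values = {1: {"CDRSum": 1.0}, 2: {"FAQ": 4.0}}
        cohort = make_cohort(
            {"P1": [CU, MCI, DEM]}, values_fn=lambda p, t: values.get(t, {})
        )
        with pytest.warns(UserWarning, match="no overlapping"):
            recs = community_distances(cohort, cognitive_partition())
        assert recs == []

    def test_time_lapse_in_years(self):
        cohort = make_cohort({"P1": [CU, MCI, MCI, DEM]})
        recs = community_distances(cohort, cognitive_partition())
        assert [r.time_lapse_years for r in recs] == [
            pytest.approx(15 / 12), pytest.approx(30 / 12)
        ]

    def test_normalized_distance_bounded_by_sqrt_community_size(
        self, default_cohort
    ):
        recs = community_distances(
            default_cohort, cognitive_partition(), scale="normalized"
        )
        bound = np.sqrt(len(COGNITIVE))
        assert all(r.distance <= bound + 1e-9 for r in recs)

    def test_triangle_inequality_across_visits(self, default_cohort):
        baseline = community_distances(default_cohort, cognitive_partition())
        consecutive = community_distances(
            default_cohort, cognitive_partition(), pairing="consecutive"
        )
        base = {(r.participant_id, r.visit_index_j): r.distance
                for r in baseline}
        cons = {(r.participant_id, r.visit_index_j): r.distance
                for r in consecutive}
        for (pid, tj), d_now in base.items():
            d_prev = base.get((pid, tj - 1), 0.0)
            step = cons[(pid, tj)]
            assert d_now <= d_prev + step + 1e-9

    def test_mean_distance_increases_with_time_lapse(self):
        rhos = []
        for seed in range(20):
            cohort = select_study_sample(
                generate_cohort(GeneratorConfig(seed=seed))
            )
            recs = community_distances(cohort, cognitive_partition())
            rho, p = spearmanr(
                [r.time_lapse_years for r in recs],
                [r.distance for r in recs],
            )
            rhos.append((rho, p))
        assert all(rho > 0 for rho, _ in rhos)
        assert np.median([p for _, p in rhos]) < 0.01


class TestBoundaryLine:
    def test_study_boundary_coefficients(self):
        line = boundary_line(9, 25)
        assert line.coefficients == (25, 9, 225)

    def test_intercepts_lie_on_line(self):
        line = boundary_line(9, 25)
        assert line.classify_side(9, 0) == "on"
        assert line.classify_side(0, 25) == "on"
        assert line.classify_side(0, 0) == "below"
        assert line.classify_side(9, 25) == "above"

    def test_non_positive_intercepts_rejected(self):
        with pytest.raises(ValueError):
            boundary_line(0, 25)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 50), st.floats(0.1, 50),
        st.floats(0, 60), st.floats(0, 60), st.floats(0.01, 100),
    )
    def test_classification_invariant_under_rescaling(self, a, b, x, y, scale):
        line = boundary_line(a, b)
        scaled = boundary_line(a, b)  # same intercepts; rescale coefficients
        bb, aa, ab = (c * scale for c in line.coefficients)
        side = "on" if abs(bb * x + aa * y - ab) <= 1e-9 * max(ab, 1) else (
            "above" if bb * x + aa * y > ab else "below"
        )
        assert side == scaled.classify_side(x, y)


class TestRiskBands:
    @pytest.mark.parametrize(
        "distance, band",
        [
            (25.0, RiskBand.HIGH),
            (20.01, RiskBand.HIGH),
            (20.0, RiskBand.MODERATE),
            (15.0, RiskBand.MODERATE),
            (10.0, RiskBand.LOW),
            (0.0, RiskBand.LOW),
        ],
    )
    def test_band_edges(self, distance, band):
        assert risk_band(distance) is band

    def test_probability_annotations(self):
        assert RiskBand.HIGH.probability_note == ">90%"
        assert RiskBand.MODERATE.probability_note == "70%"
        assert RiskBand.LOW.probability_note is None

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            risk_band(-1.0)

    def test_bands_partition_the_distance_axis(self):
        for d in np.linspace(0, 40, 101):
            assert sum(risk_band(float(d)) is b for b in RiskBand) == 1


class TestBandOutcomeRates:
    def test_all_dem_gives_unit_fraction(self):
        recs = [record(pid=f"P{i}", dist=d, dx=Diagnosis.DEM)
                for i, d in enumerate([25, 15, 5])]
        table = band_outcome_rates(recs)
        assert (table["fraction_dem"] == 1.0).all()

    def test_nine_of_ten_high_band_participants_convert(self):
        recs = []
        for i in range(10):
            dx = Diagnosis.DEM if i < 9 else Diagnosis.MCI
            recs.append(record(pid=f"P{i}", dist=30.0, dx=dx))
        table = band_outcome_rates(recs, mode="by_participant")
        high = table[table.band == "high"].iloc[0]
        assert high["n_visits"] == 10
        assert high["fraction_dem"] == pytest.approx(0.9)

    def test_by_participant_counts_later_conversion(self):
        # high-band visit while still MCI; same participant converts later
        recs = [
            record(pid="P1", tj=2, dist=25.0, dx=Diagnosis.MCI),
            record(pid="P1", tj=3, dist=4.0, dx=Diagnosis.DEM),
        ]
        by_visit = band_outcome_rates(recs, mode="by_visit")
        by_participant = band_outcome_rates(recs, mode="by_participant")
        assert by_visit[by_visit.band == "high"]["fraction_dem"].iloc[0] == 0.0
        assert (
            by_participant[by_participant.band == "high"]["fraction_dem"].iloc[0]
            == 1.0
        )

    def test_visit_counts_are_conserved(self, default_cohort):
        part = cognitive_partition()
        recs = community_distances(default_cohort, part)
        table = band_outcome_rates(recs)
        assert table["n_visits"].sum() == len(recs)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            band_outcome_rates([])


class TestSexStratifiedSummary:
    def test_simple_proportion(self):
        recs = [record(pid=f"P{i}", lapse=6.0, dist=d, sex="M")
                for i, d in enumerate([1, 2, 3, 4, 5, 5, 5, 6, 7, 8])]
        table = sex_stratified_summary(recs)
        row = table[(table.sex == "M") & (table.community_id == 0)].iloc[0]
        assert row["n_visits_after_cutoff"] == 10
        assert row["pct_distance_le_dcut"] == pytest.approx(70.0)

    def test_three_female_visits(self):
        recs = [record(pid=f"P{i}", lapse=6.0, dist=d, sex="F")
                for i, d in enumerate([2, 6, 7])]
        table = sex_stratified_summary(recs)
        row = table[(table.sex == "F")].iloc[0]
        assert row["pct_distance_le_dcut"] == pytest.approx(100 / 3, abs=0.01)

    def test_empty_stratum_has_undefined_percentages(self):
        recs = [record(lapse=2.0, sex="F")]  # nothing after the 5-year cutoff
        table = sex_stratified_summary(recs)
        row = table[table.sex == "F"].iloc[0]
        assert row["n_visits_after_cutoff"] == 0
        assert np.isnan(row["pct_distance_le_dcut"])


class TestMatchCommunities:
    def _partition(self, *sets):
        return CommunityPartition(
            communities=tuple(frozenset(s) for s in sets),
            method="cnm", modularity=None,
        )

    def test_identical_partitions_match_identically(self):
        p = self._partition("ABC", "DE")
        matches = match_communities(p, p)
        assert all(m["jaccard"] == 1.0 for m in matches)
        assert [m["community_2"] for m in matches] == [0, 1]

    def test_partial_overlap_matches_by_jaccard(self):
        p1 = self._partition({"A", "B", "C"}, {"D", "E"})
        p2 = self._partition({"A", "B"}, {"C", "D", "E"})
        matches = {tuple(m["members_1"]): m for m in match_communities(p1, p2)}
        assert matches[("A", "B", "C")]["members_2"] == ["A", "B"]
        assert matches[("A", "B", "C")]["jaccard"] == pytest.approx(2 / 3)
        assert matches[("D", "E")]["members_2"] == ["C", "D", "E"]
        assert matches[("D", "E")]["jaccard"] == pytest.approx(2 / 3)

    def test_different_universes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            match_communities(self._partition("AB"), self._partition("CD"))


class TestRepresentativeCommunity:
    def test_find_community_by_member(self, default_cohort):
        part = CommunityPartition(
            communities=(COGNITIVE, frozenset(["Diabetes", "Stroke"])),
            method="cnm", modularity=None,
        )
        assert part.communities[find_community(part, "CDRGlob")] == COGNITIVE
        with pytest.raises(KeyError):
            find_community(part, "Hypertension")
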