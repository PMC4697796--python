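"""Co-focus pairing, structure categories, landmark selection."""

import math

import numpy as np
import pytest

from focipair.cofocus import (
    Category,
    Composite,
    PairRecord,
    cross_fraction_within,
    detect_pairs,
    focus_positive_fraction,
    form_composites,
    landmark_filter_and_score,
    pair_composition_fraction,
    pair_intensity_shares,
    vde_classify_nucleus,
)
from focipair.model import LandmarkRecord, ValidationError
from focipair.synthetic import (
    PairModelParams,
    constant_sampler,
    make_nucleus,
    simulate_dsb_pattern,
    uniform_sampler,
)

from conftest import brute_nn_cross, focus_row, make_foci


class TestCrossFraction:
    def test_coincident_and_disjoint_extremes(self):
        a = make_foci([focus_row(channel="RAD51", x=x) for x in (0.0, 500.0)])
        b_same = make_foci([focus_row(channel="DMC1", x=x) for x in (0.0, 500.0)])
        b_far = make_foci([focus_row(channel="DMC1", x=x) for x in (5000.0, 9000.0)])
        assert cross_fraction_within(a, b_same) == 1.0
        assert cross_fraction_within(a, b_far) == 0.0

    def test_strict_at_radius(self):
        a = make_foci([focus_row(channel="RAD51", x=0.0)])
        b = make_foci([focus_row(channel="DMC1", x=200.0)])
        assert cross_fraction_within(a, b, radius_nm=200.0) == 0.0

    def test_matches_brute_force(self, rng):
        pts_a = rng.uniform(0, 2000, size=(40, 2))
        pts_b = rng.uniform(0, 2000, size=(25, 2))
        a = make_foci([focus_row(channel="RAD51", x=x, y=y) for x, y in pts_a])
        b = make_foci([focus_row(channel="DMC1", x=x, y=y) for x, y in pts_b])
        expect = (brute_nn_cross(pts_a, pts_b) < 200.0).mean()
        assert cross_fraction_within(a, b) == pytest.approx(expect)


class TestDetectPairs:
    def test_two_composites_single_pair(self):
        foci = make_foci(
            [focus_row(channel="RAD51", x=0.0), focus_row(channel="RAD51", x=300.0)]
        )
        pairs = detect_pairs(foci)
        assert len(pairs) == 1 and pairs[0].separation_nm == pytest.approx(300.0)

    def test_mutual_nn_prevents_chains(self):
        foci = make_foci([focus_row(channel="RAD51", x=x) for x in (0.0, 300.0, 700.0)])
        pairs = detect_pairs(foci)
        assert len(pairs) == 1
        assert {m.x_nm for m in pairs[0].members} == {0.0, 300.0}

    def test_each_composite_in_at_most_one_pair(self, rng):
        pts = rng.uniform(0, 3000, size=(30, 2))
        foci = make_foci([focus_row(channel="RAD51", x=x, y=y) for x, y in pts])
        pairs = detect_pairs(foci)
        seen = set()
        for p in pairs:
            for m in p.members:
                assert m.position not in seen
                seen.add(m.position)
            assert p.separation_nm <= 400.0

    def test_truth_recovery_on_synthetic_pattern(self):
        params = PairModelParams(
            n_dsb=8,
            pair_sep_sampler=uniform_sampler(250.0, 400.0),
            cofocus_offset_sampler=constant_sampler(0.0),
            occupancy=(1.0, 0.0, 0.0, 0.0),
        )
        rng = np.random.default_rng(17)
        n_correct = n_pairs = 0
        for i in range(20):
            nucleus = make_nucleus(400.0, nucleus_id=f"n{i}")
            foci = simulate_dsb_pattern(nucleus, params, seed=rng)
            lookup = {
                (round(r.x_nm, 6), round(r.y_nm, 6)): (r.dsb_id, r.end_id)
                for r in foci.df.itertuples()
            }
            for pair in detect_pairs(foci):
                n_pairs += 1
                tags = [
                    lookup.get((round(m.x_nm, 6), round(m.y_nm, 6))) for m in pair.members
                ]
                if None not in tags and tags[0][0] == tags[1][0] and tags[0][1] != tags[1][1]:
                    n_correct += 1
        assert n_pairs > 0
        assert n_correct / n_pairs >= 0.95


class TestPairComposition:
    def _pair(self, kind_a, kind_b, ir=(1.0, 1.0), idm=(1.0, 1.0)):
        a = Composite("a", 0.0, 0.0, kind_a, ir[0], idm[0])
        b = Composite("a", 300.0, 0.0, kind_b, ir[1], idm[1])
        return PairRecord("a", (a, b), 300.0)

    def test_all_cofocus_pairs(self):
        pairs = [self._pair("co-focus", "co-focus")] * 3
        frac, table = pair_composition_fraction(pairs)
        assert frac == 1.0 and table["co+co"] == 3

    def test_table_conserves_pair_count(self):
        pairs = [
            self._pair("co-focus", "RAD51-only"),
            self._pair("DMC1-only", "DMC1-only"),
            self._pair("co-focus", "co-focus"),
        ]
        frac, table = pair_composition_fraction(pairs)
        assert sum(table.values()) == 3
        assert frac == pytest.approx(1 / 3)

    def test_empty_is_flagged_nan(self):
        frac, _ = pair_composition_fraction([])
        assert math.isnan(frac)

    def test_generative_extremes(self):
        rng = np.random.default_rng(3)
        for occ, expect in [((1.0, 0.0, 0.0, 0.0), 1.0), ((0.0, 0.5, 0.5, 0.0), 0.0)]:
            params = PairModelParams(
                n_dsb=10,
                pair_sep_sampler=constant_sampler(300.0),
                cofocus_offset_sampler=constant_sampler(50.0),
                occupancy=occ,
            )
            foci = simulate_dsb_pattern(make_nucleus(600.0), params, seed=rng)
            pairs = detect_pairs(foci)
            if pairs:
                frac, _ = pair_composition_fraction(pairs)
                assert frac == expect


class TestIntensityShares:
    def _pair(self, ra, rb, da, db):
        a = Composite("a", 0.0, 0.0, "co-focus", ra, da)
        b = Composite("a", 300.0, 0.0, "co-focus", rb, db)
        return PairRecord("a", (a, b), 300.0)

    def test_equal_intensities_give_flat_50(self):
        result = pair_intensity_shares([self._pair(2.0, 2.0, 3.0, 3.0)] * 5)
        assert (result["shares"]["rad51_share_pct"] == 50.0).all()
        assert result["slope"] == 0.0

    def test_perfect_correlation_gives_unit_slope(self):
        pairs = [self._pair(s, 100 - s, s, 100 - s) for s in (10.0, 30.0, 60.0, 90.0)]
        result = pair_intensity_shares(pairs)
        assert result["slope"] == pytest.approx(1.0, abs=1e-9)

    def test_independent_shares_give_zero_slope(self, rng):
        pairs = [
            self._pair(r, 100 - r, d, 100 - d)
            for r, d in rng.uniform(1, 99, size=(500, 2))
        ]
        result = pair_intensity_shares(pairs)
        assert abs(result["slope"]) < 0.1

    def test_missing_channel_pair_excluded(self):
        result = pair_intensity_shares([self._pair(1.0, 1.0, 0.0, 1.0)])
        assert result["n_excluded"] == 1 and len(result["shares"]) == 0


def oracle_category(foci_df, coloc_radius=200.0, link=1000.0):
    """Independent rule-table classifier: brute-force mutual-NN merge,
    BFS connected components at 1 um, then the category table."""
    rad = foci_df[foci_df.channel == "RAD51"][["x_nm", "y_nm"]].to_numpy()
    dmc = foci_df[foci_df.channel == "DMC1"][["x_nm", "y_nm"]].to_numpy()
    n_r, n_d = len(rad), len(dmc)
    if n_r + n_d == 0:
        return "NEGATIVE"
    # mutual nearest cross-channel neighbors closer than the radius merge
    comps = []
    used_r, used_d = set(), set()
    if n_r and n_d:
        for i in range(n_r):
            dists = [math.hypot(*(rad[i] - q)) for q in dmc]
            j = int(np.argmin(dists))
            back = [math.hypot(*(dmc[j] - p)) for p in rad]
            if int(np.argmin(back)) == i and dists[j] < coloc_radius:
                comps.append(0.5 * (rad[i] + dmc[j]))  # merge position irrelevant here
                used_r.add(i)
                used_d.add(j)
    comps += [rad[i] for i in range(n_r) if i not in used_r]
    comps += [dmc[j] for j in range(n_d) if j not in used_d]
    # connected components of the <= 1 um graph
    adj = {i: set() for i in range(len(comps))}
    for i in range(len(comps)):
        for j in range(i + 1, len(comps)):
            if math.hypot(*(comps[i] - comps[j])) <= link:
                adj[i].add(j)
                adj[j].add(i)
    seen, n_complexes = set(), 0
    for i in range(len(comps)):
        if i in seen:
            continue
        n_complexes += 1
        stack = [i]
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            stack.extend(adj[k] - seen)
    many = n_r > 2 or n_d > 2
    if n_complexes == 1:
        if many:
            return "III"
        return {1: "I", 2: "II"}.get(len(comps), "III")
    return "V" if many else "IV"


class TestVdeClassifier:
    def test_single_cofocus_is_category_I(self):
        foci = make_foci(
            [focus_row(channel="RAD51", x=0.0), focus_row(channel="DMC1", x=100.0)]
        )
        assert vde_classify_nucleus(foci).category == Category.I

    def test_two_composites_within_1um_is_II(self):
        foci = make_foci([focus_row(channel="RAD51", x=x) for x in (0.0, 500.0)])
        assert vde_classify_nucleus(foci).category == Category.II

    def test_rule_table_fixtures(self):
        # 3+3 within 1 um -> III; distant singles -> IV; distant with 3 -> V
        iii = make_foci(
            [focus_row(channel="RAD51", x=x) for x in (0.0, 300.0, 600.0)]
            + [focus_row(channel="DMC1", x=x, y=50.0) for x in (0.0, 300.0, 600.0)]
        )
        iv = make_foci([focus_row(channel="RAD51", x=x) for x in (0.0, 2000.0)])
        v = make_foci([focus_row(channel="RAD51", x=x) for x in (0.0, 100.0, 2500.0)])
        assert vde_classify_nucleus(iii).category == Category.III
        assert vde_classify_nucleus(iv).category == Category.IV
        assert vde_classify_nucleus(v).category == Category.V

    def test_no_foci_is_negative(self):
        foci = make_foci([focus_row(channel="ZIP1")])
        assert vde_classify_nucleus(foci).category == Category.NEGATIVE

    def test_matches_independent_oracle_on_random_nuclei(self, rng):
        for _ in range(150):
            n_r = int(rng.integers(0, 6))
            n_d = int(rng.integers(0, 6))
            rows = [
                focus_row(channel="RAD51", x=x, y=y)
                for x, y in rng.uniform(0, 4000, size=(n_r, 2))
            ] + [
                focus_row(channel="DMC1", x=x, y=y)
                for x, y in rng.uniform(0, 4000, size=(n_d, 2))
            ]
            if not rows:
                continue
            foci = make_foci(rows)
            got = vde_classify_nucleus(foci).category.value
            assert got == oracle_category(foci.df)


class TestFocusPositiveFraction:
    @pytest.mark.parametrize(
        "positive,total,percent",
        [(54, 116, 47), (49, 88, 56), (2, 47, 4), (16, 39, 41), (19, 49, 39), (0, 10, 0)],
    )
    def test_printed_percentages(self, positive, total, percent):
        frac, pct = focus_positive_fraction(positive, total)
        assert pct == percent
        assert frac == pytest.approx(positive / total)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            focus_positive_fraction(0, 0)


class TestLandmarks:
    def _dmc(self, xs):
        return make_foci([focus_row(channel="DMC1", x=x, y=50.0) for x in xs])

    def test_three_tetO_spots_ineligible(self):
        lms = [LandmarkRecord("a", "tetO", x, 0.0) for x in (0.0, 100.0, 200.0)]
        lms.append(LandmarkRecord("a", "lacO", 600.0, 0.0))
        out = landmark_filter_and_score(self._dmc([300.0]), lms)
        row = out.iloc[0]
        assert not row.eligible and "tetO" in row.reason

    def test_pair_call_with_neighbor_at_400(self):
        lms = [LandmarkRecord("a", "tetO", 0.0, 0.0), LandmarkRecord("a", "lacO", 600.0, 0.0)]
        out = landmark_filter_and_score(self._dmc([300.0, 700.0]), lms)
        row = out.iloc[0]
        assert row.eligible and row.call == "pair"

    def test_single_call_without_neighbors(self):
        lms = [LandmarkRecord("a", "tetO", 0.0, 0.0), LandmarkRecord("a", "lacO", 600.0, 0.0)]
        out = landmark_filter_and_score(self._dmc([300.0]), lms)
        assert out.iloc[0].call == "single"

    def test_too_many_neighbors_ineligible(self):
        lms = [LandmarkRecord("a", "tetO", 0.0, 0.0), LandmarkRecord("a", "lacO", 600.0, 0.0)]
        out = landmark_filter_and_score(self._dmc([300.0, 400.0, 500.0, 700.0]), lms)
        assert not out.iloc[0].eligible

    def test_tetO_split_distance(self):
        lms = [
            LandmarkRecord("a", "tetO", 0.0, 0.0),
            LandmarkRecord("a", "tetO", 400.0, 0.0),
            LandmarkRecord("a", "lacO", 800.0, 0.0),
        ]
        out = landmark_filter_and_score(self._dmc([500.0]), lms)
        assert out.iloc[0].tetO_split_nm == pytest.approx(400.0)
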