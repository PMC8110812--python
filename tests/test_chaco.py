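import numpy as np
import pandas as pd
import pytest

from strokeconn import chaco
from conftest import (
    brute_force_chaco,
    make_toy_parcellation,
    mask_from_voxels,
    random_toy_case,
)


class TestTypes:
    def test_lesion_mask_rejects_nonbinary(self):
        with pytest.raises(ValueError, match="binary"):
            chaco.LesionMask(data=np.full((2, 2, 2), 2))

    def test_lesion_volume_ml(self):
        mask = mask_from_voxels((10, 10, 10), [(i, j, k) for i in range(10) for j in range(10) for k in range(10)])
        assert mask.volume_ml == pytest.approx(1.0)

    def test_parcellation_requires_contiguous_labels(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 3
        table = pd.DataFrame({"name": ["x"], "hemisphere": ["L"], "lobe": [""]}, index=[3])
        with pytest.raises(ValueError, match="contiguous"):
            chaco.Parcellation(labels=labels, regions=table)

    def test_parcellation_requires_nonempty_regions(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        labels[0, 0, 0] = 1
        table = pd.DataFrame(
            {"name": ["a", "b"], "hemisphere": ["L", "R"], "lobe": ["", ""]}, index=[1, 2]
        )
        with pytest.raises(ValueError, match="non-empty"):
            chaco.Parcellation(labels=labels, regions=table)

    def test_streamline_min_length(self):
        with pytest.raises(ValueError, match="at least 2"):
            chaco.Tractogram(subject_id="x", streamlines=[np.array([[0, 0, 0]])])


class TestAssignEndpoints:
    def test_cross_pair_counts_both_regions(self, spec_toy):
        shape, parc, tg = spec_toy
        out = chaco.assign_endpoints(tg, parc)
        assert out.totals[1] == 2  # A: s1, s2
        assert out.totals[2] == 3  # B: s1, s2, s3

    def test_self_pair_counts_once(self):
        parc = make_toy_parcellation((4, 1, 1))
        s = np.array([[2, 0, 0], [3, 0, 0]])  # B -> B
        tg = chaco.assign_endpoints(
            chaco.Tractogram(subject_id="x", streamlines=[s]), parc
        )
        assert tg.totals[2] == 1

    def test_background_endpoint_dropped_with_diagnostic(self):
        parc = make_toy_parcellation(
            (4, 1, 1), regions=[([(0, 0, 0)], "L"), ([(3, 0, 0)], "R")]
        )
        good = np.array([[0, 0, 0], [3, 0, 0]])
        bad = np.array([[1, 0, 0], [3, 0, 0]])  # starts on background
        tg = chaco.assign_endpoints(
            chaco.Tractogram(subject_id="x", streamlines=[good, bad]), parc
        )
        assert tg.n_streamlines == 1
        assert tg.n_dropped == 1

    def test_empty_tractogram_errors(self, spec_toy):
        _, parc, _ = spec_toy
        with pytest.raises(ValueError, match="empty"):
            chaco.assign_endpoints(chaco.Tractogram(subject_id="x", streamlines=[]), parc)


class TestLesionHits:
    def test_empty_lesion_no_hits(self, spec_toy):
        shape, parc, tg = spec_toy
        assert chaco.lesion_hits(tg, mask_from_voxels(shape, [])).size == 0

    def test_full_grid_hits_all(self, spec_toy):
        shape, parc, tg = spec_toy
        full = mask_from_voxels(shape, [(x, 0, 0) for x in range(4)])
        assert list(chaco.lesion_hits(tg, full)) == [0, 1, 2]

    def test_toy_lesion_hits_exactly_s1(self, spec_toy):
        shape, parc, tg = spec_toy
        lesion = mask_from_voxels(shape, [(0, 0, 0)])
        # brute-force: only s1's path contains (0,0,0)
        expected = [
            i
            for i, s in enumerate(tg.streamlines)
            if any(tuple(v) == (0, 0, 0) for v in s)
        ]
        assert list(chaco.lesion_hits(tg, lesion)) == expected == [0]

    def test_grid_mismatch_errors(self, spec_toy):
        _, parc, tg = spec_toy
        small = mask_from_voxels((2, 1, 1), [(0, 0, 0)])
        with pytest.raises(chaco.GridMismatchError):
            chaco.lesion_hits(tg, small)


class TestChacoSingle:
    def test_spec_worked_example(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        scores = chaco.chaco_single(tg, parc, mask_from_voxels(shape, [(0, 0, 0)]))
        assert scores[1] == pytest.approx(1 / 2)
        assert scores[2] == pytest.approx(1 / 3)

    def test_empty_lesion_all_zero(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        scores = chaco.chaco_single(tg, parc, mask_from_voxels(shape, []))
        assert (scores == 0).all()

    def test_complete_disconnection_is_one(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        full = mask_from_voxels(shape, [(x, 0, 0) for x in range(4)])
        scores = chaco.chaco_single(tg, parc, full)
        assert scores[1] == 1.0 and scores[2] == 1.0

    def test_zero_total_region_flagged_nan(self):
        parc = make_toy_parcellation(
            (4, 1, 1), regions=[([(0, 0, 0)], "L"), ([(3, 0, 0)], "R")]
        )
        s = np.array([[0, 0, 0], [0, 0, 0], [1, 0, 0], [0, 0, 0]])
        tg = chaco.assign_endpoints(chaco.Tractogram("x", [s]), parc)
        scores = chaco.chaco_single(tg, parc, mask_from_voxels((4, 1, 1), [(1, 0, 0)]))
        assert np.isnan(scores[2])  # region 2 has no streamline: undefined, not 0
        assert scores[1] == 1.0


class TestChacoScore:
    def test_two_subject_mean(self, spec_toy):
        shape, parc, tg1 = spec_toy
        tg1 = chaco.assign_endpoints(tg1, parc)
        # ref2: region A total 4 with 1 hit -> 0.25
        paths = [np.array([[0, 0, 0], [2, 0, 0]])] + [
            np.array([[1, 0, 0], [2, 0, 0]]) for _ in range(3)
        ]
        tg2 = chaco.assign_endpoints(chaco.Tractogram("ref2", paths), parc)
        lesion = mask_from_voxels(shape, [(0, 0, 0)])
        assert chaco.chaco_single(tg2, parc, lesion)[1] == pytest.approx(0.25)
        prof = chaco.chaco_score(chaco.ReferenceSet([tg1, tg2]), parc, lesion)
        assert prof.scores[1] == pytest.approx((0.5 + 0.25) / 2)

    def test_identical_subjects_mean_equals_single(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        lesion = mask_from_voxels(shape, [(0, 0, 0)])
        single = chaco.chaco_single(tg, parc, lesion)
        prof = chaco.chaco_score(chaco.ReferenceSet([tg, tg, tg]), parc, lesion)
        assert np.allclose(prof.scores, single)

    def test_empty_lesion_zero_profile(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        prof = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, mask_from_voxels(shape, []))
        assert (prof.scores == 0).all()

    def test_average_linearity(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        paths = [
            np.array([[1, 0, 0], [2, 0, 0]]),
            np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]),
        ]
        tg2 = chaco.assign_endpoints(chaco.Tractogram("ref2", paths), parc)
        lesion = mask_from_voxels(shape, [(1, 0, 0)])
        prof = chaco.chaco_score(chaco.ReferenceSet([tg, tg2]), parc, lesion)
        manual = pd.concat(
            [chaco.chaco_single(tg, parc, lesion), chaco.chaco_single(tg2, parc, lesion)],
            axis=1,
        ).mean(axis=1)
        assert np.allclose(prof.scores.fillna(-1), manual.fillna(-1))


class TestRestrictHemisphere:
    def test_right_lesion_keeps_right_regions(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        lesion = mask_from_voxels(shape, [(3, 0, 0)])  # in B (R hemisphere)
        prof = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, lesion)
        restricted = chaco.restrict_to_stroke_hemisphere(prof, lesion, parc)
        assert list(restricted.scores.index) == [2]

    def test_bilateral_lesion_errors(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        lesion = mask_from_voxels(shape, [(0, 0, 0), (3, 0, 0)])
        prof = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, lesion)
        with pytest.raises(chaco.BilateralLesionError):
            chaco.restrict_to_stroke_hemisphere(prof, lesion, parc)

    def test_contralateral_streamline_still_counts(self):
        # two streamlines: one crossing L->R, one within R; right lesion hits
        # only the crossing one, which still scores for the right region
        parc = make_toy_parcellation((4, 1, 1))
        cross = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]])  # A -> B
        local = np.array([[3, 0, 0], [2, 0, 0], [3, 0, 0]])  # B -> B, avoid (2,0,0)? includes it
        tg = chaco.assign_endpoints(chaco.Tractogram("x", [cross, local]), parc)
        lesion = mask_from_voxels((4, 1, 1), [(2, 0, 0)])
        prof = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, lesion)
        restricted = chaco.restrict_to_stroke_hemisphere(prof, lesion, parc)
        # brute force: B total = 2 (cross + local), both touch (2,0,0) -> 1.0
        bf = brute_force_chaco(
            [cross, local], [(1, 2), (2, 2)], {(2, 0, 0)}, 2
        )
        assert restricted.scores[2] == pytest.approx(bf[2])


class TestChacoChange:
    def test_identical_profiles_zero(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        lesion = mask_from_voxels(shape, [(0, 0, 0)])
        prof = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, lesion)
        assert (chaco.chaco_change(prof, prof) == 0).all()

    def test_nested_lesion_nonnegative_delta(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        l1 = mask_from_voxels(shape, [(0, 0, 0)])
        l2 = mask_from_voxels(shape, [(0, 0, 0), (2, 0, 0)])
        p1 = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, l1, time="T1")
        p2 = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, l2, time="T2")
        assert (chaco.chaco_change(p1, p2) >= 0).all()

    def test_shrinkage_allows_negative(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        l1 = mask_from_voxels(shape, [(0, 0, 0)])
        l2 = mask_from_voxels(shape, [])
        p1 = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, l1, time="T1")
        p2 = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, l2, time="T2")
        assert (chaco.chaco_change(p1, p2) < 0).any()

    def test_mismatched_regions_error(self, spec_toy):
        shape, parc, tg = spec_toy
        tg = chaco.assign_endpoints(tg, parc)
        lesion = mask_from_voxels(shape, [(3, 0, 0)])
        prof = chaco.chaco_score(chaco.ReferenceSet([tg]), parc, lesion)
        restricted = chaco.restrict_to_stroke_hemisphere(prof, lesion, parc)
        with pytest.raises(ValueError, match="region sets"):
            chaco.chaco_change(prof, restricted)


class TestOracleEquivalenceAndMonotonicity:
    def test_matches_brute_force_on_random_toys(self):
        rng = np.random.default_rng(20240917)
        n_checked = 0
        for _ in range(40):
            parc, tg_raw, lesion, lesion_voxels = random_toy_case(rng)
            try:
                tg = chaco.assign_endpoints(tg_raw, parc)
            except ValueError:
                continue
            if tg.n_streamlines == 0:
                continue
            scores = chaco.chaco_single(tg, parc, lesion)
            labels = parc.labels
            endpoint_labels = [
                (int(labels[tuple(s[0])]), int(labels[tuple(s[-1])]))
                for s in tg_raw.streamlines
            ]
            expected = brute_force_chaco(
                [list(map(tuple, s)) for s in tg_raw.streamlines],
                endpoint_labels,
                lesion_voxels,
                parc.n_regions,
            )
            for r in parc.region_ids:
                if expected[r] is None:
                    assert np.isnan(scores[r])
                else:
                    assert scores[r] == pytest.approx(expected[r]), f"region {r}"
            n_checked += 1
        assert n_checked >= 20

    def test_monotone_in_lesion(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            parc, tg_raw, lesion, lesion_voxels = random_toy_case(rng)
            try:
                tg = chaco.assign_endpoints(tg_raw, parc)
            except ValueError:
                continue
            extra = {tuple(v) for v in np.argwhere(np.ones(parc.labels.shape))[:20]}
            bigger = mask_from_voxels(parc.labels.shape, lesion_voxels | extra)
            s1 = chaco.chaco_single(tg, parc, lesion)
            s2 = chaco.chaco_single(tg, parc, bigger)
            ok = ~(s1.isna() | s2.isna())
            assert (s2[ok] >= s1[ok] - 1e-12).all()
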