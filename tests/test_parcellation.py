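"""Regional scoring: weighted averages, class profiles, lobe aggregation."""

import numpy as np
import pandas as pd
import pytest

from voxsal.parcellation import (
    class_profiles,
    lobe_aggregate,
    regional_matrix,
    regional_scores,
)
from voxsal.synthetic import make_atlas, make_cohort, recovery_spec
from voxsal.types import (
    CT,
    PD,
    AreaLabel,
    GridMismatchError,
    ProbabilisticAtlas,
    SaliencyMap,
    SubjectRecord,
)


def _smap(values, sid="s"):
    return SaliencyMap(values=np.asarray(values, dtype=np.float32), subject_id=sid)


class TestRegionalScores:
    def test_constant_map_scores_the_constant_everywhere(self, small_atlas, rng):
        v = 3.7
        scores = regional_scores(_smap(np.full(small_atlas.grid_shape, v)), small_atlas)
        np.testing.assert_allclose(scores, v, rtol=1e-5)

    def test_hand_computed_weighted_average(self):
        """Probabilities {0.5, 1.0} on saliency {2, 4}: (1 + 4) / 1.5 = 10/3."""
        probs = np.zeros((1, 2, 1, 1), dtype=np.float32)
        probs[0, 0, 0, 0] = 0.5
        probs[0, 1, 0, 0] = 1.0
        atlas = ProbabilisticAtlas(
            probs=probs,
            labels=[AreaLabel(0, "a", "L", "frontal", frozenset({"net0"}))],
        )
        sal = np.array([[[2.0]], [[4.0]]], dtype=np.float32)
        scores = regional_scores(_smap(sal), atlas)
        assert scores[0] == pytest.approx(10 / 3, abs=1e-4)

    def test_probability_rescaling_leaves_score_unchanged(self, rng):
        probs = np.zeros((1, 4, 4, 4), dtype=np.float32)
        probs[0] = rng.uniform(0.05, 0.45, (4, 4, 4))
        labels = [AreaLabel(0, "a", "L", "frontal", frozenset({"net0"}))]
        sal = rng.uniform(0, 5, (4, 4, 4))
        s1 = regional_scores(_smap(sal), ProbabilisticAtlas(probs=probs, labels=labels))
        s2 = regional_scores(
            _smap(sal), ProbabilisticAtlas(probs=2 * probs, labels=labels)
        )
        assert s1[0] == pytest.approx(s2[0], rel=1e-6)

    def test_linearity_in_the_map(self, small_atlas, rng):
        m1 = rng.uniform(0, 3, small_atlas.grid_shape)
        m2 = rng.uniform(0, 3, small_atlas.grid_shape)
        a, b = 1.7, 0.4
        lhs = regional_scores(_smap(a * m1 + b * m2), small_atlas)
        rhs = a * regional_scores(_smap(m1), small_atlas) + b * regional_scores(
            _smap(m2), small_atlas
        )
        np.testing.assert_allclose(lhs, rhs, rtol=1e-4)

    def test_matches_voxel_loop_oracle(self, rng):
        """Vectorized scoring equals a literal triple-loop weighted average."""
        atlas = make_atlas(5, (8, 8, 8), 2, seed=3, blob_sigma=1.5)
        sal = rng.uniform(0, 10, (8, 8, 8))
        scores = regional_scores(_smap(sal), atlas)
        for a in range(atlas.n_areas):
            num = den = 0.0
            for i in range(8):
                for j in range(8):
                    for k in range(8):
                        p = float(atlas.probs[a, i, j, k])
                        num += p * float(np.float32(sal[i, j, k]))
                        den += p
            assert scores[a] == pytest.approx(num / den, abs=1e-10)

    def test_grid_mismatch_is_an_error(self, small_atlas):
        with pytest.raises(GridMismatchError):
            regional_scores(_smap(np.zeros((4, 4, 4))), small_atlas)


def _subjects(classes):
    return [
        SubjectRecord(id=f"s{i}", true_class=c, predicted_class=c)
        for i, c in enumerate(classes)
    ]


class TestClassProfiles:
    def test_identical_subjects_have_zero_halfwidth(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0]] * 4, index=[f"s{i}" for i in range(4)], columns=["a", "b"]
        )
        prof = class_profiles(matrix, _subjects([PD, PD, CT, CT]))
        assert (prof["halfwidth"] == 0).all()
        assert prof.loc[(PD, "a"), "mean"] == 1.0

    def test_two_subject_halfwidth_closed_form(self):
        """Scores 0 and 2: mean 1, half-width 1.96 * sd / sqrt(2) = 1.96."""
        matrix = pd.DataFrame(
            [[0.0], [2.0]], index=["s0", "s1"], columns=["a"]
        )
        prof = class_profiles(matrix, _subjects([PD, PD]))
        assert prof.loc[(PD, "a"), "mean"] == pytest.approx(1.0)
        assert prof.loc[(PD, "a"), "halfwidth"] == pytest.approx(1.96)

    def test_translation_shifts_mean_not_halfwidth(self, rng):
        vals = rng.uniform(0, 2, (6, 3))
        ids = [f"s{i}" for i in range(6)]
        m1 = pd.DataFrame(vals, index=ids, columns=list("abc"))
        m2 = m1 + 5.0
        subs = _subjects([PD] * 6)
        p1 = class_profiles(m1, subs)
        p2 = class_profiles(m2, subs)
        np.testing.assert_allclose(p2["mean"], p1["mean"] + 5.0)
        np.testing.assert_allclose(p2["halfwidth"], p1["halfwidth"], rtol=1e-9)

    def test_single_subject_class_rejected(self):
        matrix = pd.DataFrame([[1.0], [1.0]], index=["s0", "s1"], columns=["a"])
        with pytest.raises(ValueError):
            class_profiles(matrix, _subjects([PD, CT]))


class TestLobeAggregate:
    def test_singleton_lobes_reduce_to_class_profiles(self, small_atlas, rng):
        maps = [
            _smap(rng.uniform(0, 2, small_atlas.grid_shape), sid=f"s{i}")
            for i in range(4)
        ]
        matrix = regional_matrix(maps, small_atlas)
        subs = _subjects([PD, PD, CT, CT])
        prof = class_profiles(matrix, subs)
        # restrict to a lobe that holds exactly one area per hemisphere
        lobes = lobe_aggregate(matrix, small_atlas, subs)
        singles = {}
        for lab in small_atlas.labels:
            singles.setdefault((lab.lobe, lab.hemisphere), []).append(lab.name)
        for (lobe, hemi), names in singles.items():
            if len(names) != 1:
                continue
            for cls in (PD, CT):
                assert lobes.loc[(lobe, hemi, cls), "mean"] == pytest.approx(
                    prof.loc[(cls, names[0]), "mean"], rel=1e-6
                )

    def test_two_area_lobe_takes_unweighted_mean(self):
        probs = np.zeros((2, 2, 1, 1), dtype=np.float32)
        probs[0, 0] = 1.0
        probs[1, 1] = 1.0
        atlas = ProbabilisticAtlas(
            probs=probs,
            labels=[
                AreaLabel(0, "a", "L", "frontal", frozenset({"n"})),
                AreaLabel(1, "b", "L", "frontal", frozenset({"n"})),
            ],
        )
        matrix = pd.DataFrame([[1.0, 3.0], [1.0, 3.0]], index=["s0", "s1"], columns=["a", "b"])
        out = lobe_aggregate(matrix, atlas, _subjects([PD, PD]))
        assert out.loc[("frontal", "L", PD), "mean"] == pytest.approx(2.0)

    def test_unmapped_area_is_an_error(self, small_atlas):
        matrix = pd.DataFrame(
            [[1.0]], index=["s0"], columns=["not_an_area"]
        )
        with pytest.raises(ValueError, match="not_an_area"):
            lobe_aggregate(matrix, small_atlas, _subjects([PD]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_left_lateralized_effect_shows_in_lobe_profile(self, seed):
        """Planting the effect only in left-hemisphere areas of one lobe makes
        the left lobe mean exceed its right homologue, using the generator's
        intensity-deficit maps as saliency stand-ins."""
        atlas = make_atlas(12, (16, 16, 16), 3, seed=seed, blob_sigma=2.0)
        by_lobe = {}
        for lab in atlas.labels:
            by_lobe.setdefault(lab.lobe, {"L": [], "R": []})[lab.hemisphere].append(lab.index)
        lobe = next(
            (l for l, h in by_lobe.items() if h["L"] and h["R"]), None
        )
        assert lobe is not None
        effect = tuple(by_lobe[lobe]["L"])
        spec = recovery_spec(
            atlas, seed=seed, n_per_class=12, effect_areas=effect, effect_size=60.0
        )
        subjects, volumes = make_cohort(spec, atlas)
        ct_template = np.mean(
            [v.data for s, v in zip(subjects, volumes) if s.true_class == CT], axis=0
        )
        maps = []
        for s, v in zip(subjects, volumes):
            s.predicted_class = s.true_class
            deficit = np.clip(ct_template - v.data, 0, None)
            maps.append(_smap(deficit, sid=s.id))
        matrix = regional_matrix(maps, atlas)
        out = lobe_aggregate(matrix, atlas, subjects)
        assert (
            out.loc[(lobe, "L", PD), "mean"] > out.loc[(lobe, "R", PD), "mean"]
        )
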