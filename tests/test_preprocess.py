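import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longiperf.io_core import Mask, Volume
from longiperf.preprocess import (
    DegenerateIntensityError,
    normalize_structural,
    normalize_study,
    subtract_timepoints,
    subtraction_pairs,
    zscore_perfusion,
)


def _vol(data, **kw):
    return Volume(np.asarray(data, dtype=float), **kw)


def _ref_mask(shape, n=27):
    m = np.zeros(shape, dtype=bool)
    m.flat[:n] = True
    return Mask(m, role="reference")


class TestZScorePerfusion:
    def test_closed_form(self, rng):
        shape = (6, 6, 6)
        data = np.full(shape, 120.0)
        ref = _ref_mask(shape)
        # reference voxels: mean 100, SD 10
        ref_vals = rng.normal(100, 10, ref.n_voxels)
        ref_vals = (ref_vals - ref_vals.mean()) / ref_vals.std(ddof=1) * 10 + 100
        data[ref.data] = ref_vals
        z, prov = zscore_perfusion(_vol(data), ref)
        assert prov["reference_mean"] == pytest.approx(100.0)
        assert prov["reference_sd"] == pytest.approx(10.0)
        assert z.data[~ref.data] == pytest.approx(2.0)

    def test_reference_self_normalises(self, rng):
        shape = (8, 8, 8)
        data = rng.normal(50, 7, shape)
        ref = _ref_mask(shape, n=100)
        z, _ = zscore_perfusion(_vol(data), ref)
        ref_z = z.data[ref.data]
        assert abs(ref_z.mean()) < 1e-9
        assert abs(ref_z.std(ddof=1) - 1) < 1e-9

    def test_constant_reference_rejected(self):
        shape = (5, 5, 5)
        z = np.ones(shape)
        with pytest.raises(DegenerateIntensityError, match="constant reference"):
            zscore_perfusion(_vol(z), _ref_mask(shape))

    def test_too_small_reference_rejected(self, rng):
        shape = (5, 5, 5)
        with pytest.raises(DegenerateIntensityError, match="too small"):
            zscore_perfusion(_vol(rng.normal(size=shape)), _ref_mask(shape, n=5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.1, 50),
        b=st.floats(-100, 100),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        shape = (6, 6, 6)
        data = rng.normal(10, 3, shape)
        ref = _ref_mask(shape)
        z1, _ = zscore_perfusion(_vol(data), ref)
        z2, _ = zscore_perfusion(_vol(a * data + b), ref)
        np.testing.assert_allclose(z1.data, z2.data, atol=1e-8)


class TestNormalizeStructural:
    def test_lognormal_sample_standardised(self, rng):
        shape = (22, 22, 22)  # ~10^4 voxels
        data = rng.lognormal(0, 1, shape)
        brain = Mask(np.ones(shape, dtype=bool), role="brain")
        out, prov = normalize_structural(_vol(data), brain)
        inside = out.data[brain.data]
        assert abs(np.median(inside)) <= 0.05
        mad_sd = 1.4826 * np.median(np.abs(inside - np.median(inside)))
        assert abs(mad_sd - 1) <= 0.05

    def test_constant_image_rejected(self):
        shape = (5, 5, 5)
        brain = Mask(np.ones(shape, dtype=bool), role="brain")
        with pytest.raises(DegenerateIntensityError, match="zero MAD"):
            normalize_structural(_vol(np.ones(shape)), brain)

    def test_no_log_variant_idempotent(self, rng):
        shape = (10, 10, 10)
        data = rng.normal(5, 2, shape)
        brain = Mask(np.ones(shape, dtype=bool), role="brain")
        once, _ = normalize_structural(_vol(data), brain, log_transform=False)
        twice, _ = normalize_structural(once, brain, log_transform=False)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-6)

    def test_nonpositive_intensities_shifted_and_recorded(self, rng):
        shape = (8, 8, 8)
        data = rng.normal(0, 1, shape)  # contains negatives
        brain = Mask(np.ones(shape, dtype=bool), role="brain")
        _, prov = normalize_structural(_vol(data), brain)
        assert prov["shift"] > 0


class TestSubtraction:
    def _norm_study(self, tiny_cohort, sid_idx=0, tp=1):
        sid = list(tiny_cohort.subjects)[sid_idx]
        return normalize_study(tiny_cohort.subjects[sid][tp - 1].study)

    def test_identical_studies_give_zero_difference(self, tiny_cohort):
        ns1 = self._norm_study(tiny_cohort, tp=1)
        ns2 = self._norm_study(tiny_cohort, tp=2)
        same = subtract_timepoints(ns2, ns2.__class__(**{**ns2.__dict__,
                                                         "time_point": 1}))
        # difference of a study with (a tp-relabelled copy of) itself is zero
        for seq, vol in same.volumes.items():
            assert np.abs(vol.data).max() == 0.0

    def test_constant_offset_recovered(self, tiny_cohort):
        ns1 = self._norm_study(tiny_cohort, tp=1)
        ns2 = self._norm_study(tiny_cohort, tp=2)
        shifted = ns1.__class__(**{**ns1.__dict__, "time_point": 2})
        shifted.volumes = {
            k: Volume(v.data + 0.8, spacing=v.spacing) for k, v in ns1.volumes.items()
        }
        sub = subtract_timepoints(shifted, ns1)
        for vol in sub.volumes.values():
            np.testing.assert_allclose(vol.data, 0.8, atol=1e-12)

    def test_antisymmetry_and_chain_consistency(self, tiny_cohort):
        sid = list(tiny_cohort.subjects)[0]
        studies = tiny_cohort.subjects[sid]
        ns = [normalize_study(g.study) for g in studies]
        s21 = subtract_timepoints(ns[1], ns[0])
        s12_rev = subtract_timepoints(
            ns[0].__class__(**{**ns[0].__dict__, "time_point": 3}), ns[1]
        )
        for seq in s21.volumes:
            np.testing.assert_allclose(
                s21.volumes[seq].data, -s12_rev.volumes[seq].data, atol=1e-12
            )

    def test_chain_consistency_over_three_timepoints(self):
        from longiperf.synthetic_cohort import (
            CohortConfig, default_profiles, generate_subject,
        )

        cfg = CohortConfig(grid_shape=(20, 20, 20), spacing=(3, 3, 3), seed=0)
        studies = generate_subject(
            default_profiles()["PsP"], cfg, subject_seed=12, n_time_points=3
        )
        ns = {g.study.time_point: normalize_study(g.study) for g in studies}
        s21 = subtract_timepoints(ns[2], ns[1])
        s32 = subtract_timepoints(ns[3], ns[2])
        s31 = subtract_timepoints(ns[3], ns[1])
        for seq in s31.volumes:
            np.testing.assert_allclose(
                s31.volumes[seq].data,
                s32.volumes[seq].data + s21.volumes[seq].data,
                atol=1e-9,
            )

    def test_combined_mask_is_union(self, tiny_cohort):
        sid = list(tiny_cohort.subjects)[0]
        studies = tiny_cohort.subjects[sid]
        ns1, ns2 = (normalize_study(g.study) for g in studies)
        sub = subtract_timepoints(ns2, ns1)
        expected = ns1.lesion.data | ns2.lesion.data
        np.testing.assert_array_equal(sub.lesion.data, expected)

    def test_later_must_exceed_earlier(self, tiny_cohort):
        ns1 = self._norm_study(tiny_cohort, tp=1)
        with pytest.raises(ValueError, match="later > earlier"):
            subtract_timepoints(ns1, ns1)

    def test_subtraction_schedule(self):
        assert subtraction_pairs(1) == []
        assert subtraction_pairs(2) == [(2, 1)]
        assert subtraction_pairs(3) == [(2, 1), (3, 2), (3, 1)]


class TestNormalizeStudy:
    def test_provenance_complete_for_every_map(self, tiny_cohort):
        sid = list(tiny_cohort.subjects)[0]
        ns = normalize_study(tiny_cohort.subjects[sid][0].study)
        assert set(ns.provenance) == set(ns.volumes)
        for prov in ns.provenance.values():
            assert prov  # non-empty record
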