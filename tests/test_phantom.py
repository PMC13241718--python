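"""Phantom generator: geometry, determinism, cohort splitting, rater model."""

import numpy as np
import pytest

from scarseg.phantom import (
    PhantomSpec,
    default_spec_sampler,
    generate_cohort,
    generate_slice,
    simulate_rater,
    stratified_split,
    subject_burdens,
)
from scarseg.prompts import bbox_from_mask, box_iou


class TestGenerateSlice:
    def test_zero_extent_gives_empty_scar(self):
        rec = generate_slice(PhantomSpec(grid_size=64, scar_extent_deg=0.0))
        assert not rec.scar_mask.any()

    def test_noise_free_image_has_four_levels(self, clean_slice):
        assert len(np.unique(clean_slice.image)) == 4

    def test_quarter_wedge_area_ratio(self):
        spec = PhantomSpec(
            grid_size=128, pixel_spacing_mm=1.0, scar_extent_deg=90.0,
            scar_transmurality=1.0, noise_sd=0.0, bias_amplitude=0.0,
        )
        rec = generate_slice(spec)
        ratio = rec.scar_mask.sum() / rec.myo_mask.sum()
        assert 0.23 <= ratio <= 0.27

    def test_scar_contained_in_myocardium(self, noisy_slice):
        assert not (noisy_slice.scar_mask & ~noisy_slice.myo_mask).any()

    def test_determinism(self):
        spec = PhantomSpec(grid_size=64, seed=99)
        a = generate_slice(spec)
        b = generate_slice(spec)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.scar_mask, b.scar_mask)

    def test_invariant_violations_name_the_field(self):
        with pytest.raises(Exception, match="r_endo_mm"):
            PhantomSpec(r_endo_mm=30.0, r_epi_mm=20.0)
        with pytest.raises(Exception, match="intensity_scar"):
            PhantomSpec(intensity_scar=50.0, intensity_myo=80.0)
        with pytest.raises(Exception, match="scar_transmurality"):
            PhantomSpec(scar_transmurality=0.0)

    def test_spec_json_round_trip(self):
        spec = PhantomSpec(grid_size=64, center=(30.0, 32.0), seed=5)
        assert PhantomSpec.from_json(spec.to_json()) == spec


class TestCohort:
    def test_single_subject_three_slices(self):
        recs = generate_cohort(1, default_spec_sampler(grid_size=48), 3, seed=0)
        assert len(recs) == 3
        assert len({r.subject_id for r in recs}) == 1

    def test_same_seed_identical_stacks(self):
        a = generate_cohort(3, default_spec_sampler(grid_size=48), 2, seed=4)
        b = generate_cohort(3, default_spec_sampler(grid_size=48), 2, seed=4)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.image, rb.image)

    def test_fixed_spec_sampler_identical_up_to_noise(self):
        fixed = PhantomSpec(grid_size=48, noise_sd=5.0, bias_amplitude=0.0)

        def sampler(rng):
            return fixed

        recs = generate_cohort(2, sampler, 1, seed=1)
        # noise-free renders (masks) coincide even though noise differs
        assert np.array_equal(recs[0].scar_mask, recs[1].scar_mask)
        assert not np.array_equal(recs[0].image, recs[1].image)

    def test_burden_recorded(self):
        recs = generate_cohort(2, default_spec_sampler(grid_size=48), 2, seed=2)
        burdens = subject_burdens(recs)
        for r in recs:
            assert r.meta["burden"] == burdens[r.subject_id]


class TestStratifiedSplit:
    @pytest.fixture(scope="class")
    def cohort100(self):
        return generate_cohort(100, default_spec_sampler(grid_size=32), 1, seed=3)

    def test_sizes_70_15_15(self, cohort100):
        tr, va, te = stratified_split(cohort100, (0.70, 0.15, 0.15), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 15, 15)

    def test_disjoint_and_complete(self, cohort100):
        tr, va, te = stratified_split(cohort100, seed=1)
        assert not (tr & va or tr & te or va & te)
        assert len(tr | va | te) == 100

    def test_single_subject_lands_somewhere(self):
        recs = generate_cohort(1, default_spec_sampler(grid_size=32), 1, seed=0)
        with pytest.warns(UserWarning):
            tr, va, te = stratified_split(recs, n_strata=4, seed=0)
        assert len(tr) + len(va) + len(te) == 1

    def test_burden_distributions_balanced_by_rank_test(self):
        from scipy.stats import kruskal

        recs = generate_cohort(300, default_spec_sampler(grid_size=32), 1, seed=8)
        tr, va, te = stratified_split(recs, seed=8)
        burdens = subject_burdens(recs)
        groups = [[burdens[s] for s in grp] for grp in (tr, va, te)]
        _, p = kruskal(*groups)
        assert p > 0.05


class TestSimulateRater:
    def test_zero_jitter_equals_tight_bbox(self, clean_slice):
        prompt = simulate_rater(clean_slice.scar_mask, jitter=(0.0, 0.0), n_points=0, seed=0)
        assert prompt.box == bbox_from_mask(clean_slice.scar_mask, 2)

    def test_two_raters_disagree(self, clean_slice):
        a = simulate_rater(clean_slice.scar_mask, jitter=(5.0, 0.1), n_points=0, seed=1)
        b = simulate_rater(clean_slice.scar_mask, jitter=(5.0, 0.1), n_points=0, seed=2)
        assert box_iou(a.box, b.box) < 1.0

    def test_points_inside_mask(self, clean_slice):
        prompt = simulate_rater(clean_slice.scar_mask, n_points=4, seed=3)
        for r, c in prompt.points:
            assert clean_slice.scar_mask[r, c]

    def test_empty_mask_raises(self):
        with pytest.raises(Exception):
            simulate_rater(np.zeros((16, 16), bool))

    def test_mean_axis_displacement_matches_folded_normal(self):
        """Per-axis box displacement |N(0, 5)| (rounded) should match the
        folded-normal mean 5*sqrt(2/pi) within 3 standard errors."""
        mask = np.zeros((200, 200), bool)
        mask[80:120, 80:120] = True
        base = bbox_from_mask(mask, 2)
        sd = 5.0
        n = 10_000
        disp = []
        for s in range(n):
            p = simulate_rater(mask, jitter=(sd, 0.0), n_points=0, seed=s)
            disp.append(abs(p.box[0] - base[0]))
        mean = np.mean(disp)
        folded_mean = sd * np.sqrt(2 / np.pi)
        folded_sd = sd * np.sqrt(1 - 2 / np.pi)
        assert abs(mean - folded_mean) < 3 * folded_sd / np.sqrt(n) + 0.01  # +rounding
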