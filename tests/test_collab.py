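"""Collaborative-filter mechanics, including brute-force oracle equivalence."""

import math

import numpy as np
import pytest

from cryopick.collab import (FilterConfig, apply_filters, collaborative_pick,
                             confidence_filter, extract_particles,
                             semantic_consistency_filter, size_filter)
from cryopick.proposals import InstanceProposal

CFG = FilterConfig()


# -- independent brute-force implementation of the three printed rules --------

def _oracle_filters(props, sem_mask, cfg):
    """Straight-line re-implementation used only as a test oracle."""
    from scipy import ndimage

    survivors = [p for p in props if p.score >= cfg.tau_conf]

    if len(survivors) >= 3:
        diags = sorted(p.diagonal for p in survivors)
        n = len(diags)
        med = (diags[n // 2] if n % 2 else 0.5 * (diags[n // 2 - 1] + diags[n // 2]))
        mean = sum(diags) / n
        sd = math.sqrt(sum((d - mean) ** 2 for d in diags) / n)
        survivors = [
            p for p in survivors if abs(p.diagonal - med) <= cfg.k_diag * sd
        ]
    out = []
    for p in survivors:
        w, h = p.bbox[2] - p.bbox[0], p.bbox[3] - p.bbox[1]
        if p.area >= cfg.min_area and max(w / h, h / w) <= cfg.max_aspect:
            out.append(p)
    survivors = out

    labels, n = ndimage.label(sem_mask)
    out = []
    for p in survivors:
        touched = set(np.unique(labels[p.mask])) - {0}
        if not touched:
            continue
        comp = np.isin(labels, list(touched))
        inter = np.logical_and(p.mask, comp).sum()
        union = np.logical_or(p.mask, comp).sum()
        if union and inter / union >= cfg.tau_sem:
            out.append(p)
    return out


def _random_proposals(rng, shape=(48, 48), n_max=20):
    props = []
    for _ in range(int(rng.integers(0, n_max + 1))):
        r = int(rng.integers(2, 7))
        cx = int(rng.integers(r, shape[1] - r))
        cy = int(rng.integers(r, shape[0] - r))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
        # occasionally stretch into an elongated box to hit the aspect rule
        if rng.random() < 0.2:
            mask = np.zeros(shape, dtype=bool)
            w = int(rng.integers(2, 5))
            h = int(rng.integers(8, 16))
            mask[cy : min(cy + h, shape[0]), cx : min(cx + w, shape[1])] = True
        props.append(InstanceProposal.from_mask(mask, float(rng.random())))
    return props


def _ids(props):
    return {id(p) for p in props}


class TestConfidenceFilter:
    def test_threshold_is_inclusive(self, proposal_factory):
        shape = (32, 32)
        props = [
            proposal_factory(shape, 8, 8, 3, s) for s in (0.9, 0.85, 0.80, 0.7)
        ]
        kept = confidence_filter(props, CFG)
        assert [p.score for p in kept] == [0.9, 0.85, 0.80]

    def test_zero_threshold_is_identity(self, proposal_factory):
        props = [proposal_factory((32, 32), 8, 8, 3, 0.1)]
        assert confidence_filter(props, FilterConfig(tau_conf=0.0)) == props

    def test_empty_input(self):
        assert confidence_filter([], CFG) == []


class TestSizeFilter:
    def _prop_with_diag(self, side):
        """A square proposal whose bbox diagonal is side*sqrt(2)."""
        mask = np.zeros((64, 64), dtype=bool)
        mask[1 : 1 + side, 1 : 1 + side] = True
        return InstanceProposal.from_mask(mask, 1.0)

    def test_outlier_diagonal_removed_with_k1(self):
        # bbox sides 10/11/12/40 -> diagonals d*sqrt(2); with k=1 the
        # outlier exceeds one standard deviation from the median
        props = [self._prop_with_diag(s) for s in (10, 11, 12, 40)]
        cfg = FilterConfig(k_diag=1.0, min_area=1, max_aspect=10.0)
        diags = np.array([p.diagonal for p in props])
        med, sd = np.median(diags), diags.std()
        assert abs(props[-1].diagonal - med) > sd  # the planted outlier
        kept = size_filter(props, cfg)
        assert _ids(kept) == _ids(props[:3])

    def test_equal_diagonals_all_kept(self):
        props = [self._prop_with_diag(9) for _ in range(4)]
        kept = size_filter(props, FilterConfig(min_area=1))
        assert len(kept) == 4

    def test_below_three_skips_diagonal_rule(self):
        # a wild outlier pair survives because sigma is degenerate
        props = [self._prop_with_diag(4), self._prop_with_diag(40)]
        kept = size_filter(props, FilterConfig(min_area=1, max_aspect=2.5))
        assert len(kept) == 2

    def test_area_and_aspect_still_apply(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[2:4, 2:30] = True  # aspect 14
        p = InstanceProposal.from_mask(mask, 1.0)
        assert size_filter([p], CFG) == []


class TestSemanticConsistency:
    def test_identical_component_kept(self, proposal_factory):
        p = proposal_factory((64, 64), 20, 20, 6, 1.0)
        kept = semantic_consistency_filter([p], p.mask, CFG)
        assert kept == [p]

    def test_disjoint_removed(self, proposal_factory):
        p = proposal_factory((64, 64), 20, 20, 6, 1.0)
        sem = np.zeros((64, 64), dtype=bool)
        sem[50:60, 50:60] = True
        assert semantic_consistency_filter([p], sem, CFG) == []

    def test_half_overlap_subset_iou(self):
        # proposal of area 100 inside a component of area 200 -> IoU 0.5
        prop_mask = np.zeros((64, 64), dtype=bool)
        prop_mask[10:20, 10:20] = True  # 100 px
        sem = np.zeros((64, 64), dtype=bool)
        sem[10:20, 10:30] = True  # 200 px containing the proposal
        p = InstanceProposal.from_mask(prop_mask, 1.0)
        kept = semantic_consistency_filter([p], sem, CFG)
        assert kept == [p]  # 0.5 >= 0.30
        kept = semantic_consistency_filter([p], sem, FilterConfig(tau_sem=0.51))
        assert kept == []

    def test_frame_mismatch_raises(self, proposal_factory):
        p = proposal_factory((64, 64), 20, 20, 6, 1.0)
        with pytest.raises(ValueError):
            semantic_consistency_filter([p], np.zeros((32, 32), bool), CFG)


class TestExtractParticles:
    def test_circular_mask_recovers_center_and_radius(self, proposal_factory):
        p = proposal_factory((256, 256), 100, 100, 10, 0.9)
        pset = extract_particles([p], (256, 256), (256, 256), CFG)
        got = pset.particles[0]
        assert got.x == pytest.approx(100, abs=0.5)
        assert got.y == pytest.approx(100, abs=0.5)
        assert got.radius == pytest.approx(10, abs=0.5)
        assert got.confidence == pytest.approx(0.9)

    def test_empty_list(self):
        pset = extract_particles([], (256, 256), (256, 256), CFG)
        assert len(pset) == 0

    def test_upscaling_doubles_coordinates_and_radius(self, proposal_factory):
        p = proposal_factory((256, 256), 100, 100, 10, 0.9)
        pset = extract_particles([p], (512, 512), (256, 256), CFG)
        got = pset.particles[0]
        assert got.x == pytest.approx(200, abs=1.0)
        assert got.radius == pytest.approx(20, abs=1.0)

    def test_duplicate_centers_keep_higher_score(self, proposal_factory):
        a = proposal_factory((256, 256), 100, 100, 10, 0.95)
        b = proposal_factory((256, 256), 101, 100, 10, 0.85)
        pset = extract_particles([a, b], (256, 256), (256, 256), CFG)
        assert len(pset) == 1
        assert pset.particles[0].confidence == pytest.approx(0.95)


class TestCollaborativePick:
    def test_ideal_inputs_recover_planted_particles(self, clean_scene):
        props = [
            InstanceProposal.from_mask(m, 1.0)
            for m in clean_scene.gt_instance_masks
        ]
        prob = clean_scene.gt_mask.astype(float)
        picks = collaborative_pick(prob, props, clean_scene.gt_mask.shape, CFG)
        assert len(picks) == len(clean_scene.gt_particles)
        for got, want in zip(
            sorted(picks, key=lambda p: (p.x, p.y)),
            sorted(clean_scene.gt_particles, key=lambda p: (p.x, p.y)),
        ):
            assert math.hypot(got.x - want.x, got.y - want.y) < 1.0

    def test_low_confidence_contaminants_removed_by_first_stage(
        self, clean_scene, proposal_factory
    ):
        shape = clean_scene.gt_mask.shape
        props = [
            InstanceProposal.from_mask(m, 1.0)
            for m in clean_scene.gt_instance_masks
        ]
        bait = [
            proposal_factory(shape, 30 + 40 * i, 30, 5, 0.6) for i in range(5)
        ]
        prob = clean_scene.gt_mask.astype(float)
        picks = collaborative_pick(prob, props + bait, shape, CFG)
        assert len(picks) == len(clean_scene.gt_particles)
        # oracle: stage-by-stage evaluation agrees
        kept = confidence_filter(props + bait, CFG)
        assert _ids(kept) == _ids(props)

    def test_oracle_equivalence_on_random_sets(self, rng):
        """>=200 random proposal sets match an independent brute force."""
        shape = (48, 48)
        for trial in range(200):
            props = _random_proposals(rng, shape)
            sem = np.zeros(shape, dtype=bool)
            for _ in range(int(rng.integers(0, 5))):
                r = int(rng.integers(2, 8))
                cx, cy = rng.integers(r, 48 - r, size=2)
                yy, xx = np.mgrid[0:48, 0:48]
                sem |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
            cfg = FilterConfig(
                min_area=int(rng.integers(1, 30)),
                k_diag=float(rng.uniform(0.5, 3.0)),
            )
            got = apply_filters(props, sem, cfg)
            want = _oracle_filters(props, sem, cfg)
            assert _ids(got) == _ids(want), f"trial {trial} diverged"

    def test_stages_are_contractions(self, rng):
        shape = (48, 48)
        for _ in range(30):
            props = _random_proposals(rng, shape)
            sem = rng.random(shape) > 0.7
            s1 = confidence_filter(props, CFG)
            s2 = size_filter(s1, CFG)
            s3 = semantic_consistency_filter(s2, sem, CFG)
            assert _ids(s1) <= _ids(props)
            assert _ids(s2) <= _ids(s1)
            assert _ids(s3) <= _ids(s2)

    def test_threshold_monotonicity(self, rng):
        shape = (48, 48)
        for _ in range(30):
            props = _random_proposals(rng, shape)
            sem = rng.random(shape) > 0.7
            base = len(apply_filters(props, sem, CFG))
            for tau_conf in (0.85, 0.95):
                n = len(apply_filters(props, sem,
                                      FilterConfig(tau_conf=tau_conf)))
                assert n <= base
            for tau_sem in (0.5, 0.8):
                n = len(apply_filters(props, sem,
                                      FilterConfig(tau_sem=tau_sem)))
                assert n <= base

    def test_order_invariance(self, rng):
        shape = (48, 48)
        props = _random_proposals(rng, shape)
        sem = rng.random(shape) > 0.7
        a = apply_filters(props, sem, CFG)
        perm = list(props)
        rng.shuffle(perm)
        b = apply_filters(perm, sem, CFG)
        assert _ids(a) == _ids(b)
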