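"""Potentials, joint maximization (exhaustive vs belief propagation),
stitching, and the end-to-end single-image reconstruction."""

import itertools

import numpy as np
import pytest

from exsr.database import build_database, segment, upsample
from exsr.grid import INPUT_GEOMETRY, CanvasGeometry, ImageGrid
from exsr.mrf import (
    Assignment,
    InferenceConfig,
    MRFProblem,
    connectivity_potential,
    core_overlap,
    evidence_potential,
    maximize_joint,
    reconstruct,
    stitch,
)
from exsr.simulate import LR_WIDTH_NM, SR_WIDTH_NM, make_single_set, render_filaments


def random_problem(rng, shape, max_labels=4):
    """A random grid MRF with independent normal potentials."""
    n_rows, n_cols = shape
    evidence, pairwise = {}, {}
    sizes = {}
    for i in range(n_rows):
        for j in range(n_cols):
            sizes[(i, j)] = int(rng.integers(2, max_labels + 1))
            evidence[(i, j)] = rng.normal(size=sizes[(i, j)])
    for i in range(n_rows):
        for j in range(n_cols):
            if j + 1 < n_cols:
                pairwise[((i, j), (i, j + 1))] = rng.normal(
                    size=(sizes[(i, j)], sizes[(i, j + 1)])
                )
            if i + 1 < n_rows:
                pairwise[((i, j), (i + 1, j))] = rng.normal(
                    size=(sizes[(i, j)], sizes[(i + 1, j)])
                )
    return MRFProblem(shape, evidence, pairwise)


def enumerate_scores(problem):
    """Independent oracle: score every assignment by direct summation."""
    nodes = [(i, j) for i in range(problem.shape[0]) for j in range(problem.shape[1])]
    results = []
    for combo in itertools.product(*(range(problem.n_labels(n)) for n in nodes)):
        lab = dict(zip(nodes, combo))
        s = sum(problem.evidence[n][lab[n]] for n in nodes)
        for (u, v), w in problem.pairwise.items():
            s += w[lab[u], lab[v]]
        results.append((s, combo))
    return results


class TestPotentials:
    def test_identical_patches_score_zero(self, rng):
        p = rng.random((21, 21))
        assert evidence_potential(p, p) == 0.0

    def test_single_pixel_difference(self):
        a = np.zeros((5, 5))
        b = a.copy()
        b[2, 2] = 1.0
        assert evidence_potential(a, b, sigma1=1.0) == pytest.approx(-0.5)

    def test_ranking_matches_squared_distance(self, rng):
        """Evidence ordering over 50 random candidates equals the ordering
        by exhaustively computed squared distances."""
        p = rng.random((7, 7))
        cands = rng.random((50, 7, 7))
        scores = [evidence_potential(p, c) for c in cands]
        d2 = [((p - c) ** 2).sum() for c in cands]
        np.testing.assert_array_equal(np.argsort(scores), np.argsort(d2)[::-1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            evidence_potential(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_connectivity_identical_overlap_is_zero(self, rng):
        sr = rng.random((15, 15))
        ov = core_overlap((0, 0), (0, 12), 15)
        assert connectivity_potential(sr, sr[:, :] * 0 + sr, ov) <= 0.0
        # patches cut from one global image agree exactly on the overlap
        big = rng.random((15, 27))
        a, b = big[:, :15], big[:, 12:]
        assert connectivity_potential(a, b, ov) == 0.0

    def test_connectivity_symmetric(self, rng):
        a, b = rng.random((15, 15)), rng.random((15, 15))
        ov_ij = core_overlap((0, 0), (0, 12), 15)
        ov_ji = core_overlap((0, 12), (0, 0), 15)
        assert connectivity_potential(a, b, ov_ij) == pytest.approx(
            connectivity_potential(b, a, ov_ji)
        )

    def test_hand_computed_toy_overlap(self):
        """2 x 3 overlap with pixel differences 1 and 2: sum of squares is
        1 + 4 = 5, so log-theta = -5 / (2 sigma2^2)."""
        from exsr.mrf import OverlapRegion

        a = np.zeros((2, 4))
        b = np.zeros((2, 4))
        a[0, 1] = 1.0  # overlap covers columns 1..3 of a, 0..2 of b
        b[1, 2] = 2.0
        ov = OverlapRegion(rows_i=slice(0, 2), cols_i=slice(1, 4),
                           rows_j=slice(0, 2), cols_j=slice(0, 3))
        assert ov.shape() == (2, 3)
        assert connectivity_potential(a, b, ov, sigma2=1.0) == pytest.approx(-2.5)
        assert connectivity_potential(a, b, ov, sigma2=2.0) == pytest.approx(-5 / 8)

    def test_default_input_geometry_core_overlap_is_15x3(self):
        ov = core_overlap((10, 0), (10, 12), 15)
        assert ov.shape() == (15, 3)


class TestMaximizeJoint:
    def test_single_node_takes_max_evidence(self):
        problem = MRFProblem((1, 1), {(0, 0): np.array([-2.0, -0.5, -1.0])}, {})
        for opt in ("exhaustive", "bp"):
            a = maximize_joint(problem, InferenceConfig(optimizer=opt))
            assert a.labels[0, 0] == 1
            assert a.joint_log_score == pytest.approx(-0.5)

    def test_bp_matches_exhaustive_on_2x2(self, rng):
        """BP decoding attains the true argmax score on a 2 x 2 grid with
        3 labels per node (81 combinations)."""
        problem = random_problem(rng, (2, 2), max_labels=3)
        ex = maximize_joint(problem, InferenceConfig(optimizer="exhaustive"))
        bp = maximize_joint(problem, InferenceConfig(optimizer="bp"))
        best = max(s for s, _ in enumerate_scores(problem))
        assert ex.joint_log_score == pytest.approx(best)
        assert bp.joint_log_score == pytest.approx(best, abs=1e-9)

    def test_bp_exact_on_chains(self):
        """Max-product is exact on trees: on 1 x N grids the BP decode
        equals the exhaustive argmax exactly."""
        rng = np.random.default_rng(7)
        for n in (2, 3, 5, 8):
            problem = random_problem(rng, (1, n), max_labels=4)
            ex = maximize_joint(problem, InferenceConfig(optimizer="exhaustive"))
            bp = maximize_joint(problem, InferenceConfig(optimizer="bp"))
            assert bp.joint_log_score == pytest.approx(ex.joint_log_score)
            np.testing.assert_array_equal(bp.labels, ex.labels)

    def test_bp_near_optimal_on_loopy_grids(self):
        """On 30 random grids up to 3 x 3 with up to 4 labels, the BP score
        reaches at least 99% of the exhaustive optimum's score range."""
        rng = np.random.default_rng(123)
        shapes = [(2, 2), (2, 3), (3, 3)]
        for trial in range(30):
            problem = random_problem(rng, shapes[trial % len(shapes)])
            scores = [s for s, _ in enumerate_scores(problem)]
            best, worst = max(scores), min(scores)
            bp = maximize_joint(problem, InferenceConfig(optimizer="bp"))
            assert bp.joint_log_score >= worst + 0.99 * (best - worst)

    def test_constant_pairwise_reduces_to_evidence_argmax(self, rng):
        problem = random_problem(rng, (2, 3))
        for key, w in problem.pairwise.items():
            problem.pairwise[key] = np.full_like(w, -1.3)
        bp = maximize_joint(problem, InferenceConfig(optimizer="bp"))
        for node, ev in problem.evidence.items():
            assert bp.labels[node] == int(np.argmax(ev))

    def test_score_recompute_matches_stored(self, rng):
        problem = random_problem(rng, (3, 3))
        a = maximize_joint(problem, InferenceConfig(optimizer="bp"))
        assert problem.score(a.labels) == a.joint_log_score

    def test_monotone_in_evidence(self, rng):
        """Raising one candidate's evidence never lowers the optimum."""
        problem = random_problem(rng, (2, 2), max_labels=3)
        base = maximize_joint(problem, InferenceConfig(optimizer="exhaustive"))
        problem.evidence[(0, 1)] = problem.evidence[(0, 1)].copy()
        problem.evidence[(0, 1)][0] += 2.0
        bumped = maximize_joint(problem, InferenceConfig(optimizer="exhaustive"))
        assert bumped.joint_log_score >= base.joint_log_score

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\)"):
            MRFProblem((1, 2), {(0, 0): np.array([0.0]), (0, 1): np.array([])}, {})

    def test_exhaustive_cap_enforced(self, rng):
        problem = random_problem(rng, (3, 3), max_labels=4)
        with pytest.raises(ValueError, match="cap"):
            maximize_joint(
                problem, InferenceConfig(optimizer="exhaustive", exhaustive_cap=10)
            )


class TestStitch:
    def _grid_and_candidates(self, img, k=1):
        from exsr.database import CandidateSet

        grid = segment(img, INPUT_GEOMETRY)
        m, core = INPUT_GEOMETRY.core_margin_px, INPUT_GEOMETRY.pairing_core_px
        sets = {}
        for i, r0 in enumerate(grid.row_starts):
            for j, c0 in enumerate(grid.col_starts):
                patch = img.data[r0 + m : r0 + m + core, c0 + m : c0 + m + core]
                sets[(i, j)] = CandidateSet(
                    node_id=(i, j),
                    indices=np.zeros(k, dtype=int),
                    lr_patches=np.repeat(grid.patches[i, j][None], k, axis=0),
                    sr_patches=np.repeat(patch[None], k, axis=0),
                    sq_distances=np.zeros(k),
                )
        return grid, sets

    def test_consistent_patches_reassemble_the_image(self, rng):
        """When every node's chosen patch is cut from one global image,
        stitching reproduces that image on the covered region."""
        img = ImageGrid(rng.random((45, 45)), 32.0)
        grid, sets = self._grid_and_candidates(img)
        labels = np.zeros((grid.n_rows, grid.n_cols), dtype=np.intp)
        out = stitch(Assignment(labels, 0.0, "exhaustive"), grid, sets)
        m = INPUT_GEOMETRY.core_margin_px
        covered = slice(m, 45 - m)
        np.testing.assert_allclose(out.data[covered, covered],
                                   img.data[covered, covered], rtol=1e-12)

    def test_overlap_averages_two_values(self):
        """A column covered by patches holding values a and b stitches to
        their mean."""
        from exsr.database import CandidateSet

        img = ImageGrid(np.zeros((21, 33)), 32.0)  # two nodes, one overlap
        grid = segment(img, INPUT_GEOMETRY)
        assert (grid.n_rows, grid.n_cols) == (1, 2)
        sets = {}
        for j, val in enumerate((1.0, 3.0)):
            sets[(0, j)] = CandidateSet(
                node_id=(0, j),
                indices=np.zeros(1, dtype=int),
                lr_patches=np.zeros((1, 21, 21)),
                sr_patches=np.full((1, 15, 15), val),
                sq_distances=np.zeros(1),
            )
        labels = np.zeros((1, 2), dtype=np.intp)
        out = stitch(Assignment(labels, 0.0, "bp"), grid, sets)
        # columns 15..18 are covered by both cores (anchors 3 and 15)
        np.testing.assert_allclose(out.data[5, 15:18], 2.0)
        np.testing.assert_allclose(out.data[5, 5:15], 1.0)
        np.testing.assert_allclose(out.data[5, 18:28], 3.0)


@pytest.fixture(scope="module")
def probe():
    lr_canvas = CanvasGeometry(12, 12, 160.0)
    sr_canvas = CanvasGeometry(60, 60, 32.0)
    examples = make_single_set(
        angle_stop_deg=135.0, angle_step_deg=45.0,
        lr_canvas=lr_canvas, sr_canvas=sr_canvas,
    )
    db = build_database(examples)
    lr = examples[0].lr  # an input the database has seen
    truth = examples[0].sr
    return db, lr, truth


class TestReconstruct:

    def test_beats_bicubic_on_known_structure(self, probe):
        """For an input whose structure is in the database, the inferred
        image is closer to the true SR object than bicubic up-sampling."""
        from exsr.evaluate import ssim

        db, lr, truth = probe
        sr = reconstruct(lr, db, InferenceConfig(k_candidates=10))
        assert ssim(sr, truth) > ssim(upsample(lr, 5), truth)

    def test_deterministic(self, probe):
        db, lr, _ = probe
        cfg = InferenceConfig(k_candidates=5)
        a = reconstruct(lr, db, cfg)
        b = reconstruct(lr, db, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_input_smaller_than_patch_rejected(self, probe):
        db, _, _ = probe
        small = ImageGrid(np.ones((3, 3)), 160.0)
        with pytest.raises(ValueError, match="smaller"):
            reconstruct(small, db)

    def test_pixel_size_mismatch_rejected(self, probe):
        db, lr, _ = probe
        wrong = ImageGrid(lr.data, 100.0)
        with pytest.raises(ValueError, match="pixel size"):
            reconstruct(wrong, db)
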