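"""Two-step patch inference on a Markov random field.

Every patch of the (up-sampled) input image is a node of a 4-connected
grid; its labels are the top-k database candidates.  The evidence
potential scores how well a candidate's LR patch matches the input patch,

    psi_i(x_i) = exp(-|p - L(x_i)|^2 / (2 sigma1^2)),

and the connectivity potential scores how smoothly the SR patches of
neighbouring nodes join across their overlapping region,

    theta_ij(x_i, x_j) = exp(-|O_ij(S(x_i)) - O_ji(S(x_j))|^2 / (2 sigma2^2)).

The assignment maximizing the joint probability
``P(x) ~ prod_i psi_i prod_(ij) theta_ij`` is found either by exhaustive
enumeration (small grids only) or by damped max-product loopy belief
propagation; the chosen SR patches are then stitched into the output
image, averaging where they overlap.  All scores are handled in the log
domain, so the (constant) normalization factor of P(x) never needs to be
computed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .database import CandidateSet, PatchDatabase, PatchGrid, segment, upsample
from .grid import INPUT_GEOMETRY, ImageGrid, SegmentationGeometry

__all__ = [
    "InferenceConfig",
    "OverlapRegion",
    "Assignment",
    "MRFProblem",
    "evidence_potential",
    "connectivity_potential",
    "core_overlap",
    "maximize_joint",
    "stitch",
    "reconstruct",
    "reconstruct_upsampled",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Inference parameters.

    ``sigma1`` and ``sigma2`` are the Gaussian scales of the evidence and
    connectivity potentials (both 1 by default, on the normalized unit-peak
    intensity scale).  ``k_candidates`` is the number of database matches
    retained per node.
    """

    sigma1: float = 1.0
    sigma2: float = 1.0
    k_candidates: int = 30
    optimizer: str = "bp"
    bp_max_iters: int = 50
    bp_damping: float = 0.5
    bp_tol: float = 1e-9
    exhaustive_cap: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sigma1 > 0 and self.sigma2 > 0):
            raise ValueError("sigma1 and sigma2 must be positive")
        if self.k_candidates < 1:
            raise ValueError("k_candidates must be >= 1")
        if self.optimizer not in ("bp", "exhaustive"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not 0.0 <= self.bp_damping < 1.0:
            raise ValueError("bp_damping must be in [0, 1)")


def evidence_potential(
    input_patch: np.ndarray, candidate_lr_patch: np.ndarray, sigma1: float = 1.0
) -> float:
    """log psi: minus the squared pixel distance over ``2 sigma1^2``."""
    p = np.asarray(input_patch, dtype=np.float64)
    q = np.asarray(candidate_lr_patch, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"patch shapes differ: {p.shape} vs {q.shape}")
    return float(-((p - q) ** 2).sum() / (2.0 * sigma1**2))


@dataclass(frozen=True)
class OverlapRegion:
    """Index windows of two neighbouring SR patches covering the same area."""

    rows_i: slice
    cols_i: slice
    rows_j: slice
    cols_j: slice

    def shape(self) -> tuple[int, int]:
        return (
            self.rows_i.stop - self.rows_i.start,
            self.cols_i.stop - self.cols_i.start,
        )


def core_overlap(
    pos_i: tuple[int, int], pos_j: tuple[int, int], core_px: int
) -> OverlapRegion | None:
    """Overlap windows of two ``core_px`` SR patches at global anchors.

    Returns None when the patches do not intersect.
    """
    ri, ci = pos_i
    rj, cj = pos_j
    r0, r1 = max(ri, rj), min(ri + core_px, rj + core_px)
    c0, c1 = max(ci, cj), min(ci + core_px, cj + core_px)
    if r0 >= r1 or c0 >= c1:
        return None
    return OverlapRegion(
        rows_i=slice(r0 - ri, r1 - ri),
        cols_i=slice(c0 - ci, c1 - ci),
        rows_j=slice(r0 - rj, r1 - rj),
        cols_j=slice(c0 - cj, c1 - cj),
    )


def connectivity_potential(
    sr_i: np.ndarray,
    sr_j: np.ndarray,
    overlap: OverlapRegion,
    sigma2: float = 1.0,
) -> float:
    """log theta: minus the squared difference over the shared overlap."""
    a = np.asarray(sr_i, dtype=np.float64)[overlap.rows_i, overlap.cols_i]
    b = np.asarray(sr_j, dtype=np.float64)[overlap.rows_j, overlap.cols_j]
    if a.shape != b.shape or a.size == 0:
        raise ValueError("invalid overlap windows")
    return float(-((a - b) ** 2).sum() / (2.0 * sigma2**2))


@dataclass
class Assignment:
    """One chosen candidate per grid node plus the joint log-score."""

    labels: np.ndarray  # (n_rows, n_cols) candidate indices
    joint_log_score: float
    optimizer: str
    iterations: int = 0
    converged: bool = True


@dataclass
class MRFProblem:
    """A grid MRF in log domain: per-node evidence vectors and per-edge
    pairwise matrices keyed by their node-id pair."""

    shape: tuple[int, int]
    evidence: dict  # (i, j) -> 1-D array over labels
    pairwise: dict  # ((i1,j1), (i2,j2)) -> (K1, K2) matrix

    def __post_init__(self) -> None:
        n_rows, n_cols = self.shape
        for i in range(n_rows):
            for j in range(n_cols):
                ev = self.evidence.get((i, j))
                if ev is None or len(ev) == 0:
                    raise ValueError(f"node {(i, j)} has an empty candidate set")

    def n_labels(self, node: tuple[int, int]) -> int:
        return len(self.evidence[node])

    def edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        return list(self.pairwise.keys())

    def edge_matrix(self, u, v) -> np.ndarray:
        if (u, v) in self.pairwise:
            return self.pairwise[(u, v)]
        return self.pairwise[(v, u)].T

    def score(self, labels: np.ndarray) -> float:
        """Joint log-score of a full assignment."""
        s = 0.0
        n_rows, n_cols = self.shape
        for i in range(n_rows):
            for j in range(n_cols):
                s += self.evidence[(i, j)][labels[i, j]]
        for (u, v), w in self.pairwise.items():
            s += w[labels[u], labels[v]]
        return float(s)


def _exhaustive(problem: MRFProblem, cap: int) -> Assignment:
    nodes = [
        (i, j) for i in range(problem.shape[0]) for j in range(problem.shape[1])
    ]
    sizes = [problem.n_labels(n) for n in nodes]
    total = math.prod(sizes)
    if total > cap:
        raise ValueError(
            f"{total} label combinations exceed the exhaustive cap {cap}; "
            "use the bp optimizer"
        )
    best_score = -np.inf
    best = None
    labels = np.zeros(problem.shape, dtype=np.intp)
    for combo in itertools.product(*(range(s) for s in sizes)):
        for n, lab in zip(nodes, combo):
            labels[n] = lab
        s = problem.score(labels)
        if s > best_score:  # strict: first (lexicographically lowest) max wins
            best_score = s
            best = labels.copy()
    return Assignment(best, best_score, "exhaustive")


def _bp(problem: MRFProblem, config: InferenceConfig) -> Assignment:
    """Damped max-product loopy BP with max-normalized messages.

    Messages are updated sequentially (in place, in a fixed scan order),
    which settles loopy graphs far more reliably than a synchronous
    sweep.  Beliefs are decoded after every sweep and the best-scoring
    assignment seen is returned, so an oscillating instance still yields
    the strongest decoding encountered (anytime decoding).  On trees the
    messages converge and the decoding is the exact joint maximum.
    """
    neighbours: dict = {}
    for u, v in problem.edges():
        neighbours.setdefault(u, []).append(v)
        neighbours.setdefault(v, []).append(u)
    nodes = [
        (i, j) for i in range(problem.shape[0]) for j in range(problem.shape[1])
    ]
    messages = {}
    for u in nodes:
        for v in neighbours.get(u, []):
            messages[(u, v)] = np.zeros(problem.n_labels(v))

    def decode() -> np.ndarray:
        labels = np.zeros(problem.shape, dtype=np.intp)
        for u in nodes:
            belief = problem.evidence[u].copy()
            for k in neighbours.get(u, []):
                belief += messages[(k, u)]
            labels[u] = int(np.argmax(belief))  # lowest index wins ties
        return labels

    iters = 0
    converged = len(messages) == 0
    best_labels = decode()
    best_score = problem.score(best_labels)
    for iters in range(1, config.bp_max_iters + 1):
        delta = 0.0
        for u, v in list(messages):
            old = messages[(u, v)]
            incoming = problem.evidence[u].copy()
            for k in neighbours[u]:
                if k != v:
                    incoming += messages[(k, u)]
            w = problem.edge_matrix(u, v)  # (labels_u, labels_v)
            msg = (incoming[:, None] + w).max(axis=0)
            msg -= msg.max()
            msg = config.bp_damping * old + (1.0 - config.bp_damping) * msg
            delta = max(delta, float(np.abs(msg - old).max()))
            messages[(u, v)] = msg
        labels = decode()
        score = problem.score(labels)
        if score > best_score:
            best_score = score
            best_labels = labels
        if delta < config.bp_tol:
            converged = True
            break
    return Assignment(best_labels, best_score, "bp", iters, converged)


def maximize_joint(problem: MRFProblem, config: InferenceConfig) -> Assignment:
    """Find the label assignment maximizing the joint log-probability."""
    if config.optimizer == "exhaustive":
        return _exhaustive(problem, config.exhaustive_cap)
    return _bp(problem, config)


def build_problem(
    grid: PatchGrid,
    candidate_sets: dict,
    config: InferenceConfig,
) -> MRFProblem:
    """Assemble evidence vectors and pairwise matrices from candidates.

    ``candidate_sets`` maps node ids to :class:`CandidateSet`; evidence
    reuses the squared distances from the database query.
    """
    evidence = {}
    for node, cs in candidate_sets.items():
        evidence[node] = -cs.sq_distances / (2.0 * config.sigma1**2)
    core = grid.geometry.pairing_core_px
    margin = grid.geometry.core_margin_px
    inv2 = 1.0 / (2.0 * config.sigma2**2)
    pairwise = {}
    for u, v in grid.edges():
        pos_u = (int(grid.row_starts[u[0]]) + margin, int(grid.col_starts[u[1]]) + margin)
        pos_v = (int(grid.row_starts[v[0]]) + margin, int(grid.col_starts[v[1]]) + margin)
        ov = core_overlap(pos_u, pos_v, core)
        if ov is None:
            continue
        a = candidate_sets[u].sr_patches[:, ov.rows_i, ov.cols_i].reshape(
            len(candidate_sets[u]), -1
        )
        b = candidate_sets[v].sr_patches[:, ov.rows_j, ov.cols_j].reshape(
            len(candidate_sets[v]), -1
        )
        w = np.empty((len(a), len(b)))
        for ai in range(len(a)):
            w[ai] = -((a[ai] - b) ** 2).sum(axis=1) * inv2
        pairwise[(u, v)] = w
    return MRFProblem((grid.n_rows, grid.n_cols), evidence, pairwise)


def stitch(
    assignment: Assignment,
    grid: PatchGrid,
    candidate_sets: dict,
) -> ImageGrid:
    """Place each chosen SR patch at its grid location; average overlaps."""
    core = grid.geometry.pairing_core_px
    margin = grid.geometry.core_margin_px
    acc = np.zeros(grid.image_shape, dtype=np.float64)
    cnt = np.zeros(grid.image_shape, dtype=np.float64)
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            r0 = int(grid.row_starts[i]) + margin
            c0 = int(grid.col_starts[j]) + margin
            patch = candidate_sets[(i, j)].sr_patches[assignment.labels[i, j]]
            acc[r0 : r0 + core, c0 : c0 + core] += patch
            cnt[r0 : r0 + core, c0 : c0 + core] += 1.0
    out = np.divide(acc, cnt, out=np.zeros_like(acc), where=cnt > 0)
    return ImageGrid(out, grid.pixel_size_nm)


def reconstruct_upsampled(
    up_input: ImageGrid,
    db: PatchDatabase,
    config: InferenceConfig = InferenceConfig(),
    geometry: SegmentationGeometry = INPUT_GEOMETRY,
    return_details: bool = False,
):
    """Reconstruct from an input already on the database's fine grid."""
    if geometry.patch_px != db.geometry.patch_px:
        raise ValueError("input patch size must match the database patch size")
    grid = segment(up_input, geometry)
    candidate_sets = {}
    for i in range(grid.n_rows):
        for j in range(grid.n_cols):
            candidate_sets[(i, j)] = db.query_candidates(
                grid.patches[i, j], k=config.k_candidates, node_id=(i, j)
            )
    problem = build_problem(grid, candidate_sets, config)
    assignment = maximize_joint(problem, config)
    sr = stitch(assignment, grid, candidate_sets)
    if return_details:
        return sr, assignment, grid, candidate_sets
    return sr


def reconstruct(
    lr_input: ImageGrid,
    db: PatchDatabase,
    config: InferenceConfig = InferenceConfig(),
    geometry: SegmentationGeometry = INPUT_GEOMETRY,
    return_details: bool = False,
):
    """Full single-image inference: up-sample, match, optimize, stitch.

    Deterministic for fixed inputs and configuration.
    """
    if not math.isclose(lr_input.pixel_size_nm, db.lr_pixel_size_nm):
        raise ValueError(
            f"input pixel size {lr_input.pixel_size_nm} nm does not match the "
            f"database's native LR pixel size {db.lr_pixel_size_nm} nm"
        )
    factor = int(round(db.lr_pixel_size_nm / db.pixel_size_nm))
    up = upsample(lr_input, factor)
    return reconstruct_upsampled(up, db, config, geometry, return_details)
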