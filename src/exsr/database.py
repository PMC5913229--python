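"""Patch database construction and nearest-neighbour candidate search.

Example LR images are up-sampled five-fold by bicubic interpolation so
their 160 nm pixels match the 32 nm SR grid, segmented into overlapping
21 x 21 patches every 5 pixels, and each patch's central 15 x 15 region
is paired with the co-located window of the SR image.  The flattened LR
patches are indexed in a k-d tree for exact nearest-neighbour search;
an exhaustive linear scan over the same vectors is provided as the
reference oracle.

Patch windows are anchored at their top-left pixel and advance by the
grid step; the final window in each dimension is clamped to the image
border so that every pixel is covered (see :func:`exsr.grid.window_starts`).
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.transform import resize
from sklearn.neighbors import KDTree

from .grid import DB_GEOMETRY, ImageGrid, SegmentationGeometry, window_starts
from .simulate import ExamplePairImage

__all__ = [
    "PatchGrid",
    "CandidateSet",
    "PatchDatabase",
    "upsample",
    "segment",
    "build_database",
    "linear_scan_query",
]

UPSAMPLE_FACTOR = 5


def upsample(img: ImageGrid, factor: int = UPSAMPLE_FACTOR) -> ImageGrid:
    """Bicubic up-sampling by an integer factor; pixel size shrinks to match."""
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"factor must be an integer >= 1, got {factor}")
    if factor == 1:
        return img.copy()
    out = resize(
        img.data,
        (img.height_px * factor, img.width_px * factor),
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return ImageGrid(out, img.pixel_size_nm / factor)


@dataclass
class PatchGrid:
    """The segmentation of one image into an overlapping patch grid.

    Node ``(i, j)`` is the patch anchored at ``(row_starts[i],
    col_starts[j])``; grid adjacency is 4-connected.
    """

    patches: np.ndarray  # (n_rows, n_cols, patch_px, patch_px)
    row_starts: np.ndarray
    col_starts: np.ndarray
    geometry: SegmentationGeometry
    image_shape: tuple[int, int]
    pixel_size_nm: float

    @property
    def n_rows(self) -> int:
        return len(self.row_starts)

    @property
    def n_cols(self) -> int:
        return len(self.col_starts)

    def edges(self) -> list[tuple[tuple[int, int], tuple[int, int]]]:
        """All horizontal and vertical neighbour pairs, each listed once."""
        out = []
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                if j + 1 < self.n_cols:
                    out.append(((i, j), (i, j + 1)))
                if i + 1 < self.n_rows:
                    out.append(((i, j), (i + 1, j)))
        return out


def segment(img: ImageGrid, geom: SegmentationGeometry) -> PatchGrid:
    """Cut an image into the overlapping patch grid defined by ``geom``."""
    h, w = img.shape
    rows = window_starts(h, geom.patch_px, geom.step_px)
    cols = window_starts(w, geom.patch_px, geom.step_px)
    p = geom.patch_px
    patches = np.empty((len(rows), len(cols), p, p), dtype=np.float64)
    for i, r0 in enumerate(rows):
        for j, c0 in enumerate(cols):
            patches[i, j] = img.data[r0 : r0 + p, c0 : c0 + p]
    return PatchGrid(patches, rows, cols, geom, (h, w), img.pixel_size_nm)


@dataclass
class CandidateSet:
    """Top-k database matches for one input patch, sorted by distance."""

    node_id: tuple[int, int]
    indices: np.ndarray  # database row of each candidate
    lr_patches: np.ndarray  # (k, patch_px, patch_px)
    sr_patches: np.ndarray  # (k, core_px, core_px)
    sq_distances: np.ndarray  # ascending squared pixel-value distances

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class PatchDatabase:
    """LR/SR patch pairs with an exact k-d tree index over LR patch vectors."""

    lr_patches: np.ndarray  # (n, patch_px, patch_px)
    sr_patches: np.ndarray  # (n, core_px, core_px)
    sources: np.ndarray  # (n, 3): example index, row anchor, col anchor
    geometry: SegmentationGeometry
    pixel_size_nm: float  # grid both patch kinds live on (after up-sampling)
    lr_pixel_size_nm: float  # native pixel size of LR inputs before up-sampling
    provenance: str = ""
    _tree: KDTree | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.lr_patches)

    @property
    def vectors(self) -> np.ndarray:
        return self.lr_patches.reshape(len(self.lr_patches), -1)

    @property
    def tree(self) -> KDTree:
        if self._tree is None:
            self._tree = KDTree(self.vectors)
        return self._tree

    def query_candidates(self, input_patch: np.ndarray, k: int = 30,
                         node_id: tuple[int, int] = (0, 0)) -> CandidateSet:
        """The ``k`` stored pairs nearest to ``input_patch`` in squared
        pixel-value distance, ascending; ties broken by insertion order."""
        patch = np.asarray(input_patch, dtype=np.float64)
        if patch.shape != (self.geometry.patch_px, self.geometry.patch_px):
            raise ValueError(
                f"input patch shape {patch.shape} does not match the database "
                f"geometry {(self.geometry.patch_px,) * 2}"
            )
        if k > len(self):
            warnings.warn(
                f"requested k={k} exceeds the database size {len(self)}; "
                "returning all pairs",
                stacklevel=2,
            )
            k = len(self)
        v = patch.reshape(1, -1)
        dist, _ = self.tree.query(v, k=k)
        # Re-fetch everything within the k-th distance so groups tied at
        # the cut are resolved by insertion order, then recompute exact
        # squared distances (the tree's float radii are not tie-safe).
        radius = dist[0, -1] * (1.0 + 1e-12)
        idx = self.tree.query_radius(v, r=radius)[0]
        d2 = ((self.vectors[idx] - v[0]) ** 2).sum(axis=1)
        order = np.lexsort((idx, d2))[:k]
        idx, d2 = idx[order], d2[order]
        return CandidateSet(
            node_id=node_id,
            indices=idx,
            lr_patches=self.lr_patches[idx],
            sr_patches=self.sr_patches[idx],
            sq_distances=d2,
        )

    # ------------------------------------------------------------------
    # persistence
    # ------------------------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format_version"] = 1
            f.attrs["patch_px"] = self.geometry.patch_px
            f.attrs["step_px"] = self.geometry.step_px
            f.attrs["pairing_core_px"] = self.geometry.pairing_core_px
            f.attrs["pixel_size_nm"] = self.pixel_size_nm
            f.attrs["lr_pixel_size_nm"] = self.lr_pixel_size_nm
            f.attrs["provenance"] = self.provenance
            f.create_dataset("lr_patches", data=self.lr_patches, compression="gzip")
            f.create_dataset("sr_patches", data=self.sr_patches, compression="gzip")
            f.create_dataset("sources", data=self.sources)

    @classmethod
    def load(cls, path) -> "PatchDatabase":
        with h5py.File(path, "r") as f:
            geom = SegmentationGeometry(
                patch_px=int(f.attrs["patch_px"]),
                step_px=int(f.attrs["step_px"]),
                pairing_core_px=int(f.attrs["pairing_core_px"]),
            )
            return cls(
                lr_patches=f["lr_patches"][:],
                sr_patches=f["sr_patches"][:],
                sources=f["sources"][:],
                geometry=geom,
                pixel_size_nm=float(f.attrs["pixel_size_nm"]),
                lr_pixel_size_nm=float(f.attrs["lr_pixel_size_nm"]),
                provenance=str(f.attrs["provenance"]),
            )


def linear_scan_query(
    db: PatchDatabase, input_patch: np.ndarray, k: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive top-k reference oracle: (indices, squared distances)."""
    v = np.asarray(input_patch, dtype=np.float64).ravel()
    d2 = ((db.vectors - v) ** 2).sum(axis=1)
    k = min(k, len(d2))
    order = np.lexsort((np.arange(len(d2)), d2))[:k]
    return order, d2[order]


def build_database(
    examples: list[ExamplePairImage],
    geom: SegmentationGeometry = DB_GEOMETRY,
    factor: int = UPSAMPLE_FACTOR,
) -> PatchDatabase:
    """Convert example pairs into an indexed patch database.

    Each LR example is up-sampled ``factor`` times, segmented on the
    database grid, and the central core of every LR patch is paired with
    the window of the SR image at the same physical location.
    """
    if not examples:
        raise ValueError("examples must be nonempty")
    lr_list, sr_list, src_list = [], [], []
    margin = geom.core_margin_px
    core = geom.pairing_core_px
    pixel_size = None
    lr_pixel_size = None
    for ex_idx, ex in enumerate(examples):
        up = upsample(ex.lr, factor)
        if up.shape != ex.sr.shape or not math.isclose(
            up.pixel_size_nm, ex.sr.pixel_size_nm
        ):
            raise ValueError(
                f"example {ex_idx} ({ex.category}): up-sampled LR grid "
                f"{up.shape} @ {up.pixel_size_nm} nm does not match the SR grid "
                f"{ex.sr.shape} @ {ex.sr.pixel_size_nm} nm"
            )
        if pixel_size is None:
            pixel_size = up.pixel_size_nm
            lr_pixel_size = ex.lr.pixel_size_nm
        grid = segment(up, geom)
        for i, r0 in enumerate(grid.row_starts):
            for j, c0 in enumerate(grid.col_starts):
                lr_list.append(grid.patches[i, j])
                sr_list.append(
                    ex.sr.data[r0 + margin : r0 + margin + core,
                               c0 + margin : c0 + margin + core]
                )
                src_list.append((ex_idx, r0, c0))
    lr_arr = np.asarray(lr_list)
    sr_arr = np.asarray(sr_list)
    src_arr = np.asarray(src_list, dtype=np.int64)
    digest = hashlib.sha256(lr_arr.tobytes() + sr_arr.tobytes()).hexdigest()[:16]
    return PatchDatabase(
        lr_patches=lr_arr,
        sr_patches=sr_arr,
        sources=src_arr,
        geometry=geom,
        pixel_size_nm=pixel_size,
        lr_pixel_size_nm=lr_pixel_size,
        provenance=digest,
    )
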