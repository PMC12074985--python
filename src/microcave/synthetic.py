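"""Synthetic labeled volumes, supervoxel partitions, affinity edges and
point annotations.

This module manufactures desk-scale stand-ins for the inputs a proofreading
system sees in production: a dense cellular segmentation, an
oversegmentation of each cell into supervoxels, an affinity-weighted
supervoxel adjacency list with *injected* errors (false merges across cell
boundaries, false splits inside cells), and synapse-like two-point
annotations straddling cell-cell interfaces. Ground truth is retained so
every downstream module has an oracle.

Cells and supervoxels are grown by marker-based watershed on smoothed noise,
which guarantees each label is a single 6-connected region. All generators
are deterministic functions of their ``seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import h5py
import numpy as np
import pandas as pd
from numcodecs import Zstd
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import InvalidArgumentError

DEFAULT_RESOLUTION = (8.0, 8.0, 40.0)  # nm per voxel, anisotropic EM-style


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class LabelVolume:
    """A labeled 3D grid: ground-truth cells plus a supervoxel partition.

    ``cell_labels`` and ``supervoxel_labels`` are positive exactly on the
    foreground; every supervoxel is 6-connected and contained in one cell.
    """

    shape: tuple[int, int, int]
    resolution: tuple[float, float, float]
    cell_labels: np.ndarray
    supervoxel_labels: np.ndarray | None = None

    def sv_at(self, point) -> int:
        """Supervoxel label at a voxel coordinate (0 = background)."""
        x, y, z = (int(v) for v in point)
        if not all(0 <= c < s for c, s in zip((x, y, z), self.shape)):
            raise InvalidArgumentError(f"point {(x, y, z)} outside volume {self.shape}")
        return int(self.supervoxel_labels[x, y, z])


@dataclass
class InjectedError:
    """One deliberately introduced segmentation error.

    ``merge``: an ON edge emitted between supervoxels of different cells.
    ``split``: a within-cell adjacency withheld from the edge list.
    """

    kind: Literal["merge", "split"]
    sv_a: int
    sv_b: int


@dataclass
class GroundTruth:
    sv_to_cell: dict[int, int] = field(default_factory=dict)
    injected_errors: list[InjectedError] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _smooth_noise(shape, rng, sigma=2.0):
    return ndimage.gaussian_filter(rng.random(shape), sigma=sigma)


def _growth_image(markers: np.ndarray, rng, jitter: float = 0.4) -> np.ndarray:
    """Flooding topography: distance to the nearest marker, jittered.

    Watershed on this field grows each marker into (roughly) its Voronoi
    region with irregular boundaries — balanced, 6-connected labels.
    """
    dist = ndimage.distance_transform_edt(markers == 0)
    noise = _smooth_noise(markers.shape, rng, sigma=1.5)
    return dist * (1.0 + jitter * (noise - 0.5))


def generate_cells(shape, n_cells: int, seed: int,
                   resolution=DEFAULT_RESOLUTION,
                   background_seeds: int = 1) -> LabelVolume:
    """Grow ``n_cells`` 6-connected cells by watershed from random markers.

    ``background_seeds`` extra markers become label 0, so volumes have some
    background to exercise null-supervoxel handling; set to 0 for a volume
    with no background.
    """
    shape = tuple(int(s) for s in shape)
    if n_cells < 1:
        raise InvalidArgumentError("n_cells must be >= 1")
    if any(s < 8 for s in shape):
        raise InvalidArgumentError(f"each dimension must be >= 8, got {shape}")
    n_markers = n_cells + background_seeds
    n_vox = int(np.prod(shape))
    if n_markers > n_vox:
        raise InvalidArgumentError(
            f"{n_markers} markers exceed {n_vox} voxels")

    rng = np.random.default_rng(seed)
    flat = rng.choice(n_vox, size=n_markers, replace=False)
    markers = np.zeros(shape, dtype=np.int32)
    markers.ravel()[flat] = np.arange(1, n_markers + 1)
    basins = watershed(_growth_image(markers, rng), markers, connectivity=1)
    cells = np.where(basins <= n_cells, basins, 0).astype(np.int32)
    return LabelVolume(shape=shape, resolution=tuple(resolution),
                       cell_labels=cells)


def oversegment(vol: LabelVolume, target_sv_size: int, seed: int
                ) -> tuple[LabelVolume, GroundTruth]:
    """Partition each cell into ~``target_sv_size``-voxel supervoxels.

    Supervoxels never cross cell boundaries: the watershed that grows them
    is masked to one cell at a time.
    """
    if vol.cell_labels is None:
        raise InvalidArgumentError("volume has no cell labels")
    rng = np.random.default_rng(seed)
    sv = np.zeros(vol.shape, dtype=np.int64)
    sv_to_cell: dict[int, int] = {}
    next_label = 1
    slices = ndimage.find_objects(vol.cell_labels)
    for cell, box in enumerate(slices, start=1):
        if box is None:
            continue
        mask = vol.cell_labels[box] == cell
        size = int(mask.sum())
        k = max(1, int(round(size / max(1, target_sv_size))))
        k = min(k, size)
        coords = np.flatnonzero(mask.ravel())
        picks = rng.choice(coords, size=k, replace=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers.ravel()[picks] = np.arange(1, k + 1)
        basins = watershed(_growth_image(markers, rng), markers,
                           mask=mask, connectivity=1)
        sv[box][mask] = basins[mask] + (next_label - 1)
        for j in range(1, k + 1):
            sv_to_cell[next_label - 1 + j] = int(cell)
        next_label += k
    out = LabelVolume(shape=vol.shape, resolution=vol.resolution,
                      cell_labels=vol.cell_labels, supervoxel_labels=sv)
    return out, GroundTruth(sv_to_cell=sv_to_cell)


def _adjacent_pairs(labels: np.ndarray) -> np.ndarray:
    """All unordered 6-adjacent label pairs (a < b, both nonzero)."""
    pairs = []
    for axis in range(3):
        a = np.moveaxis(labels, axis, 0)[:-1].ravel()
        b = np.moveaxis(labels, axis, 0)[1:].ravel()
        keep = (a != b) & (a > 0) & (b > 0)
        if keep.any():
            p = np.stack([a[keep], b[keep]], axis=1)
            pairs.append(np.sort(p, axis=1))
    if not pairs:
        return np.empty((0, 2), dtype=labels.dtype)
    return np.unique(np.concatenate(pairs, axis=0), axis=0)


def derive_edges(vol: LabelVolume, error_rate: float, seed: int,
                 within_cell_affinity=(0.9, 0.05),
                 false_merge_affinity=(0.3, 0.10),
                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit the affinity edge list over 6-adjacent supervoxel pairs.

    Within-cell adjacencies get high affinities; a fraction ``error_rate``
    of them is withheld (false splits). Between-cell adjacencies are OFF
    except a fraction ``error_rate`` emitted with low affinity (false
    merges). Every perturbation is recorded in ``GroundTruth``.
    """
    if vol.supervoxel_labels is None:
        raise InvalidArgumentError("volume has no supervoxel labels")
    rng = np.random.default_rng(seed)
    pairs = _adjacent_pairs(vol.supervoxel_labels)

    # total sv -> cell map from the grids
    sv_to_cell: dict[int, int] = {}
    flat_sv = vol.supervoxel_labels.ravel()
    flat_cell = vol.cell_labels.ravel()
    fg = flat_sv > 0
    # first occurrence per supervoxel suffices: supervoxels never span cells
    uniq, first = np.unique(flat_sv[fg], return_index=True)
    cells_at = flat_cell[fg][first]
    sv_to_cell = {int(s): int(c) for s, c in zip(uniq, cells_at)}

    gt = GroundTruth(sv_to_cell=sv_to_cell)
    rows = []
    for a, b in pairs:
        a, b = int(a), int(b)
        same_cell = sv_to_cell[a] == sv_to_cell[b]
        u = rng.random()
        if same_cell:
            aff = float(np.clip(rng.normal(*within_cell_affinity), 1e-3, 1.0))
            if u < error_rate:
                gt.injected_errors.append(InjectedError("split", a, b))
            else:
                rows.append((a, b, aff))
        else:
            aff = float(np.clip(rng.normal(*false_merge_affinity), 1e-3, 1.0))
            if u < error_rate:
                rows.append((a, b, aff))
                gt.injected_errors.append(InjectedError("merge", a, b))
    edges = pd.DataFrame(rows, columns=["sv_a", "sv_b", "affinity"])
    return edges, gt


def generate_annotations(vol: LabelVolume, n_synapses: int, seed: int
                         ) -> dict[str, list[dict]]:
    """Synapse-like two-point rows plus one cell-body row per cell.

    Each synapse places its pre/post points on the two sides of a randomly
    chosen cell-cell voxel interface; the size field is lognormal. Cell-body
    points sit at each cell's deepest interior voxel (EDT argmax).
    """
    if vol.supervoxel_labels is None:
        raise InvalidArgumentError("volume has no supervoxel labels")
    rng = np.random.default_rng(seed)
    cells = vol.cell_labels

    # candidate interfaces: 6-adjacent voxel pairs in different cells
    candidates = []
    for axis in range(3):
        a = np.moveaxis(cells, axis, 0)[:-1]
        b = np.moveaxis(cells, axis, 0)[1:]
        idx = np.argwhere((a != b) & (a > 0) & (b > 0))
        for loc in idx:
            p = list(loc)
            q = [loc[0] + 1, loc[1], loc[2]]
            # undo the moveaxis for coordinates
            order = list(range(3))
            order.insert(axis, order.pop(0))
            candidates.append((tuple(int(p[i]) for i in order),
                               tuple(int(q[i]) for i in order)))
    synapses: list[dict] = []
    if n_synapses > 0:
        if not candidates:
            warnings.warn("no cell-cell interface exists; 0 synapses generated")
        else:
            k = min(n_synapses, len(candidates))
            if k < n_synapses:
                warnings.warn(f"only {k} interfaces available for "
                              f"{n_synapses} requested synapses")
            picks = rng.choice(len(candidates), size=k, replace=False)
            for i in picks:
                pre, post = candidates[int(i)]
                if rng.random() < 0.5:
                    pre, post = post, pre
                synapses.append({"pre_pt": pre, "post_pt": post,
                                 "size": float(np.round(rng.lognormal(5.0, 1.0), 3))})

    bodies: list[dict] = []
    for cell, box in enumerate(ndimage.find_objects(cells), start=1):
        if box is None:
            continue
        mask = np.pad(cells[box] == cell, 1)
        edt = ndimage.distance_transform_edt(mask, sampling=vol.resolution)
        loc = np.unravel_index(int(np.argmax(edt)), mask.shape)
        bodies.append({"pt": tuple(int(c) - 1 + s.start
                                   for c, s in zip(loc, box))})
    return {"synapse": synapses, "cell_location": bodies}


# ---------------------------------------------------------------------------
# Persistence: HDF5 volume, CSV + zstd-compressed binary edge list
# ---------------------------------------------------------------------------

def save_volume(vol: LabelVolume, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("cell_labels", data=vol.cell_labels)
        if vol.supervoxel_labels is not None:
            f.create_dataset("supervoxel_labels", data=vol.supervoxel_labels)
        f.attrs["shape"] = vol.shape
        f.attrs["resolution"] = vol.resolution


def load_volume(path) -> LabelVolume:
    with h5py.File(path, "r") as f:
        cells = f["cell_labels"][:]
        sv = f["supervoxel_labels"][:] if "supervoxel_labels" in f else None
        shape = tuple(int(s) for s in f.attrs["shape"])
        res = tuple(float(r) for r in f.attrs["resolution"])
    return LabelVolume(shape=shape, resolution=res, cell_labels=cells,
                       supervoxel_labels=sv)


def save_edges_csv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, index=False)


def load_edges_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_edges_binary(edges: pd.DataFrame, path) -> None:
    """Compact binary edge list: zstd-compressed columnar arrays."""
    codec = Zstd(level=9)
    blobs, header = [], {}
    for col, dtype in (("sv_a", "<i8"), ("sv_b", "<i8"), ("affinity", "<f8")):
        raw = np.ascontiguousarray(edges[col].to_numpy(dtype=dtype)).tobytes()
        blob = codec.encode(raw)
        header[col] = {"dtype": dtype, "n": int(len(edges)),
                       "nbytes": len(blob)}
        blobs.append(blob)
    with open(path, "wb") as f:
        h = json.dumps(header).encode()
        f.write(len(h).to_bytes(8, "little"))
        f.write(h)
        for blob in blobs:
            f.write(blob)


def load_edges_binary(path) -> pd.DataFrame:
    codec = Zstd()
    with open(path, "rb") as f:
        hlen = int.from_bytes(f.read(8), "little")
        header = json.loads(f.read(hlen).decode())
        cols = {}
        for col, meta in header.items():
            raw = codec.decode(f.read(meta["nbytes"]))
            cols[col] = np.frombuffer(raw, dtype=meta["dtype"])[: meta["n"]]
    return pd.DataFrame(cols)
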