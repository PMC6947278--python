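"""Skeletonization, branch decomposition and the four SCP metrics.

The binary vessel map is thinned to 1-px centrelines, decomposed into
branches between junction / end nodes, and four quantities are measured per
region of interest:

* PD  (perfusion density, %)      - vessel pixels / region pixels x 100
* VLD (vessel length density, %)  - skeleton pixels / region pixels x 100
* VDI (vessel diameter index, µm) - vessel area / skeleton length x pitch,
                                    an average caliber
* VT  (vessel tortuosity)         - sum of branch arc lengths / sum of the
                                    straight chords between their nodes

Branch decomposition follows the usual skeleton-graph convention: skeleton
pixels with >= 3 eight-neighbours are junction pixels (adjacent junction
pixels are merged into one node cluster), pixels with exactly one neighbour
are endpoints, and branches are the maximal node-free paths between nodes.
Path length is step-summed (1 for orthogonal moves, sqrt(2) for diagonal).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage
from skimage import morphology

from .binarize import BinaryVesselMap, DegenerateInputError
from .roi import RegionMask

SQRT2 = math.sqrt(2.0)

#: value reported when a metric is undefined on its input (e.g. no skeleton
#: pixels in the region); NaN propagates through tables without crashing.
UNDEFINED_METRIC = float("nan")


@dataclasses.dataclass
class SkeletonMap:
    """1-px-wide centreline raster derived from a vessel mask."""

    mask: np.ndarray
    source: BinaryVesselMap | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclasses.dataclass
class Branch:
    """One skeleton branch between two terminal nodes."""

    actual_length_px: float
    chord_length_px: float
    midpoint: tuple[int, int]
    kind: str  # node-to-node | node-to-end | end-to-end | cycle
    pixels: list = dataclasses.field(default_factory=list, repr=False)

    @property
    def arc_chord_ratio(self) -> float:
        if self.chord_length_px <= 0:
            return float("inf")
        return self.actual_length_px / self.chord_length_px


@dataclasses.dataclass
class BranchSet:
    branches: list[Branch]

    def __len__(self) -> int:
        return len(self.branches)

    def __iter__(self):
        return iter(self.branches)


def skeletonize_mask(mask: BinaryVesselMap | np.ndarray) -> SkeletonMap:
    """Topology-preserving thinning to 1-px centrelines."""
    src = mask if isinstance(mask, BinaryVesselMap) else BinaryVesselMap(mask, "input")
    return SkeletonMap(morphology.skeletonize(src.mask), src)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _step_len(a: tuple[int, int], b: tuple[int, int]) -> float:
    return SQRT2 if (a[0] != b[0] and a[1] != b[1]) else 1.0


def analyze_branches(skel: SkeletonMap) -> BranchSet:
    """Decompose a skeleton into branches with arc and chord lengths.

    Junction clusters (8-adjacent pixels each having >= 3 neighbours) are
    merged into single nodes before path extraction, since raw neighbour
    counting fragments junctions.  Chords are measured between the terminal
    node pixels actually reached by each path.  Isolated pixels yield no
    branches; node-free closed loops are returned as ``cycle`` branches with
    zero chord.
    """
    sk = skel.mask
    if not sk.any():
        return BranchSet([])
    ncount = ndimage.convolve(sk.astype(np.uint8), _NEIGHBOR_KERNEL,
                              mode="constant", cval=0)
    is_junction = sk & (ncount >= 3)
    is_end = sk & (ncount == 1)
    is_node = is_junction | is_end
    # merge adjacent junction pixels into one node id; endpoints get their own
    junc_labels, n_junc = ndimage.label(is_junction, structure=np.ones((3, 3)))
    node_id = np.zeros(sk.shape, dtype=np.int64)
    node_id[is_junction] = junc_labels[is_junction]
    end_rows, end_cols = np.nonzero(is_end)
    for i, (r, c) in enumerate(zip(end_rows, end_cols)):
        node_id[r, c] = n_junc + 1 + i

    def neighbors(p):
        r, c = p
        for dr, dc in _OFFSETS:
            rr, cc = r + dr, c + dc
            if 0 <= rr < sk.shape[0] and 0 <= cc < sk.shape[1] and sk[rr, cc]:
                yield (rr, cc)

    visited_slab = np.zeros(sk.shape, dtype=bool)
    branches: list[Branch] = []

    def kind_of(a, b):
        a_j = is_junction[a]
        b_j = is_junction[b]
        if a_j and b_j:
            return "node-to-node"
        if a_j or b_j:
            return "node-to-end"
        return "end-to-end"

    def emit(path, start_node, end_node):
        actual = sum(_step_len(path[i], path[i + 1]) for i in range(len(path) - 1))
        chord = math.hypot(start_node[0] - end_node[0], start_node[1] - end_node[1])
        branches.append(Branch(actual, chord, path[len(path) // 2],
                               kind_of(start_node, end_node), list(path)))

    node_pixels = list(zip(*np.nonzero(is_node)))
    seen_direct = set()  # direct node-node adjacencies already emitted
    for start in node_pixels:
        for first in neighbors(start):
            if is_node[first]:
                # direct adjacency between two nodes of different clusters
                if node_id[first] != node_id[start]:
                    key = frozenset((start, first))
                    if key not in seen_direct:
                        seen_direct.add(key)
                        emit([start, first], start, first)
                continue
            if visited_slab[first]:
                continue
            # walk along slab pixels until another node is reached
            path = [start, first]
            visited_slab[first] = True
            cur = first
            while True:
                nxt_node = None
                nxt_slab = None
                recent = set(path[-3:])  # blocks diagonal back-steps
                for nb in neighbors(cur):
                    if nb in recent:
                        continue
                    if is_node[nb]:
                        if nxt_node is None:
                            nxt_node = nb
                    elif not visited_slab[nb] and nxt_slab is None:
                        nxt_slab = nb
                # do not step straight back into the start cluster through a
                # pixel touching it unless the path has actually gone somewhere
                if nxt_node is not None and (
                        node_id[nxt_node] != node_id[start] or len(path) > 2):
                    path.append(nxt_node)
                    emit(path, start, nxt_node)
                    break
                if nxt_slab is None:
                    # dead end inside slab pixels (rare rasterization corner);
                    # close the branch at the current pixel
                    emit(path, start, cur)
                    break
                visited_slab[nxt_slab] = True
                path.append(nxt_slab)
                cur = nxt_slab

    # node-free cycles: remaining unvisited slab pixels with 2 neighbours
    remaining = sk & ~visited_slab & ~is_node
    lab, n = ndimage.label(remaining, structure=np.ones((3, 3)))
    for i in range(1, n + 1):
        pix = list(zip(*np.nonzero(lab == i)))
        if len(pix) < 3:
            continue  # isolated specks
        # trace the loop to step-sum its perimeter
        start = pix[0]
        path = [start]
        prev, cur = None, start
        while True:
            nxt = None
            for nb in neighbors(cur):
                if nb != prev and lab[nb] == i and (len(path) < 3 or nb not in path[-2:]):
                    if nb == start and len(path) > 2:
                        nxt = nb
                        break
                    if nb not in path:
                        nxt = nb
                        break
            if nxt is None or nxt == start:
                break
            path.append(nxt)
            prev, cur = cur, nxt
        actual = sum(_step_len(path[j], path[j + 1]) for j in range(len(path) - 1))
        actual += _step_len(path[-1], start)
        branches.append(Branch(actual, 0.0, path[len(path) // 2], "cycle",
                               list(path)))

    return BranchSet(branches)


def prune_spurs(skel: SkeletonMap, min_px: float = 8.0,
                iterations: int = 3) -> SkeletonMap:
    """Remove short end twigs so spurious junctions do not cut long branches.

    Thinning a slightly rough vessel mask sprouts side twigs a few pixels
    long; each twig turns a through-going centreline into two branches
    joined at a fake junction, which biases branch-level statistics (chords
    get cut below the tortuosity scale).  Twigs with a free end shorter
    than ``min_px`` are deleted and the skeleton re-thinned, iterating
    because removing one layer of twigs can expose another.
    """
    sk = skel.mask.copy()
    for _ in range(iterations):
        removed = 0
        for b in analyze_branches(SkeletonMap(sk)):
            if b.kind in ("node-to-end", "end-to-end")                     and b.actual_length_px < min_px and b.kind == "node-to-end":
                for p in b.pixels[1:]:  # keep the junction-side terminal
                    sk[p] = False
                removed += 1
        if removed == 0:
            break
        sk = morphology.skeletonize(sk)
    return SkeletonMap(sk, skel.source)


# ---------------------------------------------------------------------------
# metrics


def _roi_guard(roi: RegionMask) -> None:
    if roi.pixel_count == 0:
        raise DegenerateInputError(f"region '{roi.region}' contains no pixels")


def perfusion_density(mask: BinaryVesselMap, roi: RegionMask) -> float:
    """Percent of region pixels classified as vessel."""
    _roi_guard(roi)
    return 100.0 * float((mask.mask & roi.mask).sum()) / roi.pixel_count


def vessel_length_density(skel: SkeletonMap, roi: RegionMask) -> float:
    """Percent of region pixels lying on the vessel skeleton."""
    _roi_guard(roi)
    return 100.0 * float((skel.mask & roi.mask).sum()) / roi.pixel_count


def vessel_diameter_index(mask: BinaryVesselMap, skel: SkeletonMap,
                          roi: RegionMask, pixel_pitch_um: float = 12.0,
                          as_pixels: bool = False) -> float:
    """Average vessel caliber: binarized area over skeleton area.

    Reported in µm (pixel ratio x pitch) by default; ``as_pixels`` returns
    the raw ratio.  Undefined (NaN) when the region holds no skeleton.
    """
    _roi_guard(roi)
    skel_px = float((skel.mask & roi.mask).sum())
    if skel_px == 0:
        return UNDEFINED_METRIC
    ratio = float((mask.mask & roi.mask).sum()) / skel_px
    return ratio if as_pixels else ratio * pixel_pitch_um


def vessel_tortuosity(branches: BranchSet, roi: RegionMask,
                      min_length_px: float = 3.0) -> float:
    """Sum of branch arc lengths over sum of their chords, within a region.

    Eligible branches have both terminals at junction/end nodes (cycles are
    excluded), arc length >= ``min_length_px``, and midpoint inside the
    region; assignment by midpoint avoids double-counting branches that
    straddle the annulus boundary.  Always >= 1 by construction; NaN when no
    branch qualifies.
    """
    _roi_guard(roi)
    s_actual = 0.0
    s_chord = 0.0
    for b in branches:
        if b.kind == "cycle" or b.actual_length_px < min_length_px:
            continue
        if b.chord_length_px <= 0:
            continue
        if not roi.mask[b.midpoint]:
            continue
        s_actual += b.actual_length_px
        s_chord += b.chord_length_px
    if s_chord == 0:
        return UNDEFINED_METRIC
    return s_actual / s_chord
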