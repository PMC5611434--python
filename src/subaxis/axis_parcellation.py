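"""Anterior-posterior axis parcellation of a binary subfield mask.

The algorithm divides a hippocampal-subfield mask into N (default 10) equal
segments along its long axis:

1. extract the surface voxels of the mask (6-connectivity),
2. find the two surface voxels with the greatest Euclidean distance between
   their centers (brute-force all-pairs search),
3. orient the connecting line from the most posterior to the most anterior
   endpoint,
4. divide the line into N equally spaced segments, project every mask voxel
   onto it and assign the voxel to the segment it projects into,
5. segment volume = voxel count x voxel volume.

Segment 1 is the most posterior, segment N the most anterior.  Restricting
the pair search to surface voxels is lossless: an interior voxel (all six
face-neighbours present) lies strictly inside the convex hull of its
neighbours' centers and can never attain the maximum pairwise distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .mask_model import BinaryMask, MaskError

logger = logging.getLogger("subaxis")

DEFAULT_N_SEGMENTS = 10

#: Fraction of the head+body hippocampal length occupied by the head
#: (anterior), measured on the MNI template.
DEFAULT_HEAD_FRACTION = 0.47

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class AxisLine:
    """Oriented posterior->anterior straight axis in world mm."""

    p_posterior: np.ndarray
    p_anterior: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "p_posterior", np.asarray(self.p_posterior, dtype=float)
        )
        object.__setattr__(
            self, "p_anterior", np.asarray(self.p_anterior, dtype=float)
        )
        if self.length_mm <= 0:
            raise MaskError("axis endpoints coincide: zero-length axis")

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(self.p_anterior - self.p_posterior))

    @property
    def unit(self) -> np.ndarray:
        return (self.p_anterior - self.p_posterior) / self.length_mm


@dataclass(frozen=True)
class SegmentLabeling:
    """Per-voxel segment assignment for one mask.

    ``voxels`` and ``labels`` are parallel arrays; labels run 1..n_segments
    with 1 most posterior.  ``t`` holds each voxel's unclamped projection
    parameter along the axis (0 at the posterior endpoint, 1 at the anterior
    endpoint); ``max_clamp`` is the largest adjustment applied when clamping
    t into [0, 1], in axis-length units.
    """

    voxels: np.ndarray
    labels: np.ndarray
    n_segments: int
    axis: AxisLine
    t: np.ndarray
    max_clamp: float

    def counts(self) -> np.ndarray:
        """Voxel count per segment, index 0 = segment 1 (posterior)."""
        return np.bincount(self.labels, minlength=self.n_segments + 1)[1:]


@dataclass(frozen=True)
class SegmentVolumes:
    """Per participant/hemisphere segment volumes, posterior to anterior."""

    participant_id: str
    hemisphere: str
    volumes_mm3: np.ndarray
    axis_length_mm: float

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes_mm3, dtype=float)
        if np.any(v < 0):
            raise MaskError("segment volumes must be non-negative")
        object.__setattr__(self, "volumes_mm3", v)

    @property
    def n_segments(self) -> int:
        return int(self.volumes_mm3.size)

    @property
    def total_mm3(self) -> float:
        return float(self.volumes_mm3.sum())


def extract_surface_voxels(mask: BinaryMask) -> np.ndarray:
    """Voxels with at least one of their 6 face-neighbours outside the mask.

    Out-of-grid counts as outside.  Returns an (m, 3) index array in
    lexicographic order.
    """
    if mask.n_voxels == 0:
        raise MaskError("mask is empty")
    grid = mask.to_grid()
    interior = ndimage.binary_erosion(
        grid, structure=_FACE_STRUCTURE, border_value=0
    )
    return np.argwhere(grid & ~interior)


def farthest_pair(
    points: np.ndarray, index_triples: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force O(n^2) search for the pair at maximum Euclidean distance.

    Ties (squared distances equal to within 1e-12 relative) are broken
    deterministically: among tied pairs, pick the one whose two index
    triples, sorted within the pair then compared, are lexicographically
    smallest.  When no index triples are given the point coordinates
    themselves serve as the tie-break keys.

    Returns the two points ordered by their tie-break keys.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    n = pts.shape[0]
    if n < 2:
        raise MaskError(f"need at least 2 points for a farthest pair, got {n}")
    keys = pts if index_triples is None else np.asarray(index_triples).reshape(-1, 3)

    # chunked all-pairs squared distances to bound memory
    best = -1.0
    chunk = max(1, int(2e7) // max(n, 1))
    maxima = []
    for start in range(0, n, chunk):
        d2 = cdist(pts[start : start + chunk], pts, "sqeuclidean")
        m = float(d2.max())
        maxima.append((m, start, d2))
        best = max(best, m)
    tol = best * 1e-12
    candidates: list[tuple[tuple, int, int]] = []
    for m, start, d2 in maxima:
        if m >= best - tol:
            for i_loc, j in zip(*np.nonzero(d2 >= best - tol)):
                i = start + int(i_loc)
                j = int(j)
                if i == j:
                    continue
                a, b = sorted((i, j), key=lambda k: tuple(keys[k]))
                candidates.append(
                    ((tuple(keys[a]), tuple(keys[b])), a, b)
                )
    _, i, j = min(candidates, key=lambda c: c[0])
    return pts[i], pts[j]


def orient_posterior_anterior(
    pair: tuple[np.ndarray, np.ndarray], anterior_axis: int = 1
) -> AxisLine:
    """Orient an endpoint pair posterior->anterior along the anterior axis.

    The endpoint with the smaller anterior-axis world coordinate becomes the
    posterior endpoint.  If the two endpoints tie exactly on that axis
    (anatomically implausible), the lexicographically smaller coordinate
    becomes posterior and a warning is logged.
    """
    a = np.asarray(pair[0], dtype=float)
    b = np.asarray(pair[1], dtype=float)
    if a[anterior_axis] < b[anterior_axis]:
        post, ant = a, b
    elif a[anterior_axis] > b[anterior_axis]:
        post, ant = b, a
    else:
        logger.warning(
            "axis endpoints tie on the anterior axis; falling back to "
            "lexicographic orientation (anatomically implausible input)"
        )
        post, ant = sorted((a, b), key=tuple)
    return AxisLine(p_posterior=post, p_anterior=ant)


def project_and_bin(
    mask: BinaryMask,
    axis: AxisLine,
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> SegmentLabeling:
    """Project voxel centers onto the axis and bin into equal segments.

    For voxel center x the projection parameter is
    t = ((x - p_posterior) . u) / L with u the unit axis vector and L the
    axis length.  Bins are half-open [(s-1)/n, s/n) with t = 1 assigned to
    segment n, so segment 1 is most posterior and a voxel projecting exactly
    onto a boundary goes to the higher (more anterior) segment.

    When the axis comes from the mask's own farthest surface pair, every t
    lies in [0, 1] up to floating-point error; t is clamped and the largest
    clamp adjustment recorded.
    """
    if n_segments < 2:
        raise MaskError(f"n_segments must be >= 2, got {n_segments}")
    coords = mask.world_coordinates()
    t = (coords - axis.p_posterior) @ axis.unit / axis.length_mm
    max_clamp = float(np.max(np.maximum(-t, t - 1.0), initial=0.0))
    t_cl = np.clip(t, 0.0, 1.0)
    labels = np.minimum(np.floor(n_segments * t_cl).astype(np.int64) + 1, n_segments)
    return SegmentLabeling(
        voxels=mask.voxels,
        labels=labels,
        n_segments=n_segments,
        axis=axis,
        t=t,
        max_clamp=max_clamp,
    )


def segment_volumes(
    labeling: SegmentLabeling,
    voxel_volume: float,
    participant_id: str = "",
    hemisphere: str = "",
) -> SegmentVolumes:
    """Segment volume = voxel count per segment x voxel volume (mm^3).

    Empty segments (possible for pathological shapes) are retained with
    volume 0, so the list always has n_segments entries and the volumes sum
    exactly to the total mask volume.
    """
    counts = labeling.counts()
    return SegmentVolumes(
        participant_id=participant_id,
        hemisphere=hemisphere,
        volumes_mm3=counts * float(voxel_volume),
        axis_length_mm=labeling.axis.length_mm,
    )


def parcellate(
    mask: BinaryMask,
    n_segments: int = DEFAULT_N_SEGMENTS,
    participant_id: str = "",
    hemisphere: str = "",
) -> tuple[SegmentVolumes, SegmentLabeling]:
    """Full pipeline: surface -> farthest pair -> orient -> bin -> volumes.

    Asserts the projection-range invariant: because the axis endpoints
    attain the maximum pairwise distance, no voxel can project outside the
    axis by more than floating-point error.
    """
    surface = extract_surface_voxels(mask)
    coords = mask.world_coordinates(surface)
    pair = farthest_pair(coords, index_triples=surface)
    axis = orient_posterior_anterior(pair, anterior_axis=mask.anterior_axis)
    labeling = project_and_bin(mask, axis, n_segments=n_segments)
    if labeling.max_clamp >= 1e-9:
        raise MaskError(
            "projection fell outside the axis segment by "
            f"{labeling.max_clamp:.3e} of the axis length; the axis does not "
            "come from this mask's farthest pair"
        )
    vols = segment_volumes(
        labeling, mask.voxel_volume, participant_id=participant_id,
        hemisphere=hemisphere,
    )
    return vols, labeling


def map_segment_to_region(
    segment_index: int,
    head_fraction: float = DEFAULT_HEAD_FRACTION,
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> str:
    """Classify a segment as hippocampal ``body``, ``transition`` or ``head``.

    Segment s spans fractions [(s-1)/n, s/n) of the posterior->anterior
    length.  With the head occupying the anterior ``head_fraction`` of the
    head+body length, a segment entirely below 1 - head_fraction is body,
    entirely above is head, and a segment straddling the boundary is the
    body/head transition.  With the defaults (n=10, 47% head) segments 1-5
    are body, segment 6 is the transition and segments 7-10 are head.
    """
    if not (0.0 < head_fraction < 1.0):
        raise MaskError(f"head_fraction must be in (0, 1), got {head_fraction}")
    if not (1 <= segment_index <= n_segments):
        raise MaskError(
            f"segment_index must be in 1..{n_segments}, got {segment_index}"
        )
    lo = (segment_index - 1) / n_segments
    hi = segment_index / n_segments
    boundary = 1.0 - head_fraction
    if hi <= boundary:
        return "body"
    if lo >= boundary:
        return "head"
    return "transition"
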