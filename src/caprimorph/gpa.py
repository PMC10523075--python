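"""Generalized Procrustes superimposition with sliding semi-landmarks.

All specimens are superimposed jointly: each configuration is centered,
scaled to unit centroid size and rotated (never reflected) onto the running
consensus, which is itself re-estimated and renormalized until the total
Procrustes sum of squares stabilizes.  When a slider map is supplied,
sliding passes alternate with re-superimposition: each semi-landmark moves
along the chord through its two neighbors to the point closest to the
corresponding consensus landmark, which by construction cannot increase
the specimen's distance to the consensus.

Sliding minimizes Procrustes distance (not bending energy), and the
linearized tangent is the chord through the neighboring points; curves are
not re-interpolated.  Size is recorded as centroid size before any shape
normalization, so sliding never touches it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .morphodata import LandmarkConfiguration, MorphoDataset, SliderMap

logger = logging.getLogger(__name__)


def centroid_size(coords: np.ndarray | LandmarkConfiguration) -> float:
    """Centroid size: root sum of squared landmark deviations from the centroid.

    The standard size variable of landmark morphometrics; scales linearly
    with the coordinates and is invariant to rotation and translation.
    A degenerate all-coincident configuration has CS 0 (logged).
    """
    if isinstance(coords, LandmarkConfiguration):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt(np.sum(centered**2)))
    if cs == 0.0:
        logger.warning("degenerate configuration: all landmarks coincide (CS=0)")
    return cs


def _center_and_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    centered = coords - coords.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs == 0:
        raise ValueError("cannot normalize a zero-size configuration")
    return centered / cs, float(cs)


def optimal_rotation(target: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R (det +1) minimizing ||target - moving @ R||.

    Closed form for 2-D: the optimal angle is atan2(M10-M01, M00+M11) for
    the cross-product matrix M = moving.T @ target, which never produces a
    reflection.
    """
    m = moving.T @ target
    theta = np.arctan2(m[1, 0] - m[0, 1], m[0, 0] + m[1, 1])
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _rotate_all(shapes: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """Rotate every (k,2) shape in an (n,k,2) stack onto the consensus."""
    m = np.einsum("nki,kj->nij", shapes, consensus)  # n x 2 x 2
    theta = np.arctan2(m[:, 1, 0] - m[:, 0, 1], m[:, 0, 0] + m[:, 1, 1])
    c, s = np.cos(theta), np.sin(theta)
    rot = np.empty((len(shapes), 2, 2))
    rot[:, 0, 0] = c
    rot[:, 0, 1] = -s
    rot[:, 1, 0] = s
    rot[:, 1, 1] = c
    return np.einsum("nki,nij->nkj", shapes, rot)


def procrustes_distance(
    a: np.ndarray, b: np.ndarray, allow_reflection: bool = False
) -> float:
    """Partial Procrustes distance between two configurations.

    Both inputs are centered and scaled to unit centroid size, b is rotated
    optimally onto a (rotation only; a reflection is also tried when
    ``allow_reflection``), and the root sum of squared differences is
    returned.  Zero iff the shapes differ only by a similarity transform.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    a_n, _ = _center_and_scale(a)
    b_n, _ = _center_and_scale(b)
    d = np.sqrt(np.sum((a_n - b_n @ optimal_rotation(a_n, b_n)) ** 2))
    if allow_reflection:
        b_r = b_n * np.array([-1.0, 1.0])
        d_r = np.sqrt(np.sum((a_n - b_r @ optimal_rotation(a_n, b_r)) ** 2))
        d = min(d, d_r)
    return float(d)


def slide_semilandmarks(
    shapes: np.ndarray, consensus: np.ndarray, slider_map: SliderMap
) -> np.ndarray:
    """One sliding pass: project each semi-landmark toward the consensus.

    For slider s with neighbors (b, a), the point moves along the unit
    tangent u = (p_a - p_b)/||p_a - p_b|| by t = u . (consensus_s - p_s) —
    the orthogonal projection of the consensus landmark onto the tangent
    line, which minimizes the residual to the consensus along that line.
    Fixed landmarks are untouched; sliders with coincident neighbors are
    left in place and logged.
    """
    shapes = np.asarray(shapes, dtype=float)
    out = shapes.copy()
    trip = np.asarray(slider_map.triplets, dtype=int)
    b_idx, s_idx, a_idx = trip[:, 0], trip[:, 1], trip[:, 2]
    tangent = shapes[:, a_idx, :] - shapes[:, b_idx, :]  # (n, m, 2)
    norm = np.linalg.norm(tangent, axis=2)
    degenerate = norm < 1e-300
    if degenerate.any():
        logger.warning(
            "%d sliders with coincident neighbors left in place", int(degenerate.sum())
        )
        norm = np.where(degenerate, 1.0, norm)
    u = tangent / norm[..., None]
    disp = consensus[None, s_idx, :] - shapes[:, s_idx, :]
    t = np.einsum("nmi,nmi->nm", u, disp)
    t = np.where(degenerate, 0.0, t)
    out[:, s_idx, :] = shapes[:, s_idx, :] + t[..., None] * u
    return out


@dataclass
class AlignedDataset:
    """Superimposed coordinates plus the bookkeeping of the alignment."""

    shapes: np.ndarray  # (n, k, 2) aligned, unit centroid size
    consensus: np.ndarray  # (k, 2), centroid at origin, unit CS
    centroid_sizes: np.ndarray  # (n,) from the raw configurations
    iterations_run: int
    final_change: float
    slider_map: SliderMap | None = None
    converged: bool = True
    specimen_ids: list | None = None
    ss_history: np.ndarray | None = None  # total Procrustes SS per pass

    @property
    def log_centroid_sizes(self) -> np.ndarray:
        return np.log(self.centroid_sizes)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 2k), x1 y1 x2 y2 ..."""
        return self.shapes.reshape(self.n, -1)


def _total_ss(shapes: np.ndarray, consensus: np.ndarray) -> float:
    return float(np.sum((shapes - consensus[None]) ** 2))


def _canonical_orientation(shapes: np.ndarray, consensus: np.ndarray):
    """Rotate the whole superimposition to the consensus principal axes.

    The major axis of the consensus goes to x; the remaining half-turn
    ambiguity is resolved by requiring the first landmark to sit at
    non-negative x (rotation by pi otherwise).  Makes the alignment a
    function of shape alone, independent of the arbitrary orientation of
    the input coordinate systems.
    """
    c = consensus.T @ consensus
    phi = 0.5 * np.arctan2(2.0 * c[0, 1], c[0, 0] - c[1, 1])
    # row-vector convention: p @ rot rotates points by -phi, bringing the
    # major axis (at angle phi) onto x
    cos, sin = np.cos(phi), np.sin(phi)
    rot = np.array([[cos, -sin], [sin, cos]])
    cons = consensus @ rot
    if cons[0, 0] < 0:
        rot = rot @ np.array([[-1.0, 0.0], [0.0, -1.0]])
        cons = consensus @ rot
    return shapes @ rot, cons


def _superimpose(shapes: np.ndarray, consensus: np.ndarray, tol: float, max_iter: int):
    """Classical GPA inner loop: rotate/average until the total SS settles."""
    prev = np.inf
    change = np.inf
    for it in range(1, max_iter + 1):
        shapes = _rotate_all(shapes, consensus)
        consensus, _ = _center_and_scale(shapes.mean(axis=0))
        ss = _total_ss(shapes, consensus)
        change = prev - ss
        if abs(change) < tol:
            return shapes, consensus, ss, change, True
        prev = ss
    return shapes, consensus, prev, change, False


def align_gpa(
    dataset: MorphoDataset | np.ndarray,
    slider_map: SliderMap | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    slide_passes: int = 10,
) -> AlignedDataset:
    """Generalized Procrustes Analysis, optionally with semi-landmark sliding.

    Classical GPA is run to convergence first; with a slider map, up to
    ``slide_passes`` rounds of {slide toward the consensus, renormalize,
    re-superimpose} follow, stopping early once the total Procrustes sum
    of squares changes by less than ``tol``.  Sliding under the
    Procrustes-distance criterion has a nearly flat direction (points
    re-parametrizing along the outline) along which the objective creeps
    indefinitely, so the pass cap — not ``tol`` — is the usual stopping
    rule; after a few passes the remaining displacements are orders of
    magnitude below digitizing noise.  The final configuration is rotated
    to the consensus principal axes, making the output independent of the
    input orientations.

    Parameters
    ----------
    dataset
        A :class:`MorphoDataset` (sides must already be normalized to
        right) or a raw (n, k, 2) coordinate stack.
    slider_map
        Neighbor triplets for the sliding semi-landmarks; ``None`` gives
        classical GPA on fixed landmarks only.
    tol
        Convergence threshold on the change of the total Procrustes sum of
        squares between passes.
    max_iter
        Iteration cap of each classical superimposition loop; exceeding it
        flags the result as unconverged and logs a warning.
    slide_passes
        Number of sliding rounds when ``slider_map`` is given.
    """
    ids = None
    if isinstance(dataset, MorphoDataset):
        sides = {c.side for c in dataset.configurations}
        if "left" in sides:
            raise ValueError("left-side configurations present: mirror before GPA")
        ids = dataset.specimen_ids
        raw = dataset.coords_array()
    else:
        raw = np.asarray(dataset, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != 2:
        raise ValueError(f"expected (n, k, 2) coordinates, got {raw.shape}")
    n = raw.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")

    shapes = np.empty_like(raw)
    sizes = np.empty(n)
    for i in range(n):
        try:
            shapes[i], sizes[i] = _center_and_scale(raw[i])
        except ValueError:
            name = ids[i] if ids else str(i)
            raise ValueError(f"degenerate specimen {name!r}: centroid size 0")

    consensus, _ = _center_and_scale(shapes[0])
    shapes, consensus, ss, change, converged = _superimpose(
        shapes, consensus, tol, max_iter
    )
    iterations = 1
    ss_history = [ss]
    if slider_map is not None:
        for _ in range(slide_passes):
            shapes = slide_semilandmarks(shapes, consensus, slider_map)
            for i in range(n):
                shapes[i], _ = _center_and_scale(shapes[i])
            shapes, consensus, ss_new, _, conv_i = _superimpose(
                shapes, consensus, tol, max_iter
            )
            converged = converged and conv_i
            iterations += 1
            change = ss - ss_new
            ss = ss_new
            ss_history.append(ss)
            if abs(change) < tol:
                break
    if not converged:
        logger.warning(
            "GPA superimposition did not converge in %d iterations "
            "(last change %.3e)",
            max_iter,
            change,
        )
    shapes, consensus = _canonical_orientation(shapes, consensus)
    assert abs(np.sum(consensus.mean(axis=0))) < 1e-9
    return AlignedDataset(
        shapes=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations_run=iterations,
        final_change=float(change),
        slider_map=slider_map,
        converged=converged,
        specimen_ids=ids,
        ss_history=np.array(ss_history),
    )
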