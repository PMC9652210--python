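"""Acetabular rim detection from discrete surface curvature.

The bony acetabular rim is a sharp crest: discrete mean curvature peaks
there, so the rim is recovered by thresholding a per-vertex curvature
field at a high percentile, splitting the super-threshold vertices into
connected components on the mesh graph, and keeping the component that
encircles the cup (angular span > 300° around its own best-fit axis) and
is nearest a seed point. The selected vertices feed the robust circle
fit in :mod:`acetaver.geometry`.

Curvature estimator: cotangent-Laplacian mean curvature with mixed
Voronoi vertex areas (the Meyer et al. discretisation). Curvature is an
intrinsic surface quantity, so the selection is invariant under rigid
motions of the mesh.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import (
    AcetaverError,
    DegenerateInputError,
    DetectionError,
    ValidationError,
)
from .geometry import fit_plane, plane_basis
from .mesh_io import TriangleMesh

log = logging.getLogger(__name__)

#: Minimum angular coverage (degrees) for a component to count as a rim loop.
ENCIRCLE_MIN_SPAN_DEG = 300.0


@dataclass(frozen=True)
class CurvatureField:
    """Per-vertex mean-curvature magnitude (1/mm), aligned with the mesh."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64).reshape(-1)
        )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("curvature field has non-finite values")


@dataclass(frozen=True)
class RimSelection:
    """Vertex indices delineating the acetabular ridge."""

    indices: np.ndarray
    source: str  # "automatic" | "manual"

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64).reshape(-1)
        if len(np.unique(idx)) != len(idx):
            raise ValidationError("rim selection has duplicate vertex indices")
        if len(idx) < 6:
            raise ValidationError("rim selection needs at least 6 vertices")
        object.__setattr__(self, "indices", idx)

    @property
    def n_vertices(self) -> int:
        return int(len(self.indices))


def _face_cotangents(v: np.ndarray, f: np.ndarray):
    """Cotangent of the interior angle at each face corner, plus face areas.

    Degenerate (zero-area) faces are reported via the returned mask.
    """
    p0, p1, p2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    # edge vectors leaving each corner
    u0, w0 = p1 - p0, p2 - p0
    u1, w1 = p2 - p1, p0 - p1
    u2, w2 = p0 - p2, p1 - p2
    cross = np.cross(u0, w0)
    double_area = np.linalg.norm(cross, axis=1)
    ok = double_area > 1e-12
    safe = np.where(ok, double_area, 1.0)
    cots = np.stack(
        [
            np.einsum("ij,ij->i", u0, w0) / safe,
            np.einsum("ij,ij->i", u1, w1) / safe,
            np.einsum("ij,ij->i", u2, w2) / safe,
        ],
        axis=1,
    )
    return cots, double_area / 2.0, ok


def _mixed_voronoi_areas(
    v: np.ndarray, f: np.ndarray, cots: np.ndarray, areas: np.ndarray, ok: np.ndarray
) -> np.ndarray:
    """Meyer mixed Voronoi vertex areas, vectorised over faces."""
    n = len(v)
    sq = np.stack(
        [
            np.sum((v[f[:, 1]] - v[f[:, 2]]) ** 2, axis=1),  # edge opposite corner 0
            np.sum((v[f[:, 2]] - v[f[:, 0]]) ** 2, axis=1),
            np.sum((v[f[:, 0]] - v[f[:, 1]]) ** 2, axis=1),
        ],
        axis=1,
    )
    corner_area = np.empty_like(cots)
    # Voronoi area at corner k uses the two incident edges (opposite the other
    # corners) weighted by the cotangents at those opposite corners.
    for k in range(3):
        a, b = (k + 1) % 3, (k + 2) % 3
        corner_area[:, k] = (sq[:, a] * cots[:, a] + sq[:, b] * cots[:, b]) / 8.0
    obtuse_any = (cots < 0).any(axis=1)
    for k in range(3):
        obtuse_here = cots[:, k] < 0
        corner_area[obtuse_any & obtuse_here, k] = areas[obtuse_any & obtuse_here] / 2.0
        corner_area[obtuse_any & ~obtuse_here, k] = areas[obtuse_any & ~obtuse_here] / 4.0
    corner_area[~ok] = 0.0
    out = np.zeros(n)
    for k in range(3):
        np.add.at(out, f[:, k], corner_area[:, k])
    return out


def _boundary_vertices(f: np.ndarray, n_vertices: int) -> np.ndarray:
    edges = np.sort(
        np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    mask = np.zeros(n_vertices, dtype=bool)
    boundary_edges = uniq[counts == 1]
    mask[boundary_edges.ravel()] = True
    return mask


def vertex_curvature(mesh: TriangleMesh) -> CurvatureField:
    """Discrete mean-curvature magnitude per vertex (1/mm).

    H_i = |Σ_j (cot α_ij + cot β_ij)(x_i − x_j)| / (4 A_mixed,i), the norm of
    half the cotangent-Laplacian mean-curvature normal. Boundary vertices are
    assigned 0 (their one-ring is open, the formula does not apply); zero-area
    faces are skipped with a warning.
    """
    v, f = mesh.vertices, mesh.faces
    cots, areas, ok = _face_cotangents(v, f)
    if not ok.any():
        raise DegenerateInputError("all faces are degenerate; curvature undefined")
    if not ok.all():
        log.warning("skipping %d degenerate (zero-area) faces", int((~ok).sum()))
    cots = np.where(ok[:, None], cots, 0.0)

    n = mesh.n_vertices
    # Laplacian sum S_i = Σ_j w_ij (x_i − x_j), w_ij = cot α_ij + cot β_ij.
    rows, cols, vals = [], [], []
    for k in range(3):
        a, b = (k + 1) % 3, (k + 2) % 3  # edge (a, b) is opposite corner k
        rows.extend([f[:, a], f[:, b]])
        cols.extend([f[:, b], f[:, a]])
        vals.extend([cots[:, k], cots[:, k]])
    W = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    degree = np.asarray(W.sum(axis=1)).ravel()
    S = degree[:, None] * v - W @ v

    area = _mixed_voronoi_areas(v, f, cots, areas, ok)
    H = np.zeros(n)
    interior = (area > 1e-12) & ~_boundary_vertices(f, n)
    H[interior] = np.linalg.norm(S[interior], axis=1) / (4.0 * area[interior])
    return CurvatureField(H)


def _ring_geometry(points: np.ndarray) -> tuple[float, bool]:
    """(angular span in degrees, ring-likeness) of a vertex cluster.

    Span is the angular coverage around the cluster's own best-fit axis. A
    cluster only counts as ring-like when it has a hole: its in-plane radii
    must stay well away from zero (a filled blob covers 360° around its own
    centroid, but its smallest radii vanish).
    """
    try:
        plane = fit_plane(points)
    except DegenerateInputError:
        return 0.0, False
    e1, e2 = plane_basis(plane.normal)
    rel = points - points.mean(axis=0)
    u, w = rel @ e1, rel @ e2
    radii = np.hypot(u, w)
    ring_like = np.percentile(radii, 10) > 0.4 * np.percentile(radii, 90)
    ang = np.sort(np.arctan2(w, u))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    return float(np.degrees(2 * np.pi - gaps.max())), bool(ring_like)


def select_rim(
    mesh: TriangleMesh,
    curvature: CurvatureField,
    seed=None,
    percentile: float = 90.0,
) -> RimSelection:
    """Select the high-curvature loop delineating the acetabular rim.

    Vertices above the ``percentile`` of the curvature distribution are
    grouped into connected components on the mesh edge graph; components
    that encircle their own axis (angular span > 300°) are rim candidates.
    With a ``seed`` point the candidate closest to it wins, otherwise the
    largest. Raises :class:`DetectionError` when no candidate exists —
    callers may fall back to a manual rim vertex list.
    """
    values = curvature.values
    if len(values) != mesh.n_vertices:
        raise ValidationError("curvature field is not aligned with the mesh")
    threshold = np.percentile(values, percentile)
    selected = np.flatnonzero(values > threshold)
    if len(selected) < 6:
        raise DetectionError("no high-curvature region found")

    # connected components of the selected vertices on the mesh edge graph
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[selected] = np.arange(len(selected))
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e = remap[edges]
    e = e[(e >= 0).all(axis=1)]
    graph = coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(selected),) * 2
    )
    n_comp, labels = connected_components(graph, directed=False)

    candidates = []
    for c in range(n_comp):
        idx = selected[labels == c]
        if len(idx) < 6:
            continue
        span, ring_like = _ring_geometry(mesh.vertices[idx])
        if span >= ENCIRCLE_MIN_SPAN_DEG and ring_like:
            candidates.append(idx)
    if not candidates:
        raise DetectionError(
            "no encircling high-curvature loop found (is the percentile too low,"
            " or the rim too smooth?)"
        )
    if seed is not None:
        seed = np.asarray(seed, dtype=np.float64).reshape(3)
        dists = [
            np.linalg.norm(mesh.vertices[idx] - seed, axis=1).min()
            for idx in candidates
        ]
        best = candidates[int(np.argmin(dists))]
    else:
        best = max(candidates, key=len)
    return RimSelection(best, source="automatic")


#: Percentiles tried by automatic rim detection, sharp features first.
PERCENTILE_LADDER = (97.0, 95.0, 92.5, 90.0, 87.5, 85.0, 82.5, 80.0)

#: Minimum vertex count for an automatically detected rim loop.
MIN_AUTO_RIM_VERTICES = 24

#: Maximum circle-fit RMS residual relative to the radius for a candidate.
MAX_RELATIVE_RMS = 0.05


def detect_rim(
    mesh: TriangleMesh,
    seed=None,
    percentile: float | None = None,
    smooth_iterations: int = 10,
    refine_quantile: float = 50.0,
) -> RimSelection:
    """Noise-tolerant automatic rim detection.

    Two measures make the raw percentile selection usable on imperfect
    meshes:

    * Measurement noise on the vertices inflates discrete curvature by
      σ/h² and can drown the crest, so the curvature used for *detection*
      is computed on a Laplacian-smoothed copy of the mesh; the returned
      vertex indices refer to the original geometry, which is what the
      circle fit should see.
    * The percentile that isolates the crest depends on how much of the
      surface is curved or noisy, so by default a ladder of percentiles
      (97 down to 80) is scanned. Each percentile's ring candidate is
      trimmed to the upper ``refine_quantile`` of its own curvature (the
      crest is the maximum of its band) and gated on robust circle-fit
      quality (RMS below 5% of the radius); among surviving candidates
      the one nearest the ``seed`` wins (largest without a seed). Passing
      an explicit ``percentile`` disables the ladder.
    """
    detect_mesh = mesh
    if smooth_iterations > 0:
        import trimesh as _tm

        tm = mesh.to_trimesh()
        _tm.smoothing.filter_laplacian(
            tm, lamb=0.5, iterations=smooth_iterations, volume_constraint=False
        )
        detect_mesh = TriangleMesh(
            np.asarray(tm.vertices, dtype=np.float64),
            np.asarray(tm.faces, dtype=np.int64),
        )
    curvature = vertex_curvature(detect_mesh)
    ladder = (percentile,) if percentile is not None else PERCENTILE_LADDER

    from .geometry import fit_circle3d  # local import, avoids cycle at load

    best: RimSelection | None = None
    best_score = np.inf
    seen: set[bytes] = set()
    for pct in ladder:
        try:
            sel = select_rim(detect_mesh, curvature, seed=seed, percentile=pct)
        except DetectionError:
            continue
        if refine_quantile > 0:
            vals = curvature.values[sel.indices]
            keep = vals >= np.percentile(vals, refine_quantile)
            if keep.sum() >= 6:
                span, ring_like = _ring_geometry(mesh.vertices[sel.indices[keep]])
                if span >= ENCIRCLE_MIN_SPAN_DEG and ring_like:
                    sel = RimSelection(sel.indices[keep], source="automatic")
        if sel.n_vertices < MIN_AUTO_RIM_VERTICES:
            continue
        key = sel.indices.tobytes()
        if key in seen:
            continue
        seen.add(key)
        try:
            circle = fit_circle3d(mesh.vertices[sel.indices])
        except AcetaverError as exc:
            log.debug("rim candidate at pct %.1f rejected: %s", pct, exc)
            continue
        if circle.fit_report.rms_residual > MAX_RELATIVE_RMS * circle.radius:
            continue
        if seed is not None:
            score = float(
                np.linalg.norm(
                    mesh.vertices[sel.indices] - np.asarray(seed, float), axis=1
                ).mean()
            )
        else:
            score = -float(sel.n_vertices)
        if score < best_score:
            best, best_score = sel, score
    if best is None:
        raise DetectionError(
            "no acceptable high-curvature rim loop found at any percentile"
        )
    return best


def read_rim(path: str | Path) -> RimSelection:
    """Read a manual rim override: a JSON list of vertex indices."""
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, list):
        raise ValidationError(f"rim file {path} must hold a JSON list of indices")
    return RimSelection(np.asarray(raw, dtype=np.int64), source="manual")
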