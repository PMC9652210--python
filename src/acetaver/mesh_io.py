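"""Mesh, landmark and result I/O.

Coordinate convention
---------------------
All geometry lives in the DICOM patient frame for a supine subject (LPS):
X to the patient's left, Y posterior (vertical for a supine patient on the
table), Z cranial. Anterior is therefore −Y. Units are millimetres; STL
carries no unit metadata, so this is a documented contract of the package.

STL/PLY parsing and writing are delegated to :mod:`trimesh`; validation,
welding and the :class:`TriangleMesh` contract are defined here.
"""

from __future__ import annotations

import csv
import logging
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import trimesh

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: Welding tolerance in mm: vertices closer than this are merged on read.
WELD_TOL_MM = 1e-6

#: Landmark names required to construct the anterior pelvic plane.
APP_LANDMARKS = ("ASISL", "ASISR", "PT")


@dataclass(frozen=True)
class ScannerFrame:
    """Orthonormal right-handed axes of the CT table in the data's frame.

    The default is the identity LPS frame: X transverse (patient left),
    Y sagittal (posterior; vertical for a supine patient), Z longitudinal
    (cranial).
    """

    x: tuple = (1.0, 0.0, 0.0)
    y: tuple = (0.0, 1.0, 0.0)
    z: tuple = (0.0, 0.0, 1.0)
    convention: str = "LPS"

    def __post_init__(self):
        M = np.array([self.x, self.y, self.z], dtype=np.float64)
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise ValidationError("scanner frame axes must be orthonormal")
        if np.linalg.det(M) < 0:
            raise ValidationError("scanner frame must be right-handed")
        object.__setattr__(self, "x", np.asarray(self.x, dtype=np.float64))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=np.float64))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=np.float64))

    def coords(self, v) -> np.ndarray:
        """Components of a vector along the frame axes."""
        v = np.asarray(v, dtype=np.float64).reshape(3)
        return np.array([v @ self.x, v @ self.y, v @ self.z])


#: The default DICOM patient frame for a supine subject.
LPS = ScannerFrame()


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetres.

    Attributes
    ----------
    vertices : (n, 3) float64 array
    faces : (m, 3) int array of vertex indices
    vertex_attributes : mapping of per-vertex scalar fields (e.g. curvature)
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        validate_mesh(self)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def transformed(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology with replaced vertex positions (attributes carried)."""
        return TriangleMesh(vertices, self.faces.copy(), dict(self.vertex_attributes))


class LandmarkSet(dict):
    """Named 3D anatomical points (mm), a thin dict subclass.

    Required names depend on the operation: the anterior pelvic plane needs
    ASISL, ASISR and PT; the 2D comparator additionally uses FHC_L/FHC_R
    (femoral head centres) and a posterior reference pair (SN_L/SN_R at the
    sciatic notch, or IT_L/IT_R at the ischial tuberosities). Unknown names
    are preserved.
    """

    def __init__(self, points: Mapping[str, Iterable[float]] | None = None):
        super().__init__()
        if points:
            for name, p in points.items():
                self[name] = p

    def __setitem__(self, name: str, point) -> None:
        try:
            arr = np.asarray(point, dtype=np.float64).reshape(-1)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"landmark {name!r} is not numeric: {point!r}") from exc
        if arr.shape != (3,):
            raise ValidationError(f"landmark {name!r} is not a 3D point: {point!r}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"landmark {name!r} has non-finite coordinates")
        super().__setitem__(str(name), arr)

    def require(self, *names: str) -> list[np.ndarray]:
        missing = [n for n in names if n not in self]
        if missing:
            raise ValidationError(f"missing required landmark(s): {', '.join(missing)}")
        return [self[n] for n in names]

    def transformed(self, fn) -> "LandmarkSet":
        """Apply ``fn`` (point -> point) to every landmark."""
        out = LandmarkSet()
        for name, p in self.items():
            out[name] = fn(p)
        return out


def validate_mesh(mesh: TriangleMesh) -> None:
    v, f = mesh.vertices, mesh.faces
    if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] == 0:
        raise ValidationError("mesh has no vertices or wrong vertex shape")
    if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] == 0:
        raise ValidationError("mesh has no faces or wrong face shape")
    if not np.all(np.isfinite(v)):
        raise ValidationError("mesh has non-finite vertex coordinates")
    if f.min() < 0 or f.max() >= v.shape[0]:
        raise ValidationError("face index out of range")
    if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
        raise ValidationError("a face references a repeated vertex")


def weld_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = WELD_TOL_MM
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol`` (grid quantization; idempotent)."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    new_vertices = vertices[np.sort(first)]
    new_faces = rank[inverse][faces]
    # drop faces that collapsed during welding
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return new_vertices, new_faces[keep]


def read_mesh(path: str | Path) -> TriangleMesh:
    """Read a triangle mesh from STL (binary or ASCII) or PLY.

    Duplicate vertices are welded at 1e-6 mm so STL's per-facet vertex
    replication becomes a proper indexed mesh.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        loaded = trimesh.load(str(path), process=False, force="mesh")
    except Exception as exc:  # trimesh raises assorted types on bad files
        raise FormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise ValidationError(f"mesh file {path} contains no triangles")
    v, f = weld_vertices(
        np.asarray(loaded.vertices, dtype=np.float64),
        np.asarray(loaded.faces, dtype=np.int64),
    )
    return TriangleMesh(v, f)


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as binary STL (or PLY by extension)."""
    path = Path(path)
    mesh.to_trimesh().export(str(path))


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a JSON landmark file mapping names to ``[x, y, z]`` in mm.

    A duplicated key keeps its last occurrence (JSON-dialect decision); a
    warning is logged because duplicate landmark names usually indicate an
    editing mistake.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"landmark file not found: {path}")

    def _check_dupes(pairs):
        names = [k for k, _ in pairs]
        seen = set()
        for n in names:
            if n in seen:
                log.warning("duplicate landmark %r in %s: last occurrence wins", n, path)
            seen.add(n)
        return dict(pairs)

    try:
        raw = json.loads(path.read_text(), object_pairs_hook=_check_dupes)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed landmark JSON {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValidationError(f"landmark file {path} must hold a JSON object")
    return LandmarkSet(raw)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: list(map(float, v)) for k, v in landmarks.items()}, indent=2)
        + "\n"
    )


#: Deterministic result-CSV column order (one row per hemipelvis).
RESULT_COLUMNS = (
    "id",
    "side",
    "av3d_deg",
    "av2d_stem_deg",
    "av2d_tallroth_deg",
    "lambda_deg",
    "rho_deg",
    "delta_deg",
)


def write_results(results: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write per-hemipelvis results to CSV (RFC 4180, '.' decimals).

    ``results`` is an iterable of mappings; recognised keys are
    :data:`RESULT_COLUMNS` (missing numeric fields are left empty). The
    delta column is recomputed as av3d − av2d_stem when both are present,
    so the file can never carry an inconsistent difference.
    """
    rows = list(results)
    if not rows:
        raise ValidationError("no results to write")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RESULT_COLUMNS)
        for row in rows:
            rec = dict(row)
            av3 = rec.get("av3d_deg")
            av2 = rec.get("av2d_stem_deg")
            if av3 is not None and av2 is not None:
                rec["delta_deg"] = float(av3) - float(av2)
            out = []
            for col in RESULT_COLUMNS:
                val = rec.get(col)
                if val is None:
                    out.append("")
                elif isinstance(val, float):
                    out.append(f"{val:.6f}")
                else:
                    out.append(str(val))
            writer.writerow(out)


def read_results(path: str | Path):
    """Read a result CSV back into a list of dicts (floats where possible)."""
    import pandas as pd

    df = pd.read_csv(path)
    return df.to_dict(orient="records")
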