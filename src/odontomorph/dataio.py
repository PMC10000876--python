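"""Readers, writers and validated in-memory types for crown-shape data.

All coordinates are real-valued millimetres. On-disk formats are deliberately
plain: two-column CSV for outlines, STL/PLY for meshes, JSON for landmark
sets, CSV for morphotype/measurement tables and an ESRI-style ASCII grid for
height maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import trimesh as _trimesh


class OdontomorphError(Exception):
    """Base class for package errors."""


class FormatError(OdontomorphError, ValueError):
    """Raised when an on-disk file violates its documented format."""


class DomainError(OdontomorphError, ValueError):
    """Raised when a computation is asked for outside its domain."""


# --------------------------------------------------------------------------
# outlines
# --------------------------------------------------------------------------

TOOTH_CLASSES = ("M1_upper", "M1_lower")
COHORTS = ("WT", "mutant")


def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class ClosedOutline:
    """An ordered loop of 2D points (mm); the closing edge is implicit.

    Orientation is forced counter-clockwise on construction so chirality
    conventions are uniform across the analysis; the first point is kept
    in place when the loop is reversed.
    """

    points: np.ndarray
    label: str = ""
    tooth_class: str = "M1_upper"
    cohort: str = "WT"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise FormatError("outline points must be an (n, 2) array")
        if pts.shape[0] < 3:
            raise FormatError("an outline needs at least 3 distinct points")
        if not np.all(np.isfinite(pts)):
            raise FormatError("outline coordinates must be finite")
        closed = np.vstack([pts, pts[:1]])
        if np.any(np.all(np.diff(closed, axis=0) == 0.0, axis=1)):
            raise FormatError("consecutive duplicate points in outline")
        if _signed_area(pts) < 0.0:
            pts = np.vstack([pts[:1], pts[:0:-1]])
        object.__setattr__(self, "points", pts)

    @classmethod
    def from_points(
        cls,
        points: Iterable[Iterable[float]],
        label: str = "",
        tooth_class: str = "M1_upper",
        cohort: str = "WT",
    ) -> "ClosedOutline":
        """Build an outline, collapsing exact consecutive duplicates and an
        explicit closure point (last point equal to the first)."""
        pts = np.asarray(list(points), dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise FormatError("outline points must be an (n, 2) array")
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        pts = pts[keep]
        if len(pts) > 1 and np.all(pts[-1] == pts[0]):
            pts = pts[:-1]
        if len(pts) < 3:
            raise FormatError("an outline needs at least 3 distinct points")
        return cls(pts, label=label, tooth_class=tooth_class, cohort=cohort)

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.points, self.points[:1]])
        return float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))


def read_outline(
    path: str | Path,
    label: str = "",
    tooth_class: str = "M1_upper",
    cohort: str = "WT",
) -> ClosedOutline:
    """Read a two-column (x, y) CSV, header optional, into a ClosedOutline."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such outline file: {path}")
    try:
        frame = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"unreadable outline file {path}: {exc}") from exc
    # optional single header line
    first = frame.iloc[0]
    if any(isinstance(v, str) for v in first):
        try:
            [float(v) for v in first]
        except (TypeError, ValueError):
            frame = frame.iloc[1:]
    if frame.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns, got {frame.shape[1]}")
    try:
        pts = frame.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell in outline: {exc}") from exc
    if not label:
        label = path.stem
    return ClosedOutline.from_points(pts, label=label, tooth_class=tooth_class, cohort=cohort)


def write_outline(outline: ClosedOutline, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("x,y\n")
        for x, y in outline.points:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


# --------------------------------------------------------------------------
# meshes and landmarks
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TriangleMesh:
    """A triangle surface mesh; vertices in mm, faces as vertex-index triples."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        faces = np.asarray(self.faces, dtype=np.int64)
        if verts.ndim != 2 or verts.shape[1] != 3:
            raise FormatError("mesh vertices must be an (n, 3) array")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise FormatError("mesh faces must be an (m, 3) index array")
        if not np.all(np.isfinite(verts)):
            raise FormatError("mesh vertices must be finite")
        if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
            raise FormatError("face index out of vertex range")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "faces", faces)

    @classmethod
    def from_trimesh(cls, mesh: "_trimesh.Trimesh") -> "TriangleMesh":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=np.int64))

    def to_trimesh(self) -> "_trimesh.Trimesh":
        return _trimesh.Trimesh(vertices=self.vertices.copy(), faces=self.faces.copy(), process=False)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def mean_edge_length(self) -> float:
        v, f = self.vertices, self.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return float(np.mean(np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)))


def read_mesh(path: str | Path) -> TriangleMesh:
    """Load an STL (binary or ASCII) or PLY mesh.

    Coincident vertices (within 1e-9 mm) are merged — STL stores a triangle
    soup — and zero-area faces are dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such mesh file: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty mesh file: {path}")
    try:
        loaded = _trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise FormatError(f"unreadable mesh file {path}: {exc}") from exc
    if not isinstance(loaded, _trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(f"{path}: no triangle data found")
    loaded.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
    loaded.update_faces(loaded.nondegenerate_faces(height=1e-12))
    loaded.remove_unreferenced_vertices()
    return TriangleMesh.from_trimesh(loaded)


def write_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as ASCII STL or PLY according to the file extension."""
    path = Path(path)
    tm = mesh.to_trimesh()
    suffix = path.suffix.lower()
    if suffix == ".stl":
        data = _trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(data)
    elif suffix == ".ply":
        data = _trimesh.exchange.ply.export_ply(tm, encoding="ascii")
        path.write_bytes(data)
    else:
        raise FormatError(f"unsupported mesh format: {suffix!r} (use .stl or .ply)")


HUMAN_CUSPS = ("protocone", "metacone", "paracone", "hypocone")
MOUSE_CUSPS = ("c5", "c6", "c8", "c9")
# cross-species cusp homology used for landmark pairing
DEFAULT_CUSP_PAIRING = {
    "protocone": "c5",
    "metacone": "c6",
    "paracone": "c8",
    "hypocone": "c9",
}


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3D points (mm) marking cusp tips on a crown surface."""

    entries: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, point in dict(self.entries).items():
            pt = np.asarray(point, dtype=float).reshape(3)
            if not np.all(np.isfinite(pt)):
                raise FormatError(f"landmark {name!r} has non-finite coordinates")
            clean[str(name)] = pt
        object.__setattr__(self, "entries", clean)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    @property
    def names(self) -> tuple:
        return tuple(self.entries)

    def as_array(self, names: Iterable[str]) -> np.ndarray:
        return np.array([self.entries[n] for n in names], dtype=float)


def read_landmarks(path: str | Path) -> LandmarkSet:
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except Exception as exc:
        raise FormatError(f"unreadable landmark file {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: landmark JSON must map names to [x, y, z]")
    return LandmarkSet(raw)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    payload = {name: [float(c) for c in pt] for name, pt in landmarks.entries.items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# --------------------------------------------------------------------------
# morphotype and measurement tables
# --------------------------------------------------------------------------

M1_PROFILE_STATES = ("V", "U", "missing")
M2_SPUR_STATES = ("present", "absent", "missing")
M3_C1_STATES = ("normal", "reduced", "big", "missing")
SIDES = ("right", "left")

MORPHOTYPE_TRAITS = {
    "m1_c1c2_profile": M1_PROFILE_STATES,
    "m2_spur": M2_SPUR_STATES,
    "m3_c1": M3_C1_STATES,
}

# raw survey tokens -> controlled vocabulary; "-" encodes the unremarkable
# state of each trait (spur present, c1 normal)
_M1_TOKENS = {"V-shape": "V", "U-shape": "U", "V": "V", "U": "U", "missing": "missing"}
_M2_TOKENS = {"-": "present", "no spur": "absent", "present": "present",
              "absent": "absent", "missing": "missing"}
_M3_TOKENS = {"-": "normal", "normal": "normal", "reduced": "reduced",
              "big": "big", "missing": "missing"}
_COHORT_TOKENS = {"WT": "WT", "wt": "WT", "mutant": "mutant",
                  "Jag1fl/fl": "mutant", "K14Cre;Jagged1fl/fl": "mutant"}


@dataclass(frozen=True)
class MorphotypeTable:
    """Per specimen-side categorical crown-trait scores (upper molars).

    Columns: specimen, cohort, side, m1_c1c2_profile, m2_spur, m3_c1,
    abnormal_cusp (free-text code, may be empty).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["specimen", "cohort", "side", "m1_c1c2_profile", "m2_spur", "m3_c1"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise FormatError(f"morphotype table missing columns: {missing}")
        frame = self.frame.copy()
        if "abnormal_cusp" not in frame.columns:
            frame["abnormal_cusp"] = ""
        frame["abnormal_cusp"] = frame["abnormal_cusp"].fillna("")
        for col, vocab in (("cohort", COHORTS), ("side", SIDES),
                           ("m1_c1c2_profile", M1_PROFILE_STATES),
                           ("m2_spur", M2_SPUR_STATES), ("m3_c1", M3_C1_STATES)):
            bad = set(frame[col]) - set(vocab)
            if bad:
                raise FormatError(f"unknown {col} value(s): {sorted(bad)}")
        object.__setattr__(self, "frame", frame.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


def _decode(token: str, mapping: Mapping[str, str], column: str) -> str:
    token = str(token).strip()
    if token not in mapping:
        raise FormatError(f"unknown token {token!r} in column {column!r}")
    return mapping[token]


def read_morphotype_table(path: str | Path) -> MorphotypeTable:
    """Read a long-format morphotype CSV (one row per specimen-side).

    Accepts both the raw survey tokens ("V-shape", "no spur", "-",
    "Jag1fl/fl") and the controlled vocabulary ("V", "absent", "present",
    "mutant"). Unknown tokens raise a FormatError naming the token.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"unreadable morphotype table {path}: {exc}") from exc
    required = ["specimen", "cohort", "side", "m1_c1c2_profile", "m2_spur", "m3_c1"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    rows = []
    for _, row in raw.iterrows():
        side = str(row["side"]).strip().lower()
        if side not in SIDES:
            raise FormatError(f"unknown token {row['side']!r} in column 'side'")
        rows.append({
            "specimen": str(row["specimen"]).strip(),
            "cohort": _decode(row["cohort"], _COHORT_TOKENS, "cohort"),
            "side": side,
            "m1_c1c2_profile": _decode(row["m1_c1c2_profile"], _M1_TOKENS, "m1_c1c2_profile"),
            "m2_spur": _decode(row["m2_spur"], _M2_TOKENS, "m2_spur"),
            "m3_c1": _decode(row["m3_c1"], _M3_TOKENS, "m3_c1"),
            "abnormal_cusp": str(row.get("abnormal_cusp", "")).strip(),
        })
    return MorphotypeTable(pd.DataFrame(rows))


def load_upper_molar_survey() -> MorphotypeTable:
    """The packaged upper-molar morphotype survey (33 mutant + 21 WT mice,
    scored on both sides: 108 rows)."""
    with resources.as_file(
        resources.files("odontomorph.data") / "upper_molar_morphotypes.csv"
    ) as path:
        return read_morphotype_table(path)


@dataclass(frozen=True)
class MeasurementTable:
    """Linear crown measurements (mm): L, W and the inter-cusp distances d1-d5."""

    frame: pd.DataFrame

    _VALUE_COLS = ("L", "W", "d1", "d2", "d3", "d4", "d5")

    def __post_init__(self) -> None:
        for col in ("specimen", "cohort", "tooth"):
            if col not in self.frame.columns:
                raise FormatError(f"measurement table missing column {col!r}")
        frame = self.frame.copy()
        for col in self._VALUE_COLS:
            if col not in frame.columns:
                continue
            vals = pd.to_numeric(frame[col], errors="raise")
            present = vals.notna()
            if np.any(~np.isfinite(vals[present])) or np.any(vals[present] <= 0):
                raise FormatError(f"column {col!r}: measurements must be positive and finite")
            frame[col] = vals
        object.__setattr__(self, "frame", frame.reset_index(drop=True))


def read_measurement_table(path: str | Path) -> MeasurementTable:
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"unreadable measurement table {path}: {exc}") from exc
    return MeasurementTable(frame)


# --------------------------------------------------------------------------
# height maps
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HeightMap:
    """z values on a regular (x, y) lattice; NaN cells are masked out.

    ``spacing`` is the cell size in mm (default 0.05 mm, i.e. a 50 µm grid);
    ``origin`` is the (x, y) position of cell [0, 0].
    """

    z: np.ndarray
    spacing: float = 0.05
    origin: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2:
            raise FormatError("height map must be a 2D grid")
        if not self.spacing > 0:
            raise FormatError("height-map spacing must be > 0")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "origin", (float(self.origin[0]), float(self.origin[1])))

    @property
    def mask(self) -> np.ndarray:
        """True where the cell holds a valid height."""
        return np.isfinite(self.z)

    def xy_grids(self) -> tuple:
        ny, nx = self.z.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)


_NODATA = -9999.0


def read_heightmap(path: str | Path) -> HeightMap:
    """Read an ESRI-style ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize)."""
    path = Path(path)
    header: dict = {}
    rows: list = []
    try:
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if parts[0].isalpha() or parts[0].lower().startswith(("ncols", "nrows", "xll", "yll", "cell", "nodata")):
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(v) for v in parts])
    except (OSError, ValueError, IndexError) as exc:
        raise FormatError(f"unreadable height map {path}: {exc}") from exc
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise FormatError(f"{path}: missing grid header field {key!r}")
    z = np.asarray(rows, dtype=float)
    if z.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(f"{path}: grid body does not match declared nrows x ncols")
    z = np.flipud(z)  # ASCII grids store the top row first
    nodata = header.get("nodata_value", _NODATA)
    z[z == nodata] = np.nan
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    return HeightMap(z, spacing=float(header["cellsize"]), origin=origin)


def write_heightmap(hmap: HeightMap, path: str | Path) -> None:
    ny, nx = hmap.z.shape
    z = np.where(np.isfinite(hmap.z), hmap.z, _NODATA)
    lines = [
        f"ncols {nx}",
        f"nrows {ny}",
        f"xllcorner {hmap.origin[0]!r}",
        f"yllcorner {hmap.origin[1]!r}",
        f"cellsize {hmap.spacing!r}",
        f"NODATA_value {_NODATA!r}",
    ]
    for row in np.flipud(z):
        lines.append(" ".join(f"{float(v)!r}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")
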