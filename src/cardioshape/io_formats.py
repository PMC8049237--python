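"""Legacy ASCII VTK unstructured-grid I/O and cohort CSV tables.

The published cohorts ship tetrahedral meshes as legacy ASCII VTK
UNSTRUCTURED_GRID files: POINTS (mm), CELLS, CELL_TYPES (all 10), optional
CELL_DATA with the meshing tags and two VECTORS fields for fibre and sheet
directions, and optional POINT_DATA with four scalar lookup tables holding
the UVC in the order rho, phi, Z, V (-10 sentinel outside the ventricles).
This module reads and writes exactly that layout.  Only tetrahedra are
supported; the XML VTK formats are out of scope.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .mesh import MeshIntegrityError, TetMesh, UnsupportedElementError

__all__ = [
    "VTKParseError",
    "read_vtk_mesh",
    "write_vtk_mesh",
    "write_cohort_tables",
    "read_cohort_tables",
]

VTK_TET = 10


class VTKParseError(ValueError):
    """Raised on a malformed legacy VTK file; the message names the line."""


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------
class _Tokens:
    """Line-aware token stream over an ASCII VTK body."""

    def __init__(self, lines: list[str]):
        self.lines = lines
        self.i = 0  # current line (0-based)
        self.buf: list[str] = []

    def next_line(self) -> str:
        while self.i < len(self.lines):
            line = self.lines[self.i]
            self.i += 1
            if line.strip():
                return line
        raise VTKParseError("unexpected end of file")

    def peek_keyword_line(self) -> Optional[str]:
        j = self.i
        while j < len(self.lines):
            if self.lines[j].strip():
                return self.lines[j]
            j += 1
        return None

    def read_numbers(self, count: int, kind=float) -> np.ndarray:
        """Read `count` whitespace-separated numbers spanning lines."""
        out = np.empty(count, dtype=kind)
        k = 0
        while k < count:
            if not self.buf:
                line = self.next_line()
                self.buf = line.split()
            while self.buf and k < count:
                tok = self.buf.pop(0)
                try:
                    out[k] = kind(tok)
                except ValueError as exc:
                    raise VTKParseError(
                        f"line {self.i}: expected a number, got {tok!r}"
                    ) from exc
                k += 1
        return out


def read_vtk_mesh(path: Union[str, Path]) -> TetMesh:
    """Read a legacy ASCII VTK unstructured grid into a :class:`TetMesh`.

    Raises
    ------
    VTKParseError
        On a malformed header or body (the message names the line).
    UnsupportedElementError
        If any cell type differs from 10 (tetrahedron).
    MeshIntegrityError
        If connectivity indices fall outside ``[0, n_points)``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 4:
        raise VTKParseError("line 1: file too short for a legacy VTK header")
    if not lines[0].startswith("# vtk DataFile"):
        raise VTKParseError(f"line 1: expected '# vtk DataFile ...', got {lines[0]!r}")
    if lines[2].strip().upper() != "ASCII":
        raise VTKParseError(f"line 3: expected 'ASCII', got {lines[2]!r}")
    dataset = lines[3].split()
    if len(dataset) != 2 or dataset[0] != "DATASET" or dataset[1] != "UNSTRUCTURED_GRID":
        raise VTKParseError(
            f"line 4: expected 'DATASET UNSTRUCTURED_GRID', got {lines[3]!r}"
        )

    toks = _Tokens(lines)
    toks.i = 4

    points = tets = cell_labels = fibre = sheet = None
    uvc_cols: dict[str, np.ndarray] = {}
    n_points = n_cells = 0
    section = None  # None | "cell" | "point"

    while True:
        line = toks.peek_keyword_line()
        if line is None:
            break
        key = line.split()[0].upper()
        header = toks.next_line().split()
        lineno = toks.i
        if key == "POINTS":
            n_points = int(header[1])
            points = toks.read_numbers(3 * n_points).reshape(n_points, 3)
        elif key == "CELLS":
            n_cells = int(header[1])
            total = int(header[2])
            raw = toks.read_numbers(total, kind=np.int64)
            conn, pos = [], 0
            for c in range(n_cells):
                npts = int(raw[pos])
                if npts != 4:
                    raise UnsupportedElementError(
                        f"cell {c} has {npts} vertices; only tetrahedra supported"
                    )
                conn.append(raw[pos + 1 : pos + 5])
                pos += npts + 1
            tets = np.vstack(conn)
        elif key == "CELL_TYPES":
            n = int(header[1])
            types = toks.read_numbers(n, kind=np.int64)
            bad = np.nonzero(types != VTK_TET)[0]
            if bad.size:
                raise UnsupportedElementError(
                    f"cell {bad[0]} has VTK type {types[bad[0]]}; expected 10"
                )
        elif key == "CELL_DATA":
            section = "cell"
        elif key == "POINT_DATA":
            section = "point"
        elif key == "SCALARS":
            name = header[1]
            ncomp = int(header[3]) if len(header) > 3 else 1
            nxt = toks.peek_keyword_line()
            if nxt is not None and nxt.split()[0].upper() == "LOOKUP_TABLE":
                toks.next_line()
            count = (n_cells if section == "cell" else n_points) * ncomp
            vals = toks.read_numbers(count)
            if section == "cell":
                cell_labels = vals.astype(np.int64)
            else:
                uvc_cols[name] = vals
        elif key == "VECTORS":
            name = header[1].lower()
            count = n_cells if section == "cell" else n_points
            vec = toks.read_numbers(3 * count).reshape(count, 3)
            if "sheet" in name:
                sheet = vec
            else:
                fibre = vec
        elif key == "LOOKUP_TABLE":
            # stray table definition; skip its entries if sized
            if len(header) > 2:
                toks.read_numbers(4 * int(header[2]))
        else:
            raise VTKParseError(f"line {lineno}: unrecognised section {key!r}")

    if points is None or tets is None:
        raise VTKParseError("file lacks POINTS or CELLS section")
    if tets.size and (tets.min() < 0 or tets.max() >= n_points):
        raise MeshIntegrityError(
            f"connectivity index out of range [0, {n_points})"
        )

    uvc = None
    if uvc_cols:
        order = ["rho", "phi", "Z", "V"]
        cols = [uvc_cols[k] for k in order if k in uvc_cols]
        if len(cols) != 4:
            cols = list(uvc_cols.values())  # tolerate foreign names, keep order
        uvc = np.column_stack(cols)

    return TetMesh(
        points=points,
        tets=tets,
        cell_labels=cell_labels,
        fibre_dir=fibre,
        sheet_dir=sheet,
        uvc=uvc,
        name=path.stem,
    )


# ----------------------------------------------------------------------
# writing
# ----------------------------------------------------------------------
def _fmt(values: np.ndarray, per_line: int) -> str:
    flat = np.asarray(values).reshape(-1, per_line)
    return "\n".join(" ".join(f"{v:.17g}" for v in row) for row in flat)


def write_vtk_mesh(mesh: TetMesh, path: Union[str, Path]) -> Path:
    """Write a :class:`TetMesh` as a legacy ASCII VTK unstructured grid.

    Sections are emitted in the order POINTS, CELLS, CELL_TYPES, then
    CELL_DATA (tags as SCALARS, fibre/sheet as VECTORS) and POINT_DATA
    (four UVC scalar lookup tables in the order rho, phi, Z, V) when present.
    """
    mesh.validate()
    path = Path(path)
    parts = [
        "# vtk DataFile Version 3.0",
        mesh.name,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_points} double",
        _fmt(mesh.points, 3),
        f"CELLS {mesh.n_tets} {5 * mesh.n_tets}",
        "\n".join("4 " + " ".join(str(i) for i in tet) for tet in mesh.tets),
        f"CELL_TYPES {mesh.n_tets}",
        "\n".join(["10"] * mesh.n_tets),
    ]
    has_cell_data = (
        mesh.cell_labels is not None
        or mesh.fibre_dir is not None
        or mesh.sheet_dir is not None
    )
    if has_cell_data:
        parts.append(f"CELL_DATA {mesh.n_tets}")
        if mesh.cell_labels is not None:
            parts.append("SCALARS elemTag int 1")
            parts.append("LOOKUP_TABLE default")
            parts.append("\n".join(str(v) for v in mesh.cell_labels))
        if mesh.fibre_dir is not None:
            parts.append("VECTORS fibres double")
            parts.append(_fmt(mesh.fibre_dir, 3))
        if mesh.sheet_dir is not None:
            parts.append("VECTORS sheets double")
            parts.append(_fmt(mesh.sheet_dir, 3))
    if mesh.uvc is not None:
        parts.append(f"POINT_DATA {mesh.n_points}")
        for j, name in enumerate(["rho", "phi", "Z", "V"]):
            parts.append(f"SCALARS {name} double 1")
            parts.append("LOOKUP_TABLE default")
            parts.append(_fmt(mesh.uvc[:, j], 1))
    path.write_text("\n".join(parts) + "\n")
    return path


# ----------------------------------------------------------------------
# cohort tables
# ----------------------------------------------------------------------
def write_cohort_tables(
    weights: pd.DataFrame,
    phenotypes: pd.DataFrame,
    path: Union[str, Path],
    prefix: str = "cohort",
) -> tuple[Path, Path]:
    """Write per-case mode-weight and phenotype tables as CSV.

    Both tables are indexed by case identifier; rows present in only one
    table are kept, and missing phenotype values (failed simulations) are
    written as empty fields.  Comma-separated, '.' decimal, UTF-8, header
    row mandatory; one row per case.
    """
    for tab, what in ((weights, "weights"), (phenotypes, "phenotypes")):
        if tab.index.has_duplicates:
            dup = tab.index[tab.index.duplicated()].tolist()
            raise ValueError(f"duplicate case identifiers in {what} table: {dup}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wpath = path / f"{prefix}_weights.csv"
    ppath = path / f"{prefix}_phenotypes.csv"
    weights.to_csv(wpath, index_label="case", encoding="utf-8")
    phenotypes.to_csv(ppath, index_label="case", encoding="utf-8")
    return wpath, ppath


def read_cohort_tables(
    path: Union[str, Path], prefix: str = "cohort"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the tables written by :func:`write_cohort_tables`."""
    path = Path(path)
    weights = pd.read_csv(path / f"{prefix}_weights.csv", index_col="case")
    phenotypes = pd.read_csv(path / f"{prefix}_phenotypes.csv", index_col="case")
    return weights, phenotypes
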