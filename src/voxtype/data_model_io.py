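"""Domain types and tab-delimited readers/writers.

All on-disk formats are plain text: matrices as TSV with one header row of
gene identifiers and one leading label column, gene lists and region masks
as one token per line, and result tables as TSV. Voxels are keyed by row
index (0-based); grid coordinates are metadata carried along with the atlas.
Gene matching is exact and case-sensitive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates the expected on-disk format or a type invariant."""


class AlignmentError(ValueError):
    """Gene sets of an atlas and a panel cannot be reconciled."""


def _check_nonneg_finite(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{what}: values must be finite")
    if np.any(values < 0):
        raise ValueError(f"{what}: values must be nonnegative")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what}: identifiers must be unique")


@dataclass
class ExpressionAtlas:
    """Voxel-by-gene matrix of expression energies on a regular 3D grid."""

    values: np.ndarray  # (n_voxels, n_genes), nonnegative
    gene_ids: tuple[str, ...]
    voxel_coords: np.ndarray  # (n_voxels, 3) integer grid coordinates
    grid_dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = tuple(self.gene_ids)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if self.values.ndim != 2:
            raise ValueError("atlas values must be 2-dimensional")
        _check_nonneg_finite(self.values, "ExpressionAtlas")
        _check_unique(self.gene_ids, "ExpressionAtlas gene_ids")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match number of columns")
        if self.voxel_coords.shape != (self.values.shape[0], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        dims = np.asarray(self.grid_dims)
        if np.any(self.voxel_coords < 0) or np.any(self.voxel_coords >= dims):
            raise ValueError("voxel coordinates must lie within grid_dims")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_column(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in atlas") from None
        return self.values[:, j]


@dataclass
class CellTypePanel:
    """Type-by-gene matrix of cell-type transcriptomes.

    ``type_indices`` carries the 1-based indices used in printed report
    tables; code always addresses types by 0-based row position.
    """

    values: np.ndarray  # (n_types, n_genes), nonnegative
    type_labels: tuple[str, ...]
    gene_ids: tuple[str, ...]
    type_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.type_labels = tuple(self.type_labels)
        self.gene_ids = tuple(self.gene_ids)
        if self.values.ndim != 2:
            raise ValueError("panel values must be 2-dimensional")
        _check_nonneg_finite(self.values, "CellTypePanel")
        _check_unique(self.type_labels, "CellTypePanel type_labels")
        _check_unique(self.gene_ids, "CellTypePanel gene_ids")
        if self.values.shape[0] != len(self.type_labels):
            raise ValueError("type_labels length must match number of rows")
        if self.values.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length must match number of columns")
        if self.type_indices is None:
            self.type_indices = tuple(range(1, self.values.shape[0] + 1))
        else:
            self.type_indices = tuple(int(i) for i in self.type_indices)
            if len(self.type_indices) != self.values.shape[0]:
                raise ValueError("type_indices length must match number of rows")

    @property
    def n_types(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class DensityField:
    """Voxel-by-type matrix of estimated spatial densities."""

    values: np.ndarray  # (n_voxels, n_types), nonnegative
    type_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.type_labels = tuple(self.type_labels)
        if self.values.ndim != 2:
            raise ValueError("density values must be 2-dimensional")
        _check_nonneg_finite(self.values, "DensityField")
        if self.values.shape[1] != len(self.type_labels):
            raise ValueError("type_labels length must match number of columns")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_types(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneClique:
    """A named, ordered, duplicate-free set of gene symbols."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if len(self.gene_ids) == 0:
            raise ValueError("GeneClique: must contain at least one gene")
        _check_unique(self.gene_ids, "GeneClique")

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class RegionMask:
    """A named set of voxel row indices."""

    name: str
    voxel_indices: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "voxel_indices", frozenset(int(i) for i in self.voxel_indices)
        )
        if len(self.voxel_indices) == 0:
            raise ValueError("RegionMask: must contain at least one voxel")
        if any(i < 0 for i in self.voxel_indices):
            raise ValueError("RegionMask: indices must be nonnegative")

    def validate_against(self, n_voxels: int) -> None:
        bad = [i for i in self.voxel_indices if i >= n_voxels]
        if bad:
            raise ValueError(
                f"RegionMask {self.name!r}: indices {sorted(bad)[:5]} out of "
                f"range for {n_voxels} voxels"
            )

    def __len__(self) -> int:
        return len(self.voxel_indices)


# ---------------------------------------------------------------------------
# grid helpers

def coords_to_indices(coords: np.ndarray, grid_dims: Sequence[int]) -> np.ndarray:
    """Row indices for (x, y, z) coordinates under C-order voxel layout."""
    nx, ny, nz = grid_dims
    coords = np.asarray(coords, dtype=int)
    return (coords[..., 0] * ny + coords[..., 1]) * nz + coords[..., 2]


def grid_coordinates(grid_dims: Sequence[int]) -> np.ndarray:
    """All (x, y, z) coordinates of a grid in C order, shape (nx*ny*nz, 3)."""
    nx, ny, nz = grid_dims
    return np.array(list(np.ndindex(nx, ny, nz)), dtype=int).reshape(-1, 3)


# ---------------------------------------------------------------------------
# matrix IO

_FLOAT_FMT = "%.17g"


def _parse_float(token: str, row: int, col: str) -> float:
    try:
        x = float(token)
    except ValueError:
        raise FormatError(
            f"row {row}, column {col!r}: non-numeric value {token!r}"
        ) from None
    if not np.isfinite(x):
        raise FormatError(f"row {row}, column {col!r}: non-finite value {token!r}")
    if x < 0:
        raise FormatError(f"row {row}, column {col!r}: negative value {token!r}")
    return x


def read_matrix(path: str | Path, orientation: str) -> ExpressionAtlas | CellTypePanel:
    """Read a TSV matrix file as an atlas or a panel.

    ``orientation`` is ``"rows-are-voxels"`` (atlas; row labels are
    ``x:y:z`` coordinate triples) or ``"rows-are-types"`` (panel; row
    labels are type labels). The atlas header's leading cell may encode the
    grid dimensions as ``voxel:nx:ny:nz``; otherwise dimensions are
    inferred from the maximum coordinate on each axis.
    """
    if orientation not in ("rows-are-voxels", "rows-are-types"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must contain at least one gene column")
    label_cell, gene_ids = header[0], header[1:]
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise FormatError(f"{path}: duplicate gene header(s) {dupes}")

    labels: list[str] = []
    rows: list[list[float]] = []
    for r, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: row {r} has {len(cells) - 1} values, "
                f"expected {len(gene_ids)}"
            )
        labels.append(cells[0])
        rows.append(
            [_parse_float(tok, r, gene_ids[j]) for j, tok in enumerate(cells[1:])]
        )
    if not rows:
        raise FormatError(f"{path}: no data rows")
    values = np.array(rows, dtype=float)

    if orientation == "rows-are-types":
        return CellTypePanel(values=values, type_labels=labels, gene_ids=gene_ids)

    coords = []
    for r, lab in enumerate(labels, start=1):
        parts = lab.split(":")
        if len(parts) != 3:
            raise FormatError(f"row {r}: voxel label {lab!r} is not 'x:y:z'")
        try:
            coords.append([int(p) for p in parts])
        except ValueError:
            raise FormatError(f"row {r}: voxel label {lab!r} is not integer") from None
    coords_arr = np.array(coords, dtype=int)
    dims_tok = label_cell.split(":")
    if len(dims_tok) == 4 and dims_tok[0] == "voxel":
        grid_dims = tuple(int(d) for d in dims_tok[1:])
    else:
        grid_dims = tuple(int(m) + 1 for m in coords_arr.max(axis=0))
    return ExpressionAtlas(
        values=values, gene_ids=gene_ids, voxel_coords=coords_arr, grid_dims=grid_dims
    )


def write_matrix(obj: ExpressionAtlas | CellTypePanel, path: str | Path) -> None:
    """Write an atlas or panel as TSV at full float precision (round-trip safe)."""
    path = Path(path)
    with path.open("w") as fh:
        if isinstance(obj, ExpressionAtlas):
            nx, ny, nz = obj.grid_dims
            fh.write("\t".join([f"voxel:{nx}:{ny}:{nz}", *obj.gene_ids]) + "\n")
            for coord, row in zip(obj.voxel_coords, obj.values):
                label = ":".join(str(int(c)) for c in coord)
                fh.write(
                    "\t".join([label, *(_FLOAT_FMT % x for x in row)]) + "\n"
                )
        elif isinstance(obj, CellTypePanel):
            fh.write("\t".join(["type", *obj.gene_ids]) + "\n")
            for label, row in zip(obj.type_labels, obj.values):
                fh.write(
                    "\t".join([label, *(_FLOAT_FMT % x for x in row)]) + "\n"
                )
        else:
            raise TypeError(f"cannot write object of type {type(obj).__name__}")


def write_density_field(field: DensityField, path: str | Path) -> None:
    """Write a density field as TSV (rows are voxel indices, columns types)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["voxel", *field.type_labels]) + "\n")
        for v, row in enumerate(field.values):
            fh.write("\t".join([str(v), *(_FLOAT_FMT % x for x in row)]) + "\n")


def read_density_field(path: str | Path) -> DensityField:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    labels = header[1:]
    rows = []
    for r, line in enumerate(lines[1:], start=1):
        if not line.strip():
            continue
        cells = line.split("\t")
        rows.append([_parse_float(tok, r, labels[j]) for j, tok in enumerate(cells[1:])])
    return DensityField(values=np.array(rows, dtype=float), type_labels=labels)


# ---------------------------------------------------------------------------
# gene lists, masks, tables

def read_gene_list(path: str | Path, name: str | None = None) -> GeneClique:
    """Read a clique from a one-gene-symbol-per-line text file."""
    path = Path(path)
    genes = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    seen = set()
    for g in genes:
        if g in seen:
            raise FormatError(f"{path}: duplicate gene {g!r}")
        seen.add(g)
    return GeneClique(name=name or path.stem, gene_ids=tuple(genes))


def write_gene_list(clique: GeneClique, path: str | Path) -> None:
    Path(path).write_text("\n".join(clique.gene_ids) + "\n")


def read_mask(
    path: str | Path,
    name: str | None = None,
    n_voxels: int | None = None,
    grid_dims: Sequence[int] | None = None,
) -> RegionMask:
    """Read a region mask: one voxel index (or ``x:y:z`` triple) per line.

    Coordinate triples require ``grid_dims`` for conversion to row indices.
    """
    path = Path(path)
    tokens = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not tokens:
        raise FormatError(f"{path}: empty mask file")
    indices: list[int] = []
    for r, tok in enumerate(tokens, start=1):
        if ":" in tok:
            if grid_dims is None:
                raise FormatError(
                    f"{path}: line {r}: coordinate triple requires grid_dims"
                )
            parts = tok.split(":")
            if len(parts) != 3:
                raise FormatError(f"{path}: line {r}: bad coordinate {tok!r}")
            try:
                coord = [int(p) for p in parts]
            except ValueError:
                raise FormatError(f"{path}: line {r}: bad coordinate {tok!r}") from None
            if any(c < 0 or c >= d for c, d in zip(coord, grid_dims)):
                raise FormatError(f"{path}: line {r}: coordinate {tok!r} out of grid")
            indices.append(int(coords_to_indices(np.array(coord), grid_dims)))
        else:
            try:
                indices.append(int(tok))
            except ValueError:
                raise FormatError(f"{path}: line {r}: bad index {tok!r}") from None
    if len(set(indices)) != len(indices):
        raise FormatError(f"{path}: duplicate voxel indices")
    if n_voxels is not None:
        bad = [i for i in indices if i < 0 or i >= n_voxels]
        if bad:
            raise FormatError(f"{path}: voxel index {bad[0]} out of range")
    if any(i < 0 for i in indices):
        raise FormatError(f"{path}: negative voxel index")
    return RegionMask(name=name or path.stem, voxel_indices=frozenset(indices))


def write_mask(mask: RegionMask, path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(str(i) for i in sorted(mask.voxel_indices)) + "\n"
    )


def write_table(
    rows: Iterable[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write result rows as a TSV table with a header.

    Report tables follow the layout (cell type, rank, 1-based index t,
    P_R %, psi %) where those columns apply.
    """
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    if columns is not None:
        rows = rows[list(columns)]
    rows.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# alignment

def align_genes(
    atlas: ExpressionAtlas, panel: CellTypePanel
) -> tuple[ExpressionAtlas, CellTypePanel]:
    """Restrict atlas and panel to their common genes, in atlas order.

    Panel columns are rearranged to match the atlas column order exactly.
    Dropped genes on either side are reported via logging. Raises
    :class:`AlignmentError` if the gene sets are disjoint.
    """
    panel_set = set(panel.gene_ids)
    common = [g for g in atlas.gene_ids if g in panel_set]
    if not common:
        raise AlignmentError("atlas and panel share no genes")
    dropped_atlas = [g for g in atlas.gene_ids if g not in panel_set]
    atlas_set = set(atlas.gene_ids)
    dropped_panel = [g for g in panel.gene_ids if g not in atlas_set]
    if dropped_atlas:
        logger.info("align_genes: dropping %d atlas gene(s)", len(dropped_atlas))
    if dropped_panel:
        logger.info("align_genes: dropping %d panel gene(s)", len(dropped_panel))
    if not dropped_atlas and not dropped_panel and atlas.gene_ids == panel.gene_ids:
        return atlas, panel

    a_pos = {g: j for j, g in enumerate(atlas.gene_ids)}
    p_pos = {g: j for j, g in enumerate(panel.gene_ids)}
    a_idx = [a_pos[g] for g in common]
    p_idx = [p_pos[g] for g in common]
    new_atlas = ExpressionAtlas(
        values=atlas.values[:, a_idx],
        gene_ids=tuple(common),
        voxel_coords=atlas.voxel_coords,
        grid_dims=atlas.grid_dims,
    )
    new_panel = CellTypePanel(
        values=panel.values[:, p_idx],
        type_labels=panel.type_labels,
        gene_ids=tuple(common),
        type_indices=panel.type_indices,
    )
    return new_atlas, new_panel
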