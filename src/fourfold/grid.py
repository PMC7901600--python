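"""From records to binary grids, and the partial-cube geometry.

Two geometric stages live here. *Filtering* cross-classifies a
population of individually recorded elements on ``d`` binary dimensions
into a 2^d grid of frequency counts (:func:`categorize`); collapsing a
grid dimension aggregates counts and is lossy (:func:`collapse`).

The *partial cube* is different: it adds a third dimension Z defined as
the correspondence (match/mismatch) of X and Y, which rules out four of
the eight cells. Because only four cells carry mass, every projection of
the cube — three 2x2 matrices (:func:`frame_matrix`) and six hierarchical
trees (:func:`project_tree`) — rearranges the same four counts without
aggregating, so each one is informationally equivalent to the cube and
:func:`reconstruct_cube` inverts any of them exactly. Counting spatial
arrangements at each level (cube orientations, matrix layouts, tree
leaf orders) gives 24 distinct projections apiece
(:func:`count_distinct_projections`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .tables import Dimension, FrameSpec, FrequencyTable2x2

__all__ = [
    "BinaryRecordSet",
    "BinaryGrid",
    "PartialCube",
    "TreeProjection",
    "categorize",
    "collapse",
    "grid_to_table",
    "build_partial_cube",
    "frame_matrix",
    "project_tree",
    "count_distinct_projections",
    "reconstruct_cube",
]


class BinaryRecordSet:
    """An ordered collection of records over registered binary dimensions.

    Each record maps every registered dimension label to one of that
    dimension's two categories; records with missing or unregistered
    values are rejected (the filtering step assumes exhaustive
    dichotomies, so nothing is imputed).
    """

    def __init__(
        self,
        dimensions: Sequence[Dimension],
        records: Iterable[Mapping[str, str]] = (),
    ):
        self.dimensions: tuple[Dimension, ...] = tuple(dimensions)
        self._by_label = {d.label: d for d in self.dimensions}
        if len(self._by_label) != len(self.dimensions):
            raise ValueError("duplicate dimension labels")
        self.records: list[dict[str, str]] = []
        for i, rec in enumerate(records):
            self.append(rec, _index=i)

    def append(self, record: Mapping[str, str], _index: int | None = None) -> None:
        where = f" (record {_index})" if _index is not None else ""
        clean = {}
        for dim in self.dimensions:
            if dim.label not in record:
                raise ValueError(f"missing value for dimension {dim.label!r}{where}")
            value = record[dim.label]
            if value not in dim.categories:
                raise ValueError(
                    f"value {value!r} is not a category of {dim.label!r}{where}"
                )
            clean[dim.label] = value
        self.records.append(clean)

    def __len__(self) -> int:
        return len(self.records)

    def dimension(self, label: str) -> Dimension:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown dimension {label!r}") from None


@dataclass(frozen=True)
class BinaryGrid:
    """Counts on a d-dimensional grid of category combinations.

    Missing combinations read as zero; at most 2^d entries exist.
    """

    dimensions: tuple[Dimension, ...]
    counts: Mapping[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for combo, count in self.counts.items():
            if len(combo) != len(self.dimensions):
                raise ValueError(f"combination {combo!r} has wrong arity")
            for value, dim in zip(combo, self.dimensions):
                if value not in dim.categories:
                    raise ValueError(
                        f"{value!r} is not a category of {dim.label!r}"
                    )
            if count < 0:
                raise ValueError(f"negative count for {combo!r}")

    @property
    def d(self) -> int:
        return len(self.dimensions)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, *combo: str) -> int:
        return self.counts.get(tuple(combo), 0)


def categorize(records: BinaryRecordSet, dims: Sequence[str]) -> BinaryGrid:
    """Cross-classify all records on the named dimensions (filtering)."""
    if not dims:
        raise ValueError("need at least one dimension")
    dimensions = tuple(records.dimension(label) for label in dims)
    counts: dict[tuple[str, ...], int] = {}
    for rec in records.records:
        combo = tuple(rec[label] for label in dims)
        counts[combo] = counts.get(combo, 0) + 1
    return BinaryGrid(dimensions, counts)


def collapse(grid: BinaryGrid, dim: str) -> BinaryGrid:
    """Sum counts over one dimension. Lossy: the collapsed dimension's
    split cannot be recovered from the result."""
    labels = [d.label for d in grid.dimensions]
    if dim not in labels:
        raise KeyError(f"unknown dimension {dim!r}")
    if grid.d == 1:
        raise ValueError("cannot collapse the last dimension")
    idx = labels.index(dim)
    kept = tuple(d for i, d in enumerate(grid.dimensions) if i != idx)
    counts: dict[tuple[str, ...], int] = {}
    for combo, count in grid.counts.items():
        reduced = tuple(v for i, v in enumerate(combo) if i != idx)
        counts[reduced] = counts.get(reduced, 0) + count
    return BinaryGrid(kept, counts)


def grid_to_table(
    grid: BinaryGrid,
    positive_x: str | None = None,
    positive_y: str | None = None,
    domain_tag: str | None = None,
) -> FrequencyTable2x2:
    """Frame a two-dimensional grid as a 2x2 table.

    The grid's first dimension becomes the columns (X), the second the
    rows (Y); positive categories default to each dimension's first.
    """
    if grid.d != 2:
        raise ValueError(f"need a 2-dimensional grid, got d={grid.d}")
    dim_x, dim_y = grid.dimensions
    px = positive_x or dim_x.categories[0]
    py = positive_y or dim_y.categories[0]
    frame = FrameSpec(dim_x, dim_y, px, py, domain_tag=domain_tag)
    return FrequencyTable2x2(
        grid.count(px, py),
        grid.count(dim_x.other(px), py),
        grid.count(px, dim_y.other(py)),
        grid.count(dim_x.other(px), dim_y.other(py)),
        frame,
    )


# ---------------------------------------------------------------------------
# the partial cube


#: Z-category names by semantic domain; default is the abstract pair.
_Z_NAMES = {
    None: ("match", "mismatch"),
    "diagnostics": ("correct", "incorrect"),
    "classification": ("correct", "incorrect"),
}


@dataclass(frozen=True)
class PartialCube:
    """Three binary dimensions {X, Y, Z} with Z = correspondence(X, Y).

    Only the four admissible (x, y, z) triples carry counts: cells a and
    d sit on z = match (positive-with-positive and
    negative-with-negative), b and c on z = mismatch. The four
    inadmissible triples are structurally absent.
    """

    frame: FrameSpec
    z_dim: Dimension
    a: int
    b: int
    c: int
    d: int

    @property
    def n(self):
        return self.a + self.b + self.c + self.d

    def admissible_triples(self) -> dict[tuple[str, str, str], int]:
        """Mapping (x, y, z) -> count over the four admissible cells."""
        f = self.frame
        match, mismatch = self.z_dim.categories
        return {
            (f.positive_x, f.positive_y, match): self.a,
            (f.negative_x, f.positive_y, mismatch): self.b,
            (f.positive_x, f.negative_y, mismatch): self.c,
            (f.negative_x, f.negative_y, match): self.d,
        }

    def z_margin(self) -> tuple:
        return (self.a + self.d, self.b + self.c)


def build_partial_cube(table: FrequencyTable2x2) -> PartialCube:
    """Lift a 2x2 table into the three-dimensional correspondence model."""
    names = _Z_NAMES.get(table.frame.domain_tag, _Z_NAMES[None])
    z_dim = Dimension("correspondence", names)
    return PartialCube(table.frame, z_dim, table.a, table.b, table.c, table.d)


def frame_matrix(cube: PartialCube, viewing_axis: str) -> FrequencyTable2x2:
    """Project the cube along one axis into a 2x2 matrix.

    No aggregation occurs: the four counts survive, rearranged. Viewing
    along Z reproduces the {X, Y} source table; viewing along X or Y
    yields the {Y, Z} or {X, Z} matrix with Z on the columns. The result
    is tagged with its lineage so :func:`reconstruct_cube` can invert it.
    """
    f = cube.frame
    match = cube.z_dim.categories[0]
    meta = {"viewing_axis": viewing_axis, "cube_frame": f, "z_dim": cube.z_dim}
    if viewing_axis == "Z":
        return FrequencyTable2x2(cube.a, cube.b, cube.c, cube.d, f, meta=meta)
    if viewing_axis == "X":
        frame = FrameSpec(cube.z_dim, f.dim_y, match, f.positive_y, f.domain_tag)
        return FrequencyTable2x2(cube.a, cube.b, cube.d, cube.c, frame, meta=meta)
    if viewing_axis == "Y":
        frame = FrameSpec(cube.z_dim, f.dim_x, match, f.positive_x, f.domain_tag)
        return FrequencyTable2x2(cube.a, cube.c, cube.d, cube.b, frame, meta=meta)
    raise ValueError(f"viewing_axis must be 'X', 'Y' or 'Z', got {viewing_axis!r}")


@dataclass(frozen=True)
class TreeProjection:
    """A 2x2 matrix parsed as a two-level hierarchical tree.

    The first branching criterion splits the population by one dimension
    (its margins become the two level-1 node counts); the second splits
    each branch by the other dimension, yielding four ordered leaves that
    are a permutation of {a, b, c, d}. Leaf order is left-to-right by
    (first-branch category, second category), positive categories first.
    """

    first_branch: str
    second_branch: str
    root: int
    level1: tuple[int, int]
    leaves: tuple[int, int, int, int]
    branch_categories: tuple[str, str]
    leaf_categories: tuple[tuple[str, str], ...]
    frame: FrameSpec
    meta: Mapping[str, object] = field(default_factory=dict, compare=False)

    def to_table(self) -> FrequencyTable2x2:
        """Rebuild the 2x2 matrix this tree parses."""
        f = self.frame
        cells = dict(zip(self.leaf_categories, self.leaves))
        if self.first_branch == f.dim_x.label:
            def get(x, y):
                return cells[(x, y)]
        else:
            def get(x, y):
                return cells[(y, x)]
        return FrequencyTable2x2(
            get(f.positive_x, f.positive_y),
            get(f.negative_x, f.positive_y),
            get(f.positive_x, f.negative_y),
            get(f.negative_x, f.negative_y),
            f,
            meta=self.meta,
        )


def project_tree(table: FrequencyTable2x2, first_branch: str) -> TreeProjection:
    """Stack the matrix into a tree, branching first on ``first_branch``."""
    f = table.frame
    if first_branch == f.dim_x.label:
        first_cats = (f.positive_x, f.negative_x)
        second = f.dim_y.label
        second_cats = (f.positive_y, f.negative_y)
        def cell(b1, b2):
            return table.cell(b1, b2)
    elif first_branch == f.dim_y.label:
        first_cats = (f.positive_y, f.negative_y)
        second = f.dim_x.label
        second_cats = (f.positive_x, f.negative_x)
        def cell(b1, b2):
            return table.cell(b2, b1)
    else:
        raise KeyError(f"unknown dimension {first_branch!r}")
    leaves = []
    leaf_cats = []
    for b1 in first_cats:
        for b2 in second_cats:
            leaves.append(cell(b1, b2))
            leaf_cats.append((b1, b2))
    level1 = (leaves[0] + leaves[1], leaves[2] + leaves[3])
    return TreeProjection(
        first_branch=first_branch,
        second_branch=second,
        root=table.n,
        level1=level1,
        leaves=tuple(leaves),
        branch_categories=first_cats,
        leaf_categories=tuple(leaf_cats),
        frame=f,
        meta=table.meta,
    )


def reconstruct_cube(source: FrequencyTable2x2 | TreeProjection) -> PartialCube:
    """Invert any matrix or tree projection back to the partial cube.

    Requires the projection's lineage tag (attached by
    :func:`frame_matrix`); a bare table without lineage cannot declare
    which axis it was viewed along.
    """
    if isinstance(source, TreeProjection):
        return reconstruct_cube(source.to_table())
    meta = dict(source.meta)
    axis = meta.get("viewing_axis")
    if axis is None:
        raise ValueError(
            "source is not tagged with its transform lineage; "
            "use frame_matrix/project_tree outputs or build_partial_cube directly"
        )
    frame: FrameSpec = meta["cube_frame"]
    z_dim: Dimension = meta["z_dim"]
    t = source
    if axis == "Z":
        a, b, c, d = t.a, t.b, t.c, t.d
    elif axis == "X":
        a, b, c, d = t.a, t.b, t.d, t.c
    elif axis == "Y":
        a, b, c, d = t.a, t.d, t.b, t.c
    else:  # pragma: no cover - tags are produced internally
        raise ValueError(f"bad lineage axis {axis!r}")
    return PartialCube(frame, z_dim, a, b, c, d)


# ---------------------------------------------------------------------------
# counting distinct projections


def _matrix_signatures() -> set[tuple]:
    """All (row dim, col dim, category orders) arrangements of the three
    matrix framings under the eight layout transforms."""
    dims = {
        "X": ("x+", "x-"),
        "Y": ("y+", "y-"),
        "Z": ("z+", "z-"),
    }
    framings = [("X", "Y"), ("Z", "Y"), ("Z", "X")]  # (col dim, row dim) per axis
    signatures = set()
    for col, row in framings:
        for transposed in (False, True):
            for rev_c in (False, True):
                for rev_r in (False, True):
                    ccats = dims[col][::-1] if rev_c else dims[col]
                    rcats = dims[row][::-1] if rev_r else dims[row]
                    sig = (row, col, rcats, ccats)
                    if transposed:
                        sig = (col, row, ccats, rcats)
                    signatures.add(sig)
    return signatures


def _tree_signatures() -> set[tuple]:
    """All (first branch, second branch, category orders) tree shapes."""
    dims = {
        "X": ("x+", "x-"),
        "Y": ("y+", "y-"),
        "Z": ("z+", "z-"),
    }
    signatures = set()
    for first, second in itertools.permutations(dims, 2):
        for rev1 in (False, True):
            for rev2 in (False, True):
                c1 = dims[first][::-1] if rev1 else dims[first]
                c2 = dims[second][::-1] if rev2 else dims[second]
                signatures.add((first, second, c1, c2))
    return signatures


def _cube_signatures() -> set[tuple]:
    """Proper rotations of the cube: signed permutation matrices with
    determinant +1 (mirror images deduplicate against rotations)."""
    signatures = set()
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product((1, -1), repeat=3):
            matrix = [[0, 0, 0] for _ in range(3)]
            for i, (j, s) in enumerate(zip(perm, signs)):
                matrix[i][j] = s
            det = (
                matrix[0][0] * (matrix[1][1] * matrix[2][2] - matrix[1][2] * matrix[2][1])
                - matrix[0][1] * (matrix[1][0] * matrix[2][2] - matrix[1][2] * matrix[2][0])
                + matrix[0][2] * (matrix[1][0] * matrix[2][1] - matrix[1][1] * matrix[2][0])
            )
            if det == 1:
                signatures.add(tuple(tuple(r) for r in matrix))
    return signatures


def count_distinct_projections(level: str) -> int:
    """Exhaustively enumerate and deduplicate the spatial arrangements at
    one level of the partial-cube hierarchy (``cube``, ``matrix`` or
    ``tree``); all three levels admit the same number."""
    if level == "matrix":
        return len(_matrix_signatures())
    if level == "tree":
        return len(_tree_signatures())
    if level == "cube":
        return len(_cube_signatures())
    raise ValueError(f"level must be 'cube', 'matrix' or 'tree', got {level!r}")
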