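"""Tridimensional pooling: scheme construction and pool-pattern deconvolution.

Families are arranged on a ``cube_dim`` x ``cube_dim`` x ``cube_dim`` grid and
each family is pooled three times: once with every family sharing its row (R),
column (C) and depth layer (D).  A variant carried by one family therefore
shows up in exactly one pool per axis, and the intersection of the positive
pools identifies the family.  With 512 families on an 8x8x8 grid this gives
24 pools of 64 families each.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

AXES = ("R", "C", "D")

_LABEL_RE = re.compile(r"^([RCD])(\d+)$")


class CapacityError(ValueError):
    """More families than the cube can hold."""


@dataclass(frozen=True)
class PoolingScheme:
    """A fully specified family -> (r, c, d) assignment.

    Family ``i`` occupies cell ``(r, c, d)`` with
    ``i = r * dim**2 + c * dim + d`` (row-major).  Partially filled cubes
    fill cells in index order, so trailing pools may be smaller.
    """

    cube_dim: int
    n_families: int
    _members: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.cube_dim < 1:
            raise ValueError(f"cube_dim must be >= 1, got {self.cube_dim}")
        if self.n_families < 1:
            raise ValueError(f"n_families must be >= 1, got {self.n_families}")
        if self.n_families > self.cube_dim**3:
            raise CapacityError(
                f"{self.n_families} families exceed cube capacity "
                f"{self.cube_dim}**3 = {self.cube_dim ** 3}"
            )
        members: dict[str, list[int]] = {lab: [] for lab in self.pool_labels}
        for fam in range(self.n_families):
            for lab in self.pools_of(fam):
                members[lab].append(fam)
        object.__setattr__(self, "_members", members)

    @property
    def pool_labels(self) -> list[str]:
        return [f"{ax}{i}" for ax in AXES for i in range(self.cube_dim)]

    @property
    def n_pools(self) -> int:
        return 3 * self.cube_dim

    def cell_of(self, family_id: int) -> tuple[int, int, int]:
        if not 0 <= family_id < self.n_families:
            raise KeyError(f"unknown family_id {family_id}")
        r, rem = divmod(family_id, self.cube_dim**2)
        c, d = divmod(rem, self.cube_dim)
        return r, c, d

    def family_at(self, r: int, c: int, d: int) -> int | None:
        """Inverse of :meth:`cell_of`; None for an unoccupied cell."""
        fam = r * self.cube_dim**2 + c * self.cube_dim + d
        return fam if fam < self.n_families else None

    def pools_of(self, family_id: int) -> tuple[str, str, str]:
        r, c, d = self.cell_of(family_id)
        return f"R{r}", f"C{c}", f"D{d}"

    def members(self, pool_label: str) -> list[int]:
        try:
            return list(self._members[pool_label])
        except KeyError:
            raise KeyError(f"unknown pool label {pool_label!r}") from None

    def axis_pools(self, axis: str) -> list[str]:
        if axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
        return [f"{axis}{i}" for i in range(self.cube_dim)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in range(self.n_families):
            r, c, d = self.cell_of(fam)
            rows.append((fam, r, c, d, f"R{r}", f"C{c}", f"D{d}"))
        return pd.DataFrame(
            rows,
            columns=["family_id", "r", "c", "d", "pool_R", "pool_C", "pool_D"],
        )


def build_scheme(n_families: int, cube_dim: int) -> PoolingScheme:
    """Construct the tridimensional pooling scheme.

    >>> s = build_scheme(512, 8)
    >>> s.n_pools, len(s.members("R0"))
    (24, 64)
    """
    return PoolingScheme(cube_dim=cube_dim, n_families=n_families)


@dataclass(frozen=True)
class DeconvolutionResult:
    candidate_family_ids: tuple[int, ...]
    status: str  # unique | ambiguous | incomplete | empty
    positive_pools: frozenset[str]

    def __len__(self):
        return len(self.candidate_family_ids)


def parse_pool_label(label: str) -> tuple[str, int]:
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"invalid pool label {label!r}")
    return m.group(1), int(m.group(2))


def deconvolve(scheme: PoolingScheme, positive_pools: Iterable[str]) -> DeconvolutionResult:
    """Intersect positive-pool memberships to candidate families.

    Candidates are the families belonging to at least one positive pool on
    every axis that has any positive pool.  If an axis has none, the pattern
    is *incomplete* (with two axes, candidates form a fiber of the cube; with
    none, all families remain candidates).
    """
    pools = frozenset(positive_pools)
    by_axis: dict[str, set[int]] = {ax: set() for ax in AXES}
    for lab in pools:
        ax, idx = parse_pool_label(lab)
        if idx >= scheme.cube_dim:
            raise KeyError(f"pool {lab!r} not in scheme (cube_dim={scheme.cube_dim})")
        by_axis[ax].add(idx)

    candidates = set(range(scheme.n_families))
    missing_axis = False
    for ax in AXES:
        idxs = by_axis[ax]
        if not idxs:
            missing_axis = True
            continue
        axis_members: set[int] = set()
        for i in idxs:
            axis_members.update(scheme.members(f"{ax}{i}"))
        candidates &= axis_members

    if missing_axis:
        status = "incomplete"
    elif len(candidates) == 0:
        status = "empty"
    elif len(candidates) == 1:
        status = "unique"
    else:
        status = "ambiguous"
    return DeconvolutionResult(
        candidate_family_ids=tuple(sorted(candidates)),
        status=status,
        positive_pools=pools,
    )


def write_scheme_tsv(scheme: PoolingScheme, path) -> None:
    scheme.to_frame().to_csv(path, sep="\t", index=False)


def read_scheme_tsv(path) -> PoolingScheme:
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    dim = int(df[["r", "c", "d"]].to_numpy().max()) + 1
    # Accept any dim large enough; verify the row-major convention holds.
    scheme = PoolingScheme(cube_dim=dim, n_families=n)
    expected = scheme.to_frame()
    got = df[expected.columns].reset_index(drop=True)
    if not got.equals(expected):
        raise ValueError(f"{path}: scheme TSV does not follow the row-major layout")
    return scheme
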