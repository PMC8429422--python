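"""Meta-population structures: patch graphs, I/O, and replacement weights.

A meta-population is an undirected, connected graph of patches; patch ``j``
holds a well-mixed sub-population of fixed size ``N_j``.  Per Birth-death
event an offspring stays in its natal patch with probability ``1 - lambda``
(replacing a uniform individual there, possibly its mother) and migrates with
probability ``lambda``, replacing an individual chosen among the adjacent
patches.  Two conventions for the migrating offspring are supported:

``union``
    The replaced individual is uniform over the union of all individuals in
    adjacent patches: per-individual weight ``lambda / sum_{k in V(i)} N_k``.
    This is the canonical process definition used by the exact solver and the
    simulator.
``patch``
    An adjacent patch is chosen uniformly (``1 / deg(i)``) and then an
    individual uniformly inside it: per-individual weight
    ``lambda / (deg(i) * N_j)``.  This is the kernel the low-migration
    coarse-graining uses.

The two coincide whenever all neighbours of a patch have equal size, which
holds for every structure with a closed form in this package (two-patch,
meta-star with equal patch sizes, regular graphs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "PatchGraph",
    "StructureError",
    "load_structure",
    "save_structure",
    "two_patch",
    "meta_star",
    "cycle",
    "is_isothermal",
    "replacement_weight",
    "landing_matrix",
]

CONVENTIONS = ("union", "patch")


class StructureError(ValueError):
    """Raised when a structure document fails validation."""


@dataclass(frozen=True)
class PatchGraph:
    """Undirected patch graph with per-patch carrying capacities.

    Patch order is the document order and fixes the state indexing of every
    downstream solver.  ``edges`` hold positional patch indices.
    """

    ids: tuple
    sizes: tuple
    edges: frozenset  # frozenset of frozenset({i, j}) index pairs
    _graph: nx.Graph = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise StructureError("duplicate patch ids")
        if len(self.sizes) != len(self.ids):
            raise StructureError("sizes and ids length mismatch")
        for pid, n in zip(self.ids, self.sizes):
            if int(n) != n or n < 1:
                raise StructureError(f"patch {pid!r} has non-positive size {n!r}")
        g = nx.Graph()
        g.add_nodes_from(range(len(self.ids)))
        for e in self.edges:
            pair = tuple(e)
            if len(pair) != 2:
                raise StructureError(f"self-loop on patch {self.ids[pair[0]]!r}")
            i, j = pair
            for k in (i, j):
                if not 0 <= k < len(self.ids):
                    raise StructureError(f"edge references unknown patch index {k}")
            g.add_edge(i, j)
        if len(self.ids) > 1 and not nx.is_connected(g):
            raise StructureError("patch graph must be connected")
        object.__setattr__(self, "_graph", g)

    # -- basic accessors -------------------------------------------------
    @property
    def M(self) -> int:
        """Number of patches."""
        return len(self.ids)

    @property
    def N(self) -> int:
        """Total meta-population size ``sum_j N_j``."""
        return int(sum(self.sizes))

    @property
    def size_array(self) -> np.ndarray:
        return np.asarray(self.sizes, dtype=np.int64)

    def index(self, patch_id) -> int:
        try:
            return self.ids.index(patch_id)
        except ValueError:
            raise StructureError(f"unknown patch id {patch_id!r}") from None

    def degree(self, i: int) -> int:
        return self._graph.degree[i]

    def neighbors(self, i: int) -> list[int]:
        return sorted(self._graph.neighbors(i))

    def digest(self) -> str:
        """Short stable hash of the canonical JSON document."""
        doc = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(doc).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "patches": [
                {"id": pid, "size": int(n)} for pid, n in zip(self.ids, self.sizes)
            ],
            "edges": sorted(sorted(tuple(e)) for e in self.edges),
        }

    @classmethod
    def from_lists(
        cls, sizes: Sequence[int], edges: Iterable[Sequence], ids: Sequence | None = None
    ) -> "PatchGraph":
        """Build from a list of sizes and index- (or id-) based edge pairs."""
        if ids is None:
            ids = tuple(range(len(sizes)))
        ids = tuple(ids)
        id_to_idx = {pid: k for k, pid in enumerate(ids)}
        edge_set = set()
        for e in edges:
            a, b = e
            ia = id_to_idx.get(a, a if isinstance(a, int) and 0 <= a < len(ids) else None)
            ib = id_to_idx.get(b, b if isinstance(b, int) and 0 <= b < len(ids) else None)
            if ia is None or ib is None:
                raise StructureError(f"edge {e!r} references unknown patch id")
            if ia == ib:
                raise StructureError(f"self-loop on patch {a!r}")
            edge_set.add(frozenset((ia, ib)))
        return cls(ids=ids, sizes=tuple(int(n) for n in sizes), edges=frozenset(edge_set))


# -- document I/O --------------------------------------------------------

def load_structure(source) -> PatchGraph:
    """Load a :class:`PatchGraph` from a JSON document, path, or dict.

    Document schema::

        {"patches": [{"id": <str|int>, "size": <int>}, ...],
         "edges": [[id, id], ...]}

    Patch order is the document order.  Validation errors name the offending
    element.
    """
    if isinstance(source, PatchGraph):
        return source
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if not str(source).lstrip().startswith("{") else str(source)
        doc = json.loads(text)
    if "patches" in doc:
        ids = tuple(p["id"] for p in doc["patches"])
        sizes = tuple(p["size"] for p in doc["patches"])
    elif "sizes" in doc:  # compact dialect: sizes in order, integer-indexed
        sizes = tuple(doc["sizes"])
        ids = tuple(range(len(sizes)))
    else:
        raise StructureError("document has neither 'patches' nor 'sizes'")
    return PatchGraph.from_lists(sizes, doc.get("edges", []), ids=ids)


def load_edge_list(edges_path, sizes_path) -> PatchGraph:
    """Load from a two-column TSV edge list plus a two-column (id, size) TSV."""
    ids, sizes = [], []
    for line in Path(sizes_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pid, n = line.split("\t")
        ids.append(pid)
        sizes.append(int(n))
    edges = []
    for line in Path(edges_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        a, b = line.split("\t")
        edges.append((a, b))
    return PatchGraph.from_lists(sizes, edges, ids=tuple(ids))


def save_structure(g: PatchGraph, path) -> None:
    """Write the canonical JSON dialect (keys sorted) for reproducible fixtures."""
    Path(path).write_text(json.dumps(g.to_dict(), sort_keys=True, indent=1) + "\n")


# -- common structures ---------------------------------------------------

def two_patch(N1: int, N2: int) -> PatchGraph:
    """Two patches of sizes ``N1`` and ``N2`` joined by a single link."""
    return PatchGraph.from_lists([N1, N2], [(0, 1)])


def meta_star(M: int, leaf_size: int, hub_size: int | None = None) -> PatchGraph:
    """Star of ``M`` patches: one hub (patch 0) connected to ``M - 1`` leaves."""
    if M < 2:
        raise StructureError("meta-star needs at least 2 patches")
    if hub_size is None:
        hub_size = leaf_size
    sizes = [hub_size] + [leaf_size] * (M - 1)
    return PatchGraph.from_lists(sizes, [(0, k) for k in range(1, M)])


def cycle(M: int, size: int) -> PatchGraph:
    """Cycle of ``M`` equal-size patches (a regular, hence isothermal, structure)."""
    if M < 3:
        raise StructureError("cycle needs at least 3 patches")
    return PatchGraph.from_lists([size] * M, [(k, (k + 1) % M) for k in range(M)])


# -- structural predicates and weights -----------------------------------

def is_isothermal(g: PatchGraph) -> bool:
    """True iff the patch network is regular and all patch sizes are equal.

    For such structures every individual has the same temperature (total
    incoming replacement weight) for any migration probability, so the
    fixation probability equals the well-mixed value for the total size.
    """
    degs = {g.degree(i) for i in range(g.M)}
    return len(degs) == 1 and len(set(g.sizes)) == 1


def _neighbor_mass(g: PatchGraph, i: int) -> int:
    return int(sum(g.sizes[k] for k in g.neighbors(i)))


def replacement_weight(
    g: PatchGraph, lam: float, i: int, j: int, convention: str = "union"
) -> float:
    """Per-target-individual replacement weight from source patch ``i`` to ``j``.

    The probability that the offspring of a given parent in patch ``i``
    replaces one *specific* individual in patch ``j``.  For ``j == i`` this is
    ``(1 - lambda) / N_i`` (the mother is a possible target); for adjacent
    ``j`` it is ``lambda / sum_{k in V(i)} N_k`` (union convention) or
    ``lambda / (deg(i) N_j)`` (patch convention); otherwise 0.  A sole patch
    (``M = 1``) keeps all replacement internal regardless of ``lambda``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"migration probability must lie in [0, 1], got {lam!r}")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown migration convention {convention!r}")
    for k in (i, j):
        if not 0 <= k < g.M:
            raise StructureError(f"invalid patch index {k}")
    if g.M == 1:
        return 1.0 / g.sizes[0] if j == i else 0.0
    if j == i:
        return (1.0 - lam) / g.sizes[i]
    if j in g._graph[i]:
        if convention == "union":
            return lam / _neighbor_mass(g, i)
        return lam / (g.degree(i) * g.sizes[j])
    return 0.0


def landing_matrix(
    g: PatchGraph, lam: float, convention: str = "union", dtype=np.float64
) -> np.ndarray:
    """Row-stochastic ``(M, M)`` matrix: probability an offspring of a patch-``i``
    parent lands in patch ``j`` (replacement weight times target patch size).

    ``dtype`` controls the precision of the arithmetic; the exact solver
    re-builds the matrix in extended precision for ill-conditioned small-
    migration systems.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"migration probability must lie in [0, 1], got {lam!r}")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown migration convention {convention!r}")
    lam = dtype(lam)
    one = dtype(1)
    D = np.zeros((g.M, g.M), dtype=dtype)
    if g.M == 1:
        D[0, 0] = one
        return D
    for i in range(g.M):
        D[i, i] = one - lam
        nbrs = g.neighbors(i)
        mass = dtype(sum(g.sizes[k] for k in nbrs))
        for j in nbrs:
            if convention == "union":
                D[i, j] = lam * dtype(g.sizes[j]) / mass
            else:
                D[i, j] = lam / dtype(g.degree(i))
    return D
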