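"""Skeleton domain types, SWC ingestion/emission and branch decomposition.

A traced arborisation is stored as a rooted tree of 3-D points
(:class:`ArborSkeleton`).  One SWC file corresponds to one time frame of a
time-lapse reconstruction; coordinates are interpreted in micrometres.
Downstream analyses operate on the decomposition of the tree into maximal
unbranched paths (:class:`Branch`) running between the root, branch points
(nodes with two or more children) and terminal tips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

import networkx as nx
import numpy as np

from .errors import SkeletonTopologyError, SWCFormatError

ROOT_PARENT = -1

#: SWC structure-type codes carried on the ``type`` column.  Code 2 (axon)
#: marks branch-calibre neurite, code 5 marks filopodium; anything else is
#: read back as "unspecified".  Topology never depends on these codes.
_LABEL_TO_CODE = {"branch": 2, "filopodium": 5, "unspecified": 0}
_CODE_TO_LABEL = {2: "branch", 5: "filopodium"}

STRUCTURE_LABELS = frozenset(_LABEL_TO_CODE)


@dataclass(frozen=True)
class SkeletonNode:
    """One traced point: id, position (µm), radius (µm), parent id, label."""

    id: int
    position: np.ndarray
    radius: float = 0.25
    parent_id: int = ROOT_PARENT
    structure_label: str = "unspecified"

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")
        if not np.all(np.isfinite(pos)):
            raise ValueError(f"node {self.id}: non-finite position")
        object.__setattr__(self, "position", pos)
        if self.id <= 0:
            raise ValueError(f"node id must be positive, got {self.id}")
        if self.radius < 0:
            raise ValueError(f"node {self.id}: negative radius")
        if self.structure_label not in STRUCTURE_LABELS:
            raise ValueError(f"node {self.id}: unknown structure_label "
                             f"{self.structure_label!r}")


class ArborSkeleton:
    """A validated rooted tree of :class:`SkeletonNode`.

    Parameters
    ----------
    nodes
        Nodes in any order; exactly one must carry the sentinel parent id
        ``-1``.  Every other parent reference must resolve within the
        collection and the parent graph must be acyclic.
    frame
        Time-frame index of the reconstruction (0-based).
    frame_interval
        Minutes between consecutive frames of the series the skeleton
        belongs to.
    units_per_coordinate
        Micrometres per coordinate unit (1.0 when tracing is already in µm).
    """

    def __init__(self, nodes: Iterable[SkeletonNode], frame: int = 0,
                 frame_interval: float = 1.0,
                 units_per_coordinate: float = 1.0) -> None:
        self.nodes: list[SkeletonNode] = list(nodes)
        if frame < 0:
            raise ValueError("frame must be non-negative")
        self.frame = int(frame)
        self.frame_interval = float(frame_interval)
        self.units_per_coordinate = float(units_per_coordinate)
        self._by_id: dict[int, SkeletonNode] = {}
        self._children: dict[int, list[int]] = {}
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        roots = []
        for node in self.nodes:
            if node.id in self._by_id:
                raise SWCFormatError(f"duplicate node id {node.id}")
            self._by_id[node.id] = node
            self._children.setdefault(node.id, [])
        for node in self.nodes:
            if node.parent_id == ROOT_PARENT:
                roots.append(node.id)
            elif node.parent_id not in self._by_id:
                raise SkeletonTopologyError(
                    f"node {node.id} references missing parent {node.parent_id}")
            else:
                self._children[node.parent_id].append(node.id)
        if self.nodes:
            if not roots:
                raise SkeletonTopologyError("no root node (sentinel parent -1)")
            if len(roots) > 1:
                raise SkeletonTopologyError(
                    f"multiple roots: nodes {sorted(roots)}")
            self._root_id = roots[0]
            graph = nx.DiGraph()
            graph.add_nodes_from(self._by_id)
            graph.add_edges_from(
                (n.parent_id, n.id) for n in self.nodes
                if n.parent_id != ROOT_PARENT)
            if not nx.is_arborescence(graph):
                cycle_ids = sorted({u for u, _ in nx.find_cycle(graph)}) \
                    if not nx.is_directed_acyclic_graph(graph) else []
                raise SkeletonTopologyError(
                    f"parent references do not form a tree"
                    + (f"; cycle through nodes {cycle_ids}" if cycle_ids else ""))
        else:
            self._root_id = None

    # -- accessors ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[SkeletonNode]:
        return iter(self.nodes)

    def node(self, node_id: int) -> SkeletonNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[int]:
        return list(self._children[node_id])

    @property
    def root_id(self) -> int | None:
        return self._root_id

    @property
    def node_ids(self) -> list[int]:
        return [n.id for n in self.nodes]

    def positions(self, ids: Sequence[int] | None = None) -> np.ndarray:
        """Positions (µm) as an (n, 3) array, ordered as ``ids``."""
        which = self.node_ids if ids is None else list(ids)
        if not which:
            return np.empty((0, 3))
        return np.vstack([self._by_id[i].position for i in which]) \
            * self.units_per_coordinate

    def edges(self) -> list[tuple[int, int]]:
        """(parent, child) pairs covering every non-root node once."""
        return [(n.parent_id, n.id) for n in self.nodes
                if n.parent_id != ROOT_PARENT]

    def branch_point_ids(self) -> list[int]:
        """Nodes with two or more children (graph degree ≥ 3 off the root)."""
        return [i for i, ch in self._children.items() if len(ch) >= 2]

    def tip_ids(self) -> list[int]:
        return [i for i, ch in self._children.items()
                if not ch and i != self._root_id]

    def with_labels(self, labels: dict[int, str]) -> "ArborSkeleton":
        """A copy with ``structure_label`` replaced for the given node ids."""
        new_nodes = [replace(n, structure_label=labels.get(n.id, n.structure_label))
                     for n in self.nodes]
        return ArborSkeleton(new_nodes, frame=self.frame,
                             frame_interval=self.frame_interval,
                             units_per_coordinate=self.units_per_coordinate)


@dataclass
class Branch:
    """A maximal unbranched path between root/branch points/tips.

    ``node_path`` runs from the proximal endpoint (root or branch point)
    to the distal endpoint (branch point or tip).  ``path_length`` is the
    sum of consecutive Euclidean distances, ``chord_length`` the distance
    between the two endpoints, both in µm.  ``strahler_order`` is 0 until
    assigned by :func:`arborkit.morphometry.strahler_orders`.
    """

    node_path: list[int]
    path_length: float
    chord_length: float
    is_terminal: bool
    strahler_order: int = 0

    def __post_init__(self) -> None:
        if len(self.node_path) < 2:
            raise ValueError("a branch spans at least one edge")
        # small numerical slack: path ≥ chord by the triangle inequality
        if self.path_length < self.chord_length - 1e-9:
            raise ValueError("path_length < chord_length")


# -- SWC ---------------------------------------------------------------------


def read_swc(source: str | IO[str] | IO[bytes], frame: int = 0,
             frame_interval: float = 1.0) -> ArborSkeleton:
    """Parse an SWC stream or string into a validated :class:`ArborSkeleton`.

    Accepts the conventional 7-column dialect
    (``id type x y z radius parent``) with ``#`` comment lines, as exported
    by Simple Neurite Tracer.  Coordinates are taken as µm.  Recognised
    type codes (2 → branch, 5 → filopodium) populate ``structure_label``;
    the column plays no role in topology.
    """
    if isinstance(source, (str, bytes)):
        text = source.decode() if isinstance(source, bytes) else source
    else:
        text = source.read()
        if isinstance(text, bytes):
            text = text.decode()
    nodes: list[SkeletonNode] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCFormatError(f"line {lineno}: expected 7 columns, "
                                 f"got {len(parts)}")
        try:
            nid = int(parts[0])
            code = int(parts[1])
            x, y, z, radius = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCFormatError(f"line {lineno}: {exc}") from None
        if nid in seen:
            raise SWCFormatError(f"line {lineno}: duplicate node id {nid}")
        seen.add(nid)
        try:
            nodes.append(SkeletonNode(
                id=nid, position=np.array([x, y, z]), radius=radius,
                parent_id=parent,
                structure_label=_CODE_TO_LABEL.get(code, "unspecified")))
        except ValueError as exc:
            raise SWCFormatError(f"line {lineno}: {exc}") from None
    return ArborSkeleton(nodes, frame=frame, frame_interval=frame_interval)


def write_swc(skeleton: ArborSkeleton, sink: IO[str] | None = None,
              comments: Sequence[str] = (), precision: int = 6) -> str | None:
    """Emit SWC text; round-trips ids, topology, labels and coordinates.

    When ``sink`` is None the SWC text is returned instead of written.
    """
    lines = [f"# {c}" for c in comments]
    fmt = f"{{:d}} {{:d}} {{:.{precision}f}} {{:.{precision}f}} " \
          f"{{:.{precision}f}} {{:.{precision}f}} {{:d}}"
    for node in skeleton:
        lines.append(fmt.format(
            node.id, _LABEL_TO_CODE[node.structure_label],
            node.position[0], node.position[1], node.position[2],
            node.radius, node.parent_id))
    text = "\n".join(lines) + "\n"
    if sink is None:
        return text
    sink.write(text)
    return None


# -- branch decomposition ----------------------------------------------------


def decompose_branches(skeleton: ArborSkeleton) -> list[Branch]:
    """Partition the skeleton's edges into maximal unbranched paths.

    Branch endpoints are the root, branch points (≥ 2 children) and tips;
    interior nodes of a path have exactly one child.  Every edge belongs to
    exactly one branch.  An empty or single-node skeleton yields no branches.
    """
    if len(skeleton) <= 1:
        return []
    branches: list[Branch] = []
    # start a path below the root and below every branch point (the root
    # may itself be a branch point; count it once)
    starts = list(dict.fromkeys([skeleton.root_id]
                                + skeleton.branch_point_ids()))
    for start in starts:
        for child in skeleton.children(start):
            path = [start, child]
            while True:
                nxt = skeleton.children(path[-1])
                if len(nxt) != 1:
                    break
                path.append(nxt[0])
            pos = skeleton.positions(path)
            seg = np.diff(pos, axis=0)
            path_length = float(np.sum(np.linalg.norm(seg, axis=1)))
            # clamp: mathematically chord ≤ path; float summation order can
            # break this by machine epsilon on single-edge paths
            chord_length = min(float(np.linalg.norm(pos[-1] - pos[0])),
                               path_length)
            is_terminal = not skeleton.children(path[-1])
            branches.append(Branch(node_path=path, path_length=path_length,
                                   chord_length=chord_length,
                                   is_terminal=is_terminal))
    return branches
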