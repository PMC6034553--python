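"""Neuron morphologies: section trees and SWC (7-column) I/O.

A morphology is a tree of unbranched *sections*.  Each section is a 3D
polyline with per-point diameters (μm).  The first point of a non-root
section coincides with the last point of its parent, so section length is
measured from the attachment point.  A multi-point SWC soma is collapsed to
a single equivalent-area point (common single-compartment convention).

Units: μm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# SWC structure-type codes
SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
DENDRITE_TYPES = (BASAL, APICAL)


class SWCParseError(ValueError):
    """Malformed SWC content (names the offending line)."""


class SWCStructureError(ValueError):
    """Ill-formed tree structure (orphan parents, cycles, bad geometry)."""


@dataclass
class Section:
    """An unbranched cable segment: polyline with diameters.

    ``points`` is an (n, 4) array of x, y, z, diameter.  For non-root
    sections the first row is the attachment point on the parent.
    """

    id: int
    parent_id: int | None
    type: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 4:
            raise SWCStructureError(f"section {self.id}: points must be (n, 4)")
        if np.any(self.points[:, 3] <= 0):
            raise SWCStructureError(f"section {self.id}: non-positive diameter")

    @property
    def length(self) -> float:
        """Arc length of the polyline (μm)."""
        d = np.diff(self.points[:, :3], axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())

    @property
    def diameters(self) -> np.ndarray:
        return self.points[:, 3]

    def frustum_area(self) -> float:
        """Lateral surface area (μm²) summing truncated-cone frusta."""
        p = self.points
        r = p[:, 3] / 2.0
        dl = np.sqrt((np.diff(p[:, :3], axis=0) ** 2).sum(axis=1))
        slant = np.sqrt(dl**2 + np.diff(r) ** 2)
        return float(np.pi * ((r[:-1] + r[1:]) * slant).sum())


@dataclass
class Morphology:
    """Tree of sections; the root is the soma."""

    sections: dict[int, Section] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        roots = [s for s in self.sections.values() if s.parent_id is None]
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        if roots[0].type != SOMA:
            raise SWCStructureError("root section must be the soma")
        for s in self.sections.values():
            if s.parent_id is not None:
                if s.parent_id not in self.sections:
                    raise SWCStructureError(
                        f"section {s.id}: parent {s.parent_id} does not exist"
                    )
                if s.length <= 0:
                    raise SWCStructureError(f"section {s.id}: zero length")
        # cycle check via iterative parent walk
        for s in self.sections.values():
            seen = set()
            cur: int | None = s.id
            while cur is not None:
                if cur in seen:
                    raise SWCStructureError(f"cycle through section {cur}")
                seen.add(cur)
                cur = self.sections[cur].parent_id

    @property
    def root(self) -> Section:
        return next(s for s in self.sections.values() if s.parent_id is None)

    def children(self, sec_id: int) -> list[Section]:
        return [s for s in self.sections.values() if s.parent_id == sec_id]

    def topological_order(self) -> list[Section]:
        """Sections ordered parents-before-children."""
        out, stack = [], [self.root]
        while stack:
            s = stack.pop()
            out.append(s)
            stack.extend(sorted(self.children(s.id), key=lambda c: -c.id))
        return out

    def terminal_sections(self, types: tuple[int, ...] = DENDRITE_TYPES) -> list[Section]:
        """Dendritic sections with no children (tips)."""
        return [
            s
            for s in self.sections.values()
            if s.type in types and not self.children(s.id)
        ]

    def total_length(self, types: tuple[int, ...] = DENDRITE_TYPES) -> float:
        return sum(s.length for s in self.sections.values() if s.type in types)

    def total_area(self, types: tuple[int, ...] = DENDRITE_TYPES) -> float:
        return sum(s.frustum_area() for s in self.sections.values() if s.type in types)


def _soma_equivalent(rows: list[tuple[int, int, float, float, float, float, int]]) -> Section:
    """Collapse soma sample points to one equivalent-area spherical point."""
    pts = np.array([[x, y, z, 2 * r] for (_, _, x, y, z, r, _) in rows])
    center = pts[:, :3].mean(axis=0)
    if len(rows) == 1:
        diam = pts[0, 3]
    else:
        # surface area of the frustum chain -> sphere of equal area
        sec = Section(id=-1, parent_id=None, type=SOMA, points=pts)
        area = sec.frustum_area()
        if area <= 0:  # coincident points: fall back to mean diameter
            diam = float(pts[:, 3].mean())
        else:
            diam = float(np.sqrt(area / np.pi))
    point = np.array([[center[0], center[1], center[2], diam]])
    return Section(id=1, parent_id=None, type=SOMA, points=point)


def read_swc(path: str | Path) -> Morphology:
    """Read a 7-column SWC file into a :class:`Morphology`.

    The soma (type 1) is collapsed to a single equivalent-area point; all
    soma-attached neurites anchor at the soma center.  Unbranched chains of
    same-type nodes form sections; branch points and type changes start new
    sections.
    """
    rows: dict[int, tuple[int, int, float, float, float, float, int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid, ntype = int(parts[0]), int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(f"line {lineno}: {exc}") from exc
        if r <= 0:
            raise SWCParseError(f"line {lineno}: non-positive radius")
        if nid in rows:
            raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
        rows[nid] = (nid, ntype, x, y, z, r, parent)

    if not rows:
        raise SWCParseError("empty SWC file")
    for nid, row in rows.items():
        parent = row[6]
        if parent != -1 and parent not in rows:
            raise SWCStructureError(f"node {nid}: parent {parent} does not exist")

    soma_rows = [r for r in rows.values() if r[1] == SOMA]
    if not soma_rows:
        raise SWCStructureError("no soma (type 1) nodes")
    soma = _soma_equivalent(soma_rows)
    soma_ids = {r[0] for r in soma_rows}

    children: dict[int, list[int]] = {}
    for nid, row in rows.items():
        if row[1] == SOMA:
            continue
        parent = row[6]
        key = 0 if parent in soma_ids else parent
        children.setdefault(key, []).append(nid)

    def n_children(nid: int) -> int:
        return len(children.get(nid, []))

    sections: dict[int, Section] = {1: soma}
    next_id = 2
    # walk chains starting from soma-attached nodes and from branch points
    starts: list[tuple[int, int]] = [(nid, 1) for nid in sorted(children.get(0, []))]
    while starts:
        start, parent_sec = starts.pop(0)
        if parent_sec == 1:
            origin = soma.points[0].copy()
        else:
            origin = sections[parent_sec].points[-1].copy()
        chain = [origin]
        cur = start
        first = True
        while True:
            _, ntype, x, y, z, r, _ = rows[cur]
            node = np.array([x, y, z, 2 * r])
            if first and np.allclose(node[:3], origin[:3], atol=1e-9):
                # co-located origin node: adopt its own proximal diameter
                chain[0] = node
            else:
                chain.append(node)
            first = False
            kids = children.get(cur, [])
            if len(kids) == 1 and rows[kids[0]][1] == ntype:
                cur = kids[0]
            else:
                break
        if len(chain) < 2:
            raise SWCStructureError(
                f"node {start}: zero-extent section (coincident points)")
        sec = Section(
            id=next_id,
            parent_id=parent_sec,
            type=rows[start][1],
            points=np.array(chain),
        )
        sections[next_id] = sec
        for kid in sorted(children.get(cur, [])):
            starts.append((kid, next_id))
        next_id += 1
    return Morphology(sections=sections)


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as 7-column SWC (soma = one type-1 node)."""
    lines = ["# SWC written by humanl23"]
    node_id = 1
    last_node_of: dict[int, int] = {}
    root = morph.root
    x, y, z, d = root.points[0]
    lines.append(f"1 1 {x:.4f} {y:.4f} {z:.4f} {d / 2:.4f} -1")
    last_node_of[root.id] = 1
    node_id = 2
    for sec in morph.topological_order():
        if sec.parent_id is None:
            continue
        parent_node = last_node_of[sec.parent_id]
        # the origin point is emitted as a node co-located with the parent
        # node so that the section's own proximal diameter survives a
        # write/read cycle
        for px, py, pz, pd in sec.points:
            lines.append(
                f"{node_id} {sec.type} {px:.4f} {py:.4f} {pz:.4f} {pd / 2:.4f} {parent_node}"
            )
            parent_node = node_id
            node_id += 1
        last_node_of[sec.id] = parent_node
    Path(path).write_text("\n".join(lines) + "\n")
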