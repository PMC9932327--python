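"""Labeled compartment trees: loading, validation, synthesis, path extraction.

A morphology is a rooted tree of cylindrical compartments, each labeled with
one of four types (soma, main, smooth, spiny) that determines its ion-channel
inventory.  The soma is always the single root.  Readers are provided for the
standard 7-column SWC format and for the GENESIS ".p" relative-coordinate
dialect used by the classic 1,600-compartment Purkinje model; a deterministic
generator produces reduced synthetic trees so that every experiment can run
from code alone.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class CType(enum.Enum):
    SOMA = "soma"
    MAIN = "main"
    SMOOTH = "smooth"
    SPINY = "spiny"


CTYPE_ORDER = (CType.SOMA, CType.MAIN, CType.SMOOTH, CType.SPINY)

#: default SWC integer-type -> CType map (1 soma, 3 basal dend, 4 apical).
DEFAULT_SWC_TYPE_MAP: Mapping[int, CType] = {1: CType.SOMA, 3: CType.SPINY, 4: CType.MAIN}

#: default GENESIS .p name-prefix -> CType map.
DEFAULT_P_PREFIX_MAP: Mapping[str, CType] = {
    "soma": CType.SOMA,
    "main": CType.MAIN,
    "smooth": CType.SMOOTH,
    "spiny": CType.SPINY,
    "dend": CType.SPINY,
}


class MorphologyError(ValueError):
    """Structural or parse error in a morphology source."""


@dataclass
class Passive:
    """Passive membrane parameters shared by all compartments.

    c_m: membrane capacitance, uF/cm^2.
    r_axial: intracellular (axial) resistivity, Ohm*cm.
    e_leak: leak reversal potential, mV (also the default initial voltage).
    spine_factor: multiplier on c_m for spiny compartments, compensating the
        membrane area of unmodeled spines (the leak density of spiny
        compartments in the channel file carries the same factor).
    """

    c_m: float = 1.64
    r_axial: float = 250.0
    e_leak: float = -80.0
    spine_factor: float = 5.3


@dataclass
class Compartment:
    id: int
    parent_id: int | None
    ctype: CType
    length: float  # um
    radius: float  # um
    position: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.length <= 0 or self.radius <= 0:
            raise MorphologyError(
                f"compartment {self.id}: length and radius must be positive "
                f"(got length={self.length}, radius={self.radius})"
            )


@dataclass
class Morphology:
    compartments: list[Compartment]
    passive: Passive = field(default_factory=Passive)

    def __post_init__(self):
        self._index = {c.id: i for i, c in enumerate(self.compartments)}
        if len(self._index) != len(self.compartments):
            raise MorphologyError("duplicate compartment ids")
        self.validate()

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.compartments)

    def __getitem__(self, cid: int) -> Compartment:
        return self.compartments[self._index[cid]]

    def __contains__(self, cid: int) -> bool:
        return cid in self._index

    def index_of(self, cid: int) -> int:
        return self._index[cid]

    @property
    def root(self) -> Compartment:
        return self._root

    def children(self, cid: int) -> list[int]:
        return self._children[cid]

    def validate(self) -> None:
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        self._root = roots[0]
        if self._root.ctype is not CType.SOMA:
            raise MorphologyError("root compartment must be the soma")
        children: dict[int, list[int]] = {c.id: [] for c in self.compartments}
        for c in self.compartments:
            if c.parent_id is None:
                continue
            if c.parent_id not in self._index:
                raise MorphologyError(f"compartment {c.id}: unknown parent {c.parent_id}")
            children[c.parent_id].append(c.id)
        # connectivity + acyclicity via BFS from the root
        seen = {self._root.id}
        frontier = [self._root.id]
        while frontier:
            nxt = []
            for cid in frontier:
                for ch in children[cid]:
                    if ch in seen:
                        raise MorphologyError(f"cycle detected at compartment {ch}")
                    seen.add(ch)
                    nxt.append(ch)
            frontier = nxt
        if len(seen) != len(self.compartments):
            orphans = sorted(set(self._index) - seen)
            raise MorphologyError(f"disconnected compartments: {orphans[:10]}")
        self._children = children

    def topological_ids(self) -> list[int]:
        """Ids in parent-before-child order, root first."""
        out, stack = [], [self._root.id]
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(reversed(self._children[cid]))
        return out

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "passive": vars(self.passive),
            "compartments": [
                {
                    "id": c.id,
                    "parent_id": c.parent_id,
                    "ctype": c.ctype.value,
                    "length": c.length,
                    "radius": c.radius,
                    "position": list(c.position) if c.position else None,
                }
                for c in self.compartments
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Morphology":
        payload = json.loads(text)
        comps = [
            Compartment(
                id=d["id"],
                parent_id=d["parent_id"],
                ctype=CType(d["ctype"]),
                length=d["length"],
                radius=d["radius"],
                position=tuple(d["position"]) if d.get("position") else None,
            )
            for d in payload["compartments"]
        ]
        return cls(comps, Passive(**payload.get("passive", {})))


def count_by_type(m: Morphology) -> dict[CType, int]:
    counts = {t: 0 for t in CTYPE_ORDER}
    for c in m.compartments:
        counts[c.ctype] += 1
    return counts


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(path, type_map: Mapping[int, CType] | None = None,
             passive: Passive | None = None) -> Morphology:
    """Read a 7-column SWC file (id, type, x, y, z, radius, parent).

    Each SWC point becomes one compartment; a point's length is its distance
    to the parent point (the root uses its radius as a nominal length, the
    usual single-point-soma convention).
    """
    type_map = dict(DEFAULT_SWC_TYPE_MAP if type_map is None else type_map)
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise MorphologyError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                pid = int(parts[0])
                styp = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                par = int(parts[6])
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: malformed value ({exc})") from exc
            rows[pid] = (styp, x, y, z, r, par)

    comps = []
    for pid, (styp, x, y, z, r, par) in rows.items():
        if styp not in type_map:
            raise MorphologyError(f"SWC type {styp} has no ctype mapping")
        if par == -1:
            length = max(2.0 * r, 1e-6)
            parent_id = None
        else:
            if par not in rows:
                raise MorphologyError(f"SWC point {pid}: unknown parent {par}")
            _, px, py, pz, _, _ = rows[par]
            length = math.dist((x, y, z), (px, py, pz))
            if length <= 0:
                length = max(r, 1e-6)  # coincident points: fall back to radius
            parent_id = par
        comps.append(Compartment(pid, parent_id, type_map[styp], length, r, (x, y, z)))
    return Morphology(comps, passive or Passive())


def write_swc(m: Morphology, path,
              type_map: Mapping[int, CType] | None = None) -> None:
    """Write SWC; positions are synthesized along +x for position-less trees."""
    inv = {v: k for k, v in (type_map or DEFAULT_SWC_TYPE_MAP).items()}
    inv.setdefault(CType.SMOOTH, inv.get(CType.MAIN, 4))
    pos: dict[int, tuple[float, float, float]] = {}
    lines = ["# generated by pcseq"]
    for cid in m.topological_ids():
        c = m[cid]
        if c.position is not None:
            p = c.position
        elif c.parent_id is None:
            p = (0.0, 0.0, 0.0)
        else:
            px, py, pz = pos[c.parent_id]
            p = (px + c.length, py, pz)
        pos[cid] = p
        par = -1 if c.parent_id is None else c.parent_id
        styp = inv[c.ctype]
        lines.append(f"{c.id} {styp} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c.radius:.6f} {par}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GENESIS .p dialect
# ---------------------------------------------------------------------------

def _ctype_from_name(name: str, prefix_map: Mapping[str, CType]) -> CType:
    base = name.split("[", 1)[0].lower()
    for prefix, ct in sorted(prefix_map.items(), key=lambda kv: -len(kv[0])):
        if base.startswith(prefix):
            return ct
    raise MorphologyError(f"compartment name {name!r} matches no ctype prefix")


def read_genesis_p(path, prefix_map: Mapping[str, CType] | None = None,
                   passive: Passive | None = None) -> Morphology:
    """Read the GENESIS ".p" relative-coordinate morphology dialect.

    Recognized lines are ``name parent x y z diameter`` with coordinates in
    um relative to the parent compartment; ``*``-directives and ``//``
    comments are skipped.  Compartment type comes from the name prefix via
    ``prefix_map``.  A child naming a not-yet-declared parent is a structure
    error (the classic files declare parents first).
    """
    prefix_map = dict(DEFAULT_P_PREFIX_MAP if prefix_map is None else prefix_map)
    comps: list[Compartment] = []
    name_to_id: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("//", 1)[0].strip()
            if not line or line.startswith("*"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise MorphologyError(f"{path}:{lineno}: expected >=6 fields, got {len(parts)}")
            name, parent_name = parts[0], parts[1]
            try:
                x, y, z, dia = (float(v) for v in parts[2:6])
            except ValueError as exc:
                raise MorphologyError(f"{path}:{lineno}: malformed number ({exc})") from exc
            cid = len(comps) + 1
            if name in name_to_id:
                raise MorphologyError(f"{path}:{lineno}: duplicate compartment {name!r}")
            length = math.sqrt(x * x + y * y + z * z)
            if parent_name in ("none", "nil", "-"):
                parent_id = None
                length = length if length > 0 else dia
            else:
                if parent_name == ".":
                    parent_id = cid - 1  # GENESIS shorthand: previous line
                elif parent_name in name_to_id:
                    parent_id = name_to_id[parent_name]
                else:
                    raise MorphologyError(
                        f"{path}:{lineno}: unknown parent compartment {parent_name!r}")
            comps.append(Compartment(cid, parent_id, _ctype_from_name(name, prefix_map),
                                     length, dia / 2.0))
            name_to_id[name] = cid
    return Morphology(comps, passive or Passive())


def write_genesis_p(m: Morphology, path) -> None:
    """Write the tree in the same ``name parent x y z diameter`` dialect."""
    names: dict[int, str] = {}
    counters = {t: 0 for t in CTYPE_ORDER}
    lines = ["// generated by pcseq", "*relative"]
    for cid in m.topological_ids():
        c = m[cid]
        counters[c.ctype] += 1
        name = f"{c.ctype.value}{counters[c.ctype]}" if c.ctype is not CType.SOMA else "soma"
        names[cid] = name
        parent = "none" if c.parent_id is None else names[c.parent_id]
        lines.append(f"{name} {parent} {c.length:.6f} 0 0 {2.0 * c.radius:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic reduced morphologies
# ---------------------------------------------------------------------------

@dataclass
class ReducedSpec:
    """Recipe for a reduced synthetic Purkinje-like tree.

    The tree is layered root-to-tip as soma -> main -> smooth -> spiny.  Main
    and smooth compartments form a single trunk; spiny compartments form
    ``branching`` chains hung off smooth compartments (``branching=1`` keeps
    everything on one line, the fixture used for straight-path stimulation).

    Default geometry gives a spiny-dendrite passive length constant of a few
    hundred um, i.e. several compartments, so that sequential stimulation is
    partially - not instantly - coupled along a path.
    """

    n_main: int = 2
    n_smooth: int = 6
    n_spiny: int = 30
    branching: int = 1
    seed: int = 0
    jitter: float = 0.0  # fractional radius/length jitter on spiny comps
    soma_radius: float = 15.0
    soma_length: float = 30.0
    main_radius: float = 3.0
    main_length: float = 40.0
    smooth_radius: float = 1.5
    smooth_length: float = 40.0
    spiny_radius: float = 0.8
    spiny_length: float = 40.0


def generate_reduced(spec: ReducedSpec | None = None, **kwargs) -> Morphology:
    """Deterministically build a reduced labeled tree from a ReducedSpec."""
    if spec is None:
        spec = ReducedSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a ReducedSpec or keyword overrides, not both")
    if min(spec.n_main, spec.n_smooth, spec.n_spiny) < 0:
        raise MorphologyError("compartment counts must be non-negative")
    total = 1 + spec.n_main + spec.n_smooth + spec.n_spiny
    if total < 2:
        raise MorphologyError("a reduced morphology needs at least 2 compartments")
    if spec.branching < 1:
        raise MorphologyError("branching must be >= 1")

    rng = np.random.default_rng(spec.seed)
    comps: list[Compartment] = [
        Compartment(1, None, CType.SOMA, spec.soma_length, spec.soma_radius)
    ]
    next_id = 2
    tip = 1
    for _ in range(spec.n_main):
        comps.append(Compartment(next_id, tip, CType.MAIN, spec.main_length, spec.main_radius))
        tip = next_id
        next_id += 1
    smooth_ids = []
    for _ in range(spec.n_smooth):
        comps.append(Compartment(next_id, tip, CType.SMOOTH,
                                 spec.smooth_length, spec.smooth_radius))
        smooth_ids.append(next_id)
        tip = next_id
        next_id += 1

    def jittered(base: float) -> float:
        if spec.jitter <= 0:
            return base
        return base * float(1.0 + spec.jitter * (2.0 * rng.random() - 1.0))

    if spec.n_spiny:
        # Spiny chains hang off smooth compartments such that no smooth
        # compartment exceeds `branching` children in total (the trunk child
        # of a non-tip smooth counts).  branching=1 keeps one linear chain
        # off the distal smooth tip.
        anchors = smooth_ids or [tip]
        attach_points = [anchors[-1]] * spec.branching
        for cid in reversed(anchors[:-1]):
            attach_points.extend([cid] * (spec.branching - 1))
        chain_tips = list(attach_points[:max(1, min(len(attach_points), spec.n_spiny))])
        for i in range(spec.n_spiny):
            parent = chain_tips[i % len(chain_tips)]
            comps.append(Compartment(next_id, parent, CType.SPINY,
                                     jittered(spec.spiny_length),
                                     jittered(spec.spiny_radius)))
            chain_tips[i % len(chain_tips)] = next_id
            next_id += 1
    return Morphology(comps)


# ---------------------------------------------------------------------------
# Stimulation paths
# ---------------------------------------------------------------------------

class PathError(ValueError):
    """A straight path of the requested length cannot be extracted."""


def straight_path(m: Morphology, start_id: int, n: int, toward_soma: bool = True) -> list[int]:
    """Extract a simple path of ``n`` compartments starting at ``start_id``.

    Walking toward the soma follows parent links; walking away descends
    children, choosing the largest-radius child at branch points (ties break
    to the lowest id).  The soma itself is never included: dendritic
    stimulation stops at the most proximal dendritic compartment.
    """
    if start_id not in m:
        raise PathError(f"start compartment {start_id} does not exist")
    if n < 1:
        raise PathError("path length must be >= 1")
    start = m[start_id]
    if start.ctype is CType.SOMA:
        raise PathError("paths are dendritic; start at a non-soma compartment")
    path = [start_id]
    cur = start_id
    while len(path) < n:
        if toward_soma:
            pid = m[cur].parent_id
            if pid is None or m[pid].ctype is CType.SOMA:
                raise PathError(
                    f"only {len(path)} compartments available toward the soma "
                    f"from {start_id} (requested {n})")
            nxt = pid
        else:
            kids = [k for k in m.children(cur) if m[k].ctype is not CType.SOMA]
            if not kids:
                raise PathError(
                    f"only {len(path)} compartments available away from the soma "
                    f"from {start_id} (requested {n})")
            nxt = min(kids, key=lambda k: (-m[k].radius, k))
        path.append(nxt)
        cur = nxt
    return path
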