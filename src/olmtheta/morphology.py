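"""Reduced O-LM-like morphologies.

The package replaces the reconstructed morphologies of the original model
database with parameterized synthetic trees matched on the two quantities the
experiments actually consume: total somatodendritic surface area and the
number of equal-length segments (which fixes the synapse-placement grid).
Spatial detail beyond area and segmentation does not enter any computed
result, so straight cables laid out in the plane suffice.

Conventions
-----------
* Cylinder lateral area, ``pi * diameter * length`` (no end caps).
* Segments partition each section into ``nseg`` equal lengths; electrical
  compartments and synapse sites live at segment midpoints.
* Segment ordering is depth-first starting at the soma, axon excluded; the
  synapse rule "every fourth segment" selects global indices 0, 4, 8, ...
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "SynapseSite",
    "build_reduced_morphology",
    "place_synapse_sites",
    "surface_area",
    "read_swc",
    "write_swc",
    "MORPH1_AREA_UM2",
    "MORPH2_AREA_UM2",
    "standard_morphology",
]

#: Printed somatodendritic surface areas of the two reference morphologies (µm²).
MORPH1_AREA_UM2 = 16193.6
MORPH2_AREA_UM2 = 9980.1

#: Non-axonal segment counts chosen so that every-fourth-segment placement
#: yields the reference site counts (84 -> 21 sites, 76 -> 19 sites).
MORPH1_NSEG = 84
MORPH2_NSEG = 76

_KINDS = ("soma", "dendrite", "axon")


@dataclass(frozen=True)
class Section:
    """One cylindrical cable section.

    Parameters are in µm.  ``parent_id is None`` marks the soma root.
    """

    id: int
    parent_id: int | None
    kind: str
    length: float
    diameter: float
    nseg: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown section kind {self.kind!r}")
        if not self.length > 0:
            raise ValueError("section length must be positive")
        if not self.diameter > 0:
            raise ValueError("section diameter must be positive")
        if self.nseg < 1:
            raise ValueError("nseg must be a positive integer")

    @property
    def area(self) -> float:
        """Lateral cylinder area in µm²."""
        return math.pi * self.diameter * self.length


@dataclass(frozen=True)
class SynapseSite:
    """A synapse location: fractional position along a section (segment midpoint)."""

    section_id: int
    position: float

    def __post_init__(self) -> None:
        if not 0.0 < self.position < 1.0:
            raise ValueError("site position must lie strictly inside the section")


@dataclass
class Segment:
    """One electrical compartment (internal bookkeeping, not a spec type)."""

    section_id: int
    index_in_section: int
    position: float  # midpoint, fraction of section length
    length: float  # µm
    diameter: float  # µm
    kind: str


@dataclass
class Morphology:
    """A tree of cylindrical sections rooted at a single soma section."""

    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if not self.sections:
            raise ValueError("morphology has no sections")
        ids = [s.id for s in self.sections]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate section ids")
        roots = [s for s in self.sections if s.parent_id is None]
        if len(roots) != 1:
            raise ValueError("morphology must have exactly one root section")
        if roots[0].kind != "soma":
            raise ValueError("the root section must be the soma")
        byid = {s.id: s for s in self.sections}
        for s in self.sections:
            if s.parent_id is not None and s.parent_id not in byid:
                raise ValueError(f"section {s.id} has unknown parent {s.parent_id}")
        # cycle check via walk to root
        for s in self.sections:
            seen = set()
            cur: Section | None = s
            while cur is not None:
                if cur.id in seen:
                    raise ValueError("morphology graph has a cycle")
                seen.add(cur.id)
                cur = byid.get(cur.parent_id) if cur.parent_id is not None else None

    @property
    def root(self) -> Section:
        return next(s for s in self.sections if s.parent_id is None)

    def section(self, section_id: int) -> Section:
        return next(s for s in self.sections if s.id == section_id)

    def children(self, section_id: int) -> list[Section]:
        return sorted(
            (s for s in self.sections if s.parent_id == section_id),
            key=lambda s: s.id,
        )

    def dfs_sections(self, include_axon: bool = True) -> Iterator[Section]:
        """Sections in depth-first order, soma first, children by ascending id."""
        stack = [self.root]
        while stack:
            sec = stack.pop()
            if sec.kind == "axon" and not include_axon:
                continue
            yield sec
            stack.extend(reversed(self.children(sec.id)))

    def segments(self, include_axon: bool = True) -> list[Segment]:
        """All compartments in depth-first section order."""
        out: list[Segment] = []
        for sec in self.dfs_sections(include_axon=include_axon):
            seg_len = sec.length / sec.nseg
            for j in range(sec.nseg):
                out.append(
                    Segment(
                        section_id=sec.id,
                        index_in_section=j,
                        position=(j + 0.5) / sec.nseg,
                        length=seg_len,
                        diameter=sec.diameter,
                        kind=sec.kind,
                    )
                )
        return out

    # -- geometry ----------------------------------------------------------
    @property
    def total_area(self) -> float:
        """Total lateral area over all sections (µm²)."""
        return float(sum(s.area for s in self.sections))

    def area(self, include_axon: bool = False) -> float:
        return float(
            sum(s.area for s in self.sections if include_axon or s.kind != "axon")
        )


def surface_area(morph: Morphology, include_axon: bool = False) -> float:
    """Sum of π·d·L over the selected sections, in µm²."""
    return morph.area(include_axon=include_axon)


# ---------------------------------------------------------------------------
# synthetic builder
# ---------------------------------------------------------------------------

_SOMA_DIAM = 20.0  # µm
_SOMA_LEN = 20.0  # µm
_SOMA_NSEG = 4
_STEM_DIAM = 2.0  # µm, proximal dendrite
_TIP_DIAM = 0.8  # µm, distal dendrite after the single branch point
_AXON_AREA = 200.0  # µm², excluded from the area target
_AXON_DIAM = 1.0  # µm


def build_reduced_morphology(
    target_area: float,
    n_dendrite_stems: int = 2,
    n_nonaxon_segments: int = MORPH1_NSEG,
    seed: int = 0,
) -> Morphology:
    """Build a soma + binary-branched dendrite tree hitting ``target_area``.

    The soma is a fixed 20 µm x 20 µm cylinder; each dendritic stem is a
    proximal cable (2.0 µm) branching once into two distal cables (0.8 µm,
    jittered a few percent by ``seed``).  All dendritic segments share one
    segment length, solved so the non-axon area matches the target; a short
    passive axon (200 µm²) hangs off the soma and is excluded from both the
    area target and synapse placement.

    Raises ``ValueError`` when the target is geometrically unreachable.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    if n_dendrite_stems < 0:
        raise ValueError("n_dendrite_stems must be >= 0")

    axon = lambda sid: Section(  # noqa: E731 - tiny local factory
        id=sid,
        parent_id=0,
        kind="axon",
        length=_AXON_AREA / (math.pi * _AXON_DIAM),
        diameter=_AXON_DIAM,
        nseg=1,
    )

    if n_dendrite_stems == 0:
        if n_nonaxon_segments < 1:
            raise ValueError("need at least one soma segment")
        # degenerate soma-only cylinder: pi * d * L = target exactly
        soma = Section(
            id=0,
            parent_id=None,
            kind="soma",
            length=target_area / (math.pi * _SOMA_DIAM),
            diameter=_SOMA_DIAM,
            nseg=n_nonaxon_segments,
        )
        return Morphology(sections=[soma, axon(1)])

    if n_nonaxon_segments < _SOMA_NSEG + 3 * n_dendrite_stems:
        raise ValueError(
            "n_nonaxon_segments too small for the requested number of stems"
        )

    soma = Section(
        id=0,
        parent_id=None,
        kind="soma",
        length=_SOMA_LEN,
        diameter=_SOMA_DIAM,
        nseg=_SOMA_NSEG,
    )
    dend_area = target_area - soma.area
    if dend_area <= 0:
        raise ValueError("target_area smaller than the fixed soma area")

    rng = np.random.default_rng(seed)
    n_sections = 3 * n_dendrite_stems  # stem + 2 daughters each
    n_dend_segments = n_nonaxon_segments - _SOMA_NSEG
    base, rem = divmod(n_dend_segments, n_sections)
    if base < 1:
        raise ValueError("not enough segments for every dendritic section")
    nsegs = [base + (1 if i < rem else 0) for i in range(n_sections)]

    diams: list[float] = []
    for _ in range(n_dendrite_stems):
        diams.append(_STEM_DIAM)
        for _ in range(2):
            diams.append(_TIP_DIAM * (1.0 + 0.05 * (rng.random() - 0.5)))

    # one shared segment length Delta: area = pi * Delta * sum(d_i * nseg_i)
    denom = math.pi * sum(d * n for d, n in zip(diams, nsegs))
    delta = dend_area / denom
    if delta <= 0:
        raise ValueError("area target unreachable with positive segment length")

    sections = [soma]
    sid = 1
    for stem in range(n_dendrite_stems):
        k = 3 * stem
        stem_id = sid
        sections.append(
            Section(
                id=stem_id,
                parent_id=0,
                kind="dendrite",
                length=delta * nsegs[k],
                diameter=diams[k],
                nseg=nsegs[k],
            )
        )
        sid += 1
        for d in range(2):
            sections.append(
                Section(
                    id=sid,
                    parent_id=stem_id,
                    kind="dendrite",
                    length=delta * nsegs[k + 1 + d],
                    diameter=diams[k + 1 + d],
                    nseg=nsegs[k + 1 + d],
                )
            )
            sid += 1
    sections.append(axon(sid))

    morph = Morphology(sections=sections)
    achieved = morph.area(include_axon=False)
    if abs(achieved - target_area) / target_area > 0.01:
        raise ValueError(
            f"built morphology misses the area target: {achieved:.1f} vs {target_area}"
        )
    return morph


def standard_morphology(cell: int, seed: int = 0) -> Morphology:
    """The synthetic stand-in for reference morphology 1 or 2."""
    if cell == 1:
        return build_reduced_morphology(MORPH1_AREA_UM2, 2, MORPH1_NSEG, seed=seed)
    if cell == 2:
        return build_reduced_morphology(MORPH2_AREA_UM2, 2, MORPH2_NSEG, seed=seed)
    raise ValueError("cell must be 1 or 2")


# ---------------------------------------------------------------------------
# synapse placement
# ---------------------------------------------------------------------------


def place_synapse_sites(
    morph: Morphology, rule: str = "every_fourth_segment"
) -> list[SynapseSite]:
    """Synapse sites at segment midpoints.

    ``every_fourth_segment`` walks the non-axon segments in depth-first order
    (soma segments first) and selects global indices 0, 4, 8, ...;
    ``soma_only`` returns the single midpoint of the soma.
    """
    if rule == "soma_only":
        return [SynapseSite(section_id=morph.root.id, position=0.5)]
    if rule != "every_fourth_segment":
        raise ValueError(f"unknown placement rule {rule!r}")
    sites = []
    for idx, seg in enumerate(morph.segments(include_axon=False)):
        if idx % 4 == 0:
            sites.append(
                SynapseSite(section_id=seg.section_id, position=seg.position)
            )
    return sites


# ---------------------------------------------------------------------------
# SWC i/o
# ---------------------------------------------------------------------------

_SWC_TYPE = {"soma": 1, "axon": 2, "dendrite": 3}
_SWC_KIND = {v: k for k, v in _SWC_TYPE.items()}


def write_swc(morph: Morphology, path) -> None:
    """Write the morphology as standard 7-column SWC.

    Each section becomes one sample point at its distal end; the edge from the
    parent point carries the section's radius.  The root soma gets two points
    so its length is represented.  Sections are laid out as straight cables,
    daughters fanning +/-25 degrees from the parent direction.
    """
    lines = ["# id type x y z radius parent"]
    # point bookkeeping: section id -> (swc id of distal point, xyz, angle)
    info: dict[int, tuple[int, np.ndarray, float]] = {}
    next_id = 1
    for sec in morph.dfs_sections(include_axon=True):
        t = _SWC_TYPE[sec.kind]
        r = sec.diameter / 2.0
        if sec.parent_id is None:
            p0 = np.zeros(3)
            p1 = np.array([sec.length, 0.0, 0.0])
            lines.append(f"{next_id} {t} {p0[0]:.6f} {p0[1]:.6f} {p0[2]:.6f} {r:.6f} -1")
            root_prox = next_id
            next_id += 1
            lines.append(
                f"{next_id} {t} {p1[0]:.6f} {p1[1]:.6f} {p1[2]:.6f} {r:.6f} {root_prox}"
            )
            info[sec.id] = (next_id, p1, 0.0)
            next_id += 1
        else:
            pid, ppos, pang = info[sec.parent_id]
            n_sibs = len(morph.children(sec.parent_id))
            order = [c.id for c in morph.children(sec.parent_id)].index(sec.id)
            ang = pang + math.radians(25.0) * (order - (n_sibs - 1) / 2.0)
            if sec.kind == "axon":
                ang = math.pi  # axon points backwards
            pos = ppos + sec.length * np.array([math.cos(ang), math.sin(ang), 0.0])
            lines.append(
                f"{next_id} {t} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} {r:.6f} {pid}"
            )
            info[sec.id] = (next_id, pos, ang)
            next_id += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_swc(path) -> Morphology:
    """Read an SWC file written with the one-point-per-section convention.

    Every parent->point edge becomes one cylindrical section whose diameter is
    twice the child point's radius.  Malformed lines raise with their line
    number; orphan parent references are an error.
    """
    pts: dict[int, tuple[int, np.ndarray, float, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ValueError(f"malformed SWC line {lineno}: expected 7 columns")
            try:
                pid = int(fields[0])
                ptype = int(fields[1])
                xyz = np.array([float(v) for v in fields[2:5]])
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"malformed SWC line {lineno}: {exc}") from None
            if ptype not in _SWC_KIND:
                raise ValueError(f"malformed SWC line {lineno}: unknown type {ptype}")
            if parent != -1 and parent not in pts:
                raise ValueError(
                    f"malformed SWC line {lineno}: orphan parent id {parent}"
                )
            pts[pid] = (ptype, xyz, radius, parent)
    if not pts:
        raise ValueError("empty SWC file")

    sections: list[Section] = []
    # map swc point id -> section id built from the edge ending at that point
    sec_of_point: dict[int, int] = {}
    next_sid = 0
    for pid in sorted(pts):
        ptype, xyz, radius, parent = pts[pid]
        if parent == -1:
            sec_of_point[pid] = -1  # root proximal anchor; no section yet
            continue
        pxyz = pts[parent][1]
        length = float(np.linalg.norm(xyz - pxyz))
        if length <= 0:
            raise ValueError(f"zero-length SWC edge ending at point {pid}")
        parent_sec = sec_of_point[parent]
        sections.append(
            Section(
                id=next_sid,
                parent_id=None if parent_sec == -1 else parent_sec,
                kind=_SWC_KIND[ptype],
                length=length,
                diameter=2.0 * radius,
                nseg=1,
            )
        )
        sec_of_point[pid] = next_sid
        next_sid += 1
    return Morphology(sections=sections)
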