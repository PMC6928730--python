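"""Core in-memory types shared across the package.

A cavity (tunnel) is an ordered path of spheres from a protein's active
site to its outer surface.  Each pathway point corresponds to a Voronoi
vertex determined by four surrounding atoms; those four atoms identify
the point topologically, independent of its exact coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Bondi van-der-Waals radii (Å) for the elements the generator emits;
# anything else falls back to DEFAULT_VDW_RADIUS (carbon-like).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
}
DEFAULT_VDW_RADIUS: float = 1.70

#: 20 standard residues plus HID, the delta-protonated histidine naming
#: used by simulation topologies (kept distinct from HIS throughout).
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID",
)

WATER_RESIDUES: frozenset[str] = frozenset({"HOH", "WAT", "SOL", "TIP3"})


def vdw_radius_for(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


@dataclass(frozen=True)
class Atom:
    """One atom with the bookkeeping a cavity encoder needs."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    position: np.ndarray  # shape (3,), Å
    vdw_radius: float
    is_hetero: bool = False

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.serial}: position must be 3-D")
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be > 0")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_RESIDUES

    @property
    def residue_key(self) -> tuple[str, int]:
        """(chain, res_seq) — identifies one residue in one chain."""
        return (self.chain, self.res_seq)


@dataclass
class CavityRecord:
    """On-disk representation of one cavity in one snapshot: the ordered
    spheres forming its body, optionally already encoded into node IDs."""

    cavity_id: str
    snapshot: int
    centers: np.ndarray  # (n, 3) Å
    radii: np.ndarray  # (n,) Å
    node_ids: list[str] | None = None
    lining_atom_serials: list[tuple[int, int, int, int]] | None = None

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        n = len(self.radii)
        if n < 1:
            raise ValueError(f"cavity {self.cavity_id}: needs at least one sphere")
        if self.centers.shape[0] != n:
            raise ValueError(f"cavity {self.cavity_id}: centers/radii length mismatch")
        if np.any(self.radii <= 0):
            raise ValueError(f"cavity {self.cavity_id}: radii must be > 0")
        if self.snapshot < 0:
            raise ValueError(f"cavity {self.cavity_id}: snapshot must be >= 0")
        if self.node_ids is not None and len(self.node_ids) != n:
            raise ValueError(f"cavity {self.cavity_id}: node_ids/spheres length mismatch")
        if self.lining_atom_serials is not None and len(self.lining_atom_serials) != n:
            raise ValueError(
                f"cavity {self.cavity_id}: lining_atom_serials/spheres length mismatch"
            )

    @property
    def n_spheres(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class CavityNode:
    """One pathway point: its sphere and the canonical ID built from the
    four lining atoms (dot-joined ascending serials)."""

    node_id: str
    center: np.ndarray  # (3,)
    radius: float
    lining_atom_serials: tuple[int, int, int, int]

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("node radius must be > 0")
        if len(self.lining_atom_serials) != 4:
            raise ValueError("a node has exactly 4 lining atoms")


@dataclass
class CavitySequence:
    """Ordered nodes of one cavity in one snapshot, active site first."""

    cavity_id: str
    snapshot: int
    nodes: list[CavityNode] = field(default_factory=list)

    def __post_init__(self):
        if len(self.nodes) < 1:
            raise ValueError(f"cavity {self.cavity_id}: sequence must have >= 1 node")

    @property
    def tokens(self) -> list[str]:
        return [n.node_id for n in self.nodes]

    def __len__(self) -> int:
        return len(self.nodes)

    def to_record(self) -> CavityRecord:
        return CavityRecord(
            cavity_id=self.cavity_id,
            snapshot=self.snapshot,
            centers=np.array([n.center for n in self.nodes]),
            radii=np.array([n.radius for n in self.nodes]),
            node_ids=self.tokens,
            lining_atom_serials=[n.lining_atom_serials for n in self.nodes],
        )
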