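"""Canonical node IDs and cavity sentences.

A pathway point (Voronoi vertex) is determined by four non-coplanar
atoms; the point's identity is therefore carried by those four atoms,
not by its coordinates.  Sorting the four atom serials ascending and
dot-joining them gives a canonical, permutation-invariant node ID:
``(2,3,1,4) -> "1.2.3.4"``.  A cavity is then the sentence of node IDs
along its pathway, active site -> surface.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateNodeError
from .structures import Atom, CavityNode, CavityRecord, CavitySequence

LiningMode = Literal["center", "surface"]


def canonical_node_id(atom_serials: Sequence[int]) -> str:
    """Dot-joined ascending sort of four distinct positive atom serials.

    Permutation-invariant and idempotent: all 24 orderings of the same
    four serials map to one ID.
    """
    serials = list(atom_serials)
    if len(serials) != 4:
        raise ValueError(f"a node needs exactly 4 atom serials, got {len(serials)}")
    ints = []
    for s in serials:
        i = int(s)
        if i != s or i <= 0:
            raise ValueError(f"atom serial must be a positive integer, got {s!r}")
        ints.append(i)
    if len(set(ints)) != 4:
        raise DegenerateNodeError(
            f"duplicate atom serial in {ints}: a Voronoi vertex needs four distinct atoms"
        )
    return ".".join(str(s) for s in sorted(ints))


def select_lining_atoms(
    sphere_center: np.ndarray,
    atoms: Sequence[Atom],
    mode: LiningMode = "center",
) -> list[int]:
    """Serials of the four atoms closest to a pathway sphere's center.

    mode "center"  : plain Euclidean center-to-center distance.
    mode "surface" : center distance minus the atom's vdW radius, i.e.
                     distance to the atom's sphere surface (MOLE-style).

    Ties break toward the lower serial.  The result preserves distance
    order (closest first); canonicalization is a separate step.
    """
    if len(atoms) < 4:
        raise ValueError(f"need at least 4 atoms to line a node, got {len(atoms)}")
    if mode not in ("center", "surface"):
        raise ValueError(f"unknown lining mode '{mode}'")
    center = np.asarray(sphere_center, dtype=float)
    positions = np.array([a.position for a in atoms])
    dists = np.linalg.norm(positions - center, axis=1)
    if mode == "surface":
        dists = dists - np.array([a.vdw_radius for a in atoms])
    serials = np.array([a.serial for a in atoms])
    order = np.lexsort((serials, dists))  # distance first, serial breaks ties
    return [int(serials[i]) for i in order[:4]]


def encode_sequence(
    record: CavityRecord,
    atoms: Sequence[Atom],
    mode: LiningMode = "center",
) -> CavitySequence:
    """Encode a cavity record into a sentence of canonical node IDs.

    One node per sphere, in sphere order.  Consecutive spheres that share
    the same four lining atoms yield identical consecutive tokens, which
    are deliberately kept: token frequency is signal for the skip-gram
    model downstream.
    """
    if not atoms:
        raise ValueError("atom list is empty")
    nodes: list[CavityNode] = []
    for i, (center, radius) in enumerate(zip(record.centers, record.radii)):
        try:
            serials = select_lining_atoms(center, atoms, mode=mode)
            node_id = canonical_node_id(serials)
        except (ValueError, DegenerateNodeError) as exc:
            raise type(exc)(f"cavity {record.cavity_id}, sphere {i}: {exc}") from exc
        nodes.append(CavityNode(
            node_id=node_id,
            center=center,
            radius=float(radius),
            lining_atom_serials=tuple(serials),
        ))
    return CavitySequence(cavity_id=record.cavity_id, snapshot=record.snapshot, nodes=nodes)


def encode_records(
    records: Sequence[CavityRecord],
    atoms: Sequence[Atom],
    mode: LiningMode = "center",
) -> list[CavitySequence]:
    return [encode_sequence(rec, atoms, mode=mode) for rec in records]
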