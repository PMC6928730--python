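"""Synthetic molecules, channel templates, and noisy cavity trajectories.

Real cavity corpora come from a Voronoi-based extractor run over a
molecular-dynamics trajectory: a handful of recurring transport channels
reappear snapshot after snapshot with small per-snapshot variation.
This module emulates that statistical shape with known ground truth so
every downstream stage can be validated: a fixed random "molecule" of
hard-sphere atoms, k channel templates (smooth waypoint paths with a
radius profile and a bottleneck), and per-snapshot cavity sequences
derived from a template with token-level dropout and swap noise.

There is no physical realism here — no force field, no solvent, no
attempt to mimic any particular protein's geometry.  What is preserved
is what the representation sees: recurring lining-atom contexts per
channel, plus controllable noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io as c2v_io
from .encoding import canonical_node_id, select_lining_atoms
from .errors import GenerationError
from .structures import AMINO_ACIDS, Atom, CavityNode, CavitySequence, vdw_radius_for

#: element frequencies roughly matching protein composition
_ELEMENTS = ("H", "C", "N", "O", "S")
_ELEMENT_WEIGHTS = (0.48, 0.32, 0.08, 0.10, 0.02)


@dataclass
class ChannelTemplate:
    """Ground-truth channel: waypoints with a per-waypoint radius.

    The label is the pattern index that every trajectory derived from
    this template carries; recovery experiments compare clusterings
    against it.
    """

    template_id: int
    waypoints: np.ndarray  # (m, 3) Å
    base_radius_profile: np.ndarray  # (m,) Å
    label: int
    base_nodes: list[CavityNode] = field(default_factory=list)

    def __post_init__(self):
        self.waypoints = np.asarray(self.waypoints, dtype=float).reshape(-1, 3)
        self.base_radius_profile = np.asarray(self.base_radius_profile, dtype=float)
        if len(self.waypoints) < 2:
            raise ValueError(f"template {self.template_id}: needs >= 2 waypoints")
        if len(self.base_radius_profile) != len(self.waypoints):
            raise ValueError(f"template {self.template_id}: radius/waypoint length mismatch")
        if np.any(self.base_radius_profile <= 0):
            raise ValueError(f"template {self.template_id}: radii must be > 0")
        steps = np.linalg.norm(np.diff(self.waypoints, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError(f"template {self.template_id}: waypoint spacing must be > 0")

    @property
    def n_waypoints(self) -> int:
        return len(self.waypoints)


@dataclass
class SyntheticDataset:
    """Atoms + templates + labelled noisy trajectories, fully seeded."""

    atoms: list[Atom]
    templates: list[ChannelTemplate]
    sequences: list[CavitySequence]
    labels: dict[str, int]
    seed: int

    def __post_init__(self):
        known = {t.template_id for t in self.templates}
        for cid, lab in self.labels.items():
            if lab not in known:
                raise ValueError(f"sequence '{cid}' labelled with unknown template {lab}")

    def corpus(self) -> list[tuple[str, list[str]]]:
        return [(s.cavity_id, s.tokens) for s in self.sequences]

    def write(self, out_dir) -> dict[str, Path]:
        """Write atoms.pdb, cavities.jsonl, corpus.txt, labels.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "atoms": out / "atoms.pdb",
            "cavities": out / "cavities.jsonl",
            "corpus": out / "corpus.txt",
            "labels": out / "labels.tsv",
        }
        c2v_io.write_pdb(self.atoms, paths["atoms"])
        c2v_io.write_cavity_records((s.to_record() for s in self.sequences),
                                    paths["cavities"])
        c2v_io.write_corpus(self.sequences, paths["corpus"])
        c2v_io.write_labels_tsv(self.labels, paths["labels"])
        return paths


def generate_molecule(
    n_atoms: int,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    seed: int = 0,
) -> list[Atom]:
    """A random hard-sphere molecule: atoms uniform in a box.

    Atoms get serials 1..n_atoms, elements drawn with protein-like
    frequencies, residue names from the 20 standard codes plus HID
    (about four atoms per residue), and Bondi vdW radii.
    """
    if n_atoms < 8:
        raise ValueError("n_atoms must be >= 8 (a node needs 4 atoms; fewer than "
                         "8 gives degenerate corpora)")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive extents")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, box, size=(n_atoms, 3))
    elements = rng.choice(_ELEMENTS, size=n_atoms, p=_ELEMENT_WEIGHTS)
    n_res = (n_atoms + 3) // 4
    res_names = rng.choice(AMINO_ACIDS, size=n_res)
    atoms = []
    within: dict[int, int] = {}
    for i in range(n_atoms):
        res_idx = i // 4
        within[res_idx] = within.get(res_idx, 0) + 1
        el = str(elements[i])
        atoms.append(Atom(
            serial=i + 1,
            name=f"{el}{within[res_idx]}",
            element=el,
            res_name=str(res_names[res_idx]),
            res_seq=res_idx + 1,
            chain="A",
            position=positions[i],
            vdw_radius=vdw_radius_for(el),
        ))
    return atoms


def _make_template_path(
    rng: np.random.Generator,
    box: np.ndarray,
    length_range: tuple[int, int],
    spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated random walk through the box with a smooth radius
    profile carrying one forced bottleneck dip."""
    m = int(rng.integers(length_range[0], length_range[1] + 1))
    margin = 3.0
    start = rng.uniform(0.3 * box, 0.7 * box)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    points = [start]
    for _ in range(m - 1):
        direction = direction + 0.35 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nxt = points[-1] + spacing * direction
        # reflect off the walls to stay inside the box
        for ax in range(3):
            if nxt[ax] < margin:
                nxt[ax] = 2 * margin - nxt[ax]
                direction[ax] = -direction[ax]
            elif nxt[ax] > box[ax] - margin:
                nxt[ax] = 2 * (box[ax] - margin) - nxt[ax]
                direction[ax] = -direction[ax]
        points.append(nxt)
    waypoints = np.array(points)
    # smooth radius walk in [0.8, 3.0] Å with a bottleneck dip
    radii = np.empty(m)
    radii[0] = rng.uniform(1.5, 2.5)
    for i in range(1, m):
        radii[i] = np.clip(radii[i - 1] + rng.normal(0.0, 0.2), 0.8, 3.0)
    if m >= 3:
        dip = int(rng.integers(1, m - 1))
        radii[dip] = max(0.6, radii[dip] * 0.45)
    return waypoints, radii


def generate_template(
    template_id: int,
    atoms: Sequence[Atom],
    seed: int = 0,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    length_range: tuple[int, int] = (10, 40),
    spacing: float = 1.5,
    search_radius: float = 10.0,
    mode: str = "center",
) -> ChannelTemplate:
    """One channel template with its base (noise-free) node sequence."""
    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    waypoints, radii = _make_template_path(rng, box, length_range, spacing)
    positions = np.array([a.position for a in atoms])
    base_nodes: list[CavityNode] = []
    for center, radius in zip(waypoints, radii):
        near = np.linalg.norm(positions - center, axis=1) <= search_radius
        nearby = [a for a, m in zip(atoms, near) if m]
        if len(nearby) < 4:
            raise GenerationError(
                f"template {template_id}: fewer than 4 atoms within "
                f"{search_radius} Å of waypoint {center.round(2).tolist()}"
            )
        serials = select_lining_atoms(center, nearby, mode=mode)
        base_nodes.append(CavityNode(
            node_id=canonical_node_id(serials),
            center=center,
            radius=float(radius),
            lining_atom_serials=tuple(serials),
        ))
    return ChannelTemplate(
        template_id=template_id,
        waypoints=waypoints,
        base_radius_profile=radii,
        label=template_id,
        base_nodes=base_nodes,
    )


def generate_trajectories(
    k_templates: int = 3,
    n_per_template: int = 50,
    node_dropout_prob: float = 0.0,
    node_swap_prob: float = 0.0,
    seed: int = 0,
    n_atoms: int = 400,
    box: Sequence[float] = (40.0, 40.0, 40.0),
    length_range: tuple[int, int] = (10, 40),
    spacing: float = 1.5,
    search_radius: float = 10.0,
    mode: str = "center",
) -> SyntheticDataset:
    """k channel templates, n noisy trajectories each, with labels.

    Each trajectory copies its template's base node walk, then applies
    independent per-node noise: dropout removes the node, swap replaces
    its four lining atoms with four distinct random atoms (geometry
    kept).  If dropout removes every node, the first node is retained so
    the sequence stays valid.  Bit-for-bit reproducible for a given
    seed.
    """
    if k_templates < 1:
        raise ValueError("k_templates must be >= 1")
    if n_per_template < 1:
        raise ValueError("n_per_template must be >= 1")
    for name, p in (("node_dropout_prob", node_dropout_prob),
                    ("node_swap_prob", node_swap_prob)):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"{name} must be in [0, 1), got {p}")

    ss = np.random.SeedSequence(seed)
    mol_seed, tmpl_seed, noise_seed = (int(s % 2**31) for s in ss.generate_state(3))
    atoms = generate_molecule(n_atoms, box=box, seed=mol_seed)
    tmpl_rng = np.random.default_rng(tmpl_seed)
    templates = [
        generate_template(
            t, atoms,
            seed=int(tmpl_rng.integers(0, 2**31)),
            box=box, length_range=length_range, spacing=spacing,
            search_radius=search_radius, mode=mode,
        )
        for t in range(k_templates)
    ]

    rng = np.random.default_rng(noise_seed)
    n_total_atoms = len(atoms)
    sequences: list[CavitySequence] = []
    labels: dict[str, int] = {}
    for tmpl in templates:
        for rep in range(n_per_template):
            nodes = list(tmpl.base_nodes)
            if node_dropout_prob > 0:
                keep = rng.random(len(nodes)) >= node_dropout_prob
                if not keep.any():
                    keep[0] = True
                nodes = [n for n, k in zip(nodes, keep) if k]
            if node_swap_prob > 0:
                swapped = []
                for node in nodes:
                    if rng.random() < node_swap_prob:
                        serials = tuple(
                            int(s) + 1 for s in
                            rng.choice(n_total_atoms, size=4, replace=False)
                        )
                        node = replace(node,
                                       node_id=canonical_node_id(serials),
                                       lining_atom_serials=serials)
                    swapped.append(node)
                nodes = swapped
            cid = f"t{tmpl.template_id}s{rep}"
            sequences.append(CavitySequence(cavity_id=cid, snapshot=rep, nodes=nodes))
            labels[cid] = tmpl.template_id
    return SyntheticDataset(atoms=atoms, templates=templates,
                            sequences=sequences, labels=labels, seed=seed)
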