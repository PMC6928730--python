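"""Pattern analysis of cavity vectors.

Clustering groups the trajectories of a cavity across snapshots into
recurring change patterns; hierarchical clustering (average link on
1 - cosine) serves when the number of patterns is unknown, K-means when
a 2-D t-SNE view has suggested it.  Length-width profiles expose the
bottleneck structure of each pathway, and amino-acid profiles tally the
residues lining each cavity so that patterns can be attributed to
specific residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .structures import Atom, CavitySequence

__all__ = [
    "ClusterAssignment",
    "LengthWidthProfile",
    "AminoAcidProfile",
    "hierarchical_cluster",
    "kmeans_cluster",
    "project_2d",
    "length_width_profile",
    "amino_acid_profile",
    "plot_length_width",
]


@dataclass
class ClusterAssignment:
    """cavity_id -> dense cluster index, plus how it was produced."""

    assignments: dict[str, int]
    method: Literal["hierarchical", "kmeans"]
    parameters: dict
    n_clusters: int
    linkage_matrix: np.ndarray | None = None  # scipy dendrogram encoding
    inertia: float | None = None

    def __post_init__(self):
        labels = set(self.assignments.values())
        if labels != set(range(self.n_clusters)):
            raise ValueError("cluster indices must be dense 0..n_clusters-1")

    def labels_for(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignments[i] for i in ids])


def _ids_and_matrix(vectors) -> tuple[list[str], np.ndarray]:
    if isinstance(vectors, Mapping):
        ids = list(vectors)
        X = np.array([np.asarray(vectors[i], dtype=float) for i in ids])
    else:
        ids = [cv.cavity_id for cv in vectors]
        X = np.array([cv.vector for cv in vectors])
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate cavity_id among input vectors")
    return ids, X


def _dense_labels(raw: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel clusters to 0..k-1 in order of first appearance."""
    remap: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out, len(remap)


def hierarchical_cluster(
    vectors,
    n_clusters: int | None = None,
    distance_threshold: float | None = None,
    linkage_method: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering on cosine distance (1 - cosine).

    Exactly one cut criterion must be given: a target number of clusters
    or a cophenetic distance threshold (a threshold yielding a single
    cluster is legitimate).  The scipy linkage matrix is kept on the
    result so the dendrogram can be drawn or re-cut.
    """
    if (n_clusters is None) == (distance_threshold is None):
        raise ValueError("give exactly one of n_clusters / distance_threshold")
    if linkage_method not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage '{linkage_method}'")
    ids, X = _ids_and_matrix(vectors)
    if len(ids) < 2:
        raise ValueError("need at least 2 vectors to cluster")
    D = pdist(X, metric="cosine")
    Z = linkage(D, method=linkage_method)
    if n_clusters is not None:
        raw = fcluster(Z, t=n_clusters, criterion="maxclust")
        params = {"linkage": linkage_method, "n_clusters": n_clusters}
    else:
        raw = fcluster(Z, t=distance_threshold, criterion="distance")
        params = {"linkage": linkage_method, "distance_threshold": distance_threshold}
    labels, k = _dense_labels(raw)
    return ClusterAssignment(
        assignments=dict(zip(ids, (int(x) for x in labels))),
        method="hierarchical", parameters=params, n_clusters=k, linkage_matrix=Z,
    )


def kmeans_cluster(
    vectors,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterAssignment:
    """Lloyd's K-means on L2-normalized vectors (best of n_init restarts).

    Normalizing each vector to unit length makes squared Euclidean
    distance a monotone function of cosine distance, so the partition
    respects the same similarity notion as the hierarchical route.
    """
    ids, X = _ids_and_matrix(vectors)
    n = len(ids)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm vector cannot be normalized for clustering")
    Xn = X / norms
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    raw = km.fit_predict(Xn)
    labels, k_eff = _dense_labels(raw)
    return ClusterAssignment(
        assignments=dict(zip(ids, (int(x) for x in labels))),
        method="kmeans",
        parameters={"k": k, "seed": seed, "n_init": n_init},
        n_clusters=k_eff,
        inertia=float(km.inertia_),
    )


def project_2d(
    vectors,
    perplexity: float = 30.0,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """t-SNE projection to 2-D for visual inspection of cluster counts.

    The projection is for choosing the number of patterns by eye; it is
    never used as clustering input.  Requires n > 3 * perplexity.
    """
    ids, X = _ids_and_matrix(vectors)
    n = len(ids)
    if n <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} cavities (need n > 3*perplexity)"
        )
    ts = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    Y = ts.fit_transform(X)
    if not np.isfinite(Y).all():
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return {cid: (float(x), float(y)) for cid, (x, y) in zip(ids, Y)}


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class LengthWidthProfile:
    """Arc length along the pathway (X) against sphere radius (Y).

    The bottleneck — the narrowest sphere — limits which ligands can
    traverse the cavity; its index and radius are reported directly.
    """

    cavity_id: str
    arc_lengths: np.ndarray  # (n,), non-decreasing, starts at 0
    radii: np.ndarray  # (n,)
    bottleneck_index: int
    bottleneck_radius: float

    @property
    def samples(self) -> list[tuple[float, float]]:
        return [(float(a), float(r)) for a, r in zip(self.arc_lengths, self.radii)]

    @property
    def length(self) -> float:
        return float(self.arc_lengths[-1])


def length_width_profile(sequence: CavitySequence) -> LengthWidthProfile:
    """Cumulative center-to-center arc length and radius per node.

    arc_length(0) = 0; the bottleneck is the first radius minimum.
    """
    centers = np.array([n.center for n in sequence.nodes])
    radii = np.array([n.radius for n in sequence.nodes])
    steps = np.linalg.norm(np.diff(centers, axis=0), axis=1) if len(centers) > 1 else []
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    b = int(np.argmin(radii))
    return LengthWidthProfile(
        cavity_id=sequence.cavity_id,
        arc_lengths=arc,
        radii=radii,
        bottleneck_index=b,
        bottleneck_radius=float(radii[b]),
    )


@dataclass
class AminoAcidProfile:
    """Residue composition of one cavity, or the mean over a cluster."""

    unit: str  # cavity_id or "cluster:<k>"
    counts: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.counts.values()))


def _cavity_residue_counts(
    sequence: CavitySequence, atom_by_serial: Mapping[int, Atom],
    count_atoms: bool = False,
) -> dict[str, float]:
    if count_atoms:
        counts: dict[str, float] = {}
        for node in sequence.nodes:
            for serial in node.lining_atom_serials:
                if serial not in atom_by_serial:
                    raise KeyError(
                        f"cavity {sequence.cavity_id}: lining atom serial {serial} "
                        "absent from the atom table"
                    )
                res = atom_by_serial[serial].res_name
                counts[res] = counts.get(res, 0.0) + 1.0
        return counts
    residues: dict[tuple[str, int], str] = {}
    for node in sequence.nodes:
        for serial in node.lining_atom_serials:
            if serial not in atom_by_serial:
                raise KeyError(
                    f"cavity {sequence.cavity_id}: lining atom serial {serial} "
                    "absent from the atom table"
                )
            atom = atom_by_serial[serial]
            residues[atom.residue_key] = atom.res_name
    counts = {}
    for res_name in residues.values():
        counts[res_name] = counts.get(res_name, 0.0) + 1.0
    return counts


def amino_acid_profile(
    sequences: Sequence[CavitySequence],
    atoms: Sequence[Atom],
    assignment: ClusterAssignment | None = None,
    count_atoms: bool = False,
) -> list[AminoAcidProfile]:
    """Residue composition per cavity, or averaged per cluster.

    By default each distinct residue (chain + res_seq) with at least one
    lining atom counts once, tallied by 3-letter code — HID stays
    distinct from HIS.  ``count_atoms`` switches to counting lining
    atoms per residue type instead.  With a cluster assignment, each
    cluster's profile is the arithmetic mean of its members' counts.
    """
    atom_by_serial = {a.serial: a for a in atoms}
    per_cavity = {
        seq.cavity_id: _cavity_residue_counts(seq, atom_by_serial, count_atoms)
        for seq in sequences
    }
    if assignment is None:
        return [AminoAcidProfile(unit=cid, counts=c) for cid, c in per_cavity.items()]
    members: dict[int, list[str]] = {}
    for cid in per_cavity:
        members.setdefault(assignment.assignments[cid], []).append(cid)
    profiles = []
    for k in sorted(members):
        codes: set[str] = set()
        for cid in members[k]:
            codes.update(per_cavity[cid])
        mean = {
            code: sum(per_cavity[cid].get(code, 0.0) for cid in members[k]) / len(members[k])
            for code in sorted(codes)
        }
        profiles.append(AminoAcidProfile(unit=f"cluster:{k}", counts=mean))
    return profiles


def plot_length_width(profiles: Sequence[LengthWidthProfile], path,
                      highlight: str | None = None) -> None:
    """Static length-width view: one line per cavity, bottleneck visible
    as the curve's minimum.  ``highlight`` draws one cavity in red."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for prof in profiles:
        if highlight is not None and prof.cavity_id == highlight:
            continue
        ax.plot(prof.arc_lengths, prof.radii, color="0.2", lw=0.8, alpha=0.6)
    if highlight is not None:
        for prof in profiles:
            if prof.cavity_id == highlight:
                ax.plot(prof.arc_lengths, prof.radii, color="red", lw=1.8)
    ax.set_xlabel("length from active site (Å)")
    ax.set_ylabel("cavity radius (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
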