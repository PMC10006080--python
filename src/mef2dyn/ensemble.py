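"""Conformational-ensemble analysis of disordered peptide trajectories.

Disordered ~37-residue peptides do not fold to a single structure, so their
MD ensembles are summarised by intra-molecular residue-residue contacts.
Each saved snapshot yields a contact set; two snapshots are compared with
the similarity statistic

    f_S = |C_i ∩ C_j| / |(C_i ∪ C_j) − (C_i ∩ C_j)|

i.e. the number of shared contacts divided by the number of non-shared ones
(related to the Jaccard index J by f_S = J / (1 − J)).  Snapshots with
f_S above a threshold (default 0.5, equivalent to J > 1/3) are linked, the
connected components of that graph form initial clusters, and clusters are
then joined when their high-frequency contact motifs are themselves similar.
Per-cluster contact-frequency maps and the fraction of contacts involving a
chosen domain (e.g. the beta-domain) summarise the result.

Equilibrated-window selection, radius of gyration, RMSD to the mean
structure and a compactness classification round out the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .profiles import DomainWindow

__all__ = [
    "Trajectory",
    "ContactTrajectory",
    "ContactCriteria",
    "ClusterInfo",
    "ClusterResult",
    "EnsembleMetrics",
    "load_trajectory",
    "select_equilibrated_window",
    "pool_equilibrated_windows",
    "radius_of_gyration",
    "rg_series",
    "rmsd_to_mean",
    "extract_contacts",
    "contact_trajectory",
    "contact_similarity",
    "similarity_matrix",
    "cluster_snapshots",
    "cluster_contact_map",
    "domain_contact_fraction",
    "classify_compactness",
    "read_contact_table",
    "write_contact_table",
]

Pair = tuple[int, int]
ContactSet = frozenset


@dataclass
class Trajectory:
    """Coordinate snapshots of one MD replica.

    Coordinates are in nm.  ``residue_index`` maps each atom to a 1-based
    peptide-local residue number; ``elements`` are element symbols used to
    distinguish heavy atoms from hydrogens.  Frame times default to the
    save-interval grid ``timestep_ps, 2*timestep_ps, ...``.
    """

    xyz: np.ndarray                      # (n_frames, n_atoms, 3), nm
    masses: np.ndarray                   # (n_atoms,), amu
    residue_index: np.ndarray            # (n_atoms,), 1-based
    elements: np.ndarray | None = None   # (n_atoms,), e.g. "C", "H"
    timestep_ps: float = 10.0
    replica: str = "rep1"
    time_ps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        n_atoms = self.xyz.shape[1]
        if self.masses.size != n_atoms or self.residue_index.size != n_atoms:
            raise ValueError("atom metadata length must match atom count")
        if self.timestep_ps <= 0:
            raise ValueError("timestep must be positive")
        if self.elements is None:
            self.elements = np.array(["C"] * n_atoms)
        else:
            self.elements = np.asarray(self.elements, dtype=str)
        if self.time_ps is None:
            self.time_ps = self.timestep_ps * np.arange(1, self.n_frames + 1)
        else:
            self.time_ps = np.asarray(self.time_ps, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) if self.residue_index.size else 0

    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])


def load_trajectory(topology, *trajectory_files, replica: str = "rep1"
                    ) -> Trajectory:
    """Load a Trajectory from standard MD files via mdtraj.

    ``topology`` is a PDB (or any mdtraj-readable topology); trajectory
    files may be DCD/XTC/etc.  With no trajectory files the topology's own
    coordinates are used.
    """
    import mdtraj as md

    if trajectory_files:
        traj = md.load(list(map(str, trajectory_files)), top=str(topology))
    else:
        traj = md.load(str(topology))
    top = traj.topology
    masses = np.array([a.element.mass for a in top.atoms])
    resid = np.array([a.residue.index + 1 for a in top.atoms])
    elements = np.array([a.element.symbol for a in top.atoms])
    dt = float(traj.timestep) if traj.n_frames > 1 else 10.0
    time_ps = np.asarray(traj.time, dtype=float)
    if np.all(time_ps == 0):
        time_ps = None
    return Trajectory(xyz=traj.xyz.astype(float), masses=masses,
                      residue_index=resid, elements=elements,
                      timestep_ps=dt, replica=replica, time_ps=time_ps)


# ---------------------------------------------------------------------------
# Window selection & geometry


def select_equilibrated_window(traj: Trajectory,
                               window_ns: tuple[float, float] = (70.0, 100.0)
                               ) -> np.ndarray:
    """Frame indices whose times fall in the half-open window [start, end) ns.

    The half-open convention makes a 30 ns window at a 10 ps save interval
    contain exactly 3000 frames.
    """
    start_ps, end_ps = (1000.0 * w for w in window_ns)
    if start_ps > end_ps:
        raise IndexError("window start exceeds window end")
    t = traj.time_ps
    if end_ps > t[-1] + 0.5 * traj.timestep_ps and end_ps > start_ps:
        raise IndexError(
            f"window end {window_ns[1]} ns beyond trajectory end "
            f"{t[-1] / 1000.0} ns")
    return np.nonzero((t >= start_ps) & (t < end_ps))[0]


def pool_equilibrated_windows(trajectories: Sequence[Trajectory],
                              window_ns: tuple[float, float] = (70.0, 100.0)
                              ) -> list[tuple[Trajectory, np.ndarray]]:
    """Per-replica equilibrated frame indices, in input (replica) order."""
    return [(t, select_equilibrated_window(t, window_ns))
            for t in trajectories]


def radius_of_gyration(xyz: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance of atoms from the centre of mass (nm)."""
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * xyz).sum(axis=0) / total
    sq = ((xyz - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / total))


def rg_series(traj: Trajectory,
              frames: np.ndarray | None = None) -> np.ndarray:
    """Radius of gyration for each (selected) frame."""
    idx = np.arange(traj.n_frames) if frames is None else frames
    return np.array([radius_of_gyration(traj.xyz[i], traj.masses)
                     for i in idx])


def _kabsch_rmsd(coords: np.ndarray, reference: np.ndarray) -> float:
    """RMSD after optimal (Kabsch) superposition, unweighted."""
    x = coords - coords.mean(axis=0)
    y = reference - reference.mean(axis=0)
    cov = x.T @ y
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    diff = x @ rot - y
    return float(np.sqrt((diff ** 2).sum() / len(x)))


def rmsd_to_mean(traj: Trajectory,
                 frames: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD to the ensemble-average structure (nm).

    The average structure of a disordered ensemble is not a physical
    conformation; the series is used only to judge equilibration plateaus.
    """
    idx = np.arange(traj.n_frames) if frames is None else frames
    mean_structure = traj.xyz[idx].mean(axis=0)
    return np.array([_kabsch_rmsd(traj.xyz[i], mean_structure) for i in idx])


# ---------------------------------------------------------------------------
# Contacts


@dataclass(frozen=True)
class ContactCriteria:
    """Distance-based contact definition (pluggable).

    A residue pair (i, j) with |i − j| >= ``min_separation`` is in contact
    when any inter-residue heavy-atom distance is <= ``cutoff_nm``.
    Alternative multi-criterion engines (hydrogen bonds, salt bridges, ...)
    can be substituted by any object with the same ``pairs`` signature.
    """

    cutoff_nm: float = 0.45
    min_separation: int = 3

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("contact cutoff must be positive")

    def pairs(self, xyz: np.ndarray, residue_index: np.ndarray,
              heavy: np.ndarray) -> ContactSet:
        xyz = xyz[heavy]
        resid = residue_index[heavy]
        dist = cdist(xyz, xyz)
        close = dist <= self.cutoff_nm
        ii, jj = np.nonzero(close)
        ri, rj = resid[ii], resid[jj]
        keep = rj - ri >= self.min_separation
        return frozenset(zip(ri[keep].tolist(), rj[keep].tolist()))


def extract_contacts(traj: Trajectory, frame: int,
                     criteria: ContactCriteria | None = None) -> ContactSet:
    """Contact set of one frame under the given criteria."""
    criteria = criteria or ContactCriteria()
    return criteria.pairs(traj.xyz[frame], traj.residue_index,
                          traj.heavy_mask())


@dataclass
class ContactTrajectory:
    """Ordered per-snapshot contact sets (pooled across replicas)."""

    snapshots: list
    times_ps: np.ndarray | None = None
    n_residues: int = 0
    true_labels: np.ndarray | None = None   # planted ground truth, if any

    def __post_init__(self) -> None:
        self.snapshots = [frozenset((min(i, j), max(i, j)) for i, j in s
                                    if i != j)
                          for s in self.snapshots]
        if self.times_ps is not None:
            self.times_ps = np.asarray(self.times_ps, dtype=float)
            if np.any(np.diff(self.times_ps) <= 0):
                raise ValueError("frame times must be strictly increasing")
        if not self.n_residues:
            top = [max(max(p) for p in s) for s in self.snapshots if s]
            self.n_residues = max(top) if top else 0

    def __len__(self) -> int:
        return len(self.snapshots)


def contact_trajectory(trajectories: Sequence[Trajectory],
                       window_ns: tuple[float, float] = (70.0, 100.0),
                       criteria: ContactCriteria | None = None
                       ) -> ContactTrajectory:
    """Pool equilibrated windows of all replicas into one contact trajectory."""
    criteria = criteria or ContactCriteria()
    snapshots = []
    n_res = 0
    for traj, idx in pool_equilibrated_windows(trajectories, window_ns):
        heavy = traj.heavy_mask()
        n_res = max(n_res, traj.n_residues)
        for i in idx:
            snapshots.append(criteria.pairs(traj.xyz[i], traj.residue_index,
                                            heavy))
    return ContactTrajectory(snapshots=snapshots, n_residues=n_res)


# ---------------------------------------------------------------------------
# Similarity and clustering


def contact_similarity(ci: Iterable, cj: Iterable) -> float:
    """f_S = shared contacts / non-shared contacts.

    Conventions for the degenerate cases where the printed formula divides
    by zero: identical sets (including empty vs empty) return +inf — they
    co-cluster at any threshold; an empty set against a non-empty one
    shares nothing and returns 0.
    """
    a, b = frozenset(ci), frozenset(cj)
    inter = len(a & b)
    sym = len(a) + len(b) - 2 * inter
    if sym == 0:
        return float("inf")
    return inter / sym


def _snapshot_matrix(ct: ContactTrajectory) -> tuple[np.ndarray, list]:
    """Boolean snapshot-by-pair incidence matrix over the observed pair union."""
    universe = sorted(set().union(*ct.snapshots)) if ct.snapshots else []
    index = {p: k for k, p in enumerate(universe)}
    mat = np.zeros((len(ct), len(universe)), dtype=np.int32)
    for i, s in enumerate(ct.snapshots):
        for p in s:
            mat[i, index[p]] = 1
    return mat, universe


def similarity_matrix(ct: ContactTrajectory) -> np.ndarray:
    """Dense pairwise f_S matrix (inf on identical pairs of sets)."""
    mat, _ = _snapshot_matrix(ct)
    inter = mat @ mat.T
    sizes = mat.sum(axis=1)
    sym = sizes[:, None] + sizes[None, :] - 2 * inter
    with np.errstate(divide="ignore", invalid="ignore"):
        fs = np.where(sym > 0, inter / np.maximum(sym, 1), np.inf)
    return fs


@dataclass
class ClusterInfo:
    """One cluster: member snapshot indices and its contact-frequency map."""

    members: np.ndarray
    frequencies: dict

    @property
    def population(self) -> int:
        return len(self.members)

    def high_frequency_set(self, merge_fraction: float = 0.5) -> ContactSet:
        """Contacts present in at least ``merge_fraction`` of members."""
        cut = merge_fraction * self.population
        return frozenset(p for p, c in self.frequencies.items() if c >= cut)


@dataclass
class ClusterResult:
    """Snapshot clustering: assignment plus population-ranked clusters.

    ``labels[i]`` is the cluster of snapshot ``i``; label 0 is the most
    populated cluster (ties broken by smallest member index).
    """

    labels: np.ndarray
    clusters: list
    n_residues: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.clusters])


def _tally(ct: ContactTrajectory, members: np.ndarray) -> dict:
    freq: dict = {}
    for i in members:
        for p in ct.snapshots[i]:
            freq[p] = freq.get(p, 0) + 1
    return freq


def cluster_snapshots(ct: ContactTrajectory, threshold: float = 0.5,
                      merge_fraction: float = 0.5,
                      join_clusters: bool = True) -> ClusterResult:
    """Two-stage contact-map clustering of an ensemble.

    Stage 1 links snapshots i, j whenever f_S(C_i, C_j) > ``threshold``
    (strict) and takes connected components of the resulting graph.
    Stage 2 joins components based on the frequencies of their common
    contacts: each component is summarised by the set of contacts present
    in at least ``merge_fraction`` of its members, and the component pair
    whose summary sets have the highest f_S above the threshold is merged,
    iterating to a fixed point (deterministic: ties go to the lowest
    component indices).  Clusters are ranked by population.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = len(ct)
    if n == 0:
        return ClusterResult(labels=np.array([], dtype=int), clusters=[],
                             n_residues=ct.n_residues)
    fs = similarity_matrix(ct)
    adj = fs > threshold
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    groups = [np.nonzero(comp == k)[0] for k in range(n_comp)]

    if join_clusters and len(groups) > 1:
        while True:
            summaries = []
            for g in groups:
                freq = _tally(ct, g)
                cut = merge_fraction * len(g)
                summaries.append(frozenset(p for p, c in freq.items()
                                           if c >= cut))
            best: tuple | None = None
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    s = contact_similarity(summaries[a], summaries[b])
                    if s > threshold and (best is None or s > best[0]):
                        best = (s, a, b)
            if best is None:
                break
            _, a, b = best
            merged = np.sort(np.concatenate([groups[a], groups[b]]))
            groups = [g for k, g in enumerate(groups) if k not in (a, b)]
            groups.append(merged)

    # rank by population, ties by smallest member index
    order = sorted(range(len(groups)),
                   key=lambda k: (-len(groups[k]), int(groups[k].min())))
    labels = np.empty(n, dtype=int)
    clusters = []
    for rank, k in enumerate(order):
        members = np.sort(groups[k])
        labels[members] = rank
        clusters.append(ClusterInfo(members=members,
                                    frequencies=_tally(ct, members)))
    return ClusterResult(labels=labels, clusters=clusters,
                         n_residues=ct.n_residues)


def cluster_contact_map(result: ClusterResult, cluster: int,
                        n_residues: int | None = None) -> np.ndarray:
    """Symmetric residue-by-residue matrix of member-snapshot counts.

    Entry (i−1, j−1) is the number of member snapshots of the cluster in
    which residues i and j are in contact.  Typically only the few most
    populated clusters (four by convention here) are rendered.
    """
    info = result.clusters[cluster]
    if info.population == 0:
        raise ValueError("cluster is empty")
    n = n_residues or result.n_residues
    mat = np.zeros((n, n), dtype=int)
    for (i, j), c in info.frequencies.items():
        mat[i - 1, j - 1] = c
        mat[j - 1, i - 1] = c
    return mat


def domain_contact_fraction(result: ClusterResult, window: DomainWindow,
                            mode: Literal["both_in", "any_in"] = "both_in"
                            ) -> float:
    """Fraction of contact occurrences involving the domain window.

    Occurrences are weighted by snapshot counts (a contact sampled in m
    member snapshots counts m times).  ``both_in`` requires both residues
    of the pair inside the window, ``any_in`` at least one; both modes are
    exposed because "contacts within a domain" is ambiguous.
    """
    total = 0
    hit = 0
    for info in result.clusters:
        for (i, j), c in info.frequencies.items():
            total += c
            a, b = window.contains(i), window.contains(j)
            if (a and b) if mode == "both_in" else (a or b):
                hit += c
    return hit / total if total else 0.0


# ---------------------------------------------------------------------------
# Compactness


@dataclass
class EnsembleMetrics:
    rg_series: np.ndarray
    rmsd_series: np.ndarray | None = None
    equilibration: tuple[int, int] | None = None
    compactness: str = ""


def classify_compactness(rg: np.ndarray, reference_rg: float,
                         tolerance: float = 0.05) -> str:
    """'compact' / 'extended' / 'mixed' by median Rg against a reference.

    ``tolerance`` is an absolute Rg margin in nm (default 0.05 nm) around
    the reference within which the ensemble is called mixed.
    """
    rg = np.asarray(rg, dtype=float)
    if rg.size == 0:
        raise ValueError("rg series is empty")
    med = float(np.median(rg))
    if med < reference_rg - tolerance:
        return "compact"
    if med > reference_rg + tolerance:
        return "extended"
    return "mixed"


# ---------------------------------------------------------------------------
# Contact-set I/O


def write_contact_table(ct: ContactTrajectory, path) -> None:
    """Tab-separated (frame, res_i, res_j) records, one row per contact."""
    import pandas as pd

    rows = [(f, i, j) for f, s in enumerate(ct.snapshots)
            for i, j in sorted(s)]
    pd.DataFrame(rows, columns=["frame", "res_i", "res_j"]).to_csv(
        path, sep="\t", index=False)


def read_contact_table(path, n_frames: int | None = None
                       ) -> ContactTrajectory:
    """Inverse of :func:`write_contact_table`; empty frames are preserved
    when ``n_frames`` is given."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    top = int(df["frame"].max()) + 1 if len(df) else 0
    n = n_frames if n_frames is not None else top
    snaps: list[set] = [set() for _ in range(n)]
    for f, i, j in df.itertuples(index=False):
        snaps[int(f)].add((int(i), int(j)))
    return ContactTrajectory(snapshots=snaps)
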