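"""Variant design from per-residue dynamics descriptors.

The MEF2D transactivation domain carries a seven-residue, alternatively
spliced acidic segment (the beta-domain, residues 286-292 in full-protein
UniProt Q14814 numbering).  Upstream sequence predictors assign each residue
three probabilities:

``p_D``
    probability of structural disorder in the free (unbound) state,
``p_DD``
    probability of forming disordered ("fuzzy") interactions with partners,
``p_DP``
    droplet-promoting probability — the propensity to drive liquid-liquid
    phase separation,

optionally together with multiplicity-of-binding-modes (MBM) region
annotations and a whole-protein droplet probability ``p_LLPS``.  This module
consumes such profiles (it never re-implements the predictors), averages the
descriptors over a residue window, scores candidate mutations by the window
deltas relative to the wild type, classifies beta-domain dynamics
(similar / mobile / rigid), and places variants on the droplet landscape
(p_DP versus an MBM coordinate; points above the diagonal favour liquid-like
assemblies, points below favour solid-like ones).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResidueProfile",
    "DomainWindow",
    "VariantSpec",
    "DynamicsSummary",
    "BETA_DOMAIN",
    "DISORDER_THRESHOLD",
    "average_window",
    "classify_disorder",
    "delta_dynamics",
    "classify_variant",
    "droplet_landscape",
    "rank_candidates",
    "summarize_variant",
    "full_to_peptide",
    "peptide_to_full",
    "read_profile_table",
    "write_summary_table",
    "read_fasta_sequence",
    "toy_profile",
]

#: Disorder/order boundary on the window-mean p_D (inclusive: >= is disordered).
DISORDER_THRESHOLD = 0.3085

#: First residue of the 37-residue peptide model in full-protein numbering.
PEPTIDE_OFFSET = 265


@dataclass(frozen=True)
class DomainWindow:
    """Inclusive 1-based residue window ``[start, end]``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


#: The beta-domain window in full-protein (Q14814) numbering.
BETA_DOMAIN = DomainWindow(286, 292)


@dataclass
class ResidueProfile:
    """Per-residue dynamics descriptors for a protein sequence.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence.
    positions : sequence of int
        1-based residue numbers (full-protein numbering), strictly increasing.
    p_D, p_DD, p_DP : array-like of float
        Per-residue probabilities in [0, 1] (see module docstring).
    mbm_regions : iterable of (start, end), optional
        Residue ranges flagged as multiplicity-of-binding-modes regions.
    p_llps : float, optional
        Whole-protein droplet probability.
    name : str
        Label used in reports.
    """

    sequence: str
    positions: np.ndarray
    p_D: np.ndarray
    p_DD: np.ndarray
    p_DP: np.ndarray
    mbm_regions: tuple[tuple[int, int], ...] = ()
    p_llps: float | None = None
    name: str = "profile"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        for attr in ("p_D", "p_DD", "p_DP"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.shape != self.positions.shape:
                raise ValueError(f"{attr} length {arr.size} != positions length "
                                 f"{self.positions.size}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"{attr} values must lie in [0, 1]")
            setattr(self, attr, arr)
        if len(self.sequence) != self.positions.size:
            raise ValueError("sequence length does not match profile length")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.mbm_regions = tuple((int(a), int(b)) for a, b in self.mbm_regions)
        if self.p_llps is not None and not 0 <= self.p_llps <= 1:
            raise ValueError("p_llps must lie in [0, 1]")

    def __len__(self) -> int:
        return self.positions.size

    def window_mask(self, window: DomainWindow) -> np.ndarray:
        mask = (self.positions >= window.start) & (self.positions <= window.end)
        covered = self.positions[mask]
        if covered.size != len(window):
            raise IndexError(
                f"window {window.start}-{window.end} not fully covered by "
                f"profile positions {self.positions[0]}-{self.positions[-1]}")
        return mask

    def mbm_fraction(self, window: DomainWindow) -> float:
        """Fraction of window residues inside a flagged MBM region."""
        inside = 0
        for pos in range(window.start, window.end + 1):
            if any(a <= pos <= b for a, b in self.mbm_regions):
                inside += 1
        return inside / len(window)

    def apply_mutations(self, spec: "VariantSpec",
                        p_D: np.ndarray | None = None,
                        p_DD: np.ndarray | None = None,
                        p_DP: np.ndarray | None = None) -> "ResidueProfile":
        """Return a mutant profile with the given sequence edits.

        The descriptor arrays of the mutant must come from re-running the
        upstream predictors on the mutated sequence; when omitted they
        default to the parent's values (useful only for bookkeeping tests).
        """
        seq = list(self.sequence)
        index = {p: i for i, p in enumerate(self.positions)}
        for pos, wt, mut in spec.mutations:
            i = index[pos]
            if seq[i] != wt:
                raise ValueError(
                    f"wild-type residue mismatch at {pos}: profile has "
                    f"{seq[i]}, mutation says {wt}")
            seq[i] = mut
        return ResidueProfile(
            sequence="".join(seq), positions=self.positions.copy(),
            p_D=self.p_D if p_D is None else p_D,
            p_DD=self.p_DD if p_DD is None else p_DD,
            p_DP=self.p_DP if p_DP is None else p_DP,
            mbm_regions=self.mbm_regions, p_llps=self.p_llps, name=spec.name)


@dataclass(frozen=True)
class VariantSpec:
    """A named set of point mutations ``(position, wt_residue, mut_residue)``."""

    name: str
    mutations: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations",
                           tuple((int(p), w, m) for p, w, m in self.mutations))

    @property
    def first_position(self) -> int:
        return min(p for p, _, _ in self.mutations) if self.mutations else 0


@dataclass
class DynamicsSummary:
    """Window-averaged descriptors of a variant and its deltas vs reference."""

    name: str
    mean_p_D: float
    mean_p_DD: float
    mean_p_DP: float
    delta_p_D: float = 0.0
    delta_p_DD: float = 0.0
    delta_p_DP: float = 0.0
    disorder_class: str = ""
    dynamics_class: str = ""
    landscape: str = ""
    landscape_distance: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# Operations


def average_window(profile: ResidueProfile,
                   window: DomainWindow = BETA_DOMAIN
                   ) -> tuple[float, float, float]:
    """Arithmetic means of (p_D, p_DD, p_DP) over the window residues."""
    mask = profile.window_mask(window)
    return (float(profile.p_D[mask].mean()),
            float(profile.p_DD[mask].mean()),
            float(profile.p_DP[mask].mean()))


def classify_disorder(mean_p_D: float,
                      threshold: float = DISORDER_THRESHOLD) -> str:
    """'disordered' iff the window-mean p_D reaches the threshold (inclusive)."""
    if not 0 <= mean_p_D <= 1:
        raise ValueError("mean_p_D must lie in [0, 1]")
    return "disordered" if mean_p_D >= threshold else "ordered"


def delta_dynamics(mut: ResidueProfile, wt: ResidueProfile,
                   window: DomainWindow = BETA_DOMAIN
                   ) -> tuple[float, float, float]:
    """Mutant-minus-wild-type window means for each descriptor."""
    if len(mut) != len(wt) or not np.array_equal(mut.positions, wt.positions):
        raise ValueError("profiles must share length and residue numbering")
    m = average_window(mut, window)
    w = average_window(wt, window)
    return tuple(a - b for a, b in zip(m, w))  # type: ignore[return-value]


def classify_variant(delta_p_D: float, epsilon: float = 0.05) -> str:
    """Dynamics class relative to the reference.

    ``mobile`` for an increase in window-mean disorder of at least epsilon,
    ``rigid`` for a decrease of at least epsilon, ``similar`` otherwise.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if delta_p_D >= epsilon:
        return "mobile"
    if delta_p_D <= -epsilon:
        return "rigid"
    return "similar"


def droplet_landscape(point: tuple[float, float],
                      boundary_tolerance: float = 0.05
                      ) -> tuple[str, float]:
    """Classify a (p_DP, MBM) point against the landscape diagonal.

    Returns ``(class, signed_distance)`` where the signed distance is the
    perpendicular distance to the identity diagonal, positive above it
    (p_DP > MBM, liquid-favouring) and negative below (solid-favouring);
    points within ``boundary_tolerance`` of the diagonal are 'boundary'.
    """
    p_dp, mbm = point
    if not (0 <= p_dp <= 1 and 0 <= mbm <= 1):
        raise ValueError("landscape coordinates must lie in [0, 1]")
    distance = (p_dp - mbm) / np.sqrt(2.0)
    if distance > boundary_tolerance:
        label = "liquid-favoring"
    elif distance < -boundary_tolerance:
        label = "solid-favoring"
    else:
        label = "boundary"
    return label, float(distance)


def rank_candidates(candidates: Sequence[tuple[VariantSpec, DynamicsSummary]]
                    ) -> list[tuple[VariantSpec, DynamicsSummary]]:
    """Order candidate variants for selection.

    Structural disorder is the primary ranking: sort by |delta_p_D|
    descending, ties broken by |delta_p_DP| descending, then by the first
    mutated position ascending.  The sort is stable, so the output is a
    permutation of the input with deterministic tie handling.
    """
    return sorted(
        candidates,
        key=lambda c: (-abs(c[1].delta_p_D), -abs(c[1].delta_p_DP),
                       c[0].first_position))


def summarize_variant(mut: ResidueProfile, wt: ResidueProfile,
                      window: DomainWindow = BETA_DOMAIN,
                      threshold: float = DISORDER_THRESHOLD,
                      epsilon: float = 0.05,
                      boundary_tolerance: float = 0.05) -> DynamicsSummary:
    """Full per-variant report: means, deltas, classes, landscape position.

    The MBM landscape coordinate is the window's flagged MBM fraction when
    region flags are the only MBM information available.
    """
    mean_d, mean_dd, mean_dp = average_window(mut, window)
    deltas = delta_dynamics(mut, wt, window)
    label, dist = droplet_landscape((mean_dp, mut.mbm_fraction(window)),
                                    boundary_tolerance)
    return DynamicsSummary(
        name=mut.name,
        mean_p_D=mean_d, mean_p_DD=mean_dd, mean_p_DP=mean_dp,
        delta_p_D=deltas[0], delta_p_DD=deltas[1], delta_p_DP=deltas[2],
        disorder_class=classify_disorder(mean_d, threshold),
        dynamics_class=classify_variant(deltas[0], epsilon),
        landscape=label, landscape_distance=dist)


# ---------------------------------------------------------------------------
# Numbering helpers


def full_to_peptide(position: int, offset: int = PEPTIDE_OFFSET) -> int:
    """Map full-protein residue numbering to peptide-local (offset -> 1)."""
    local = position - offset + 1
    if local < 1:
        raise ValueError(f"position {position} precedes peptide start {offset}")
    return local


def peptide_to_full(position: int, offset: int = PEPTIDE_OFFSET) -> int:
    """Map peptide-local residue numbering back to full-protein numbering."""
    if position < 1:
        raise ValueError("peptide-local positions are 1-based")
    return position + offset - 1


# ---------------------------------------------------------------------------
# I/O


def read_profile_table(path, sequence: str | None = None,
                       name: str = "profile") -> ResidueProfile:
    """Read a tab-separated per-residue profile.

    Expected columns: ``position``, ``residue``, ``p_D``, ``p_DD``, ``p_DP``
    and optionally ``mbm_flag`` (0/1); contiguous flagged runs become MBM
    regions.  ``sequence`` overrides the residue column when given.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"position", "residue", "p_D", "p_DD", "p_DP"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile table missing columns: {sorted(missing)}")
    seq = sequence if sequence is not None else "".join(df["residue"])
    regions: list[tuple[int, int]] = []
    if "mbm_flag" in df.columns:
        flagged = df.loc[df["mbm_flag"].astype(int) == 1, "position"].to_numpy()
        for pos in flagged:
            if regions and pos == regions[-1][1] + 1:
                regions[-1] = (regions[-1][0], int(pos))
            else:
                regions.append((int(pos), int(pos)))
    return ResidueProfile(sequence=seq,
                          positions=df["position"].to_numpy(),
                          p_D=df["p_D"].to_numpy(),
                          p_DD=df["p_DD"].to_numpy(),
                          p_DP=df["p_DP"].to_numpy(),
                          mbm_regions=tuple(regions), name=name)


def write_summary_table(summaries: Iterable[DynamicsSummary], path) -> None:
    """Write per-variant summaries as a tab-separated machine-readable table."""
    pd.DataFrame([s.to_dict() for s in summaries]).to_csv(
        path, sep="\t", index=False)


def read_fasta_sequence(path) -> str:
    """First sequence of a FASTA file (via Biopython)."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq)


# ---------------------------------------------------------------------------
# Toy surrogate predictor (testing only)

_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1}


def toy_profile(sequence: str, start_position: int = 1,
                window: int = 7, name: str = "toy") -> ResidueProfile:
    """Toy charge/hydropathy surrogate for the upstream predictors.

    Synthetic stand-in used only for end-to-end tests: smooths per-residue
    mean net charge and Kyte-Doolittle hydropathy over a sliding window and
    maps (high charge, low hydropathy) to high disorder via a logistic.  It
    reproduces the qualitative behaviour real predictors share (charged
    sequences disordered, hydrophobic/aromatic ones ordered) and nothing
    more; never use it in place of real predictor output.
    """
    seq = sequence.upper()
    n = len(seq)
    charge = np.array([abs(_CHARGE.get(a, 0.0)) for a in seq])
    hydro = np.array([_KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    half = window // 2
    sm_charge = np.empty(n)
    sm_hydro = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm_charge[i] = charge[lo:hi].mean()
        sm_hydro[i] = hydro[lo:hi].mean()
    p_d = 1.0 / (1.0 + np.exp(-(2.5 * sm_charge - 0.9 * sm_hydro - 0.8)))
    p_dd = np.clip(0.6 * p_d + 0.2, 0, 1)
    p_dp = np.clip(p_d * (0.4 + 0.6 * sm_charge), 0, 1)
    positions = np.arange(start_position, start_position + n)
    return ResidueProfile(sequence=seq, positions=positions,
                          p_D=p_d, p_DD=p_dd, p_DP=p_dp, name=name)
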