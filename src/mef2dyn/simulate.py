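"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage has a generator that emulates the shape of the
corresponding experimental data — disorder-descriptor profiles with planted
window effects, contact trajectories with planted cluster motifs,
bead-chain conformers of tunable compactness, monoexponential relaxation
decays on the study's delay schedules, Stejskal–Tanner gradient decays on
the 32-step schedule, two-component FRAP traces, and nuclei-count /
reporter tables with planted effect sizes.  Each generator returns its
ground truth alongside the data so downstream stages are tested as
``recover(generate(theta)) ≈ theta``.  All randomness flows through numpy
Generators; the same seed reproduces the same output bit-for-bit.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nmr
from .ensemble import ContactTrajectory, Trajectory
from .frap import FrapTrace
from .profiles import BETA_DOMAIN, DomainWindow, ResidueProfile

__all__ = [
    "GeneratorConfig",
    "gen_profiles",
    "gen_contact_trajectory",
    "gen_conformers",
    "gen_relaxation",
    "gen_spectral_density_rates",
    "gen_dosy",
    "gen_frap",
    "gen_counts_and_readings",
]

#: 37-residue peptide model sequence (beta-domain plus flanking regions).
PEPTIDE_SEQUENCE = "SRKPDLRVITSQAGKGLMHHLTEDHLDLNNAQRLGVS"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class GeneratorConfig:
    """Shared seeded random source with deterministic per-stage streams.

    Stage streams are derived from the run seed and a CRC32 of the stage
    name, so adding or reordering stages never perturbs the others.
    """

    seed: int = 0

    def rng(self, stage: str) -> np.random.Generator:
        child = np.random.SeedSequence(
            [int(self.seed), zlib.crc32(stage.encode())])
        return np.random.default_rng(child)


# ---------------------------------------------------------------------------
# Profiles


def gen_profiles(seed=0,
                 effects: dict | None = None,
                 window: DomainWindow = BETA_DOMAIN,
                 start_position: int = 265,
                 n_residues: int = 37,
                 roughness: float = 0.02,
                 ) -> tuple[ResidueProfile, dict, dict]:
    """Wild-type plus variant profiles with planted window-mean deltas.

    ``effects`` maps variant name -> additive p_D effect on the window
    residues (positive = more disordered/mobile, negative = more rigid);
    the defaults plant one variant per dynamics class.  p_DD and p_DP
    receive half and the same effect respectively, and everything is
    clipped to [0, 1] (with a warning if clipping bites).  Returns
    (wild_type, variants, truth) where truth records each requested delta.
    """
    if effects is None:
        effects = {"var_similar": 0.0, "var_mobile": 0.2, "var_rigid": -0.2}
    rng = _rng(seed)
    positions = np.arange(start_position, start_position + n_residues)
    in_window = (positions >= window.start) & (positions <= window.end)
    # disordered flanks around a moderately ordered window, like a short
    # ordered motif embedded in a disordered transactivation region
    base_d = np.where(in_window, 0.28, 0.62)
    base_d = np.clip(base_d + roughness * rng.standard_normal(n_residues),
                     0.02, 0.98)
    base_dd = np.clip(0.55 + 0.4 * (base_d - 0.5)
                      + roughness * rng.standard_normal(n_residues), 0, 1)
    base_dp = np.clip(0.5 + 0.6 * (base_d - 0.5)
                      + roughness * rng.standard_normal(n_residues), 0, 1)
    seq = (PEPTIDE_SEQUENCE * (n_residues // len(PEPTIDE_SEQUENCE) + 1))[:n_residues]
    wt = ResidueProfile(sequence=seq, positions=positions, p_D=base_d,
                        p_DD=base_dd, p_DP=base_dp, name="wt")
    variants: dict = {}
    truth: dict = {}
    for name, eff in effects.items():
        d = base_d + np.where(in_window, eff, 0.0)
        dd = base_dd + np.where(in_window, 0.5 * eff, 0.0)
        dp = base_dp + np.where(in_window, eff, 0.0)
        for label, arr in (("p_D", d), ("p_DD", dd), ("p_DP", dp)):
            if np.any((arr < 0) | (arr > 1)):
                warnings.warn(f"{name}: {label} effect clipped to [0, 1]",
                              stacklevel=2)
        variants[name] = ResidueProfile(
            sequence=seq, positions=positions,
            p_D=np.clip(d, 0, 1), p_DD=np.clip(dd, 0, 1),
            p_DP=np.clip(dp, 0, 1), name=name)
        truth[name] = {"delta_p_D": float(eff),
                       "class": ("similar" if abs(eff) < 0.05 else
                                 "mobile" if eff > 0 else "rigid")}
    return wt, variants, truth


# ---------------------------------------------------------------------------
# Contact trajectories with planted clusters


def _pair_universe(n_residues: int, min_separation: int = 3) -> list:
    return [(i, j) for i in range(1, n_residues + 1)
            for j in range(i + min_separation, n_residues + 1)]


def gen_contact_trajectory(seed=0, k: int = 2, n_frames: int = 120,
                           motif_size: int = 8, n_residues: int = 37,
                           noise_rate: float = 0.0,
                           dropout: float = 0.0) -> ContactTrajectory:
    """Contact trajectory drawn from k disjoint planted contact motifs.

    Each frame copies one motif (cycling through motifs so every one is
    populated), loses each motif contact with probability ``dropout`` and
    gains each off-motif contact with probability ``noise_rate``.  The
    planted frame labels are attached as ``true_labels``.  A warning is
    issued when the noise level approaches the separation bound beyond
    which exact recovery by f_S > 0.5 clustering is no longer guaranteed.
    """
    rng = _rng(seed)
    universe = _pair_universe(n_residues)
    if k * motif_size > len(universe):
        raise ValueError("motifs exceed the available pair universe")
    chosen = rng.choice(len(universe), size=k * motif_size, replace=False)
    motifs = [frozenset(universe[idx] for idx in chosen[m * motif_size:
                                                        (m + 1) * motif_size])
              for m in range(k)]
    off_motif = [p for i, p in enumerate(universe) if i not in set(chosen)]
    # Same-motif frames share ~m(1-dropout)^2 contacts against a symmetric
    # difference of ~2e noise + 2m*dropout(1-dropout) dropped contacts;
    # f_S > 0.5 needs the shared set to exceed half the difference.
    expected_noise = noise_rate * len(off_motif)
    bound = motif_size * (1.0 - dropout) * (1.0 - 2.0 * dropout)
    if expected_noise >= 0.8 * max(bound, 0.0):
        warnings.warn("noise at or above the motif separation bound; exact "
                      "cluster recovery is not guaranteed", stacklevel=2)
    labels = np.array([f % k for f in range(n_frames)])
    snapshots = []
    for lab in labels:
        contacts = {p for p in motifs[lab] if rng.random() >= dropout}
        contacts.update(p for p in off_motif if rng.random() < noise_rate)
        snapshots.append(frozenset(contacts))
    return ContactTrajectory(snapshots=snapshots, n_residues=n_residues,
                             true_labels=labels)


# ---------------------------------------------------------------------------
# Bead-chain conformers


def gen_conformers(seed=0, n_frames: int = 50, chain_length: int = 37,
                   collapse_bias: float = 0.5, bond_nm: float = 0.38,
                   min_dist_nm: float = 0.30, bead_mass: float = 110.0,
                   timestep_ps: float = 10.0, max_retries: int = 200,
                   replica: str = "rep1") -> Trajectory:
    """Self-avoiding random-walk bead chains of tunable compactness.

    Each residue is one bead on a ``bond_nm`` lattice-free walk; a step
    direction mixes an isotropic random direction with the direction back
    toward the chain's centre of mass, weighted by ``collapse_bias`` in
    [0, 1].  Higher bias yields lower median radius of gyration (monotone
    in expectation).  Steps clashing with earlier beads (< ``min_dist_nm``)
    are re-drawn; persistent failure raises after ``max_retries`` restarts.
    """
    if not 0.0 <= collapse_bias <= 1.0:
        raise ValueError("collapse_bias must lie in [0, 1]")
    rng = _rng(seed)
    frames = np.empty((n_frames, chain_length, 3))
    for f in range(n_frames):
        for attempt in range(max_retries + 1):
            coords = _grow_chain(rng, chain_length, collapse_bias, bond_nm,
                                 min_dist_nm)
            if coords is not None:
                frames[f] = coords
                break
        else:
            raise RuntimeError("self-avoiding walk failed: chain density "
                               "incompatible with the clash distance")
    return Trajectory(xyz=frames,
                      masses=np.full(chain_length, bead_mass),
                      residue_index=np.arange(1, chain_length + 1),
                      elements=np.array(["C"] * chain_length),
                      timestep_ps=timestep_ps, replica=replica)


def _grow_chain(rng, n, bias, bond, min_dist):
    coords = np.zeros((n, 3))
    n_draws = 60
    for i in range(1, n):
        placed = False
        for attempt in range(n_draws):
            # anneal the collapse bias toward isotropic draws so dense
            # chains can still find a clash-free direction
            bias_eff = bias * (1.0 - attempt / n_draws)
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            if bias_eff > 0 and i > 1:
                com = coords[:i].mean(axis=0)
                back = com - coords[i - 1]
                norm = np.linalg.norm(back)
                if norm > 1e-9:
                    u = (1.0 - bias_eff) * u + bias_eff * back / norm
                    u /= np.linalg.norm(u)
            cand = coords[i - 1] + bond * u
            if i < 2 or np.min(np.linalg.norm(coords[:i - 1] - cand,
                                              axis=1)) >= min_dist:
                coords[i] = cand
                placed = True
                break
        if not placed:
            return None
    return coords


# ---------------------------------------------------------------------------
# NMR decays


def gen_relaxation(seed=0, kind: str = "T1", t_ms: float = 400.0,
                   residues=(6, 17, 21, 26, 28), i0: float = 1.0,
                   noise: float = 0.0, delays_ms=None,
                   field_mhz: float = 700.0
                   ) -> tuple[nmr.RelaxationSeries, dict]:
    """Monoexponential relaxation decays on the study delay schedules.

    ``t_ms`` may be a scalar (shared by all residues) or a mapping
    residue -> T.  Noise is additive Gaussian with sigma = ``noise`` · I0.
    The default residues are the leucine positions of the labelled peptide.
    Returns (series, truth) with truth mapping residue -> generating T.
    """
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    rng = _rng(seed)
    if delays_ms is None:
        delays_ms = nmr.T1_DELAYS_MS if kind == "T1" else nmr.T2_DELAYS_MS
    delays_ms = np.asarray(delays_ms, dtype=float)
    t_map = (dict(t_ms) if isinstance(t_ms, dict)
             else {r: float(t_ms) for r in residues})
    intensities = {}
    for res in residues:
        clean = i0 * np.exp(-delays_ms / t_map[res])
        intensities[res] = clean + noise * i0 * rng.standard_normal(
            delays_ms.size)
    series = nmr.RelaxationSeries(delays_ms=delays_ms,
                                  intensities=intensities, kind=kind,
                                  field_mhz=field_mhz)
    return series, {"t_ms": t_map, "i0": i0, "noise": noise}


def gen_spectral_density_rates(tau_c_ns: float, field_mhz: float = 700.0,
                               constants: nmr.NitrogenConstants = nmr.N15
                               ) -> tuple[float, float, float]:
    """(R1, R2, NOE) from a single-Lorentzian spectral density.

    Forward model of the reduced mapping: J(ω) = (2/5)·τc/(1 + (ωτc)²)
    evaluated at 0, ωN and 0.87 ωH only, combined with the same dipolar and
    CSA constants the inverse mapping uses.  Deterministic — serves as the
    round-trip oracle for :func:`mef2dyn.nmr.reduced_spectral_density`.
    """
    tau = tau_c_ns * 1e-9
    omega_h, omega_n = constants.omegas(field_mhz)

    def j(omega):
        return 0.4 * tau / (1.0 + (omega * tau) ** 2)

    d2 = constants.dipolar ** 2
    c = omega_n * abs(constants.csa_ppm) * 1e-6 / np.sqrt(3.0)
    c2 = c * c
    j0, jn, jh = j(0.0), j(omega_n), j(0.87 * omega_h)
    r1 = d2 / 4.0 * (3.0 * jn + 7.0 * jh) + c2 * jn
    r2 = (d2 / 8.0 * (4.0 * j0 + 3.0 * jn + 13.0 * jh)
          + c2 / 6.0 * (4.0 * j0 + 3.0 * jn))
    sigma = d2 / 4.0 * 5.0 * jh
    noe = 1.0 + constants.gamma_h / constants.gamma_n * sigma / r1
    return float(r1), float(r2), float(noe)


def gen_dosy(seed=0, d: float = 1.54e-10, i0: float = 1.0,
             noise: float = 0.0, gradients_gcm=None,
             delta_s: float = 2e-3, big_delta_s: float = 75e-3
             ) -> tuple[nmr.DosyDecay, dict]:
    """Stejskal–Tanner gradient decay with a known diffusion coefficient.

    Defaults follow the acquisition used in the study: 32 gradient
    increments from 5 % to 95 % of 57.7 G/cm, δ = 2 ms, Δ = 75 ms.  Noise
    is multiplicative Gaussian (sigma = ``noise``).
    """
    if d <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    rng = _rng(seed)
    if gradients_gcm is None:
        gradients_gcm = nmr.dosy_gradient_schedule()
    decay = nmr.DosyDecay(gradients_gcm=gradients_gcm,
                          intensities=np.ones_like(gradients_gcm),
                          delta_s=delta_s, big_delta_s=big_delta_s)
    clean = i0 * np.exp(-d * decay.b_values())
    noisy = clean * (1.0 + noise * rng.standard_normal(clean.size))
    decay.intensities = np.clip(noisy, 1e-12, None)
    return decay, {"d": d, "i0": i0, "noise": noise}


# ---------------------------------------------------------------------------
# FRAP traces


def gen_frap(seed=0, mobile_fraction: float = 0.6, tau_s: float = 15.0,
             bleach_depth: float = 0.8, n_pre: int = 10, n_post: int = 120,
             dt_s: float = 1.0, noise: float = 0.0,
             acq_bleach_rate: float = 0.0, background: float = 100.0,
             amplitude: float = 1000.0) -> tuple[FrapTrace, dict]:
    """Two-ROI FRAP trace with known recovery kinetics.

    The underlying recovery is single-exponential: the bleach drops the
    normalized signal to N₊ = 1 − ``bleach_depth`` and it recovers toward
    N∞ = N₊ + mobile_fraction · (1 − N₊) with time constant ``tau_s``.
    ``acq_bleach_rate`` applies multiplicative acquisition photobleaching
    exp(−rate·t) to both ROIs equally, which the double normalization must
    cancel.  Noise is multiplicative Gaussian on the background-subtracted
    signals.  Default shape: 120 post-bleach points over 120 s.
    """
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must lie in [0, 1]")
    if noise < 0:
        raise ValueError("noise level must be non-negative")
    rng = _rng(seed)
    n_tot = n_pre + n_post
    time_s = dt_s * np.arange(n_tot)
    t_post = time_s[n_pre:] - time_s[n_pre]
    n_plus = 1.0 - bleach_depth
    n_inf = n_plus + mobile_fraction * (1.0 - n_plus)
    n_true = np.ones(n_tot)
    n_true[n_pre:] = n_inf - (n_inf - n_plus) * np.exp(-t_post / tau_s)
    acq = np.exp(-acq_bleach_rate * time_s)
    sig_total = amplitude * acq
    sig_bleach = 0.4 * amplitude * acq * n_true
    if noise > 0:
        sig_total = sig_total * (1.0 + noise * rng.standard_normal(n_tot))
        sig_bleach = sig_bleach * (1.0 + noise * rng.standard_normal(n_tot))
    trace = FrapTrace(time_s=time_s,
                      i_bleach=background + sig_bleach,
                      i_total=background + sig_total,
                      i_background=np.full(n_tot, background),
                      pre_bleach=np.arange(n_pre))
    truth = {"mobile_fraction": mobile_fraction, "tau_s": tau_s,
             "n_plus": n_plus, "n_inf": n_inf, "half_time_s":
             tau_s * np.log(2.0), "normalized": n_true}
    return trace, truth


# ---------------------------------------------------------------------------
# Counts and reporter readings


def gen_counts_and_readings(seed=0,
                            effects: dict | None = None,
                            fusion: dict | None = None,
                            n_experiments: int = 4, n_replicates: int = 3,
                            noise: float = 0.05, n_fields: int = 15,
                            nuclei_per_field: int = 120
                            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Nuclei-count and dual-reporter tables with planted effect sizes.

    ``effects`` maps variant -> true activity ratio relative to wild type
    (e.g. 1.78 for a 178 % variant); ``fusion`` maps variant -> true fusion
    index.  Reporter structure: ``n_experiments`` independent batches of
    ``n_replicates`` technical replicates each, galactosidase log-normal,
    luciferase = galactosidase · batch ratio · effect · (1 + noise).
    Multinucleated counts are binomial per visual field.
    """
    if effects is None:
        effects = {"wt": 1.0, "var_rigid": 1.78, "var_mobile": 1.25}
    if fusion is None:
        fusion = {"wt": 0.30, "var_rigid": 0.45, "var_mobile": 0.35}
    rng = _rng(seed)
    readings = []
    for exp in range(1, n_experiments + 1):
        batch_ratio = float(np.exp(rng.normal(0.0, 0.1)))
        for variant, eff in effects.items():
            for rep in range(1, n_replicates + 1):
                gal = float(rng.lognormal(np.log(1000.0), 0.1))
                luc = gal * batch_ratio * eff * (
                    1.0 + noise * rng.standard_normal())
                readings.append(dict(variant=variant, experiment=exp,
                                     replicate=rep, luciferase=luc,
                                     galactosidase=gal))
    counts = []
    for variant, fi in fusion.items():
        for fld in range(1, n_fields + 1):
            total = int(rng.poisson(nuclei_per_field))
            total = max(total, 1)
            multi = int(rng.binomial(total, fi))
            counts.append(dict(variant=variant, field=fld,
                               multinucleated=multi, total=total))
    truth = {"effects": dict(effects), "fusion": dict(fusion)}
    return pd.DataFrame(counts), pd.DataFrame(readings), truth
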