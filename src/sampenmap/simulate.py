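"""Synthetic two-group fMRI-like cohorts with a designed entropy difference.

The generator emulates the shape of a short resting-state acquisition —
133 volumes at TR = 2 s on a reducible grid (default 32x32x12, full-size
64x64x23) with an ellipsoidal 'brain' sitting on a dark background — while
keeping the temporal statistics simple enough to verify: every in-brain
voxel carries an AR(1) process.  AR(1) regularity rises with the lag-1
coefficient phi, and SampEn falls correspondingly, so giving the elderly
group a larger phi encodes the loss-of-entropy-with-age premise with a
single, recoverable parameter; the phi = 0 case reduces to i.i.d. Gaussian
noise with a closed-form SampEn check.

Per-voxel series:

    baseline_in + signal_amplitude * AR1(phi, unit innovations)
                + drift_amplitude * sin(2*pi*t*TR/drift_period + phase)

with a uniformly random phase per voxel; background voxels are
baseline_out plus faint white noise.  Subject-level variability enters as
Gaussian jitter on phi (clipped to [0, 0.95)), and elderly subjects get an
extra phi increment inside a fixed ellipsoidal 'effect region' so a
voxel-wise group comparison has a known target.  Ages are group metadata
drawn uniformly from disjoint ranges; they influence nothing but the
roster, so the SampEn-age correlation arises purely through the group
construction, mirroring a two-group study design.

Everything is reproducible: subject k of a cohort uses seed
``master_seed + k``, and i.i.d. replicate k of the bias experiment uses
``seed + k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volume import BrainMask, Volume4D

__all__ = [
    "EllipsoidSpec", "CohortSpec", "SyntheticSubject",
    "make_ellipsoid_mask", "simulate_subject", "simulate_cohort",
    "simulate_iid_gaussian", "TINY_GRID",
]

#: Reduced grid for quick end-to-end runs (CI-scale).
TINY_GRID = (16, 16, 8)

PHI_MAX = 0.95  # AR(1) coefficients are clipped below this


@dataclass(frozen=True)
class EllipsoidSpec:
    """Axis-aligned ellipsoid in voxel coordinates (fractions of the grid)."""

    center_frac: tuple[float, float, float]
    semi_axes_frac: tuple[float, float, float]

    def voxel_geometry(self, grid) -> tuple[np.ndarray, np.ndarray]:
        g = np.asarray(grid, dtype=float)
        return np.asarray(self.center_frac) * (g - 1), np.asarray(self.semi_axes_frac) * g


@dataclass
class CohortSpec:
    """The stated world of the synthetic study.

    Defaults emulate the acquisition the pipeline targets (133 volumes,
    TR 2 s) on a reduced grid, with group AR(1) coefficients 0.30 (younger)
    vs 0.55 (elderly), subject jitter SD 0.05, an elderly-only effect region
    of +0.15 phi, ~2% BOLD-like fluctuations on a bright baseline, and a
    slow sinusoidal drift that the 128 s high-pass removes.
    """

    n_young: int = 10
    n_old: int = 10
    grid: tuple[int, int, int] = (32, 32, 12)
    n_volumes: int = 133
    tr_seconds: float = 2.0
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    phi_young: float = 0.30
    phi_old: float = 0.55
    phi_subject_sd: float = 0.05
    brain: EllipsoidSpec = field(default_factory=lambda: EllipsoidSpec(
        center_frac=(0.5, 0.5, 0.5), semi_axes_frac=(0.42, 0.42, 0.42)))
    effect_region: EllipsoidSpec = field(default_factory=lambda: EllipsoidSpec(
        center_frac=(0.65, 0.5, 0.55), semi_axes_frac=(0.12, 0.12, 0.15)))
    effect_extra_phi: float = 0.15
    baseline_in: float = 1000.0
    baseline_out: float = 10.0
    background_noise_sd: float = 1.0
    signal_amplitude: float = 20.0
    drift_period_s: float = 300.0
    drift_amplitude: float = 10.0
    age_range_young: tuple[float, float] = (20.0, 30.0)
    age_range_old: tuple[float, float] = (60.0, 80.0)
    master_seed: int = 2014

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("both groups need at least one subject")
        if not (0 <= self.phi_young < PHI_MAX and 0 <= self.phi_old < PHI_MAX):
            raise ValueError(f"group phis must lie in [0, {PHI_MAX})")
        if not self.phi_old > self.phi_young:
            raise ValueError("phi_old must exceed phi_young "
                             "(elderly more regular => lower entropy)")
        if self.phi_subject_sd < 0:
            raise ValueError("phi_subject_sd must be >= 0")
        if self.signal_amplitude <= 0:
            raise ValueError("degenerate cohort: signal_amplitude must be positive "
                             "(constant in-mask series carry no entropy signal)")
        if self.n_volumes < 4:
            raise ValueError("need at least 4 volumes")

    @property
    def n_subjects(self) -> int:
        return self.n_young + self.n_old


@dataclass
class SyntheticSubject:
    """One simulated acquisition with its ground truth."""

    subject_id: str
    volume: Volume4D
    group: str
    age: float
    true_phi: float
    seed: int


def make_ellipsoid_mask(grid, center, semi_axes) -> BrainMask:
    """Voxels with normalized squared distance <= 1 from ``center``.

    ``center`` and ``semi_axes`` are in voxel units; raises if no voxel
    falls inside.
    """
    grid = tuple(int(g) for g in grid)
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semi_axes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semi-axes must be positive")
    idx = np.indices(grid, dtype=float)
    d2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    include = d2 <= 1.0
    if not include.any():
        raise ValueError("ellipsoid contains no voxel")
    return BrainMask(include)


def _brain_and_effect_masks(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    c, s = spec.brain.voxel_geometry(spec.grid)
    brain = make_ellipsoid_mask(spec.grid, c, s).include
    c, s = spec.effect_region.voxel_geometry(spec.grid)
    effect = make_ellipsoid_mask(spec.grid, c, s).include
    return brain, effect


def _ar1(phi: np.ndarray, innovations: np.ndarray) -> np.ndarray:
    """Stationary AR(1) paths, one per row, with per-row coefficient."""
    V, T = innovations.shape
    x = np.empty((V, T))
    x[:, 0] = innovations[:, 0] / np.sqrt(1.0 - phi ** 2)
    for t in range(1, T):
        x[:, t] = phi * x[:, t - 1] + innovations[:, t]
    return x


def simulate_subject(spec: CohortSpec, group: str, subject_index: int) -> SyntheticSubject:
    """Generate one subject deterministically from ``master_seed + subject_index``."""
    if group not in ("younger", "elderly"):
        raise ValueError("group must be 'younger' or 'elderly'")
    seed = int(spec.master_seed) + int(subject_index)
    rng = np.random.default_rng(seed)
    lo, hi = spec.age_range_young if group == "younger" else spec.age_range_old
    age = float(rng.uniform(lo, hi))
    base_phi = spec.phi_young if group == "younger" else spec.phi_old
    phi_subj = float(np.clip(base_phi + rng.normal(0.0, spec.phi_subject_sd),
                             0.0, PHI_MAX - 1e-9))

    brain, effect = _brain_and_effect_masks(spec)
    V = int(brain.sum())
    T = spec.n_volumes
    phi_vox = np.full(V, phi_subj)
    if group == "elderly":
        in_effect = effect[brain]
        phi_vox[in_effect] = np.clip(phi_vox[in_effect] + spec.effect_extra_phi,
                                     0.0, PHI_MAX - 1e-9)

    ar = _ar1(phi_vox, rng.standard_normal((V, T)))
    t_sec = np.arange(T) * spec.tr_seconds
    phase = rng.uniform(0.0, 2.0 * np.pi, size=V)
    drift = spec.drift_amplitude * np.sin(
        2.0 * np.pi * t_sec[None, :] / spec.drift_period_s + phase[:, None])
    series = spec.baseline_in + spec.signal_amplitude * ar + drift

    data = np.empty((*spec.grid, T))
    data[~brain] = spec.baseline_out + spec.background_noise_sd * rng.standard_normal(
        (int((~brain).sum()), T))
    data[brain] = series
    vol = Volume4D(data, voxel_size_mm=spec.voxel_size_mm, tr_seconds=spec.tr_seconds)
    return SyntheticSubject(subject_id=f"{group[:5]}-{subject_index:03d}", volume=vol,
                            group=group, age=age, true_phi=phi_subj, seed=seed)


def simulate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """All subjects (younger first) plus a roster table.

    Roster columns: subject_id, group, age, true_phi, seed.  Deterministic
    given ``spec.master_seed``.
    """
    subjects = []
    for k in range(spec.n_young):
        subjects.append(simulate_subject(spec, "younger", k))
    for k in range(spec.n_old):
        subjects.append(simulate_subject(spec, "elderly", spec.n_young + k))
    roster = pd.DataFrame([
        {"subject_id": s.subject_id, "group": s.group, "age": s.age,
         "true_phi": s.true_phi, "seed": s.seed}
        for s in subjects])
    return subjects, roster


def simulate_iid_gaussian(N: int, n_reps: int, seed: int) -> np.ndarray:
    """``(n_reps, N)`` i.i.d. standard-Gaussian series; row k from seed + k."""
    if N < 4:
        raise ValueError("N must be >= 4")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    out = np.empty((n_reps, N))
    for k in range(n_reps):
        out[k] = np.random.default_rng(int(seed) + k).standard_normal(N)
    return out
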