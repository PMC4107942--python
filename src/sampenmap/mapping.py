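"""Voxel-wise SampEn maps and per-subject whole-brain summaries.

A map is computed voxel by voxel over the in-mask support of a standardized
4D volume, at a configurable data length N (the FIRST N post-preprocessing
time points are kept, preserving the steady-state head of the scan).
Undefined estimates are carried with an explicit reason code rather than
silently dropped: for short BOLD records the estimator genuinely fails on
some voxels, and whether a subject then contributes at a given N is a
policy decision ('propagate' excludes the subject's mean, mirroring cohort
members that return no value; 'ignore_undefined' averages the defined
voxels and reports the undefined fraction).

``whole_brain_means`` is the fast path used by the cohort analysis: the
template distance profiles at the maximum data length contain those of every
shorter length as leading sub-blocks (truncation keeps the head of the
series), so all requested N — and likewise a whole tolerance grid — are
evaluated from one pass over the voxels.  Equivalence with the per-map
route is covered by tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from . import core
from .core import SampEnParams
from .volume import BrainMask, Volume4D

__all__ = [
    "CODE_OK", "CODE_NO_M_MATCHES", "CODE_NO_M1_MATCHES",
    "CODE_SERIES_TOO_SHORT", "CODE_ZERO_VARIANCE", "CODE_MASKED",
    "REASON_NAMES",
    "EntropyMap", "WholeBrainMean", "SubjectRecord",
    "VoxelwiseSampEn",
    "truncate_to_length", "voxelwise_sampen", "mean_whole_brain",
    "whole_brain_means", "mean_sampen_over_r_grid",
]

CODE_OK = core.CODE_OK
CODE_NO_M_MATCHES = core.CODE_NO_M_MATCHES
CODE_NO_M1_MATCHES = core.CODE_NO_M1_MATCHES
CODE_SERIES_TOO_SHORT = core.CODE_SERIES_TOO_SHORT
CODE_ZERO_VARIANCE = core.CODE_ZERO_VARIANCE
CODE_MASKED = 5

REASON_NAMES = {
    CODE_OK: core.REASON_OK,
    CODE_NO_M_MATCHES: core.REASON_NO_M_MATCHES,
    CODE_NO_M1_MATCHES: core.REASON_NO_M1_MATCHES,
    CODE_SERIES_TOO_SHORT: core.REASON_SERIES_TOO_SHORT,
    CODE_ZERO_VARIANCE: core.REASON_ZERO_VARIANCE,
    CODE_MASKED: "masked",
}


@dataclass
class EntropyMap:
    """3D grid of per-voxel SampEn values with undefined markers.

    ``values`` is NaN wherever the estimate is undefined; ``reasons`` holds
    the per-voxel reason code (out-of-mask voxels are CODE_MASKED).
    """

    values: np.ndarray
    reasons: np.ndarray
    mask: BrainMask
    params: SampEnParams
    data_length: int

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.include.shape:
            raise ValueError("values grid must match mask grid")
        defined = np.isfinite(self.values)
        if np.any(defined & (self.reasons != CODE_OK)):
            raise ValueError("defined values must carry reason 'ok'")
        if np.any(self.values[defined] < 0):
            raise ValueError("SampEn values cannot be negative")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_undefined_in_mask(self) -> int:
        return int((self.mask.include & ~self.defined).sum())

    def save(self, path, voxel_size_mm=(4.0, 4.0, 4.0)) -> None:
        """Write NIfTI (undefined encoded as NaN) plus a JSON sidecar."""
        import nibabel as nib

        img = nib.Nifti1Image(self.values.astype(np.float32),
                              np.diag([*voxel_size_mm, 1.0]))
        nib.save(img, str(path))
        sidecar = {
            "params": {"m": self.params.m, "r": self.params.r,
                       "tau": self.params.tau, "r_mode": self.params.r_mode},
            "data_length": self.data_length,
            "undefined_count": self.n_undefined_in_mask,
            "mask_voxels": self.mask.n_voxels,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)


@dataclass(frozen=True)
class WholeBrainMean:
    """Mean whole-brain SampEn under a stated undefined-voxel policy."""

    value: float | None
    policy: str
    n_defined: int
    n_undefined: int

    @property
    def is_defined(self) -> bool:
        return self.value is not None

    @property
    def undefined_fraction(self) -> float:
        total = self.n_defined + self.n_undefined
        return self.n_undefined / total if total else 1.0


@dataclass
class SubjectRecord:
    """One subject's group membership, age, and per-N whole-brain means."""

    subject_id: str
    group: str
    age: float
    mean_sampen: dict[int, float | None]

    def __post_init__(self) -> None:
        if self.group not in ("younger", "elderly"):
            raise ValueError("group must be 'younger' or 'elderly'")
        if not (self.age > 0):
            raise ValueError("age must be positive")


def truncate_to_length(vol: Volume4D, N: int) -> Volume4D:
    """Keep the first N time points (the steady-state head of the scan)."""
    if N > vol.n_volumes:
        raise ValueError(f"cannot truncate to {N}: volume has {vol.n_volumes} time points")
    return vol.with_data(vol.data[..., :N].copy())


class VoxelwiseSampEn(BaseEstimator):
    """Estimator computing per-voxel SampEn maps over a brain mask.

    Parameters mirror :class:`~sampenmap.core.SampEnParams`; ``data_length``
    optionally truncates the series first.  ``map(vol, mask)`` returns an
    :class:`EntropyMap`.
    """

    def __init__(self, m: int = 2, r: float = 0.3, tau: int = 1,
                 r_mode: str = "sd_scaled", data_length: int | None = None,
                 chunk_voxels: int = 256):
        self.m = m
        self.r = r
        self.tau = tau
        self.r_mode = r_mode
        self.data_length = data_length
        self.chunk_voxels = chunk_voxels

    def _params(self) -> SampEnParams:
        return SampEnParams(m=self.m, r=self.r, tau=self.tau, r_mode=self.r_mode)

    def map(self, vol: Volume4D, mask: BrainMask) -> EntropyMap:
        mask.check_congruent(vol)
        params = self._params()
        if self.data_length is not None:
            vol = truncate_to_length(vol, self.data_length)
        N = vol.n_volumes
        X = vol.data[mask.include]  # (V, N)
        values_flat, reasons_flat = core.batch_sampen(X, params, chunk=self.chunk_voxels)
        values = np.full(vol.spatial_shape, np.nan)
        reasons = np.full(vol.spatial_shape, CODE_MASKED, dtype=np.uint8)
        values[mask.include] = values_flat
        reasons[mask.include] = reasons_flat
        return EntropyMap(values=values, reasons=reasons, mask=mask,
                          params=params, data_length=N)


def voxelwise_sampen(vol: Volume4D, mask: BrainMask,
                     params: SampEnParams = SampEnParams()) -> EntropyMap:
    """Per-voxel SampEn map of a (standardized) volume over its mask."""
    return VoxelwiseSampEn(m=params.m, r=params.r, tau=params.tau,
                           r_mode=params.r_mode).map(vol, mask)


def mean_whole_brain(emap: EntropyMap, policy: str = "propagate") -> WholeBrainMean:
    """Mean SampEn over in-mask voxels.

    ``propagate``: undefined as soon as any in-mask voxel is undefined
    (mirrors subjects that return no whole-brain value at short N).
    ``ignore_undefined``: mean over defined in-mask voxels, with the
    undefined fraction reported alongside.
    """
    if policy not in ("propagate", "ignore_undefined"):
        raise ValueError("policy must be 'propagate' or 'ignore_undefined'")
    inc = emap.mask.include
    vals = emap.values[inc]
    defined = np.isfinite(vals)
    n_def, n_undef = int(defined.sum()), int((~defined).sum())
    if n_def == 0 or (policy == "propagate" and n_undef > 0):
        return WholeBrainMean(None, policy, n_def, n_undef)
    return WholeBrainMean(float(vals[defined].mean()), policy, n_def, n_undef)


# ---------------------------------------------------------------------------
# Fast multi-length / multi-tolerance whole-brain means
# ---------------------------------------------------------------------------

def _masked_series(vol: Volume4D, mask: BrainMask) -> np.ndarray:
    mask.check_congruent(vol)
    return vol.data[mask.include]


def _means_from_values(values: np.ndarray, policy: str) -> WholeBrainMean:
    defined = np.isfinite(values)
    n_def, n_undef = int(defined.sum()), int((~defined).sum())
    if n_def == 0 or (policy == "propagate" and n_undef > 0):
        return WholeBrainMean(None, policy, n_def, n_undef)
    return WholeBrainMean(float(values[defined].mean()), policy, n_def, n_undef)


def whole_brain_means(vol: Volume4D, mask: BrainMask, data_lengths,
                      params: SampEnParams = SampEnParams(),
                      policy: str = "propagate",
                      chunk_voxels: int = 256) -> dict[int, WholeBrainMean]:
    """Per-subject mean whole-brain SampEn at several data lengths at once.

    Computes the Chebyshev template profiles once at max(N) per voxel chunk
    and reads every shorter length off their leading sub-blocks; the
    sd-scaled tolerance is recomputed from each truncated series.  Agrees
    with ``mean_whole_brain(voxelwise_sampen(truncate_to_length(...)))``.
    """
    if policy not in ("propagate", "ignore_undefined"):
        raise ValueError("policy must be 'propagate' or 'ignore_undefined'")
    lengths = sorted({int(N) for N in data_lengths})
    if lengths[-1] > vol.n_volumes:
        raise ValueError(f"data length {lengths[-1]} exceeds {vol.n_volumes} time points")
    m, tau = params.m, params.tau
    n_full = lengths[-1]
    X = _masked_series(vol, mask)[:, :n_full]
    V = X.shape[0]
    values = {N: np.full(V, np.nan) for N in lengths}
    for c0 in range(0, V, chunk_voxels):
        c1 = min(c0 + chunk_voxels, V)
        Xc = X[c0:c1]
        d_m, d_m1 = core._batch_profiles(Xc, m, tau)
        for N in lengths:
            n_t = N - m * tau
            if n_t < 2:
                continue  # stays NaN (series too short)
            if params.r_mode == "sd_scaled":
                sd = Xc[:, :N].std(axis=1, ddof=1)
                r_abs = np.where(sd > 0, params.r * sd, -1.0)  # -1: no match possible
            else:
                r_abs = np.full(c1 - c0, float(params.r))
            thr = r_abs[:, None, None]
            b_m = (d_m[:, :n_t, :n_t] <= thr).sum(axis=(1, 2)) - n_t
            b_m1 = (d_m1[:, :n_t, :n_t] <= thr).sum(axis=(1, 2)) - n_t
            v, _ = core._values_from_counts(b_m, b_m1)
            v[(params.r_mode == "sd_scaled") & (r_abs < 0)] = np.nan
            values[N][c0:c1] = v
    return {N: _means_from_values(values[N], policy) for N in lengths}


def mean_sampen_over_r_grid(vol: Volume4D, mask: BrainMask, r_grid,
                            m: int = 2, tau: int = 1, N: int | None = None,
                            policy: str = "propagate",
                            chunk_voxels: int = 256) -> dict[float, WholeBrainMean]:
    """Mean whole-brain SampEn at every tolerance of ``r_grid`` in one pass.

    Used by the ROC tolerance sweep: the distance profiles are independent
    of r, so only the counting step repeats per grid value.  Tolerances are
    sd-scaled per voxel.
    """
    r_grid = [float(r) for r in r_grid]
    if not r_grid or any(r <= 0 for r in r_grid):
        raise ValueError("r_grid must be a nonempty list of positive tolerances")
    if N is None:
        N = vol.n_volumes
    vol = truncate_to_length(vol, N)
    X = _masked_series(vol, mask)
    V = X.shape[0]
    n_t = N - m * tau
    if n_t < 2:
        raise core.SeriesTooShortError(f"N={N} leaves {n_t} templates")
    values = {r: np.full(V, np.nan) for r in r_grid}
    for c0 in range(0, V, chunk_voxels):
        c1 = min(c0 + chunk_voxels, V)
        Xc = X[c0:c1]
        d_m, d_m1 = core._batch_profiles(Xc, m, tau)
        sd = Xc.std(axis=1, ddof=1)
        for r in r_grid:
            r_abs = np.where(sd > 0, r * sd, -1.0)
            thr = r_abs[:, None, None]
            b_m = (d_m <= thr).sum(axis=(1, 2)) - n_t
            b_m1 = (d_m1 <= thr).sum(axis=(1, 2)) - n_t
            v, _ = core._values_from_counts(b_m, b_m1)
            v[r_abs < 0] = np.nan
            values[r][c0:c1] = v
    return {r: _means_from_values(values[r], policy) for r in r_grid}
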