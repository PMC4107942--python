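"""Simplified preprocessing chain for 4D BOLD volumes.

Stages (in the order they are applied before entropy mapping):

1. discard the initial dummy volumes acquired before steady state;
2. temporal high-pass filtering by regressing out low-frequency discrete
   cosine basis functions (SPM-style, default 128 s cutoff);
3. spatial Gaussian smoothing at a fixed FWHM (default 8 mm isotropic);
4. brain masking by thresholding the temporal-mean image at a fraction of
   its maximum (default 0.1);
5. per-voxel standardization to zero mean and unit SD, so a single
   tolerance value r serves every voxel regardless of signal amplitude.

Motion correction is deliberately a no-op here: the pipeline is exercised on
simulated data without motion, and a realignment slot would add nothing
testable.

Each stage is a scikit-learn transformer over :class:`~sampenmap.volume.Volume4D`
objects; ``build_preprocessing_pipeline`` composes them into an sklearn
:class:`~sklearn.pipeline.Pipeline`.  Module-level functions are thin wrappers
over the transformers.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline

from .volume import BrainMask, Volume4D

__all__ = [
    "DiscardInitialVolumes",
    "DCTHighPass",
    "GaussianSmooth",
    "VoxelStandardizer",
    "build_preprocessing_pipeline",
    "preprocess",
    "discard_initial_volumes",
    "dct_highpass",
    "gaussian_smooth",
    "compute_mask",
    "standardize_voxels",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class _VolumeTransformer(TransformerMixin, BaseEstimator):
    """Stateless transformer over Volume4D objects; fit is validation only."""

    def fit(self, X: Volume4D, y=None):
        if not isinstance(X, Volume4D):
            raise TypeError("expected a Volume4D")
        return self


class DiscardInitialVolumes(_VolumeTransformer):
    """Drop the first ``n_discard`` time points (dummy scans)."""

    def __init__(self, n_discard: int = 5):
        self.n_discard = n_discard

    def transform(self, X: Volume4D) -> Volume4D:
        k = int(self.n_discard)
        if k < 0:
            raise ValueError("n_discard must be non-negative")
        if k >= X.n_volumes:
            raise ValueError(
                f"discarding {k} of {X.n_volumes} volumes leaves nothing")
        return X.with_data(X.data[..., k:].copy())


class DCTHighPass(_VolumeTransformer):
    """High-pass filter by projecting out low-frequency DCT regressors.

    The regressor count is K = floor(2 * T * TR / cutoff) — the number of
    discrete cosine basis functions (excluding the constant) whose
    frequencies fall below 1/cutoff Hz.  The voxel's temporal mean is
    preserved (the basis is orthogonal to the constant), so only drift is
    removed.  With K = 0 the input passes through unchanged.
    """

    def __init__(self, cutoff_seconds: float = 128.0):
        self.cutoff_seconds = cutoff_seconds

    def transform(self, X: Volume4D) -> Volume4D:
        cutoff = float(self.cutoff_seconds)
        T = X.n_volumes
        if T < 4:
            raise ValueError("need at least 4 time points to high-pass filter")
        if cutoff <= 2.0 * X.tr_seconds:
            raise ValueError("cutoff must exceed twice the TR")
        K = int(np.floor(2.0 * T * X.tr_seconds / cutoff))
        if K == 0:
            logger.info("DCT high-pass: cutoff %.1f s removes no component at "
                        "T=%d, TR=%.2f s; returning input unchanged", cutoff, T, X.tr_seconds)
            return X.with_data(X.data.copy())
        t = np.arange(T)
        # Orthonormal DCT-II basis, components k = 1..K (constant excluded).
        basis = np.stack([np.sqrt(2.0 / T) * np.cos(np.pi * k * (2 * t + 1) / (2 * T))
                          for k in range(1, K + 1)], axis=1)
        flat = X.data.reshape(-1, T)
        coeffs = flat @ basis
        filtered = flat - coeffs @ basis.T
        return X.with_data(filtered.reshape(X.data.shape))


class GaussianSmooth(_VolumeTransformer):
    """Separable 3D Gaussian smoothing of every time point.

    ``fwhm_mm`` is converted to a per-axis sigma in voxels using the voxel
    size; the kernel is truncated at 4 sigma with zero-padded edges (so
    interior voxels of a constant image are unchanged while edge voxels
    attenuate).
    """

    def __init__(self, fwhm_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)):
        self.fwhm_mm = fwhm_mm

    def transform(self, X: Volume4D) -> Volume4D:
        fwhm = np.asarray(self.fwhm_mm, dtype=float)
        if fwhm.shape != (3,) or np.any(fwhm <= 0):
            raise ValueError("fwhm_mm must be three positive reals")
        sigma_vox = fwhm / FWHM_TO_SIGMA / np.asarray(X.voxel_size_mm)
        out = ndimage.gaussian_filter(
            X.data, sigma=(*sigma_vox, 0.0), mode="constant", cval=0.0, truncate=4.0)
        return X.with_data(out)


def compute_mask(vol: Volume4D, fraction: float = 0.1) -> BrainMask:
    """Brain mask: temporal-mean intensity >= fraction * global maximum.

    Voxels with zero temporal variance are excluded as well (they cannot
    carry an sd-scaled entropy estimate).  Raises if the mask comes out
    empty.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    mean_img = vol.data.mean(axis=3)
    include = mean_img >= fraction * mean_img.max()
    include &= vol.data.var(axis=3) > 0
    if not include.any():
        raise ValueError("mask is empty after intensity and variance rules")
    return BrainMask(include)


class VoxelStandardizer(_VolumeTransformer):
    """Standardize every in-mask voxel series to mean 0, SD 1 (ddof=1).

    If no mask is supplied, ``fit`` derives one with :func:`compute_mask`
    at ``mask_fraction``; the mask used is exposed as ``mask_``.
    Out-of-mask voxels are zeroed.
    """

    def __init__(self, mask: BrainMask | None = None, mask_fraction: float = 0.1):
        self.mask = mask
        self.mask_fraction = mask_fraction

    def fit(self, X: Volume4D, y=None):
        super().fit(X)
        self.mask_ = self.mask if self.mask is not None else compute_mask(X, self.mask_fraction)
        self.mask_.check_congruent(X)
        return self

    def transform(self, X: Volume4D) -> Volume4D:
        if not hasattr(self, "mask_"):
            self.fit(X)
        inc = self.mask_.include
        series = X.data[inc]  # (V, T)
        sd = series.std(axis=1, ddof=1)
        if np.any(sd == 0):
            idx = np.argwhere(inc)[np.nonzero(sd == 0)[0][0]]
            raise ValueError(
                f"in-mask voxel {tuple(int(i) for i in idx)} has zero temporal SD; "
                "the mask should have excluded it")
        out = np.zeros_like(X.data)
        out[inc] = (series - series.mean(axis=1, keepdims=True)) / sd[:, None]
        return X.with_data(out)


def build_preprocessing_pipeline(n_discard: int = 5, cutoff_seconds: float = 128.0,
                                 fwhm_mm: tuple[float, float, float] = (8.0, 8.0, 8.0),
                                 mask_fraction: float = 0.1,
                                 mask: BrainMask | None = None) -> Pipeline:
    """The full chain as an sklearn Pipeline: discard -> highpass -> smooth -> standardize."""
    return Pipeline([
        ("discard", DiscardInitialVolumes(n_discard)),
        ("highpass", DCTHighPass(cutoff_seconds)),
        ("smooth", GaussianSmooth(fwhm_mm)),
        ("standardize", VoxelStandardizer(mask=mask, mask_fraction=mask_fraction)),
    ])


def preprocess(vol: Volume4D, n_discard: int = 5, cutoff_seconds: float = 128.0,
               fwhm_mm: tuple[float, float, float] = (8.0, 8.0, 8.0),
               mask_fraction: float = 0.1) -> tuple[Volume4D, BrainMask]:
    """Run the default chain; returns the standardized volume and its mask."""
    pipe = build_preprocessing_pipeline(n_discard, cutoff_seconds, fwhm_mm, mask_fraction)
    out = pipe.fit_transform(vol)
    return out, pipe.named_steps["standardize"].mask_


# -- thin functional wrappers -----------------------------------------------

def discard_initial_volumes(vol: Volume4D, k: int) -> Volume4D:
    return DiscardInitialVolumes(k).transform(vol)


def dct_highpass(vol: Volume4D, cutoff_seconds: float = 128.0) -> Volume4D:
    return DCTHighPass(cutoff_seconds).transform(vol)


def gaussian_smooth(vol: Volume4D, fwhm_mm=(8.0, 8.0, 8.0)) -> Volume4D:
    return GaussianSmooth(fwhm_mm).transform(vol)


def standardize_voxels(vol: Volume4D, mask: BrainMask) -> Volume4D:
    return VoxelStandardizer(mask=mask).fit(vol).transform(vol)
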