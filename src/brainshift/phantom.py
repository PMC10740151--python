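"""Synthetic pre-op / intra-op volume pairs with known ground-truth deformation.

The phantom is a textured ellipsoidal "brain" (optionally containing a
ventricle ellipsoid and a tumor sphere) deformed by a sum of smooth Gaussian
bumps.  The intra-operative volume is produced by backward-warping the
pre-operative volume with the ground-truth field, optionally zeroing a
resection region, and adding noise.  Everything is deterministic under the
spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    DenseDeformationField,
    ImageVolume,
    LabelVolume,
    invert_displacements,
    warp_image,
)

__all__ = ["GaussianBump", "PhantomSpec", "make_phantom", "apply_resection",
           "true_forward_displacements"]

BRAIN, VENTRICLE, TUMOR = 1, 2, 3


@dataclass
class GaussianBump:
    """One smooth displacement bump: ``amp * dir * exp(-|x-c|^2 / (2 w^2))``."""

    center: tuple = (32.0, 32.0, 32.0)
    amplitude: float = 3.0          # mm, peak displacement magnitude
    width: float = 10.0             # mm, Gaussian sigma
    direction: tuple = (1.0, 0.0, 0.0)

    def __post_init__(self):
        if self.amplitude < 0 or self.width <= 0:
            raise ValueError("bump amplitude must be >= 0 and width > 0")
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("bump direction must be non-zero")
        self.direction = tuple(d / n)

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        r2 = np.sum((pts - np.asarray(self.center)) ** 2, axis=-1)
        mag = self.amplitude * np.exp(-r2 / (2.0 * self.width**2))
        return mag[..., None] * np.asarray(self.direction)


@dataclass
class PhantomSpec:
    grid_size: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    brain_center: tuple = (32.0, 32.0, 32.0)
    brain_axes: tuple = (22.0, 20.0, 19.0)       # ellipsoid semi-axes, mm
    ventricle_center: tuple = (28.0, 32.0, 32.0)
    ventricle_axes: tuple | None = (6.0, 4.5, 4.5)
    tumor_center: tuple = (40.0, 32.0, 30.0)
    tumor_radius: float | None = 5.0
    texture_base: float = 100.0
    background_intensity: float = 70.0           # surrounding-tissue level
    background_texture_scale: float = 0.5        # texture fraction outside brain
    texture_amplitude: float = 10.0              # intensity std per band
    texture_corr_len: tuple = (0.8, 2.0, 4.0)    # band correlation lengths, voxels
    bumps: list = dfield(default_factory=lambda: [GaussianBump(width=16.0)])
    resection: bool = False
    resection_center: tuple | None = None        # defaults to tumor sphere
    resection_radius: float | None = None
    noise_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if any(n < 8 for n in self.grid_size):
            raise ValueError("grid_size components must be >= 8")


def _ellipsoid_mask(pts: np.ndarray, center, axes) -> np.ndarray:
    q = (pts - np.asarray(center)) / np.asarray(axes)
    return np.sum(q * q, axis=-1) <= 1.0


def _world_grid(spec: PhantomSpec) -> np.ndarray:
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in spec.grid_size], indexing="ij"), axis=-1
    ).astype(float)
    return idx * np.asarray(spec.spacing)


def _check_fold_free(truth: DenseDeformationField) -> None:
    sp = np.asarray(truth.spacing)
    J = np.empty(truth.shape + (3, 3))
    for a in range(3):
        for b in range(3):
            J[..., a, b] = np.gradient(truth.vectors[..., a], sp[b], axis=b)
    det = np.linalg.det(np.eye(3) + J)
    if det.min() <= 0.0:
        raise ValueError(
            "ground-truth deformation folds (non-positive Jacobian); "
            "reduce bump amplitude or increase width"
        )


def make_phantom(spec: PhantomSpec):
    """Build ``(pre, labels, truth, intra)`` for a phantom specification.

    ``truth`` is the backward (pull) deformation field:
    ``intra(v) = pre(v + truth(v))`` before resection/noise.
    """
    rng = np.random.default_rng(spec.seed)
    pts = _world_grid(spec)

    brain = _ellipsoid_mask(pts, spec.brain_center, spec.brain_axes)
    labels = np.zeros(spec.grid_size, dtype=np.int32)
    labels[brain] = BRAIN
    if spec.ventricle_axes is not None:
        vent = _ellipsoid_mask(pts, spec.ventricle_center, spec.ventricle_axes) & brain
        labels[vent] = VENTRICLE
    if spec.tumor_radius is not None:
        tum = (
            np.sum((pts - np.asarray(spec.tumor_center)) ** 2, axis=-1)
            <= spec.tumor_radius**2
        ) & brain
        labels[tum] = TUMOR

    # multi-band texture: block matching needs structure at several scales,
    # otherwise small blocks find spurious near-perfect matches in the window
    corr = np.atleast_1d(np.asarray(spec.texture_corr_len, dtype=float))
    tex = np.zeros(spec.grid_size)
    for cl in corr:
        t = gaussian_filter(rng.standard_normal(spec.grid_size), cl)
        tex += spec.texture_amplitude * t / max(t.std(), 1e-12)
    clip = 4 * spec.texture_amplitude * len(corr)
    intensity = np.full(
        spec.grid_size,
        spec.background_intensity,
    ) + spec.background_texture_scale * np.clip(tex, -clip, clip)
    base = {BRAIN: spec.texture_base, VENTRICLE: 0.6 * spec.texture_base,
            TUMOR: 1.4 * spec.texture_base}
    for lab, b in base.items():
        m = labels == lab
        intensity[m] = b + np.clip(tex[m], -clip, clip)
    pre = ImageVolume(intensity, spec.spacing, (0.0, 0.0, 0.0))
    lab_vol = LabelVolume(labels, spec.spacing, (0.0, 0.0, 0.0))

    # ground-truth backward field: Gaussian bumps tapered to zero outside brain
    disp = np.zeros(spec.grid_size + (3,))
    for bump in spec.bumps:
        disp += bump.evaluate(pts)
    taper = gaussian_filter(brain.astype(float), 3.0 / np.asarray(spec.spacing).mean())
    disp *= np.clip(taper, 0.0, 1.0)[..., None]
    truth = DenseDeformationField(disp, spec.spacing, (0.0, 0.0, 0.0))
    if any(b.amplitude > 0 for b in spec.bumps):
        _check_fold_free(truth)

    intra = warp_image(pre, truth, background=spec.background_intensity)
    if spec.resection:
        c = spec.resection_center or spec.tumor_center
        r = spec.resection_radius or spec.tumor_radius
        if r is None:
            raise ValueError("resection requested but no region (tumor) defined")
        intra = apply_resection(intra, c, r)
    if spec.noise_sigma > 0:
        intra = ImageVolume(
            intra.data + spec.noise_sigma * rng.standard_normal(spec.grid_size),
            intra.spacing,
            intra.origin,
        )
    return pre, lab_vol, truth, intra


def apply_resection(vol: ImageVolume, center, radius: float,
                    background: float = 0.0) -> ImageVolume:
    """Zero out a spherical region (world mm) of a volume."""
    pts = np.stack(
        np.meshgrid(*[np.arange(n) for n in vol.shape], indexing="ij"), axis=-1
    ).astype(float) * np.asarray(vol.spacing) + np.asarray(vol.origin)
    mask = np.sum((pts - np.asarray(center)) ** 2, axis=-1) <= radius**2
    data = np.array(vol.data, dtype=float, copy=True)
    data[mask] = background
    return ImageVolume(data, vol.spacing, vol.origin)


def true_forward_displacements(truth: DenseDeformationField,
                               points: np.ndarray) -> np.ndarray:
    """Forward displacement of material points implied by the backward truth field.

    This is the quantity a registration solver's vertex displacements should
    recover; see :func:`brainshift.core.invert_displacements`.
    """
    return invert_displacements(truth, points)
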