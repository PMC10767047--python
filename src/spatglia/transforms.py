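"""Geometric transforms between image and spot coordinate frames.

All transforms act on points given as ``(x, y)`` pixel coordinates with
``x`` increasing rightwards (columns) and ``y`` increasing downwards
(rows), 0-based, matching image array indexing ``image[y, x]``.

A :class:`TransformChain` is an ordered composition: ``chain.apply(p)``
applies the first transform, then the second, and so on.  Chains built by
the registration stage map *moving*-image coordinates into the *fixed*
(spot) frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates


def _as_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError(f"points must be (n, 2) (x, y); got shape {pts.shape}")
    return pts


class Transform:
    """Base class; subclasses implement ``apply`` and ``inverse``."""

    def apply(self, points: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def inverse(self) -> "Transform":  # pragma: no cover
        raise NotImplementedError


@dataclass
class AffineTransform(Transform):
    """p' = A p + t with a 2x2 matrix ``A`` and translation ``t``."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    @property
    def homogeneous(self) -> np.ndarray:
        H = np.eye(3)
        H[:2, :2] = self.matrix
        H[:2, 2] = self.translation
        return H


@dataclass
class RigidTransform(Transform):
    """Rotation by ``theta`` (radians, about ``center``) plus translation.

    ``p' = R (p - c) + c + t``.
    """

    theta: float
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)
        self.center = np.asarray(self.center, dtype=float).reshape(2)

    @property
    def rotation(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return (pts - self.center) @ self.rotation.T + self.center + self.translation

    def as_affine(self) -> AffineTransform:
        R = self.rotation
        t = self.center + self.translation - R @ self.center
        return AffineTransform(R, t)

    def inverse(self) -> "RigidTransform":
        # forward: p' = R(p - c) + c + t  =>  p = R^T(p' - c - t) + c,
        # i.e. rotation -theta about c with translation -R^T t.
        return RigidTransform(-self.theta, -self.rotation.T @ self.translation,
                              center=self.center)


@dataclass
class DisplacementField(Transform):
    """Dense nonlinear mapping ``p' = p + u(p)``.

    ``field`` has shape (H, W, 2) storing the (x, y) displacement sampled
    on the pixel grid of the domain frame.  Off-grid points use bilinear
    interpolation; the inverse is approximated by fixed-point iteration.
    """

    displacement: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[2] != 2:
            raise ValueError("displacement must have shape (H, W, 2)")

    def _interp(self, pts: np.ndarray) -> np.ndarray:
        coords = [pts[:, 1], pts[:, 0]]  # (row, col) order for map_coordinates
        ux = map_coordinates(self.displacement[..., 0], coords, order=1, mode="nearest")
        uy = map_coordinates(self.displacement[..., 1], coords, order=1, mode="nearest")
        return np.column_stack([ux, uy])

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts + self._interp(pts)

    def inverse(self, n_iter: int = 20) -> "_IterativeInverse":
        return _IterativeInverse(self, n_iter=n_iter)


@dataclass
class _IterativeInverse(Transform):
    """Approximate inverse of a displacement field (fixed-point iteration)."""

    forward: DisplacementField
    n_iter: int = 20

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        q = pts.copy()
        for _ in range(self.n_iter):
            q = pts - self.forward._interp(q)
        return q

    def inverse(self) -> DisplacementField:
        return self.forward


@dataclass
class TransformChain(Transform):
    """Ordered composition of transforms with named end frames."""

    transforms: list
    domain: str = "moving"
    codomain: str = "fixed"

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        for t in self.transforms:
            pts = t.apply(pts)
        return pts

    def inverse(self) -> "TransformChain":
        return TransformChain([t.inverse() for t in reversed(self.transforms)],
                              domain=self.codomain, codomain=self.domain)

    def __len__(self) -> int:
        return len(self.transforms)


def identity_chain() -> TransformChain:
    return TransformChain([AffineTransform(np.eye(2), np.zeros(2))])


def warp_image(image: np.ndarray, mapping: Transform,
               output_shape: tuple[int, int] | None = None,
               order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Resample ``image`` on an output grid through ``mapping``.

    ``out[y, x] = image(mapping((x, y)))`` — i.e. ``mapping`` sends output
    (destination-frame) coordinates to sampling coordinates in ``image``.
    """
    if output_shape is None:
        output_shape = image.shape[:2]
    h, w = output_shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = mapping.apply(pts)
    sampled = map_coordinates(np.asarray(image, dtype=float),
                              [src[:, 1], src[:, 0]], order=order,
                              mode="constant", cval=cval)
    return sampled.reshape(h, w)
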