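"""Geometric image model and NIfTI I/O.

All spatial quantities are expressed in millimetres.  Voxel indices are
0-based and the continuous index of a voxel centre is integral (the
NIfTI/ITK convention), so the affine of an :class:`Image3D` maps the
continuous index ``v`` to the world point ``origin + direction @
diag(spacing) @ v``.

A 2D multi-slice acquisition is represented as a :class:`Stack` of
:class:`Slice` objects.  Each slice keeps its own rigid pose (pixel index
coordinates to world mm) plus a rigid *correction* transform which is the
motion estimate attached to the slice; the effective pose of a slice is
``correction ∘ pose``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "RigidTransform",
    "Image3D",
    "Slice",
    "Stack",
    "read_image",
    "write_image",
    "split_stack",
    "stack_to_volume",
    "voxel_to_world",
    "world_to_voxel",
    "propagate_mask",
    "linear_intensity_correction",
    "polynomial_bias_correction",
]

_ORTHO_TOL = 1e-6


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass(frozen=True)
class RigidTransform:
    """Rigid body transform ``p -> rotation @ p + translation`` in world mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = _as_vec3(self.translation)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-5):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_params(params, center=None) -> "RigidTransform":
        """Build from 6 parameters: 3 Euler angles (deg, x-y-z extrinsic)
        and 3 translations (mm), rotating about ``center`` (world mm)."""
        rx, ry, rz, tx, ty, tz = np.asarray(params, dtype=float)
        R = _euler_xyz(np.deg2rad([rx, ry, rz]))
        t = np.array([tx, ty, tz])
        if center is not None:
            c = _as_vec3(center)
            t = t + c - R @ c
        return RigidTransform(R, t)

    def params(self, center=None) -> np.ndarray:
        """Inverse of :meth:`from_params`: 3 Euler angles (deg) + 3 mm."""
        angles = np.rad2deg(_euler_angles_xyz(self.rotation))
        t = self.translation.copy()
        if center is not None:
            c = _as_vec3(center)
            t = t - c + self.rotation @ c
        return np.concatenate([angles, t])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def _euler_xyz(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _euler_angles_xyz(R) -> np.ndarray:
    # inverse of _euler_xyz (Rz @ Ry @ Rx); gimbal lock handled crudely,
    # adequate for the small-angle motion estimates this package produces
    sy = -R[2, 0]
    sy = np.clip(sy, -1.0, 1.0)
    ay = np.arcsin(sy)
    if abs(sy) < 1.0 - 1e-9:
        ax = np.arctan2(R[2, 1], R[2, 2])
        az = np.arctan2(R[1, 0], R[0, 0])
    else:
        ax = np.arctan2(-R[1, 2], R[1, 1])
        az = 0.0
    return np.array([ax, ay, az])


@dataclass
class Image3D:
    """Scalar 3D lattice with world geometry.

    Parameters
    ----------
    data : (n0, n1, n2) float array
    spacing : mm per axis, strictly positive
    origin : world position (mm) of voxel (0, 0, 0)
    direction : 3x3 orthonormal matrix of voxel axis directions
    mask : optional binary array of identical dimensions
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be 3D, got {self.data.ndim}D")
        self.spacing = _as_vec3(self.spacing)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be strictly positive")
        self.origin = _as_vec3(self.origin)
        self.direction = np.asarray(self.direction, dtype=float).reshape(3, 3)
        if not np.allclose(self.direction.T @ self.direction, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("direction matrix is not orthonormal")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask dimensions do not match data")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] = self.direction @ np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def like(self, data: np.ndarray, mask=None) -> "Image3D":
        """New image with this geometry and the given voxel data."""
        return Image3D(data, self.spacing.copy(), self.origin.copy(),
                       self.direction.copy(), mask)


def voxel_to_world(img: Image3D, index) -> np.ndarray:
    """Map (possibly fractional, possibly out-of-bounds) voxel indices to
    world mm: ``origin + direction @ diag(spacing) @ index``."""
    idx = np.asarray(index, dtype=float)
    M = img.direction @ np.diag(img.spacing)
    return idx @ M.T + img.origin


def world_to_voxel(img: Image3D, points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    M = img.direction @ np.diag(img.spacing)
    return (pts - img.origin) @ np.linalg.inv(M).T


def read_image(path) -> Image3D:
    """Load a NIfTI-1 volume into an :class:`Image3D`.

    The affine is decomposed into spacing (column norms), direction
    (normalized columns) and origin; intensities are left unmodified.
    """
    nii = nib.load(str(path))
    data = np.asanyarray(nii.dataobj).astype(float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D payload, got {data.ndim}D")
    A = np.asarray(nii.affine, dtype=float)
    if abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: affine is not invertible")
    spacing = np.linalg.norm(A[:3, :3], axis=0)
    direction = A[:3, :3] / spacing
    return Image3D(data, spacing, A[:3, 3], direction)


def write_image(img: Image3D, path) -> None:
    """Write as NIfTI-1 with 32-bit float intensities."""
    nii = nib.Nifti1Image(img.data.astype(np.float32), img.affine)
    nib.save(nii, str(path))


@dataclass
class Slice:
    """One 2D slice acquisition with full 3D geometry.

    ``pose`` maps pixel index coordinates ``(i, j, 0)`` scaled by
    ``(s1, s2, s3)`` to world mm; ``correction`` is the current rigid
    motion estimate, applied in world space on top of the pose.
    """

    pixels: np.ndarray
    in_plane_spacing: tuple
    thickness: float
    pose: RigidTransform
    correction: RigidTransform = field(default_factory=RigidTransform.identity)
    stack_id: int = 0
    slice_index: int = 0
    inlier: bool = True
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        s1, s2 = self.in_plane_spacing
        if s1 <= 0 or s2 <= 0 or self.thickness <= 0:
            raise ValueError("slice spacings must be strictly positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("slice mask dimensions do not match pixels")

    @property
    def spacing3(self) -> np.ndarray:
        return np.array([self.in_plane_spacing[0], self.in_plane_spacing[1],
                         self.thickness])

    def effective_pose(self) -> RigidTransform:
        return self.correction.compose(self.pose)

    def pixel_centers_world(self, step: int = 1) -> np.ndarray:
        """World coordinates of (sub-sampled) pixel centres, shape (n, 3)."""
        n1, n2 = self.pixels.shape
        ii, jj = np.meshgrid(np.arange(0, n1, step), np.arange(0, n2, step),
                             indexing="ij")
        idx = np.stack([ii.ravel(), jj.ravel(), np.zeros(ii.size)], axis=1)
        eff = self.effective_pose()
        return eff.apply(idx * self.spacing3)

    def center_world(self) -> np.ndarray:
        n1, n2 = self.pixels.shape
        c = np.array([(n1 - 1) / 2.0, (n2 - 1) / 2.0, 0.0]) * self.spacing3
        return self.effective_pose().apply(c)


@dataclass
class Stack:
    """Ordered slices sharing acquisition geometry."""

    slices: list
    plane_label: str = "axial"
    stack_id: int = 0

    def __post_init__(self):
        if not self.slices:
            raise ValueError("stack must contain at least one slice")
        sp0 = self.slices[0].in_plane_spacing
        th0 = self.slices[0].thickness
        for s in self.slices:
            if not (np.allclose(s.in_plane_spacing, sp0) and np.isclose(s.thickness, th0)):
                raise ValueError("all slices in a stack must share spacings")
        idx = [s.slice_index for s in self.slices]
        if sorted(idx) != list(range(min(idx), min(idx) + len(idx))):
            raise ValueError("slice_index values must be unique and contiguous")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def in_plane_spacing(self):
        return self.slices[0].in_plane_spacing

    @property
    def thickness(self) -> float:
        return self.slices[0].thickness


def split_stack(img: Image3D, mask: Image3D | None = None) -> Stack:
    """Decompose a loaded multi-slice volume into a :class:`Stack`.

    Slice ``k`` holds the 2D plane ``img.data[:, :, k]``; its pose maps
    pixel index ``(i, j, 0)`` to the world position of voxel ``(i, j, k)``.
    """
    if mask is not None and mask.data.shape != img.data.shape:
        raise ValueError("mask dimensions do not match stack")
    n_slices = img.shape[2]
    slices = []
    for k in range(n_slices):
        t = voxel_to_world(img, (0.0, 0.0, float(k)))
        sl_mask = None
        if mask is not None:
            sl_mask = mask.data[:, :, k] > 0.5
        slices.append(Slice(
            pixels=img.data[:, :, k].copy(),
            in_plane_spacing=(img.spacing[0], img.spacing[1]),
            thickness=float(img.spacing[2]),
            pose=RigidTransform(img.direction.copy(), t),
            stack_id=0,
            slice_index=k,
            mask=sl_mask,
        ))
    return Stack(slices=slices)


def stack_to_volume(stack: Stack) -> Image3D:
    """Reassemble a stack's pixel arrays into a volume on the nominal
    (pose-only, correction ignored) stack lattice."""
    sls = sorted(stack.slices, key=lambda s: s.slice_index)
    data = np.stack([s.pixels for s in sls], axis=2)
    first = sls[0]
    return Image3D(data, first.spacing3, first.pose.translation,
                   first.pose.rotation)


def propagate_mask(mask_stack: Image3D, target: Image3D) -> Image3D:
    """Resample a binary mask onto the target lattice by world-space
    nearest-neighbour lookup; out-of-field voxels are set to 0."""
    src = mask_stack.data > 0.5
    if not src.any():
        warnings.warn("propagate_mask: input mask is empty")
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in target.shape], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    world = voxel_to_world(target, idx)
    vox = world_to_voxel(mask_stack, world)
    out = ndimage.map_coordinates(src.astype(float), vox.T, order=0,
                                  mode="constant", cval=0.0)
    return target.like((out > 0.5).astype(float).reshape(target.shape))


def resample(img: Image3D, target: Image3D, order: int = 1) -> Image3D:
    """Resample an image onto the target lattice through world
    coordinates (trilinear by default); out-of-field voxels are 0."""
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in target.shape], indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    vox = world_to_voxel(img, voxel_to_world(target, idx))
    out = ndimage.map_coordinates(img.data, vox.T, order=order,
                                  mode="constant", cval=0.0)
    return target.like(out.reshape(target.shape))


def _sample_reference_at_slices(stack: Stack, reference: Image3D):
    """Trilinear reference samples at every slice pixel centre."""
    out = []
    for s in stack.slices:
        vox = world_to_voxel(reference, s.pixel_centers_world())
        vals = ndimage.map_coordinates(reference.data, vox.T, order=1,
                                       mode="constant", cval=0.0)
        out.append(vals.reshape(s.pixels.shape))
    return out


def linear_intensity_correction(stack: Stack, reference: Image3D,
                                mask: Image3D | None = None) -> Stack:
    """Per-stack affine intensity map ``a*y + b`` fitted by least squares
    against reference intensities inside the mask, applied to all pixels.

    With fewer than 2 distinct masked intensity pairs (or a constant
    stack) the identity map is applied with a warning.
    """
    ref_samples = _sample_reference_at_slices(stack, reference)
    ys, rs = [], []
    for s, ref2d in zip(stack.slices, ref_samples):
        m = s.mask if s.mask is not None else np.ones_like(s.pixels, dtype=bool)
        if mask is not None:
            vox = world_to_voxel(mask, s.pixel_centers_world())
            in_roi = ndimage.map_coordinates(mask.data, vox.T, order=0,
                                             mode="constant", cval=0.0)
            m = m & (in_roi.reshape(s.pixels.shape) > 0.5)
        ys.append(s.pixels[m])
        rs.append(ref2d[m])
    y = np.concatenate(ys) if ys else np.array([])
    r = np.concatenate(rs) if rs else np.array([])
    a, b = 1.0, 0.0
    if y.size < 2 or np.ptp(y) < 1e-12:
        warnings.warn("linear_intensity_correction: degenerate design, "
                      "identity map applied")
    else:
        A = np.stack([y, np.ones_like(y)], axis=1)
        (a, b), *_ = np.linalg.lstsq(A, r, rcond=None)
    new_slices = [replace(s, pixels=a * s.pixels + b) for s in stack.slices]
    return Stack(new_slices, stack.plane_label, stack.stack_id)


def polynomial_bias_correction(img: Image3D, mask: np.ndarray,
                               order: int = 2) -> Image3D:
    """Divide out a smooth multiplicative intensity field.

    A low-order 3D polynomial is least-squares fitted to the masked log
    intensities and removed, preserving the masked mean.  This is a simple
    preprocessing aid for slowly varying shading; it is off by default in
    all pipelines (digital phantoms carry no shading).
    """
    m = np.asarray(mask, dtype=bool)
    vals = img.data[m]
    pos = vals > 1e-8
    if pos.sum() < 10:
        warnings.warn("polynomial_bias_correction: too few positive voxels")
        return img.like(img.data.copy())
    coords = np.argwhere(m)[pos].astype(float)
    coords = (coords - coords.mean(0)) / (coords.std(0) + 1e-12)
    logv = np.log(vals[pos])
    terms = [np.ones(len(coords))]
    for _ in range(1, order + 1):
        terms.extend([coords[:, a] ** _ for a in range(3)])
    X = np.stack(terms, axis=1)
    beta, *_ = np.linalg.lstsq(X, logv, rcond=None)

    all_idx = np.argwhere(np.ones(img.shape, dtype=bool)).astype(float)
    mu, sd = np.argwhere(m)[pos].astype(float).mean(0), np.argwhere(m)[pos].astype(float).std(0) + 1e-12
    z = (all_idx - mu) / sd
    terms = [np.ones(len(z))]
    for _ in range(1, order + 1):
        terms.extend([z[:, a] ** _ for a in range(3)])
    field_log = np.stack(terms, axis=1) @ beta
    field = np.exp(field_log - field_log.mean()).reshape(img.shape)
    return img.like(img.data / field)
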