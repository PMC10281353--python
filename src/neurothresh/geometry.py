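"""Cell-centred frames, rotated cubic sampling grids, and E-field tensors.

A neuron's local coordinate system uses the somatodendritic axis as the polar
axis ẑc and a stored reference tangent x̂c as the azimuth origin.  The CNN
input is the field sampled on an N×N×N cubic lattice of side ``l`` centred on
the soma, expressed in the (azimuthally rotated) cell frame — so a neuron
rotated together with its grid sees an identical tensor for an identically
co-rotated field, the property that makes the 12 azimuthal rotations valid
data augmentation.

Tensors can be normalized by the centre-voxel field magnitude and optionally
converted to a 4-channel spherical representation (|E|, θE, cos φE, sin φE)
that removes the 0/360° azimuth discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CellFrame",
    "GridSpec",
    "FieldTensor",
    "N_ROTATIONS",
    "ROTATION_STEP_DEG",
    "rotation_angle",
    "build_grid_points",
    "sample_tensor",
    "normalize_by_center",
    "to_spherical_channels",
    "spherical_to_cartesian",
    "upsample_tensor",
]

#: 12 azimuthal rotations in 30° steps
N_ROTATIONS = 12
ROTATION_STEP_DEG = 30.0


class GeometryError(ValueError):
    pass


class DegenerateFieldError(GeometryError):
    """Zero centre-voxel magnitude: the position must be discarded upstream."""


def rotation_angle(j: int) -> float:
    """Azimuthal rotation angle in radians for rotation index j ∈ 0..11."""
    if not 0 <= int(j) < N_ROTATIONS:
        raise GeometryError(f"rotation index must be in 0..{N_ROTATIONS - 1}, got {j}")
    return np.deg2rad(ROTATION_STEP_DEG) * int(j)


@dataclass(frozen=True)
class CellFrame:
    """Right-handed orthonormal cell frame at the soma.

    ẑc is the somatodendritic axis (polar axis); x̂c the azimuth reference;
    ŷc = ẑc × x̂c completes the frame.
    """

    origin: tuple
    z_axis: tuple
    x_axis: tuple

    def __post_init__(self):
        z = np.asarray(self.z_axis, dtype=float)
        x = np.asarray(self.x_axis, dtype=float)
        if abs(np.linalg.norm(z) - 1) > 1e-9 or abs(np.linalg.norm(x) - 1) > 1e-9:
            raise GeometryError("frame axes must be unit vectors")
        if abs(z @ x) > 1e-9:
            raise GeometryError("x̂c must be orthogonal to ẑc")

    @property
    def origin_vec(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def basis(self, rot: int = 0) -> np.ndarray:
        """3×3 matrix whose columns are (x̂c, ŷc, ẑc) rotated by 30°·rot about ẑc."""
        z = np.asarray(self.z_axis, dtype=float)
        x = np.asarray(self.x_axis, dtype=float)
        y = np.cross(z, x)
        a = rotation_angle(rot)
        xr = np.cos(a) * x + np.sin(a) * y
        yr = np.cross(z, xr)
        return np.column_stack([xr, yr, z])

    @staticmethod
    def from_normal(origin, z_axis, reference=None) -> "CellFrame":
        """Build a frame from a polar axis, choosing/projecting the azimuth ref."""
        z = np.asarray(z_axis, dtype=float)
        z = z / np.linalg.norm(z)
        if reference is None:
            reference = np.array([1.0, 0.0, 0.0])
            if abs(reference @ z) > 0.9:
                reference = np.array([0.0, 1.0, 0.0])
        r = np.asarray(reference, dtype=float)
        x = r - (r @ z) * z
        n = np.linalg.norm(x)
        if n < 1e-12:
            raise GeometryError("azimuth reference parallel to polar axis")
        return CellFrame(tuple(np.asarray(origin, float)), tuple(z), tuple(x / n))


@dataclass(frozen=True)
class GridSpec:
    """Cubic sampling lattice: N (odd) points per dimension, side length l mm.

    Defaults follow cell dimensions: 2 mm suits L2/3-like cells, 1.5 mm
    L4/L5-like cells.
    """

    N: int = 9
    l: float = 1.5

    def __post_init__(self):
        if self.N < 3 or self.N % 2 == 0:
            raise GeometryError("N must be odd and ≥ 3")
        if self.l <= 0:
            raise GeometryError("side length must be positive")

    @property
    def spacing(self) -> float:
        return self.l / (self.N - 1)

    @property
    def axis_coords(self) -> np.ndarray:
        """Lattice coordinates along one axis, centred on 0 (mm)."""
        return np.linspace(-self.l / 2, self.l / 2, self.N)


@dataclass(frozen=True)
class FieldTensor:
    """N×N×N×C sampled field tensor in the (rotated) cell frame.

    C=3 holds Cartesian components; C=4 the spherical channels
    (|E|, θE, cos φE, sin φE).  When normalized, the centre magnitude in
    V/m per A/μs is stored so device intensities can be recovered.
    """

    values: np.ndarray
    spec: GridSpec
    channels: str = "cartesian"  # or "spherical"
    normalized: bool = False
    center_magnitude: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        N = self.spec.N
        C = 3 if self.channels == "cartesian" else 4
        if v.shape != (N, N, N, C):
            raise GeometryError(
                f"tensor shape {v.shape} inconsistent with N={N}, channels={self.channels}"
            )
        object.__setattr__(self, "values", v)

    @property
    def center_index(self) -> tuple:
        c = self.spec.N // 2
        return (c, c, c)

    @property
    def center_vector(self) -> np.ndarray:
        return self.values[self.center_index]


def build_grid_points(frame: CellFrame, spec: GridSpec, rot: int = 0) -> np.ndarray:
    """World-frame lattice points (N³×3 mm), centre point exactly the soma.

    Ordering is C-order over (i, j, k) along the rotated (x̂c, ŷc, ẑc) axes.
    """
    c = spec.axis_coords
    ii, jj, kk = np.meshgrid(c, c, c, indexing="ij")
    local = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    R = frame.basis(rot)
    pts = frame.origin_vec + local @ R.T
    pts[local.shape[0] // 2] = frame.origin_vec  # centre exact
    return pts


def sample_tensor(source, frame: CellFrame, spec: GridSpec, rot: int = 0) -> FieldTensor:
    """Sample a field on the rotated grid, expressed in the rotated cell frame."""
    from .field_sources import evaluate_field

    pts = build_grid_points(frame, spec, rot)
    E_world = evaluate_field(source, pts)
    R = frame.basis(rot)
    E_local = E_world @ R  # R.T applied row-wise
    N = spec.N
    return FieldTensor(E_local.reshape(N, N, N, 3), spec, "cartesian", False, None)


def normalize_by_center(t: FieldTensor) -> FieldTensor:
    """Divide all Cartesian components by the centre-voxel magnitude.

    Idempotent up to bookkeeping: renormalizing a normalized tensor leaves
    the values unchanged and keeps the originally stored magnitude.
    """
    if t.channels != "cartesian":
        raise GeometryError("normalize_by_center expects a Cartesian tensor")
    mag = float(np.linalg.norm(t.center_vector))
    if mag <= 0.0:
        raise DegenerateFieldError("zero field magnitude at grid centre")
    stored = t.center_magnitude if t.normalized else mag
    return FieldTensor(t.values / mag, t.spec, "cartesian", True, stored)


def to_spherical_channels(t: FieldTensor) -> FieldTensor:
    """Convert Cartesian channels to (|E|, θE, cos φE, sin φE).

    θE ∈ [0, π] is measured from ẑc, φE from x̂c.  At poles (tangential
    component below 1e-12) the azimuth is fixed to (cos, sin) = (1, 0).
    """
    if t.channels != "cartesian":
        raise GeometryError("expected a Cartesian tensor")
    v = t.values
    mag = np.linalg.norm(v, axis=-1)
    tang = np.hypot(v[..., 0], v[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(mag > 0, np.arccos(np.clip(v[..., 2] / np.maximum(mag, 1e-300), -1, 1)), 0.0)
        cosphi = np.where(tang > 1e-12, v[..., 0] / np.maximum(tang, 1e-300), 1.0)
        sinphi = np.where(tang > 1e-12, v[..., 1] / np.maximum(tang, 1e-300), 0.0)
    out = np.stack([mag, theta, cosphi, sinphi], axis=-1)
    return FieldTensor(out, t.spec, "spherical", t.normalized, t.center_magnitude)


def spherical_to_cartesian(t: FieldTensor) -> FieldTensor:
    """Inverse of :func:`to_spherical_channels` (exact away from poles)."""
    if t.channels != "spherical":
        raise GeometryError("expected a spherical tensor")
    mag, theta, cosphi, sinphi = np.moveaxis(t.values, -1, 0)
    st = np.sin(theta)
    v = np.stack([mag * st * cosphi, mag * st * sinphi, mag * np.cos(theta)], axis=-1)
    return FieldTensor(v, t.spec, "cartesian", t.normalized, t.center_magnitude)


def upsample_tensor(t: FieldTensor, N_target: int) -> FieldTensor:
    """Trilinear upsampling of the lattice to ``N_target`` (odd, ≥ N).

    Exact for affine fields; original lattice values are preserved at
    coincident nodes (N_target = N returns a copy).
    """
    from scipy.interpolate import RegularGridInterpolator

    if N_target < t.spec.N:
        raise GeometryError("N_target must be ≥ the tensor's N")
    if N_target % 2 == 0:
        raise GeometryError("N_target must be odd")
    if N_target == t.spec.N:
        return replace(t, values=t.values.copy())
    c = t.spec.axis_coords
    interp = RegularGridInterpolator((c, c, c), t.values, method="linear")
    new_spec = GridSpec(N_target, t.spec.l)
    cc = new_spec.axis_coords
    ii, jj, kk = np.meshgrid(cc, cc, cc, indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    # clamp FP overshoot of the outermost coordinate into the hull
    pts = np.clip(pts, c[0], c[-1])
    vals = interp(pts).reshape(N_target, N_target, N_target, t.values.shape[-1])
    return FieldTensor(vals, new_spec, t.channels, t.normalized, t.center_magnitude)
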