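"""Analytic and tabulated E-field distributions.

All sources report the induced electric field in V/m *per unit stimulator
intensity*, where intensity is the coil current rate of change in A/μs.
Scaling the stimulator therefore scales every field linearly; thresholds in
stimulator units are obtained by dividing a V/m threshold by the per-unit
field magnitude at the point of interest.

Positions are in mm, world frame.  Five source kinds are provided:

``uniform``
    A constant vector field, the zeroth-order local approximation.
``linear``
    An affine field E(x) = E0 + G (x − x0); useful as an exactly known
    gradient-rich field.
``dipole_coil``
    The primary (magnetically induced) field of a set of magnetic dipoles,
    emulating the spatial structure of a figure-of-eight TMS coil.  The
    secondary charge-accumulation field of a volume conductor is deliberately
    omitted — the goal is realistic spatial structure, not FEM fidelity.
``point_source``
    Monopolar current injection in an infinite homogeneous medium
    (intracortical microstimulation analogue).
``scattered``
    Tabulated vectors at scattered points, locally interpolated from the
    k nearest samples (default k=10) by an affine least-squares fit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "FieldSource",
    "UniformField",
    "LinearField",
    "DipoleCoilField",
    "PointSourceField",
    "ScatteredField",
    "CompositeField",
    "RotatedField",
    "rotate_field",
    "evaluate_field",
    "interpolate_scattered",
    "figure_eight_coil",
    "read_field_table",
    "write_field_table",
]

#: mm exclusion radius around a point current source
POINT_SOURCE_EXCLUSION_MM = 1e-6

#: μ0 / 4π in T·m/A
_MU0_OVER_4PI = 1e-7


class FieldError(ValueError):
    """Raised for domain or configuration errors of a field source."""


def _as_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise FieldError(f"points must be M×3, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise FieldError("points must be finite")
    return pts


class FieldSource:
    """Base class: an E-field evaluable at arbitrary world points."""

    kind: str = "abstract"

    def evaluate(self, points) -> np.ndarray:
        """Return M×3 field vectors (V/m per A/μs) at M×3 points (mm)."""
        raise NotImplementedError

    def scaled(self, s: float) -> "FieldSource":
        """Return a source whose field is ``s`` times this one."""
        return _ScaledField(self, float(s))


@dataclass(frozen=True)
class _ScaledField(FieldSource):
    base: FieldSource
    s: float
    kind = "scaled"

    def evaluate(self, points) -> np.ndarray:
        return self.s * self.base.evaluate(points)


@dataclass(frozen=True)
class UniformField(FieldSource):
    """Constant field: ``magnitude`` V/m per A/μs along unit ``direction``."""

    direction: tuple = (0.0, 0.0, 1.0)
    magnitude: float = 100.0
    kind = "uniform"

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise FieldError("uniform field direction must be a unit vector")

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * np.asarray(self.direction, dtype=float)

    def evaluate(self, points) -> np.ndarray:
        pts = _as_points(points)
        return np.broadcast_to(self.vector, (pts.shape[0], 3)).copy()

    def scaled(self, s: float) -> "UniformField":
        return UniformField(self.direction, self.magnitude * s)


@dataclass(frozen=True)
class LinearField(FieldSource):
    """Affine field E(x) = E0 + G (x − origin).

    G is the 3×3 spatial Jacobian in V/m per mm per A/μs.
    """

    origin: tuple = (0.0, 0.0, 0.0)
    E0: tuple = (100.0, 0.0, 0.0)
    jacobian: tuple = ((0.0,) * 3,) * 3
    kind = "linear"

    @property
    def G(self) -> np.ndarray:
        return np.asarray(self.jacobian, dtype=float).reshape(3, 3)

    def evaluate(self, points) -> np.ndarray:
        pts = _as_points(points)
        rel = pts - np.asarray(self.origin, dtype=float)
        return np.asarray(self.E0, dtype=float) + rel @ self.G.T

    def scaled(self, s: float) -> "LinearField":
        E0 = tuple(s * np.asarray(self.E0, dtype=float))
        G = tuple(map(tuple, s * self.G))
        return LinearField(self.origin, E0, G)


@dataclass(frozen=True)
class DipoleCoilField(FieldSource):
    """Primary induced E-field of a set of magnetic dipoles.

    E(x) = −(μ0/4π) Σ_d (m_d × (x − p_d)) / |x − p_d|³ · dI/dt,
    with positions in mm (converted to m internally), moments in A·m² per
    ampere of coil current, and dI/dt fixed at 1 A/μs so the output is per
    unit stimulator intensity.
    """

    positions: tuple = ()  # D×3 mm
    moments: tuple = ()  # D×3 A·m² per A
    didt_scale: float = 1.0  # A/μs
    standoff_mm: float = 2.0  # coil-to-surface distance, bookkeeping only
    kind = "dipole_coil"

    @property
    def pos(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float).reshape(-1, 3)

    @property
    def mom(self) -> np.ndarray:
        return np.asarray(self.moments, dtype=float).reshape(-1, 3)

    def evaluate(self, points) -> np.ndarray:
        pts = _as_points(points)
        # work in metres; dI/dt in A/s
        r = (pts[:, None, :] - self.pos[None, :, :]) * 1e-3  # M×D×3
        d2 = np.einsum("mdk,mdk->md", r, r)
        inv_r3 = 1.0 / (d2 * np.sqrt(d2))  # 1/|r|³ without fractional pow
        rx, ry, rz = r[..., 0], r[..., 1], r[..., 2]
        mx, my, mz = self.mom[:, 0], self.mom[:, 1], self.mom[:, 2]
        cx = (my * rz - mz * ry) * inv_r3
        cy = (mz * rx - mx * rz) * inv_r3
        cz = (mx * ry - my * rx) * inv_r3
        E = np.stack([cx.sum(axis=1), cy.sum(axis=1), cz.sum(axis=1)], axis=1)
        return E * (-_MU0_OVER_4PI * self.didt_scale * 1e6)

    def scaled(self, s: float) -> "DipoleCoilField":
        return DipoleCoilField(
            self.positions, self.moments, self.didt_scale * s, self.standoff_mm
        )


def figure_eight_coil(
    center=(0.0, 0.0, 15.0),
    wing_offset_mm: float = 22.0,
    wing_radius_mm: float = 12.0,
    n_dipoles_per_wing: int = 16,
    moment_per_dipole: float = 0.05,
    axis=(0.0, 0.0, 1.0),
) -> DipoleCoilField:
    """Build a figure-of-eight coil emulation from two rings of dipoles.

    The two wings carry opposite-sign moments along ``axis`` so the induced
    field adds beneath the coil centre, the familiar focal figure-8 pattern.
    Default moments give ~100 V/m per A/μs roughly 15 mm under the centre.
    """
    center = np.asarray(center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # in-plane basis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(helper @ axis) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    ang = 2 * np.pi * np.arange(n_dipoles_per_wing) / n_dipoles_per_wing
    ring = wing_radius_mm * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    positions, moments = [], []
    for sign in (+1.0, -1.0):
        wing_center = center + sign * wing_offset_mm * u
        positions.append(wing_center + ring)
        moments.append(np.tile(sign * moment_per_dipole * axis, (n_dipoles_per_wing, 1)))
    return DipoleCoilField(
        positions=tuple(map(tuple, np.vstack(positions))),
        moments=tuple(map(tuple, np.vstack(moments))),
    )


@dataclass(frozen=True)
class PointSourceField(FieldSource):
    """Monopolar current source in an infinite homogeneous medium.

    E(x) = I r̂ / (4π σ |r|²); with I in mA, r in mm and σ in S/m the result
    is in V/m (mA·mm⁻² / (S/m) = V/m after unit bookkeeping: 1e-3 A /
    (S/m · 1e-6 m²) = 1e3 V/m per mm² — handled below).
    """

    location: tuple = (0.0, 0.0, 0.0)
    sigma: float = 0.275  # S/m, gray matter
    current_mA: float = 1.0  # per unit stimulator intensity
    kind = "point_source"

    def evaluate(self, points) -> np.ndarray:
        pts = _as_points(points)
        r = pts - np.asarray(self.location, dtype=float)
        dist = np.linalg.norm(r, axis=1)
        if np.any(dist < POINT_SOURCE_EXCLUSION_MM):
            raise FieldError(
                "point inside exclusion radius of point source "
                f"({POINT_SOURCE_EXCLUSION_MM} mm)"
            )
        # I/(4πσ r²) with r in m gives V/m; r here is mm → factor 1e6; I in mA → 1e-3.
        coeff = self.current_mA * 1e-3 / (4 * np.pi * self.sigma) * 1e6
        return coeff * r / dist[:, None] ** 3

    def scaled(self, s: float) -> "PointSourceField":
        return PointSourceField(self.location, self.sigma, self.current_mA * s)


@dataclass
class ScatteredField(FieldSource):
    """Tabulated vectors at scattered points with local affine interpolation.

    Interpolation fits, per query point and per component, a degree-1
    polynomial over the ``k`` nearest samples by least squares and evaluates
    it at the query.  A rank-deficient neighbourhood falls back to
    inverse-distance weighting over the same neighbours.
    """

    points: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    vectors: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    k: int = 10
    kind = "scattered"

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.vectors = np.asarray(self.vectors, dtype=float).reshape(-1, 3)
        if self.points.shape[0] == 0:
            raise FieldError("scattered field requires at least one sample")
        if self.points.shape != self.vectors.shape:
            raise FieldError("points and vectors must have matching shapes")
        if self.points.shape[0] < self.k:
            raise FieldError(
                f"scattered field has {self.points.shape[0]} samples, fewer "
                f"than neighbor count k={self.k}"
            )
        self._tree = cKDTree(self.points)

    def evaluate(self, points) -> np.ndarray:
        return interpolate_scattered(self, points)

    def scaled(self, s: float) -> "ScatteredField":
        return ScatteredField(self.points.copy(), s * self.vectors, self.k)


def interpolate_scattered(fld: ScatteredField, query) -> np.ndarray:
    """Local affine least-squares interpolation over k nearest neighbours."""
    q = _as_points(query)
    dist, idx = fld._tree.query(q, k=fld.k)
    if fld.k == 1:
        dist, idx = dist[:, None], idx[:, None]
    out = np.empty((q.shape[0], 3))
    for i in range(q.shape[0]):
        nbr = fld.points[idx[i]]
        vals = fld.vectors[idx[i]]
        # centred design for conditioning
        A = np.hstack([np.ones((fld.k, 1)), nbr - q[i]])
        sol, _, rank, _ = np.linalg.lstsq(A, vals, rcond=None)
        if rank == 4:
            out[i] = sol[0]  # affine fit evaluated at the query point
        else:
            d = np.maximum(dist[i], 1e-12)
            if d[0] < 1e-12:  # coincident sample
                out[i] = vals[0]
            else:
                w = 1.0 / d
                out[i] = (w[:, None] * vals).sum(axis=0) / w.sum()
    return out


@dataclass(frozen=True)
class CompositeField(FieldSource):
    """Superposition of field sources (fields add linearly)."""

    sources: tuple = ()
    kind = "composite"

    def evaluate(self, points) -> np.ndarray:
        pts = _as_points(points)
        E = np.zeros((pts.shape[0], 3))
        for s in self.sources:
            E += s.evaluate(pts)
        return E

    def scaled(self, s: float) -> "CompositeField":
        return CompositeField(tuple(src.scaled(s) for src in self.sources))


@dataclass(frozen=True)
class RotatedField(FieldSource):
    """A field source rigidly rotated about an axis through ``center``.

    E'(x) = R E(R⁻¹ (x − c) + c), with R the rotation by ``angle_rad`` about
    the unit ``axis``.  Used to state (and test) the rotation equivariance of
    grid sampling: co-rotating field and grid leaves the sampled tensor
    unchanged.
    """

    base: FieldSource = None
    axis: tuple = (0.0, 0.0, 1.0)
    angle_rad: float = 0.0
    center: tuple = (0.0, 0.0, 0.0)
    kind = "rotated"

    def _R(self) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        a = a / np.linalg.norm(a)
        t = self.angle_rad
        K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
        return np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)

    def evaluate(self, points) -> np.ndarray:
        pts = _as_points(points)
        R = self._R()
        c = np.asarray(self.center, dtype=float)
        back = (pts - c) @ R + c  # R⁻¹ applied row-wise
        return self.base.evaluate(back) @ R.T


def rotate_field(source: FieldSource, axis, angle_rad: float, center=(0, 0, 0)) -> RotatedField:
    """Rigidly rotate a field source about an axis through ``center``."""
    return RotatedField(source, tuple(np.asarray(axis, float)), float(angle_rad), tuple(np.asarray(center, float)))


def evaluate_field(source: FieldSource, points) -> np.ndarray:
    """Evaluate any field source at M×3 points (mm) → M×3 V/m per A/μs."""
    E = source.evaluate(points)
    if not np.all(np.isfinite(E)):
        raise FieldError("field evaluation produced non-finite vectors")
    return E


# ---------------------------------------------------------------------------
# Tabulated field file I/O: TSV/CSV with header  x y z Ex Ey Ez
# ---------------------------------------------------------------------------

_COLUMNS = ["x", "y", "z", "Ex", "Ey", "Ez"]


def read_field_table(path_or_buf, k: int = 10) -> ScatteredField:
    """Read a tabulated field (columns x y z Ex Ey Ez; '#' comments)."""
    import pandas as pd

    df = pd.read_csv(path_or_buf, sep=None, engine="python", comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise FieldError(f"field table missing columns: {missing}")
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    vec = df[["Ex", "Ey", "Ez"]].to_numpy(dtype=float)
    return ScatteredField(pts, vec, k=min(k, len(df)))


def write_field_table(path, points, vectors, comment: str | None = None) -> None:
    """Write a tabulated field as TSV (units mm and V/m per A/μs)."""
    import pandas as pd

    pts = _as_points(points)
    vec = np.asarray(vectors, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(np.hstack([pts, vec]), columns=_COLUMNS)
    buf = io.StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
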