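"""E-field characterization metrics and threshold-error summaries.

* Jacobian-norm gradient metric: per grid node, the Frobenius norm of the
  3×3 spatial Jacobian of the field (all nine ∂E_a/∂b terms), summarized by
  the median over all N³ nodes.  In center-normalized mode the field is
  first divided by the centre-node magnitude, making the metric a relative
  gradient in 1/mm.
* Interpolated-field errors at the AP initiation site: absolute percent
  error in magnitude and the angle (rad) between interpolated and actual
  vectors.
* Threshold error summaries: MAPE, median APE, R² (from an ordinary
  least-squares fit of predicted on actual), and signed percent errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FieldTensor, GridSpec

__all__ = [
    "GradientMetric",
    "APSiteError",
    "jacobian_norm_metric",
    "interp_field_at_point",
    "ap_site_error",
    "error_summaries",
]


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class GradientMetric:
    node_norms: np.ndarray  # N×N×N Frobenius norms
    median: float
    mode: str  # "center-normalized" (1/mm) or "raw" (V/m per mm)


@dataclass(frozen=True)
class APSiteError:
    interp: np.ndarray
    actual: np.ndarray
    magnitude_percent_error: float
    signed_percent_error: float
    angle_error_rad: float


def jacobian_norm_metric(t: FieldTensor, mode: str = "center-normalized") -> GradientMetric:
    """Median Frobenius norm of the per-node field Jacobian.

    Derivatives use central differences at interior nodes and one-sided
    differences at faces (exact for affine fields).  Requires N ≥ 3 and a
    Cartesian tensor.
    """
    if t.channels != "cartesian":
        raise MetricsError("gradient metric requires a Cartesian tensor")
    if t.spec.N < 3:
        raise MetricsError("N ≥ 3 required for a derivative stencil")
    v = t.values
    if mode == "center-normalized":
        mag = np.linalg.norm(t.center_vector)
        if mag <= 0:
            raise MetricsError("zero centre magnitude in center-normalized mode")
        v = v / mag
    elif mode != "raw":
        raise MetricsError(f"unknown mode '{mode}'")
    h = t.spec.spacing
    # np.gradient: central interior, one-sided faces — 3 spatial axes × 3 components
    grads = np.gradient(v, h, h, h, axis=(0, 1, 2))
    J = np.stack(grads, axis=-1)  # N×N×N×(component a)×(axis b) = ∂E_a/∂b
    norms = np.sqrt(np.sum(J ** 2, axis=(-2, -1)))
    return GradientMetric(norms, float(np.median(norms)), mode)


def interp_field_at_point(t: FieldTensor, point_cell_frame) -> np.ndarray:
    """Trilinear interpolation of the tensor at a cell-frame point (mm)."""
    from scipy.interpolate import RegularGridInterpolator

    p = np.asarray(point_cell_frame, dtype=float)
    c = t.spec.axis_coords
    if np.any(p < c[0] - 1e-12) or np.any(p > c[-1] + 1e-12):
        raise MetricsError(f"point {p} outside the sampling cube (±{c[-1]} mm)")
    interp = RegularGridInterpolator((c, c, c), t.values, method="linear")
    return interp(np.clip(p, c[0], c[-1])[None])[0]


def ap_site_error(interp, actual) -> APSiteError:
    """Magnitude percent error and angle error between two field vectors."""
    vi = np.asarray(interp, dtype=float)
    va = np.asarray(actual, dtype=float)
    na = np.linalg.norm(va)
    ni = np.linalg.norm(vi)
    if na <= 0:
        raise MetricsError("actual vector must be nonzero")
    signed = 100.0 * (ni - na) / na
    if ni <= 0:
        angle = np.pi  # undefined direction → sentinel
    else:
        angle = float(np.arccos(np.clip(vi @ va / (ni * na), -1.0, 1.0)))
    return APSiteError(vi, va, abs(signed), signed, angle)


def error_summaries(pred, actual) -> dict:
    """MAPE, median APE, R² and signed percent errors of threshold estimates.

    R² is the coefficient of determination of a simple linear regression of
    predicted on actual (the square of their correlation).
    """
    p = np.asarray(pred, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.size < 2:
        raise MetricsError("need ≥ 2 aligned prediction/actual pairs")
    if np.any(a <= 0):
        raise MetricsError("actual thresholds must be positive")
    signed = 100.0 * (p - a) / a
    ape = np.abs(signed)
    if np.allclose(p, p[0]) or np.allclose(a, a[0]):
        r2 = 1.0 if np.allclose(p, a) else 0.0
    else:
        r2 = float(np.corrcoef(p, a)[0, 1] ** 2)
    return {
        "mape": float(np.mean(ape)),
        "median_ape": float(np.median(ape)),
        "r2": r2,
        "signed_percent_errors": signed,
    }
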