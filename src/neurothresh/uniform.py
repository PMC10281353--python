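"""Baseline threshold estimation under the uniform-field approximation.

Thresholds are pre-computed for uniform E-fields applied over a grid of
directions (polar θ, azimuthal φ in the cell frame, default 5° steps — 2522
unique directions after collapsing the poles), forming a
threshold–direction map.  To estimate the threshold of a neuron in a
non-uniform field, the somatic E-field vector is rotated into the cell
frame, its (θ, φ) computed, and the map bilinearly interpolated (with
explicit azimuthal wraparound); dividing the interpolated V/m threshold by
the somatic field magnitude per A/μs converts to stimulator intensity.

The uniform-field extracellular potential at a compartment (x, y, z) in mm is

    Ve = −|E| (x sinθ cosφ + y sinθ sinφ + z cosθ)   [mV],

with the soma (origin) at zero potential.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DirectionAngles",
    "ThresholdDirectionMap",
    "extracellular_potential",
    "direction_set",
    "build_map",
    "map_for_neuron",
    "estimate_threshold",
    "save_map",
    "load_map",
]


class UniformEstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class DirectionAngles:
    """Uniform-field direction: polar θ ∈ [0,180]°, azimuth φ ∈ [0,360)°."""

    theta_deg: float
    phi_deg: float

    def __post_init__(self):
        if not 0.0 <= self.theta_deg <= 180.0:
            raise UniformEstimatorError("θ must be in [0, 180]°")
        if not 0.0 <= self.phi_deg < 360.0:
            raise UniformEstimatorError("φ must be in [0, 360)°")

    @property
    def unit_vector(self) -> np.ndarray:
        t = np.deg2rad(self.theta_deg)
        p = np.deg2rad(self.phi_deg)
        return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def extracellular_potential(compartments, magnitude: float, direction: DirectionAngles) -> np.ndarray:
    """Uniform-field potentials (mV) at M×3 cell-frame compartments (mm)."""
    if magnitude < 0:
        raise UniformEstimatorError("field magnitude must be ≥ 0")
    xyz = np.atleast_2d(np.asarray(compartments, dtype=float))
    return -magnitude * (xyz @ direction.unit_vector)


def direction_set(step_deg: float = 5.0) -> list:
    """Unique directions on the (θ, φ) grid; poles deduplicated.

    Count = (180/step − 1) · (360/step) + 2; e.g. 2522 for 5° steps.
    """
    if 180.0 % step_deg or 360.0 % step_deg:
        raise UniformEstimatorError("step must divide both 180 and 360")
    out = [DirectionAngles(0.0, 0.0)]
    for t in np.arange(step_deg, 180.0, step_deg):
        for p in np.arange(0.0, 360.0, step_deg):
            out.append(DirectionAngles(float(t), float(p)))
    out.append(DirectionAngles(180.0, 0.0))
    return out


@dataclass(frozen=True)
class ThresholdDirectionMap:
    """Thresholds (V/m) on the full (θ, φ) lattice, pole rows replicated.

    ``thresholds`` has shape (180/step + 1) × (360/step); rows for θ=0 and
    θ=180 are constant across φ (stored replicated for interpolation
    convenience).
    """

    thresholds: np.ndarray
    step_deg: float = 5.0
    neuron_id: str = ""
    waveform: str = "monophasic"

    def __post_init__(self):
        nt = int(round(180 / self.step_deg)) + 1
        np_ = int(round(360 / self.step_deg))
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.shape != (nt, np_):
            raise UniformEstimatorError(f"map must be {nt}×{np_}, got {thr.shape}")
        for row in (0, -1):
            finite = thr[row][np.isfinite(thr[row])]
            if finite.size and np.ptp(finite) > 1e-9:
                raise UniformEstimatorError("pole rows must be constant across φ")
        object.__setattr__(self, "thresholds", thr)

    @property
    def theta_grid(self) -> np.ndarray:
        return np.arange(0.0, 180.0 + self.step_deg / 2, self.step_deg)

    @property
    def phi_grid(self) -> np.ndarray:
        return np.arange(0.0, 360.0, self.step_deg)


def build_map(threshold_fn, step_deg: float = 5.0, neuron_id: str = "",
              waveform: str = "monophasic") -> ThresholdDirectionMap:
    """Evaluate ``threshold_fn(DirectionAngles) -> V/m`` on the full lattice."""
    nt = int(round(180 / step_deg)) + 1
    np_ = int(round(360 / step_deg))
    thr = np.empty((nt, np_))
    for i, t in enumerate(np.arange(0.0, 180.0 + step_deg / 2, step_deg)):
        if i in (0, nt - 1):
            v = threshold_fn(DirectionAngles(float(t), 0.0))
            _check_value(v)
            thr[i, :] = v
            continue
        for j, p in enumerate(np.arange(0.0, 360.0, step_deg)):
            v = threshold_fn(DirectionAngles(float(t), float(p)))
            _check_value(v)
            thr[i, j] = v
    return ThresholdDirectionMap(thr, step_deg, neuron_id, waveform)


def _check_value(v: float) -> None:
    if np.isfinite(v) and v < 0:
        raise UniformEstimatorError("threshold function returned a negative value")


def map_for_neuron(neuron, waveform, step_deg: float = 5.0) -> ThresholdDirectionMap:
    """Threshold–direction map of a surrogate neuron (closed-form per direction)."""
    return build_map(
        lambda d: neuron.uniform_threshold(d.unit_vector, waveform),
        step_deg,
        neuron_id=f"{neuron.cell_type}_clone{neuron.clone_id}",
        waveform=waveform.label,
    )


def estimate_threshold(tdm: ThresholdDirectionMap, E_soma_cell_frame) -> tuple:
    """Estimate (V/m, A/μs) thresholds from the somatic field vector.

    ``E_soma_cell_frame`` is the somatic E-field vector per unit stimulator
    intensity, already rotated into the cell frame used by the map.  Bilinear
    interpolation on the (θ, φ) lattice with azimuthal wraparound.
    """
    E = np.asarray(E_soma_cell_frame, dtype=float)
    mag = np.linalg.norm(E)
    if mag <= 0:
        raise UniformEstimatorError("zero somatic field vector")
    theta = np.rad2deg(np.arccos(np.clip(E[2] / mag, -1.0, 1.0)))
    phi = np.rad2deg(np.arctan2(E[1], E[0])) % 360.0
    step = tdm.step_deg
    thr = tdm.thresholds
    it = min(int(theta // step), thr.shape[0] - 2)
    ip = int(phi // step) % thr.shape[1]
    ft = theta / step - it
    fp = phi / step - ip
    ip1 = (ip + 1) % thr.shape[1]  # φ wraparound: column 360° = column 0°
    v = ((1 - ft) * (1 - fp) * thr[it, ip]
         + (1 - ft) * fp * thr[it, ip1]
         + ft * (1 - fp) * thr[it + 1, ip]
         + ft * fp * thr[it + 1, ip1])
    return float(v), float(v / mag)


# ---------------------------------------------------------------------------
# Map file I/O: TSV matrix + JSON sidecar
# ---------------------------------------------------------------------------

def save_map(tdm: ThresholdDirectionMap, tsv_path, sidecar_path=None) -> None:
    import pandas as pd

    df = pd.DataFrame(tdm.thresholds, index=tdm.theta_grid, columns=tdm.phi_grid)
    df.index.name = "theta_deg"
    df.to_csv(tsv_path, sep="\t")
    sidecar_path = sidecar_path or str(tsv_path) + ".json"
    with open(sidecar_path, "w") as f:
        json.dump({
            "neuron_id": tdm.neuron_id,
            "waveform": tdm.waveform,
            "step_deg": tdm.step_deg,
            "units": "V/m (soma-referenced threshold)",
        }, f, indent=1)


def load_map(tsv_path, sidecar_path=None) -> ThresholdDirectionMap:
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    sidecar_path = sidecar_path or str(tsv_path) + ".json"
    with open(sidecar_path) as f:
        meta = json.load(f)
    return ThresholdDirectionMap(df.to_numpy(), meta["step_deg"],
                                 meta["neuron_id"], meta["waveform"])
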