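"""Threshold dataset construction: sample enumeration, tensor/threshold
pairing, train/validation split, and median-label collapsing.

A sample is identified by (cell type, clone, position, stimulation-direction
label, azimuthal rotation, waveform).  A full training set enumerates
positions × directions × rotations; e.g. 2999 positions × 4 directions × 12
rotations gives 143,952 unique field–threshold combinations.  Records whose
neuron is not activatable (or whose soma field vanishes) are dropped and
counted.

``collapse_median`` builds the labels for population-level ("median")
estimators: for each (position, direction) the label is the median threshold
over clones × rotations, paired with each of the 12 rotated tensors of a
reference clone — one inference then replaces the 60 (5 clones × 12
rotations) needed to compute the same statistic from cell-specific
estimators.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .geometry import GridSpec, N_ROTATIONS, to_spherical_channels

__all__ = [
    "SampleKey",
    "ThresholdDataset",
    "enumerate_samples",
    "build_dataset",
    "split_train_val",
    "collapse_median",
    "convert_to_spherical",
    "save_dataset",
    "load_dataset",
]


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class SampleKey:
    cell_type: str
    clone_id: int
    position_id: int
    direction: str  # e.g. P-A, A-P, L-M, M-L
    rotation: int  # 0..11
    waveform: str

    def __post_init__(self):
        if not 0 <= self.rotation < N_ROTATIONS:
            raise DatasetError(f"rotation must be 0..{N_ROTATIONS - 1}")


@dataclass
class ThresholdDataset:
    """Aligned (tensor, threshold, key) records plus provenance metadata."""

    tensors: np.ndarray  # S×N×N×N×C
    thresholds: np.ndarray  # S, V/m soma-referenced
    soma_magnitudes: np.ndarray  # S, V/m per A/μs (for device-intensity conversion)
    keys: list  # S SampleKeys
    spec: GridSpec
    channels: str = "cartesian"
    normalized: bool = True
    waveform: str = "monophasic"
    seed: int | None = None
    n_dropped: int = 0
    role: str = "full"  # full/train/val/test

    def __post_init__(self):
        S = len(self.keys)
        if not (self.tensors.shape[0] == self.thresholds.shape[0] == S):
            raise DatasetError("tensors, thresholds and keys must be aligned 1:1")
        if len(set(self.keys)) != S:
            raise DatasetError("duplicate sample keys")
        if S and (np.any(~np.isfinite(self.thresholds)) or np.any(self.thresholds <= 0)):
            raise DatasetError("thresholds must be positive and finite")

    def __len__(self) -> int:
        return len(self.keys)

    def subset(self, indices, role: str) -> "ThresholdDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            tensors=self.tensors[idx],
            thresholds=self.thresholds[idx],
            soma_magnitudes=self.soma_magnitudes[idx],
            keys=[self.keys[i] for i in idx],
            role=role,
        )


def enumerate_samples(
    n_positions: int,
    directions,
    n_rotations: int = N_ROTATIONS,
    cell_type: str = "L5_PC",
    clone_id: int = 1,
    waveform: str = "monophasic",
) -> list:
    """Position-major, then direction, then rotation enumeration of keys."""
    if n_positions < 1 or len(directions) < 1 or n_rotations < 1:
        raise DatasetError("all counts must be ≥ 1")
    return [
        SampleKey(cell_type, clone_id, p, d, r, waveform)
        for p in range(n_positions)
        for d in directions
        for r in range(n_rotations)
    ]


def build_dataset(
    population,
    neuron,
    sources: dict,
    spec: GridSpec,
    waveform,
    seed: int | None = None,
    rotations=range(N_ROTATIONS),
    channels: str = "cartesian",
) -> ThresholdDataset:
    """Assemble one record per (position × direction × rotation).

    ``sources`` maps direction labels to field sources.  Tensors are
    normalized by the centre magnitude (and optionally converted to
    spherical channels afterwards, making the |E| channel relative).
    Not-activatable or zero-soma-field records are dropped and counted.
    """
    from .field_sources import evaluate_field
    from .geometry import FieldTensor, build_grid_points
    from .surrogate import DEFAULT_CAP, DRIVE_EPS

    tensors, thresholds, mags, keys = [], [], [], []
    n_dropped = 0
    rotations = list(rotations)
    N3 = spec.N ** 3
    K = neuron.K
    P, U, w = neuron.positions_arr, neuron.directions_arr, neuron.weights_arr
    for placement in population:
        frame = placement.frame
        for label, source in sources.items():
            # one batched field evaluation per (position, direction): all 12
            # rotated grids + terminal sets + the soma point
            try:
                Rs = [frame.basis(rot) for rot in rotations]
                grid_pts = np.vstack([build_grid_points(frame, spec, rot) for rot in rotations])
                term_pts = np.vstack([frame.origin_vec + P @ R.T for R in Rs])
                E_all = evaluate_field(
                    source, np.vstack([grid_pts, term_pts, frame.origin_vec[None]]))
            except Exception:
                n_dropped += len(rotations)
                continue
            E_grid, E_term = E_all[: len(rotations) * N3], E_all[len(rotations) * N3: -1]
            soma_mag = float(np.linalg.norm(E_all[-1]))
            if soma_mag <= 0.0:
                n_dropped += len(rotations)
                continue
            for i, rot in enumerate(rotations):
                R = Rs[i]
                drives = np.maximum(0.0, np.sum(E_term[i * K:(i + 1) * K] * (U @ R.T), axis=1))
                active = drives > DRIVE_EPS
                if not np.any(active):
                    n_dropped += 1
                    continue
                s_star = waveform.factor * float(np.min(w[active] / drives[active]))
                if s_star > DEFAULT_CAP:
                    n_dropped += 1
                    continue
                local = (E_grid[i * N3:(i + 1) * N3] @ R).reshape(spec.N, spec.N, spec.N, 3)
                center_mag = float(np.linalg.norm(local[spec.N // 2, spec.N // 2, spec.N // 2]))
                if center_mag <= 0.0:
                    n_dropped += 1
                    continue
                t = FieldTensor(local / center_mag, spec, "cartesian", True, center_mag)
                if channels == "spherical":
                    t = to_spherical_channels(t)
                tensors.append(t.values)
                thresholds.append(s_star * soma_mag)
                mags.append(center_mag)
                keys.append(
                    SampleKey(neuron.cell_type, neuron.clone_id, placement.position_id,
                              label, rot, waveform.label)
                )
    if not tensors:
        raise DatasetError("all records were dropped")
    return ThresholdDataset(
        np.asarray(tensors), np.asarray(thresholds), np.asarray(mags), keys,
        spec, channels, True, waveform.label, seed, n_dropped,
    )


def convert_to_spherical(ds: ThresholdDataset) -> ThresholdDataset:
    """Re-express a Cartesian dataset's tensors in the 4 spherical channels.

    Record identity (keys, thresholds, magnitudes) is preserved, so the two
    representations can be compared on literally the same samples.
    """
    from .geometry import FieldTensor

    if ds.channels != "cartesian":
        raise DatasetError("expected a Cartesian dataset")
    out = np.asarray([
        to_spherical_channels(FieldTensor(t, ds.spec, "cartesian", ds.normalized, None)).values
        for t in ds.tensors
    ])
    return replace(ds, tensors=out, channels="spherical")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_val(ds: ThresholdDataset, frac_train: float = 0.85, seed: int = 0,
                    by_position: bool = False):
    """Disjoint, exhaustive 85/15 split, stratified by direction label.

    |train| = round-half-up(frac_train · S) overall; within each direction
    stratum the same rule is applied and strata are trimmed/topped up to hit
    the global count exactly.  ``by_position`` groups whole positions into
    the same side instead of splitting record-wise.
    """
    S = len(ds)
    if S < 2:
        raise DatasetError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    n_train = _round_half_up(frac_train * S)
    train_idx = []
    if by_position:
        positions = sorted({k.position_id for k in ds.keys})
        perm = rng.permutation(len(positions))
        n_pos_train = _round_half_up(frac_train * len(positions))
        train_pos = {positions[i] for i in perm[:n_pos_train]}
        train_idx = [i for i, k in enumerate(ds.keys) if k.position_id in train_pos]
    else:
        by_dir = {}
        for i, k in enumerate(ds.keys):
            by_dir.setdefault(k.direction, []).append(i)
        for d in sorted(by_dir):
            idx = np.asarray(by_dir[d])
            perm = rng.permutation(len(idx))
            n_d = _round_half_up(frac_train * len(idx))
            train_idx.extend(idx[perm[:n_d]].tolist())
        # adjust to the exact global count (stratum rounding can drift by ±1)
        train_set = set(train_idx)
        if len(train_idx) > n_train:
            drop = rng.permutation(sorted(train_set))[: len(train_idx) - n_train]
            train_set -= set(drop.tolist())
        elif len(train_idx) < n_train:
            pool = [i for i in range(S) if i not in train_set]
            add = rng.permutation(pool)[: n_train - len(train_idx)]
            train_set |= set(add.tolist())
        train_idx = sorted(train_set)
    val_idx = sorted(set(range(S)) - set(train_idx))
    return ds.subset(train_idx, "train"), ds.subset(val_idx, "val")


def collapse_median(ds: ThresholdDataset, n_clones: int = 5,
                    n_rotations: int = N_ROTATIONS) -> ThresholdDataset:
    """Median-label dataset for population-level estimators.

    For each (position, direction): the label is the median threshold over
    all clones × rotations (even counts use the mean of the two central
    order statistics); the 12 rotated tensors of the lowest clone id are
    retained, each paired with the identical median label.
    """
    groups = {}
    for i, k in enumerate(ds.keys):
        groups.setdefault((k.position_id, k.direction), []).append(i)
    tensors, thresholds, mags, keys = [], [], [], []
    ref_clone = min(k.clone_id for k in ds.keys)
    for (pos, direction), idx in sorted(groups.items()):
        seen = {(ds.keys[i].clone_id, ds.keys[i].rotation) for i in idx}
        clones = sorted({c for c, _ in seen})
        expected = {(c, r) for c in clones for r in range(n_rotations)}
        if len(clones) != n_clones or seen != expected:
            missing = sorted(expected - seen)
            raise DatasetError(
                f"position {pos} direction {direction}: incomplete clone×rotation "
                f"coverage, missing {missing if missing else 'clones'}"
            )
        med = float(np.median(ds.thresholds[idx]))
        for i in idx:
            k = ds.keys[i]
            if k.clone_id != ref_clone:
                continue
            tensors.append(ds.tensors[i])
            thresholds.append(med)
            mags.append(ds.soma_magnitudes[i])
            keys.append(replace_key(k, clone_id=0))
    return ThresholdDataset(
        np.asarray(tensors), np.asarray(thresholds), np.asarray(mags), keys,
        ds.spec, ds.channels, ds.normalized, ds.waveform, ds.seed, ds.n_dropped,
        role="median",
    )


def replace_key(k: SampleKey, **kw) -> SampleKey:
    d = dict(cell_type=k.cell_type, clone_id=k.clone_id, position_id=k.position_id,
             direction=k.direction, rotation=k.rotation, waveform=k.waveform)
    d.update(kw)
    return SampleKey(**d)


# ---------------------------------------------------------------------------
# HDF5 archive
# ---------------------------------------------------------------------------

def save_dataset(ds: ThresholdDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("tensors", data=ds.tensors, compression="gzip")
        f.create_dataset("thresholds", data=ds.thresholds)
        f.create_dataset("soma_magnitudes", data=ds.soma_magnitudes)
        keys_json = [json.dumps(vars(k)) for k in ds.keys]
        f.create_dataset("keys", data=np.array(keys_json, dtype=h5py.string_dtype()))
        f.attrs.update(
            N=ds.spec.N, l=ds.spec.l, channels=ds.channels,
            normalized=ds.normalized, waveform=ds.waveform,
            seed=-1 if ds.seed is None else ds.seed,
            n_dropped=ds.n_dropped, role=ds.role,
        )


def load_dataset(path) -> ThresholdDataset:
    import h5py

    with h5py.File(path, "r") as f:
        keys = [SampleKey(**json.loads(s)) for s in f["keys"].asstr()]
        seed = int(f.attrs["seed"])
        return ThresholdDataset(
            f["tensors"][...], f["thresholds"][...], f["soma_magnitudes"][...], keys,
            GridSpec(int(f.attrs["N"]), float(f.attrs["l"])),
            str(f.attrs["channels"]), bool(f.attrs["normalized"]),
            str(f.attrs["waveform"]), None if seed < 0 else seed,
            int(f.attrs["n_dropped"]), str(f.attrs["role"]),
        )
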