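"""Surrogate neurons with closed-form activation thresholds.

Biophysically detailed cable models are expensive; here they are replaced by
a terminal-based surrogate that captures the mechanism by which TMS activates
cortical neurons — action potentials start at axon terminals aligned with
the local E-field, and thresholds fall with local field magnitude.  Each
surrogate has K terminals, terminal k at position p_k (cell frame, mm) with
preferred direction û_k and sensitivity weight w_k (V/m).  Under a field E
per unit stimulator intensity, terminal k's drive is

    drive_k = max(0, E(world(p_k)) · world(û_k)),

and the stimulator-intensity threshold is

    s* = c_w · min_{k: drive_k > ε} w_k / drive_k,

with c_w a per-waveform factor (the surrogate has no temporal dynamics, so
waveform dependence enters only through this factor, mirroring the fact that
each trained estimator is waveform-specific).  The soma-referenced threshold
in V/m is s* · |E(soma)| per unit intensity.  If no terminal has positive
drive the neuron is "not activatable" (sentinel, capped).

This closed form is exactly monotone in intensity, so it doubles as a spike
oracle for validating the 2%-window binary threshold search that the full
simulations use.

The module also provides population placement on a parametric cortical sheet
(soma depths per layer, somatodendritic axis along the inward surface
normal, 12 azimuthal rotations in 30° steps), morphological "clones", pulse
waveform templates, and quasipotential integration along a morphology tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CellFrame, N_ROTATIONS

__all__ = [
    "SurrogateNeuron",
    "PulseWaveform",
    "PlacementSheet",
    "Placement",
    "MorphologyTree",
    "NOT_ACTIVATABLE",
    "DEFAULT_CAP",
    "DRIVE_EPS",
    "WAVEFORM_FACTORS",
    "monophasic_waveform",
    "biphasic_waveform",
    "default_neuron",
    "generate_population",
    "generate_clones",
    "analytic_threshold",
    "spike_oracle",
    "binary_search_threshold",
    "quasipotential",
    "resample_tree",
]

#: terminals with drive below this (V/m per unit intensity) are inactive
DRIVE_EPS = 1e-9

#: default intensity cap (A/μs) above which a neuron is "not activatable"
DEFAULT_CAP = 1e5

#: sentinel returned for not-activatable configurations
NOT_ACTIVATABLE = np.inf

#: default waveform threshold factors c_w (biphasic pulses are somewhat less
#: efficient per unit peak dI/dt than monophasic ones)
WAVEFORM_FACTORS = {"monophasic": 1.0, "biphasic": 1.15}

#: default terminal counts per cell-type label
DEFAULT_TERMINAL_COUNTS = {"L23_PC": 8, "L4_LBC": 12, "L5_PC": 10}

#: default grid side length per cell type (mm)
DEFAULT_GRID_SIDE = {"L23_PC": 2.0, "L4_LBC": 1.5, "L5_PC": 1.5}


class SurrogateError(ValueError):
    pass


@dataclass(frozen=True)
class PulseWaveform:
    """Normalized pulse waveform: unit peak amplitude, sample step dt (μs)."""

    label: str
    samples: tuple
    dt: float = 5.0

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if abs(np.max(np.abs(s)) - 1.0) > 1e-9:
            raise SurrogateError("waveform must be normalized to unit peak amplitude")

    @property
    def factor(self) -> float:
        try:
            return WAVEFORM_FACTORS[self.label]
        except KeyError:
            raise SurrogateError(f"no threshold factor for waveform '{self.label}'")


def monophasic_waveform(dt: float = 5.0, duration_us: float = 300.0) -> PulseWaveform:
    """Synthetic monophasic template: fast rise, overdamped decay."""
    t = np.arange(0.0, duration_us, dt)
    s = np.exp(-t / 70.0) - np.exp(-t / 15.0)
    s = s / np.max(np.abs(s))
    return PulseWaveform("monophasic", tuple(s), dt)


def biphasic_waveform(dt: float = 5.0, duration_us: float = 300.0) -> PulseWaveform:
    """Synthetic biphasic template: damped cosine cycle."""
    t = np.arange(0.0, duration_us, dt)
    s = np.cos(2 * np.pi * t / 250.0) * np.exp(-t / 200.0)
    s = s / np.max(np.abs(s))
    return PulseWaveform("biphasic", tuple(s), dt)


@dataclass(frozen=True)
class SurrogateNeuron:
    """Terminal-based surrogate neuron (see module docstring).

    Terminal positions/directions are in the cell frame; positions must lie
    within the cell's grid side length of the origin so the sampling grid
    covers every potential activation site.
    """

    cell_type: str
    clone_id: int
    positions: tuple  # K×3 mm, cell frame
    directions: tuple  # K×3 unit vectors, cell frame
    weights: tuple  # K, V/m
    grid_side: float = 1.5

    def __post_init__(self):
        P = self.positions_arr
        U = self.directions_arr
        w = self.weights_arr
        if len(P) < 1:
            raise SurrogateError("surrogate needs at least one terminal")
        if not (len(P) == len(U) == len(w)):
            raise SurrogateError("terminal arrays must have equal length")
        if np.any(np.abs(np.linalg.norm(U, axis=1) - 1) > 1e-9):
            raise SurrogateError("terminal directions must be unit vectors")
        if np.any(w <= 0):
            raise SurrogateError("terminal weights must be positive")
        if np.any(np.linalg.norm(P, axis=1) > self.grid_side):
            raise SurrogateError("terminal positions must lie within the grid side length")

    @property
    def positions_arr(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float).reshape(-1, 3)

    @property
    def directions_arr(self) -> np.ndarray:
        return np.asarray(self.directions, dtype=float).reshape(-1, 3)

    @property
    def weights_arr(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float).reshape(-1)

    @property
    def K(self) -> int:
        return len(self.weights_arr)

    def uniform_threshold(self, direction, waveform: PulseWaveform) -> float:
        """Closed-form threshold (V/m) for a uniform field along ``direction``.

        Positions drop out for uniform fields; only alignment with the
        terminal directions matters, giving the threshold anisotropy that
        threshold–direction maps capture.
        """
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        drive = np.maximum(0.0, self.directions_arr @ d)
        active = drive > DRIVE_EPS
        if not np.any(active):
            return NOT_ACTIVATABLE
        return waveform.factor * float(np.min(self.weights_arr[active] / drive[active]))


def _fibonacci_directions(K: int, rng, jitter: float = 0.2) -> np.ndarray:
    """Jittered quasi-uniform directions on the sphere (seeded random pose).

    Axon terminals of real neurons point every which way, so for every field
    direction some terminal is reasonably aligned and the threshold–direction
    map is finite everywhere; i.i.d. random directions can leave parts of the
    sphere uncovered, producing non-activatable directions no cable model
    exhibits.
    """
    i = np.arange(K)
    z = 1.0 - 2.0 * (i + 0.5) / K
    phi = np.pi * (1 + np.sqrt(5.0)) * i
    r = np.sqrt(1 - z ** 2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    dirs += jitter * rng.standard_normal((K, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    # random global pose so clones/neurons do not share a fixed lattice
    Q, R = np.linalg.qr(rng.standard_normal((3, 3)))
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return dirs @ Q.T


def default_neuron(
    cell_type: str = "L5_PC",
    clone_id: int = 1,
    seed: int = 0,
    n_terminals: int | None = None,
    weight_range=(75.0, 200.0),
) -> SurrogateNeuron:
    """Deterministic seeded surrogate for a cell-type label.

    Terminals are placed inside a cube of half-side 0.45·l (well inside the
    sampling grid) with jittered quasi-uniform directions, so thresholds
    depend on off-centre field values — the feature a soma-only uniform-field
    estimate cannot capture — and every field direction activates the cell.
    """
    rng = np.random.default_rng(seed + 977 * clone_id)
    K = n_terminals or DEFAULT_TERMINAL_COUNTS.get(cell_type, 8)
    l = DEFAULT_GRID_SIDE.get(cell_type, 1.5)
    pos = rng.uniform(-0.45 * l, 0.45 * l, size=(K, 3))
    dirs = _fibonacci_directions(K, rng)
    w = rng.uniform(*weight_range, size=K)
    return SurrogateNeuron(
        cell_type, clone_id, tuple(map(tuple, pos)), tuple(map(tuple, dirs)), tuple(w), l
    )


def generate_clones(
    base: SurrogateNeuron,
    n_clones: int = 5,
    position_jitter: float = 0.05,
    direction_jitter: float = 0.05,
    weight_jitter: float = 0.05,
    seed: int = 0,
) -> list:
    """Morphological clones: jittered terminals, preserved cell type.

    Jitters are fractional scales of Gaussian perturbations (positions
    relative to the grid side, weights multiplicative); directions are
    renormalized after perturbation.  ``jitter=0`` gives identical copies.
    Deterministic given the seed.
    """
    if n_clones < 1:
        raise SurrogateError("n_clones must be ≥ 1")
    rng = np.random.default_rng(seed)
    clones = []
    for c in range(1, n_clones + 1):
        P = base.positions_arr + position_jitter * base.grid_side * rng.standard_normal((base.K, 3))
        P = np.clip(P, -0.49 * base.grid_side, 0.49 * base.grid_side)
        U = base.directions_arr + direction_jitter * rng.standard_normal((base.K, 3))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        w = base.weights_arr * np.exp(weight_jitter * rng.standard_normal(base.K))
        clones.append(
            SurrogateNeuron(
                base.cell_type, c, tuple(map(tuple, P)), tuple(map(tuple, U)),
                tuple(w), base.grid_side,
            )
        )
    return clones


# ---------------------------------------------------------------------------
# Placement on a parametric cortical sheet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlacementSheet:
    """Parametric cortical surface z = A·cos(2πx/λ) over a rectangle.

    A corrugated sheet mimicking gyral crowns and sulcal walls; neurons sit
    below the surface at layer-specific normalized depths of the gray-matter
    thickness, with somatodendritic axis along the inward surface normal.
    """

    amplitude: float = 3.0  # A, mm
    wavelength: float = 20.0  # λ, mm
    x_extent: tuple = (-15.0, 15.0)
    y_extent: tuple = (-15.0, 15.0)
    thickness: float = 2.5  # gray-matter thickness, mm
    layer_depths: tuple = (("L23_PC", 0.4), ("L4_LBC", 0.5), ("L5_PC", 0.75))

    def surface_point(self, x: float, y: float) -> np.ndarray:
        z = self.amplitude * np.cos(2 * np.pi * x / self.wavelength)
        return np.array([x, y, z])

    def inward_normal(self, x: float) -> np.ndarray:
        """Unit normal pointing down into the tissue (−ẑ for a flat sheet)."""
        slope = -self.amplitude * 2 * np.pi / self.wavelength * np.sin(
            2 * np.pi * x / self.wavelength
        )
        n = np.array([slope, 0.0, -1.0])  # −(−dz/dx, 0, 1) direction
        return n / np.linalg.norm(n)

    def depth_of(self, cell_type: str) -> float:
        for label, d in self.layer_depths:
            if label == cell_type:
                return d
        raise SurrogateError(f"no layer depth for cell type '{cell_type}'")


@dataclass(frozen=True)
class Placement:
    """One neuron position: world origin, cell frame, 12 available rotations."""

    position_id: int
    frame: CellFrame


def generate_population(
    sheet: PlacementSheet,
    n_positions: int,
    seed: int,
    cell_type: str = "L5_PC",
) -> list:
    """Quasi-uniform seeded placement of ``n_positions`` somas on the sheet.

    Uses jittered stratified sampling over the rectangle (near-uniform
    coverage without lattice artefacts).  Each placement gets a seeded random
    azimuth reference tangent, realizing the initial random azimuthal
    orientation; rotation indices 0..11 then step by 30°.
    """
    if n_positions < 1:
        raise SurrogateError("n_positions must be ≥ 1")
    rng = np.random.default_rng(seed)
    depth = sheet.depth_of(cell_type) * sheet.thickness
    # stratified grid of cells covering the rectangle
    nx = int(np.ceil(np.sqrt(n_positions)))
    ny = int(np.ceil(n_positions / nx))
    xs = np.linspace(*sheet.x_extent, nx + 1)
    ys = np.linspace(*sheet.y_extent, ny + 1)
    placements = []
    pid = 0
    for i in range(nx):
        for j in range(ny):
            if pid >= n_positions:
                break
            x = rng.uniform(xs[i], xs[i + 1])
            y = rng.uniform(ys[j], ys[j + 1])
            surf = sheet.surface_point(x, y)
            n_in = sheet.inward_normal(x)
            origin = surf + depth * n_in
            # random azimuth reference in the tangent plane
            t = rng.standard_normal(3)
            frame = CellFrame.from_normal(origin, n_in, reference=t)
            placements.append(Placement(pid, frame))
            pid += 1
    return placements


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

def _terminal_drives(neuron: SurrogateNeuron, source, frame: CellFrame, rot: int) -> np.ndarray:
    """Per-terminal drives (V/m per unit intensity) for a placed, rotated neuron."""
    from .field_sources import evaluate_field

    R = frame.basis(rot)
    world_pos = frame.origin_vec + neuron.positions_arr @ R.T
    world_dir = neuron.directions_arr @ R.T
    E = evaluate_field(source, world_pos)
    return np.maximum(0.0, np.sum(E * world_dir, axis=1))


def soma_field_magnitude(source, frame: CellFrame) -> float:
    """|E(soma)| in V/m per unit stimulator intensity."""
    from .field_sources import evaluate_field

    return float(np.linalg.norm(evaluate_field(source, frame.origin_vec[None, :])[0]))


def analytic_threshold(
    neuron: SurrogateNeuron,
    source,
    placement: Placement,
    rot: int,
    waveform: PulseWaveform,
    cap: float = DEFAULT_CAP,
) -> tuple:
    """Closed-form threshold: (V/m soma-referenced, stimulator A/μs).

    Returns ``(NOT_ACTIVATABLE, NOT_ACTIVATABLE)`` if no terminal has
    positive drive or the intensity threshold exceeds ``cap``.
    """
    frame = placement.frame
    mag = soma_field_magnitude(source, frame)
    if mag <= 0.0:
        raise SurrogateError("zero E-field magnitude at the soma")
    drives = _terminal_drives(neuron, source, frame, rot)
    active = drives > DRIVE_EPS
    if not np.any(active):
        return NOT_ACTIVATABLE, NOT_ACTIVATABLE
    s_star = waveform.factor * float(np.min(neuron.weights_arr[active] / drives[active]))
    if s_star > cap:
        return NOT_ACTIVATABLE, NOT_ACTIVATABLE
    return s_star * mag, s_star


def spike_oracle(
    neuron: SurrogateNeuron,
    source,
    placement: Placement,
    rot: int,
    waveform: PulseWaveform,
    intensity: float,
) -> bool:
    """Fired ⇔ intensity ≥ the closed-form intensity threshold (monotone)."""
    _, s_star = analytic_threshold(neuron, source, placement, rot, waveform, cap=np.inf)
    return bool(intensity >= s_star)


def binary_search_threshold(
    oracle,
    lo: float = 1.0,
    hi: float = 1000.0,
    rel_window: float = 0.02,
    cap: float = DEFAULT_CAP,
    max_iter: int = 200,
) -> float:
    """Find the minimum firing intensity within a relative window (default 2%).

    ``oracle(intensity) -> bool`` must be a monotone step.  The bracket upper
    bound is doubled (up to ``cap``) until it fires; bisection then narrows
    until hi/lo ≤ 1 + rel_window, and the upper bound — the smallest intensity
    known to fire — is returned.  The result lies in
    [true threshold, true threshold · (1 + rel_window)].
    """
    if not lo < hi:
        raise SurrogateError("binary search requires lo < hi")
    if oracle(lo):
        # already firing at the lower bound: refine downward toward zero
        while lo > 1e-12 and oracle(lo / 2):
            hi = lo
            lo = lo / 2
        if lo <= 1e-12:
            return lo
    while not oracle(hi):
        if hi >= cap:
            return NOT_ACTIVATABLE
        lo = hi
        hi = min(2 * hi, cap)
    if oracle(lo) and not oracle(hi):
        raise SurrogateError("non-monotone oracle: fired at lo but not hi")
    for _ in range(max_iter):
        if hi / lo <= 1 + rel_window:
            break
        mid = np.sqrt(lo * hi)  # geometric midpoint suits a relative window
        if oracle(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# Quasipotential along a morphology tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphologyTree:
    """Polyline morphology: node positions (mm) and parent indices (root −1)."""

    nodes: tuple  # n×3 mm
    parents: tuple  # n ints, parents[0] == -1

    @property
    def nodes_arr(self) -> np.ndarray:
        return np.asarray(self.nodes, dtype=float).reshape(-1, 3)

    def __post_init__(self):
        par = np.asarray(self.parents, dtype=int)
        if par[0] != -1:
            raise SurrogateError("node 0 must be the root (parent −1)")
        if np.any(par[1:] < 0) or np.any(par[1:] >= len(par)):
            raise SurrogateError("invalid parent indices")
        # connectivity: every node must reach the root
        for i in range(1, len(par)):
            j, hops = i, 0
            while j != -1:
                j = par[j] if j != 0 else -1
                hops += 1
                if hops > len(par):
                    raise SurrogateError("disconnected or cyclic morphology tree")


def resample_tree(tree: MorphologyTree, max_seg_um: float = 20.0) -> MorphologyTree:
    """Subdivide edges so no segment exceeds ``max_seg_um`` (default 20 μm)."""
    nodes = [tuple(p) for p in tree.nodes_arr]
    parents = list(tree.parents)
    max_mm = max_seg_um * 1e-3
    P = tree.nodes_arr
    for child in range(1, len(tree.parents)):
        parent = tree.parents[child]
        a, b = P[parent], P[child]
        length = np.linalg.norm(b - a)
        n_seg = int(np.ceil(length / max_mm)) if length > 0 else 1
        if n_seg <= 1:
            continue
        prev = parent
        for s in range(1, n_seg):
            mid = a + (b - a) * s / n_seg
            nodes.append(tuple(mid))
            parents.append(prev)
            prev = len(nodes) - 1
        parents[child] = prev
    return MorphologyTree(tuple(nodes), tuple(parents))


def quasipotential(tree: MorphologyTree, source, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Path-integrated quasipotential ψ per node, in mV (ψ(root) = 0).

    ψ(child) = ψ(parent) − E(segment midpoint) · (child − parent), the
    discrete line integral of the field along each neural process
    (V/m × mm = mV).  Exact for uniform fields, where ψ(x) = −E·(x − root).
    """
    from .field_sources import evaluate_field

    P = tree.nodes_arr + np.asarray(origin, dtype=float)
    n = len(P)
    psi = np.zeros(n)
    parents = np.asarray(tree.parents, dtype=int)
    mids = 0.5 * (P[1:] + P[parents[1:]])
    E = evaluate_field(source, mids)
    seg = P[1:] - P[parents[1:]]
    drops = np.sum(E * seg, axis=1)
    # accumulate in index order; resampled trees keep parent < child except
    # subdivided edges, so iterate until settled (tree depth bounded passes)
    order = _topological_order(parents)
    drop_of_child = {c + 1: d for c, d in enumerate(drops)}
    for node in order:
        if node == 0:
            continue
        psi[node] = psi[parents[node]] - drop_of_child[node]
    return psi


def _topological_order(parents: np.ndarray) -> list:
    children = {}
    for c, p in enumerate(parents):
        if c == 0:
            continue
        children.setdefault(p, []).append(c)
    order, stack = [], [0]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(children.get(node, []))
    if len(order) != len(parents):
        raise SurrogateError("disconnected morphology tree")
    return order
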