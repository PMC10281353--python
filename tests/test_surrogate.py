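import numpy as np
import pytest

from neurothresh.field_sources import PointSourceField, UniformField, figure_eight_coil
from neurothresh.geometry import CellFrame
from neurothresh.surrogate import (
    NOT_ACTIVATABLE,
    MorphologyTree,
    Placement,
    PlacementSheet,
    SurrogateError,
    analytic_threshold,
    binary_search_threshold,
    default_neuron,
    generate_clones,
    generate_population,
    monophasic_waveform,
    biphasic_waveform,
    quasipotential,
    resample_tree,
    spike_oracle,
)


class TestWaveforms:
    def test_unit_peak(self):
        for wf in (monophasic_waveform(), biphasic_waveform()):
            assert np.max(np.abs(wf.samples)) == pytest.approx(1.0)

    def test_factors(self):
        assert monophasic_waveform().factor == 1.0
        assert biphasic_waveform().factor == 1.15


class TestPopulation:
    def test_count_and_determinism(self):
        sheet = PlacementSheet()
        a = generate_population(sheet, 50, seed=7)
        b = generate_population(sheet, 50, seed=7)
        assert len(a) == 50
        for pa, pb in zip(a, b):
            assert pa.frame == pb.frame

    def test_flat_sheet_normals_point_down(self):
        sheet = PlacementSheet(amplitude=0.0)
        pop = generate_population(sheet, 10, seed=0)
        for p in pop:
            assert np.allclose(p.frame.z_axis, [0, 0, -1], atol=1e-12)

    def test_polar_axis_perpendicular_to_surface_tangents(self):
        sheet = PlacementSheet()
        depth = sheet.depth_of("L5_PC") * sheet.thickness
        for p in generate_population(sheet, 20, seed=3):
            z = np.asarray(p.frame.z_axis)
            # surface point lies `depth` back along the inward normal
            x_surf = p.frame.origin[0] - depth * z[0]
            slope = -sheet.amplitude * 2 * np.pi / sheet.wavelength * np.sin(
                2 * np.pi * x_surf / sheet.wavelength)
            tangent = np.array([1.0, 0.0, slope])
            assert abs(z @ tangent) <= 1e-6 * np.linalg.norm(tangent)

    def test_larger_population(self):
        pop = generate_population(PlacementSheet(), 3000, seed=1)
        assert len(pop) == 3000


class TestClones:
    def test_zero_jitter_identical(self, seeded_neuron):
        clones = generate_clones(seeded_neuron, 3, 0.0, 0.0, 0.0, seed=5)
        for c in clones:
            assert np.allclose(c.positions_arr, seeded_neuron.positions_arr)
            assert np.allclose(c.directions_arr, seeded_neuron.directions_arr)
            assert np.allclose(c.weights_arr, seeded_neuron.weights_arr)

    def test_five_clones_seeded_reproducible(self, seeded_neuron):
        a = generate_clones(seeded_neuron, 5, seed=9)
        b = generate_clones(seeded_neuron, 5, seed=9)
        assert len(a) == 5
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.positions_arr, cb.positions_arr)
            assert np.array_equal(ca.weights_arr, cb.weights_arr)

    def test_directions_renormalized(self, seeded_neuron):
        for c in generate_clones(seeded_neuron, 5, direction_jitter=0.5, seed=2):
            assert np.allclose(np.linalg.norm(c.directions_arr, axis=1), 1.0, atol=1e-9)


class TestAnalyticThreshold:
    def test_aligned_terminal_threshold_independent_of_magnitude(
            self, single_terminal_neuron, placement, waveform):
        for mag in (10.0, 100.0, 400.0):
            src = UniformField((0, 0, 1), mag)
            thr, _ = analytic_threshold(single_terminal_neuron, src, placement, 0, waveform)
            assert thr == pytest.approx(100.0)

    def test_sixty_degree_misalignment_doubles_threshold(
            self, single_terminal_neuron, placement, waveform):
        d = (np.sin(np.pi / 3), 0.0, np.cos(np.pi / 3))
        thr, _ = analytic_threshold(
            single_terminal_neuron, UniformField(d, 120.0), placement, 0, waveform)
        assert thr == pytest.approx(200.0)

    def test_orthogonal_field_not_activatable(self, single_terminal_neuron, placement, waveform):
        thr, s = analytic_threshold(
            single_terminal_neuron, UniformField((1, 0, 0), 100.0), placement, 0, waveform)
        assert thr == NOT_ACTIVATABLE and s == NOT_ACTIVATABLE

    def test_matches_brute_force_over_terminals(self, placement, waveform, coil):
        """K=8 random terminals in a dipole-coil field: the threshold equals an
        exhaustive min over terminals computed in a separate loop."""
        neuron = default_neuron("L23_PC", seed=11)
        thr, s = analytic_threshold(neuron, coil, placement, 4, waveform)
        R = placement.frame.basis(4)
        best = np.inf
        from neurothresh.field_sources import evaluate_field

        for p, u, w in zip(neuron.positions_arr, neuron.directions_arr, neuron.weights_arr):
            E = evaluate_field(coil, (placement.frame.origin_vec + R @ p)[None])[0]
            drive = max(0.0, E @ (R @ u))
            if drive > 1e-9:
                best = min(best, waveform.factor * w / drive)
        assert s == pytest.approx(best, rel=1e-12)

    def test_scale_invariance_of_vm_threshold(self, placement, waveform, coil):
        neuron = default_neuron(seed=3)
        thr1, s1 = analytic_threshold(neuron, coil, placement, 0, waveform)
        thr2, s2 = analytic_threshold(neuron, coil.scaled(3.0), placement, 0, waveform)
        assert thr2 == pytest.approx(thr1, rel=1e-12)
        assert s2 == pytest.approx(s1 / 3.0, rel=1e-12)

    def test_zero_soma_field_is_error(self, single_terminal_neuron, placement, waveform):
        from neurothresh.field_sources import LinearField

        src = LinearField(E0=(0.0, 0.0, 0.0),
                          jacobian=((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0)))
        with pytest.raises(SurrogateError):
            analytic_threshold(single_terminal_neuron, src, placement, 0, waveform)


class TestSpikeOracleAndSearch:
    def test_zero_intensity_never_fires(self, seeded_neuron, placement, waveform, coil):
        assert not spike_oracle(seeded_neuron, coil, placement, 0, waveform, 0.0)

    def test_monotone_step_at_threshold(self, seeded_neuron, placement, waveform, coil):
        _, s = analytic_threshold(seeded_neuron, coil, placement, 0, waveform)
        assert spike_oracle(seeded_neuron, coil, placement, 0, waveform, s * 1.001)
        assert not spike_oracle(seeded_neuron, coil, placement, 0, waveform, s * 0.999)

    def test_sweep_has_unique_crossing(self, seeded_neuron, placement, waveform, coil):
        _, s = analytic_threshold(seeded_neuron, coil, placement, 0, waveform)
        grid = np.geomspace(s / 10, s * 10, 201)
        fired = [spike_oracle(seeded_neuron, coil, placement, 0, waveform, i) for i in grid]
        flips = np.sum(np.diff(np.asarray(fired, dtype=int)) != 0)
        assert flips == 1
        assert grid[int(np.argmax(fired))] >= s

    def test_search_within_two_percent_of_closed_form(self):
        s_true = 100.0
        est = binary_search_threshold(lambda i: i >= s_true, 1.0, 1000.0, 0.02)
        assert s_true <= est <= s_true * 1.02

    def test_wide_window_bracket(self):
        est = binary_search_threshold(lambda i: i >= 100.0, 50.0, 200.0, rel_window=0.5)
        assert 100.0 <= est <= 150.0

    def test_upper_bound_doubles_until_found(self):
        est = binary_search_threshold(lambda i: i >= 900.0, 1.0, 2.0, 0.02)
        assert 900.0 <= est <= 918.0

    def test_cap_gives_sentinel(self):
        est = binary_search_threshold(lambda i: False, 1.0, 2.0, cap=1e3)
        assert est == NOT_ACTIVATABLE

    def test_firing_at_lo_refines_downward(self):
        est = binary_search_threshold(lambda i: i >= 0.5, 1.0, 10.0, 0.02)
        assert 0.5 <= est <= 0.5 * 1.02


class TestPointSourceCurrentDistance:
    def test_threshold_nondecreasing_with_distance(self, waveform):
        """Current–distance relationship: farther sources need more current."""
        neuron = default_neuron(seed=8)
        thresholds = []
        for dist in (3.0, 5.0, 8.0, 12.0, 20.0):
            src = PointSourceField((0.0, 0.0, dist))
            frame = CellFrame((0, 0, 0), (0, 0, 1), (1, 0, 0))
            _, s = analytic_threshold(neuron, src, Placement(0, frame), 0, waveform)
            thresholds.append(s)
        assert np.all(np.diff(thresholds) >= 0)


class TestQuasipotential:
    def test_uniform_field_straight_process(self):
        tree = resample_tree(MorphologyTree(((0, 0, 0), (0, 0, 1.0)), (-1, 0)))
        psi = quasipotential(tree, UniformField((0, 0, 1), 100.0))
        tip = np.argmax(tree.nodes_arr[:, 2])
        assert psi[tip] == pytest.approx(-100.0)

    def test_uniform_field_path_independent(self, rng):
        # a branched tree: ψ(x) = −E·(x − soma) regardless of path
        nodes = [(0, 0, 0), (0.3, 0, 0.2), (0.5, 0.2, 0.5), (0.1, -0.4, 0.3), (0.6, 0.1, 0.9)]
        parents = (-1, 0, 1, 0, 2)
        tree = resample_tree(MorphologyTree(tuple(nodes), parents))
        E = np.array([40.0, -70.0, 110.0])
        psi = quasipotential(tree, UniformField(tuple(E / np.linalg.norm(E)), np.linalg.norm(E)))
        expected = -(tree.nodes_arr @ E)
        assert np.allclose(psi, expected, atol=1e-9)

    def test_linear_field_matches_fine_quadrature(self, linear_field):
        tree = resample_tree(MorphologyTree(((0, 0, 0), (0.4, 0.7, 1.0)), (-1, 0)), 20.0)
        psi = quasipotential(tree, linear_field)
        tip = len(tree.parents) - 1
        # independent oracle: dense midpoint quadrature along the segment
        a, b = np.zeros(3), np.array([0.4, 0.7, 1.0])
        ts = np.linspace(0, 1, 20001)
        mids = a + np.outer((ts[:-1] + ts[1:]) / 2, b - a)
        E = linear_field.evaluate(mids)
        integral = -np.sum(E @ (b - a)) * (ts[1] - ts[0])
        tip_idx = np.argmax(np.linalg.norm(tree.nodes_arr, axis=1))
        assert psi[tip_idx] == pytest.approx(integral, rel=1e-3)

    def test_segments_resampled_below_20um(self):
        tree = resample_tree(MorphologyTree(((0, 0, 0), (0, 0, 1.0)), (-1, 0)), 20.0)
        P = tree.nodes_arr
        for child in range(1, len(tree.parents)):
            seg = np.linalg.norm(P[child] - P[tree.parents[child]])
            assert seg <= 20e-3 + 1e-12

    def test_disconnected_tree_rejected(self):
        with pytest.raises(SurrogateError):
            MorphologyTree(((0, 0, 0), (1, 1, 1)), (-1, 5))


class TestThresholdAnisotropy:
    def test_single_terminal_cosine_law(self, single_terminal_neuron, placement, waveform):
        """threshold(θ) = w·c_w / cosθ on the activatable hemisphere."""
        for theta in (0.0, 0.3, 0.8, 1.2):
            d = (np.sin(theta), 0.0, np.cos(theta))
            src = UniformField(d, 77.0)
            thr, _ = analytic_threshold(single_terminal_neuron, src, placement, 0, waveform)
            assert thr == pytest.approx(100.0 / np.cos(theta), rel=1e-9)
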