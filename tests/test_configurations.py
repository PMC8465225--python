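"""Idealized configuration generators and the radius-of-gyration calculator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyfluid.configurations import (
    Configuration,
    dense_sphere,
    dense_sphere_rg,
    parabola,
    rg_of,
    ring,
    ring_rg,
    saw_walk,
    shell_structure,
    sparse_sphere,
    sparse_sphere_rg,
    straight_rope,
    straight_rope_rg,
)


class TestRgOf:
    def test_single_monomer(self):
        assert rg_of(np.array([[3.0, -1.0, 2.0]])) == 0.0

    def test_two_monomers_at_distance_two(self):
        assert rg_of(np.array([[0.0, 0, 0], [2.0, 0, 0]])) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rg_of(np.zeros((0, 3)))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=2, max_value=40),
           st.tuples(*[st.floats(-50, 50) for _ in range(3)]))
    def test_translation_invariance(self, n, shift):
        rng = np.random.default_rng(n)
        pts = rng.normal(size=(n, 3)) * 3.0
        assert rg_of(pts + np.asarray(shift)) == pytest.approx(rg_of(pts), abs=1e-9)


class TestStraightRope:
    @pytest.mark.parametrize("n, expected", [(20, 11.53), (40, 23.09), (2, 1.0)])
    def test_reference_values(self, n, expected):
        assert round(straight_rope_rg(n), 2) == expected

    @pytest.mark.parametrize("n", [1, 2, 7, 20, 60])
    def test_coordinates_match_closed_form(self, n):
        cfg = straight_rope(n)
        assert rg_of(cfg) == pytest.approx(straight_rope_rg(n), rel=1e-12)

    def test_spacing_is_one_diameter(self):
        cfg = straight_rope(10)
        gaps = np.diff(cfg.coords[:, 0])
        assert np.allclose(gaps, 2.0)
        assert cfg.min_pair_distance() >= 2.0 - 1e-9


class TestRing:
    @pytest.mark.parametrize("n, expected", [(50, 8.0), (20, 3.2)])
    def test_reference_values(self, n, expected):
        assert round(ring_rg(n), 1) == expected

    @pytest.mark.parametrize("n", [3, 12, 50, 61])
    def test_all_monomers_equidistant_from_centroid(self, n):
        cfg = ring(n)
        assert rg_of(cfg) == pytest.approx(n / (2 * math.pi), rel=1e-12)
        d = np.linalg.norm(cfg.coords - cfg.coords.mean(0), axis=1)
        assert np.allclose(d, d[0])

    def test_perimeter_rule_alternative(self):
        assert ring_rg(20, perimeter_rule=True) == pytest.approx(20 / math.pi)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ring(2)


class TestDenseSphere:
    def test_shell_capacities_sequence(self):
        caps = [n for _, n in shell_structure(1 + 7 + 19 + 37 + 61)]
        assert caps == [1, 7, 19, 37, 61]
        radii = [r for r, _ in shell_structure(64)]
        assert radii == [0.0, 2.0, 4.0, 6.0]

    def test_capacities_within_volume_ratio_bound(self):
        # cumulative monomers inside radius R = 2k - 1 never exceed R^3/r^3
        total = 0
        for k, (radius, n) in enumerate(shell_structure(500), start=1):
            total += n
            assert total <= (2 * k - 1) ** 3

    @pytest.mark.parametrize("n, expected", [(40, 4.5), (20, 3.3), (30, 3.8)])
    def test_reference_values(self, n, expected):
        assert round(dense_sphere_rg(n), 1) == expected

    def test_single_monomer(self):
        assert dense_sphere_rg(1) == 0.0
        assert rg_of(dense_sphere(1)) == 0.0

    @pytest.mark.parametrize("n", [1, 8, 20, 27, 40, 64])
    def test_coordinates_reproduce_shell_accounting(self, n):
        cfg = dense_sphere(n)
        assert rg_of(cfg, center=np.zeros(3)) == pytest.approx(dense_sphere_rg(n), rel=1e-12)

    @pytest.mark.parametrize("n", [8, 20, 40, 64])
    def test_hard_sphere_non_overlap(self, n):
        assert dense_sphere(n).min_pair_distance() >= 2.0 - 1e-9


class TestSparseSphere:
    def test_single_monomer(self):
        assert sparse_sphere_rg(1) == 0.0

    def test_reference_value_within_construction_uncertainty(self):
        assert sparse_sphere_rg(20) == pytest.approx(4.7, abs=0.3)

    @pytest.mark.parametrize("n", range(2, 70, 7))
    def test_always_larger_than_dense(self, n):
        assert sparse_sphere_rg(n) > dense_sphere_rg(n)

    def test_coordinates_reproduce_scaled_accounting(self):
        cfg = sparse_sphere(40)
        assert rg_of(cfg, center=np.zeros(3)) == pytest.approx(sparse_sphere_rg(40), rel=1e-12)


class TestParabola:
    def test_two_monomers_symmetric_pair(self):
        cfg = parabola(2)
        assert cfg.N == 2
        # mirror pair: Rg is half the center separation
        sep = np.linalg.norm(cfg.coords[0] - cfg.coords[1])
        assert rg_of(cfg) == pytest.approx(sep / 2)

    @pytest.mark.parametrize("n", [2, 5, 20, 21])
    def test_symmetric_about_axis(self, n):
        cfg = parabola(n)
        assert cfg.coords[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(cfg.coords[:, 1], cfg.coords[:, 0] ** 2)

    def test_arc_steps_are_monomer_lengths(self):
        """Chords between consecutive arc positions approach the unit step."""
        cfg = parabola(21)
        arm = cfg.coords[np.argsort(cfg.coords[:, 0])]  # sweep one arm to the other
        chords = np.linalg.norm(np.diff(arm[arm[:, 0] >= -1e-12], axis=0), axis=1)
        assert np.all(chords <= 1.0 + 1e-9)
        assert np.all(chords > 0.93)  # curvature shortens chords only slightly

    def test_reference_value_matches_at_n20(self):
        assert rg_of(parabola(20)) == pytest.approx(3.5, abs=0.05)

    def test_direct_rg_equals_formula_path(self):
        # distances to the discrete center of mass, accumulated explicitly
        cfg = parabola(20)
        com = cfg.coords.mean(0)
        manual = math.sqrt(np.mean(((cfg.coords - com) ** 2).sum(1)))
        assert rg_of(cfg) == pytest.approx(manual, rel=1e-15)


class TestSawWalk:
    def test_single_monomer(self):
        assert rg_of(saw_walk(1, seed=1)) == 0.0

    def test_deterministic_for_fixed_seed(self):
        a = saw_walk(40, seed=123)
        b = saw_walk(40, seed=123)
        assert np.array_equal(a.coords, b.coords)
        c = saw_walk(40, seed=124)
        assert not np.array_equal(a.coords, c.coords)

    def test_bonds_and_excluded_volume(self):
        cfg = saw_walk(60, seed=7)
        bonds = np.linalg.norm(np.diff(cfg.coords, axis=0), axis=1)
        assert np.allclose(bonds, 2.0)
        assert cfg.min_pair_distance() >= 2.0 - 1e-9


class TestOrderingAndExport:
    def test_rg_ordering_of_generated_configurations(self):
        """Compactness ordering DS < Pa < SS < SR for short chains."""
        for n in (20, 30):
            assert (
                dense_sphere_rg(n)
                < rg_of(parabola(n))
                < sparse_sphere_rg(n)
                < straight_rope_rg(n)
            )

    def test_rg_ordering_of_printed_reference_column(self):
        # the printed column preserves DS < Pa < SS < SR up to N = 40; at
        # N = 50 the printed Pa (6.7) overtakes the printed SS (6.6)
        from polyfluid.report import build_fixture

        fx = build_fixture(4)
        for n in (20, 30, 40):
            row = str(n)
            assert (
                fx.cell(row, "DS").printed
                < fx.cell(row, "Pa").printed
                < fx.cell(row, "SS").printed
                < fx.cell(row, "SR").printed
            )

    def test_xyz_roundtrip(self, tmp_path):
        cfg = dense_sphere(20)
        path = tmp_path / "ds20.xyz"
        text = cfg.to_xyz(path)
        lines = path.read_text().splitlines()
        assert lines == text.splitlines()
        assert lines[0] == "20"
        assert len(lines) == 22
        fields = lines[2].split()
        assert fields[0] == "C" and len(fields) == 4
        parsed = np.array([[float(x) for x in ln.split()[1:]] for ln in lines[2:]])
        assert np.allclose(parsed, cfg.coords, atol=1e-7)
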