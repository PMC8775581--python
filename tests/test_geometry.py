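"""Cell-model geometry: gold equivalence, masses, sampling, ray tracing."""

import math

import numpy as np
import pytest

import celldose as cd
from celldose.geometry import GoldConfig


class TestGoldEquivalence:
    def test_equivalent_sphere_radius_identity(self):
        assert cd.equivalent_gold_sphere_radius(1, 4.0) == pytest.approx(2e-3)

    def test_equivalent_sphere_cube_root_scaling(self):
        assert cd.equivalent_gold_sphere_radius(8, 4.0) == pytest.approx(4e-3)

    def test_standard_nanoparticle_load_gives_1p3_um(self):
        r = cd.equivalent_gold_sphere_radius(2.83e8, 4.0)
        assert r == pytest.approx(1.3, abs=0.05)  # 2 significant figures

    def test_shell_thickness_30_nm(self):
        t = cd.gold_shell_thickness(2.83e8, 4.0, 5.0)
        assert round(t) == 30

    def test_zero_count_zero_thickness(self):
        assert cd.gold_shell_thickness(0, 4.0, 5.0) == 0.0

    def test_exact_cubic_within_1_percent_of_thin_shell(self):
        thin = cd.gold_shell_thickness(2.83e8, 4.0, 5.0)
        exact = cd.gold_shell_thickness(2.83e8, 4.0, 5.0, exact=True)
        assert abs(exact - thin) / exact < 0.01

    def test_configured_solid_volume_matches_np_volume(self):
        v_np = 2.83e8 * (math.pi / 6.0) * (4e-3) ** 3  # um^3
        shell = cd.standard_gold_shell_model()
        assert shell.region_volume_um3("gold") == pytest.approx(v_np, rel=0.02)
        sphere = cd.standard_central_sphere_model()
        assert sphere.region_volume_um3("gold") == pytest.approx(v_np, rel=0.02)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            cd.equivalent_gold_sphere_radius(-1, 4.0)
        with pytest.raises(ValueError):
            cd.gold_shell_thickness(10, -4.0, 5.0)


class TestMasses:
    def test_nucleus_mass(self, model):
        # (4/3) pi (5 um)^3 x 1000 kg/m^3
        assert model.region_mass_kg("nucleus") == pytest.approx(5.24e-13,
                                                                rel=1e-3)

    def test_gold_shell_mass(self, gold_shell_model):
        # 4 pi r^2 t x 19300 kg/m^3
        assert gold_shell_model.region_mass_kg("gold") == pytest.approx(
            1.8e-13, rel=0.03)

    def test_unknown_region_raises(self, model):
        with pytest.raises(KeyError):
            model.region_mass_kg("mitochondrion")

    def test_volume_conservation(self, gold_shell_model):
        total = sum(gold_shell_model.region_volume_um3(r)
                    for r in gold_shell_model.cell_regions)
        analytic = 4.0 / 3.0 * math.pi * 12.5 ** 3
        assert total == pytest.approx(analytic, rel=1e-9)

    def test_scoring_shells_inside_cytoplasm(self, gold_shell_model):
        radii = dict(gold_shell_model.shell_radii())
        assert radii["shell_6"] < gold_shell_model.cell_radius_um

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            cd.CellModel(nucleus_radius_um=13.0)
        with pytest.raises(ValueError):
            cd.CellModel(gold=GoldConfig("central_sphere",
                                         sphere_radius_um=6.0))


class TestSampling:
    def test_nucleus_mean_radius_is_three_quarters(self, model, rng):
        pts = model.sample_point("nucleus", rng, 100_000)
        r = np.linalg.norm(pts, axis=1)
        se = r.std() / np.sqrt(len(r))
        assert abs(r.mean() - 3.75) < 4 * se

    def test_cytoplasm_containment(self, model, rng):
        r = np.linalg.norm(model.sample_point("cytoplasm", rng, 20_000),
                           axis=1)
        assert np.all((r > 5.0) & (r < 12.5))

    def test_medium_probe_box_binomial(self, model, rng):
        # points in a probe sub-box match its volume share within 3 sigma
        pts = model.sample_point("medium", rng, 100_000)
        lo, hi = 500.0, 1500.0  # um, inside medium, away from the cells
        inside = np.all((pts > lo) & (pts < hi), axis=1)
        p = (hi - lo) ** 3 / model.region_volume_um3("medium")
        se = math.sqrt(p * (1 - p) / len(pts))
        assert abs(inside.mean() - p) < 3 * se

    def test_rejection_sampled_volumes_match_analytic(self, gold_shell_model,
                                                      rng):
        # independent oracle: hit-or-miss volume of cytoplasm + nucleus
        n = 1_000_000
        box = gold_shell_model.cell_radius_um
        pts = rng.uniform(-box, box, (n, 3))
        r = np.linalg.norm(pts, axis=1)
        v_box = (2 * box) ** 3
        for region, mask in [
                ("nucleus", r < 5.0),
                ("cytoplasm", (r > 5.0902) & (r < 12.5))]:
            mc = mask.mean() * v_box
            assert mc == pytest.approx(
                gold_shell_model.region_volume_um3(region), rel=0.01)


class TestRayTracing:
    def test_nesting_order_from_center(self, gold_shell_model):
        segs = gold_shell_model.segment_path(
            np.zeros(3), np.array([0.0, 0.0, 1.0]), 20.0)
        names = [r for r, _ in segs]
        assert names[0] == "nucleus"
        assert names[1] == "gold"
        assert names[-2] == "cytoplasm"
        assert names[-1] == "medium"

    def test_nucleus_chord_through_center(self, model):
        segs = model.segment_path(np.array([0.0, 0.0, -12.4]),
                                  np.array([0.0, 0.0, 1.0]), 30.0)
        chords = {r: l for r, l in segs}
        assert chords["nucleus"] == pytest.approx(10.0, abs=1e-9)

    def test_segment_lengths_sum_to_max_length(self, gold_shell_model, rng):
        from celldose.geometry import _isotropic

        for _ in range(50):
            origin = gold_shell_model.sample_point("cytoplasm", rng, 1)[0]
            d = _isotropic(rng, 1)[0]
            segs = gold_shell_model.segment_path(origin, d, 40.0)
            assert sum(l for _, l in segs) == pytest.approx(40.0, rel=1e-9)

    def test_neighbor_cells_are_seen(self, model):
        # ray along +x from the centre passes through the x-neighbour
        segs = model.segment_path(np.zeros(3), np.array([1.0, 0.0, 0.0]),
                                  40.0)
        assert any(r == "neighbor" for r, _ in segs)

    def test_non_unit_direction_rejected(self, model):
        with pytest.raises(ValueError, match="unit"):
            model.segment_path(np.zeros(3), np.array([1.0, 1.0, 0.0]), 5.0)
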