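"""Template generator, landmark emulation, detailed mesh, materials."""

import numpy as np
import pytest

from spondylofem.fem.elements import hex_jacobians
from spondylofem.geometry import (compute_spinopelvic_params, measure_slip)
from spondylofem.synthetic_data import (
    CurveAngles,
    PatientScalars,
    UnrealizableTargetError,
    build_detailed_mesh,
    default_material_library,
    generate_patient_landmarks,
    generate_template_geometry,
    region_material_key,
)


class TestTemplateGeometry:
    def test_defaults_reproduce_reference_patient(self, baseline_template):
        p = baseline_template.params
        assert p.pi_deg == pytest.approx(61.0, abs=0.1)
        assert p.ss_deg == pytest.approx(52.0, abs=0.1)
        assert p.grade == "II"
        assert baseline_template.patient.height_cm == pytest.approx(157.2)
        assert baseline_template.patient.weight_kg == pytest.approx(45.5)
        assert baseline_template.patient.age_yr == pytest.approx(14.0)

    def test_high_grade_round_trip(self):
        t = generate_template_geometry((75.0, 60.0, 80.0))
        assert t.params.pi_deg == pytest.approx(75.0, abs=0.1)
        assert t.params.ss_deg == pytest.approx(60.0, abs=0.1)
        assert t.params.slip_pct == pytest.approx(80.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_targets_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        ss = rng.uniform(35, 65)
        pi = ss + rng.uniform(-5, 30)
        slip = rng.uniform(0, 90)
        t = generate_template_geometry((pi, ss, slip))
        lms = t.landmarks
        p = compute_spinopelvic_params(lms, lms)
        assert p.pi_deg == pytest.approx(pi, abs=0.1)
        assert p.ss_deg == pytest.approx(ss, abs=0.1)
        assert measure_slip(lms) == pytest.approx(slip, abs=0.1)

    def test_unrealizable_targets_raise(self):
        with pytest.raises(UnrealizableTargetError):
            generate_template_geometry((10.0, 70.0, 30.0))  # PT = -60
        with pytest.raises(UnrealizableTargetError):
            generate_template_geometry((61.0, 52.0, -10.0))

    def test_landmark_counts_match_reconstruction_protocol(
            self, baseline_template):
        baseline_template.landmarks.validate_reconstruction_counts()
        counts = baseline_template.landmarks.counts()
        assert counts["pelvis"] == 23
        assert counts["L3"] == 17
        assert counts["rib_left_05"] == 11
        assert sum(k.startswith("rib_") for k in counts) == 24


class TestPatientLandmarks:
    def test_zero_noise_returns_template_exactly(self, baseline_template):
        out = generate_patient_landmarks(baseline_template, 0.0, seed=1)
        np.testing.assert_array_equal(
            out.points("L5"), baseline_template.landmarks.points("L5"))

    def test_same_seed_reproducible(self, baseline_template):
        a = generate_patient_landmarks(baseline_template, 3.3, seed=42)
        b = generate_patient_landmarks(baseline_template, 3.3, seed=42)
        np.testing.assert_array_equal(a.frame.to_numpy(), b.frame.to_numpy())

    def test_mean_displacement_matches_chi_distribution(self,
                                                        baseline_template):
        """Monte Carlo check of the 3.3 mm isotropic noise: the mean point
        displacement equals sigma * E[chi_3] = sigma * sqrt(2) *
        Gamma(2)/Gamma(3/2)."""
        sd = 3.3
        out = generate_patient_landmarks(baseline_template, sd, seed=3)
        d = np.linalg.norm(
            out.frame[["x_mm", "y_mm", "z_mm"]].to_numpy()
            - baseline_template.landmarks.frame[
                ["x_mm", "y_mm", "z_mm"]].to_numpy(), axis=1)
        from scipy.special import gamma as g
        expected = sd * np.sqrt(2) * g(2.0) / g(1.5)
        n = len(d)
        se = sd * 0.7 / np.sqrt(n)  # generous bound on the standard error
        assert d.mean() == pytest.approx(expected, abs=5 * se)

    def test_negative_noise_rejected(self, baseline_template):
        with pytest.raises(ValueError):
            generate_patient_landmarks(baseline_template, -1.0)


class TestDetailedMesh:
    def test_all_jacobians_positive_at_default_resolution(
            self, baseline_template):
        m = build_detailed_mesh(baseline_template, resolution=12)
        assert hex_jacobians(m.hex_coords()).min() > 0
        assert 3000 <= m.n_hex <= 8000

    def test_growth_plates_have_three_zones_each(self, small_model):
        regions = set(small_model.hex_region)
        for plate in ("gp_l5", "gp_s1"):
            zones = {r for r in regions if r.startswith(plate)}
            assert zones == {f"{plate}_sensitive", f"{plate}_newbone",
                             f"{plate}_transition"}

    def test_lysis_disconnects_arch_from_body_through_pars(
            self, baseline_template):
        """With bilateral lysis every arch-to-body path runs through the
        sacrum (facets), never through pars elements; without lysis the
        pars provides a direct connection (brute-force graph check)."""

        def adjacency(model, drop_regions=()):
            adj = {i: set() for i in range(model.n_nodes)}
            for b in model.beams:
                if b.region in drop_regions:
                    continue
                i, j = b.nodes
                adj[i].add(j)
                adj[j].add(i)
            for s in model.springs:
                i, j = s.nodes
                adj[i].add(j)
                adj[j].add(i)
            for cell in model.hex_conn:
                for a in cell:
                    adj[a].update(int(x) for x in cell if x != a)
            return adj

        def reachable(adj, start, blocked=frozenset()):
            seen, stack = {start}, [start]
            while stack:
                n = stack.pop()
                for nb in adj[n]:
                    if nb not in seen and nb not in blocked:
                        seen.add(nb)
                        stack.append(nb)
            return seen

        lysed = build_detailed_mesh(baseline_template, resolution=6,
                                    pars_lysis=True)
        intact = build_detailed_mesh(baseline_template, resolution=6,
                                     pars_lysis=False)
        assert not any(b.region == "pars" for b in lysed.beams)
        assert sum(b.region == "pars" for b in intact.beams) == 2
        spin = int(lysed.group("l5_posterior_arch")[-1])
        body = int(lysed.group("plate_l5_inferior")[0])
        # still one connected structure with lysis (path via the facets)
        adj = adjacency(lysed)
        assert body in reachable(adj, spin)
        # but blocking the sacrum cuts the arch off the body
        sacrum = set(int(x) for x in lysed.group("sacrum"))
        assert body not in reachable(adj, spin, blocked=frozenset(sacrum))
        # without lysis the pars carries a direct path around the sacrum
        adj2 = adjacency(intact)
        sacrum2 = set(int(x) for x in intact.group("sacrum"))
        spin2 = int(intact.group("l5_posterior_arch")[-1])
        assert body in reachable(adj2, spin2, blocked=frozenset(sacrum2))

    def test_minimum_resolution_enforced(self, baseline_template):
        with pytest.raises(ValueError):
            build_detailed_mesh(baseline_template, resolution=1)

    def test_ribcage_flag(self, baseline_template):
        with_ribs = build_detailed_mesh(baseline_template, resolution=6)
        without = build_detailed_mesh(baseline_template, resolution=6,
                                      include_ribcage=False)
        assert sum(b.region == "rib" for b in with_ribs.beams) > 0
        assert sum(b.region == "rib" for b in without.beams) == 0

    def test_mesh_json_round_trip(self, small_model, tmp_path):
        path = tmp_path / "mesh.json"
        small_model.to_json(path)
        from spondylofem.fem.mesh import SpineModel
        back = SpineModel.from_json(path)
        np.testing.assert_allclose(back.positions, small_model.positions)
        np.testing.assert_array_equal(back.hex_conn, small_model.hex_conn)
        assert back.hex_region == small_model.hex_region
        assert len(back.beams) == len(small_model.beams)
        assert back.chain_levels == small_model.chain_levels


class TestMaterialLibrary:
    def test_every_mesh_region_has_a_material(self, small_model):
        lib = default_material_library()
        for label in set(small_model.hex_region):
            m = lib.solid_for_region(label)
            assert m.E > 0
            assert 0 < m.nu < 0.5

    def test_region_key_mapping(self):
        assert region_material_key("cortical_L4") == "cortical"
        assert region_material_key("gp_s1_sensitive") == "gp_sensitive"
        assert region_material_key("nucleus_L5S1") == "nucleus"
        assert region_material_key("pelvis_bone") == "pelvis_bone"

    def test_modulus_override_scales_assembled_stiffness_linearly(
            self, baseline_template):
        """Doubling one region's E doubles its elements' contribution."""
        from spondylofem.fem.solve import assemble_global_stiffness
        lib = default_material_library()
        m1 = build_detailed_mesh(baseline_template, resolution=4,
                                 materials=lib, include_ribcage=False)
        lib2 = lib.override({"solids": {"nucleus": {"E": 2.0}}})
        m2 = build_detailed_mesh(baseline_template, resolution=4,
                                 materials=lib2, include_ribcage=False)
        idx = m1.elements_in_regions("nucleus_L5S1")
        assert np.allclose(m2.hex_E[idx], 2.0 * m1.hex_E[idx])
        from spondylofem.fem.elements import hex_stiffness_batch
        K1 = hex_stiffness_batch(m1.hex_coords()[idx], m1.hex_E[idx],
                                 m1.hex_nu[idx])
        K2 = hex_stiffness_batch(m2.hex_coords()[idx], m2.hex_E[idx],
                                 m2.hex_nu[idx])
        np.testing.assert_allclose(K2, 2.0 * K1, rtol=1e-12)

    def test_material_validation(self):
        from spondylofem.synthetic_data import Material
        with pytest.raises(ValueError):
            Material(E=-1.0, nu=0.3)
        with pytest.raises(ValueError):
            Material(E=10.0, nu=0.6)

    def test_resolution_robust_region_ordering(self, baseline_template):
        """Meshes at two resolutions agree on which region carries the
        maximal slip shear in the S1 growth plate."""
        from spondylofem.experiment_design import run_case
        from spondylofem.config import default_config
        winners = []
        for res in (6, 12):
            cfg = default_config()
            cfg["mesh"]["resolution"] = res
            summaries, _, _ = run_case(baseline_template, 61.0, 52.0, 30.0,
                                       cfg)
            table = summaries["s1_growth_plate"].table
            winners.append(table["max_tau_slip"].idxmax())
        assert winners[0] == winners[1]
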