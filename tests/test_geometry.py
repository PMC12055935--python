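"""Lesion geometry: nondimensional defect parametrization, cross-sections,
carving, and the study enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lesionlab import (
    DefectSpec,
    LesionConfig,
    build_cross_section,
    build_solid,
    carve_defect,
    chord_angle,
    chord_from_w,
    enumerate_study_models,
    normalized_length,
    normalized_width,
    solid_for_model,
)
from lesionlab.geometry import MATERIAL_IDS
from lesionlab.mesh import voxelize


class TestChordParametrization:
    @pytest.mark.parametrize(
        "chord, r_c, expected",
        [
            (0.0, 1.2, 0.0),
            (2.4, 1.2, 180.0),
            (math.sqrt(2.0), 1.0, 90.0),
        ],
    )
    def test_limiting_angles(self, chord, r_c, expected):
        assert chord_angle(chord, r_c) == pytest.approx(expected, abs=1e-10)

    @given(st.floats(0.0, 1.0), st.floats(0.5, 3.0))
    def test_arccos_form_equals_chord_law(self, frac, r_c):
        """arccos(1 - w~^2/2r^2) agrees with 2 arcsin(w~/2r) on the domain."""
        chord = frac * 2.0 * r_c
        oracle = math.degrees(2.0 * math.asin(chord / (2.0 * r_c)))
        assert chord_angle(chord, r_c) == pytest.approx(oracle, rel=1e-10, abs=1e-10)

    def test_domain_errors_name_the_bound(self):
        with pytest.raises(ValueError, match="diameter"):
            chord_angle(2.5, 1.2)
        with pytest.raises(ValueError, match="positive"):
            chord_angle(0.5, -1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            chord_angle(-0.1, 1.0)
        with pytest.raises(ValueError, match="180"):
            chord_from_w(0.9, 270.0, 1.0)

    @pytest.mark.parametrize("theta, theta_c, expected", [(30.0, 90.0, 1 / 3), (90.0, 90.0, 1.0)])
    def test_normalized_width_levels(self, theta, theta_c, expected):
        r_c = 1.2
        chord = 2.0 * r_c * math.sin(math.radians(theta / 2.0))
        assert normalized_width(chord, r_c, theta_c) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0.01, 0.99), st.sampled_from([90.0, 270.0]), st.floats(0.5, 2.5))
    def test_width_round_trip(self, w, theta_c, r_c):
        if w * theta_c > 180.0:
            return
        chord = chord_from_w(w, theta_c, r_c)
        assert normalized_width(chord, r_c, theta_c) == pytest.approx(w, rel=1e-10)

    def test_chord_from_w_closed_form(self):
        assert chord_from_w(0.0, 90.0, 1.0) == 0.0
        assert chord_from_w(1.0, 90.0, 1.0) == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_normalized_length(self):
        assert normalized_length(10.0 / 3.0, 10.0) == pytest.approx(1 / 3)
        assert normalized_length(10.0, 10.0) == 1.0
        with pytest.raises(ValueError):
            normalized_length(11.0, 10.0)


class TestCrossSection:
    def test_mid_lesion_stenosis_is_exact(self, default_config):
        cs = build_cross_section(default_config, default_config.lesion_center)
        healthy = math.pi * default_config.healthy_lumen_radius**2
        assert cs.area("lumen") == pytest.approx(0.30 * healthy, rel=1e-12)

    def test_healthy_section_ring_radii(self, default_config):
        cs = build_cross_section(default_config, 1.0)
        assert cs.labels == {"lumen", "media-intima", "adventitia"}
        media = [r for r in cs.regions if r.label == "media-intima"][0]
        adv = [r for r in cs.regions if r.label == "adventitia"][0]
        assert (media.r_in, media.r_out) == (1.5, 1.82)
        assert adv.r_out == pytest.approx(2.16)

    def test_calcium_angular_measure(self, default_config):
        cs = build_cross_section(default_config, default_config.lesion_center)
        spans = [r.theta1 - r.theta0 for r in cs.regions if r.label == "calcium"]
        assert sum(spans) == pytest.approx(270.0)
        cfg90 = LesionConfig(calcium_arc_angle=90.0)
        cs90 = build_cross_section(cfg90, cfg90.lesion_center)
        assert sum(r.theta1 - r.theta0 for r in cs90.regions if r.label == "calcium") == pytest.approx(90.0)

    @pytest.mark.parametrize("z", [0.5, 13.5, 14.9, 15.5, 20.0, 24.9, 26.5, 39.5])
    def test_area_conservation_along_axis(self, default_config, z):
        """Labeled ring areas partition the section: they sum to the area
        enclosed by the outer boundary."""
        cs = build_cross_section(default_config, z)
        assert cs.total_area == pytest.approx(cs.outer_area(), rel=1e-9)

    def test_conservation_with_carved_defect(self, default_config):
        cs = build_cross_section(
            default_config, default_config.lesion_center, DefectSpec("centered", 1 / 3, 1.0)
        )
        assert cs.total_area == pytest.approx(cs.outer_area(), rel=1e-9)

    def test_calcium_confined_to_lesion(self, default_config):
        z0, z1 = default_config.lesion_z_window
        assert "calcium" not in build_cross_section(default_config, z0 - 0.5).labels
        assert "calcium" in build_cross_section(default_config, z0 + 0.5).labels
        assert "calcium" not in build_cross_section(default_config, z1 + 0.5).labels

    def test_z_outside_artery_raises(self, default_config):
        with pytest.raises(ValueError, match="outside the artery"):
            build_cross_section(default_config, -1.0)


class TestCarveDefect:
    def test_through_splits_calcium_in_two(self, default_config):
        for w in (1 / 3, 2 / 3):
            solid = carve_defect(build_solid(default_config), DefectSpec("through", w, 1.0))
            assert solid.calcium_component_count() == 2

    @pytest.mark.parametrize("sub", ["sided", "centered"])
    def test_partial_defects_leave_one_component(self, default_config, sub):
        solid = build_solid(default_config, DefectSpec(sub, 2 / 3, 2 / 3))
        assert solid.calcium_component_count() == 1

    def test_carved_volume_matches_sector_fraction(self, default_config):
        intact = build_solid(default_config)
        for w, l in [(1 / 3, 1 / 3), (2 / 3, 2 / 3), (1 / 3, 1.0)]:
            sub = "through" if l == 1.0 else "centered"
            carved = carve_defect(intact, DefectSpec(sub, w, l))
            expected = w * l * intact.calcium_volume()
            assert carved.carved_volume() == pytest.approx(expected, rel=1e-12)

    def test_carved_volume_against_voxel_oracle(self, default_config):
        """Analytic carve volume agrees with a voxel count to <=1%.

        Voxel counting is averaged over randomized sub-pitch grid offsets to
        cancel grid-alignment bias at the carve's planar faces."""
        defect = DefectSpec("centered", 2 / 3, 2 / 3)
        solid = build_solid(default_config, defect)
        intact = build_solid(default_config)
        pitch = 0.03
        rmax = default_config.calcium_outer_radius + pitch
        dz0, dz1 = defect.z_window(default_config)
        rng = np.random.default_rng(0)
        estimates = []
        for _ in range(5):
            ox, oy, oz = rng.uniform(0.0, pitch, size=3)
            xs = np.arange(-rmax, rmax + pitch, pitch) + ox
            ys = np.arange(-rmax, rmax + pitch, pitch) + oy
            zs = np.arange(dz0 - 0.5, dz1 + 0.5, pitch) + oz
            X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
            n_intact = np.sum(intact.material_at(X, Y, Z) == MATERIAL_IDS["calcium"])
            n_carved = np.sum(solid.material_at(X, Y, Z) == MATERIAL_IDS["calcium"])
            estimates.append((n_intact - n_carved) * pitch**3)
        assert np.mean(estimates) == pytest.approx(solid.carved_volume(), rel=0.01)

    def test_idempotent_and_monotone(self, default_config):
        base = build_solid(default_config)
        d = DefectSpec("sided", 1 / 3, 2 / 3)
        once = carve_defect(base, d)
        twice = carve_defect(once, d)
        assert once.calcium_volume() == twice.calcium_volume()
        vols = [
            carve_defect(base, DefectSpec("centered", w, l)).calcium_volume()
            for w, l in [(1 / 3, 1 / 3), (1 / 3, 2 / 3), (2 / 3, 2 / 3)]
        ]
        assert vols[0] > vols[1] > vols[2]

    def test_box_mode_volume_consistent_with_classifier(self, default_config):
        """The prismatic-box carve volume (planar boolean x length) agrees
        with an offset-averaged voxel count of the point classifier."""
        d = DefectSpec("centered", 1 / 3, 2 / 3)
        box = build_solid(default_config, d, carve_mode="box")
        intact = build_solid(default_config)
        assert 0.0 < box.carved_volume() < intact.calcium_volume()
        pitch = 0.03
        rmax = default_config.calcium_outer_radius + pitch
        dz0, dz1 = d.z_window(default_config)
        rng = np.random.default_rng(1)
        estimates = []
        for _ in range(5):
            ox, oy, oz = rng.uniform(0.0, pitch, size=3)
            xs = np.arange(-rmax, rmax + pitch, pitch) + ox
            zs = np.arange(dz0 - 0.5, dz1 + 0.5, pitch) + oz
            X, Y, Z = np.meshgrid(xs, xs + (oy - ox), zs, indexing="ij")
            n_i = np.sum(intact.material_at(X, Y, Z) == MATERIAL_IDS["calcium"])
            n_b = np.sum(box.material_at(X, Y, Z) == MATERIAL_IDS["calcium"])
            estimates.append((n_i - n_b) * pitch**3)
        assert np.mean(estimates) == pytest.approx(box.carved_volume(), rel=0.01)

    def test_invalid_defects_rejected(self):
        with pytest.raises(ValueError):
            DefectSpec("sided", 1.0, 0.5)  # sided cannot consume the whole arc
        with pytest.raises(ValueError):
            DefectSpec("through", 0.5, 0.5)  # through must span the lesion
        with pytest.raises(ValueError):
            DefectSpec("centered", 1.5, 0.5)


class TestStudyEnumeration:
    def test_full_design_has_22_models(self):
        specs = enumerate_study_models()
        assert len(specs) == 22

    def test_eleven_models_per_arc(self):
        specs = enumerate_study_models()
        for arc in (90.0, 270.0):
            sub = [s for s in specs if s.arc_angle == arc]
            assert len(sub) == 11
            kinds = {"intact": 0, "sided": 0, "centered": 0, "through": 0}
            for s in sub:
                kinds["intact" if s.is_intact else s.defect.sub_model] += 1
            assert kinds == {"intact": 1, "sided": 4, "centered": 4, "through": 2}

    def test_identifiers_unique_and_stable(self):
        a = [s.identifier for s in enumerate_study_models()]
        b = [s.identifier for s in enumerate_study_models()]
        assert a == b
        assert len(set(a)) == 22

    def test_count_invariant_to_dimensions(self):
        cfg = LesionConfig(artery_length=60.0, lesion_length=20.0, calcium_thickness=0.8)
        assert len(enumerate_study_models(cfg)) == 22

    def test_solid_for_model_applies_arc(self, default_config):
        spec = [s for s in enumerate_study_models() if s.arc_angle == 90.0][0]
        solid = solid_for_model(spec, default_config)
        assert solid.config.calcium_arc_angle == 90.0
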