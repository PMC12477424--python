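import json
import math

import numpy as np
import pytest

from reefscape.fov import FovConfig, station_fov
from reefscape.grid import extract_profile
from reefscape.refuge import RefugeConfig, depression_mask, label_refuges
from reefscape.rugosity import planar_rugosity
from reefscape.simulate import (
    SITES,
    SPECIES_TAXA,
    SurfaceSpec,
    carve_pits,
    example_effect_spec,
    make_behavior_table,
    make_study_layout,
    make_surface,
)


class TestMakeSurface:
    def test_deterministic_under_seed(self):
        a = make_surface(SurfaceSpec(length=5, seed=3))
        b = make_surface(SurfaceSpec(length=5, seed=3))
        assert np.array_equal(a.elevations, b.elevations)

    def test_zero_relief_is_flat_open_smooth(self):
        g = make_surface(SurfaceSpec(length=5, relief_amplitude=0.0, seed=0))
        assert np.all(g.elevations == 0.0)
        assert planar_rugosity(g).rugosity == 0.0

    def test_relief_amplitude_sets_elevation_sd(self):
        g = make_surface(SurfaceSpec(length=10, relief_amplitude=0.12, seed=1))
        assert g.elevations.std() == pytest.approx(0.12, rel=1e-6)

    def test_larger_relief_increases_rugosity(self):
        rugs = [
            planar_rugosity(
                make_surface(SurfaceSpec(length=5, relief_amplitude=a, seed=4))
            ).rugosity
            for a in (0.05, 0.15, 0.30)
        ]
        assert rugs[0] < rugs[1] < rugs[2]

    def test_ridge_obstructs_view_at_analytic_angle(self):
        # a 0.5-m ridge whose crest is 0.5 m from the station: the eye sits
        # 2 cm above a flat substrate, so tan(angle) = 0.48 / 0.5
        g = make_surface(
            SurfaceSpec(length=6, relief_amplitude=0.0,
                        ridges=((3.0, 0.5, 0.05),), seed=0)
        )
        prof = extract_profile(g, (0.5, 1.0), (5.5, 1.0), g.cell_size)
        m = station_fov(prof, 2.0, +1, FovConfig(section_length=5.0))
        expect = (90 - math.degrees(math.atan2(0.48, 0.5))) / 90
        assert m.fov == pytest.approx(expect, abs=0.01)


class TestCarvePits:
    def test_zero_pits_leave_grid_unchanged(self):
        g = make_surface(SurfaceSpec(length=3, relief_amplitude=0.0, seed=0))
        carved, ledger = carve_pits(g, 0, (0.1, 0.2), (0.05, 0.1),
                                    np.random.default_rng(0))
        assert np.array_equal(carved.elevations, g.elevations)
        assert ledger.pits == []

    def test_ledger_matches_refuge_module_on_flat_base(self):
        g = make_surface(SurfaceSpec(length=6, width=3, relief_amplitude=0.0, seed=0))
        carved, ledger = carve_pits(
            g, 10, (0.2, 0.25), (0.05, 0.09), np.random.default_rng(5), margin=0.4,
        )
        cfg = RefugeConfig()
        for thr in cfg.depth_thresholds:
            rs = label_refuges(depression_mask(carved, thr, cfg), carved, cfg, thr)
            assert rs.count == ledger.expected_count(thr) == 10

    def test_shallow_pit_detected_only_at_lowest_threshold(self):
        g = make_surface(SurfaceSpec(length=3, relief_amplitude=0.0, seed=0))
        carved, _ = carve_pits(g, 1, (0.07, 0.07), (0.06, 0.06),
                               np.random.default_rng(1), margin=0.5)
        cfg = RefugeConfig()
        counts = {
            thr: label_refuges(depression_mask(carved, thr, cfg), carved, cfg).count
            for thr in cfg.depth_thresholds
        }
        assert counts[0.05] == 1
        assert counts[0.10] == 0 and counts[0.15] == 0

    def test_infeasible_placement_raises(self):
        g = make_surface(SurfaceSpec(length=1, width=1, relief_amplitude=0.0, seed=0))
        with pytest.raises(ValueError):
            carve_pits(g, 3, (0.1, 0.1), (0.4, 0.4), np.random.default_rng(0))


class TestStudyLayout:
    def test_study_preset_area_per_site(self):
        grids, manifest = make_study_layout(preset="study", seed=0)
        assert len(grids) == 3
        for site, site_grids in grids.items():
            assert len(site_grids) == 12
            # realized raster area differs from nominal only by pixel rounding
            area = sum(g.extent_x * g.extent_y for g in site_grids)
            assert area == pytest.approx(600.0, rel=5e-3)
        assert manifest["n_transects"] * manifest["length_m"] * manifest["width_m"] == 600.0

    def test_desk_preset_small_and_deterministic(self):
        g1, m1 = make_study_layout(preset="desk", seed=1, n_transects=3)
        g2, m2 = make_study_layout(preset="desk", seed=1, n_transects=3)
        assert m1 == m2
        for site in g1:
            for a, b in zip(g1[site], g2[site]):
                assert np.array_equal(a.elevations, b.elevations)
            assert g1[site][0].extent_x == pytest.approx(5.0, abs=0.02)

    def test_site_rugosity_ordering_matches_generating_relief(self):
        grids, _ = make_study_layout(preset="desk", seed=2, n_transects=4)
        mean_rug = {
            site: np.mean([planar_rugosity(g).rugosity for g in gs])
            for site, gs in grids.items()
        }
        # generating relief: Little Bight > Coral View > Sturch Bank
        assert mean_rug["Little Bight"] > mean_rug["Coral View"] > mean_rug["Sturch Bank"]

    def test_manifest_roundtrips_through_json(self):
        _, manifest = make_study_layout(preset="desk", seed=3, n_transects=2)
        assert json.loads(json.dumps(manifest)) == manifest


class TestBehaviorTable:
    def test_noiseless_zero_slope_limit_equals_cell_means(self):
        spec = example_effect_spec(
            seed=0, residual_sd=1e-12, body_length_slope=0.0,
            group_size_slope=0.0, start_distance_slope=0.0,
            observer_offsets={"A": 0.0, "B": 0.0}, n_per_cell=5,
        )
        t = make_behavior_table(spec)
        for (sp, site), mean in spec.cell_means.items():
            sub = t[(t.species == sp) & (t.site == site)]
            assert np.allclose(sub["fid_cm"], mean, atol=1e-9)

    def test_deterministic_under_seed(self):
        s = example_effect_spec(seed=9)
        a, b = make_behavior_table(s), make_behavior_table(s)
        assert a.equals(b)

    def test_damselfish_refuge_flight_frequency(self):
        spec = example_effect_spec(
            species=("Stegastes adustus",), sites=("Coral View",),
            cell_means={("Stegastes adustus", "Coral View"): 20.0},
            seed=123, n_per_cell=10_000,
        )
        t = make_behavior_table(spec)
        prop = (t["escape_category"] == "fled_refuge").mean()
        assert prop == pytest.approx(0.651, abs=0.01)

    def test_schema_and_invariants(self):
        t = make_behavior_table(example_effect_spec(seed=4))
        assert set(SITES) == set(t["site"].unique())
        assert set(t["taxon"]) <= {"damselfish", "parrotfish", "wrasse"}
        assert (t["start_distance_cm"] >= t["fid_cm"]).all()
        assert (t["fid_cm"] >= 0).all()
        assert t["body_length_cm"].between(3, 24).all()
        assert t["group_size"].between(1, 10).all()
        # distance columns present exactly for their category
        fled_open = t["escape_category"] == "fled_open"
        assert t.loc[fled_open, "distance_open_cm"].notna().all()
        assert t.loc[~fled_open, "distance_open_cm"].isna().all()

    def test_all_study_species_have_taxa(self):
        assert len(SPECIES_TAXA) == 10
        counts = {}
        for taxon in SPECIES_TAXA.values():
            counts[taxon] = counts.get(taxon, 0) + 1
        assert counts == {"wrasse": 2, "parrotfish": 4, "damselfish": 4}
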