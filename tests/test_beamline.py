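import numpy as np
import pytest

from protonarc.beamline import (
    BeamConfig,
    BeamlineSettings,
    DoseModel,
    Spot,
    beam_axes,
    block_spots,
    compute_dij,
    compute_dose_influence,
    generate_candidate_spots,
    make_beam_set,
    read_dose_influence,
    wet_at_points,
    write_dose_influence,
)
from protonarc.fixtures import slab_phantom
from protonarc.phantom import GridSpec, Phantom
from protonarc.scenarios import Scenario, build_scenarios

NOMINAL = Scenario((0.0, 0.0, 0.0), 1.0, "nominal")
FINE = BeamlineSettings(lateral_spacing_mm=5.0, el_spacing_mm=5.0, margin_mm=0.0,
                        raymarch_step_mm=1.0)


class TestMakeBeamSet:
    def test_pat36_gantry_angles_are_exact_decades(self):
        beams = make_beam_set("pat36")
        assert [b.gantry_deg for b in beams] == [10.0 * k for k in range(36)]
        assert all(b.couch_deg == 0 and not b.range_shifter for b in beams)

    def test_cs4_printed_angles_with_shifters(self):
        beams = make_beam_set("cs4")
        assert [(b.gantry_deg, b.couch_deg) for b in beams] == [
            (150, 0), (60, 0), (300, 0), (210, 0)]
        assert all(b.range_shifter and b.rs_wet_mm == 34.0 for b in beams)

    def test_cs6_shifter_off_only_at_160_and_200(self):
        beams = make_beam_set("cs6")
        assert [(b.gantry_deg, b.couch_deg) for b in beams] == [
            (200, 0), (260, 20), (310, 0), (50, 0), (100, 340), (160, 0)]
        no_rs = {b.gantry_deg for b in beams if not b.range_shifter}
        assert no_rs == {160.0, 200.0}

    def test_bao_candidates_are_72_equiangular(self):
        beams = make_beam_set("bao_candidates")
        assert len(beams) == 72
        diffs = np.diff([b.gantry_deg for b in beams])
        assert np.allclose(diffs, 360.0 / 72.0)

    def test_explicit_requires_angles_and_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            make_beam_set("explicit")
        with pytest.raises(ValueError):
            make_beam_set("spiral")


class TestWet:
    def test_uniform_slab_wet_equals_density_times_depth(self):
        ph = slab_phantom(160.0, (80.0, 120.0), spacing_mm=2.0)
        d, _, _ = beam_axes(BeamConfig(0.0))
        pts = np.array([[0.0, y, 0.0] for y in (10.0, 50.0, 100.0, 150.0)])
        wet = wet_at_points(ph, d, pts, 1.0, step_mm=0.5)
        assert np.allclose(wet, pts[:, 1], atol=0.75)

    def test_wet_scales_with_density(self):
        ph = slab_phantom(160.0, (80.0, 120.0), spacing_mm=2.0, density=1.03)
        d, _, _ = beam_axes(BeamConfig(0.0))
        wet = wet_at_points(ph, d, np.array([[0.0, 100.0, 0.0]]), 1.0, step_mm=0.5)
        assert wet[0] == pytest.approx(103.0, abs=1.0)

    def test_range_scale_multiplies_wet(self):
        ph = slab_phantom(160.0, (80.0, 120.0), spacing_mm=2.0)
        d, _, _ = beam_axes(BeamConfig(0.0))
        pts = np.array([[0.0, 100.0, 0.0]])
        w1 = wet_at_points(ph, d, pts, 1.0, 0.5)
        w2 = wet_at_points(ph, d, pts, 1.03, 0.5)
        assert w2[0] == pytest.approx(1.03 * w1[0])


class TestCandidateSpots:
    def test_slab_el_ladder_covers_target_wet_span(self):
        # voxel centers span WET 80..120 -> nine 5 mm layers at 80,85,...,120
        ph = slab_phantom(160.0, (79.0, 121.0), spacing_mm=2.0)
        spots = generate_candidate_spots(ph, BeamConfig(0.0), 0, FINE)
        central = [s for s in spots if abs(s.lateral_mm[0]) < 1e-9]
        assert sorted(s.nominal_range_mm for s in central) == [80, 85, 90, 95, 100, 105, 110, 115, 120]

    def test_point_target_gets_at_least_one_spot(self):
        ph = slab_phantom(160.0, (99.0, 101.0), spacing_mm=2.0)
        spots = generate_candidate_spots(ph, BeamConfig(0.0), 0, FINE)
        assert spots
        assert any(abs(s.nominal_range_mm - 100.0) <= 5.0 for s in spots)

    def test_empty_target_warns_and_returns_nothing(self):
        ph = slab_phantom(160.0, (80.0, 120.0), spacing_mm=2.0)
        masks = dict(ph.masks)
        masks["ctv70"] = np.zeros(ph.grid.shape, bool)
        empty = Phantom(ph.grid, ph.density, masks, ph.roles)
        with pytest.warns(UserWarning):
            assert generate_candidate_spots(empty, BeamConfig(0.0), 0, FINE) == []

    def test_opposed_beams_give_mirrored_spot_sets(self):
        # symmetric phantom: beams 0 and 180 deg must mirror in the lateral axis
        grid = GridSpec((41, 41, 1), (4.0, 4.0, 4.0), (-82.0, -82.0, -2.0))
        pts = grid.voxel_centers()
        r2 = (pts[:, 0] ** 2 + pts[:, 1] ** 2).reshape(grid.shape)
        body = r2 <= 75.0**2
        target = r2 <= 20.0**2
        ph = Phantom(grid, np.where(body, 1.0, 0.0), {"body": body, "ctv70": target},
                     {"body": "body", "ctv70": "target_high"})
        s0 = generate_candidate_spots(ph, BeamConfig(0.0), 0, FINE)
        s180 = generate_candidate_spots(ph, BeamConfig(180.0), 0, FINE)
        set0 = {(s.el_index, round(s.lateral_mm[0], 6)) for s in s0}
        set180 = {(s.el_index, round(-s.lateral_mm[0], 6)) for s in s180}
        assert set0 == set180

    def test_shifter_added_to_nominal_range(self):
        ph = slab_phantom(160.0, (79.0, 121.0), spacing_mm=2.0)
        no_rs = generate_candidate_spots(ph, BeamConfig(0.0), 0, FINE)
        rs = generate_candidate_spots(ph, BeamConfig(0.0, range_shifter=True), 0, FINE)
        assert {s.nominal_range_mm - 34.0 for s in rs} == {s.nominal_range_mm for s in no_rs}


class TestDoseEngine:
    def _single_spot_dose(self, ph, beam, spot, scenario=NOMINAL, settings=FINE):
        D = compute_dij(ph, [beam], [spot], scenario, settings)
        return np.asarray(D.todense())[:, 0].reshape(ph.grid.shape)

    def test_peak_at_nominal_range_in_water(self):
        ph = slab_phantom(160.0, (79.0, 121.0), spacing_mm=2.0)
        dose = self._single_spot_dose(ph, BeamConfig(0.0), Spot(0, 20, 100.0, (0.0, 0.0), 0))
        col = dose[ph.grid.shape[0] // 2, :, 0]
        ypeak = ph.grid.axis_centers(1)[np.argmax(col)]
        assert abs(ypeak - 100.0) <= 2.0

    def test_undershoot_scenario_pulls_peak_back(self):
        ph = slab_phantom(160.0, (79.0, 121.0), spacing_mm=2.0)
        under = Scenario((0.0, 0.0, 0.0), 1.03, "undershoot")
        dose = self._single_spot_dose(ph, BeamConfig(0.0), Spot(0, 20, 100.0, (0.0, 0.0), 0), under)
        col = dose[ph.grid.shape[0] // 2, :, 0]
        ypeak = ph.grid.axis_centers(1)[np.argmax(col)]
        # one voxel of quantization plus the sub-mm proximal bias of the
        # plateau term under the Gaussian-smeared peak
        assert abs(ypeak - 100.0 / 1.03) <= 2.5
        nom = self._single_spot_dose(ph, BeamConfig(0.0), Spot(0, 20, 100.0, (0.0, 0.0), 0))
        ypeak_nom = ph.grid.axis_centers(1)[np.argmax(nom[ph.grid.shape[0] // 2, :, 0])]
        assert 0.0 < ypeak_nom - ypeak <= 2.0 + (100.0 - 100.0 / 1.03)

    def test_setup_shift_translates_dose(self):
        ph = slab_phantom(159.0, (75.0, 123.0), spacing_mm=3.0, width_mm=90.0)
        spot = Spot(0, 20, 100.0, (0.0, 0.0), 0)
        nom = self._single_spot_dose(ph, BeamConfig(0.0), spot)
        shifted = self._single_spot_dose(
            ph, BeamConfig(0.0), spot, Scenario((3.0, 0.0, 0.0), 1.0, "+x")
        )
        # dose_s(x) = dose_nom(x + 3 mm): one voxel at 3 mm spacing
        assert np.allclose(shifted[:-1, 5:-5, 0], nom[1:, 5:-5, 0], atol=1e-6)

    def test_lateral_sigma_wider_with_range_shifter(self):
        model = DoseModel()
        z = np.array([100.0])
        assert model.sigma(z, True)[0] > model.sigma(z, False)[0]

    def test_penumbra_wider_with_shifter_at_matched_peak_depth(self):
        ph = slab_phantom(160.0, (79.0, 121.0), spacing_mm=2.0)
        d_no = self._single_spot_dose(ph, BeamConfig(0.0), Spot(0, 20, 100.0, (0.0, 0.0), 0))
        d_rs = self._single_spot_dose(
            ph, BeamConfig(0.0, range_shifter=True), Spot(0, 20, 134.0, (0.0, 0.0), 0)
        )

        def width_80_20(dose):
            iy = np.argmin(np.abs(ph.grid.axis_centers(1) - 100.0))
            prof = dose[:, iy, 0]
            prof = prof / prof.max()
            xs = ph.grid.axis_centers(0)
            right = prof[xs >= 0]
            x_r = xs[xs >= 0]
            x80 = np.interp(-0.8, -right, x_r)  # falling profile
            x20 = np.interp(-0.2, -right, x_r)
            return x20 - x80

        assert width_80_20(d_rs) > width_80_20(d_no)

    def test_dose_nonnegative_and_linear_in_weights(self):
        ph = slab_phantom(120.0, (59.0, 91.0), spacing_mm=3.0)
        dij = compute_dose_influence(ph, [BeamConfig(0.0)], build_scenarios(mode="nominal_only"), FINE)
        assert (dij.nominal.data >= 0).all()
        w = np.linspace(0, 2, dij.n_spots)
        assert np.allclose(dij.dose(3.0 * w), 3.0 * dij.dose(w))

    def test_round_trip_io(self, tmp_path):
        ph = slab_phantom(120.0, (59.0, 91.0), spacing_mm=3.0)
        dij = compute_dose_influence(ph, [BeamConfig(0.0)], build_scenarios(mode="nominal_only"), FINE)
        write_dose_influence(dij, tmp_path / "dij")
        back = read_dose_influence(tmp_path / "dij")
        assert back.spots == dij.spots
        assert np.allclose((back.nominal - dij.nominal).toarray(), 0, atol=1e-7)


class TestBlocking:
    def _slab_with_block(self, x_lo, x_hi, y_lo=30.0, y_hi=45.0):
        ph = slab_phantom(160.0, (79.0, 121.0), spacing_mm=2.0, width_mm=80.0)
        xs = ph.grid.axis_centers(0)
        ys = ph.grid.axis_centers(1)
        block = np.zeros(ph.grid.shape, bool)
        block[np.ix_((xs >= x_lo) & (xs <= x_hi), (ys >= y_lo) & (ys <= y_hi), [0])] = True
        masks = dict(ph.masks)
        masks["block"] = block & ph.body_mask
        roles = dict(ph.roles)
        roles["block"] = "blocking"
        return Phantom(ph.grid, ph.density, masks, roles)

    def test_no_blocking_is_identity(self):
        ph = self._slab_with_block(1000.0, 2000.0)  # empty blocking mask
        beams = [BeamConfig(0.0)]
        spots = generate_candidate_spots(ph, beams[0], 0, FINE)
        assert block_spots(spots, ph, ["block"], beams, FINE) == spots

    def test_full_aperture_occlusion_removes_all_spots(self):
        ph = self._slab_with_block(-100.0, 100.0)
        beams = [BeamConfig(0.0)]
        spots = generate_candidate_spots(ph, beams[0], 0, FINE)
        assert block_spots(spots, ph, ["block"], beams, FINE) == []

    def test_partial_block_matches_bruteforce_ray_oracle(self):
        ph = self._slab_with_block(-21.0, 1.0)
        beams = [BeamConfig(0.0)]
        spots = generate_candidate_spots(ph, beams[0], 0, FINE)
        kept = block_spots(spots, ph, ["block"], beams, FINE)
        kept_ids = {s.id for s in kept}

        # independent dense ray-march oracle (plain python stepping)
        block = ph.masks["block"]
        grid = ph.grid
        for s in spots:
            hit = False
            wet = 0.0
            y = -20.0
            x = s.lateral_mm[0]
            while y < 170.0 and wet < s.nominal_range_mm:
                i = int(np.floor((x - grid.origin_mm[0]) / grid.spacing_mm[0]))
                j = int(np.floor((y - grid.origin_mm[1]) / grid.spacing_mm[1]))
                if 0 <= i < grid.shape[0] and 0 <= j < grid.shape[1]:
                    if block[i, j, 0]:
                        hit = True
                        break
                    wet += ph.density[i, j, 0] * 0.25
                y += 0.25
            assert (s.id not in kept_ids) == hit, f"spot {s.id} at x={x}"

    def test_blocking_is_a_filter_and_idempotent(self):
        ph = self._slab_with_block(-21.0, 1.0)
        beams = [BeamConfig(0.0)]
        spots = generate_candidate_spots(ph, beams[0], 0, FINE)
        kept = block_spots(spots, ph, ["block"], beams, FINE)
        assert set(s.id for s in kept) <= set(s.id for s in spots)
        assert block_spots(kept, ph, ["block"], beams, FINE) == kept

    def test_unknown_structure_name_rejected(self):
        ph = slab_phantom(120.0, (59.0, 91.0), spacing_mm=3.0)
        with pytest.raises(KeyError):
            block_spots([], ph, ["missing"], [BeamConfig(0.0)])
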