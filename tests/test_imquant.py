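import numpy as np
import pytest

from cyclefate import simulate_cohort
from cyclefate.imquant import (
    ImageParams,
    _disk_offsets,
    _ring_offsets,
    detect_nuclei,
    flatten_background,
    link_tracks,
    measure_cell,
)
from cyclefate.render import FieldRenderer, RenderParams

from conftest import zero_noise_config


@pytest.fixture(scope="module")
def clean_cells():
    cfg = zero_noise_config(condition="glucose_depletion", n_mothers=6, rng_seed=2)
    return simulate_cohort(cfg)


def _noise_free_params(**kw):
    kw.setdefault("shape", (256, 256))
    kw.setdefault("background_level", 0.0)
    kw.setdefault("bias_amplitude", 0.0)
    return RenderParams(**kw)


class TestGeometry:
    def test_disk_and_ring_disjoint(self):
        p = ImageParams()
        disk = set(zip(*_disk_offsets(p.nuclear_radius)))
        ring = set(zip(*_ring_offsets(p.nuclear_radius, p.ring_width)))
        assert disk.isdisjoint(ring)

    def test_uniform_disk_and_ring_ratio(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        d2 = (yy - 32) ** 2 + (xx - 32) ** 2
        img[d2 <= 25] = 100.0
        img[(d2 > 25) & (d2 <= 81)] = 60.0
        m = measure_cell({"CDK2": img}, (32, 32), ImageParams())
        assert m.nuclear_means["CDK2"] == pytest.approx(100.0)
        assert m.cyt_cdk2_mean == pytest.approx(60.0)
        assert m.cdk2_ratio == pytest.approx(0.6)

    def test_edge_clipped_cell_flagged_ring_omitted(self):
        img = np.ones((64, 64))
        m = measure_cell({"CDK2": img}, (6, 32), ImageParams())
        assert any("edge" in f for f in m.flags)
        assert np.isnan(m.cyt_cdk2_mean)

    def test_neighbour_in_ring_flags_contamination(self):
        img = np.ones((64, 64))
        m = measure_cell(
            {"CDK2": img}, (32, 32), ImageParams(), other_centers=[(32, 41)]
        )
        assert any("contaminated" in f for f in m.flags)


class TestFlattenBackground:
    def test_flat_image_no_cells_corrects_to_zero(self):
        corr, _ = flatten_background(np.full((256, 256), 7.0), ImageParams())
        assert np.abs(corr).max() < 1e-9

    def test_linear_bias_residual_under_five_percent(self):
        yy, xx = np.mgrid[0:256, 0:256]
        bias = 1 + 0.3 * (xx / 256 - 0.5) + 0.2 * (yy / 256 - 0.5)
        img = bias * 10.0
        corr, _ = flatten_background(img, ImageParams())
        assert np.ptp(corr) < 0.05 * np.ptp(img)

    def test_bias_free_image_near_identity(self, clean_cells):
        ren = FieldRenderer(clean_cells.tracks,
                            _noise_free_params(background_level=10.0))
        imgs, truth = ren.render_frame(1.0, 0)
        corr, _ = flatten_background(imgs["H1"], ImageParams())
        for _, row in truth.iterrows():
            m = measure_cell({"H1": corr}, (row.y, row.x), ImageParams())
            assert m.nuclear_means["H1"] == pytest.approx(row.H1, rel=0.01)

    def test_zero_image_skips_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            corr, _ = flatten_background(np.zeros((128, 128)), ImageParams())
        assert np.abs(corr).max() == 0.0


class TestDetectNuclei:
    def test_single_nucleus_found_within_one_pixel(self, clean_cells):
        ren = FieldRenderer(clean_cells.tracks[:1], _noise_free_params())
        imgs, truth = ren.render_frame(clean_cells.tracks[0].times[0], 0)
        det = detect_nuclei(imgs["H1"], ImageParams())
        assert len(det) == 1
        assert np.hypot(det[0, 0] - truth.y.iloc[0],
                        det[0, 1] - truth.x.iloc[0]) <= 1.0

    def test_rendered_field_detection_accuracy(self):
        cfg = zero_noise_config(condition="control", n_mothers=20, rng_seed=9)
        coh = simulate_cohort(cfg)
        ren = FieldRenderer(coh.mothers, _noise_free_params(shape=(512, 512)))
        imgs, truth = ren.render_frame(1.0, 0)
        det = detect_nuclei(imgs["H1"], ImageParams())
        assert len(det) == len(truth) == 20
        matched = 0
        for _, row in truth.iterrows():
            d = np.hypot(det[:, 0] - row.y, det[:, 1] - row.x).min()
            matched += d <= 2.0
        assert matched / len(truth) >= 0.95

    def test_rendered_truth_table_positive_intensities(self):
        cfg = zero_noise_config(condition="control", n_mothers=20, rng_seed=9)
        coh = simulate_cohort(cfg)
        ren = FieldRenderer(
            coh.mothers, _noise_free_params(shape=(512, 512), bias_amplitude=0.2)
        )
        _, truth = ren.render_frame(1.0, 0)
        assert len(truth) == 20
        assert (truth[["Cdt1", "Geminin", "SLBP", "H1", "cdk2_nuc"]] > 0).all().all()

    def test_blank_frame_empty(self):
        assert len(detect_nuclei(np.zeros((128, 128)), ImageParams())) == 0

    def test_field_too_small_rejected(self, clean_cells):
        with pytest.raises(ValueError, match="too small"):
            FieldRenderer(clean_cells.tracks, RenderParams(shape=(64, 64)))

    def test_remeasured_nuclear_means_within_two_percent(self, clean_cells):
        ren = FieldRenderer(clean_cells.tracks, _noise_free_params())
        imgs, truth = ren.render_frame(2.0, 0)
        params = ImageParams()
        det = detect_nuclei(imgs["H1"], params)
        for _, row in truth.iterrows():
            i = int(np.argmin(np.hypot(det[:, 0] - row.y, det[:, 1] - row.x)))
            m = measure_cell(imgs, tuple(det[i]), params)
            for ch in ("Cdt1", "Geminin", "SLBP", "H1"):
                assert m.nuclear_means[ch] == pytest.approx(row[ch], rel=0.02)


class TestLinking:
    def test_stationary_cells_one_track_each(self):
        pts = np.array([[20.0, 20.0], [60.0, 60.0], [100.0, 40.0]])
        tracks = link_tracks([pts] * 10, max_disp=5.0)
        assert len(tracks) == 3
        assert all(len(t.frames) == 10 for t in tracks)

    def test_division_recovered_as_two_children(self):
        frames = [np.array([[50.0, 50.0]])] * 3 + [
            np.array([[44.0, 50.0], [56.0, 50.0]])
        ] * 3
        tracks = link_tracks(frames, max_disp=8.0)
        parents = [t for t in tracks if t.parent_id is not None]
        assert len(parents) == 2
        assert {p.parent_id for p in parents} == {0}

    def test_slow_drift_links_mostly_correct(self, clean_cells):
        ren = FieldRenderer(
            clean_cells.tracks, _noise_free_params(drift_sigma=0.3, rng_seed=4)
        )
        times = np.arange(-10.0, 20.0, 0.25)
        stacks, truth = ren.render_movie(times)
        params = ImageParams()
        dets = [detect_nuclei(f, params) for f in stacks["H1"]]
        tracks = link_tracks(dets, max_disp=8.0)
        by_fr = {f: g for f, g in truth.groupby("frame")}
        good = tot = 0
        for tr in tracks:
            ids = []
            for f, (cy, cx) in zip(tr.frames, tr.coords):
                g = by_fr.get(f)
                if g is None or not len(g):
                    continue
                d = np.hypot(g.y - cy, g.x - cx)
                ids.append(g.iloc[int(np.argmin(d))].cell_id)
            tot += max(len(ids) - 1, 0)
            good += sum(a == b for a, b in zip(ids, ids[1:]))
        assert tot > 0
        assert good / tot >= 0.95

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            link_tracks([np.zeros((1, 2))], max_disp=5.0)
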