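import numpy as np
import pytest

from motanlage import adhesion_quant as aq
from motanlage import expression_fold as ef
from motanlage import msd_analysis as ma
from motanlage import synthetic_data as sd


class TestMotilityParams:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(p_move_to_pause=1.5), "p_move_to_pause"),
            (dict(p_pause_to_move=-0.1), "p_pause_to_move"),
            (dict(speed_mean=-1.0), "speed_mean"),
            (dict(speed_sd=-0.5), "speed_sd"),
            (dict(turn_kappa=-2.0), "turn_kappa"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, msg):
        base = dict(
            p_move_to_pause=0.1,
            p_pause_to_move=0.3,
            speed_mean=0.5,
            speed_sd=0.1,
            turn_kappa=1.0,
        )
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            sd.MotilityParams(**base)

    def test_stationary_fraction(self):
        p = sd.MotilityParams(0.1, 0.3, 0.5, 0.1, 1.0)
        assert p.stationary_moving_fraction == pytest.approx(0.75)


class TestSimulateTracks:
    def test_degenerate_persistent_limit(self):
        p = sd.MotilityParams(
            p_move_to_pause=0.0,
            p_pause_to_move=1.0,
            speed_mean=1.0,
            speed_sd=0.0,
            turn_kappa=1e8,
            pause_jitter_um=0.0,
        )
        ts = sd.simulate_tracks(p, 3, 25, 5.0, seed=0)
        for tr in ts.tracks:
            steps = tr.step_lengths()
            assert np.allclose(steps, 5.0)
            # near-straight: net displacement almost equals path length
            net = np.linalg.norm(tr.positions[-1] - tr.positions[0])
            assert net == pytest.approx(steps.sum(), rel=1e-4)

    def test_determinism(self):
        p = sd.preset_params("WT")
        a = sd.simulate_tracks(p, 4, 25, 5.0, seed=99)
        b = sd.simulate_tracks(p, 4, 25, 5.0, seed=99)
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_different_seed_differs(self):
        p = sd.preset_params("WT")
        a = sd.simulate_tracks(p, 2, 25, 5.0, seed=1)
        b = sd.simulate_tracks(p, 2, 25, 5.0, seed=2)
        assert not np.array_equal(a.tracks[0].positions, b.tracks[0].positions)

    def test_tracks_start_at_origin(self):
        ts = sd.simulate_tracks(sd.preset_params("MUT"), 3, 10, 5.0, seed=0)
        for tr in ts.tracks:
            np.testing.assert_array_equal(tr.positions[0], [0.0, 0.0])

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(n_cells=0), "n_cells"),
            (dict(n_points=0), "n_points"),
            (dict(dt_min=-5.0), "dt_min"),
        ],
    )
    def test_bad_sizes_named(self, kwargs, msg):
        args = dict(n_cells=2, n_points=25, dt_min=5.0, seed=0)
        args.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            sd.simulate_tracks(sd.preset_params("WT"), **args)

    def test_isotropic_msd_closed_form(self):
        # kappa = 0, never pausing, fixed speed: per-axis step variance is
        # L^2/2, so MSD(k dt) = 2 (L^2/2) k = L^2 k.
        p = sd.MotilityParams(0.0, 1.0, 0.6, 0.0, 0.0, pause_jitter_um=0.0)
        ts = sd.simulate_tracks(p, 2000, 25, 5.0, seed=3)
        lags = [20.0, 40.0, 60.0, 80.0, 100.0, 120.0]
        curve = ma.displacement_msd(list(ts.tracks), lags)
        L2 = (0.6 * 5.0) ** 2
        expected = L2 * np.asarray(lags) / 5.0
        assert np.all(
            np.abs(curve.mean_squares_um2 / expected - 1.0) < 0.05
        )

    def test_two_state_chain_stationary_fraction(self):
        # long-run moving fraction matches p_pm / (p_mp + p_pm) within 3 MC SE
        p = sd.MotilityParams(0.2, 0.3, 0.5, 0.0, 0.0)
        n_points = 1001
        n_cells = 100  # 10^5 intervals total
        ts = sd.simulate_tracks(p, n_cells, n_points, 5.0, seed=8)
        moving = 0
        total = 0
        for tr in ts.tracks:
            steps = tr.step_lengths()
            moving += int((steps > 1.0).sum())  # jitter is ~0.1 um << 1 um
            total += steps.size
        frac = moving / total
        target = p.stationary_moving_fraction
        # intervals are autocorrelated; conservative SE uses an effective
        # sample size shrunk by the chain's mixing factor
        rho = 1.0 - p.p_move_to_pause - p.p_pause_to_move
        n_eff = total * (1 - rho) / (1 + rho)
        se = np.sqrt(target * (1 - target) / n_eff)
        assert abs(frac - target) < 3 * se


class TestPresets:
    def test_unknown_group(self):
        with pytest.raises(KeyError):
            sd.preset_params("XX")

    @pytest.mark.parametrize("group", ["WT", "HET", "MUT"])
    def test_groups_labelled(self, group):
        assert sd.preset_params(group).group_label == group


class TestAdhesionScene:
    def test_all_leading(self):
        scene = sd.simulate_adhesion_scene(3, 0, 2.0, 0.0, seed=1)
        for pos, _ in scene.puncta:
            proj = (pos - scene.centroid) @ scene.polarity_axis
            assert proj > 0
        assert scene.truth_counts == (3, 0)

    def test_empty_scene(self):
        scene = sd.simulate_adhesion_scene(0, 0, 2.0, 0.0, seed=1)
        assert scene.puncta == ()
        assert scene.truth_counts == (0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_adhesion_scene(-1, 0, 2.0, 0.0, seed=1)

    def test_truth_counts_recoverable(self):
        scene = sd.simulate_adhesion_scene(14, 12, 2.14, 0.5, seed=7)
        puncta = [
            aq.Punctum(position=pos, area_um2=area)
            for pos, area in scene.puncta
        ]
        labels = aq.partition_edges(
            puncta, scene.centroid, scene.polarity_axis
        )
        n_lead = sum(1 for l in labels if l == aq.LEADING)
        n_trail = sum(1 for l in labels if l == aq.TRAILING)
        assert (n_lead, n_trail) == scene.truth_counts

    def test_determinism(self):
        a = sd.simulate_adhesion_scene(5, 5, 2.0, 0.3, seed=4)
        b = sd.simulate_adhesion_scene(5, 5, 2.0, 0.3, seed=4)
        for (pa, aa), (pb, ab) in zip(a.puncta, b.puncta):
            np.testing.assert_array_equal(pa, pb)
            assert aa == ab


class TestRenderPuncta:
    def test_empty_scene_zero_grid(self):
        scene = sd.simulate_adhesion_scene(0, 0, 2.0, 0.0, seed=1)
        img = sd.render_puncta_image(scene, 0.2, 0.3, noise_sd=0.0)
        assert np.all(img == 0.0)

    def test_single_punctum_peak_location(self):
        scene = sd.simulate_adhesion_scene(1, 0, 2.0, 0.0, seed=2)
        img = sd.render_puncta_image(scene, 0.2, 0.3, noise_sd=0.0)
        (pos, _area) = scene.puncta[0]
        origin = sd.image_origin(scene)
        row, col = np.unravel_index(np.argmax(img), img.shape)
        px = 0.2
        peak_xy = origin + (np.array([col, row]) + 0.5) * px
        assert np.all(np.abs(peak_xy - pos) <= px)

    def test_bad_pixel_size(self):
        scene = sd.simulate_adhesion_scene(1, 0, 2.0, 0.0, seed=2)
        with pytest.raises(ValueError):
            sd.render_puncta_image(scene, 0.0, 0.3)

    def test_detection_round_trip(self):
        # 3 well-separated puncta recovered exactly
        scene = sd.AdhesionScene(
            cell_id="c",
            centroid=np.zeros(2),
            polarity_axis=np.array([1.0, 0.0]),
            puncta=(
                (np.array([-6.0, 0.0]), 3.0),
                (np.array([0.0, 6.0]), 3.0),
                (np.array([6.0, 0.0]), 3.0),
            ),
            truth_counts=(1, 2),
        )
        img = sd.render_puncta_image(scene, 0.2, 0.3, noise_sd=0.0)
        origin = sd.image_origin(scene)
        puncta = aq.detect_puncta(
            img, 0.2, threshold=0.05, min_area_um2=0.2,
            origin_um=tuple(origin),
        )
        assert len(puncta) == 3


class TestSimulateExpression:
    def _spec(self, noise=0.0, outlier=0.0):
        return sd.ExpressionSpec(
            genes=(("g1", 100.0, 110.0, 120.0, noise),
                   ("g2", 50.0, 40.0, 200.0, noise)),
            outlier_rate=outlier,
        )

    def test_zero_noise_exact(self):
        df = sd.simulate_expression(self._spec(), seed=0)
        for gene, mean in (("g1", 100.0), ("g2", 50.0)):
            vals = df[(df.gene == gene) & (df.genotype == "WT")]["value"]
            assert np.allclose(vals, mean)

    def test_seed_reproducibility(self):
        a = sd.simulate_expression(self._spec(noise=5.0), seed=3)
        b = sd.simulate_expression(self._spec(noise=5.0), seed=3)
        assert a.equals(b)

    def test_outlier_rate_one_always_flagged(self):
        df = sd.simulate_expression(
            self._spec(noise=1.0, outlier=1.0), seed=5
        )
        for (gene, genotype), sub in df.groupby(["gene", "genotype"]):
            vals = sub.sort_values("replicate")["value"].to_list()
            _, flagged = ef.replicate_filter(vals)
            assert flagged is not None, f"{gene}/{genotype} not flagged"


class TestSimulateDnaHistogram:
    def test_pure_g1_single_narrow_peak(self):
        spec = sd.DnaHistogramSpec(
            fractions=(1.0, 0.0, 0.0), cv=1e-6, n_cells=1000
        )
        hist = sd.simulate_dna_histogram(spec, seed=0)
        nonzero = np.flatnonzero(hist.counts)
        assert nonzero.size <= 2  # all mass in one (or two adjacent) bins
        center = hist.centers[np.argmax(hist.counts)]
        assert center == pytest.approx(100.0, rel=0.02)

    def test_determinism(self):
        spec = sd.DnaHistogramSpec(fractions=(0.7, 0.2, 0.1), n_cells=5000)
        a = sd.simulate_dna_histogram(spec, seed=2)
        b = sd.simulate_dna_histogram(spec, seed=2)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            sd.DnaHistogramSpec(fractions=(0.5, 0.2, 0.2))
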