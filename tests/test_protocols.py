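import numpy as np
import pytest

from whorfnet.architecture import AREA_INDEX, CELLS_PER_AREA, N_E
from whorfnet.params import SimulationParams
from whorfnet.patterns import COLOR_TAGS, generate_pattern_set
from whorfnet.protocols import (
    ExperimentPlan, LabelMapping, build_phase1_frame, build_phase2_frame,
    phase1_stimulus_types, run_experiment, run_extraction_trial,
    run_recognition_trial,
)


@pytest.fixture(scope="module")
def patterns():
    return generate_pattern_set(3)


class TestLabelMappings:
    def test_english_two_words(self):
        m = LabelMapping.english()
        assert m.word_index("blue_light") == m.word_index("blue_dark")
        assert m.word_index("green_light") == m.word_index("green_dark")
        assert len(set(m.mapping.values())) == 2

    def test_russian_three_words(self):
        m = LabelMapping.russian()
        assert m.word_index("blue_light") != m.word_index("blue_dark")
        assert m.word_index("green_light") == m.word_index("green_dark")
        assert len(set(m.mapping.values())) == 3

    def test_all_colors_mapped(self):
        with pytest.raises(ValueError):
            LabelMapping("x", {"blue_light": 1})


class TestScheduling:
    def test_phase1_counts_and_reshuffling(self, params):
        """Each of the 7 stimulus types appears exactly n times; the order
        differs across seeds (randomized-permutation contract)."""
        labels = list(range(7))
        n = 20
        base = np.repeat(np.arange(7), n)
        s1 = np.random.default_rng(1).permutation(base)
        s2 = np.random.default_rng(2).permutation(base)
        for sched in (s1, s2):
            assert len(sched) == 7 * n
            assert all((sched == k).sum() == n for k in labels)
        assert not np.array_equal(s1, s2)

    def test_phase1_has_seven_stimulus_types(self, patterns):
        assert len(phase1_stimulus_types(patterns)) == 7

    def test_default_phase2_trial_count(self, params):
        # 4 color-label pairings x 1000 randomized trials
        assert 4 * params.trials_phase2_per_pairing == 4000

    def test_phase2_label_presentation_counts(self, params):
        # english: 2000 presentations of each word; russian: w3 2000, w1/w2 1000
        n = params.trials_phase2_per_pairing
        eng = LabelMapping.english()
        rus = LabelMapping.russian()
        eng_counts = {w: sum(n for t in COLOR_TAGS if eng.word_index(t) == w) for w in (1, 2)}
        rus_counts = {w: sum(n for t in COLOR_TAGS if rus.word_index(t) == w) for w in (1, 2, 3)}
        assert eng_counts == {1: 2000, 2: 2000}
        assert rus_counts == {1: 1000, 2: 1000, 3: 2000}


class TestStimulusFrames:
    def test_phase1_color_frame(self, patterns, params):
        rng = np.random.default_rng(0)
        frame = build_phase1_frame("blue_light", patterns, params, rng)
        v1 = frame.drive[:CELLS_PER_AREA]
        assert (v1 >= params.inp_strength).sum() == 22
        # noise drive reaches the three non-relevant primaries
        for area in ("A1", "M1i", "M1L"):
            a = AREA_INDEX[area]
            assert frame.drive[a * CELLS_PER_AREA:(a + 1) * CELLS_PER_AREA].sum() > 0
        # secondary areas receive nothing
        to = AREA_INDEX["TO"]
        assert frame.drive[to * CELLS_PER_AREA:(to + 1) * CELLS_PER_AREA].sum() == 0

    def test_phase1_word_frame_drives_both_halves(self, patterns, params):
        rng = np.random.default_rng(0)
        frame = build_phase1_frame("word2", patterns, params, rng)
        for area in ("A1", "M1i"):
            a = AREA_INDEX[area]
            seg = frame.drive[a * CELLS_PER_AREA:(a + 1) * CELLS_PER_AREA]
            assert (seg >= params.inp_strength).sum() == 22

    def test_phase2_frame_copresents_color_and_label(self, patterns, params):
        rng = np.random.default_rng(0)
        frame = build_phase2_frame("blue_dark", patterns, LabelMapping.russian(), params, rng)
        for area in ("V1", "A1", "M1i"):
            a = AREA_INDEX[area]
            seg = frame.drive[a * CELLS_PER_AREA:(a + 1) * CELLS_PER_AREA]
            assert (seg >= params.inp_strength).sum() == 22
        m1l = AREA_INDEX["M1L"]
        assert frame.drive[m1l * CELLS_PER_AREA:(m1l + 1) * CELLS_PER_AREA].sum() > 0


class TestExtractionAndRecognition:
    def test_extraction_tensor_shape(self, network, patterns):
        t = run_extraction_trial(network, patterns.color("blue_light"), seed=0)
        assert t.shape == (12, 625, 30)

    def test_extraction_freezes_weights(self, network, patterns):
        before = network.weight_hash()
        run_extraction_trial(network, patterns.color("blue_light"), seed=0)
        assert network.weight_hash() == before

    def test_silent_network_gives_zero_tensor(self, network, patterns):
        t = run_extraction_trial(
            network, patterns.color("blue_light"), seed=0, baseline_noise=False
        )
        # untrained weak weights: activity stays within the stimulated area
        assert t.shape == (12, 625, 30)
        assert (t >= 0).all()

    def test_recognition_raster_window(self, network, patterns, params):
        r = run_recognition_trial(network, patterns.color("blue_dark"), seed=0)
        assert r.shape == (params.recog_baseline_steps + params.stim_steps_recog
                           + params.recog_post_steps, N_E)
        assert r.shape[0] == 40

    def test_recognition_noise_free_baseline_silent(self, network, patterns, params):
        r = run_recognition_trial(
            network, patterns.color("blue_dark"), seed=0, baseline_noise=False
        )
        assert not r[:params.recog_baseline_steps].any()


@pytest.fixture(scope="module")
def tiny_result():
    plan = ExperimentPlan(
        params=SimulationParams(), master_seed=11, n_networks=1,
        trials_phase1=2, trials_phase2=2,
    )
    return run_experiment(plan)


class TestExperiment:
    def test_three_model_types(self, tiny_result):
        assert set(tiny_result.rate_tensors[0]) == {"perceptual", "english", "russian"}

    def test_language_branches_share_phase1_weights(self, tiny_result):
        h = tiny_result.weight_hashes[0]
        assert h["english_start"] == h["russian_start"] == h["phase1"]

    def test_all_colors_extracted(self, tiny_result):
        for model, tensors in tiny_result.rate_tensors[0].items():
            assert set(tensors) == set(COLOR_TAGS)

    def test_rasters_for_language_models_only(self, tiny_result):
        assert set(tiny_result.rasters[0]) == {"english", "russian"}

    def test_reproducible_from_master_seed(self, tiny_result):
        plan = ExperimentPlan(
            params=SimulationParams(), master_seed=11, n_networks=1,
            trials_phase1=2, trials_phase2=2,
        )
        again = run_experiment(plan)
        t0 = tiny_result.rate_tensors[0]["english"]["blue_light"]
        t1 = again.rate_tensors[0]["english"]["blue_light"]
        assert np.array_equal(t0, t1)
        assert again.weight_hashes == tiny_result.weight_hashes
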