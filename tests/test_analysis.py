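import numpy as np
import pytest

from whorfnet.analysis import (
    CellAssembly, compute_rdm, count_shared_unique, exclude_networks,
    extract_assembly, activation_vectors, mmn_trace,
)
from whorfnet.architecture import AREA_NAMES, CELLS_PER_AREA, GROUPINGS, N_E, AREA_INDEX
from whorfnet.params import SimulationParams


P = SimulationParams()


def tensor(**area_traces):
    """(12, 625, 30) tensor with selected per-cell traces, zero elsewhere."""
    t = np.zeros((12, CELLS_PER_AREA, 30))
    for area, traces in area_traces.items():
        for cell, trace in traces.items():
            t[AREA_INDEX[area], cell, :] = trace
    return t


class TestExtraction:
    def test_all_zero_tensor_gives_empty_assembly(self):
        ca = extract_assembly(np.zeros((12, 625, 30)), P)
        assert all(len(ca.in_region(a)) == 0 for a in AREA_NAMES)

    def test_threshold_is_gamma_times_area_peak(self):
        # area max 0.4 -> gamma=0.5 threshold 0.2: a cell peaking at 0.19 is
        # excluded; with the 20% rule (gamma=0.2, threshold 0.08) it is included
        t = tensor(V1={0: 0.4, 1: 0.19})
        ca_default = extract_assembly(t, P)
        ca_20 = extract_assembly(t, P, gamma=0.2)
        assert 1 not in ca_default.in_region("V1")
        assert 1 in ca_20.in_region("V1")
        assert 0 in ca_default.in_region("V1")

    def test_membership_at_any_single_step(self):
        t = np.zeros((12, 625, 30))
        t[0, 0, :] = 0.4
        t[0, 1, 17] = 0.35  # a single-step excursion above threshold
        ca = extract_assembly(t, P)
        assert 1 in ca.in_region("V1")

    def test_min_peak_rate_gates_area(self):
        t = tensor(V1={0: 0.19})  # below min_peak_rate 0.2
        assert len(extract_assembly(t, P).in_region("V1")) == 0

    def test_gamma_monotonicity(self):
        rng = np.random.default_rng(0)
        t = rng.random((12, 625, 30)) * 0.5
        strict = extract_assembly(t, P, gamma=0.5)
        loose = extract_assembly(t, P, gamma=0.2)
        for a in AREA_NAMES:
            assert strict.in_region(a) <= loose.in_region(a)

    def test_default_gamma(self):
        assert P.gamma_ca == 0.5


class TestActivationVectors:
    def test_constant_trace_mean(self):
        t = tensor(TO={3: 0.25})
        v = activation_vectors(t)
        assert v[AREA_INDEX["TO"], 3] == pytest.approx(0.25)

    def test_zero_tensor(self):
        assert not activation_vectors(np.zeros((12, 625, 30))).any()

    def test_equals_naive_loop(self):
        rng = np.random.default_rng(1)
        t = rng.random((12, 625, 30))
        v = activation_vectors(t)
        for a in range(0, 12, 5):
            for c in range(0, 625, 100):
                assert v[a, c] == pytest.approx(sum(t[a, c, s] for s in range(30)) / 30)


class TestRDM:
    def _vecs(self, arrays):
        return {k: v for k, v in arrays.items()}

    def test_identical_vectors_zero_distance(self):
        v = np.random.default_rng(0).random((12, 625))
        rdm, _ = compute_rdm({"a": v, "b": v.copy()}, "visual", order=("a", "b"))
        assert rdm[0, 1] == 0.0

    def test_three_four_five(self):
        a = np.zeros((12, 625))
        b = np.zeros((12, 625))
        b[0, 0], b[0, 1] = 3.0, 4.0
        rdm, _ = compute_rdm({"a": a, "b": b}, ("V1",), order=("a", "b"))
        assert rdm[0, 1] == pytest.approx(5.0)

    def test_metric_axioms(self):
        rng = np.random.default_rng(2)
        vecs = {t: rng.random((12, 625)) for t in "abcd"}
        rdm, _ = compute_rdm(vecs, "all_relevant", order=tuple("abcd"))
        assert np.allclose(rdm, rdm.T)
        assert np.allclose(np.diag(rdm), 0)
        assert (rdm >= 0).all()

    def test_grouping_mean_vs_concat(self):
        rng = np.random.default_rng(3)
        vecs = {t: rng.random((12, 625)) for t in "ab"}
        mean_rdm, _ = compute_rdm(vecs, "visual", order=("a", "b"))
        regs = GROUPINGS["visual"]
        per_region = [
            compute_rdm(vecs, (r,), order=("a", "b"))[0][0, 1] for r in regs
        ]
        assert mean_rdm[0, 1] == pytest.approx(np.mean(per_region))
        concat_rdm, _ = compute_rdm(vecs, "visual", order=("a", "b"), mode="concat")
        assert concat_rdm[0, 1] == pytest.approx(
            np.sqrt(np.sum([d**2 * 1 for d in per_region]) )
        )

    def test_missing_stimulus_errors(self):
        with pytest.raises(ValueError):
            compute_rdm({"a": np.zeros((12, 625))}, "visual", order=("a", "b"))


def assembly(region_sets, tag=""):
    members = {a: frozenset() for a in AREA_NAMES}
    members.update({a: frozenset(s) for a, s in region_sets.items()})
    return CellAssembly(tag=tag, members=members, peaks={a: 1.0 for a in AREA_NAMES})


class TestNeuronTypes:
    def test_set_arithmetic(self):
        c = count_shared_unique(assembly({"V1": {1, 2, 3}}), assembly({"V1": {3, 4}}))
        assert c.shared["V1"] == 1
        assert c.unique_light["V1"] + c.unique_dark["V1"] == 3
        assert c.sharedness(("V1",)) == pytest.approx(25.0)

    def test_disjoint_and_identical(self):
        a = assembly({"AT": {1, 2}})
        b = assembly({"AT": {3, 4}})
        assert count_shared_unique(a, b).sharedness(("AT",)) == 0.0
        assert count_shared_unique(a, a).sharedness(("AT",)) == 100.0

    def test_grouping_totals_are_region_sums(self):
        a = assembly({"V1": {1}, "TO": {1, 2}})
        b = assembly({"V1": {1}, "TO": {2, 3}})
        c = count_shared_unique(a, b)
        assert c.shared_total(("V1", "TO")) == 2
        assert c.unique_total(("V1", "TO")) == 2

    def test_empty_regions_give_nan(self):
        c = count_shared_unique(assembly({}), assembly({}))
        assert np.isnan(c.sharedness(("PB",)))


class TestMMN:
    def test_unique_is_total_minus_shared(self):
        light = assembly({"V1": {0, 1, 2}}, "light")
        dark = assembly({"V1": {2, 3}}, "dark")
        raster = np.zeros((40, N_E), dtype=np.uint8)
        raster[5, [0, 1, 2, 3, 10]] = 1   # cell 10 is outside both assemblies
        tr = mmn_trace(raster, light, dark)
        assert tr.r_total[5] == 3          # responsive to light: cells 0,1,2
        assert tr.r_shared[5] == 1         # shared: cell 2
        assert tr.unique[5] == 2
        assert (tr.unique >= 0).all()

    def test_identical_responsive_sets_give_zero_unique(self):
        a = assembly({"V1": {0, 1}}, "light")
        raster = np.zeros((40, N_E), dtype=np.uint8)
        raster[:, [0, 1]] = 1
        tr = mmn_trace(raster, a, a)
        assert not tr.unique.any()

    def test_window_mean_covers_ten_steps_post_offset(self):
        a = assembly({"V1": {0}}, "light")
        b = assembly({"V1": {1}}, "dark")
        raster = np.zeros((40, N_E), dtype=np.uint8)
        offset = P.recog_baseline_steps + P.stim_steps_recog   # step 12
        raster[offset + 2:offset + 12, 0] = 1
        tr = mmn_trace(raster, a, b)
        assert tr.window_mean(offset) == pytest.approx(1.0)
        assert tr.window_mean(offset, lo=12, hi=22) == pytest.approx(0.0)


class TestExclusion:
    def test_merged_assemblies_flagged(self):
        base = set(range(40))
        cas = {"a": assembly({"AT": base}), "b": assembly({"AT": base | {99}})}
        flags = exclude_networks([cas], P)
        assert flags == [True]   # Jaccard 40/41 > 0.8

    def test_separated_assemblies_retained(self):
        cas = {"a": assembly({"AT": {1, 2, 3}}), "b": assembly({"AT": {3, 4, 5}})}
        assert exclude_networks([cas], P) == [False]

    def test_overgrown_recruitment_flagged(self):
        cas = {"a": assembly({"AT": set(range(400))})}   # 400/625 > 0.5
        assert exclude_networks([cas], P) == [True]
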