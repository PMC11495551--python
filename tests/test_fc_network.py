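"""Connectivity matrices, group tests, contrasts, and network assembly."""

import numpy as np
import pandas as pd
import pytest

from nadnirs import fc_network as fcn


def _fc(z_rows, subject=0, phase="PreRest", n_channels=None):
    z = np.asarray(z_rows, float)
    n_ch = n_channels or int((1 + np.sqrt(1 + 8 * len(z))) / 2)
    return fcn.FCMatrix(subject, phase, z, np.zeros(len(z), bool), n_ch, 1000)


class TestFCMatrix:
    def test_pair_count_46_channels(self, rng):
        data = rng.standard_normal((46, 1000))
        m = fcn.fc_matrix(data)
        assert m.n_pairs == 1035            # (46 x 45) / 2

    def test_oracle_double_loop(self, rng):
        """Matches a naive per-pair Pearson loop to 1e-12 on a small fixture."""
        data = rng.standard_normal((5, 100))
        m = fcn.fc_matrix(data)
        k = 0
        for i in range(5):
            for j in range(i + 1, 5):
                xi, xj = data[i], data[j]
                r = (np.sum((xi - xi.mean()) * (xj - xj.mean()))
                     / np.sqrt(np.sum((xi - xi.mean()) ** 2)
                               * np.sum((xj - xj.mean()) ** 2)))
                assert m.z[k] == pytest.approx(np.arctanh(r), abs=1e-12)
                k += 1

    def test_duplicated_channel_clipped_and_flagged(self, rng):
        x = rng.standard_normal(500)
        data = np.vstack([x, x, rng.standard_normal(500)])
        m = fcn.fc_matrix(data)
        assert m.flagged[0]                     # pair (1, 2) is r = 1
        assert np.isfinite(m.z[0])
        assert m.z[0] == pytest.approx(np.arctanh(fcn.Z_CLIP))

    def test_zero_variance_channel_flagged_nan(self, rng):
        data = np.vstack([np.ones(100), rng.standard_normal((2, 100))])
        m = fcn.fc_matrix(data)
        assert m.flagged[0] and m.flagged[1]
        assert np.isnan(m.z[0]) and np.isnan(m.z[1])
        assert np.isfinite(m.z[2])

    def test_affine_invariance(self, rng):
        data = rng.standard_normal((4, 300))
        scaled = data * np.array([[2.0], [-3.0], [0.5], [10.0]]) + 7.0
        a, b = fcn.fc_matrix(data), fcn.fc_matrix(scaled)
        # sign flips where a channel was negatively rescaled; compare magnitude
        assert np.allclose(np.abs(a.z), np.abs(b.z), atol=1e-10)

    def test_unusable_segment_rejected(self):
        from nadnirs.preproc_fc import PhaseSegment
        seg = PhaseSegment(0, "PreRest", None, None, 50.0, False, 1)
        with pytest.raises(fcn.FCError):
            fcn.fc_matrix(seg)

    def test_independent_channels_null_z_scale(self, rng):
        """|z| of independent white-noise pairs stays within ~2 SD = 2/sqrt(n-3)."""
        hits = 0
        trials = 200
        for _ in range(trials):
            m = fcn.fc_matrix(rng.standard_normal((2, 900)))
            hits += abs(m.z[0]) < 2 / np.sqrt(897)
        assert hits / trials > 0.90


class TestGroupTest:
    def test_bonferroni_threshold_value(self):
        assert 0.05 / 1035 == pytest.approx(4.83e-5, rel=0.01)

    def test_all_zero_matrices_nothing_significant(self):
        ms = [_fc(np.zeros(6), subject=s) for s in range(5)]
        out = fcn.group_fc_test(ms)
        for level in (0.05, 5e-6):
            assert not out[f"passed_{level:g}"].any()

    def test_strong_pair_passes_all_levels(self, rng):
        z = np.zeros((18, 6))
        z[:, 2] = 1.5 + 0.05 * rng.standard_normal(18)
        ms = [_fc(z[s], subject=s) for s in range(18)]
        out = fcn.group_fc_test(ms)
        assert out.loc[2, "passed_0.05"]
        assert out.loc[2, "passed_5e-09"]

    def test_thresholds_downward_closed(self, rng):
        z = rng.standard_normal((10, 10)) * 0.3 + 0.2
        ms = [_fc(z[s], subject=s, n_channels=5) for s in range(10)]
        out = fcn.group_fc_test(ms)
        levels = sorted((0.05, 5e-6, 5e-7, 5e-8, 5e-9), reverse=True)
        for loose, strict in zip(levels, levels[1:]):
            assert (out[f"passed_{strict:g}"] <= out[f"passed_{loose:g}"]).all()

    def test_planted_edges_recovered(self, rng):
        """Loading-0.8 edges (r ~ 0.64) pass family level 0.05 with n=18."""
        edge_pairs = [0, 7, 11]
        hits = 0
        for _ in range(20):
            ms = []
            for s in range(18):
                n_ch, n_t = 6, 900
                noise = rng.standard_normal((n_ch, n_t))
                f = rng.standard_normal(n_t)
                data = noise.copy()
                # loading 0.8 on channels {1,2}, {2,4}? build simple shared factor
                for ch in (0, 1, 2):
                    data[ch] = 0.8 * f + np.sqrt(1 - 0.64) * noise[ch]
                ms.append(fcn.fc_matrix(data, subject=s))
            out = fcn.group_fc_test(ms)
            ok = all(out.loc[k, "passed_0.05"] for k in (0, 1, 5))  # pairs 1-2,1-3,2-3
            hits += ok
        assert hits / 20 >= 0.9


class TestContrast:
    def test_identical_phases_degenerate(self):
        ms_a = [_fc(np.full(6, 0.4), subject=s, phase="Learning") for s in range(6)]
        ms_b = [_fc(np.full(6, 0.4), subject=s, phase="PreRest") for s in range(6)]
        out = fcn.fc_contrast(ms_a, ms_b)
        assert (out.t == 0).all()
        assert (out.p == 1).all()

    def test_planted_increase_detected_with_direction(self, rng):
        ms_a, ms_b = [], []
        for s in range(12):
            za = rng.standard_normal(6) * 0.05
            zb = rng.standard_normal(6) * 0.05
            za[3] += 0.5
            ms_a.append(_fc(za, subject=s, phase="Learning"))
            ms_b.append(_fc(zb, subject=s, phase="PreRest"))
        out = fcn.fc_contrast(ms_a, ms_b)
        assert out.loc[3, "p"] < 0.05
        assert out.loc[3, "direction"] == "increased"

    def test_unpaired_subjects_flagged(self):
        out = fcn.fc_contrast([_fc(np.zeros(6), subject=0)],
                              [_fc(np.zeros(6), subject=1)])
        assert out.empty

    def test_delta_z_attrs_align(self, rng):
        ms_a = [_fc(rng.standard_normal(6), subject=s) for s in range(4)]
        ms_b = [_fc(rng.standard_normal(6), subject=s) for s in range(4)]
        out = fcn.fc_contrast(ms_a, ms_b)
        d = out.attrs["delta_z"]
        assert d.shape == (4, 6)
        assert out.attrs["subjects"] == [0, 1, 2, 3]


class TestSeedCorrelationAndAssembly:
    def _toy(self, rng, n_subj=20, couple=-0.9):
        """4 channels; seed edges (1,2),(1,3) and non-seed edge (2,3) coupled
        to the seed-1 activation."""
        n_pairs = 6  # pairs of 4 channels: (1,2),(1,3),(1,4),(2,3),(2,4),(3,4)
        u = rng.standard_normal(n_subj)
        delta_z = 0.1 * rng.standard_normal((n_subj, n_pairs))
        delta_z[:, 0] += u                      # edge (1, 2)
        delta_z[:, 1] += u                      # edge (1, 3)
        delta_z[:, 3] += u                      # edge (2, 3)
        act = pd.DataFrame({1: couple * u + 0.2 * rng.standard_normal(n_subj)},
                           index=range(n_subj))
        eligible = np.array([True, True, False, True, False, False])
        return delta_z, act, eligible, list(range(n_subj))

    def test_planted_coupling_recovered(self, rng):
        delta_z, act, eligible, subjects = self._toy(rng)
        out = fcn.seed_activation_correlation(delta_z, act, [1], eligible, 4,
                                              subjects)
        row = out[(out.ch_a == 1) & (out.ch_b == 2)]
        assert row.significant.iloc[0]
        assert row.r.iloc[0] < -0.5

    def test_constant_activation_flagged(self, rng):
        delta_z, act, eligible, subjects = self._toy(rng)
        act[1] = 1.0
        out = fcn.seed_activation_correlation(delta_z, act, [1], eligible, 4,
                                              subjects)
        assert not out.computed.any()

    def test_assembled_network_types(self, rng):
        delta_z, act, eligible, subjects = self._toy(rng)
        corrs = fcn.seed_activation_correlation(delta_z, act, [1], eligible, 4,
                                                subjects)
        net = fcn.assemble_network(corrs, delta_z, act, [1], eligible, 4, subjects)
        types = dict(zip(map(tuple, net.edges[["ch_a", "ch_b"]].values),
                         net.edges.edge_type))
        assert types.get((1, 2)) == "seed_edge"
        # (2, 3) touches no seed but both channels appear in seed edges and it
        # couples to every seed -> nonseed_edge
        assert types.get((2, 3)) == "nonseed_edge"

    def test_empty_inputs_empty_network(self):
        corrs = pd.DataFrame(columns=["ch_a", "ch_b", "seed", "r", "p", "n",
                                      "computed", "significant"])
        act = pd.DataFrame({1: [0.1, 0.2, 0.3]}, index=[0, 1, 2])
        net = fcn.assemble_network(corrs, np.zeros((3, 6)), act, [1],
                                   np.zeros(6, bool), 4, [0, 1, 2])
        assert net.edges.empty
        assert net.edge_pairs == set()

    def test_graph_export(self, rng):
        delta_z, act, eligible, subjects = self._toy(rng)
        corrs = fcn.seed_activation_correlation(delta_z, act, [1], eligible, 4,
                                                subjects)
        net = fcn.assemble_network(corrs, delta_z, act, [1], eligible, 4, subjects)
        g = net.to_graph()
        assert set(map(tuple, map(sorted, g.edges))) == net.edge_pairs


class TestBaselineDependence:
    def test_iid_phases_regress_to_minus_inv_sqrt2(self, rng):
        """corr(X, Y - X) for i.i.d. X, Y concentrates near -1/sqrt(2)."""
        n_subj, n_pairs = 2000, 20
        x = rng.standard_normal((n_subj, n_pairs))
        y = rng.standard_normal((n_subj, n_pairs))
        out = fcn.baseline_dependence(x, y - x)
        assert out.r.mean() == pytest.approx(-1 / np.sqrt(2), abs=0.02)

    def test_constant_delta_flagged(self):
        x = np.random.default_rng(0).standard_normal((10, 3))
        out = fcn.baseline_dependence(x, np.full((10, 3), 0.5))
        assert not out.computed.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(fcn.FCError):
            fcn.baseline_dependence(np.zeros((5, 3)), np.zeros((4, 3)))
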