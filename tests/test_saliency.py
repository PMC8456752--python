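"""Guided Grad-CAM: analytic checks, codec equivariance, aggregation."""

import numpy as np
import pytest

import connectoscramble as cs
from connectoscramble import edges, member, nn, saliency


def hand_network(rng, rows=115, cols=58, positive=False):
    cfg = cs.MemberConfig(n_filters=4, dense_units=(8,), epochs=1)
    net = member.build_member(cfg, grid=(rows, cols), rng=rng)
    if positive:
        for layer in net.layers:
            for p in layer.params:
                p[...] = np.abs(p)
    return net


def fake_member(net, codec, test_ids=None, mask=None):
    n_test = 2 if test_ids is None else len(test_ids)
    return member.TrainedMember(
        network=net, codec=codec, config=cs.MemberConfig(epochs=1),
        mask=mask, train_ids=np.array([100, 101]), val_ids=np.array([102]),
        test_ids=np.arange(n_test) if test_ids is None else test_ids,
        test_probabilities=np.full((n_test, 2), 0.5),
        best_epoch=0,
    )


class TestMemberCam:
    def test_zero_head_weights_give_zero_cam(self, rng):
        net = hand_network(np.random.default_rng(0))
        net.layers[-1].W[...] = 0.0
        net.layers[-1].b[...] = 0.0
        tm = fake_member(net, member.PermutationCodec.random(1))
        grids = rng.standard_normal((2, 115, 58, 3)).astype(np.float32)
        cam = saliency.member_cam(tm, grids, target_class=1)
        assert cam.shape == (2, 3, edges.N_EDGES)
        assert np.allclose(cam, 0.0)

    def test_all_positive_network_matches_closed_form(self):
        """With positive weights, positive inputs and single-filter conv,
        guided backprop equals the plain gradient, so the CAM has the
        closed form  relu(mean_r a_r u_r) ... broadcast x gradient."""
        rng = np.random.default_rng(1)
        rows, cols = 5, 4
        conv = nn.RowConv(cols * 3, 1, rng)
        dense = nn.Dense(rows, 2, rng)
        for p in (conv.W, conv.b, dense.W, dense.b):
            p[...] = np.abs(p)
        net = nn.Network(
            [member._GridToRows(cols), conv, nn.ReLU(), nn.Flatten(), dense],
            conv_relu_index=2,
        )
        x = np.abs(rng.standard_normal((1, rows, cols, 3))).astype(np.float32)

        # closed form: a_r = v . x_r, logit_1 grad on fmap = u_r,
        # alpha = mean(u), cam_row = alpha * a_r, input grad = u_r * v_c
        v = conv.W[:, 0]
        u = dense.W[:, 1]
        a = x.reshape(1, rows, -1)[0] @ v
        alpha = u.mean()
        cam_rows = np.maximum(alpha * a, 0.0)
        input_grad = u[:, None] * v[None, :]
        expect_grid = np.maximum(
            cam_rows[:, None] * input_grad, 0.0
        ).reshape(rows, cols, 3)

        codec = member.PermutationCodec(permutation=np.arange(rows * cols))
        tm = fake_member(net, codec, test_ids=np.array([0]))
        got = saliency.member_cam(tm, x, target_class=1)[0]   # (3, n)
        got_grid = np.moveaxis(got.reshape(3, rows, cols), 0, -1)
        assert np.allclose(got_grid, expect_grid, rtol=1e-4, atol=1e-6)

    def test_codec_equivariance(self, rng):
        """Permuting input edges together with the codec leaves the
        edge-space CAM unchanged."""
        net = hand_network(np.random.default_rng(2))
        vals = rng.uniform(-1, 1, (1, 3, edges.N_EDGES))
        conn = edges.unvectorize(vals, diagonal=1.0)
        codec_a = member.PermutationCodec.random(10)
        grid_a = member.scramble(conn, codec_a)
        tm_a = fake_member(net, codec_a, test_ids=np.array([0]))
        cam_a = saliency.member_cam(tm_a, grid_a, 1)

        # relabel every edge e -> perm[e] and compensate inside the codec so
        # the network sees the identical grid
        perm = rng.permutation(edges.N_EDGES)
        inv_perm = np.argsort(perm)
        vals_p = vals[..., inv_perm]            # vals_p[perm[e]] == vals[e]
        conn_p = edges.unvectorize(vals_p, diagonal=1.0)
        codec_c = member.PermutationCodec(
            permutation=perm[codec_a.permutation])
        grid_c = member.scramble(conn_p, codec_c)
        assert np.allclose(grid_c, grid_a)
        tm_c = fake_member(net, codec_c, test_ids=np.array([0]))
        cam_c = saliency.member_cam(tm_c, grid_c, 1)
        # cam_c lives in relabelled edge space; undoing the relabelling
        # recovers the original edge-space CAM
        assert np.allclose(cam_c[..., perm], cam_a, atol=1e-6)

    def test_fully_connected_baseline_rejected(self):
        cfg = cs.MemberConfig(convolutional=False, epochs=1)
        net = member.build_member(cfg)
        tm = fake_member(net, member.PermutationCodec.random(0))
        with pytest.raises(ValueError, match="convolutional"):
            saliency.member_cam(tm, np.zeros((1, 115, 58, 3)), 1)


class TestAggregation:
    def _cohort(self, rng, n=6):
        vals = rng.uniform(-0.5, 0.5, (n, 3, edges.N_EDGES))
        return edges.unvectorize(vals, diagonal=1.0)

    def test_single_member_mean_and_symmetry(self, rng):
        conn = self._cohort(rng)
        net = hand_network(np.random.default_rng(3))
        tm = fake_member(net, member.PermutationCodec.random(4),
                         test_ids=np.array([0, 2, 4]))
        cams = saliency.aggregate_cams([tm], conn, np.arange(6))
        assert set(cams) == {"0", "2", "4"}
        for scam in cams.values():
            assert np.allclose(scam.cam, scam.cam.T)
            assert (scam.cam >= 0).all()
            assert np.allclose(np.diag(scam.cam), 0.0)

    def test_identical_members_idempotent_and_order_invariant(self, rng):
        conn = self._cohort(rng)
        net = hand_network(np.random.default_rng(5))
        codec = member.PermutationCodec.random(6)
        tm1 = fake_member(net, codec, test_ids=np.array([1, 3]))
        tm2 = fake_member(net, codec, test_ids=np.array([1, 3]))
        solo = saliency.aggregate_cams([tm1], conn, np.arange(6))
        both = saliency.aggregate_cams([tm1, tm2], conn, np.arange(6))
        swapped = saliency.aggregate_cams([tm2, tm1], conn, np.arange(6))
        for sid in solo:
            assert np.allclose(both[sid].cam, solo[sid].cam)
            assert np.allclose(both[sid].cam, swapped[sid].cam)

    def test_uncovered_subjects_warned_and_excluded(self, rng):
        conn = self._cohort(rng)
        net = hand_network(np.random.default_rng(7))
        tm = fake_member(net, member.PermutationCodec.random(8),
                         test_ids=np.array([0]))
        with pytest.warns(UserWarning, match="no member"):
            cams = saliency.aggregate_cams([tm], conn, np.arange(6))
        assert set(cams) == {"0"}

    def test_empty_member_list_rejected(self, rng):
        with pytest.raises(ValueError):
            saliency.aggregate_cams([], self._cohort(rng), np.arange(6))


class TestEffectSizes:
    def test_cohens_d_direct_computation(self, rng):
        rest = rng.standard_normal(100_000)
        group = rng.standard_normal(50_000) + 1.0   # shifted by one sd
        assert saliency.cohens_d(group, rest) == pytest.approx(1.0, abs=0.02)
        assert saliency.cohens_d(rest[:50_000], rest[50_000:]) == pytest.approx(
            0.0, abs=0.02)

    def test_zero_pooled_sd_reported_nan(self):
        assert np.isnan(saliency.cohens_d(np.ones(5), np.ones(7)))

    def test_report_shape_and_sign_convention(self, networks, rng):
        # construct CAMs with elevated values on SAL inner edges
        import pandas as pd

        sal = networks["SAL"].inner_edges
        cams = {}
        conds = []
        for i in range(8):
            vec = rng.random(edges.N_EDGES) * 0.1
            vec[sal] += 1.0
            cams[str(i)] = saliency.SubjectCAM(
                subject_id=str(i), cam=edges.unvectorize(vec, diagonal=0.0),
                n_members=1)
            conds.append(i % 2)
        table = pd.DataFrame({"subject_id": [str(i) for i in range(8)],
                              "condition": conds})
        report = saliency.network_effect_sizes(cams, networks, table)
        assert len(report) == 3 * 2 * 2   # networks x modes x strata
        sal_inner = report.query(
            "network == 'SAL' and edge_set == 'inner'")["d"]
        assert (sal_inner > 1.0).all()    # planted edges higher -> positive d
        dmn_inner = report.query(
            "network == 'DMN' and edge_set == 'inner'")["d"]
        assert (dmn_inner.abs() < 0.2).all()
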