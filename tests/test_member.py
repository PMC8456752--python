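"""Permutation codec, scrambling, member architecture and training."""

import numpy as np
import pytest

import connectoscramble as cs
from connectoscramble import edges, member, nn


def random_connectome(rng, n=1):
    vals = rng.uniform(-1, 1, (n, 3, edges.N_EDGES))
    out = edges.unvectorize(vals, diagonal=1.0)
    return out[0] if n == 1 else out


class TestCodec:
    def test_round_trip_identity_all_edges_and_bands(self, rng):
        codec = member.PermutationCodec.random(seed=5)
        x = random_connectome(rng)
        grid = member.scramble(x, codec)
        assert grid.shape == (115, 58, 3)
        assert np.array_equal(member.unscramble(grid, codec),
                              edges.vectorize(x))

    def test_identity_permutation_is_row_major_upper_triangle(self, rng):
        codec = member.PermutationCodec(permutation=np.arange(edges.N_EDGES))
        x = random_connectome(rng)
        grid = member.scramble(x, codec)
        expect = edges.vectorize(x).reshape(3, 115, 58)
        assert np.array_equal(np.moveaxis(grid, -1, 0), expect)

    def test_constant_matrix_gives_constant_grid(self):
        x = edges.unvectorize(np.full((3, edges.N_EDGES), 0.25), diagonal=1.0)
        grid = member.scramble(x, member.PermutationCodec.random(9))
        assert np.all(grid == 0.25)

    def test_same_permutation_across_bands(self, rng):
        codec = member.PermutationCodec.random(seed=2)
        vals = rng.uniform(-1, 1, edges.N_EDGES)
        x = edges.unvectorize(np.stack([vals, vals * 2, vals * 3]), diagonal=1.0)
        grid = member.scramble(x, codec)
        assert np.allclose(grid[..., 1], 2 * grid[..., 0])
        assert np.allclose(grid[..., 2], 3 * grid[..., 0])

    def test_non_bijection_rejected(self):
        with pytest.raises(ValueError):
            member.PermutationCodec(permutation=np.zeros(6670, dtype=int))

    def test_occlusion_mask_half_grid(self, rng):
        x = random_connectome(rng)
        mask = np.sort(rng.choice(edges.N_EDGES, member.HALF_EDGES,
                                  replace=False))
        codec = member.PermutationCodec.random(3, n_edges=member.HALF_EDGES)
        grid = member.scramble(x, codec, mask=mask)
        assert grid.shape == (115, 29, 3)
        # unmasked edges recoverable; masked edges never entered
        recovered = member.unscramble(grid, codec)
        assert np.array_equal(recovered, edges.vectorize(x)[:, mask])

    def test_bad_mask_size_rejected(self, rng):
        x = random_connectome(rng)
        codec = member.PermutationCodec.random(3, n_edges=member.HALF_EDGES)
        with pytest.raises(ValueError, match="3335"):
            member.scramble(x, codec, mask=np.arange(100))


class TestArchitecture:
    def test_softmax_output_and_param_count_determinism(self, rng):
        cfg = cs.MemberConfig(epochs=1)
        net_a = member.build_member(cfg, rng=np.random.default_rng(0))
        net_b = member.build_member(cfg, rng=np.random.default_rng(1))
        x = rng.standard_normal((4, 115, 58, 3)).astype(np.float32)
        probs = nn.softmax(net_a.forward(x))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert net_a.n_parameters() == net_b.n_parameters()
        assert np.isfinite(net_a.n_parameters())
        # different seeds produce different initial weights
        assert not np.array_equal(net_a.layers[1].W, net_b.layers[1].W)

    def test_conv_filter_spans_full_row(self):
        cfg = cs.MemberConfig()
        net = member.build_member(cfg)
        conv = net.layers[1]
        assert conv.W.shape == (58 * 3, 256)   # one row across all 3 bands

    def test_fully_connected_baseline_has_no_conv(self):
        cfg = cs.MemberConfig(convolutional=False)
        net = member.build_member(cfg)
        assert net.conv_relu_index is None
        assert not any(isinstance(l, nn.RowConv) for l in net.layers)


class TestSplits:
    def test_ratio_and_disjointness(self):
        labels = np.array([0, 1] * 60)
        tr, va, te = member.split_indices(labels, (4, 1, 1),
                                          np.random.default_rng(0))
        assert len(tr) + len(va) + len(te) == 120
        assert not (set(tr) & set(va) | set(tr) & set(te) | set(va) & set(te))
        assert len(te) == 20 and len(va) == 20     # floor(120/6) per split
        for part in (tr, va, te):
            assert len(np.unique(labels[part])) == 2

    def test_too_few_subjects_error(self):
        labels = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="split"):
            member.split_indices(labels, (4, 1, 1), np.random.default_rng(0))


class TestTraining:
    def test_planted_effect_member_exceeds_chance(self, small_trained_member,
                                                  planted_rest_cohort):
        _, table, _ = planted_rest_cohort
        labels = table["sex"].to_numpy()
        tm = small_trained_member
        score = cs.auroc(tm.test_probabilities[:, 1], labels[tm.test_ids])
        assert score > 0.8

    def test_train_test_disjoint_structurally(self, small_trained_member):
        tm = small_trained_member
        assert not (set(tm.test_ids) & set(tm.train_ids))
        assert not (set(tm.test_ids) & set(tm.val_ids))

    def test_shuffled_labels_near_chance(self, planted_rest_cohort):
        _, table, stacks = planted_rest_cohort
        rng = np.random.default_rng(11)
        shuffled = rng.permutation(table["sex"].to_numpy())
        cfg = cs.MemberConfig(epochs=4, seed=8)
        tm = cs.train_member(stacks[:300], shuffled[:300], cfg)
        score = cs.auroc(tm.test_probabilities[:, 1], shuffled[:300][tm.test_ids])
        assert 0.25 < score < 0.75

    def test_reproducible_with_fixed_seed(self, planted_rest_cohort):
        _, table, stacks = planted_rest_cohort
        labels = table["sex"].to_numpy()
        cfg = cs.MemberConfig(epochs=2, seed=13)
        a = cs.train_member(stacks[:200], labels[:200], cfg)
        b = cs.train_member(stacks[:200], labels[:200], cfg)
        assert np.array_equal(a.test_probabilities, b.test_probabilities)
        assert np.array_equal(a.codec.permutation, b.codec.permutation)
        assert a.best_epoch == b.best_epoch


class TestCheckpointing:
    def test_save_load_round_trip(self, tmp_path, small_trained_member,
                                  planted_rest_cohort):
        _, table, stacks = planted_rest_cohort
        tm = small_trained_member
        member.save_member(tm, tmp_path / "m0")
        loaded = member.load_member(tmp_path / "m0")
        assert np.array_equal(loaded.codec.permutation, tm.codec.permutation)
        assert np.array_equal(loaded.test_ids, tm.test_ids)
        assert loaded.best_epoch == tm.best_epoch
        grids = member.scramble(stacks[tm.test_ids], tm.codec).astype(np.float32)
        assert np.array_equal(loaded.network.predict_proba(grids),
                              tm.network.predict_proba(grids))
        assert (tmp_path / "m0" / "training_log.csv").exists()
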