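"""Context-attention: partitioning, bias, dense oracle, block contracts."""

import numpy as np
import pytest

from lcanet import attention as A
from lcanet.attention import (
    AttentionConfig,
    context_attention_forward,
    fold_query,
    init_context_attention,
    qkv_project,
    scaled_attention,
    split_kv,
    split_query,
)


def sym_pad(arr, size):
    """Symmetric-pad a (C,H,W) array to (C,size,size) — oracle helper."""
    idx_r = np.pad(np.arange(arr.shape[1]), (0, size - arr.shape[1]),
                   mode="symmetric")
    idx_c = np.pad(np.arange(arr.shape[2]), (0, size - arr.shape[2]),
                   mode="symmetric")
    return arr[:, idx_r][:, :, idx_c]


def brute_force_attention(q, k, v, table, radius, s=1):
    """Naive loop oracle: every query pixel against every kv-window pixel.

    Enumerates all N2 overlapping 10x10 windows explicitly, so duplicated
    key pixels each contribute their own softmax entry (the M1 x M2
    formulation taken literally).
    """
    C, H, W = q.shape
    Pq = A.padded_size(max(H, W))
    Pk = A.kv_padded_size(max(H, W))
    qp = sym_pad(q, Pq)
    kp = sym_pad(k, Pk)
    vp = sym_pad(v, Pk)
    entries = []
    for sr in range(0, Pk - 10 + 1, s):
        for sc in range(0, Pk - 10 + 1, s):
            for r in range(sr, sr + 10):
                for c in range(sc, sc + 10):
                    entries.append((r, c))
    ent = np.array(entries)
    kmat = kp[:, ent[:, 0], ent[:, 1]].T        # (M2, C)
    vmat = vp[:, ent[:, 0], ent[:, 1]].T
    out = np.zeros((C, Pq, Pq))
    for qr in range(Pq):
        for qc in range(Pq):
            dr = np.clip(qr - ent[:, 0], -radius, radius) + radius
            dc = np.clip(qc - ent[:, 1], -radius, radius) + radius
            logits = (kmat @ qp[:, qr, qc] + table[dr, dc]) / np.sqrt(C)
            w = np.exp(logits - logits.max())
            w /= w.sum()
            out[:, qr, qc] = w @ vmat
    return out[:, :H, :W]


class TestPartitioning:
    @pytest.mark.parametrize("hw,n1,m1", [(256, 1024, 65536), (8, 1, 64),
                                          (20, 9, 576), (64, 64, 4096)])
    def test_query_patch_counts(self, hw, n1, m1):
        ps = split_query(np.zeros((1, 2, hw, hw)))
        assert ps.patch_count == n1
        assert ps.flattened_length == m1
        assert ps.patches.shape == (1, n1, 64, 2)

    @pytest.mark.parametrize("hw,s,n2", [(16, 1, 49), (10, 1, 1), (32, 2, 144),
                                         (64, 1, 3025)])
    def test_kv_patch_counts(self, hw, s, n2):
        ps = split_kv(np.zeros((1, 3, hw, hw)), s)
        assert ps.patch_count == n2
        assert ps.flattened_length == n2 * 100

    def test_invalid_stride_rejected(self):
        with pytest.raises(ValueError):
            split_kv(np.zeros((1, 1, 16, 16)), 0)

    def test_patch_coordinates_index_the_padded_map(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 3, 16, 16))
        ps = split_kv(x, 1)
        flat = np.asarray(ps.flat())[0]  # (M2, C)
        assert np.allclose(flat, x[0, :, ps.rows, ps.cols])

    def test_fold_query_inverts_split(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 5, 20, 12))
        ps = split_query(x)
        back = fold_query(ps.flat(), ps)
        assert np.allclose(back, x)


class TestScaledAttention:
    def test_softmax_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        q, k, v = (rng.normal(size=(2, 4, 16, 16)) for _ in range(3))
        table = rng.normal(size=(31, 31)) * 0.3
        out, w = scaled_attention(split_query(q), split_kv(k, 1),
                                  split_kv(v, 1), table, 15,
                                  return_weights=True)
        assert np.allclose(np.asarray(w).sum(axis=-1), 1.0, atol=1e-6)

    def test_constant_values_give_constant_output(self):
        rng = np.random.default_rng(3)
        q, k = (rng.normal(size=(1, 3, 16, 16)) for _ in range(2))
        v = np.ones((1, 3, 16, 16)) * np.array([2.0, -1.0, 0.5])[None, :,
                                                                 None, None]
        out = scaled_attention(split_query(q), split_kv(k, 1), split_kv(v, 1),
                               np.zeros((31, 31)), 15)
        out = np.asarray(out)
        assert np.allclose(out, np.array([2.0, -1.0, 0.5])[None, None, :],
                           atol=1e-9)

    def test_dominant_logit_selects_one_value_row(self):
        # one key matches the query direction with a +30 margin
        C = 4
        q = np.zeros((1, C, 16, 16))
        q[0, 0] = 30.0 * np.sqrt(C)
        k = np.zeros((1, C, 16, 16))
        k[0, 0, 5, 5] = 1.0
        rng = np.random.default_rng(4)
        v = rng.normal(size=(1, C, 16, 16))
        out = scaled_attention(split_query(q), split_kv(k, 1), split_kv(v, 1),
                               np.zeros((31, 31)), 15)
        out = np.asarray(out)[0]
        # every query should reproduce the value at the dominating key pixel
        assert np.allclose(out, v[0, :, 5, 5], atol=1e-6)

    @pytest.mark.parametrize("hw,s", [(12, 1), (16, 1), (16, 2), (10, 1)])
    def test_matches_loop_oracle(self, hw, s):
        rng = np.random.default_rng(hw + s)
        q, k, v = (rng.normal(size=(1, 4, hw, hw)) for _ in range(3))
        table = rng.normal(size=(31, 31)) * 0.2
        qp = split_query(q)
        flat = scaled_attention(qp, split_kv(k, s), split_kv(v, s), table, 15)
        got = np.asarray(fold_query(flat, qp))[0]
        want = brute_force_attention(q[0], k[0], v[0], table, 15, s)
        denom = np.maximum(np.abs(want), 1e-3)
        assert np.max(np.abs(got - want) / denom) <= 1e-5

    @pytest.mark.parametrize("hw,s", [(12, 1), (16, 1), (16, 2)])
    def test_dense_fast_path_matches_windowed_formulation(self, hw, s):
        rng = np.random.default_rng(10 * hw + s)
        q, k, v = (rng.normal(size=(2, 4, hw, hw)) for _ in range(3))
        table = rng.normal(size=(31, 31)) * 0.2
        qp = split_query(q)
        ref = fold_query(
            scaled_attention(qp, split_kv(k, s), split_kv(v, s), table, 15), qp
        )
        fast = A._global_attention_dense(q, k, v, table, 15, s)
        assert np.allclose(np.asarray(fast), np.asarray(ref), atol=1e-10)

    def test_permuting_kv_windows_leaves_output_unchanged(self):
        rng = np.random.default_rng(6)
        q, k, v = (rng.normal(size=(1, 3, 16, 16)) for _ in range(3))
        table = rng.normal(size=(31, 31)) * 0.2
        qp, kp, vp = split_query(q), split_kv(k, 1), split_kv(v, 1)
        ref = scaled_attention(qp, kp, vp, table, 15)
        perm = np.random.default_rng(7).permutation(kp.patch_count)

        def permute(ps):
            pix = ps.window * ps.window
            rows = ps.rows.reshape(ps.patch_count, pix)[perm].ravel()
            cols = ps.cols.reshape(ps.patch_count, pix)[perm].ravel()
            return A.PatchSet(np.asarray(ps.patches)[:, perm], ps.window,
                              ps.stride, ps.grid, ps.padded_hw, ps.orig_hw,
                              rows, cols)

        out = scaled_attention(qp, permute(kp), permute(vp), table, 15)
        assert np.allclose(np.asarray(out), np.asarray(ref), atol=1e-12)


class TestBias:
    def test_bias_depends_only_on_relative_offset(self):
        table = np.arange(31 * 31, dtype=float).reshape(31, 31)
        phi = A.materialize_bias(table, np.array([3, 7]), np.array([2, 6]),
                                 np.array([1, 5]), np.array([0, 4]), 15)
        # both pairs have offset (+2, +2) -> same entry on the diagonal
        assert phi[0, 0] == phi[1, 1]

    def test_offsets_clip_at_the_table_radius(self):
        table = np.zeros((7, 7))  # radius 3
        table[0, 0] = 5.0
        phi = A.materialize_bias(table, np.array([0]), np.array([0]),
                                 np.array([30]), np.array([30]), 3)
        assert phi[0, 0] == 5.0


class TestBlockForward:
    def test_constant_input_qkv_reduce_to_bias_patterns(self):
        rng = np.random.default_rng(8)
        p = init_context_attention(rng, 4)
        x = np.full((1, 4, 16, 16), 3.7)
        q, k, v = qkv_project(p, x)
        # LN of a constant field is zero, so only the projection bias remains
        assert np.allclose(np.asarray(q),
                           p["q"]["b"].reshape(1, -1, 1, 1), atol=1e-10)
        assert np.allclose(np.asarray(k),
                           p["k"]["b"].reshape(1, -1, 1, 1), atol=1e-10)
        assert q.shape[2:] == x.shape[2:]

    def test_identity_projections_with_norm_disabled(self):
        rng = np.random.default_rng(9)
        p = init_context_attention(rng, 3, AttentionConfig(embed_ratio=1.0))
        eye = np.eye(3).reshape(3, 3, 1, 1)
        for name in ("q", "k", "v"):
            p[name]["w"] = eye.copy()
            p[name]["b"] = np.zeros(3)
        x = rng.normal(size=(1, 3, 12, 12))
        q, k, v = qkv_project(p, x, normalize=False)
        for out in (q, k, v):
            assert np.allclose(np.asarray(out), x)

    def test_zero_output_projections_make_block_identity(self):
        rng = np.random.default_rng(10)
        p = init_context_attention(rng, 4, zero_output=True)
        x = rng.normal(size=(1, 4, 16, 16))
        y = context_attention_forward(p, x)
        assert np.allclose(np.asarray(y), x, atol=1e-12)

    @pytest.mark.parametrize("mode", ["global", "paired"])
    def test_output_shape_matches_input(self, mode):
        rng = np.random.default_rng(11)
        p = init_context_attention(rng, 8)
        x = rng.normal(size=(2, 8, 32, 32))
        y = context_attention_forward(p, x, cfg=AttentionConfig(mode=mode))
        assert y.shape == x.shape

    def test_encoder_variant_equals_decoder_with_self_skip(self):
        rng = np.random.default_rng(12)
        p = init_context_attention(rng, 4)
        x = rng.normal(size=(1, 4, 16, 16))
        enc = context_attention_forward(p, x)
        dec = context_attention_forward(p, x, skip=x)
        assert np.allclose(np.asarray(enc), np.asarray(dec))

    def test_decoder_upsamples_key_value_to_skip_resolution(self):
        rng = np.random.default_rng(13)
        p = init_context_attention(rng, 4)
        deep = rng.normal(size=(1, 4, 8, 8))
        skip = rng.normal(size=(1, 4, 16, 16))
        y = context_attention_forward(p, deep, skip=skip)
        assert y.shape == skip.shape

    def test_channel_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        p = init_context_attention(rng, 4)
        with pytest.raises(ValueError, match="channel"):
            context_attention_forward(p, rng.normal(size=(1, 4, 16, 16)),
                                      skip=rng.normal(size=(1, 2, 16, 16)))

    def test_paired_mode_translation_equivariance_with_zero_bias(self):
        # content supported in the map interior, shifted by one full window
        rng = np.random.default_rng(15)
        p = init_context_attention(rng, 4)
        p["bias_table"] = np.zeros_like(p["bias_table"])
        cfg = AttentionConfig(mode="paired")
        x = np.zeros((1, 4, 32, 32))
        x[:, :, 10:14, 10:14] = rng.normal(size=(1, 4, 4, 4))
        y = np.asarray(context_attention_forward(p, x, cfg=cfg))
        xs = np.roll(x, 8, axis=3)
        ys = np.asarray(context_attention_forward(p, xs, cfg=cfg))
        assert np.allclose(np.roll(y, 8, axis=3)[:, :, 10:14, 12:28],
                           ys[:, :, 10:14, 12:28], atol=1e-10)

    def test_unknown_mode_rejected(self):
        rng = np.random.default_rng(16)
        p = init_context_attention(rng, 4)
        with pytest.raises(ValueError, match="mode"):
            context_attention_forward(p, rng.normal(size=(1, 4, 16, 16)),
                                      cfg=AttentionConfig(mode="banana"))
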