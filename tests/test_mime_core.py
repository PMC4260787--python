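import numpy as np
import pytest

from mimenet.cmi_estimation import estimate_cmi, jitter
from mimenet.mime_core import (DRIVEN, DRIVER, CausalityMatrix, MimeParams,
                               MixedEmbedding, build_candidates,
                               causality_matrix, mime_causality,
                               select_mixed_embedding, _pair_rng,
                               _standardize_series)
from mimenet.signal_io import (MultichannelRecording, build_augmented,
                               standardize)

from conftest import ar1_pair, eeg_like_pair


class TestMimeParams:
    def test_defaults(self):
        p = MimeParams()
        assert p.T == 1 and p.Lx == p.Ly == 5
        assert p.A == 0.95 and p.k == 4 and p.max_cycles == 10

    @pytest.mark.parametrize("bad", [
        dict(A=0.0), dict(A=1.0), dict(T=0), dict(Lx=0), dict(Ly=0),
        dict(T=6), dict(k=0), dict(max_cycles=0),
    ])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            MimeParams(**bad)

    def test_horizon_within_lags(self):
        MimeParams(T=3, Lx=3, Ly=5)  # fine: T <= min(Lx, Ly)
        with pytest.raises(ValueError, match="min"):
            MimeParams(T=4, Lx=3, Ly=5)


class TestBuildCandidates:
    def test_counts_default(self):
        x, y = ar1_pair(0, 0.0, n=300)
        future, cands = build_candidates(x, y, MimeParams())
        assert len(cands) == 10
        assert future.shape[1] == 1
        assert sum(c.source == DRIVER for c in cands) == 5

    def test_counts_asymmetric(self):
        x, y = ar1_pair(0, 0.0, n=300)
        future, cands = build_candidates(x, y, MimeParams(T=2, Lx=3, Ly=5))
        assert len(cands) == 8
        assert future.shape[1] == 2

    def test_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            build_candidates(np.zeros(20), np.zeros(20), MimeParams())

    def test_alignment(self):
        x, y = ar1_pair(1, 0.0, n=200)
        params = MimeParams(T=1, Lx=3, Ly=3)
        future, cands = build_candidates(x, y, params)
        t = np.arange(2, 199)  # lmax-1 .. n-T-1
        assert np.array_equal(future[:, 0], y[t + 1])
        lookup = {(c.source, c.lag): c.values for c in cands}
        assert np.array_equal(lookup[(DRIVER, 0)], x[t])
        assert np.array_equal(lookup[(DRIVER, 2)], x[t - 2])
        assert np.array_equal(lookup[(DRIVEN, 1)], y[t - 1])


def _prepared_clouds(x, y, params, seed=0):
    xs = _standardize_series(x)
    ys = _standardize_series(y)
    rng = _pair_rng(xs, ys, seed)
    return build_candidates(jitter(xs, rng), jitter(ys, rng), params)


class TestSelectMixedEmbedding:
    def test_strong_lagged_coupling_selected_first(self):
        # y_t = 0.9 x_{t-2} + small noise: brute-force argmax of the
        # first-cycle criterion must be the driver at lag 2
        rng = np.random.default_rng(3)
        n = 800
        x = rng.normal(size=n)
        y = np.zeros(n)
        y[2:] = 0.9 * x[:-2] + 0.1 * rng.normal(size=n - 2)
        params = MimeParams()
        future, cands = _prepared_clouds(x, y, params)
        emb = select_mixed_embedding(future, cands, params)
        assert emb.components[0] == (DRIVER, 1)  # x_{t-1} predicts y_{t+1}
        scores = [estimate_cmi(future, c.values, None, params.k)
                  for c in cands]
        best = cands[int(np.argmax(scores))]
        assert (best.source, best.lag) == emb.components[0]

    def test_pure_autoregression_selects_driven_only(self):
        x, y = ar1_pair(4, 0.0, n=800, a=0.9)
        params = MimeParams()
        future, cands = _prepared_clouds(x, y, params)
        emb = select_mixed_embedding(future, cands, params)
        assert len(emb) >= 1
        assert all(src == DRIVEN for src, _ in emb.components)

    def test_white_noise_future_empty_embedding(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=600)
        y = rng.normal(size=600)
        params = MimeParams()
        future, cands = _prepared_clouds(x, y, params)
        emb = select_mixed_embedding(future, cands, params)
        if emb.components:  # any spurious pick carries only estimator noise
            assert emb.selection_trace[0].criterion < 0.05

    def test_trace_records_every_cycle(self):
        x, y = ar1_pair(6, 0.8, n=600)
        params = MimeParams(max_cycles=3)
        future, cands = _prepared_clouds(x, y, params)
        emb = select_mixed_embedding(future, cands, params)
        assert 1 <= len(emb.selection_trace) <= 3
        assert len(emb) <= 3
        accepted = [t for t in emb.selection_trace if t.accepted]
        assert len(accepted) == len(emb)

    def test_empty_candidates_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_mixed_embedding(np.zeros((100, 1)), [], MimeParams())


class TestMimeCausality:
    def test_range_and_direction(self):
        x, y = ar1_pair(0, 0.8)
        fwd = mime_causality(x, y, seed=0)
        rev = mime_causality(y, x, seed=0)
        assert 0.0 <= rev < fwd <= 1.0
        assert fwd > 0.2

    def test_no_driver_components_zero(self):
        # independent EEG-like channels: no driver component survives the
        # stopping rule, so the empty-numerator convention gives exactly 0
        x, y = eeg_like_pair(11, 1000)
        r, emb = mime_causality(x, y, seed=0, return_embedding=True)
        assert all(src == DRIVEN for src, _ in emb.components)
        assert r == 0.0

    def test_deterministic_under_seed(self):
        x, y = ar1_pair(1, 0.8, n=700)
        assert mime_causality(x, y, seed=3) == mime_causality(x, y, seed=3)

    def test_constant_series_error(self):
        with pytest.raises(ValueError, match="constant"):
            mime_causality(np.ones(300), np.random.default_rng(0).normal(
                size=300))

    def test_short_series_error(self):
        with pytest.raises(ValueError, match="too short"):
            mime_causality(np.arange(50.0), np.arange(50.0))


class TestCausalityMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="diagonal"):
            CausalityMatrix(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            CausalityMatrix(np.array([[0, 2.0], [0, 0]]), ["a", "b"])
        with pytest.raises(ValueError, match="shape"):
            CausalityMatrix(np.zeros((2, 2)), ["a", "b", "c"])

    def test_requires_standardized(self, small_recording):
        with pytest.raises(ValueError, match="standardized"):
            causality_matrix(small_recording)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(0)
        rec = standardize(MultichannelRecording(
            rng.normal(size=(2, 500)), 100, ["a", "b"]))
        mat = causality_matrix(rec, MimeParams())
        assert mat.values.max() < 0.3
        assert np.all(np.diag(mat.values) == 0)

    def test_planted_couplings_are_top_entries(self):
        from mimenet.synthetic_data import CouplingSpec, gen_coupled_linear
        spec = CouplingSpec(n_channels=4,
                            couplings=[(0, 1, 1, 0.8), (2, 3, 1, 0.8)],
                            base_process="bandlimited", fs=100,
                            duration_s=6.0, seed=0)
        rec, _ = gen_coupled_linear(spec)
        mat = causality_matrix(standardize(rec), seed=0)
        vals = mat.values.copy()
        np.fill_diagonal(vals, -1)
        flat = np.argsort(vals, axis=None)[-2:]
        top2 = {tuple(np.unravel_index(i, vals.shape)) for i in flat}
        assert top2 == {(0, 1), (2, 3)}

    def test_augmented_block_structure(self):
        rng = np.random.default_rng(1)
        recs = [MultichannelRecording(rng.normal(size=(8, 200)), 100,
                                      [f"c{i}" for i in range(8)],
                                      subject_id=s) for s in "AB"]
        aug = standardize(build_augmented(*recs))
        # pairs=[] computes no entries but keeps the block layout
        mat = causality_matrix(aug, pairs=[])
        assert mat.values.shape == (16, 16)
        assert mat.block("A", "A").shape == (8, 8)
        assert mat.block("A", "B").shape == (8, 8)
        assert mat.block_boundaries == {"A": (0, 8), "B": (8, 16)}

    def test_pair_value_invariant_to_other_channels(self):
        # jitter is keyed by the pair's data, so adding channels or
        # relabeling uninvolved ones never changes an entry
        rng = np.random.default_rng(2)
        data3 = rng.normal(size=(3, 400))
        rec3 = standardize(MultichannelRecording(data3, 100, list("abc")))
        rec2 = standardize(MultichannelRecording(data3[:2], 100, list("xy")))
        m3 = causality_matrix(rec3, seed=5, pairs=[(0, 1)])
        m2 = causality_matrix(rec2, seed=5, pairs=[(0, 1)])
        assert m3.values[0, 1] == m2.values[0, 1]

    def test_stack_order_equivariance(self):
        rng = np.random.default_rng(3)
        recs = [MultichannelRecording(rng.normal(size=(2, 300)), 100,
                                      ["c0", "c1"], subject_id=s)
                for s in "AB"]
        ab = standardize(build_augmented(recs[0], recs[1]))
        ba = standardize(build_augmented(recs[1], recs[0]))
        mat_ab = causality_matrix(ab, seed=1)
        mat_ba = causality_matrix(ba, seed=1)
        perm = [2, 3, 0, 1]
        assert np.array_equal(mat_ab.values,
                              mat_ba.values[np.ix_(perm, perm)])

    def test_save_load_roundtrip(self, tmp_path):
        vals = np.array([[0.0, 0.4], [0.1, 0.0]])
        from mimenet.signal_io import WindowSpec
        mat = CausalityMatrix(vals, ["a", "b"],
                              window=WindowSpec(1.0, 2, 1.01, 2.0),
                              block_boundaries={"A": (0, 1), "B": (1, 2)},
                              params=MimeParams().as_dict())
        p = tmp_path / "mat.csv"
        mat.save(p)
        back = CausalityMatrix.load(p)
        assert np.array_equal(back.values, vals)
        assert back.channel_labels == ["a", "b"]
        assert back.window.index == 2
        assert back.block_boundaries == {"A": (0, 1), "B": (1, 2)}


def test_mixed_embedding_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        MixedEmbedding(components=[(DRIVER, 1), (DRIVER, 1)],
                       selection_trace=[])
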