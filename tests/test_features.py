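import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pentamut.features import (
    AA_ORDER,
    ALLOWED_WINDOWS,
    INFO_CAP,
    PSSM_SCORE_RANGE,
    FeatureDescriptor,
    FeatureTrack,
    TrackStore,
    assemble_vector,
    candidate_descriptors,
    encode_composition,
    encode_difference,
    encode_length_bins,
    encode_window,
    parse_pssm,
    propensity_scale,
    propensity_track,
    selected_model_descriptors,
    track_from_tsv,
    track_to_tsv,
    write_pssm,
)
from pentamut.fragments import Pentamer, PentamerPair


class TestLengthBins:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (100, (1, 0.5, 0, 0)),
            (30, (0.5, 0, 0, 0)),
            (300, (1, 1, 1, 1)),
            (60, (0.5, 0, 0, 0)),
            (61, (1, 0.5, 0, 0)),
            (240, (1, 1, 1, 0.5)),
            (241, (1, 1, 1, 1)),
            (1, (0.5, 0, 0, 0)),
        ],
    )
    def test_examples(self, length, expected):
        np.testing.assert_array_equal(encode_length_bins(length), expected)

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            encode_length_bins(0)


class TestComposition:
    def test_single_residue_type(self):
        comp = encode_composition("AAAA")
        assert comp[AA_ORDER.index("A")] == 1.0
        assert comp.sum() == pytest.approx(1.0)

    def test_two_residue_mix(self):
        comp = encode_composition("ACACAC")
        assert comp[AA_ORDER.index("A")] == pytest.approx(0.5)
        assert comp[AA_ORDER.index("C")] == pytest.approx(0.5)

    def test_x_excluded_entirely(self):
        comp = encode_composition("AXAX")
        assert comp[AA_ORDER.index("A")] == 1.0

    def test_all_x_gives_zeros(self):
        np.testing.assert_array_equal(encode_composition("XXX"), np.zeros(20))

    def test_counting_oracle(self, rng):
        seq = "".join(rng.choice(list(AA_ORDER), size=1000))
        comp = encode_composition(seq)
        for i, aa in enumerate(AA_ORDER):
            assert comp[i] == pytest.approx(seq.count(aa) / 1000)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            encode_composition("")


class TestWindow:
    def _track(self, n=20, width=2):
        values = np.arange(n * width, dtype=float).reshape(n, width)
        return FeatureTrack("c", "t", values / values.max())

    def test_window_one_is_center_only(self):
        track = self._track()
        np.testing.assert_array_equal(
            encode_window(track, 7, 1), track.values[7]
        )

    def test_boundary_zero_padded(self):
        track = self._track()
        out = encode_window(track, 0, 5).reshape(5, 2)
        np.testing.assert_array_equal(out[:2], np.zeros((2, 2)))
        np.testing.assert_array_equal(out[2:], track.values[:3])

    def test_interior_equals_direct_slice(self):
        track = self._track()
        out = encode_window(track, 10, 5)
        np.testing.assert_array_equal(out, track.values[8:13].ravel())

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            encode_window(self._track(), 5, 4)
        with pytest.raises(ValueError):
            encode_window(self._track(), 5, 7)  # odd but not in allowed set

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(1, 40),
        center=st.integers(0, 39),
        window=st.sampled_from(ALLOWED_WINDOWS),
    )
    def test_never_reads_out_of_range(self, n, center, window):
        track = FeatureTrack("c", "t", np.random.default_rng(0).random((n, 3)))
        if center >= n:
            with pytest.raises(ValueError):
                encode_window(track, center, window)
            return
        out = encode_window(track, center, window)
        assert out.shape == (3 * window,)
        assert np.all(np.isfinite(out))


class TestDifference:
    def test_negative_delta(self):
        np.testing.assert_allclose(encode_difference(0.7, 0.4), [0.3, 0.0])

    def test_positive_delta(self):
        np.testing.assert_allclose(encode_difference(0.4, 0.7), [0.3, 1.0])

    def test_tie_is_positive(self):
        np.testing.assert_array_equal(encode_difference(0.5, 0.5), [0.0, 1.0])

    @settings(max_examples=100, deadline=None)
    @given(wt=st.floats(0, 1), mut=st.floats(0, 1))
    def test_antisymmetry(self, wt, mut):
        fwd = encode_difference(wt, mut)
        rev = encode_difference(mut, wt)
        assert fwd[0] == pytest.approx(rev[0])
        if wt != mut:
            assert fwd[1] != rev[1]


class TestPropensities:
    def test_helix_breaker_apa(self):
        track = propensity_track("APA", propensity_scale("helix_breaker"))
        np.testing.assert_array_equal(track.values.ravel(), [0.0, 1.0, 0.0])

    def test_mass_extremes(self):
        scale = propensity_scale("mass")
        assert scale["G"] == 0.0
        assert scale["W"] == 1.0

    def test_charge_three_level(self):
        scale = propensity_scale("charge")
        track = propensity_track("DKA", scale)
        np.testing.assert_array_equal(track.values.ravel(), [0.0, 1.0, 0.5])

    def test_x_position_is_zero(self):
        track = propensity_track("AXA", propensity_scale("volume"))
        assert track.values[1, 0] == 0.0

    @pytest.mark.parametrize(
        "name", ["mass", "volume", "hydrophobicity", "cbeta_branching",
                 "helix_breaker", "charge"]
    )
    def test_all_scales_normalized(self, name):
        scale = propensity_scale(name)
        vals = [scale[aa] for aa in AA_ORDER]
        assert min(vals) == 0.0 and max(vals) == 1.0


class TestPssm:
    def _synthetic(self, rng, n=12):
        seq = "".join(rng.choice(list(AA_ORDER), size=n))
        scores = rng.integers(-10, 11, size=(n, 20)).astype(float)
        freqs = rng.dirichlet(np.ones(20), size=n).round(2)
        info = rng.random(n) * 1.9
        return seq, scores, freqs, info

    def test_round_trip(self, rng):
        seq, scores, freqs, info = self._synthetic(rng)
        text = write_pssm(seq, scores, freqs, info)
        tracks = parse_pssm(text, expected_length=len(seq))
        lo, hi = PSSM_SCORE_RANGE
        np.testing.assert_allclose(
            tracks["pssm"].values, (scores - lo) / (hi - lo), atol=1e-9
        )
        np.testing.assert_allclose(
            tracks["freq"].values, np.round(freqs * 100) / 100, atol=1e-9
        )
        np.testing.assert_allclose(
            tracks["info"].values.ravel(), np.round(info, 2) / INFO_CAP, atol=1e-9
        )

    def test_zero_scores_map_to_half(self, rng):
        seq = "ACD"
        text = write_pssm(seq, np.zeros((3, 20)), np.full((3, 20), 0.05),
                          np.zeros(3))
        tracks = parse_pssm(text)
        np.testing.assert_allclose(tracks["pssm"].values, 0.5)

    def test_length_mismatch_raises(self, rng):
        seq, scores, freqs, info = self._synthetic(rng)
        text = write_pssm(seq, scores, freqs, info)
        with pytest.raises(ValueError, match="rows"):
            parse_pssm(text, expected_length=len(seq) + 1)

    def test_garbage_raises(self):
        with pytest.raises(ValueError):
            parse_pssm("this is not a pssm\n")


class TestTrackTsv:
    def test_round_trip(self, rng):
        track = FeatureTrack("c1", "ss", rng.random((8, 3)))
        back = track_from_tsv(track_to_tsv(track), "c1", "ss")
        np.testing.assert_allclose(back.values, track.values, atol=1e-6)

    def test_bad_header(self):
        with pytest.raises(ValueError):
            track_from_tsv("pos\tv0\n0\t1.0\n", "c", "t")


def make_pair(store, seq_a="ALKVGWYFDE", seq_b="ALRVGWYFDE", start=0, wt_is_a=True):
    coords = np.arange(15, dtype=float).reshape(5, 3)
    pa = Pentamer("ca", start, seq_a[start : start + 5], coords)
    pb = Pentamer("cb", start, seq_b[start : start + 5], coords + 0.1)
    store.add_sequence("ca", seq_a)
    store.add_sequence("cb", seq_b)
    return PentamerPair(pa, pb, source_identity=90.0, wt_is_a=wt_is_a)


def fill_tracks(store, refs=("ca", "cb"), n=10, seed=0):
    from pentamut.structure_io import ProteinChain, Residue
    from pentamut.synthetic import make_synthetic_tracks

    for i, ref in enumerate(refs):
        chain = ProteinChain(source_id=ref)
        seq = store.sequence(ref)
        for j, aa in enumerate(seq):
            chain.residues.append(Residue(name="ALA", one_letter=aa, seq_id=str(j)))
        for name, track in make_synthetic_tracks(chain, seed + i).items():
            store.add_track(ref, track)


class TestAssemble:
    def test_selected_descriptors_width_147(self):
        assert sum(d.width for d in selected_model_descriptors()) == 147

    def test_assembled_vector_has_width_147(self):
        store = TrackStore()
        pair = make_pair(store)
        fill_tracks(store)
        vec = assemble_vector(pair, selected_model_descriptors(), store)
        assert len(vec) == 147

    def test_empty_descriptor_list(self):
        store = TrackStore()
        pair = make_pair(store)
        vec = assemble_vector(pair, [], store)
        assert len(vec) == 0 and vec.layout == []

    def test_width_conservation_any_descriptors(self):
        store = TrackStore()
        pair = make_pair(store)
        fill_tracks(store)
        descs = candidate_descriptors()
        vec = assemble_vector(pair, descs, store)
        assert len(vec) == sum(d.width for d in descs)
        offsets = [o for _, o, _ in vec.layout]
        assert offsets == sorted(offsets)

    def test_all_values_in_unit_interval(self):
        store = TrackStore()
        pair = make_pair(store)
        fill_tracks(store)
        vec = assemble_vector(pair, candidate_descriptors(), store)
        assert vec.values.min() >= 0.0 and vec.values.max() <= 1.0

    def test_missing_track_warns_and_zero_fills(self):
        store = TrackStore()
        pair = make_pair(store)
        desc = FeatureDescriptor("flexibility_w21", "local", track="flexibility",
                                 window=21, channels=1)
        with pytest.warns(UserWarning, match="flexibility"):
            vec = assemble_vector(pair, [desc], store)
        np.testing.assert_array_equal(vec.values, np.zeros(21))

    def test_missing_track_strict_raises(self):
        store = TrackStore()
        pair = make_pair(store)
        desc = FeatureDescriptor("flexibility_w21", "local", track="flexibility",
                                 window=21, channels=1)
        with pytest.raises(KeyError):
            assemble_vector(pair, [desc], store, strict=True)

    def test_role_swap_flips_sign_bits(self):
        store = TrackStore()
        pair_fwd = make_pair(store, wt_is_a=True)
        pair_rev = make_pair(store, wt_is_a=False)
        fill_tracks(store)
        # the column difference always reads the wild-type chain's matrix, so
        # magnitude symmetry under role swap requires both chains to carry the
        # same matrix (true in production: one PSSM per protein pair context)
        shared = store.track("ca", "pssm").values
        store.add_track("cb", FeatureTrack("cb", "pssm", shared))
        descs = [
            FeatureDescriptor("psic_diff", "difference", track="psic", channels=1),
            FeatureDescriptor("pssm_diff", "difference", track="pssm",
                              diff_source="column"),
            FeatureDescriptor("vol_diff", "difference", track="volume",
                              diff_source="scale"),
        ]
        fwd = assemble_vector(pair_fwd, descs, store).values
        rev = assemble_vector(pair_rev, descs, store).values
        mags_f, signs_f = fwd[0::2], fwd[1::2]
        mags_r, signs_r = rev[0::2], rev[1::2]
        np.testing.assert_allclose(mags_f, mags_r, atol=1e-12)
        for mf, sf, sr in zip(mags_f, signs_f, signs_r):
            if mf > 0:
                assert sf != sr

    def test_global_features(self):
        store = TrackStore()
        pair = make_pair(store)
        fill_tracks(store)
        descs = [
            FeatureDescriptor("length_bins", "global"),
            FeatureDescriptor("composition", "global"),
            FeatureDescriptor("ss_content", "global"),
            FeatureDescriptor("acc_content", "global"),
        ]
        vec = assemble_vector(pair, descs, store)
        assert len(vec) == 30
        np.testing.assert_array_equal(vec.values[:4], encode_length_bins(10))
        assert vec.values[4:24].sum() == pytest.approx(1.0)
        # predicted-content fractions over 3 states sum to 1
        assert vec.values[24:27].sum() == pytest.approx(1.0)
        assert vec.values[27:30].sum() == pytest.approx(1.0)

    def test_pssm_column_difference_reads_amino_acid_columns(self):
        store = TrackStore()
        pair = make_pair(store, wt_is_a=True)  # wt center K, mut center R
        values = np.full((10, 20), 0.5)
        values[2, AA_ORDER.index("K")] = 0.9
        values[2, AA_ORDER.index("R")] = 0.6
        store.add_track("ca", FeatureTrack("ca", "pssm", values))
        desc = FeatureDescriptor("pssm_diff", "difference", track="pssm",
                                 diff_source="column")
        vec = assemble_vector(pair, [desc], store)
        np.testing.assert_allclose(vec.values, [0.3, 0.0], atol=1e-12)


class TestDescriptorValidation:
    def test_bad_window(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("x", "local", track="ss", window=4, channels=3)

    def test_window_only_for_local(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("x", "global", window=5)

    def test_bad_kind(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("x", "magic")

    def test_bad_diff_source(self):
        with pytest.raises(ValueError):
            FeatureDescriptor("x", "difference", track="t", diff_source="nope")
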