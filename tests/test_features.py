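"""Alignment cleaning, profiles, entropy, tiling, volume assembly, cropping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from distnet.distmap import DistanceMap
from distnet.features import (Alignment, Feature1D, Feature2D, FeatureVolume,
                              assemble_volume, clean_alignment, crop_or_pad,
                              sequence_profile, shannon_entropy, tile_1d)

aln_rows = st.lists(
    st.text(alphabet="AC-", min_size=6, max_size=6), min_size=1, max_size=12)


class TestCleanAlignment:
    def test_identity_when_clean(self):
        aln = Alignment(rows=["ACDEF", "ACDEG", "AC-EF"])
        assert clean_alignment(aln).rows == aln.rows

    def test_all_gap_and_duplicates_removed(self):
        aln = Alignment(rows=["ACDEF", "AC-EF", "AC-EF", "-----", "AAAEF"])
        cleaned = clean_alignment(aln)
        assert len(cleaned.rows) == 3
        assert cleaned.rows[0] == "ACDEF"

    def test_matches_set_based_oracle(self, rng):
        base = ["".join(rng.choice(list("ACDG-"), size=8)) for _ in range(100)]
        base += base[:17]  # planted duplicates
        rng.shuffle(base)
        rows = ["ACDGACDG"] + base
        cleaned = clean_alignment(Alignment(rows=rows))
        oracle = []
        seen = set()
        for i, r in enumerate(rows):
            if i > 0 and set(r) == {"-"}:
                continue
            if r not in seen:
                seen.add(r)
                oracle.append(r)
        assert cleaned.rows == oracle

    @settings(deadline=None, max_examples=50)
    @given(rows=aln_rows)
    def test_idempotent(self, rows):
        if set(rows[0]) == {"-"}:
            rows[0] = "ACACAC"  # query must not be all gaps
        once = clean_alignment(Alignment(rows=rows))
        twice = clean_alignment(once)
        assert once.rows == twice.rows


class TestProfileAndEntropy:
    def test_single_sequence_one_hot(self):
        profile = sequence_profile(Alignment(rows=["ACD"]))
        assert profile.values.shape == (3, 21)
        np.testing.assert_allclose(profile.values.sum(axis=1), 1.0)
        assert profile.values[0, 0] == 1.0  # A
        assert profile.values[1, 1] == 1.0  # C

    def test_half_half_column(self):
        profile = sequence_profile(Alignment(rows=["A", "A", "C", "C"]))
        assert profile.values[0, 0] == pytest.approx(0.5)
        assert profile.values[0, 1] == pytest.approx(0.5)

    def test_profile_matches_counting_oracle(self, rng):
        from distnet.features import PROFILE_ALPHABET

        rows = ["".join(rng.choice(list("ACDEFG-"), size=12))
                for _ in range(50)]
        rows[0] = rows[0].replace("-", "A")
        profile = sequence_profile(Alignment(rows=rows))
        for j in range(12):
            col = [r[j] for r in rows if r[j] != "-"]
            for sym in set(col):
                k = PROFILE_ALPHABET.index(sym)
                assert profile.values[j, k] == pytest.approx(
                    col.count(sym) / len(col))

    def test_entropy_reference_values(self):
        conserved = shannon_entropy(Alignment(rows=["A", "A", "A"]))
        assert conserved.values[0, 0] == pytest.approx(0.0)
        half = shannon_entropy(Alignment(rows=["A", "A", "C", "C"]))
        assert half.values[0, 0] == pytest.approx(1.0)
        four = shannon_entropy(Alignment(rows=["A", "C", "D", "E"]))
        assert four.values[0, 0] == pytest.approx(2.0)


class TestTiling:
    def test_constant_vector(self):
        tiles = tile_1d(Feature1D(name="entropy", values=np.full((4, 1), 0.7)), 4)
        assert len(tiles) == 2
        for t in tiles:
            np.testing.assert_allclose(t.values, 0.7)

    def test_row_tiled_definition(self, rng):
        v = rng.random(6)
        tiles = tile_1d(Feature1D(name="entropy", values=v[:, None]), 6)
        row_tiled = tiles[0].values
        col_tiled = tiles[1].values
        for i in range(6):
            np.testing.assert_allclose(row_tiled[i], v)
            np.testing.assert_allclose(col_tiled[:, i], v)

    def test_three_component_feature_yields_six_channels(self, rng):
        ss3 = rng.dirichlet(np.ones(3), size=10)
        tiles = tile_1d(Feature1D(name="ss3", values=ss3), 10)
        assert len(tiles) == 6
        assert all(t.values.shape == (10, 10) for t in tiles)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tile_1d(Feature1D(name="entropy", values=np.zeros((5, 1))), 6)


class TestAssembleVolume:
    def test_zero_features_zero_volume(self):
        volume = assemble_volume(
            [Feature1D(name="entropy", values=np.zeros((4, 1)))],
            [Feature2D(name="ccmpred", values=np.zeros((4, 4)))])
        assert volume.values.shape == (4, 4, 3)
        assert np.all(volume.values == 0)

    def test_channel_count_one_2d_plus_one_1d(self, rng):
        volume = assemble_volume(
            [Feature1D(name="solvent_acc", values=rng.random((5, 1)))],
            [Feature2D(name="potential", values=rng.random((5, 5)))])
        assert volume.num_channels == 3
        assert volume.channel_names[0] == "potential"

    def test_full_manifest_channel_count(self):
        from distnet.synthetic import (NUM_CHANNELS, SyntheticSpec,
                                       make_features, make_protein)

        spec = SyntheticSpec(length=24, seed=3)
        volume = make_features(make_protein(spec), spec)
        assert volume.num_channels == NUM_CHANNELS == len(volume.channel_names)

    def test_nan_rejected(self):
        bad = np.zeros((4, 4))
        bad[1, 2] = np.nan
        with pytest.raises(ValueError):
            assemble_volume([], [Feature2D(name="ccmpred", values=bad)])


def _volume_and_labels(rng, L, C=2):
    values = rng.random((L, L, C))
    volume = FeatureVolume(values=values,
                           channel_names=[f"ch{c}" for c in range(C)])
    from scipy.spatial.distance import cdist

    coords = rng.uniform(0, 20, (L, 3))
    labels = DistanceMap(values=cdist(coords, coords),
                         mask=np.ones((L, L), bool))
    return volume, labels


class TestCropOrPad:
    def test_identity_window(self, rng):
        volume, labels = _volume_and_labels(rng, 16)
        out_v, out_l = crop_or_pad(volume, labels, crop=16, pad=0, rng_seed=0)
        np.testing.assert_allclose(out_v.values, volume.values)
        np.testing.assert_allclose(out_l.values, labels.values)
        assert out_l.mask.all()

    def test_pad_five_centers_small_target(self, rng):
        # L + 2*pad == crop leaves exactly one window with the map centered
        volume, labels = _volume_and_labels(rng, 118)
        out_v, out_l = crop_or_pad(volume, labels, crop=128, pad=5, rng_seed=4)
        assert out_v.values.shape == (128, 128, 2)
        np.testing.assert_allclose(out_v.values[5:123, 5:123], volume.values)
        assert np.all(out_v.values[:5] == 0) and np.all(out_v.values[:, :5] == 0)
        assert not out_l.mask[:5].any() and not out_l.mask[123:].any()
        assert out_l.mask[5:123, 5:123].all()

    def test_seed_reproducibility(self, rng):
        volume, labels = _volume_and_labels(rng, 40)
        a = crop_or_pad(volume, labels, crop=16, pad=5, rng_seed=99)
        b = crop_or_pad(volume, labels, crop=16, pad=5, rng_seed=99)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[1].values, b[1].values)

    def test_labels_and_features_share_window(self, rng):
        # plant a channel equal to the label distances; it must track the crop
        L = 30
        _, labels = _volume_and_labels(rng, L)
        volume = FeatureVolume(values=labels.values[:, :, None],
                               channel_names=["planted"])
        out_v, out_l = crop_or_pad(volume, labels, crop=12, pad=3, rng_seed=7)
        np.testing.assert_allclose(out_v.values[:, :, 0][out_l.mask],
                                   out_l.values[out_l.mask])

    def test_probability_channels_stay_in_unit_interval(self, rng):
        volume, labels = _volume_and_labels(rng, 20)
        out_v, _ = crop_or_pad(volume, labels, crop=24, pad=2, rng_seed=0)
        assert out_v.values.min() >= 0.0 and out_v.values.max() <= 1.0
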