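import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chimeranet import chimera_builder as cb
from chimeranet.exceptions import ChimeraTooLong, ValidationError
from chimeranet.sequence_io import DatasetTable, RegionInterval, SequenceRecord

_RC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp(seq):
    return "".join(_RC[b] for b in reversed(seq))


def _brute_force_pad_hits(pad, mirna_seq, k=4):
    """Independent oracle: count pad k-mers that are the reverse complement
    of some k-mer of the miRNA (Watson-Crick only)."""
    mirna_kmers = {mirna_seq[i : i + k] for i in range(len(mirna_seq) - k + 1)}
    return sum(
        _revcomp(pad[i : i + k]) in mirna_kmers for i in range(len(pad) - k + 1)
    )


def _random_seq(rng, n):
    return "".join("AUGC"[i] for i in rng.integers(0, 4, n))


class TestConcatenate:
    def test_mirna_prefix_preserved(self, rng):
        mirna = SequenceRecord("m", _random_seq(rng, 21))
        site = _random_seq(rng, 89)
        raw = cb.concatenate_chimera(mirna, site)
        assert len(raw) == 110
        assert raw.startswith(mirna.seq) and raw.endswith(site)

    def test_overlength_rejected(self, rng):
        mirna = SequenceRecord("m", _random_seq(rng, 22))
        with pytest.raises(ChimeraTooLong):
            cb.concatenate_chimera(mirna, _random_seq(rng, 90))

    def test_empty_site_rejected(self, rng):
        mirna = SequenceRecord("m", _random_seq(rng, 21))
        with pytest.raises(ValidationError):
            cb.concatenate_chimera(mirna, "")


class TestPadGeneration:
    def test_zero_length(self, rng):
        assert cb.generate_pad("ACGUACGU", 0, rng) == ""

    def test_no_four_mer_pairs_with_mirna(self):
        rng = np.random.default_rng(99)
        for trial in range(20):
            mirna = _random_seq(rng, 21)
            pad = cb.generate_pad(mirna, 20, rng)
            assert len(pad) == 20
            assert _brute_force_pad_hits(pad, mirna) == 0

    def test_deterministic_under_seed(self):
        mirna = "ACGUACGUACGUACGUACGUA"
        p1 = cb.generate_pad(mirna, 30, np.random.default_rng(7))
        p2 = cb.generate_pad(mirna, 30, np.random.default_rng(7))
        assert p1 == p2

    def test_pad_chimera_identity_at_full_length(self, rng):
        raw = _random_seq(rng, 110)
        assert cb.pad_chimera(raw, raw[:21], rng) == raw

    def test_pad_chimera_preserves_prefix(self):
        rng = np.random.default_rng(3)
        raw = _random_seq(rng, 95)
        full = cb.pad_chimera(raw, raw[:21], rng)
        assert len(full) == 110
        assert full[:95] == raw
        assert _brute_force_pad_hits(full[95:], raw[:21]) == 0

    def test_overlength_raw_rejected(self, rng):
        with pytest.raises(ChimeraTooLong):
            cb.pad_chimera(_random_seq(rng, 111), "ACGU", rng)


class TestOneHot:
    def test_base_a_maps_to_first_column(self, rng):
        seq = "A" + _random_seq(rng, 109)
        mat = cb.encode_one_hot(seq)
        assert mat.shape == (110, 4)
        assert mat[0].tolist() == [1, 0, 0, 0]

    def test_column_order_a_u_g_c(self):
        mat = cb.encode_one_hot("AUGC" + "A" * 106)
        assert mat[:4].tolist() == [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="AUGC", min_size=110, max_size=110))
    def test_rows_one_hot_and_decode_inverts(self, seq):
        mat = cb.encode_one_hot(seq)
        assert (mat.sum(axis=1) == 1).all()
        assert cb.decode_one_hot(mat) == seq

    def test_wrong_length_rejected(self):
        with pytest.raises(ValidationError):
            cb.encode_one_hot("ACGU")

    def test_encode_batch_shape(self, small_table):
        batch = cb.encode_batch(small_table.subset(range(8)))
        assert batch.data.shape == (8, 110, 4)
        assert batch.labels.shape == (8,)


@pytest.fixture(scope="module")
def neg_inputs():
    rng = np.random.default_rng(11)
    mirnas = [SequenceRecord(f"m{i}", _random_seq(rng, 21)) for i in range(4)]
    transcripts, regions = [], []
    for i in range(6):
        tid = f"t{i}"
        transcripts.append(SequenceRecord(tid, _random_seq(rng, 1500)))
        regions += [
            RegionInterval(tid, 0, 200, "UTR5"),
            RegionInterval(tid, 200, 1100, "ORF"),
            RegionInterval(tid, 1100, 1500, "UTR3"),
        ]
    return mirnas, transcripts, regions


class TestNegativeSampling:
    def test_region_ratio_7_2_1(self, neg_inputs):
        mirnas, transcripts, regions = neg_inputs
        chims = cb.sample_negative_sites(
            transcripts, regions, 10, mirnas, cb.NegativeGenConfig(), set(),
            np.random.default_rng(0),
        )
        counts = {r: sum(c.region == r for c in chims) for r in ("UTR3", "UTR5", "ORF")}
        assert counts == {"UTR3": 7, "UTR5": 2, "ORF": 1}

    def test_largest_remainder_apportionment_at_scale(self, neg_inputs):
        mirnas, transcripts, regions = neg_inputs
        chims = cb.sample_negative_sites(
            transcripts, regions, 2000, mirnas, cb.NegativeGenConfig(), set(),
            np.random.default_rng(0),
        )
        counts = {r: sum(c.region == r for c in chims) for r in ("UTR3", "UTR5", "ORF")}
        assert counts == {"UTR3": 1400, "UTR5": 400, "ORF": 200}

    def test_zero_requested(self, neg_inputs):
        mirnas, transcripts, regions = neg_inputs
        assert cb.sample_negative_sites(
            transcripts, regions, 0, mirnas, cb.NegativeGenConfig(), set(),
            np.random.default_rng(0),
        ) == []

    def test_chimeras_full_length_without_pad(self, neg_inputs):
        mirnas, transcripts, regions = neg_inputs
        chims = cb.sample_negative_sites(
            transcripts, regions, 30, mirnas, cb.NegativeGenConfig(), set(),
            np.random.default_rng(2),
        )
        for c in chims:
            assert c.pad_seq == ""
            assert len(c.full_seq) == 110
            assert c.label == 0

    def test_forbidden_pairs_never_produced(self, neg_inputs):
        mirnas, transcripts, regions = neg_inputs
        forbidden = {(m.id, t.id) for m in mirnas[:2] for t in transcripts}
        chims = cb.sample_negative_sites(
            transcripts, regions, 50, mirnas, cb.NegativeGenConfig(), forbidden,
            np.random.default_rng(3),
        )
        assert all(c.mirna_id in ("m2", "m3") for c in chims)

    def test_all_pairs_forbidden_fails_cleanly(self, neg_inputs):
        mirnas, transcripts, regions = neg_inputs
        forbidden = {(m.id, t.id) for m in mirnas for t in transcripts}
        with pytest.raises(ValidationError):
            cb.sample_negative_sites(
                transcripts, regions, 5, mirnas, cb.NegativeGenConfig(), forbidden,
                np.random.default_rng(4),
            )


class TestSplits:
    def test_split_is_disjoint_partition(self, small_table):
        tr, val, te = cb.split_dataset(small_table, (240, 30, 30), np.random.default_rng(1))
        assert (len(tr), len(val), len(te)) == (240, 30, 30)
        merged = sorted(tr.sequences + val.sequences + te.sequences)
        assert merged == sorted(small_table.sequences)

    def test_split_deterministic(self, small_table):
        a = cb.split_dataset(small_table, (240, 30, 30), np.random.default_rng(1))
        b = cb.split_dataset(small_table, (240, 30, 30), np.random.default_rng(1))
        for x, y in zip(a, b):
            assert x == y

    def test_split_size_mismatch_rejected(self, small_table):
        with pytest.raises(ValidationError):
            cb.split_dataset(small_table, (240, 30, 31), np.random.default_rng(1))

    def test_kfold_sizes_differ_by_at_most_one(self, small_table):
        folds = cb.kfold_split(small_table.subset(range(10)), 3, np.random.default_rng(1))
        assert sorted(len(f) for f in folds) == [3, 3, 4]

    def test_kfold_union_is_input_multiset(self, small_table):
        folds = cb.kfold_split(small_table, 7, np.random.default_rng(1))
        merged = sorted(s for f in folds for s in f.sequences)
        assert merged == sorted(small_table.sequences)

    def test_kfold_stratified_keeps_both_classes(self, small_table):
        folds = cb.kfold_split(small_table, 10, np.random.default_rng(1), stratify=True)
        for f in folds:
            assert set(f.labels) == {0, 1}

    def test_kfold_k_larger_than_table_rejected(self, small_table):
        with pytest.raises(ValidationError):
            cb.kfold_split(small_table.subset(range(3)), 4, np.random.default_rng(1))
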