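"""Preprocessing: demultiplexing, trimming, UMI deduplication, FASTA I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selexgram.seqio import (
    PoolManifest,
    RawRead,
    Rejection,
    SequenceTag,
    TrimmedRead,
    UNASSIGNED,
    dedupe_umi,
    demultiplex,
    preprocess,
    read_tags_fasta,
    trim_and_filter,
    write_tags_fasta,
)
from selexgram.simulate import SelexSimConfig, decorate_pool, simulate_selex_rounds

from conftest import random_tags


def _read(seq: str, ident: str = "r") -> RawRead:
    return RawRead(ident, seq)


class TestDemultiplex:
    def test_exact_barcode_assignment_and_conservation(self, manifest):
        reads = (
            [_read("ACGU" + "A" * 30, f"s1_{i}") for i in range(5)]
            + [_read("GUCA" + "C" * 30, f"s2_{i}") for i in range(3)]
            + [_read("UUUU" + "G" * 30, f"x_{i}") for i in range(2)]
        )
        bins = demultiplex(reads, manifest)
        assert len(bins["S1"]) == 5
        assert len(bins["S2"]) == 3
        assert len(bins[UNASSIGNED]) == 2
        assert sum(len(v) for v in bins.values()) == len(reads)
        # barcode is stripped from assigned reads
        assert all(r.sequence == "A" * 30 for r in bins["S1"])

    def test_empty_stream_gives_empty_bins(self, manifest):
        bins = demultiplex([], manifest)
        assert all(len(v) == 0 for v in bins.values())

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            PoolManifest(samples={"a": "ACGU", "b": "ACGU"}, adapters=("G", "C"))


class TestTrimAndFilter:
    def test_insert_recovered_by_construction(self, manifest_no_umi):
        insert = "ACGU" * 10  # 40 nt
        read = _read("GGGAGA" + insert + "UCCUCA")
        res = trim_and_filter(read, manifest_no_umi)
        assert isinstance(res, TrimmedRead)
        assert res.tag.insert == insert
        assert res.umi == ""

    @pytest.mark.parametrize(
        "insert_len,reason",
        [(37, "too_short"), (41, "too_long"), (38, None), (40, None)],
    )
    def test_length_bounds(self, manifest_no_umi, insert_len, reason):
        read = _read("GGGAGA" + "A" * insert_len + "UCCUCA")
        res = trim_and_filter(read, manifest_no_umi)
        if reason is None:
            assert isinstance(res, TrimmedRead)
        else:
            assert isinstance(res, Rejection) and res.reason == reason

    def test_missing_adapter_rejected(self, manifest_no_umi):
        res = trim_and_filter(_read("GGGAGA" + "A" * 40), manifest_no_umi)
        assert isinstance(res, Rejection) and res.reason == "adapter_not_found"
        res = trim_and_filter(_read("A" * 40 + "UCCUCA"), manifest_no_umi)
        assert isinstance(res, Rejection) and res.reason == "adapter_not_found"

    def test_ambiguous_base_rejected(self, manifest_no_umi):
        read = _read("GGGAGA" + "A" * 20 + "N" + "A" * 19 + "UCCUCA")
        res = trim_and_filter(read, manifest_no_umi)
        assert isinstance(res, Rejection) and res.reason == "ambiguous_base"

    def test_umi_extracted_before_insert(self, manifest):
        insert = "C" * 40
        read = _read("GGGAGA" + "GAUCC" + insert + "UCCUCA")
        res = trim_and_filter(read, manifest, sample="S1", round_label="R1")
        assert isinstance(res, TrimmedRead)
        assert res.umi == "GAUCC"
        assert res.tag.insert == insert
        assert (res.tag.sample, res.tag.round) == ("S1", "R1")


class TestDedupe:
    def test_same_umi_same_insert_collapses(self):
        tag = SequenceTag("A" * 40, "S1", "R1")
        out = dedupe_umi([("ACGUA", tag), ("ACGUA", SequenceTag("A" * 40, "S1", "R1"))])
        assert len(out) == 1

    def test_different_umis_kept(self):
        tag = SequenceTag("A" * 40, "S1", "R1")
        out = dedupe_umi([("ACGUA", tag), ("CCGUA", tag)])
        assert len(out) == 2

    def test_empty_umis_identity(self):
        tags = [("", SequenceTag("A" * 40, "S1", "R1")) for _ in range(3)]
        assert len(dedupe_umi(tags)) == 3

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGU", min_size=5, max_size=5),
                st.text(alphabet="ACGU", min_size=8, max_size=8),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_never_grows(self, pairs):
        tagged = [(umi, SequenceTag(ins, "S", "R")) for umi, ins in pairs]
        once = dedupe_umi(tagged)
        assert len(once) <= len(tagged)
        # oracle: first occurrence per (umi, insert) in input order
        seen, expected = set(), []
        for umi, ins in pairs:
            if (umi, ins) not in seen:
                seen.add((umi, ins))
                expected.append((umi, ins))
        assert [t.insert for t in once] == [ins for _, ins in expected]
        # idempotence: deduplicating the survivors is the identity
        survivors = [(u, SequenceTag(i, "S", "R")) for u, i in expected]
        assert [t.insert for t in dedupe_umi(survivors)] == [i for _, i in expected]


def test_fasta_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    tags = [SequenceTag(s, "S1", "R4") for s in random_tags(rng, 20)]
    path = tmp_path / "tags.fa"
    write_tags_fasta(tags, path)
    back = read_tags_fasta(path)
    assert [(t.insert, t.sample, t.round) for t in back] == [
        (t.insert, t.sample, t.round) for t in tags
    ]


def test_preprocess_end_to_end(manifest):
    """Simulated pool dressed with barcode/adapters/UMIs survives preprocessing."""
    pool = simulate_selex_rounds(SelexSimConfig(pool_size=50, seed=11)).pools[0]
    reads = decorate_pool(pool, "ACGU", manifest.adapters, umi_length=5, seed=12)
    result = preprocess(reads, manifest, "R0")
    tags = result.tags["S1"]
    assert {t.insert for t in tags} == set(pool)
    assert all(38 <= len(t.insert) <= 40 for t in tags)
    assert all(set(t.insert) <= set("ACGU") for t in tags)
    stats = result.stats.set_index("sample")
    assert stats.loc["S1", "input_reads"] == 50
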