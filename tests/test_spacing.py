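"""CA-rich classification, pair-spacing counts, z-ranking, group profiles."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from selexgram.spacing import (
    CA_RICH_TETRAMERS,
    GGC_CORE,
    N_PAIRS,
    PairSpacingCounts,
    RankedPairs,
    annotation_mask,
    build_group_profiles,
    classify_ca_rich,
    count_pair_spacings,
    pair_profile,
    profiles_to_frame,
    z_and_rank,
)
from selexgram._encode import kmer_to_index

from conftest import random_tags


def brute_force_ca_rich(t: str) -> bool:
    """Independent four-clause re-statement of the CA-rich definition."""
    return (
        "G" not in t
        and len([c for c in t if c in "CA"]) >= 3
        and any(t[i : i + 2] in ("CA", "AC") for i in range(3))
        and "CCC" not in t
        and "AAA" not in t
    )


def naive_pair_counts(tags, max_gap=25):
    """Double-loop oracle over all tetramer start positions; binary per tag."""
    cells = {}
    for tag in tags:
        seen = set()
        L = len(tag)
        for i in range(L - 3):
            for j in range(i + 4, L - 3):
                gap = j - i - 4
                if gap > max_gap:
                    break
                seen.add((tag[i : i + 4], tag[j : j + 4], gap))
        for key in seen:
            cells[key] = cells.get(key, 0) + 1
    return cells


class TestCaRichClassifier:
    @pytest.mark.parametrize(
        "tet,expected",
        [("CACA", True), ("GGCA", False), ("AAAC", False), ("UCAC", True),
         ("CCCA", False), ("ACUC", True), ("UUCA", False)],
    )
    def test_examples(self, tet, expected):
        assert classify_ca_rich(tet) is expected

    def test_exhaustive_equivalence_and_count(self):
        tets = ["".join(t) for t in product("ACGU", repeat=4)]
        positives = [t for t in tets if classify_ca_rich(t)]
        assert positives == [t for t in tets if brute_force_ca_rich(t)]
        assert len(positives) == 30
        assert set(positives) == set(CA_RICH_TETRAMERS)

    def test_non_tetramer_rejected(self):
        with pytest.raises(ValueError):
            classify_ca_rich("CACAA")


class TestPairCounts:
    def test_single_occurrence_geometry(self):
        counts = count_pair_spacings(["GGCAUUCACA" + "G" * 30])
        idx = kmer_to_index("GGCA") * 256 + kmer_to_index("CACA")
        assert counts.counts[idx, 2] == 1
        rev = kmer_to_index("CACA") * 256 + kmer_to_index("GGCA")
        assert counts.counts[rev].sum() == 0

    def test_universe_shape(self):
        counts = count_pair_spacings(["ACGU" * 10])
        assert counts.counts.shape == (65536, 26)
        assert N_PAIRS == 65536

    def test_max_gap_validation(self):
        with pytest.raises(ValueError):
            count_pair_spacings(["ACGUACGU"], max_gap=-1)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_naive_oracle(self, seed):
        tags = random_tags(np.random.default_rng(seed), 50)
        counts = count_pair_spacings(tags)
        oracle = naive_pair_counts(tags)
        nz = np.nonzero(counts.counts)
        assert len(nz[0]) == len(oracle)
        for pair_idx, gap in zip(*nz):
            from selexgram._encode import index_to_kmer

            m1 = index_to_kmer(int(pair_idx) // 256, 4)
            m2 = index_to_kmer(int(pair_idx) % 256, 4)
            assert counts.counts[pair_idx, gap] == oracle[(m1, m2, int(gap))]

    def test_gap_window_geometry_on_40mers(self):
        """In a 40-nt tag the extreme gaps 0 and 25 are both reachable."""
        head = "GGCA" + "CACA"  # gap 0
        tail = "GGCA" + "U" * 25 + "CGGC"  # gap 25, total 33 nt
        counts = count_pair_spacings([head + "U" * 32, "UUUCGGG" + tail])
        assert counts.counts[kmer_to_index("GGCA") * 256 + kmer_to_index("CACA"), 0] == 1
        assert counts.counts[kmer_to_index("GGCA") * 256 + kmer_to_index("CGGC"), 25] == 1


class TestZAndRank:
    def test_uniform_counts_zero_everywhere(self):
        c = PairSpacingCounts(np.full((N_PAIRS, 26), 3, dtype=np.int64), 10)
        corrected, ranked = z_and_rank(c, c)
        assert np.all(corrected == 0)
        assert np.all(ranked.pairs["mean_z"] == 0)

    def test_identical_control_cancels(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 20, (N_PAIRS, 26)).astype(np.int64)
        c1 = PairSpacingCounts(counts, 30)
        c2 = PairSpacingCounts(counts.copy(), 30)
        corrected, _ = z_and_rank(c1, c2)
        np.testing.assert_allclose(corrected, 0, atol=1e-12)

    def test_ranking_sorted_with_lexicographic_ties(self):
        counts = np.zeros((N_PAIRS, 26), dtype=np.int64)
        hi = [kmer_to_index("CACA") * 256 + kmer_to_index("ACAC"),
              kmer_to_index("ACAC") * 256 + kmer_to_index("CACA")]
        counts[hi, :] = 5
        sample = PairSpacingCounts(counts, 10)
        control = PairSpacingCounts(np.zeros_like(counts), 10)
        _, ranked = z_and_rank(sample, control)
        top2 = ranked.pairs.head(2)
        # equal mean z -> lexicographically smaller ordered pair first
        assert list(top2["m1"]) == ["ACAC", "CACA"]
        assert (ranked.pairs["mean_z"].diff().dropna() <= 1e-12).all()


def _ranked_from_pairs(pairs):
    df = pd.DataFrame(pairs, columns=["m1", "m2"])
    df["mean_z"] = np.linspace(5, 1, len(df))
    return RankedPairs(df, top_k=500)


class TestGroupProfiles:
    def setup_method(self):
        ca = [t for t in CA_RICH_TETRAMERS]
        pairs = [(ca[i], ca[i + 1]) for i in range(12)]  # 12 CA/CA pairs
        pairs += [(ca[0], "GGCA"), ("GGCA", ca[1]), (ca[2], "CGGC"), ("CGGC", ca[3])]
        pairs += [("GGCA", "GGCA"), ("GGCA", "CGGC"), ("CGGC", "CGGC")]
        self.ranked = _ranked_from_pairs(pairs)
        self.corrected = np.random.default_rng(0).normal(size=(N_PAIRS, 26))

    def test_full_length_groups(self):
        profiles = build_group_profiles(self.ranked, self.corrected, "full_length")
        by = {p.group: p for p in profiles}
        assert list(by) == list("abcdef")
        assert len(by["a"].member_pairs) == 10  # top-10 CA/CA only
        assert len(by["f"].member_pairs) == 3
        core_pairs = {(a, b) for a in GGC_CORE for b in GGC_CORE}
        assert set(by["f"].member_pairs) <= core_pairs
        assert all(len(p.mean_z_by_gap) == 26 for p in profiles)
        assert all(p.annotation_threshold == 4.6 for p in profiles)

    def test_profile_values_are_member_means(self):
        profiles = build_group_profiles(self.ranked, self.corrected, "full_length")
        by = {p.group: p for p in profiles}
        b = by["b"]
        rows = np.array([pair_profile(self.corrected, m1, m2) for m1, m2 in b.member_pairs])
        np.testing.assert_allclose(b.mean_z_by_gap, rows.mean(axis=0))

    def test_kh_derivatives_reuse_groups_b_to_e(self):
        profiles = build_group_profiles(self.ranked, self.corrected, "kh")
        assert [p.group for p in profiles] == ["b", "c", "d", "e"]
        assert all(p.annotation_threshold == 2.5 for p in profiles)

    def test_rrm12_merges_by_group_letter(self):
        profiles = build_group_profiles(self.ranked, self.corrected, "rrm12")
        by = {p.group: p for p in profiles}
        assert set(by) == {"a", "b+d", "c+e"}
        full = {p.group: p for p in build_group_profiles(self.ranked, self.corrected, "full_length")}
        assert by["b+d"].member_pairs == full["b"].member_pairs + full["d"].member_pairs

    def test_empty_group_flagged_not_error(self):
        ranked = _ranked_from_pairs([("GGCA", "GGCA")])
        profiles = build_group_profiles(ranked, self.corrected, "full_length")
        by = {p.group: p for p in profiles}
        assert by["a"].empty and not by["f"].empty

    def test_annotation_marks_cells_above_threshold(self):
        profiles = build_group_profiles(self.ranked, self.corrected, "kh")
        frame = profiles_to_frame(profiles)
        mask = annotation_mask(profiles)
        assert mask.to_numpy().tolist() == (frame > 2.5).to_numpy().tolist()
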