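"""Ordered tetramer-pair spacing analysis of selection-round tags.

A tag contains the ordered pair (m1, m2) at gap g when m1 starts at some
position i and m2 starts at i + 4 + g; the gap is the number of nucleotides
strictly between the end of m1 and the start of m2 (the N_g of a
"GGCA-N20-CACA" layout). Containment per (pair, gap, tag) is binary. All
65,536 ordered pairs x 26 gaps (0-25) form the cell universe; cell
frequencies are z-scored jointly over that universe, corrected by
subtracting the matched control z, and pairs are ranked by their mean
corrected z over the 26 gaps. The top-500 ranked pairs of a reference
(full-length protein) sample seed six motif-class groups:

    (a) top-10 pairs of two CA-rich tetramers
    (b) CA-rich 5' + GGCA 3'         (c) GGCA 5' + CA-rich 3'
    (d) CA-rich 5' + CGGC 3'         (e) CGGC 5' + CA-rich 3'
    (f) two GGC-core elements (GGCA/CGGC)

whose per-gap mean profiles give the spacing heat maps. A CA-rich tetramer
contains no G, has at least three C/A residues, at least one adjacent C-A or
A-C alternation, and no CCC or AAA run (30 of the 256 tetramers qualify).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ._encode import (
    encode_matrix,
    group_by_length,
    index_to_kmer,
    kmer_index_matrix,
    kmer_to_index,
)
from .enrichment import zscore_frequencies
from .seqio import SequenceTag

logger = logging.getLogger(__name__)

MAX_GAP = 25
N_PAIRS = 256 * 256
TOP_K = 500

GGC_CORE = ("GGCA", "CGGC")

#: heat-map annotation thresholds by sample kind
ANNOTATION_THRESHOLDS = {"full_length": 4.6, "rrm12": 4.6, "kh": 2.5}


def classify_ca_rich(tetramer: str) -> bool:
    """Four-clause CA-rich predicate on a single tetramer.

    True iff the tetramer has no G, at least three C/A residues, an adjacent
    "CA" or "AC", and contains neither "CCC" nor "AAA".
    """
    t = tetramer.upper().replace("T", "U")
    if len(t) != 4 or set(t) - set("ACGU"):
        raise ValueError(f"input must be a tetramer over A/C/G/U, got {tetramer!r}")
    if "G" in t:
        return False
    if sum(c in "CA" for c in t) < 3:
        return False
    if "CA" not in t and "AC" not in t:
        return False
    if "CCC" in t or "AAA" in t:
        return False
    return True


CA_RICH_TETRAMERS: tuple[str, ...] = tuple(
    "".join(t) for t in product("ACGU", repeat=4) if classify_ca_rich("".join(t))
)


@dataclass
class PairSpacingCounts:
    """Tag-containment counts for every (ordered pair, gap) cell."""

    counts: np.ndarray = field(repr=False)  # (65536, max_gap+1) int64
    total_tags: int = 0
    max_gap: int = MAX_GAP
    sample: str = ""
    round: str = ""

    @property
    def frequencies(self) -> np.ndarray:
        if self.total_tags == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_tags


@dataclass
class RankedPairs:
    """Ordered tetramer pairs ranked by mean corrected z over gaps 0-25."""

    pairs: pd.DataFrame = field(repr=False)  # columns m1, m2, mean_z
    top_k: int = TOP_K

    def top(self) -> pd.DataFrame:
        return self.pairs.head(self.top_k)


@dataclass
class ClassSpacingProfile:
    group: str
    member_pairs: list[tuple[str, str]]
    mean_z_by_gap: np.ndarray = field(repr=False)  # (26,)
    annotation_threshold: float = 4.6
    empty: bool = False


def count_pair_spacings(
    tags: Iterable[SequenceTag | str],
    max_gap: int = MAX_GAP,
    sample: str = "",
    round_label: str = "",
) -> PairSpacingCounts:
    """Count tags containing each ordered tetramer pair at each gap 0..max_gap."""
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    seqs = [t.insert if isinstance(t, SequenceTag) else t for t in tags]
    counts = np.zeros((N_PAIRS, max_gap + 1), dtype=np.int64)
    for length, group in group_by_length(seqs).items():
        if length < 8:
            raise ValueError("tags must be at least 8 nt for pair counting")
        tet = kmer_index_matrix(encode_matrix(group), 4)
        w_total = tet.shape[1]
        for g in range(max_gap + 1):
            w = w_total - 4 - g
            if w <= 0:
                break
            left = tet[:, :w]
            right = tet[:, 4 + g :]
            valid = (left >= 0) & (right >= 0)
            keys = np.where(valid, left * 256 + right, -1)
            srt = np.sort(keys, axis=1)
            first = np.ones_like(srt, dtype=bool)
            first[:, 1:] = srt[:, 1:] != srt[:, :-1]
            vals = srt[first & (srt >= 0)]
            counts[:, g] += np.bincount(vals, minlength=N_PAIRS)
    return PairSpacingCounts(counts, len(seqs), max_gap, sample, round_label)


def z_and_rank(
    sample_counts: PairSpacingCounts,
    control_counts: PairSpacingCounts,
    top_k: int = TOP_K,
) -> tuple[np.ndarray, RankedPairs]:
    """Control-corrected cell z-scores and the pair ranking by mean z.

    Cell frequencies are standardized jointly over the full pair x gap
    universe (population sd); correction subtracts the control cell z. The
    per-pair score is the arithmetic mean of its corrected z over all gaps;
    ties are broken by lexicographic pair order.
    """
    if sample_counts.max_gap != control_counts.max_gap:
        raise ValueError("sample and control must share max_gap")
    z_sample = _cell_z(sample_counts.frequencies)
    z_control = _cell_z(control_counts.frequencies)
    corrected = z_sample - z_control
    mean_z = corrected.mean(axis=1)
    order = np.lexsort((np.arange(N_PAIRS), -mean_z))
    m1 = [index_to_kmer(i // 256, 4) for i in order]
    m2 = [index_to_kmer(i % 256, 4) for i in order]
    df = pd.DataFrame({"m1": m1, "m2": m2, "mean_z": mean_z[order]})
    return corrected, RankedPairs(df, top_k=top_k)


def _cell_z(freq: np.ndarray) -> np.ndarray:
    flat = zscore_frequencies(freq.ravel())
    return flat.reshape(freq.shape)


def pair_profile(corrected: np.ndarray, m1: str, m2: str) -> np.ndarray:
    """Corrected-z spacing profile (one value per gap) of one ordered pair."""
    return corrected[kmer_to_index(m1) * 256 + kmer_to_index(m2)]


def _group_members(top: pd.DataFrame) -> dict[str, list[tuple[str, str]]]:
    ca = set(CA_RICH_TETRAMERS)
    core = set(GGC_CORE)
    members: dict[str, list[tuple[str, str]]] = {g: [] for g in "abcdef"}
    for m1, m2 in zip(top["m1"], top["m2"]):
        if m1 in ca and m2 in ca and len(members["a"]) < 10:
            members["a"].append((m1, m2))
        if m1 in ca and m2 == "GGCA":
            members["b"].append((m1, m2))
        if m1 == "GGCA" and m2 in ca:
            members["c"].append((m1, m2))
        if m1 in ca and m2 == "CGGC":
            members["d"].append((m1, m2))
        if m1 == "CGGC" and m2 in ca:
            members["e"].append((m1, m2))
        if m1 in core and m2 in core:
            members["f"].append((m1, m2))
    return members


def build_group_profiles(
    ranked_reference: RankedPairs,
    corrected: np.ndarray,
    sample_kind: str = "full_length",
) -> list[ClassSpacingProfile]:
    """Per-gap mean corrected-z profiles for the motif-class groups.

    Group membership is determined on the reference sample's top-500 ranking
    (group (a) limited to the 10 highest-ranked CA/CA pairs) and then applied
    to the corrected z of the sample being profiled. ``sample_kind`` selects
    the presentation: ``full_length`` emits groups a-f; ``kh`` derivatives
    reuse groups b-e; ``rrm12`` emits group a plus the two merged summaries
    b+d and c+e.
    """
    if sample_kind not in ANNOTATION_THRESHOLDS:
        raise ValueError(f"sample_kind must be one of {sorted(ANNOTATION_THRESHOLDS)}")
    threshold = ANNOTATION_THRESHOLDS[sample_kind]
    members = _group_members(ranked_reference.top())
    if sample_kind == "full_length":
        selected: list[tuple[str, list[tuple[str, str]]]] = [
            (g, members[g]) for g in "abcdef"
        ]
    elif sample_kind == "kh":
        selected = [(g, members[g]) for g in "bcde"]
    else:  # rrm12: merged by group letter
        selected = [
            ("a", members["a"]),
            ("b+d", members["b"] + members["d"]),
            ("c+e", members["c"] + members["e"]),
        ]
    n_gaps = corrected.shape[1]
    profiles = []
    for label, pairs in selected:
        if not pairs:
            logger.warning("group %s has no member pairs in the top-%d", label, ranked_reference.top_k)
            profiles.append(
                ClassSpacingProfile(label, [], np.zeros(n_gaps), threshold, empty=True)
            )
            continue
        rows = [kmer_to_index(m1) * 256 + kmer_to_index(m2) for m1, m2 in pairs]
        profiles.append(
            ClassSpacingProfile(label, pairs, corrected[rows].mean(axis=0), threshold)
        )
    return profiles


def profiles_to_frame(profiles: list[ClassSpacingProfile]) -> pd.DataFrame:
    """Heat-map-ready matrix: one row per group, one column per gap."""
    data = {p.group: p.mean_z_by_gap for p in profiles}
    df = pd.DataFrame(data).T
    df.columns = [f"gap_{g}" for g in range(df.shape[1])]
    return df


def annotation_mask(profiles: list[ClassSpacingProfile]) -> pd.DataFrame:
    """Boolean matrix marking cells whose mean z exceeds the sample-kind threshold."""
    df = profiles_to_frame(profiles)
    thr = pd.Series({p.group: p.annotation_threshold for p in profiles})
    return df.gt(thr, axis=0)


def plot_group_heatmap(profiles: list[ClassSpacingProfile], path: str) -> None:
    """Render the group x gap profile matrix as a heat map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profiles_to_frame(profiles)
    mask = annotation_mask(profiles)
    fig, ax = plt.subplots(figsize=(10, 1 + 0.5 * len(df)))
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="viridis")
    ys, xs = np.where(mask.to_numpy())
    ax.scatter(xs, ys, s=12, facecolors="none", edgecolors="white")
    ax.set_yticks(range(len(df)), df.index)
    ax.set_xticks(range(0, df.shape[1], 5))
    ax.set_xlabel("gap (nt)")
    fig.colorbar(im, ax=ax, label="mean corrected z")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
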