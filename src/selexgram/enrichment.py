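"""k-mer enrichment z-scores for selection-round tag pools.

For each k-mer (k = 4, 5, 6 -> 256, 1024, 4096 motifs) the pipeline counts
the number of tags *containing* the motif at least once (presence, not
occurrences), converts containment frequencies to z-scores standardized over
the full 4**k motif universe of one sample/round, and corrects each sample
z-score by subtracting the matched negative-control (e.g. GST round) z-score
for the same motif:

    f(m)   = containment_count(m) / total_tags
    z_raw  = (f(m) - mean_f) / sd_f          (population sd over the universe)
    z_corr = z_raw,sample(m) - z_raw,control(m)

A zero-variance table (all motifs equally frequent) yields all-zero z-scores.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._encode import (
    encode_matrix,
    group_by_length,
    index_to_kmer,
    kmer_index_matrix,
    row_presence_counts,
)
from .seqio import SequenceTag

logger = logging.getLogger(__name__)

VALID_K = (4, 5, 6)
DEFAULT_HIGHLIGHT_Z = 1.5


@dataclass
class MotifCountTable:
    """Per-motif tag-containment counts for one sample/round."""

    k: int
    sample: str
    round: str
    counts: np.ndarray = field(repr=False)
    total_tags: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(f"counts must cover all {4 ** self.k} motifs")
        if self.counts.min() < 0 or self.counts.max() > self.total_tags:
            raise ValueError("counts must lie in [0, total_tags]")

    @property
    def frequencies(self) -> np.ndarray:
        if self.total_tags == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_tags

    def motifs(self) -> list[str]:
        return [index_to_kmer(i, self.k) for i in range(4**self.k)]


@dataclass
class CorrelationResult:
    sample_x: str
    sample_y: str
    r: float
    n_motifs: int
    highlight_threshold: float = DEFAULT_HIGHLIGHT_Z


def _tag_sequences(tags: Iterable[SequenceTag | str]) -> list[str]:
    return [t.insert if isinstance(t, SequenceTag) else t for t in tags]


def count_kmer_containment(
    tags: Iterable[SequenceTag | str],
    k: int,
    sample: str = "",
    round_label: str = "",
) -> MotifCountTable:
    """Count tags containing each of the 4**k motifs at least once."""
    if k not in VALID_K:
        if k < 1:
            raise ValueError(f"k must be a positive integer, got {k}")
        warnings.warn(f"k={k} is outside the standard set {VALID_K}", stacklevel=2)
    seqs = _tag_sequences(tags)
    universe = 4**k
    counts = np.zeros(universe, dtype=np.int64)
    for length, group in group_by_length(seqs).items():
        if length < k:
            raise ValueError(f"all tags must have length >= k (found {length} < {k})")
        ids = kmer_index_matrix(encode_matrix(group), k)
        counts += row_presence_counts(ids, universe)
    return MotifCountTable(k, sample, round_label, counts, len(seqs))


def zscore_frequencies(freq: np.ndarray) -> np.ndarray:
    """Standardize frequencies over the motif universe (population sd).

    Zero variance is a degenerate table; all z-scores are defined as 0.
    """
    sd = float(np.std(freq))
    # guard against a constant vector whose floating-point sd is merely ~1e-17
    if sd <= 1e-12 * max(1.0, float(np.abs(freq).max())):
        logger.info("zero-variance frequency vector; z-scores set to 0")
        return np.zeros_like(freq, dtype=float)
    return (freq - freq.mean()) / sd


def compute_z_scores(table: MotifCountTable, control: MotifCountTable) -> pd.DataFrame:
    """Raw and control-corrected z-scores for every motif of one table.

    Returns a DataFrame indexed 0..4**k-1 with columns ``motif``, ``count``,
    ``frequency``, ``z_raw``, ``z_corrected``; sample/round are stored in
    ``DataFrame.attrs``.
    """
    if table.k != control.k:
        raise ValueError("sample and control tables must share k")
    if table.round != control.round:
        logger.warning(
            "round labels differ between sample (%s) and control (%s)",
            table.round,
            control.round,
        )
    z_raw = zscore_frequencies(table.frequencies)
    z_ctrl = zscore_frequencies(control.frequencies)
    df = pd.DataFrame(
        {
            "motif": table.motifs(),
            "count": table.counts,
            "frequency": table.frequencies,
            "z_raw": z_raw,
            "z_corrected": z_raw - z_ctrl,
        }
    )
    df.attrs["sample"] = table.sample
    df.attrs["round"] = table.round
    df.attrs["k"] = table.k
    return df


def rank_top_motifs(
    stats_df: pd.DataFrame, n: int = 10, highlight_threshold: float = DEFAULT_HIGHLIGHT_Z
) -> pd.DataFrame:
    """Top-n motifs by corrected z, ties broken lexicographically by motif.

    Adds a boolean ``highlighted`` column marking motifs whose corrected
    z-score exceeds the highlight threshold (default 1.5).
    """
    if stats_df.empty:
        raise ValueError("stats table must be non-empty")
    ranked = stats_df.sort_values(
        ["z_corrected", "motif"], ascending=[False, True], kind="mergesort"
    ).head(min(n, len(stats_df)))
    ranked = ranked.copy()
    ranked["highlighted"] = ranked["z_corrected"] > highlight_threshold
    ranked.attrs.update(stats_df.attrs)
    return ranked.reset_index(drop=True)


def z_correlation(
    stats_x: pd.DataFrame,
    stats_y: pd.DataFrame,
    highlight_threshold: float = DEFAULT_HIGHLIGHT_Z,
) -> CorrelationResult:
    """Pearson correlation of corrected z-scores over the shared motif universe."""
    if list(stats_x["motif"]) != list(stats_y["motif"]):
        raise ValueError("both collections must cover the identical motif universe")
    x = stats_x["z_corrected"].to_numpy()
    y = stats_y["z_corrected"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(
        sample_x=stats_x.attrs.get("sample", "x"),
        sample_y=stats_y.attrs.get("sample", "y"),
        r=r,
        n_motifs=len(x),
        highlight_threshold=highlight_threshold,
    )


def write_motif_table(stats_df: pd.DataFrame, path: str) -> None:
    stats_df.to_csv(path, sep="\t", index=False)
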