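"""Synthetic data generators: SELEX rounds, 101-mer fixtures, and a regulome.

``simulate_selex_rounds`` emulates iterative in vitro selection from a
random N40 RNA pool: round 0 is uniform random; each subsequent round is
drawn from the previous one with replacement, with probability proportional
to w(s)**schedule[r], where the selection weight

    w(s) = 1 + sum_motif gain * [s contains motif]
             + sum_pair  gain * [s contains (m1, m2) at the planted gap]

is additive in planted motif/pair affinities and the per-round exponent
schedule mimics increasing wash stringency. All generators are
deterministic under a fixed seed.

``make_fixture_101mers`` builds the rationally designed 101-nt RNA with the
layout GGCA-N20-CACA-N14-CACA-N22-CGGC-N4-(CA)4 plus its mutant series.
Spacer and flank nucleotides are drawn from {U, G} in a fixed pattern that
contains no GGC-core or CA-element occurrence (including across block
junctions); scan results on the fixtures depend only on the motif layout,
not on spacer identity.

``generate_regulome`` builds UTR-like regions with planted motif arrays
(copies of the wild-type 101-mer template embedded in a GGC-core-free random
background), lognormal expression levels, and Poisson CLIP tag counts whose
rate increases with the planted array count:

    tags ~ Poisson(expression * (lambda0 + lambda1 * k))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._encode import BASES, encode, kmer_index_matrix, kmer_to_index
from .seqio import RawRead

logger = logging.getLogger(__name__)

_GGCA = kmer_to_index("GGCA")
_CGGC = kmer_to_index("CGGC")


# --------------------------------------------------------------------------
# SELEX round simulation
# --------------------------------------------------------------------------


@dataclass
class SelexSimConfig:
    pool_size: int = 50_000
    insert_length: int = 40
    rounds: int = 4
    planted_motifs: list[tuple[str, float]] = field(default_factory=list)
    planted_pairs: list[tuple[str, str, int, float]] = field(default_factory=list)
    stringency_schedule: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size <= 0:
            raise ValueError("pool_size must be positive")
        if self.stringency_schedule is None:
            # wash stringency rises each round; simplest monotone analog
            self.stringency_schedule = [1.0 + 0.5 * r for r in range(self.rounds)]
        if len(self.stringency_schedule) != self.rounds:
            raise ValueError("stringency_schedule length must equal rounds")
        if any(s < 1 for s in self.stringency_schedule):
            raise ValueError("stringency exponents must be >= 1")
        for _, gain in self.planted_motifs:
            if not np.isfinite(gain) or gain < 0:
                raise ValueError("motif gains must be finite and >= 0")
        for _, _, gap, gain in self.planted_pairs:
            if gap < 0 or not np.isfinite(gain) or gain < 0:
                raise ValueError("pair gaps must be >= 0 and gains finite >= 0")


@dataclass
class SelexRounds:
    """Per-round pools; ``pools[0]`` is the unselected random pool."""

    config: SelexSimConfig
    pools: list[list[str]]

    def round_pool(self, r: int) -> list[str]:
        return self.pools[r]


def _selection_weights(mat: np.ndarray, config: SelexSimConfig) -> np.ndarray:
    n = mat.shape[0]
    w = np.ones(n)
    kmer_cache: dict[int, np.ndarray] = {}

    def ids_for(k: int) -> np.ndarray:
        if k not in kmer_cache:
            kmer_cache[k] = kmer_index_matrix(mat, k)
        return kmer_cache[k]

    for motif, gain in config.planted_motifs:
        k = len(motif)
        contains = (ids_for(k) == kmer_to_index(motif)).any(axis=1)
        w += gain * contains
    if config.planted_pairs:
        tet = ids_for(4)
        width = tet.shape[1]
        for m1, m2, gap, gain in config.planted_pairs:
            wlen = width - 4 - gap
            if wlen <= 0:
                continue
            hit = (
                (tet[:, :wlen] == kmer_to_index(m1))
                & (tet[:, 4 + gap :] == kmer_to_index(m2))
            ).any(axis=1)
            w += gain * hit
    return w


def simulate_selex_rounds(config: SelexSimConfig) -> SelexRounds:
    """Simulate selection rounds; returns pools for rounds 0..rounds."""
    rng = np.random.default_rng(config.seed)
    mat = rng.integers(0, 4, size=(config.pool_size, config.insert_length), dtype=np.uint8)
    neutral = not config.planted_motifs and not config.planted_pairs
    pools = [_decode_pool(mat)]
    for r in range(config.rounds):
        if neutral:
            idx = rng.integers(0, config.pool_size, size=config.pool_size)
        else:
            w = _selection_weights(mat, config) ** config.stringency_schedule[r]
            idx = rng.choice(config.pool_size, size=config.pool_size, p=w / w.sum())
        mat = mat[idx]
        pools.append(_decode_pool(mat))
    return SelexRounds(config, pools)


def _decode_pool(mat: np.ndarray) -> list[str]:
    lut = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    buf = lut[mat].tobytes().decode("ascii")
    L = mat.shape[1]
    return [buf[i : i + L] for i in range(0, len(buf), L)]


def decorate_pool(
    pool: list[str],
    barcode: str,
    adapters: tuple[str, str],
    umi_length: int = 5,
    seed: int = 0,
) -> list[RawRead]:
    """Dress inserts as raw reads (barcode + 5' adapter + UMI + insert + 3'
    adapter) for end-to-end preprocessing tests."""
    rng = np.random.default_rng(seed)
    a5, a3 = adapters
    reads = []
    for i, insert in enumerate(pool):
        umi = "".join(BASES[b] for b in rng.integers(0, 4, size=umi_length))
        seq = barcode + a5 + umi + insert + a3
        reads.append(RawRead(f"read{i}", seq, "I" * len(seq)))
    return reads


def write_pool_fasta(pool: list[str], path: str | Path, prefix: str = "tag") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(pool):
            fh.write(f">{prefix}{i}\n{seq}\n")


# --------------------------------------------------------------------------
# 101-mer fixture series
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture101:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 101:
            raise ValueError("fixture sequences must be exactly 101 nt")


# block layout of the wild-type 101-mer; spacers/flanks are motif-free {U,G}
_WT_BLOCKS: tuple[tuple[str, str], ...] = (
    ("flank5", "UGUGUGUG"),
    ("ggc", "GGCA"),
    ("sp", "G" + "U" * 18 + "G"),  # N20
    ("ca", "CACA"),
    ("sp", "G" + "U" * 12 + "G"),  # N14
    ("ca", "CACA"),
    ("sp", "G" + "U" * 20 + "G"),  # N22
    ("ggc", "CGGC"),
    ("sp", "GUUG"),  # N4
    ("carep", "CACACACA"),  # (CA)4
    ("flank3", "GUGUGUGUG"),
)

FIXTURE_NAMES = (
    "WT",
    "CA->UG",
    "GGC->UG",
    "allUG",
    "GGC<->CA",
    "GGC<->CA_UG",
    "(CA)4<->",
)


def _assemble(blocks: list[tuple[str, str]]) -> str:
    return "".join(seq for _, seq in blocks)


def make_fixture_101mers() -> dict[str, Fixture101]:
    """The seven named 101-nt fixtures (wild type and mutant series).

    Mutants differ from the wild type only at motif positions: CA->UG and
    GGC->UG replace the respective elements with UG runs; allUG replaces
    both; GGC<->CA swaps the 5' GGCA anchor with the first internal CACA;
    GGC<->CA_UG additionally mutates the remaining CA elements to UG; and
    (CA)4<-> relocates the (CA)4 repeat to the 5' end by block exchange with
    the 5' flank.
    """
    wt = [list(b) for b in _WT_BLOCKS]

    def mutate(kinds: set[str]) -> list:
        out = []
        for kind, seq in wt:
            if kind in kinds:
                seq = "UG" * (len(seq) // 2)
            out.append((kind, seq))
        return out

    def swap(blocks: list, i: int, j: int) -> list:
        out = [list(b) for b in blocks]
        out[i][1], out[j][1] = out[j][1], out[i][1]
        return [tuple(b) for b in out]

    ggc_ca = swap(wt, 1, 3)  # GGCA <-> first CACA
    # after the swap, mutate the blocks that still hold CA elements
    ggc_ca_ug = [
        (kind, "UG" * (len(seq) // 2) if seq in ("CACA", "CACACACA") else seq)
        for kind, seq in ggc_ca
    ]
    fixtures = {
        "WT": _assemble([tuple(b) for b in wt]),
        "CA->UG": _assemble(mutate({"ca", "carep"})),
        "GGC->UG": _assemble(mutate({"ggc"})),
        "allUG": _assemble(mutate({"ca", "carep", "ggc"})),
        "GGC<->CA": _assemble(ggc_ca),
        "GGC<->CA_UG": _assemble(ggc_ca_ug),
        "(CA)4<->": _assemble(swap(wt, 0, 9)),
    }
    return {name: Fixture101(name, seq) for name, seq in fixtures.items()}


def write_fixture_fasta(path: str | Path) -> None:
    safe = {"(CA)4<->": "CA4_relocated"}
    with open(path, "w") as fh:
        for name, fx in make_fixture_101mers().items():
            label = safe.get(name, name.replace("<->", "_swap_").replace("->", "_to_"))
            fh.write(f">{label} {name}\n{fx.sequence}\n")


# --------------------------------------------------------------------------
# Synthetic regulome
# --------------------------------------------------------------------------


@dataclass
class RegulomeConfig:
    n_regions: int = 2000
    length_range: tuple[int, int] = (1500, 3000)
    #: planted-array-count distribution; keys are exact counts
    array_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.44, 1: 0.16, 2: 0.08, 3: 0.08, 4: 0.24}
    )
    expression_mu: float = 1.0
    expression_sigma: float = 1.0
    lambda0: float = 2.0  # baseline tags per unit expression
    lambda1: float = 4.0  # extra rate per planted array
    array_tag_bias: float = 0.5  # fraction of tags drawn inside array spans
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.array_count_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("array_count_distribution must sum to 1")
        if self.lambda0 < 0 or self.lambda1 < 0:
            raise ValueError("tag rates must be >= 0")
        if not 0 <= self.array_tag_bias <= 1:
            raise ValueError("array_tag_bias must be in [0, 1]")


@dataclass
class Regulome:
    config: RegulomeConfig
    regions: list[tuple[str, str]]  # (region_id, sequence)
    truth: pd.DataFrame = field(repr=False)
    tags: pd.DataFrame = field(repr=False)  # chrom, start, end
    expression: pd.Series = field(repr=False)


# minimum background separating two planted templates so that anchors of
# neighboring arrays sit > 200 nt apart (cross-template anchor gap =
# separation + 29 nt of template flanks)
_TEMPLATE_SEP = 180
_EDGE_MARGIN = 10


def _scrub_ggc(codes: np.ndarray, protected: np.ndarray, rng: np.random.Generator) -> None:
    """Mutate background bases (to U) until no GGC-core occurrence touches
    an unprotected position; planted cores inside templates stay intact."""
    n = len(codes)
    while True:
        ids = np.zeros(n - 3, dtype=np.int32)
        for j in range(4):
            ids = ids * 4 + codes[j : n - 3 + j].astype(np.int32)
        occ = np.where((ids == _GGCA) | (ids == _CGGC))[0]
        dirty = [p for p in occ if not protected[p : p + 4].all()]
        if not dirty:
            return
        for p in dirty:
            for q in range(p, p + 4):
                if not protected[q]:
                    codes[q] = 3  # U
                    break


def generate_regulome(config: RegulomeConfig) -> Regulome:
    """Generate regions, planted-array truth, expression, and CLIP tags."""
    rng = np.random.default_rng(config.seed)
    template = encode(make_fixture_101mers()["WT"].sequence)
    tlen = len(template)
    ks = sorted(config.array_count_distribution)
    probs = [config.array_count_distribution[k] for k in ks]
    lo, hi = config.length_range
    regions: list[tuple[str, str]] = []
    truth_rows = []
    tag_rows = []
    expr = {}
    lut = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    for i in range(config.n_regions):
        rid = f"region_{i:05d}"
        k = int(rng.choice(ks, p=probs))
        length = int(rng.integers(lo, hi + 1))
        required = k * tlen + max(k - 1, 0) * _TEMPLATE_SEP + 2 * _EDGE_MARGIN
        if length < required:
            logger.info("region %s extended from %d to %d nt for %d arrays", rid, length, required, k)
            length = required
        codes = rng.integers(0, 4, size=length, dtype=np.uint8)
        protected = np.zeros(length, dtype=bool)
        spans = []
        if k > 0:
            free = length - required
            extra = rng.multinomial(free, [1.0 / (k + 1)] * (k + 1))
            pos = _EDGE_MARGIN + int(extra[0])
            for j in range(k):
                codes[pos : pos + tlen] = template
                protected[pos : pos + tlen] = True
                spans.append((pos, pos + tlen))
                pos += tlen + _TEMPLATE_SEP + int(extra[j + 1])
        _scrub_ggc(codes, protected, rng)
        seq = lut[codes].tobytes().decode("ascii")
        regions.append((rid, seq))
        e = float(rng.lognormal(config.expression_mu, config.expression_sigma))
        expr[rid] = e
        rate = e * (config.lambda0 + config.lambda1 * k)
        n_tags = int(rng.poisson(rate))
        for _ in range(n_tags):
            if spans and rng.random() < config.array_tag_bias:
                s, t = spans[int(rng.integers(0, len(spans)))]
                p = int(rng.integers(s, t))
            else:
                p = int(rng.integers(0, length))
            tag_rows.append({"chrom": rid, "start": p, "end": p + 1})
        truth_rows.append(
            {"region_id": rid, "length": length, "n_arrays": k, "expression": e, "tag_count": n_tags}
        )
    truth = pd.DataFrame(truth_rows)
    tags = pd.DataFrame(tag_rows, columns=["chrom", "start", "end"])
    return Regulome(config, regions, truth, tags, pd.Series(expr, name="expression"))


def regions_frame(regulome: Regulome) -> pd.DataFrame:
    """Region table (chrom/start/end/region_id) with each region as its own
    coordinate system, matching the tags BED."""
    return pd.DataFrame(
        {
            "chrom": [rid for rid, _ in regulome.regions],
            "start": 0,
            "end": [len(seq) for _, seq in regulome.regions],
            "region_id": [rid for rid, _ in regulome.regions],
        }
    )


def write_regulome(regulome: Regulome, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "regions.fa", "w") as fh:
        for rid, seq in regulome.regions:
            fh.write(f">{rid}\n{seq}\n")
    regions_frame(regulome)[["chrom", "start", "end", "region_id"]].to_csv(
        out / "regions.bed", sep="\t", header=False, index=False
    )
    regulome.tags.to_csv(out / "tags.bed", sep="\t", header=False, index=False)
    regulome.expression.to_csv(out / "expression.tsv", sep="\t", header=False)
    regulome.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
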