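"""Base-composition statistics for miRNA and small-RNA sequence sets.

Covers single-sequence GC content, per-segment GC along annotated
precursors, position-specific nucleotide and dinucleotide frequency
matrices (optionally abundance-weighted), a dinucleotide-preserving
shuffle null, random subsampling controls, and distribution comparison
via the Mann-Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mirsig.seqio import PrecursorRecord

log = logging.getLogger(__name__)

ALPHABET = "ACGU"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)

# lookup table: ASCII byte -> alphabet index (255 = invalid)
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _i in _INDEX.items():
    _LUT[ord(_c)] = _i


def gc_content(sequence: str) -> float:
    """GC fraction: (#G + #C) divided by sequence length."""
    if not sequence:
        raise ValueError("gc_content of an empty sequence is undefined")
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


# --------------------------------------------------------------------------
# Precursor segment analysis

SEGMENTS = ("arm5", "mature5p", "loop", "mature3p", "arm3")


@dataclass
class SegmentGc:
    """GC fraction and length of each precursor segment.

    Zero-length segments report a GC of ``None`` (undefined) rather than
    zero, so that segment means are not dragged toward zero by degenerate
    geometry. Lengths always sum to the precursor length.
    """

    gc: dict[str, Optional[float]]
    lengths: dict[str, int]


def gc_by_segment(precursor: PrecursorRecord) -> SegmentGc:
    """Per-segment GC along a precursor with both mature arms annotated.

    Segments (1-based, inclusive): arm5 = [1, 5p.start-1], the 5p mature,
    loop = [5p.end+1, 3p.start-1], the 3p mature, arm3 = [3p.end+1, L].
    """
    if precursor.mature5p_span is None or precursor.mature3p_span is None:
        raise ValueError(f"precursor {precursor.id!r} must have both mature "
                         "spans annotated")
    s5, e5 = precursor.mature5p_span
    s3, e3 = precursor.mature3p_span
    L = precursor.length
    spans = {
        "arm5": (1, s5 - 1),
        "mature5p": (s5, e5),
        "loop": (e5 + 1, s3 - 1),
        "mature3p": (s3, e3),
        "arm3": (e3 + 1, L),
    }
    gc: dict[str, Optional[float]] = {}
    lengths: dict[str, int] = {}
    for name, (start, end) in spans.items():
        length = max(0, end - start + 1)
        lengths[name] = length
        if length == 0:
            gc[name] = None
            log.debug("segment %s of %r is empty; GC undefined",
                      name, precursor.id)
        else:
            gc[name] = gc_content(precursor.sequence[start - 1:end])
    assert sum(lengths.values()) == L
    return SegmentGc(gc=gc, lengths=lengths)


# --------------------------------------------------------------------------
# Position frequency matrices

@dataclass
class PositionFrequencyMatrix:
    """Per-position nucleotide probabilities for a fixed-length set.

    ``freq`` has shape (L, 4) with columns ordered A, C, G, U; each row
    sums to 1. ``weighting`` records whether sequences counted once each
    ("unique") or proportionally to read counts ("abundance").
    """

    L: int
    freq: np.ndarray
    n_sequences: int
    weighting: str = "unique"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (self.L, 4):
            raise ValueError(f"freq must have shape ({self.L}, 4)")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's probabilities must sum to 1")
        if (self.freq < 0).any() or (self.freq > 1).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(ALPHABET))
        df.insert(0, "position", np.arange(1, self.L + 1))
        df["GC"] = df["G"] + df["C"]
        return df


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 index matrix."""
    if not seqs:
        raise ValueError("empty sequence set")
    L = len(seqs[0])
    bad = [s for s in seqs if len(s) != L]
    if bad:
        raise ValueError(f"sequences of mixed length (expected {L}): "
                         f"{bad[:5]}{'...' if len(bad) > 5 else ''}")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    idx = _LUT[arr].reshape(len(seqs), L)
    if (idx == 255).any():
        raise ValueError("sequences contain characters outside A/C/G/U")
    return idx


def position_frequency_matrix(seqs: Sequence[str],
                              weighting: str = "unique",
                              counts: Optional[Sequence[float]] = None,
                              ) -> PositionFrequencyMatrix:
    """Relative nucleotide frequency at each position of a uniform-length set.

    In "abundance" mode each sequence is weighted by its read count, which
    reproduces statistics over redundant (uncollapsed) reads; counts must
    then be supplied, one per sequence.
    """
    if weighting not in ("unique", "abundance"):
        raise ValueError("weighting must be 'unique' or 'abundance'")
    if (counts is not None) != (weighting == "abundance"):
        raise ValueError("counts must be supplied iff weighting='abundance'")
    idx = encode_sequences(list(seqs))
    n, L = idx.shape
    if weighting == "abundance":
        w = np.asarray(counts, dtype=float)
        if w.shape != (n,):
            raise ValueError("one count per sequence required")
    else:
        w = np.ones(n)
    total = w.sum()
    freq = np.zeros((L, 4))
    for base in range(4):
        freq[:, base] = ((idx == base) * w[:, None]).sum(axis=0) / total
    return PositionFrequencyMatrix(L=L, freq=freq, n_sequences=n,
                                   weighting=weighting)


@dataclass
class GcRatioTrack:
    """Per-position fraction of sequences carrying G or C."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def au(self) -> np.ndarray:
        return 1.0 - self.values


def gc_ratio_track(pfm: PositionFrequencyMatrix) -> GcRatioTrack:
    """GC ratio at each position: freq(G) + freq(C)."""
    return GcRatioTrack(values=pfm.freq[:, _INDEX["G"]] + pfm.freq[:, _INDEX["C"]])


@dataclass
class DinucleotideFrequency:
    """Per-position dinucleotide frequencies plus pooled summaries."""

    L: int
    freq: np.ndarray  # shape (L-1, 16), rows sum to 1
    pooled: dict[str, float]
    n_sequences: int

    @property
    def pooled_au(self) -> float:
        """Pooled frequency of the AU dinucleotide."""
        return self.pooled["AU"]

    @property
    def pooled_gc(self) -> float:
        """Pooled frequency of the GC dinucleotide."""
        return self.pooled["GC"]


def dinucleotide_position_frequency(seqs: Sequence[str]) -> DinucleotideFrequency:
    """Frequency of each of the 16 dinucleotides at positions 1..L-1."""
    idx = encode_sequences(list(seqs))
    n, L = idx.shape
    if L < 2:
        raise ValueError("sequences must be at least 2 nt for dinucleotides")
    di = idx[:, :-1] * 4 + idx[:, 1:]  # (n, L-1), values 0..15
    freq = np.zeros((L - 1, 16))
    for k in range(16):
        freq[:, k] = (di == k).sum(axis=0) / n
    pooled_counts = np.bincount(di.ravel(), minlength=16).astype(float)
    pooled_counts /= pooled_counts.sum()
    pooled = {DINUCLEOTIDES[k]: pooled_counts[k] for k in range(16)}
    return DinucleotideFrequency(L=L, freq=freq, pooled=pooled, n_sequences=n)


# --------------------------------------------------------------------------
# Shuffle and sampling nulls

def dinucleotide_shuffle(sequence: str,
                         seed: Optional[int] = None,
                         rng: Optional[np.random.Generator] = None) -> str:
    """Shuffle a sequence while preserving its dinucleotide multiset.

    Uses the Euler-path construction (Altschul-Erickson): the sequence is a
    walk on the dinucleotide transition multigraph, and a random Eulerian
    path with the same start and end vertex is drawn. Mononucleotide
    counts and the first and last base are preserved by construction, so
    terminal positions are *not* randomized — positional nulls built from
    this shuffle apply to interior positions.
    """
    if len(sequence) < 2:
        raise ValueError("dinucleotide shuffle requires length >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    if len(set(sequence)) == 1:
        return sequence

    # adjacency: vertex (base) -> list of successor bases (edge multiset)
    edges: dict[str, list[str]] = {}
    for a, b in zip(sequence, sequence[1:]):
        edges.setdefault(a, []).append(b)
    start, end = sequence[0], sequence[-1]
    vertices = list(edges)

    # Pick a random "last edge" out of every vertex except the sink so the
    # last edges form an arborescence into the sink; retry until connected.
    while True:
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == end:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in vertices:
            if v == end:
                continue
            # follow last edges; must reach the sink without cycling
            seen = {v}
            cur = v
            while cur != end:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    # order each vertex's edges: random permutation of the rest, then the
    # reserved last edge
    ordered: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v != end:
            pool.remove(last_edge[v])
        perm = [pool[i] for i in rng.permutation(len(pool))]
        if v != end:
            perm.append(last_edge[v])
        ordered[v] = perm

    # walk the Eulerian path
    pos = {v: 0 for v in vertices}
    out = [start]
    cur = start
    for _ in range(len(sequence) - 1):
        nxt = ordered[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def random_sample_control(seqs: Sequence[str], k: int,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None) -> list[str]:
    """Reproducible uniform subsample of ``k`` sequences without replacement."""
    n = len(seqs)
    if k > n:
        raise ValueError(f"cannot sample {k} from {n} sequences")
    if rng is None:
        rng = np.random.default_rng(seed)
    chosen = rng.choice(n, size=k, replace=False)
    return [seqs[i] for i in sorted(chosen)]


def compare_distributions(sample_a: Sequence[float],
                          sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two GC-fraction samples.

    Delegates to :func:`scipy.stats.mannwhitneyu` (tie-corrected normal
    approximation for large samples). Returns ``(U, p)`` where U is the
    statistic for ``sample_a``.
    """
    if len(sample_a) < 2 or len(sample_b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    res = stats.mannwhitneyu(sample_a, sample_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
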