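"""GC structure around miRNA target sites on mRNAs.

Plant miRNAs pair near-perfectly with a 21-nt window of their target
mRNA, so a positional signature on the miRNA implies a complementary
signature on the target site. This module computes sliding-window GC
profiles, a position-specific GC background from random cDNA windows,
background-normalized per-position GC ratios over annotated sites, the
antiparallel miRNA-to-target coordinate map, and a naive complementarity
site finder for pipelines lacking an external target predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from mirsig.seqio import SeqRecord

log = logging.getLogger(__name__)

SITE_LENGTH = 21

#: Watson-Crick pair score 1.0; G:U wobble scores ``wobble`` (default 0.5),
#: the common weighting in plant target-prediction practice.
_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclass
class TargetSite:
    """A 21-nt miRNA binding site on an mRNA (1-based inclusive span)."""

    mrna_id: str
    span: tuple[int, int]
    mirna_id: str = ""

    def __post_init__(self) -> None:
        start, end = self.span
        if end - start + 1 != SITE_LENGTH:
            raise ValueError(f"target site must span {SITE_LENGTH} nt, "
                             f"got {self.span}")
        if start < 1:
            raise ValueError(f"span start must be >= 1, got {start}")


@dataclass
class GcProfile:
    """Sliding-window GC values along a sequence."""

    values: np.ndarray
    window: int = SITE_LENGTH
    step: int = 1
    anchor: int = 1  # 1-based start coordinate of the first window


@dataclass
class BackgroundGc:
    """Per-position GC fraction of random 21-nt windows drawn from cDNAs."""

    values: np.ndarray  # length 21
    n_windows: int
    seed: Optional[int] = None


def _gc_indicator(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return ((arr == ord("G")) | (arr == ord("C"))).astype(float)


def sliding_window_gc(sequence: str, window: int = SITE_LENGTH,
                      step: int = 1) -> GcProfile:
    """GC fraction in every ``window``-nt window advancing by ``step``."""
    if len(sequence) < window:
        raise ValueError(f"sequence shorter ({len(sequence)}) than the "
                         f"window ({window})")
    ind = _gc_indicator(sequence)
    cum = np.concatenate([[0.0], np.cumsum(ind)])
    starts = np.arange(0, len(sequence) - window + 1, step)
    values = (cum[starts + window] - cum[starts]) / window
    return GcProfile(values=values, window=window, step=step, anchor=1)


def background_position_gc(cdnas: Sequence[SeqRecord | str],
                           n_windows: int = 10_000,
                           seed: Optional[int] = None,
                           rng: Optional[np.random.Generator] = None,
                           ) -> BackgroundGc:
    """Per-position GC of random 21-nt windows from a cDNA pool.

    Windows are drawn uniformly over all eligible (sequence, start) pairs,
    i.e. longer cDNAs contribute proportionally more windows. cDNAs
    shorter than 21 nt are skipped; an empty eligible pool is an error.
    """
    seqs = [c.sequence if isinstance(c, SeqRecord) else c for c in cdnas]
    eligible = [(s, len(s) - SITE_LENGTH + 1) for s in seqs
                if len(s) >= SITE_LENGTH]
    if not eligible:
        raise ValueError("no cDNA of at least 21 nt to sample windows from")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.array([n for _, n in eligible])
    cum = np.cumsum(counts)
    draws = rng.integers(0, cum[-1], size=n_windows)
    gc_counts = np.zeros(SITE_LENGTH)
    for d in draws:
        seq_idx = int(np.searchsorted(cum, d, side="right"))
        start = int(d - (cum[seq_idx - 1] if seq_idx else 0))
        window = eligible[seq_idx][0][start:start + SITE_LENGTH]
        gc_counts += _gc_indicator(window)
    return BackgroundGc(values=gc_counts / n_windows, n_windows=n_windows,
                        seed=seed)


@dataclass
class NormalizedSiteGc:
    """Background-normalized per-position GC ratios around target sites."""

    site_ratio: np.ndarray       # length 21
    upstream_ratio: Optional[np.ndarray]
    downstream_ratio: Optional[np.ndarray]
    n_sites: int
    n_upstream: int
    n_downstream: int


def normalized_site_gc(sites: Sequence[TargetSite],
                       mrnas: Mapping[str, str] | Sequence[SeqRecord],
                       background: BackgroundGc) -> NormalizedSiteGc:
    """Per-position GC of target sites divided by the cDNA background.

    ``ratio[i]`` is the fraction of sites carrying G/C at site position i
    (5'->3' on the mRNA) divided by ``background.values[i]``. The same
    ratio is computed for the adjacent upstream and downstream 21-nt
    windows; a site too close to an mRNA end simply drops out of that
    window's denominator (logged).
    """
    if not sites:
        raise ValueError("no target sites supplied")
    if (background.values <= 0).any():
        raise ValueError("background GC must be positive at every position")
    if not isinstance(mrnas, Mapping):
        mrnas = {r.id: r.sequence for r in mrnas}

    def accumulate(spans: Iterable[tuple[str, int, int]]) -> tuple[np.ndarray, int]:
        total = np.zeros(SITE_LENGTH)
        n = 0
        for mrna_id, start, end in spans:
            seq = mrnas[mrna_id]
            if start < 1 or end > len(seq):
                log.info("window (%d, %d) outside %r; skipped", start, end, mrna_id)
                continue
            total += _gc_indicator(seq[start - 1:end])
            n += 1
        return total, n

    site_total, n_sites = accumulate(
        (s.mrna_id, s.span[0], s.span[1]) for s in sites)
    if n_sites == 0:
        raise ValueError("no target site lies within its mRNA bounds")
    up_total, n_up = accumulate(
        (s.mrna_id, s.span[0] - SITE_LENGTH, s.span[0] - 1) for s in sites)
    down_total, n_down = accumulate(
        (s.mrna_id, s.span[1] + 1, s.span[1] + SITE_LENGTH) for s in sites)

    site_ratio = (site_total / n_sites) / background.values
    upstream = (up_total / n_up) / background.values if n_up else None
    downstream = (down_total / n_down) / background.values if n_down else None
    return NormalizedSiteGc(site_ratio=site_ratio, upstream_ratio=upstream,
                            downstream_ratio=downstream, n_sites=n_sites,
                            n_upstream=n_up, n_downstream=n_down)


def mirna_target_position_map(i: int) -> int:
    """Target-site position paired with miRNA position ``i``.

    Two antiparallel 21-mers pair position i (miRNA, 5'->3') with
    position 22 - i of the site read 5'->3' on the mRNA; e.g. miRNA
    position 12 pairs with target position 10. The map is an involution.
    """
    if not 1 <= i <= SITE_LENGTH:
        raise ValueError(f"position must be in [1, {SITE_LENGTH}], got {i}")
    return SITE_LENGTH + 1 - i


@dataclass
class SiteHit:
    site: TargetSite
    score: float


def pair_score(mirna_base: str, target_base: str, wobble: float = 0.5) -> float:
    pair = (mirna_base, target_base)
    if pair in _WC_PAIRS:
        return 1.0
    if pair in _WOBBLE_PAIRS:
        return wobble
    return 0.0


def find_site_naive(mirna: str, mrna: SeqRecord | str,
                    mirna_id: str = "", wobble: float = 0.5,
                    ) -> Optional[SiteHit]:
    """Best 21-nt complementarity window of an mRNA for a miRNA.

    Scores each window by antiparallel base pairing (Watson-Crick 1.0,
    G:U wobble ``wobble``), ties broken toward the smallest start. This
    is deliberately simple plumbing — no free-energy model, bulges or
    expectation scoring as in dedicated target predictors.
    """
    if isinstance(mrna, SeqRecord):
        mrna_id_, seq = mrna.id, mrna.sequence
    else:
        mrna_id_, seq = "mrna", mrna
    if len(seq) < SITE_LENGTH:
        raise ValueError("mRNA shorter than 21 nt")
    if len(mirna) != SITE_LENGTH:
        raise ValueError("miRNA must be 21 nt for the naive finder")

    m = np.frombuffer(mirna.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n_windows = len(seq) - SITE_LENGTH + 1
    scores = np.zeros(n_windows)
    # miRNA position i (1-based) pairs with window offset 21 - i
    score_lut = np.zeros((256, 256))
    for (a, b) in _WC_PAIRS:
        score_lut[ord(a), ord(b)] = 1.0
    for (a, b) in _WOBBLE_PAIRS:
        score_lut[ord(a), ord(b)] = wobble
    for i in range(SITE_LENGTH):
        offset = SITE_LENGTH - 1 - i
        scores += score_lut[m[i], t[offset:offset + n_windows]]
    best = int(np.argmax(scores))  # argmax returns the first maximum
    site = TargetSite(mrna_id=mrna_id_, span=(best + 1, best + SITE_LENGTH),
                      mirna_id=mirna_id)
    return SiteHit(site=site, score=float(scores[best]))
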