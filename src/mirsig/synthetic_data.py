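"""Synthetic inputs with the statistical structure the analyses assume.

Generates every artifact the pipeline consumes at desk scale: 21-nt
miRNA populations drawn from positional probabilities, hairpin
precursors with AU-rich arms and a GC-rich miRNA/miRNA* duplex, dicing
read pools with canonical/isomiR/sib-miR structure, mRNAs with planted
reverse-complement target sites, and a "paperlike" four-stem construct
whose mature inserts span 28%, 52% (with signature), 52% (scrambled
signature) and 71% GC.

Default parameters are the study conditions the analyses were built
around: arm/loop GC of 0.30 (plant precursor arms are AU-rich), duplex
GC near 0.52, dicing fidelity 0.8, mRNA background GC 0.42
(Arabidopsis cDNA-like), 500-nt mRNAs. Sampling is position-independent
within a sequence; dinucleotide structure is exercised only through the
shuffle control, which is what the analyses measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from mirsig.amir_design import design_star
from mirsig.composition import ALPHABET, PositionFrequencyMatrix
from mirsig.seqio import PrecursorRecord, ReadRecord, SeqRecord, reverse_complement
from mirsig.signature import SignatureModel, default_signature_model
from mirsig.target_analysis import SITE_LENGTH, TargetSite

_BASES = np.array(list(ALPHABET))
_GC_SET = ("G", "C")
_AU_SET = ("A", "U")

#: base that neither Watson-Crick pairs nor wobbles with the key base
_NON_PAIRING = {"A": "C", "C": "A", "G": "A", "U": "C"}

DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {20: 0.15, 21: 0.50, 22: 0.20, 24: 0.15}


@dataclass
class GeneratorConfig:
    """Bundled generator defaults (the study conditions)."""

    seed: int = 0
    n_mirnas: int = 1000
    n_reads: int = 10_000
    arm_gc: float = 0.30
    loop_gc: float = 0.30
    arm_length: int = 30
    loop_length: int = 40
    duplex_gc: float = 0.52
    dicing_fidelity: float = 0.80
    background_gc: float = 0.42
    mrna_length: int = 500
    site_position: int = 240
    signature_frac: float = 0.70
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))

    def __post_init__(self) -> None:
        for name in ("arm_gc", "loop_gc", "duplex_gc", "dicing_fidelity",
                     "background_gc", "signature_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("arm_length", "loop_length", "mrna_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _rng(seed: Optional[int], rng: Optional[np.random.Generator]
         ) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(seed)


def random_sequence(length: int, gc: float,
                    rng: np.random.Generator) -> str:
    """i.i.d. sequence with expected GC fraction ``gc`` (A/U and G/C split
    evenly within their groups)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A, C, G, U
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


# --------------------------------------------------------------------------
# miRNA populations

def signature_pfm(model: Optional[SignatureModel] = None,
                  core_strength: float = 0.90,
                  loose_strength: float = 0.70,
                  background_gc: float = 0.50) -> PositionFrequencyMatrix:
    """A positional probability matrix realizing a signature model.

    Core positions favour their preferred base class with probability
    ``core_strength``, loose positions with ``loose_strength``; positions
    outside the model split according to ``background_gc``. Probability
    within a base class is split evenly (G vs C, A vs U).
    """
    if model is None:
        model = default_signature_model()
    freq = np.zeros((model.length, 4))
    for pos in range(1, model.length + 1):
        if pos in model.core_gc_positions:
            gc = core_strength
        elif pos in model.core_au_positions:
            gc = 1 - core_strength
        elif pos in model.loose_gc_positions:
            gc = loose_strength
        elif pos in model.loose_au_positions:
            gc = 1 - loose_strength
        else:
            gc = background_gc
        freq[pos - 1] = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return PositionFrequencyMatrix(L=model.length, freq=freq,
                                   n_sequences=0, weighting="unique")


def gen_mirnas(pfm: PositionFrequencyMatrix | np.ndarray, n: int,
               seed: Optional[int] = None,
               rng: Optional[np.random.Generator] = None) -> list[str]:
    """Sample ``n`` sequences with positions drawn independently from a PFM."""
    rng = _rng(seed, rng)
    freq = pfm.freq if isinstance(pfm, PositionFrequencyMatrix) else np.asarray(pfm)
    L = freq.shape[0]
    idx = np.empty((n, L), dtype=np.int64)
    for i in range(L):
        idx[:, i] = rng.choice(4, size=n, p=freq[i])
    return ["".join(row) for row in _BASES[idx]]


# --------------------------------------------------------------------------
# Precursors and dicing reads

def gen_precursor(mature: str,
                  arm_length: int = 30, loop_length: int = 40,
                  arm_gc: float = 0.30, loop_gc: float = 0.30,
                  seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None,
                  precursor_id: str = "synthetic-precursor",
                  ) -> PrecursorRecord:
    """A hairpin-layout precursor: arm5 + mature + loop + star + arm3.

    The star strand follows canonical duplex geometry (19-bp pairing,
    2-nt 3' overhang); spans of both arms are recorded exactly.
    """
    rng = _rng(seed, rng)
    star = design_star(mature).star
    arm5 = random_sequence(arm_length, arm_gc, rng)
    loop = random_sequence(loop_length, loop_gc, rng)
    arm3 = random_sequence(arm_length, arm_gc, rng)
    seq = arm5 + mature + loop + star + arm3
    s5 = arm_length + 1
    s3 = arm_length + len(mature) + loop_length + 1
    return PrecursorRecord(id=precursor_id, sequence=seq,
                           mature5p_span=(s5, s5 + len(mature) - 1),
                           mature3p_span=(s3, s3 + len(star) - 1))


def gen_dicing_reads(precursor: PrecursorRecord,
                     fidelity: float = 0.80, n: int = 10_000,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     length_weights: Optional[Mapping[int, float]] = None,
                     boundary_frac: float = 0.7,
                     library_total: Optional[int] = None,
                     ) -> list[ReadRecord]:
    """A collapsed read pool emulating dicing of one precursor.

    Each of ``n`` molecules is, with probability ``fidelity``, the exact
    mature or star sequence (equal odds); otherwise an imprecise product:
    with probability ``boundary_frac`` an isomiR starting within +/-3 nt
    of a mature-arm 5' boundary, else a sib-miR at a uniform random
    start. Variant lengths are drawn from ``length_weights`` (default
    20/21/22/24 nt at 0.15/0.50/0.20/0.15). Reads are collapsed to
    unique sequences with counts and RPM (against ``library_total``,
    default ``n``).
    """
    if precursor.mature5p_span is None or precursor.mature3p_span is None:
        raise ValueError("precursor must have both mature spans")
    rng = _rng(seed, rng)
    weights = dict(length_weights or DEFAULT_LENGTH_WEIGHTS)
    lengths = np.array(sorted(weights))
    probs = np.array([weights[k] for k in lengths], dtype=float)
    probs /= probs.sum()
    L = precursor.length
    mature = precursor.subsequence(precursor.mature5p_span)
    star = precursor.subsequence(precursor.mature3p_span)
    boundaries = [precursor.mature5p_span[0], precursor.mature3p_span[0]]

    counts: dict[str, int] = {}
    u = rng.random(n)
    for i in range(n):
        if u[i] < fidelity:
            seq = mature if rng.random() < 0.5 else star
        else:
            length = int(lengths[rng.choice(len(lengths), p=probs)])
            if rng.random() < boundary_frac:
                start = boundaries[rng.integers(2)] + int(rng.integers(-3, 4))
            else:
                start = int(rng.integers(1, L - length + 2))
            start = min(max(1, start), L - length + 1)
            seq = precursor.sequence[start - 1:start - 1 + length]
        counts[seq] = counts.get(seq, 0) + 1
    total = library_total if library_total is not None else n
    reads = [ReadRecord(sequence=s, count=c, rpm=c / total * 1e6)
             for s, c in counts.items()]
    reads.sort(key=lambda r: (-r.count, r.sequence))
    return reads


# --------------------------------------------------------------------------
# Target mRNAs

def gen_target_mrna(mirna: str,
                    mrna_length: int = 500, background_gc: float = 0.42,
                    site_position: int = 240,
                    mismatch_positions: Sequence[int] = (),
                    seed: Optional[int] = None,
                    rng: Optional[np.random.Generator] = None,
                    mrna_id: str = "synthetic-mrna",
                    mirna_id: str = "mirna",
                    ) -> tuple[SeqRecord, TargetSite]:
    """An i.i.d. background mRNA with a planted reverse-complement site.

    ``mismatch_positions`` are 1-based site coordinates whose base is
    replaced by one that neither Watson-Crick pairs nor G:U wobbles with
    the corresponding miRNA base, so the naive finder's score drops by
    exactly one per mismatch.
    """
    if len(mirna) != SITE_LENGTH:
        raise ValueError(f"miRNA must be {SITE_LENGTH} nt")
    if not (1 <= site_position and site_position + SITE_LENGTH - 1 <= mrna_length):
        raise ValueError(f"site at {site_position} does not fit in a "
                         f"{mrna_length}-nt mRNA")
    rng = _rng(seed, rng)
    seq = list(random_sequence(mrna_length, background_gc, rng))
    site = list(reverse_complement(mirna))
    for j in mismatch_positions:
        if not 1 <= j <= SITE_LENGTH:
            raise ValueError(f"mismatch position {j} outside [1, {SITE_LENGTH}]")
        mirna_base = mirna[SITE_LENGTH - j]  # miRNA position 22 - j
        site[j - 1] = _NON_PAIRING[mirna_base]
    seq[site_position - 1:site_position - 1 + SITE_LENGTH] = site
    record = SeqRecord(id=mrna_id, sequence="".join(seq))
    target = TargetSite(mrna_id=mrna_id,
                        span=(site_position, site_position + SITE_LENGTH - 1),
                        mirna_id=mirna_id)
    return record, target


def gen_random_cdnas(n: int, length: int = 500, gc: float = 0.42,
                     seed: Optional[int] = None,
                     rng: Optional[np.random.Generator] = None,
                     ) -> list[SeqRecord]:
    """A pool of i.i.d. cDNA-like sequences for background sampling."""
    rng = _rng(seed, rng)
    return [SeqRecord(id=f"cdna{i + 1}", sequence=random_sequence(length, gc, rng))
            for i in range(n)]


# --------------------------------------------------------------------------
# Signature-bearing read mixtures

def gen_signature_read(model: SignatureModel, rng: np.random.Generator) -> str:
    """A 21-mer satisfying every core position and the 40-60% GC band."""
    seq = [""] * model.length
    free = [p for p in range(1, model.length + 1)
            if p not in model.core_gc_positions
            and p not in model.core_au_positions]
    for p in model.core_gc_positions:
        seq[p - 1] = _GC_SET[rng.integers(2)]
    for p in model.core_au_positions:
        seq[p - 1] = _AU_SET[rng.integers(2)]
    # total GC of 9..12 out of 21 stays inside the band
    k_gc = int(rng.integers(5, 9))
    gc_slots = set(rng.choice(len(free), size=k_gc, replace=False))
    for slot, p in enumerate(free):
        pool = _GC_SET if slot in gc_slots else _AU_SET
        seq[p - 1] = pool[rng.integers(2)]
    return "".join(seq)


def gen_read_pool(model: Optional[SignatureModel] = None,
                  signature_frac: float = 0.70, n: int = 10_000,
                  seed: Optional[int] = None,
                  rng: Optional[np.random.Generator] = None,
                  ) -> list[ReadRecord]:
    """A 21-nt read pool with a planted fraction of band-and-signature reads.

    Non-signature reads are generated like signature reads and then have
    one random core position flipped to a violating base, so the planted
    mixture weight is recovered exactly by the band-and-signature
    fraction (up to collapse of duplicate sequences).
    """
    if model is None:
        model = default_signature_model()
    rng = _rng(seed, rng)
    core = sorted(model.core_gc_positions | model.core_au_positions)
    counts: dict[str, int] = {}
    u = rng.random(n)
    for i in range(n):
        seq = gen_signature_read(model, rng)
        if u[i] >= signature_frac:
            p = core[rng.integers(len(core))]
            pool = _AU_SET if p in model.core_gc_positions else _GC_SET
            seq = seq[:p - 1] + pool[rng.integers(2)] + seq[p:]
        counts[seq] = counts.get(seq, 0) + 1
    reads = [ReadRecord(sequence=s, count=c, rpm=c / n * 1e6)
             for s, c in counts.items()]
    reads.sort(key=lambda r: (-r.count, r.sequence))
    return reads


# --------------------------------------------------------------------------
# The four-stem "paperlike" construct

@dataclass
class PaperlikeConstruct:
    """An artificial precursor with four tandem stem-loops.

    All four stems share an identical backbone layout and differ only in
    their miRNA/miRNA* inserts: 28% GC, 52% GC with the core signature,
    52% GC with a scrambled (core-violating) signature, and 71% GC.
    """

    construct: SeqRecord
    stems: dict[str, PrecursorRecord]
    matures: dict[str, str]
    mature_spans: dict[str, tuple[int, int]]  # global coordinates


STEM_ORDER = ("gc28", "gc52_sig", "gc52_scr", "gc71")


def _mature_with_gc(n_gc: int, rng: np.random.Generator,
                    exclude_gc_position: Optional[int] = None) -> str:
    positions = [p for p in range(1, 22) if p != exclude_gc_position]
    gc_pos = set(int(positions[i])
                 for i in rng.choice(len(positions), size=n_gc, replace=False))
    return "".join((_GC_SET if p in gc_pos else _AU_SET)[rng.integers(2)]
                   for p in range(1, 22))


def _scrambled_mature(model: SignatureModel, rng: np.random.Generator) -> str:
    """Same GC count as a signature-bearing 52% insert, core fully violated."""
    seq = [""] * 21
    for p in model.core_gc_positions:
        seq[p - 1] = _AU_SET[rng.integers(2)]
    for p in model.core_au_positions:
        seq[p - 1] = _GC_SET[rng.integers(2)]
    free = [p for p in range(1, 22)
            if p not in model.core_gc_positions
            and p not in model.core_au_positions]
    gc_slots = set(rng.choice(len(free), size=7, replace=False))
    for slot, p in enumerate(free):
        pool = _GC_SET if slot in gc_slots else _AU_SET
        seq[p - 1] = pool[rng.integers(2)]
    return "".join(seq)


def _signature_mature(model: SignatureModel, rng: np.random.Generator) -> str:
    """Core-satisfying insert with 11/21 GC (52%)."""
    while True:
        seq = gen_signature_read(model, rng)
        if seq.count("G") + seq.count("C") == 11:
            return seq


def build_paperlike_construct(seed: Optional[int] = None,
                              config: Optional[GeneratorConfig] = None,
                              rng: Optional[np.random.Generator] = None,
                              ) -> PaperlikeConstruct:
    """Build the four-stem construct with 28/52+sig/52-scr/71% GC inserts."""
    cfg = config or GeneratorConfig(seed=seed if seed is not None else 0)
    rng = _rng(seed if seed is not None else cfg.seed, rng)
    model = default_signature_model()
    matures = {
        "gc28": _mature_with_gc(6, rng, exclude_gc_position=8),
        "gc52_sig": _signature_mature(model, rng),
        "gc52_scr": _scrambled_mature(model, rng),
        "gc71": _mature_with_gc(15, rng),
    }
    stems: dict[str, PrecursorRecord] = {}
    mature_spans: dict[str, tuple[int, int]] = {}
    parts: list[str] = []
    offset = 0
    for name in STEM_ORDER:
        stem = gen_precursor(matures[name], arm_length=cfg.arm_length,
                             loop_length=cfg.loop_length, arm_gc=cfg.arm_gc,
                             loop_gc=cfg.loop_gc, rng=rng,
                             precursor_id=f"stem-{name}")
        stems[name] = stem
        s5, e5 = stem.mature5p_span
        mature_spans[name] = (offset + s5, offset + e5)
        parts.append(stem.sequence)
        offset += stem.length
    construct = SeqRecord(id="four-stem-construct", sequence="".join(parts))
    return PaperlikeConstruct(construct=construct, stems=stems,
                              matures=matures, mature_spans=mature_spans)


#: Per-stem share of molecules and dicing fidelity used when simulating
#: reads from the four-stem construct: the signature-bearing 52% stem is
#: processed preferentially and precisely, the scrambled stem less so,
#: the 28% and 71% stems poorly.
PAPERLIKE_STEM_SHARE = {"gc28": 0.075, "gc52_sig": 0.70,
                       "gc52_scr": 0.15, "gc71": 0.075}
PAPERLIKE_STEM_FIDELITY = {"gc28": 0.40, "gc52_sig": 0.80,
                           "gc52_scr": 0.50, "gc71": 0.40}


def gen_paperlike_reads(construct: PaperlikeConstruct, n: int = 10_000,
                        seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None,
                        ) -> list[ReadRecord]:
    """Dicing reads over the four-stem construct with stem-biased processing."""
    rng = _rng(seed, rng)
    merged: dict[str, int] = {}
    for name in STEM_ORDER:
        n_stem = int(round(n * PAPERLIKE_STEM_SHARE[name]))
        reads = gen_dicing_reads(construct.stems[name],
                                 fidelity=PAPERLIKE_STEM_FIDELITY[name],
                                 n=n_stem, rng=rng, library_total=n)
        for r in reads:
            merged[r.sequence] = merged.get(r.sequence, 0) + r.count
    total = sum(merged.values())
    out = [ReadRecord(sequence=s, count=c, rpm=c / total * 1e6)
           for s, c in merged.items()]
    out.sort(key=lambda r: (-r.count, r.sequence))
    return out
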