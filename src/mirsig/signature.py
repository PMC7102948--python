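"""The positional GC signature model for 21-nt plant miRNAs.

The model encodes the processing-linked positional preferences of mature
plant miRNAs: G/C strongly preferred at positions 8-9 and 18-19, A/U at
positions 5, 7, 10 and 15 (the core), with weaker G/C preference at 2-4,
6 and 21 and weaker A/U preference at 17 and 20, inside an overall GC
band of 40-60%. Positions are 1-based from the 5' end of the mature
strand. Sequences of other lengths are outside the signature's domain
and are rejected rather than truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from mirsig.composition import gc_content
from mirsig.seqio import ReadRecord

log = logging.getLogger(__name__)

#: Mature osa-miR528-5p (miRBase release 21), a monocot miRNA with 62% GC
#: whose positions 7 and 10 carry G/C in violation of the core A/U
#: preference.
OSA_MIR528_5P = "UGGAAGGGGCAUGCAGAGGAG"

#: miR528-m1: positions 7 and 10 substituted to A and U, bringing GC down
#: to 52% and completing the core signature.
OSA_MIR528_5P_M1 = OSA_MIR528_5P[:6] + "A" + OSA_MIR528_5P[7:9] + "U" + OSA_MIR528_5P[10:]

GC_BASES = frozenset("GC")
AU_BASES = frozenset("AU")


@dataclass(frozen=True)
class SignatureModel:
    """Positional G/C-A/U preference sets with weights and a GC band.

    ``core_policy`` controls the boolean signature call: "strict" demands
    every core position match; "at-least-k" demands ``min_core_matches``
    of them.
    """

    core_gc_positions: frozenset[int] = frozenset({8, 9, 18, 19})
    core_au_positions: frozenset[int] = frozenset({5, 7, 10, 15})
    loose_gc_positions: frozenset[int] = frozenset({2, 3, 4, 6, 21})
    loose_au_positions: frozenset[int] = frozenset({17, 20})
    loose_weight: float = 0.5
    gc_band: tuple[float, float] = (0.40, 0.60)
    length: int = 21
    core_policy: str = "strict"
    min_core_matches: int = 8

    def __post_init__(self) -> None:
        sets = [self.core_gc_positions, self.core_au_positions,
                self.loose_gc_positions, self.loose_au_positions]
        all_positions: list[int] = []
        for s in sets:
            all_positions.extend(s)
        if len(all_positions) != len(set(all_positions)):
            raise ValueError("signature position sets must be disjoint")
        if any(p < 1 or p > self.length for p in all_positions):
            raise ValueError(f"positions must lie in [1, {self.length}]")
        if not (0 < self.loose_weight <= 1):
            raise ValueError("loose_weight must be in (0, 1]")
        if not (0 <= self.gc_band[0] <= self.gc_band[1] <= 1):
            raise ValueError("gc_band must be an interval within [0, 1]")
        if self.core_policy not in ("strict", "at-least-k"):
            raise ValueError("core_policy must be 'strict' or 'at-least-k'")

    @property
    def n_core(self) -> int:
        return len(self.core_gc_positions) + len(self.core_au_positions)

    @property
    def gc_positions(self) -> frozenset[int]:
        return self.core_gc_positions | self.loose_gc_positions

    @property
    def au_positions(self) -> frozenset[int]:
        return self.core_au_positions | self.loose_au_positions


def default_signature_model() -> SignatureModel:
    """The default signature: core G/C {8,9,18,19}, core A/U {5,7,10,15},
    loose G/C {2,3,4,6,21}, loose A/U {17,20}, GC band [0.40, 0.60]."""
    return SignatureModel()


@dataclass
class SignatureReport:
    """Outcome of scoring one 21-nt sequence against a signature model."""

    sequence: str
    matches: dict[int, bool]
    core_matches: int
    loose_matches: int
    score: float
    has_signature: bool
    gc: float
    in_band: bool


def evaluate_signature(sequence: str,
                       model: Optional[SignatureModel] = None) -> SignatureReport:
    """Score a sequence against the positional signature.

    A position matches when it carries G/C and sits in a G/C-preference
    set, or carries A/U and sits in an A/U-preference set. The score is
    core matches (weight 1) plus loose matches times ``loose_weight``.
    Sequences whose length differs from the model's are rejected.
    """
    if model is None:
        model = default_signature_model()
    if len(sequence) != model.length:
        raise ValueError(f"signature is defined for {model.length}-nt "
                         f"sequences; got {len(sequence)} nt")
    matches: dict[int, bool] = {}
    core = 0
    loose = 0
    for pos in sorted(model.gc_positions | model.au_positions):
        base = sequence[pos - 1]
        if pos in model.core_gc_positions:
            ok = base in GC_BASES
            core += ok
        elif pos in model.core_au_positions:
            ok = base in AU_BASES
            core += ok
        elif pos in model.loose_gc_positions:
            ok = base in GC_BASES
            loose += ok
        else:
            ok = base in AU_BASES
            loose += ok
        matches[pos] = bool(ok)
    score = core * 1.0 + loose * model.loose_weight
    if model.core_policy == "strict":
        has_signature = core == model.n_core
    else:
        has_signature = core >= model.min_core_matches
    gc = gc_content(sequence)
    in_band = model.gc_band[0] <= gc <= model.gc_band[1]
    return SignatureReport(sequence=sequence, matches=matches,
                           core_matches=core, loose_matches=loose,
                           score=score, has_signature=has_signature,
                           gc=gc, in_band=in_band)


@dataclass
class SignatureFraction:
    """Fraction of 21-nt reads that pass both the GC band and the signature."""

    unique_fraction: Optional[float]
    weighted_fraction: Optional[float]
    n_unique: int
    total_count: float


def signature_fraction(reads: Iterable[ReadRecord],
                       model: Optional[SignatureModel] = None,
                       ) -> SignatureFraction:
    """Fraction of 21-nt reads that are in the GC band AND carry the signature.

    Returns both the unique-sequence fraction and the abundance-weighted
    (per-read-count) fraction, with their denominators. When no read has
    the signature length both fractions are None (undefined) and a
    warning is logged.
    """
    if model is None:
        model = default_signature_model()
    n_unique = 0
    n_pass = 0
    total = 0.0
    total_pass = 0.0
    for read in reads:
        if read.length != model.length:
            continue
        rep = evaluate_signature(read.sequence, model)
        hit = rep.in_band and rep.has_signature
        n_unique += 1
        total += read.count
        if hit:
            n_pass += 1
            total_pass += read.count
    if n_unique == 0:
        log.warning("no %d-nt reads; signature fraction undefined", model.length)
        return SignatureFraction(None, None, 0, 0.0)
    return SignatureFraction(unique_fraction=n_pass / n_unique,
                             weighted_fraction=total_pass / total,
                             n_unique=n_unique, total_count=total)


# --------------------------------------------------------------------------
# Serialization

def model_to_yaml(model: SignatureModel, path: str | Path) -> None:
    data = {
        "core_gc_positions": sorted(model.core_gc_positions),
        "core_au_positions": sorted(model.core_au_positions),
        "loose_gc_positions": sorted(model.loose_gc_positions),
        "loose_au_positions": sorted(model.loose_au_positions),
        "loose_weight": model.loose_weight,
        "gc_band": list(model.gc_band),
        "length": model.length,
        "core_policy": model.core_policy,
        "min_core_matches": model.min_core_matches,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=False)


def model_from_yaml(path: str | Path) -> SignatureModel:
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return SignatureModel(
        core_gc_positions=frozenset(data["core_gc_positions"]),
        core_au_positions=frozenset(data["core_au_positions"]),
        loose_gc_positions=frozenset(data["loose_gc_positions"]),
        loose_au_positions=frozenset(data["loose_au_positions"]),
        loose_weight=float(data.get("loose_weight", 0.5)),
        gc_band=tuple(data.get("gc_band", (0.40, 0.60))),
        length=int(data.get("length", 21)),
        core_policy=data.get("core_policy", "strict"),
        min_core_matches=int(data.get("min_core_matches", 8)),
    )
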