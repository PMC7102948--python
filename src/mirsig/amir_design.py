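"""Signature-aware artificial-miRNA (amiR) design and ranking.

amiRs are designed 21-mers embedded in a natural precursor backbone in
place of the endogenous miRNA/miRNA* pair. Dicing releases a 19-bp
duplex with 2-nt 3' overhangs, so the star strand's first 19 nt are the
reverse complement of the guide's first 19 nt and guide position i pairs
with star position 20 - i. Candidates are ranked by GC band membership,
signature score, distance from 50% GC, and 5'-U (AGO1 loading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from mirsig.composition import gc_content
from mirsig.seqio import PrecursorRecord, reverse_complement
from mirsig.signature import (SignatureModel, SignatureReport,
                              default_signature_model, evaluate_signature)

log = logging.getLogger(__name__)

GUIDE_LENGTH = 21
PAIRED_LENGTH = 19
OVERHANG_LENGTH = 2


@dataclass
class DuplexDesign:
    """A guide/star duplex with canonical dicing geometry."""

    guide: str
    star: str
    paired_length: int = PAIRED_LENGTH
    overhang_length: int = OVERHANG_LENGTH

    def pairing_map(self) -> dict[int, int]:
        """Guide position -> star position (both 1-based) over the duplex."""
        return {i: PAIRED_LENGTH + 1 - i for i in range(1, PAIRED_LENGTH + 1)}


def design_star(guide: str, overhang: str = "UU") -> DuplexDesign:
    """Design the star strand for a 21-nt guide.

    Star positions 1..19 are the reverse complement of guide positions
    1..19; star positions 20-21 are the 2-nt 3' overhang, ``UU`` by
    default. (Real backbones derive the unpaired bases from precursor
    context and may carry deliberate mismatches; those can be injected
    afterwards at user-chosen positions.)
    """
    if len(guide) != GUIDE_LENGTH:
        raise ValueError(f"guide must be {GUIDE_LENGTH} nt, got {len(guide)}")
    if len(overhang) != OVERHANG_LENGTH:
        raise ValueError(f"overhang must be {OVERHANG_LENGTH} nt")
    star = reverse_complement(guide[:PAIRED_LENGTH]) + overhang
    return DuplexDesign(guide=guide, star=star)


def inject_mismatches(design: DuplexDesign, star_positions: Sequence[int],
                      replacement: str = "A") -> DuplexDesign:
    """Replace star bases at the given 1-based positions (mismatch design)."""
    star = list(design.star)
    for pos in star_positions:
        if not 1 <= pos <= len(star):
            raise ValueError(f"star position {pos} out of range")
        star[pos - 1] = replacement
    return replace(design, star="".join(star))


def embed_in_backbone(backbone: PrecursorRecord, guide: str, star: str,
                      guide_arm: str = "5p") -> PrecursorRecord:
    """Swap a backbone precursor's miRNA/miRNA* for a designed guide/star.

    The guide replaces the mature span of ``guide_arm`` and the star the
    other span; lengths must match exactly (no indel surgery), so every
    base outside the two spans is preserved byte-for-byte.
    """
    if backbone.mature5p_span is None or backbone.mature3p_span is None:
        raise ValueError("backbone must have both mature spans annotated")
    if guide_arm not in ("5p", "3p"):
        raise ValueError("guide_arm must be '5p' or '3p'")
    five, three = (guide, star) if guide_arm == "5p" else (star, guide)
    s5, e5 = backbone.mature5p_span
    s3, e3 = backbone.mature3p_span
    if len(five) != e5 - s5 + 1:
        raise ValueError(f"5p insert length {len(five)} != span length {e5 - s5 + 1}")
    if len(three) != e3 - s3 + 1:
        raise ValueError(f"3p insert length {len(three)} != span length {e3 - s3 + 1}")
    seq = backbone.sequence
    new_seq = seq[:s5 - 1] + five + seq[e5:s3 - 1] + three + seq[e3:]
    return PrecursorRecord(id=f"{backbone.id}-amir", sequence=new_seq,
                           species=backbone.species,
                           mature5p_span=backbone.mature5p_span,
                           mature3p_span=backbone.mature3p_span,
                           family=backbone.family)


@dataclass
class AmirCandidate:
    """A 21-nt amiR candidate with its composition and signature scores."""

    name: str
    sequence: str
    gc: float
    report: SignatureReport
    five_prime_u: bool
    rank: Optional[int] = None


def rank_amirs(candidates: Iterable[tuple[str, str] | AmirCandidate],
               model: Optional[SignatureModel] = None,
               ) -> list[AmirCandidate]:
    """Rank amiR candidates by composition and signature.

    Ordering keys, in descending priority: (1) inside the 40-60% GC band;
    (2) signature score, higher first; (3) |GC - 0.5|, smaller first;
    (4) 5'-U before non-U (AGO1 association); (5) lexicographic sequence
    for determinism. This ordering is this package's synthesis of the
    qualitative processing hierarchy (band and core signature dominate);
    supply a custom model to change the scored positions.
    """
    if model is None:
        model = default_signature_model()
    built: list[AmirCandidate] = []
    for cand in candidates:
        if isinstance(cand, AmirCandidate):
            name, seq = cand.name, cand.sequence
        else:
            name, seq = cand
        report = evaluate_signature(seq, model)
        built.append(AmirCandidate(name=name, sequence=seq, gc=report.gc,
                                   report=report,
                                   five_prime_u=seq.startswith("U")))
    built.sort(key=lambda c: (not c.report.in_band, -c.report.score,
                              abs(c.gc - 0.5), not c.five_prime_u,
                              c.sequence))
    for i, cand in enumerate(built, start=1):
        cand.rank = i
    return built


def anthocyanin_content(abs530: float, abs657: float,
                        fresh_weight_g: float) -> float:
    """Relative anthocyanin per gram fresh weight from a methanol extract.

    Computed as (A530 - 0.25 x A657) x 5 / fresh weight, the standard
    chlorophyll-corrected absorbance readout. Negative corrected values
    are returned as-is with a warning (they indicate a blank/chlorophyll
    problem, not a computation error).
    """
    if abs530 < 0 or abs657 < 0:
        raise ValueError("absorbances must be non-negative")
    if fresh_weight_g <= 0:
        raise ValueError("fresh weight must be positive")
    value = (abs530 - 0.25 * abs657) * 5 / fresh_weight_g
    if value < 0:
        log.warning("negative corrected anthocyanin value %.4f", value)
    return value
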