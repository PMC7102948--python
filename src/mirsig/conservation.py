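"""Conserved vs less-conserved miRNA family classification.

A family counts as conserved when it is annotated in at least one dicot
species and at least one monocot species; families restricted to a single
clade (or a single species) are less-conserved. Species from other lineages
(mosses, lycophytes, algae, gymnosperms) contribute to neither clade and so
cannot confer conserved status on their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mirsig.seqio import MirnaRecord

log = logging.getLogger(__name__)

CLADES = ("dicot", "monocot", "other")

#: Clade assignments for common miRBase plant species codes. Users working
#: with additional species supply their own map (``load_clade_map``).
DEFAULT_CLADE_MAP: dict[str, str] = {
    # dicots
    "ath": "dicot", "aly": "dicot", "gma": "dicot", "mtr": "dicot",
    "vvi": "dicot", "stu": "dicot", "sly": "dicot", "ptc": "dicot",
    "csi": "dicot", "bna": "dicot", "bra": "dicot", "ghr": "dicot",
    "gra": "dicot", "cme": "dicot", "ccl": "dicot", "mdm": "dicot",
    "ppe": "dicot", "fve": "dicot", "cpa": "dicot", "rco": "dicot",
    "lja": "dicot", "nta": "dicot", "han": "dicot", "aqc": "dicot",
    # monocots
    "osa": "monocot", "zma": "monocot", "sbi": "monocot", "tae": "monocot",
    "hvu": "monocot", "bdi": "monocot", "ssp": "monocot", "sof": "monocot",
    "ata": "monocot", "aet": "monocot", "mac": "monocot", "egu": "monocot",
    "far": "monocot", "osj": "monocot",
    # neither clade under the classification rule
    "ppt": "other", "smo": "other", "cre": "other", "pab": "other",
    "pta": "other", "mpo": "other",
}


class UnknownSpeciesError(KeyError):
    """A species code in the data has no clade assignment."""


@dataclass
class FamilyStatus:
    """Clade co-occurrence summary for one miRNA family."""

    family: str
    status: str  # "conserved" | "less_conserved"
    n_dicot_species: int
    n_monocot_species: int


def load_clade_map(path: str | Path) -> dict[str, str]:
    """Load a two-column ``species_code<TAB>clade`` table."""
    clades: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'species<TAB>clade'")
            code, clade = parts
            if clade not in CLADES:
                raise ValueError(f"line {lineno}: clade must be one of {CLADES}, "
                                 f"got {clade!r}")
            clades[code] = clade
    return clades


def classify_families(records: Iterable[MirnaRecord],
                      clades: Mapping[str, str] | None = None,
                      ) -> dict[str, FamilyStatus]:
    """Classify each miRNA family as conserved or less-conserved.

    A species is counted once per family regardless of how many paralogues
    or arms it contributes. Records with an empty family are excluded and
    logged; species codes missing from the clade map raise
    :class:`UnknownSpeciesError` listing all offenders.
    """
    if clades is None:
        clades = DEFAULT_CLADE_MAP
    records = list(records)
    skipped = sum(1 for r in records if not r.family)
    if skipped:
        log.warning("%d records without a parsed family were excluded from "
                    "conservation classification", skipped)
    unresolved = sorted({r.species for r in records
                         if r.family and r.species not in clades})
    if unresolved:
        raise UnknownSpeciesError(
            f"species codes without a clade assignment: {unresolved}")

    species_by_family: dict[str, set[str]] = {}
    for rec in records:
        if rec.family:
            species_by_family.setdefault(rec.family, set()).add(rec.species)

    out: dict[str, FamilyStatus] = {}
    for family, species in sorted(species_by_family.items()):
        n_dicot = sum(1 for s in species if clades[s] == "dicot")
        n_monocot = sum(1 for s in species if clades[s] == "monocot")
        status = "conserved" if (n_dicot >= 1 and n_monocot >= 1) else "less_conserved"
        out[family] = FamilyStatus(family=family, status=status,
                                   n_dicot_species=n_dicot,
                                   n_monocot_species=n_monocot)
    return out


def partition_records(records: Iterable[MirnaRecord],
                      statuses: Mapping[str, FamilyStatus],
                      ) -> tuple[list[MirnaRecord], list[MirnaRecord]]:
    """Split records into (conserved, less_conserved) by family status.

    Records with an empty or unclassified family are omitted from both
    sets, so the two lists form a disjoint partition of classifiable
    records.
    """
    conserved: list[MirnaRecord] = []
    less: list[MirnaRecord] = []
    for rec in records:
        if not rec.family or rec.family not in statuses:
            continue
        if statuses[rec.family].status == "conserved":
            conserved.append(rec)
        else:
            less.append(rec)
    return conserved, less
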