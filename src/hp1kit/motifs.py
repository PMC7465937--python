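"""Degenerate-pentapeptide motif scanning.

HP1 chromoshadow-domain (CSD) dimers bind short linear motifs of the form
P-x-V-x-L, where "x" is any amino acid and the V/L anchors are conserved.
Degenerate variants substitute the first anchor: L-x-V-x-L and C-x-V-x-L.
This module locates every such pentapeptide in protein sequences, records
the +1/-1 flanking residues (candidate affinity modifiers), and summarizes
cohorts as "percent of proteins carrying at least one motif".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

#: the 20 standard amino-acid one-letter codes
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity codes tolerated in input sequences but never matched by wildcards
AMBIGUITY_AA = "XBZU"

#: motif class name -> position-1 anchor residue; positions 3 and 5 are the
#: conserved V and L anchors in every class, positions 2 and 4 are wildcards.
MOTIF_CLASSES: Dict[str, str] = {"PxVxL": "P", "LxVxL": "L", "CxVxL": "C"}

_STANDARD_SET = frozenset(STANDARD_AA)


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with an identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if self.sequence != self.sequence.upper():
            raise ValueError(f"sequence of {self.id!r} must be upper-case")
        allowed = _STANDARD_SET | set(AMBIGUITY_AA)
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in allowed:
                raise ValueError(
                    f"protein {self.id!r}: invalid residue {aa!r} at position {pos}"
                )


@dataclass(frozen=True)
class MotifHit:
    """A located pentapeptide: class, 1-based start, sequence and flanks.

    ``flank_minus1`` / ``flank_plus1`` are the residues immediately before /
    after the pentapeptide, or ``"-"`` at a sequence edge.
    """

    protein_id: str
    motif_class: str
    start: int
    pentapeptide: str
    flank_minus1: str
    flank_plus1: str


@dataclass(frozen=True)
class MotifSummary:
    """Cohort-level summary: how many proteins carry at least one motif."""

    cohort_label: str
    n_total: int
    n_with_motif: int
    percent: int
    per_class_counts: Dict[str, int]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (9/13 -> 69%)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def window_matches(window: str, motif_class: str) -> bool:
    """Test one 5-residue window against one motif class.

    Anchor positions (1, 3, 5) match only the literal residue; wildcard
    positions (2, 4) match any of the 20 standard residues but not the
    ambiguity codes X/B/Z/U.
    """
    anchor1 = MOTIF_CLASSES[motif_class]
    return (
        len(window) == 5
        and window[0] == anchor1
        and window[2] == "V"
        and window[4] == "L"
        and window[1] in _STANDARD_SET
        and window[3] in _STANDARD_SET
    )


def scan_protein(
    record: ProteinRecord, classes: Iterable[str] = tuple(MOTIF_CLASSES)
) -> List[MotifHit]:
    """Scan every length-5 window of one protein against the requested classes.

    All matches are reported, including overlapping windows and multiple
    motifs per protein; hits are sorted by start position then class name.
    Sequences shorter than 5 residues yield an empty list.
    """
    class_list = sorted(set(classes))
    if not class_list:
        raise ValueError("at least one motif class is required")
    for name in class_list:
        if name not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {name!r}")
    seq = record.sequence
    hits: List[MotifHit] = []
    for i in range(len(seq) - 4):
        window = seq[i : i + 5]
        for name in class_list:
            if window_matches(window, name):
                hits.append(
                    MotifHit(
                        protein_id=record.id,
                        motif_class=name,
                        start=i + 1,
                        pentapeptide=window,
                        flank_minus1=seq[i - 1] if i > 0 else "-",
                        flank_plus1=seq[i + 5] if i + 5 < len(seq) else "-",
                    )
                )
    return hits


def scan_proteome(
    records: Sequence[ProteinRecord],
    classes: Iterable[str] = tuple(MOTIF_CLASSES),
) -> Tuple[List[MotifHit], List[str]]:
    """Scan a proteome; returns (hits in stable input order, no-hit protein ids).

    Protein identifiers must be unique.
    """
    seen: Set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate protein identifier {rec.id!r}")
        seen.add(rec.id)
    hits: List[MotifHit] = []
    no_hit: List[str] = []
    for rec in records:
        rec_hits = scan_protein(rec, classes)
        hits.extend(rec_hits)
        if not rec_hits:
            no_hit.append(rec.id)
    return hits, no_hit


def summarize_cohort(
    hits: Iterable[MotifHit], cohort_ids: Sequence[str], label: str
) -> MotifSummary:
    """Summarize a cohort: a protein counts once however many hits it has.

    ``percent`` is rounded to the nearest integer, ties away from zero —
    the convention under which 9 of 13 prints as 69% and 30 of 86 as 35%.
    """
    if not cohort_ids:
        raise ValueError("cohort is empty")
    cohort = set(cohort_ids)
    if len(cohort) != len(cohort_ids):
        raise ValueError("cohort contains duplicate protein ids")
    with_motif: Set[str] = set()
    per_class: Dict[str, Set[str]] = {}
    for hit in hits:
        if hit.protein_id in cohort:
            with_motif.add(hit.protein_id)
            per_class.setdefault(hit.motif_class, set()).add(hit.protein_id)
    n_total = len(cohort)
    n_with = len(with_motif)
    return MotifSummary(
        cohort_label=label,
        n_total=n_total,
        n_with_motif=n_with,
        percent=_round_half_away(100.0 * n_with / n_total),
        per_class_counts={k: len(v) for k, v in sorted(per_class.items())},
    )
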