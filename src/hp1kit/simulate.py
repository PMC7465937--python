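"""Seeded generators for synthetic inputs with exact planted truth.

Three generators emulate the statistical structure of the pipeline's real
inputs so every stage is testable without downloads:

* :func:`generate_proteome` — random proteins with planted CSD-binding
  pentapeptides; rejection resampling removes incidental matches so the
  planted set is the exact ground truth.
* :func:`generate_peak_pair` — a query/reference ChIP-seq peak pair with an
  exactly controlled overlap fraction (or fully independent placement for
  null calibration).
* :func:`generate_landscape` — a chromosome peak landscape with a
  high-median heterochromatin block abutting a low-median euchromatic
  region at a known border, emitted as narrowPeak-style peaks.

Every generator draws from a single explicit ``numpy`` RNG stream per call
and is bit-reproducible under a fixed seed.  Each returns a
:class:`TruthRecord` that, together with pipeline determinism, suffices to
predict the expected pipeline output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .intervals import Genome, GenomicInterval, PeakSet
from .motifs import (
    MOTIF_CLASSES,
    STANDARD_AA,
    ProteinRecord,
    scan_protein,
)

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth serialized next to each generated dataset."""

    kind: str  # {"motif", "overlap_pair", "landscape"}
    params: Dict[str, Any]
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "params": self.params, "seed": self.seed},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(kind=d["kind"], params=d["params"], seed=d["seed"])


# ---------------------------------------------------------------------------
# proteomes with planted motifs


def _plant_window(motif_class: str, rng: np.random.Generator) -> str:
    anchor1 = MOTIF_CLASSES[motif_class]
    w2, w4 = rng.choice(list(STANDARD_AA), size=2)
    return f"{anchor1}{w2}V{w4}L"


def generate_proteome(
    n_proteins: int = 20,
    length_mean: float = 500.0,
    planted: Sequence[Tuple[int, int, str]] = (),
    seed: int = 0,
) -> Tuple[List[ProteinRecord], TruthRecord]:
    """Random proteome with planted motifs and no incidental matches.

    ``planted`` lists (protein_index, start, motif_class) with 0-based
    protein index and 1-based residue start, pairwise non-overlapping
    within a protein.  Background residues are uniform over the 20 standard
    amino acids; any 5-residue window that incidentally matches a motif
    class (including windows straddling planted flanks) is resampled, so
    scanning the output finds exactly the planted hits.  Protein lengths
    are Poisson around ``length_mean`` and extended where needed to fit a
    planted motif.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    by_protein: Dict[int, List[Tuple[int, str]]] = {}
    for idx, start, cls in planted:
        if not 0 <= idx < n_proteins:
            raise ValueError(f"planted protein index {idx} out of range")
        if start < 1:
            raise ValueError(f"planted start {start} must be >= 1 (1-based)")
        if cls not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {cls!r}")
        for other, _ in by_protein.get(idx, []):
            if abs(other - start) < 5:
                raise ValueError(
                    f"planted motifs overlap in protein {idx} "
                    f"(starts {other} and {start})"
                )
        by_protein.setdefault(idx, []).append((start, cls))

    alphabet = np.array(list(STANDARD_AA))
    records: List[ProteinRecord] = []
    for i in range(n_proteins):
        length = max(int(rng.poisson(length_mean)), 20)
        plants = sorted(by_protein.get(i, []))
        if plants:
            length = max(length, plants[-1][0] + 4)
        seq = list(rng.choice(alphabet, size=length))
        anchored = [False] * length  # anchor positions of planted motifs
        planted_keys = set()
        for start, cls in plants:
            i0 = start - 1
            window = _plant_window(cls, rng)
            for k, aa in enumerate(window):
                seq[i0 + k] = aa
            for k in (0, 2, 4):
                anchored[i0 + k] = True
            planted_keys.add((start, cls))

        # rejection resampling: redraw free residues of incidental matches
        for _ in range(_MAX_REJECTION_ROUNDS):
            rec = ProteinRecord(id=f"prot_{i}", sequence="".join(seq))
            incidental = [
                h
                for h in scan_protein(rec)
                if (h.start, h.motif_class) not in planted_keys
            ]
            if not incidental:
                break
            for h in incidental:
                free = [
                    p for p in range(h.start - 1, h.start + 4) if not anchored[p]
                ]
                if not free:
                    raise ValueError(
                        f"protein {i}: incidental motif at {h.start} cannot be "
                        "removed without disturbing planted anchors"
                    )
                for p in free:
                    seq[p] = str(rng.choice(alphabet))
        else:
            raise RuntimeError("rejection resampling did not converge")
        records.append(ProteinRecord(id=f"prot_{i}", sequence="".join(seq)))

    truth = TruthRecord(
        kind="motif",
        params={
            "n_proteins": n_proteins,
            "length_mean": length_mean,
            "planted": [
                [idx, start, cls] for idx, start, cls in planted
            ],
        },
        seed=seed,
    )
    return records, truth


# ---------------------------------------------------------------------------
# peak pairs with controlled overlap


def _draw_length(rng: np.random.Generator, length_mean: float) -> int:
    return max(int(rng.poisson(length_mean)), 1)


def _uniform_interval(
    rng: np.random.Generator, genome: Genome, length_mean: float
) -> GenomicInterval:
    chroms = list(genome.chrom_sizes)
    weights = np.array([genome.length(c) for c in chroms], dtype=float)
    chrom = chroms[int(rng.choice(len(chroms), p=weights / weights.sum()))]
    clen = genome.length(chrom)
    length = min(_draw_length(rng, length_mean), clen)
    start = int(rng.integers(0, clen - length + 1))
    return GenomicInterval(chrom, start, start + length)


def generate_peak_pair(
    genome: Genome,
    n_query: int = 200,
    n_ref: int = 200,
    overlap_frac: Optional[float] = 0.4,
    length_mean: float = 300.0,
    seed: int = 0,
) -> Tuple[PeakSet, PeakSet, TruthRecord]:
    """Query/reference peak pair with an exactly controlled overlap count.

    Reference peaks are placed uniformly (chromosomes weighted by length).
    ``round(overlap_frac * n_query)`` query peaks are forced to intersect a
    uniformly chosen reference peak by >= 1 bp; the remainder are placed by
    rejection until they intersect no reference peak, so the overlap count
    is exact by construction.  With ``overlap_frac=None`` the query peaks
    are placed uniformly and independently of the reference — the null
    configuration used for permutation-test calibration.
    """
    if n_query < 1 or n_ref < 1:
        raise ValueError("n_query and n_ref must be >= 1")
    if overlap_frac is not None and not 0.0 <= overlap_frac <= 1.0:
        raise ValueError("overlap_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    refs = [_uniform_interval(rng, genome, length_mean) for _ in range(n_ref)]

    queries: List[GenomicInterval] = []
    if overlap_frac is None:
        queries = [_uniform_interval(rng, genome, length_mean) for _ in range(n_query)]
        n_forced = None
    else:
        n_forced = round(overlap_frac * n_query)
        for _ in range(n_forced):
            for _attempt in range(_MAX_REJECTION_ROUNDS):
                r = refs[int(rng.integers(0, len(refs)))]
                clen = genome.length(r.chrom)
                length = min(_draw_length(rng, length_mean), clen)
                lo = max(r.start - length + 1, 0)
                hi = min(r.end - 1, clen - length)
                if lo > hi:
                    continue
                start = int(rng.integers(lo, hi + 1))
                queries.append(
                    GenomicInterval(r.chrom, start, start + length)
                )
                break
            else:
                raise RuntimeError("could not place a forced-overlap query peak")
        for _ in range(n_query - n_forced):
            for _attempt in range(_MAX_REJECTION_ROUNDS):
                cand = _uniform_interval(rng, genome, length_mean)
                if not any(cand.overlaps(r) for r in refs):
                    queries.append(cand)
                    break
            else:
                raise RuntimeError(
                    "could not place a non-overlapping query peak; genome too crowded"
                )

    truth = TruthRecord(
        kind="overlap_pair",
        params={
            "n_query": n_query,
            "n_ref": n_ref,
            "overlap_frac": overlap_frac,
            "n_overlapping": n_forced,
            "length_mean": length_mean,
            "chrom_sizes": dict(genome.chrom_sizes),
        },
        seed=seed,
    )
    return PeakSet(queries, genome), PeakSet(refs, genome), truth


# ---------------------------------------------------------------------------
# border landscapes


def generate_landscape(
    chrom_length: int = 25_000_000,
    border_pos: int = 7_000_000,
    high_mean: float = 3.0,
    low_mean: float = 0.4,
    sd: float = 0.3,
    peaks_per_bin_mean: float = 20.0,
    bin_size: int = 500_000,
    seed: int = 0,
    chrom: str = "chr2R",
    peak_halfwidth: int = 100,
    height_floor: float = 0.05,
) -> Tuple[PeakSet, TruthRecord]:
    """Step-shaped peak landscape with a known heterochromatin border.

    Summits are placed uniformly within each ``bin_size`` bin with a
    Poisson count per bin; heights are normal with mean ``high_mean``
    before ``border_pos`` and ``low_mean`` after, truncated at a small
    positive floor.  Peaks are emitted with explicit summits so the border
    caller sees a narrowPeak-like input.
    """
    if chrom_length <= 0 or bin_size <= 0:
        raise ValueError("chrom_length and bin_size must be positive")
    if border_pos % bin_size != 0:
        raise ValueError("border_pos must be a multiple of bin_size")
    if not 0 < border_pos < chrom_length:
        raise ValueError("border_pos must fall inside the chromosome")
    if not high_mean > low_mean > 0:
        raise ValueError("need high_mean > low_mean > 0")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if peaks_per_bin_mean <= 0:
        raise ValueError("peaks_per_bin_mean must be positive")
    rng = np.random.default_rng(seed)
    genome = Genome({chrom: chrom_length})

    intervals: List[GenomicInterval] = []
    pos = 0
    while pos < chrom_length:
        hi = min(pos + bin_size, chrom_length)
        n = int(rng.poisson(peaks_per_bin_mean))
        summits = np.sort(rng.integers(pos, hi, size=n))
        mean = high_mean if pos < border_pos else low_mean
        heights = np.maximum(rng.normal(mean, sd, size=n), height_floor)
        for s, h in zip(summits, heights):
            start = max(int(s) - peak_halfwidth, 0)
            end = min(int(s) + peak_halfwidth + 1, chrom_length)
            intervals.append(
                GenomicInterval(chrom, start, end, float(h), int(s))
            )
        pos = hi

    truth = TruthRecord(
        kind="landscape",
        params={
            "chrom": chrom,
            "chrom_length": chrom_length,
            "border_pos": border_pos,
            "high_mean": high_mean,
            "low_mean": low_mean,
            "sd": sd,
            "peaks_per_bin_mean": peaks_per_bin_mean,
            "bin_size": bin_size,
        },
        seed=seed,
    )
    return PeakSet(intervals, genome), truth
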