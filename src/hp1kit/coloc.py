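"""Peak co-localization with a randomization null.

The observed statistic is the number (and percentage) of query peaks that
intersect at least one reference peak by >= 1 bp.  Significance is assessed
by repeatedly re-placing the reference peaks uniformly at random on their
own chromosomes (lengths and chromosome assignment preserved, so
chromosome-level peak density is retained) and recomputing the statistic.
The empirical p-value uses the add-one estimator (1 + b) / (n_perm + 1) and
can therefore never be exactly zero; the z-score is the observed count
standardized by the null mean and sample standard deviation, so enrichment
gives z > 0 and depletion (fewer overlaps than expected by chance) gives
z < 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .intervals import Genome, GenomicInterval, PeakSet

ALTERNATIVES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class OverlapStat:
    """Count and percentage of query peaks touching the reference set."""

    n_query: int
    n_overlapping: int
    pct: float


@dataclass(frozen=True)
class PermutationResult:
    observed: OverlapStat
    null_mean: float
    null_sd: float
    z_score: Optional[float]
    p_empirical: float
    alternative: str
    n_perm: int
    seed: int

    @property
    def z_defined(self) -> bool:
        return self.z_score is not None


def _chrom_arrays(peaks: PeakSet) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    out: Dict[str, list] = {}
    for iv in peaks:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        chrom: (
            np.array([s for s, _ in pairs], dtype=np.int64),
            np.array([e for _, e in pairs], dtype=np.int64),
        )
        for chrom, pairs in out.items()
    }


def _count_overlapping(
    q_starts: np.ndarray,
    q_ends: np.ndarray,
    r_starts: np.ndarray,
    r_ends: np.ndarray,
) -> int:
    """Number of query intervals with >= 1 bp intersection with any reference.

    Reference intervals are sorted by start; a query [qs, qe) hits the set
    iff some reference has start < qe and a running-max end > qs.
    """
    order = np.argsort(r_starts, kind="stable")
    rs = r_starts[order]
    re_max = np.maximum.accumulate(r_ends[order])
    idx = np.searchsorted(rs, q_ends, side="left")  # refs with start < qe
    hit = idx > 0
    hit[hit] = re_max[idx[hit] - 1] > q_starts[hit]
    return int(hit.sum())


def overlap_stat(query: PeakSet, ref: PeakSet) -> OverlapStat:
    """Fraction of query peaks co-localizing (>= 1 bp, half-open) with ref.

    Each query interval counts once however many reference intervals it
    touches.  An empty query set is an error (the percentage is undefined).
    """
    if len(query) == 0:
        raise ValueError("query peak set is empty; percentage undefined")
    if query.genome != ref.genome:
        raise ValueError("query and reference must share a genome")
    q = _chrom_arrays(query)
    r = _chrom_arrays(ref)
    n_over = 0
    for chrom, (qs, qe) in q.items():
        if chrom in r:
            n_over += _count_overlapping(qs, qe, *r[chrom])
    return OverlapStat(
        n_query=len(query),
        n_overlapping=n_over,
        pct=100.0 * n_over / len(query),
    )


def randomize_peaks(peaks: PeakSet, rng) -> PeakSet:
    """Re-place every peak uniformly on its own chromosome.

    Each interval keeps its chromosome and length; the new start is drawn
    uniformly from [0, chrom_len - length].  Heights are carried along and
    the summit keeps its offset from the interval start.  Placements are
    independent, so randomized intervals may overlap each other.

    ``rng`` is a ``numpy.random.Generator`` (or an integer seed).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    new = []
    for iv in peaks:
        clen = peaks.genome.length(iv.chrom)
        if iv.length > clen:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} longer than its chromosome"
            )
        start = int(rng.integers(0, clen - iv.length + 1))
        summit = None if iv.summit is None else start + (iv.summit - iv.start)
        new.append(
            GenomicInterval(iv.chrom, start, start + iv.length, iv.height, summit)
        )
    return PeakSet(new, peaks.genome)


def permutation_test(
    query: PeakSet,
    ref: PeakSet,
    n_perm: int = 1000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> PermutationResult:
    """Randomization test for query/reference peak co-localization.

    The query set is held fixed; the reference set is randomized ``n_perm``
    times by :func:`randomize_peaks` and the null statistic is the overlap
    count recomputed against each randomized reference.  For the two-sided
    alternative, a null draw is at least as extreme as the observation when
    |draw - null_mean| >= |observed - null_mean|.

    When the null distribution is degenerate (sd = 0) the z-score is
    undefined (``None``) but the empirical p is still computed from counts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    observed = overlap_stat(query, ref)

    rng = np.random.default_rng(seed)
    genome = query.genome
    q = _chrom_arrays(query)
    # reference geometry per chromosome: interval lengths only
    r_lengths: Dict[str, np.ndarray] = {}
    for iv in ref:
        r_lengths.setdefault(iv.chrom, []).append(iv.length)
    r_lengths = {c: np.array(v, dtype=np.int64) for c, v in r_lengths.items()}
    for chrom, lens in r_lengths.items():
        if lens.max(initial=0) > genome.length(chrom):
            raise ValueError(f"reference interval longer than chromosome {chrom!r}")

    null = np.empty(n_perm, dtype=np.int64)
    for k in range(n_perm):
        count = 0
        for chrom, lens in r_lengths.items():
            clen = genome.length(chrom)
            starts = rng.integers(0, clen - lens + 1)
            if chrom in q:
                qs, qe = q[chrom]
                count += _count_overlapping(qs, qe, starts, starts + lens)
        null[k] = count

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    obs = observed.n_overlapping
    if alternative == "greater":
        b = int(np.sum(null >= obs))
    elif alternative == "less":
        b = int(np.sum(null <= obs))
    else:
        b = int(np.sum(np.abs(null - null_mean) >= abs(obs - null_mean)))
    p = (1 + b) / (n_perm + 1)
    z = (obs - null_mean) / null_sd if null_sd > 0 else None
    return PermutationResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z_score=z,
        p_empirical=p,
        alternative=alternative,
        n_perm=n_perm,
        seed=seed,
    )
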