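"""Epigenomic border calling from binned peak-summit heights.

Pericentric heterochromatin carries dense, high ChIP-seq peaks for HP1a and
associated marks; euchromatin does not.  The border between the two is
called by (1) taking the genome-wide median of peak summit heights, (2)
binning peak summits every ``bin_size`` bp from an origin (the centromeric
end of a chromosome arm) toward the telomere, (3) walking the bins in scan
order and marking the edge at the first bin whose median summit height
falls strictly below the global median.  Multiple tracks (e.g. HP1a,
Su(var)3-9, H3K9me3) can be combined into a consensus call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .intervals import PeakSet

DEFAULT_BIN_SIZE = 500_000  # 0.5 Mb, the scan resolution along the arm


@dataclass(frozen=True)
class BinProfile:
    """One scan bin: genomic extent, peak count and median summit height.

    ``bin_index`` counts from the origin in scan order.  Empty bins get
    ``median_height`` 0: a stretch without peaks cannot be heterochromatic
    under this statistic.
    """

    bin_index: int
    bin_start: int
    bin_end: int
    n_peaks: int
    median_height: float


@dataclass(frozen=True)
class BinnedProfile:
    """A full scan of one chromosome arm: origin, direction and bins."""

    chrom: str
    origin: int
    direction: str
    bin_size: int
    bins: tuple

    def __iter__(self):
        return iter(self.bins)

    def __len__(self):
        return len(self.bins)


@dataclass(frozen=True)
class BorderCall:
    """A called heterochromatin/euchromatin border on one chromosome arm.

    ``border_pos`` is ``None`` when no bin falls below the global median.
    By default it is the origin-proximal boundary of the first below-median
    bin — the last coordinate known to be heterochromatin-adjacent.
    """

    chrom: str
    border_pos: Optional[int]
    global_median: float
    bin_size: int
    direction: str
    profile: BinnedProfile


@dataclass(frozen=True)
class ConsensusBorder:
    chrom: str
    direction: str
    agreement: bool
    consensus_pos: Optional[float]
    tolerance: int
    border_positions: tuple


def global_median_height(peaks: PeakSet) -> float:
    """Genome-wide median of peak heights (even counts: mean of the two
    central values).  Every peak must carry a height."""
    heights = peaks.heights()
    if not heights:
        raise ValueError("cannot take the median of an empty peak set")
    if any(h is None for h in heights):
        raise ValueError("all peaks must carry a height")
    return float(np.median(heights))


def _summit(iv) -> int:
    # midpoint imputation for formats without an explicit summit
    return iv.summit if iv.summit is not None else iv.midpoint()


def bin_profile(
    peaks: PeakSet,
    chrom: str,
    origin: int,
    direction: str,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinnedProfile:
    """Bin peak summits every ``bin_size`` bp from ``origin`` toward the
    telomere-side chromosome end.

    ``direction`` is "increasing" (scan toward larger coordinates) or
    "decreasing".  Bins are half-open on the scan axis: a summit exactly at
    a bin boundary belongs to the higher-index bin.  Peaks on other
    chromosomes are ignored; peaks without summits use the interval
    midpoint.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    clen = peaks.genome.length(chrom)
    if not 0 <= origin <= clen:
        raise ValueError(f"origin {origin} outside [0, {clen}]")
    extent = clen - origin if direction == "increasing" else origin
    if extent <= 0:
        raise ValueError("scan extent is empty; origin sits at the scanned end")
    n_bins = math.ceil(extent / bin_size)

    heights_per_bin: List[list] = [[] for _ in range(n_bins)]
    for iv in peaks.on_chrom(chrom):
        s = _summit(iv)
        d = s - origin if direction == "increasing" else origin - s
        if 0 <= d < extent:
            heights_per_bin[d // bin_size].append(iv.height)

    bins = []
    for i, hs in enumerate(heights_per_bin):
        if direction == "increasing":
            lo = origin + i * bin_size
            hi = min(origin + (i + 1) * bin_size, clen)
        else:
            lo = max(origin - (i + 1) * bin_size, 0)
            hi = origin - i * bin_size
        if hs and any(h is None for h in hs):
            raise ValueError("all binned peaks must carry a height")
        median = float(np.median(hs)) if hs else 0.0
        bins.append(BinProfile(i, lo, hi, len(hs), median))
    return BinnedProfile(chrom, origin, direction, bin_size, tuple(bins))


def call_border(
    profile: BinnedProfile,
    global_median: float,
    min_run: int = 1,
    report: str = "start",
) -> BorderCall:
    """Mark the border at the first bin whose median decays below the
    global median (strict: a bin exactly at the median does not trigger).

    ``min_run`` requires that many consecutive below-median bins before
    the first of them is declared the border.  ``report`` selects which
    coordinate of the triggering bin is reported: its origin-proximal
    boundary ("start", default), its distal boundary ("end"), or the
    "midpoint".
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if report not in ("start", "end", "midpoint"):
        raise ValueError("report must be 'start', 'end' or 'midpoint'")
    below = [b.median_height < global_median for b in profile.bins]
    border_bin: Optional[BinProfile] = None
    for i in range(len(below) - min_run + 1):
        if all(below[i : i + min_run]):
            border_bin = profile.bins[i]
            break
    pos: Optional[int] = None
    if border_bin is not None:
        proximal, distal = (
            (border_bin.bin_start, border_bin.bin_end)
            if profile.direction == "increasing"
            else (border_bin.bin_end, border_bin.bin_start)
        )
        if report == "start":
            pos = proximal
        elif report == "end":
            pos = distal
        else:
            pos = (border_bin.bin_start + border_bin.bin_end) // 2
    return BorderCall(
        chrom=profile.chrom,
        border_pos=pos,
        global_median=global_median,
        bin_size=profile.bin_size,
        direction=profile.direction,
        profile=profile,
    )


def consensus_border(
    calls: Sequence[BorderCall], tolerance: int
) -> ConsensusBorder:
    """Combine border calls from several tracks scanned the same way.

    Agreement holds when every call has a border and the maximum pairwise
    distance between border positions is <= ``tolerance`` bp; the consensus
    coordinate is the median of the border positions.
    """
    if len(calls) < 2:
        raise ValueError("consensus requires at least two border calls")
    chroms = {c.chrom for c in calls}
    directions = {c.direction for c in calls}
    if len(chroms) != 1 or len(directions) != 1:
        raise ValueError("all calls must share one chromosome and direction")
    positions = tuple(c.border_pos for c in calls)
    if any(p is None for p in positions):
        return ConsensusBorder(
            chrom=calls[0].chrom,
            direction=calls[0].direction,
            agreement=False,
            consensus_pos=None,
            tolerance=tolerance,
            border_positions=positions,
        )
    spread = max(positions) - min(positions)
    return ConsensusBorder(
        chrom=calls[0].chrom,
        direction=calls[0].direction,
        agreement=spread <= tolerance,
        consensus_pos=float(np.median(positions)),
        tolerance=tolerance,
        border_positions=positions,
    )
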