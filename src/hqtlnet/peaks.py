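"""Population consensus peak map from per-individual reproducible peak sets.

A genomic position belongs to a candidate consensus region when it is
covered by peaks from at least ``min_support`` individuals (a per-base
majority rule). Candidate regions separated by fewer than ``merge_gap``
base pairs are then merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import GenomicInterval, GenotypeTable, ValidationError, is_autosome


@dataclass
class ConsensusPeakMap:
    """Sorted, disjoint consensus intervals with per-interval support.

    ``support`` holds, per merged interval, the maximum number of
    contributing individuals over the bases it covers.
    """

    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    support: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        by_chrom: dict[str, int] = {}
        for iv in self.intervals:
            prev = by_chrom.get(iv.chrom)
            if prev is not None and iv.start < prev:
                raise ValidationError("consensus intervals must be sorted and disjoint")
            by_chrom[iv.chrom] = iv.end

    def contains(self, chrom: str, pos: int) -> bool:
        return any(iv.contains(chrom, pos) for iv in self.intervals)


def _coverage_regions(events: list[tuple[int, int]], min_support: int):
    """Maximal runs with coverage >= min_support from (pos, +-1) events.

    Yields (start, end, max_coverage_within_run).
    """
    events.sort()
    cov = 0
    run_start = None
    run_max = 0
    k = 0
    n = len(events)
    while k < n:
        pos = events[k][0]
        while k < n and events[k][0] == pos:
            cov += events[k][1]
            k += 1
        if cov >= min_support and run_start is None:
            run_start = pos
            run_max = cov
        elif run_start is not None:
            if cov >= min_support:
                run_max = max(run_max, cov)
            else:
                yield run_start, pos, run_max
                run_start = None
    # events always end with coverage 0, so no open run remains


def consensus_map(per_individual_peaks: list[list[GenomicInterval]],
                  min_support: int = 13, merge_gap: int = 147,
                  mark: str = "H3K27ac") -> ConsensusPeakMap:
    """Build the consensus peak map.

    Parameters
    ----------
    per_individual_peaks
        One disjoint interval list per individual.
    min_support
        Minimum number of individuals whose peaks must cover a base.
    merge_gap
        Adjacent support-passing regions separated by *fewer than* this many
        bp are merged (a 146 bp gap merges at the default; 147 does not).
    """
    n_ind = len(per_individual_peaks)
    if min_support > n_ind:
        raise ValidationError(
            f"min_support={min_support} exceeds number of individuals ({n_ind})"
        )
    events_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for peaks in per_individual_peaks:
        for iv in peaks:
            ev = events_by_chrom.setdefault(iv.chrom, [])
            ev.append((iv.start, +1))
            ev.append((iv.end, -1))

    intervals: list[GenomicInterval] = []
    support: list[int] = []
    for chrom in sorted(events_by_chrom):
        merged: list[list[int]] = []  # [start, end, max_support]
        for start, end, smax in _coverage_regions(events_by_chrom[chrom], min_support):
            if merged and start - merged[-1][1] < merge_gap:
                merged[-1][1] = end
                merged[-1][2] = max(merged[-1][2], smax)
            else:
                merged.append([start, end, smax])
        for start, end, smax in merged:
            intervals.append(GenomicInterval(chrom, start, end))
            support.append(smax)
    return ConsensusPeakMap(mark=mark, intervals=intervals, support=support)


def variants_in_peaks(gt: GenotypeTable, peak_map: ConsensusPeakMap,
                      extra_maps: list[ConsensusPeakMap] | None = None) -> list[str]:
    """Candidate SNPs for hQTL testing.

    Returns ids of autosomal variants that fall inside any consensus
    interval (of the given map, or of any map when several marks are
    supplied) and are heterozygous in at least one sample.
    """
    maps = [peak_map] + list(extra_maps or [])
    # index intervals per chromosome for binary search
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in maps:
        for iv in m.intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in per_chrom:
        per_chrom[chrom].sort()

    out: list[str] = []
    chroms = gt.variants["chrom"].to_numpy()
    poss = gt.variants["pos"].to_numpy()
    het_any = ((gt.hap1 >= 0) & (gt.hap2 >= 0) & (gt.hap1 != gt.hap2)).any(axis=1)
    for i, vid in enumerate(gt.variants.index):
        if not is_autosome(chroms[i]) or not het_any[i]:
            continue
        ivs = per_chrom.get(chroms[i])
        if not ivs:
            continue
        starts = [s for s, _ in ivs]
        j = int(np.searchsorted(starts, poss[i], side="right")) - 1
        if j >= 0 and ivs[j][0] <= poss[i] < ivs[j][1]:
            out.append(vid)
    return out
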