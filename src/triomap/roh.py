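"""Sliding-window runs-of-homozygosity detection and genomic inbreeding.

The detector slides a fixed-size window (in SNVs) one SNV at a time
along each chromosome; a window "passes" when it holds at most
``max_het_per_window`` heterozygous and ``max_miss_per_window`` missing
calls.  Each SNV is scored by the fraction of windows covering it that
pass; SNVs above the ``window_hit_fraction`` threshold whose own call is
not heterozygous form candidate runs of consecutive qualifying SNVs,
and runs are reported as segments when they satisfy the minimum length,
minimum SNV count, and minimum SNV density.  Defaults follow published
guidance for WGS-density cattle data: 20-SNV windows, <= 4 hets per
window, >= 200 kb, >= 66 SNVs, >= 1 SNV per 50 kb.

F_ROH is the summed segment length divided by the autosomal genome
length covered by SNV positions (2,488,313,529 bp for the cattle set
this models; configurable for scaled-down genomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import (BOVINE_AUTOSOME_SNV_BP, HET, MISSING, GenotypeMatrix,
                        ROHProfile, ROHSegment, TriomapError, VariantSite)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ROHParams:
    window_snv: int = 20
    max_het_per_window: int = 4
    max_miss_per_window: int = 1
    min_length_bp: int = 200_000
    min_snv: int = 66
    #: ceiling on mean bp per SNV within a segment (1 SNV per 50 kb)
    max_bp_per_snv: float = 50_000.0
    window_hit_fraction: float = 0.05

    def __post_init__(self) -> None:
        if min(self.window_snv, self.min_length_bp, self.min_snv) < 1 \
                or self.max_bp_per_snv <= 0:
            raise TriomapError("ROH parameters must be positive")


def detect_segments(calls: np.ndarray, positions: np.ndarray, chrom: str,
                    sample: str, params: ROHParams = ROHParams()
                    ) -> list[ROHSegment]:
    """Detect ROH on one chromosome of one sample.

    ``calls`` and ``positions`` must be position-sorted and QC-filtered.
    A chromosome with fewer SNVs than the window size yields no segments.
    """
    g = np.asarray(calls)
    pos = np.asarray(positions, dtype=np.int64)
    n = g.size
    W = params.window_snv
    if n < W:
        log.debug("chromosome %s has %d < %d SNVs; no ROH search", chrom, n, W)
        return []
    het = np.concatenate(([0], np.cumsum(g == HET)))
    mis = np.concatenate(([0], np.cumsum(g == MISSING)))
    n_windows = n - W + 1
    win_het = het[W:] - het[:-W]
    win_mis = mis[W:] - mis[:-W]
    win_pass = ((win_het <= params.max_het_per_window)
                & (win_mis <= params.max_miss_per_window))
    cpass = np.concatenate(([0], np.cumsum(win_pass)))
    j = np.arange(n)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, n_windows - 1)
    covering = hi - lo + 1
    passing = cpass[hi + 1] - cpass[lo]
    qualifies = (passing / covering > params.window_hit_fraction) & (g != HET)

    segments: list[ROHSegment] = []
    idx = np.flatnonzero(qualifies)
    if idx.size == 0:
        return segments
    gaps = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], gaps + 1))
    run_ends = np.concatenate((gaps, [idx.size - 1]))
    for s, e in zip(run_starts, run_ends):
        i0, i1 = int(idx[s]), int(idx[e])
        length = int(pos[i1] - pos[i0] + 1)
        n_snv = i1 - i0 + 1
        if (length >= params.min_length_bp and n_snv >= params.min_snv
                and length / n_snv <= params.max_bp_per_snv):
            segments.append(ROHSegment(sample=sample, chrom=chrom,
                                       start_bp=int(pos[i0]),
                                       end_bp=int(pos[i1]), n_snv=n_snv))
    return segments


def detect_roh(matrix: GenotypeMatrix, sample: str,
               params: ROHParams = ROHParams()) -> list[ROHSegment]:
    """Genome-wide ROH search for one sample over all chromosomes."""
    g = matrix.sample_calls(sample)
    pos = matrix.positions
    out: list[ROHSegment] = []
    for chrom, idx in matrix.chrom_indices().items():
        out.extend(detect_segments(g[idx], pos[idx], chrom, sample, params))
    return out


def roh_profile(matrix: GenotypeMatrix, sample: str,
                params: ROHParams = ROHParams(),
                genome_denominator_bp: int = BOVINE_AUTOSOME_SNV_BP
                ) -> ROHProfile:
    return ROHProfile(sample=sample,
                      segments=detect_roh(matrix, sample, params),
                      genome_denominator_bp=genome_denominator_bp)


def f_roh(segments: list[ROHSegment],
          genome_denominator_bp: int = BOVINE_AUTOSOME_SNV_BP) -> float:
    """Genomic inbreeding coefficient: total ROH length / genome length.

    Segments must be non-overlapping within each sample's chromosome;
    overlap is a violated invariant and raises.
    """
    by_chrom: dict[tuple[str, str], list[ROHSegment]] = {}
    for s in segments:
        by_chrom.setdefault((s.sample, s.chrom), []).append(s)
    for group in by_chrom.values():
        group.sort(key=lambda s: s.start_bp)
        for a, b in zip(group, group[1:]):
            if b.start_bp <= a.end_bp:
                raise TriomapError(
                    f"overlapping ROH segments on {a.chrom}: "
                    f"[{a.start_bp},{a.end_bp}] and [{b.start_bp},{b.end_bp}]")
    total = sum(s.length_bp for s in segments)
    return total / genome_denominator_bp


def shared_roh(profiles: list[ROHProfile]) -> list[tuple[str, int, int]]:
    """Maximal intervals covered by at least one segment of *every* sample.

    Returns ``(chrom, start_bp, end_bp)`` tuples (1-based inclusive);
    an empty list is a legitimate result.
    """
    if len(profiles) < 2:
        raise TriomapError("shared_roh needs at least two profiles")
    n = len(profiles)
    chroms: set[str] = set()
    for p in profiles:
        chroms.update(s.chrom for s in p.segments)
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(chroms, key=_chrom_sort_key):
        events: list[tuple[int, int]] = []
        for p in profiles:
            for s in p.segments:
                if s.chrom == chrom:
                    events.append((s.start_bp, +1))
                    events.append((s.end_bp + 1, -1))
        events.sort()
        depth = 0
        start = None
        i = 0
        while i < len(events):
            pos = events[i][0]
            while i < len(events) and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth == n and start is None:
                start = pos
            elif depth < n and start is not None:
                out.append((chrom, start, pos - 1))
                start = None
    return out


def _chrom_sort_key(chrom: str):
    try:
        return (int(chrom), "")
    except ValueError:
        return (10**9, chrom)


def colocalize(variant: VariantSite, profile: ROHProfile) -> ROHSegment | None:
    """The unique segment containing the variant position, or ``None``.

    Segment ends are inclusive: a variant 1 bp past a segment end does
    not colocalize.
    """
    for seg in profile.segments:
        if seg.contains(variant.chrom, variant.pos):
            return seg
    return None


def plot_segments(profiles: list[ROHProfile], path: str,
                  min_length_bp: int = 0) -> None:
    """Simple per-chromosome ROH track plot (one row per sample)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({s.chrom for p in profiles for s in p.segments},
                    key=_chrom_sort_key)
    fig, ax = plt.subplots(figsize=(10, 1 + 0.5 * len(profiles)))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    offsets = {}
    off = 0
    for c in chroms:
        offsets[c] = off
        off += max((s.end_bp for p in profiles for s in p.segments
                    if s.chrom == c), default=0) + 1
    for i, p in enumerate(profiles):
        for s in p.segments:
            if s.length_bp < min_length_bp:
                continue
            x0 = offsets[s.chrom] + s.start_bp
            ax.plot([x0, x0 + s.length_bp], [i, i],
                    color=colors[i % len(colors)], lw=6, solid_capstyle="butt")
    ax.set_yticks(range(len(profiles)))
    ax.set_yticklabels([p.sample for p in profiles])
    ax.set_xlabel("concatenated autosome position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
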