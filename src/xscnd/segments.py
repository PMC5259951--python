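"""Sliding-window scan for large segmental copy-number divergent regions.

A fixed-width window (20 kb) moves along each chromosome in 10-kb steps.
A window scores positive for a class (CNE or CNR) when the merged gene
bodies of that class cover at least ``min_cov`` (5 kb) of the window;
if both classes reach the cut-off the window is ambiguous and scored
``none`` with a warning.  Runs of at least three step-adjacent windows
with the same positive sign merge into one segment call — three
consecutive 20-kb windows at 10-kb steps span 40 kb and guarantee at
least 10 kb of concordant divergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CNE, CNR, ValidationError

logger = logging.getLogger(__name__)

NONE_SIGN = "none"


@dataclass(frozen=True)
class WindowCall:
    chrom: str
    start: int
    end: int  # start + window size (may overhang the chromosome end)
    covered_bases: int
    sign: str


@dataclass(frozen=True)
class SegmentCall:
    chrom: str
    start: int
    end: int
    sign: str
    n_windows: int


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals (so overlapping genes count once)."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _coverage(merged: list[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in merged)


def window_scan(
    calls: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window: int = 20_000,
    step: int = 10_000,
    min_cov: int = 5_000,
) -> list[WindowCall]:
    """Score fixed-width sliding windows by concordant CND gene coverage.

    ``calls`` needs columns chrom, start, end, cnd_class (0-based
    half-open gene-body coordinates of called genes).  Windows anchor at
    position 0; a final partial window is kept when at least half of it
    lies on the chromosome.
    """
    if step > window:
        raise ValidationError("step must not exceed window (windows must overlap)")
    for col in ("chrom", "start", "end", "cnd_class"):
        if col not in calls.columns:
            raise ValidationError(f"calls table lacks column {col!r}")
    unknown = set(calls["chrom"]) - set(chrom_lengths)
    if unknown:
        raise ValidationError(f"unknown chromosomes in calls: {sorted(unknown)}")

    by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for row in calls.itertuples():
        if row.cnd_class in (CNE, CNR):
            by_chrom.setdefault(row.chrom, {CNE: [], CNR: []})[row.cnd_class].append(
                (int(row.start), int(row.end))
            )

    out: list[WindowCall] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        merged = {
            cls: merge_intervals(by_chrom.get(chrom, {}).get(cls, []))
            for cls in (CNE, CNR)
        }
        start = 0
        while start < length:
            end = start + window
            if min(end, length) - start < window // 2:
                break  # final fragment shorter than half a window
            cov = {cls: _coverage(merged[cls], start, end) for cls in (CNE, CNR)}
            hits = [cls for cls in (CNE, CNR) if cov[cls] >= min_cov]
            if len(hits) == 2:
                logger.warning(
                    "window %s:%d-%d reaches %d bp for both classes; scored none",
                    chrom,
                    start,
                    end,
                    min_cov,
                )
                sign, covered = NONE_SIGN, max(cov.values())
            elif hits:
                sign, covered = hits[0], cov[hits[0]]
            else:
                sign, covered = NONE_SIGN, max(cov.values())
            out.append(WindowCall(chrom, start, end, covered, sign))
            start += step
    return out


def merge_large_regions(
    windows: list[WindowCall],
    min_consecutive: int = 3,
    step: int = 10_000,
) -> list[SegmentCall]:
    """Merge runs of step-adjacent concordant positive windows.

    A maximal run of at least ``min_consecutive`` windows with the same
    positive sign becomes one segment spanning the union of the run.
    """
    segments: list[SegmentCall] = []
    run: list[WindowCall] = []

    def _flush() -> None:
        if len(run) >= min_consecutive:
            segments.append(
                SegmentCall(
                    run[0].chrom,
                    run[0].start,
                    run[-1].end,
                    run[0].sign,
                    len(run),
                )
            )

    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    for w in ordered:
        if (
            run
            and w.sign == run[-1].sign
            and w.sign in (CNE, CNR)
            and w.chrom == run[-1].chrom
            and w.start - run[-1].start == step
        ):
            run.append(w)
        else:
            _flush()
            run = [w] if w.sign in (CNE, CNR) else []
    _flush()
    return segments


def segments_to_frame(segments: list[SegmentCall]) -> pd.DataFrame:
    """BED-style frame (name = sign, score = n_windows)."""
    return pd.DataFrame(
        [(s.chrom, s.start, s.end, s.sign, s.n_windows) for s in segments],
        columns=["chrom", "start", "end", "name", "score"],
    )
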