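"""Significant-region calling and overlap with GWAS windows.

A significant marker's localization is only as sharp as the 100-marker window
that produced its statistic, so each significant marker contributes the
physical span of that window; overlapping or abutting spans on a chromosome
merge into one region.  Regions carry the peak (marker of maximal windowed
statistic), the merged limits, their length and the count of significant
markers — the schema of the published region table, with names RAS<chrom>.<k>.

GWAS hits contribute +/-50 kb windows around each significant position;
overlapping windows merge.  The overlap report pairs every region with every
window on the same chromosome and measures overlap length, gap, and the
distance from the region peak to the underlying GWAS hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ChromosomeMismatchError, ConfigError

GWAS_FLANK_BP = 50_000


@dataclass
class QtlRegion:
    """A called significant interval (1-based, closed coordinates)."""

    name: str
    chrom: str
    peak_pos_bp: int
    start_bp: int
    end_bp: int
    n_sig_snps: int

    def __post_init__(self):
        if not (self.start_bp <= self.peak_pos_bp <= self.end_bp):
            raise ValueError("region peak must lie within its limits")
        if self.n_sig_snps < 1:
            raise ValueError("a region needs at least one significant marker")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of closed bp intervals; abutting intervals (gap 0) merge too."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def call_regions(profile: pd.DataFrame, window: int = 100) -> list[QtlRegion]:
    """Merge the window spans of significant markers into QTL regions.

    ``profile`` needs columns chrom, pos, ed4, significant, ordered by
    (chrom, pos).  For the marker at within-chromosome index j the source
    window covers indices [j - (w-1)//2, j + w//2]; its physical span is the
    positions of those flanking markers.  No significant markers -> empty
    list.
    """
    need = {"chrom", "pos", "ed4", "significant"}
    if not need.issubset(profile.columns):
        raise ConfigError(f"profile lacks columns {sorted(need - set(profile.columns))}")
    left, right = (window - 1) // 2, window // 2
    regions: list[QtlRegion] = []
    for name, sub in profile.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        ed4 = sub["ed4"].to_numpy(dtype=float)
        sig = sub["significant"].to_numpy(dtype=bool)
        idx = np.flatnonzero(sig)
        if idx.size == 0:
            continue
        spans = [
            (int(pos[j - left]), int(pos[j + right]))
            for j in idx
        ]
        for k, (s, e) in enumerate(_merge_intervals(spans), start=1):
            inside = (pos >= s) & (pos <= e)
            n_sig = int((sig & inside).sum())
            cand = np.flatnonzero(inside & np.isfinite(ed4))
            peak = int(pos[cand[np.argmax(ed4[cand])]])
            regions.append(
                QtlRegion(
                    name=f"RAS{name.removeprefix('chr')}.{k}",
                    chrom=name, peak_pos_bp=peak, start_bp=s, end_bp=e,
                    n_sig_snps=n_sig,
                )
            )
    return regions


def regions_to_frame(regions: list[QtlRegion], mbp: bool = False) -> pd.DataFrame:
    """Region list as a table; ``mbp=True`` gives the human-readable Mbp form
    (2 decimals), otherwise coordinates stay in bp."""
    rows = []
    for r in regions:
        if mbp:
            rows.append(
                (r.name, r.chrom, round(r.peak_pos_bp / 1e6, 2),
                 f"{r.start_bp / 1e6:.2f}-{r.end_bp / 1e6:.2f}",
                 round(r.length_bp / 1e6, 2), r.n_sig_snps)
            )
        else:
            rows.append(
                (r.name, r.chrom, r.peak_pos_bp, r.start_bp, r.end_bp,
                 r.length_bp, r.n_sig_snps)
            )
    cols = (
        ["name", "chrom", "peak_mbp", "range_mbp", "length_mbp", "n_sig_snps"]
        if mbp
        else ["name", "chrom", "peak_pos_bp", "start_bp", "end_bp", "length_bp", "n_sig_snps"]
    )
    return pd.DataFrame(rows, columns=cols)


def write_bed(regions: list[QtlRegion], path):
    """Regions as BED (0-based, half-open), converted at this boundary only."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.name}\n")


def gwas_windows(hits: pd.DataFrame, flank: int = GWAS_FLANK_BP) -> pd.DataFrame:
    """+/-``flank`` windows around GWAS hits, merged per chromosome.

    ``hits`` needs columns chrom, pos (bp) and may carry p_value.  Windows
    are clipped at the chromosome start (bp 1).  Returns columns chrom,
    start, end, n_hits, hit_pos (comma-joined source positions); the merged
    window count never exceeds the hit count.
    """
    if hits.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_hits", "hit_pos"])
    rows = []
    for name, sub in hits.sort_values(["chrom", "pos"]).groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        merged: list[list] = []
        for p in pos:
            s, e = max(int(p) - flank, 1), int(p) + flank
            if merged and s <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2].append(int(p))
            else:
                merged.append([s, e, [int(p)]])
        for s, e, hs in merged:
            rows.append((name, s, e, len(hs), ",".join(map(str, hs))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_hits", "hit_pos"])


@dataclass
class OverlapSummary:
    n_regions: int
    n_regions_overlapped: int
    n_windows: int
    n_windows_overlapped: int


def overlap_report(regions: list[QtlRegion],
                   windows: pd.DataFrame) -> tuple[pd.DataFrame, OverlapSummary]:
    """Pair every region with every GWAS window on the same chromosome.

    Per pair: ``overlap_bp`` (end-minus-start convention, 0 if disjoint),
    ``gap_bp`` (separation when disjoint, else 0), ``peak_to_window_bp``
    (distance from the region peak to the nearest window edge, 0 if inside)
    and ``peak_to_hit_bp`` (distance from the peak to the nearest source hit,
    when windows carry hit positions).  Raises when the two inputs share no
    chromosome names at all, listing the unmatched names.
    """
    rchroms = {r.chrom for r in regions}
    wchroms = set(windows["chrom"]) if len(windows) else set()
    if rchroms and wchroms and not (rchroms & wchroms):
        raise ChromosomeMismatchError(rchroms, wchroms)

    rows = []
    overlapped_regions: set[str] = set()
    overlapped_windows: set[int] = set()
    for r in regions:
        for wi, w in windows[windows["chrom"] == r.chrom].iterrows():
            ov = max(0, min(r.end_bp, w["end"]) - max(r.start_bp, w["start"]))
            gap = max(0, max(r.start_bp, w["start"]) - min(r.end_bp, w["end"]))
            if w["start"] <= r.peak_pos_bp <= w["end"]:
                pw = 0
            else:
                pw = min(abs(r.peak_pos_bp - w["start"]), abs(r.peak_pos_bp - w["end"]))
            hit_d = np.nan
            if "hit_pos" in w and w["hit_pos"]:
                hs = [int(x) for x in str(w["hit_pos"]).split(",")]
                hit_d = min(abs(r.peak_pos_bp - h) for h in hs)
            if ov > 0:
                overlapped_regions.add(r.name)
                overlapped_windows.add(wi)
            rows.append((r.name, r.chrom, w["start"], w["end"], ov, gap, pw, hit_d))
    report = pd.DataFrame(
        rows,
        columns=["region", "chrom", "window_start", "window_end",
                 "overlap_bp", "gap_bp", "peak_to_window_bp", "peak_to_hit_bp"],
    )
    summary = OverlapSummary(
        n_regions=len(regions),
        n_regions_overlapped=len(overlapped_regions),
        n_windows=len(windows),
        n_windows_overlapped=len(overlapped_windows),
    )
    return report, summary
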