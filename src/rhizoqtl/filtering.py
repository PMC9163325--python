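"""SNP-quality cascade for bulk allele-depth tables.

The raw pooled-sequencing calls are polarized so that the reference allele is
always the low-phenotype parent's allele, then passed through an ordered
filter cascade:

1. multiallelic sites;
2. sites whose pooled alternate-allele read fraction across both bulks is
   below a minimum (0.25 by default; an optional symmetric mode also drops
   the mirrored high tail);
3. sites whose total depth (summed over bulks) falls below the 25th or above
   the 95th percentile of the post-step-2 depth distribution (linear
   interpolation; boundary values are retained);
4. sites missing in too many bulks — with two bulks the operative rule is
   "missing in at least one bulk";
5. sites with pooled minor-allele frequency under 5% (on read counts).

Each removal is attributed to the first applicable filter, and the report
records the running counts plus the frozen depth bounds so the cascade can be
re-applied idempotently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

DEPTH_COLS = ["ref_depth_low", "alt_depth_low", "ref_depth_high", "alt_depth_high"]


@dataclass
class FilterParams:
    """Thresholds of the cascade; defaults are the published values."""

    min_total_allele_freq: float = 0.25
    symmetric_freq_filter: bool = False
    depth_lower_pct: float = 25.0
    depth_upper_pct: float = 95.0
    frozen_depth_bounds: tuple[float, float] | None = None
    max_missing_frac: float = 0.5
    min_maf: float = 0.05


@dataclass
class FilterStep:
    name: str
    removed: int
    remaining: int


@dataclass
class FilterReport:
    """Ordered audit trail of the cascade."""

    n_input: int
    steps: list[FilterStep] = field(default_factory=list)
    depth_bounds: tuple[float, float] | None = None

    def add(self, name: str, removed: int, remaining: int):
        self.steps.append(FilterStep(name, int(removed), int(remaining)))

    @property
    def n_remaining(self) -> int:
        return self.steps[-1].remaining if self.steps else self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.removed, s.remaining) for s in self.steps],
            columns=["filter", "sites_removed", "sites_remaining"],
        )

    def validate(self):
        remaining = self.n_input
        total_removed = 0
        for s in self.steps:
            if s.remaining != remaining - s.removed:
                raise ValueError(f"inconsistent counts at step {s.name!r}")
            remaining = s.remaining
            total_removed += s.removed
        if self.steps and self.steps[-1].remaining != self.n_input - total_removed:
            raise ValueError("final remaining != input - total removed")


@dataclass
class PolarizeStats:
    n_kept: int
    n_swapped: int
    n_dropped: int


def _as_parent_map(low_parent) -> dict:
    if isinstance(low_parent, pd.DataFrame):
        return {
            (r.chrom, int(r.pos)): r.allele
            for r in low_parent.itertuples(index=False)
        }
    return dict(low_parent)


def parental_alleles(table: pd.DataFrame) -> pd.DataFrame:
    """Low-parent allele per site from an already-polarized table."""
    return pd.DataFrame(
        {"chrom": table["chrom"], "pos": table["pos"], "allele": table["ref"]}
    )


def polarize(table: pd.DataFrame, low_parent) -> tuple[pd.DataFrame, PolarizeStats]:
    """Orient every site so the reference allele is the low-parent allele.

    ``low_parent`` maps (chrom, pos) -> allele (dict or a DataFrame with
    columns chrom, pos, allele).  Sites where the declared parental allele is
    already the reference are kept unchanged; sites where it is the alternate
    allele have ref/alt and the corresponding depths swapped in both bulks;
    sites where neither allele matches (or with no declared allele) are
    dropped and counted.  Applying the operation twice is the identity.
    """
    parent = _as_parent_map(low_parent)
    t = table.copy()
    keys = list(zip(t["chrom"], t["pos"].astype(int)))
    declared = np.array([parent.get(k) for k in keys], dtype=object)
    ref = t["ref"].to_numpy(dtype=object).copy()
    alt = t["alt"].to_numpy(dtype=object).copy()
    keep = declared == ref
    swap = (~keep) & (declared == alt)
    drop = ~(keep | swap)

    if swap.any():
        for bulk in ("low", "high"):
            r, a = f"ref_depth_{bulk}", f"alt_depth_{bulk}"
            rv, av = t[r].to_numpy().copy(), t[a].to_numpy().copy()
            t.loc[swap, r] = av[swap]
            t.loc[swap, a] = rv[swap]
        t.loc[swap, "ref"] = alt[swap]
        t.loc[swap, "alt"] = ref[swap]
    out = t[~drop].reset_index(drop=True)
    return out, PolarizeStats(int(keep.sum()), int(swap.sum()), int(drop.sum()))


def _pooled_alt_freq(t: pd.DataFrame) -> np.ndarray:
    alt = (t["alt_depth_low"] + t["alt_depth_high"]).to_numpy(dtype=float)
    tot = t[DEPTH_COLS].sum(axis=1).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, alt / tot, np.nan)


def filter_cascade(table: pd.DataFrame,
                   params: FilterParams | None = None) -> tuple[pd.DataFrame, FilterReport]:
    """Run the ordered SNP-quality cascade; returns (filtered table, report).

    Percentile depth bounds are computed on the table that survives the
    frequency filter unless ``params.frozen_depth_bounds`` pins them, in
    which case the cascade is strictly idempotent.
    """
    p = params or FilterParams()
    report = FilterReport(n_input=len(table))
    t = table

    # 1. multiallelic sites
    multi = t["multiallelic"].to_numpy(dtype=bool)
    t = t[~multi]
    report.add("multiallelic", multi.sum(), len(t))

    # 2. pooled alternate-allele read fraction
    f = _pooled_alt_freq(t)
    low = np.where(np.isnan(f), False, f < p.min_total_allele_freq)
    if p.symmetric_freq_filter:
        low |= np.where(np.isnan(f), False, f > 1.0 - p.min_total_allele_freq)
    t = t[~low]
    report.add("total_allele_freq", low.sum(), len(t))

    # 3. depth percentiles on the post-step-2 distribution; boundaries kept
    tot = t[DEPTH_COLS].sum(axis=1).to_numpy(dtype=float)
    if p.frozen_depth_bounds is not None:
        lo, hi = p.frozen_depth_bounds
    elif len(t):
        lo, hi = np.percentile(tot, [p.depth_lower_pct, p.depth_upper_pct])
    else:
        lo, hi = 0.0, 0.0
    report.depth_bounds = (float(lo), float(hi))
    bad_depth = (tot < lo) | (tot > hi)
    t = t[~bad_depth]
    report.add("depth_percentile", bad_depth.sum(), len(t))

    # 4. missing bulks
    miss_frac = (
        t["missing_low"].to_numpy(dtype=float) + t["missing_high"].to_numpy(dtype=float)
    ) / 2.0
    missing = miss_frac >= p.max_missing_frac
    t = t[~missing]
    report.add("missing", missing.sum(), len(t))

    # 5. pooled minor-allele frequency
    f = _pooled_alt_freq(t)
    maf = np.minimum(f, 1.0 - f)
    rare = np.where(np.isnan(maf), True, maf < p.min_maf)
    t = t[~rare]
    report.add("maf", rare.sum(), len(t))

    report.validate()
    return t.reset_index(drop=True), report
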