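"""Euclidean-distance allele-frequency scan for bulked-segregant analysis.

At each filtered marker the alternate-allele frequency is estimated from read
depths in the low and high bulk.  The per-marker statistic is the Euclidean
distance between the bulk allele-frequency vectors,

    ED_m = sqrt((f_aL - f_aH)^2 + (f_AL - f_AH)^2) = sqrt(2) |f_aL - f_aH|,

which is zero when the bulks carry the same allele mix and sqrt(2) when they
are fixed for opposite alleles.  To suppress sequencing noise, the cumulative
ED over sliding windows of 100 consecutive markers is raised to the fourth
power and assigned to the window-centre marker (ED4).  Significance is judged
against a simulated no-QTL null: bulks of the observed size drawn from the
Mendelian 1:2:1 F2 genotype distribution, read counts binomial at the
observed per-site depths, with the genome-wide maximum ED4 calibrating a
family-wise 95% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

F2_GENOTYPE_PROBS = (0.25, 0.5, 0.25)  # Mendelian 1:2:1 segregation


def bulk_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Read-based allele frequencies per bulk: f_a = alt / (alt + ref).

    Returns a frame with columns chrom, pos, f_alt_low, f_alt_high (the
    reference-allele frequencies are the complements).  Zero-depth bulks
    yield NaN and should have been removed by the filter cascade.
    """
    out = table[["chrom", "pos"]].copy()
    for bulk in ("low", "high"):
        alt = table[f"alt_depth_{bulk}"].to_numpy(dtype=float)
        tot = alt + table[f"ref_depth_{bulk}"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"f_alt_{bulk}"] = np.where(tot > 0, alt / tot, np.nan)
    return out


def ed_statistic(f_alt_low, f_alt_high, variant: str = "between"):
    """Per-marker Euclidean distance between bulk allele frequencies.

    ``variant="between"`` (default) contrasts each allele's frequency across
    bulks: sqrt(2) |f_aL - f_aH|.  ``variant="within"`` is the literal
    within-bulk contrast sqrt((f_aL - f_AL)^2 + (f_aH - f_AH)^2), kept for
    comparison; it measures distance from 0.5 inside each bulk rather than
    divergence between bulks.
    """
    fl = np.asarray(f_alt_low, dtype=float)
    fh = np.asarray(f_alt_high, dtype=float)
    for f in (fl, fh):
        vals = f[np.isfinite(f)]
        if vals.size and (np.any(vals < 0) or np.any(vals > 1)):
            raise ConfigError("allele frequencies must lie in [0, 1]")
    if variant == "between":
        out = np.sqrt((fl - fh) ** 2 + ((1 - fl) - (1 - fh)) ** 2)
    elif variant == "within":
        out = np.sqrt((fl - (1 - fl)) ** 2 + (fh - (1 - fh)) ** 2)
    else:
        raise ConfigError(f"unknown ED variant {variant!r}")
    return float(out) if out.ndim == 0 else out


def _sliding_window(ed2d: np.ndarray, window: int, stat: str) -> np.ndarray:
    """Windowed statistic along the last axis; NaN where no full window.

    ``stat="sum4"``: (sum of ED over the window)^4.  ``stat="pow4sum"``:
    sum of ED^4 over the window.  Values sit at the window-centre position
    start + (window - 1) // 2.
    """
    m = ed2d.shape[-1]
    out = np.full(ed2d.shape, np.nan)
    if m < window:
        return out
    base = ed2d if stat == "sum4" else ed2d ** 4
    cs = np.cumsum(base, axis=-1)
    sums = cs[..., window - 1:].copy()
    sums[..., 1:] -= cs[..., :-window]
    if stat == "sum4":
        sums = sums ** 4
    centre = (window - 1) // 2
    out[..., centre:centre + sums.shape[-1]] = sums
    return out


def window_statistic(ed: np.ndarray, chroms: np.ndarray, window: int = 100,
                     stat: str = "sum4") -> np.ndarray:
    """Windowed fourth-power ED over sliding windows of consecutive markers.

    Windows never span chromosomes; markers whose window would be truncated
    carry NaN.  Markers must already be ordered by (chrom, pos).
    """
    if stat not in ("sum4", "pow4sum"):
        raise ConfigError(f"unknown window statistic {stat!r}")
    if window < 1:
        raise ConfigError("window size must be >= 1")
    ed = np.asarray(ed, dtype=float)
    chroms = np.asarray(chroms)
    out = np.full(ed.shape, np.nan)
    for name in pd.unique(chroms):
        sel = chroms == name
        if sel.sum() < window:
            continue
        out[sel] = _sliding_window(ed[sel][None, :], window, stat)[0]
    return out


def ed_profile(table: pd.DataFrame, window: int = 100, variant: str = "between",
               stat: str = "sum4") -> pd.DataFrame:
    """Per-marker profile: chrom, pos, f_alt_low/high, ed, ed4."""
    prof = bulk_frequencies(table)
    prof["ed"] = ed_statistic(prof["f_alt_low"], prof["f_alt_high"], variant)
    prof["ed4"] = window_statistic(
        prof["ed"].to_numpy(), prof["chrom"].to_numpy(), window, stat
    )
    prof.attrs["ed_variant"] = variant
    prof.attrs["window"] = window
    prof.attrs["window_stat"] = stat
    return prof


def simulate_null_maxima(chroms, depth_low, depth_high, bulk_size: int,
                         n_sims: int, seed: int = 0, window: int = 100,
                         variant: str = "between", stat: str = "sum4") -> np.ndarray:
    """Per-genome maximum ED4 under the no-QTL null, one value per simulation.

    Each simulated genome redraws both bulk compositions by sampling
    ``bulk_size`` F2 genotypes from the 1:2:1 distribution independently per
    marker and bulk, then read counts Binomial(observed depth, pooled bulk
    frequency).  Depths are taken per site from the data being scanned so the
    null shares its noise structure.
    """
    rng = np.random.default_rng(seed)
    chroms = np.asarray(chroms)
    dl = np.asarray(depth_low, dtype=np.int64)
    dh = np.asarray(depth_high, dtype=np.int64)
    if np.any(dl <= 0) or np.any(dh <= 0):
        raise ConfigError("null simulation requires positive per-bulk depths")
    m = len(chroms)
    freqs = []
    for d in (dl, dh):
        counts = rng.multinomial(bulk_size, F2_GENOTYPE_PROBS, size=(n_sims, m))
        f_true = (counts[..., 1] + 2 * counts[..., 2]) / (2.0 * bulk_size)
        alt = rng.binomial(d, f_true)
        freqs.append(alt / d)
    ed = ed_statistic(freqs[0], freqs[1], variant)

    maxima = np.full(n_sims, -np.inf)
    any_window = False
    for name in pd.unique(chroms):
        sel = chroms == name
        if sel.sum() < window:
            continue
        any_window = True
        ed4 = _sliding_window(ed[:, sel], window, stat)
        maxima = np.maximum(maxima, np.nanmax(ed4, axis=-1))
    if not any_window:
        raise ConfigError("no chromosome holds a full window; cannot simulate null")
    return maxima


@dataclass
class ScanThreshold:
    """Genome-wide significance cutoff for the windowed statistic."""

    value: float
    alpha: float
    mode: str          # "genome_max" or "per_marker"
    n_sims: int
    seed: int
    window: int
    variant: str
    stat: str


def significance_threshold(chroms, depth_low, depth_high, bulk_size: int,
                           n_sims: int = 200, alpha: float = 0.05, seed: int = 0,
                           window: int = 100, variant: str = "between",
                           stat: str = "sum4",
                           mode: str = "genome_max") -> ScanThreshold:
    """Simulated null threshold at level ``alpha`` for the ED4 profile.

    ``mode="genome_max"`` (default) takes the (1 - alpha) quantile of the
    per-genome maximum, controlling the family-wise false-positive rate
    across all markers.  ``mode="per_marker"`` pools the null window values
    over markers and genomes and takes their (1 - alpha) quantile — less
    conservative, for exploratory scans.
    """
    if n_sims < 20:
        raise ConfigError("n_sims < 20 makes the null quantile unstable")
    if not (0.0 < alpha <= 1.0):
        raise ConfigError("alpha must lie in (0, 1]")
    if alpha == 1.0:
        # limiting case: no evidence demanded, every windowed marker passes
        return ScanThreshold(value=0.0, alpha=alpha, mode=mode, n_sims=n_sims,
                             seed=seed, window=window, variant=variant, stat=stat)
    if mode == "genome_max":
        maxima = simulate_null_maxima(
            chroms, depth_low, depth_high, bulk_size, n_sims, seed, window,
            variant, stat,
        )
        value = float(np.quantile(maxima, 1.0 - alpha))
    elif mode == "per_marker":
        rng = np.random.default_rng(seed)
        chroms = np.asarray(chroms)
        dl = np.asarray(depth_low, dtype=np.int64)
        dh = np.asarray(depth_high, dtype=np.int64)
        m = len(chroms)
        freqs = []
        for d in (dl, dh):
            counts = rng.multinomial(bulk_size, F2_GENOTYPE_PROBS, size=(n_sims, m))
            f_true = (counts[..., 1] + 2 * counts[..., 2]) / (2.0 * bulk_size)
            freqs.append(rng.binomial(d, f_true) / d)
        ed = ed_statistic(freqs[0], freqs[1], variant)
        pooled = []
        for name in pd.unique(chroms):
            sel = chroms == name
            if sel.sum() < window:
                continue
            ed4 = _sliding_window(ed[:, sel], window, stat)
            pooled.append(ed4[np.isfinite(ed4)])
        if not pooled:
            raise ConfigError("no chromosome holds a full window; cannot simulate null")
        value = float(np.quantile(np.concatenate(pooled), 1.0 - alpha))
    else:
        raise ConfigError(f"unknown threshold mode {mode!r}")
    return ScanThreshold(value=value, alpha=alpha, mode=mode, n_sims=n_sims,
                         seed=seed, window=window, variant=variant, stat=stat)


def mark_significant(profile: pd.DataFrame, threshold: ScanThreshold | float) -> pd.DataFrame:
    """Attach threshold and boolean significance flags to a profile."""
    value = threshold.value if isinstance(threshold, ScanThreshold) else float(threshold)
    out = profile.copy()
    out["threshold"] = value
    ed4 = out["ed4"].to_numpy(dtype=float)
    out["significant"] = np.where(np.isfinite(ed4), ed4 >= value, False)
    return out


def plot_profile(profile: pd.DataFrame, path, threshold: float | None = None):
    """One panel per chromosome: ED4 against physical position (Mbp)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(pd.unique(profile["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)),
                             squeeze=False, sharey=True)
    for ax, name in zip(axes[:, 0], chroms):
        sub = profile[profile["chrom"] == name]
        ax.plot(sub["pos"] / 1e6, sub["ed4"], lw=0.8, color="steelblue")
        if threshold is not None:
            ax.axhline(threshold, ls="--", color="gray", lw=0.8)
        ax.set_ylabel("ED$^4$")
        ax.set_title(name, fontsize=9, loc="left")
    axes[-1, 0].set_xlabel("position (Mbp)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
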