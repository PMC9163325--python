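"""Synthetic F2 mapping population and pooled-sequencing generator.

This module produces every input the downstream analysis consumes:

* ``simulate_f2`` — F2 genotypes from a biparental cross, one meiosis per
  gamete under Haldane's no-interference model;
* ``simulate_phenotypes`` — a quantitative rhizosheath phenotype (root-adhering
  soil mass over root tissue mass, RAS/RT) with block effects, QTL effects and
  a residual scaled to hit a target broad-sense heritability;
* ``simulate_bulk_reads`` — pooled sequencing of two phenotypic-extreme bulks,
  with overdispersed depth, binomial allele sampling, missingness and
  multiallelic contamination;
* ``simulate_inbred_panel`` — a simple line-replicate trial for heritability
  estimation (random line effects, within-line residuals).

Genotypes are coded 0/1/2 as copies of the high-phenotype parent allele.  In
the read tables the reference allele is the low-parent allele, so the
alternate allele is the high-parent allele throughout — the same polarization
the variant-filtering stage enforces on real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: fallback residual standard deviation (log-ratio scale) when neither a
#: heritability target nor an explicit residual is configured
DEFAULT_RESIDUAL_SD = 0.35

#: grand mean of log(RAS/RT); exp(3.1) ~ 22, the scale observed in F2 trials
DEFAULT_MEAN_LOG_RATIO = 3.1


def _norm_chrom(c) -> str:
    """Normalize a chromosome label: 5 -> 'chr5', 'chr5' -> 'chr5'."""
    s = str(c)
    return s if s.startswith("chr") else f"chr{s}"


@dataclass(frozen=True)
class Qtl:
    """A single QTL: additive effect ``a`` and dominance ``d`` on the
    phenotype scale, located at a physical position on one chromosome.

    Genotypic value is ``a * (g - 1) + d * 1{g == 1}`` for genotype code
    ``g`` (copies of the high-parent allele).
    """

    chrom: str
    pos_bp: float
    additive: float
    dominance: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))


@dataclass
class SimConfig:
    """Full parameterization of the F2 + pooled-sequencing generator.

    Defaults mirror the design of the source experiment: 547 F2 individuals
    from two inbred parents, 7 chromosomes, ~23k biallelic SNPs, mean pooled
    depth 875X, five phenotyping blocks.
    """

    n_chromosomes: int = 7
    chrom_lengths_bp: tuple = ()
    map_lengths_morgans: tuple = ()
    n_markers_per_chrom: int = 3300
    n_f2: int = 547
    qtls: tuple = ()
    heritability_target: float | None = None
    mean_log_ratio: float = DEFAULT_MEAN_LOG_RATIO
    residual_sd: float | None = None
    n_blocks: int = 5
    block_effect_sd: float = 0.15
    mean_depth: float = 875.0
    depth_dispersion: float = 0.2
    missing_rate: float = 0.02
    multiallelic_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not self.chrom_lengths_bp:
            self.chrom_lengths_bp = (250_000_000,) * self.n_chromosomes
        if not self.map_lengths_morgans:
            self.map_lengths_morgans = (1.4,) * self.n_chromosomes
        self.chrom_lengths_bp = tuple(float(x) for x in self.chrom_lengths_bp)
        self.map_lengths_morgans = tuple(float(x) for x in self.map_lengths_morgans)
        self.qtls = tuple(
            q if isinstance(q, Qtl) else Qtl(*q) for q in self.qtls
        )
        self._validate()

    def _validate(self):
        c = self
        if c.n_chromosomes < 1 or c.n_markers_per_chrom < 1 or c.n_f2 < 1 or c.n_blocks < 1:
            raise ConfigError("all counts must be >= 1")
        if len(c.chrom_lengths_bp) != c.n_chromosomes:
            raise ConfigError("chrom_lengths_bp must have one entry per chromosome")
        if len(c.map_lengths_morgans) != c.n_chromosomes:
            raise ConfigError("map_lengths_morgans must have one entry per chromosome")
        if any(l <= 0 for l in c.chrom_lengths_bp):
            raise ConfigError("chromosome physical lengths must be > 0")
        if any(m < 0 for m in c.map_lengths_morgans):
            raise ConfigError("genetic map lengths must be >= 0")
        if c.heritability_target is not None and not (0.0 <= c.heritability_target <= 1.0):
            raise ConfigError("heritability_target must lie in [0, 1]")
        for name in ("missing_rate", "multiallelic_rate"):
            v = getattr(c, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if c.mean_depth <= 0 or c.depth_dispersion < 0:
            raise ConfigError("mean_depth must be > 0 and depth_dispersion >= 0")
        chrom_len = {
            _norm_chrom(i + 1): L for i, L in enumerate(c.chrom_lengths_bp)
        }
        for q in c.qtls:
            if q.chrom not in chrom_len:
                raise ConfigError(f"QTL on unknown chromosome {q.chrom!r}")
            if not (0 <= q.pos_bp <= chrom_len[q.chrom]):
                raise ConfigError(f"QTL position {q.pos_bp} outside {q.chrom}")

    @property
    def chrom_names(self) -> list[str]:
        return [_norm_chrom(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class F2Genotypes:
    """Genotype codes per individual per marker plus the marker map.

    ``genotypes`` has shape (n_f2, n_markers), values in {0, 1, 2} counting
    copies of the high-parent allele.  ``marker_map`` columns: chrom, pos_bp,
    pos_morgans, sorted by (chrom, pos_bp) with strictly increasing positions
    within each chromosome.
    """

    genotypes: np.ndarray
    marker_map: pd.DataFrame
    ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.ids:
            self.ids = [f"F2_{i + 1:04d}" for i in range(self.genotypes.shape[0])]
        bad = ~np.isin(self.genotypes, (0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous marker index range per chromosome."""
        out = {}
        chroms = self.marker_map["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


def _marker_positions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniformly scattered, strictly increasing marker positions per chromosome."""
    rows = []
    for i, name in enumerate(config.chrom_names):
        L = int(config.chrom_lengths_bp[i])
        n = config.n_markers_per_chrom
        pos = np.unique(rng.integers(1, L + 1, size=n))
        while pos.size < n:  # top up collisions; rare for realistic L >> n
            extra = rng.integers(1, L + 1, size=n - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(pos[:n])
        morgans = pos / L * config.map_lengths_morgans[i]
        rows.append(pd.DataFrame({"chrom": name, "pos_bp": pos, "pos_morgans": morgans}))
    return pd.concat(rows, ignore_index=True)


def simulate_gametes(config: SimConfig, n_gametes: int,
                     marker_map: pd.DataFrame | None = None,
                     rng: np.random.Generator | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw F1 gametes at the marker positions.

    Crossovers follow a Poisson process on the genetic map (Haldane, no
    interference); restricted to the markers this is a Markov chain whose
    switch probability between adjacent markers is the Haldane recombination
    fraction c = (1 - exp(-2 d)) / 2 of their map distance d.  Returns a
    (n_gametes, n_markers) 0/1 array (1 = high-parent allele) and the map.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if marker_map is None:
        marker_map = _marker_positions(config, rng)
    out = np.empty((n_gametes, len(marker_map)), dtype=np.int8)
    chroms = marker_map["chrom"].to_numpy()
    morgans = marker_map["pos_morgans"].to_numpy()
    start = 0
    for i, name in enumerate(config.chrom_names):
        sel = chroms == name
        m = int(sel.sum())
        d = np.diff(morgans[sel])
        if config.map_lengths_morgans[i] == 0 and m > 1:
            warnings.warn(
                f"{name}: zero genetic map length with {m} markers — all markers "
                "fully linked, no recombinants will be produced",
                stacklevel=2,
            )
        c = 0.5 * (1.0 - np.exp(-2.0 * d))
        first = rng.integers(0, 2, size=(n_gametes, 1), dtype=np.int8)
        switches = (rng.random((n_gametes, m - 1)) < c).astype(np.int8)
        parity = np.cumsum(switches, axis=1, dtype=np.int32) & 1
        block = np.concatenate([first, first ^ parity.astype(np.int8)], axis=1)
        out[:, start:start + m] = block
        start += m
    return out, marker_map


def simulate_f2(config: SimConfig) -> F2Genotypes:
    """Simulate an F2 population by pairing two independent F1 gametes.

    Marginal genotype frequencies converge to the Mendelian 1:2:1 as n grows;
    linkage between markers follows the Haldane map function.
    """
    rng = np.random.default_rng(config.seed)
    gametes, marker_map = simulate_gametes(config, 2 * config.n_f2, rng=rng)
    genotypes = gametes[0::2] + gametes[1::2]
    return F2Genotypes(genotypes=genotypes.astype(np.int8), marker_map=marker_map)


def _genetic_values(genotypes: F2Genotypes, config: SimConfig) -> np.ndarray:
    """Summed QTL effects per individual; each QTL acts at its nearest marker."""
    g_sum = np.zeros(genotypes.n_individuals)
    mm = genotypes.marker_map
    for q in config.qtls:
        on = mm.index[mm["chrom"] == q.chrom]
        if len(on) == 0:
            raise ConfigError(f"no markers on {q.chrom} to host the QTL")
        pos = mm.loc[on, "pos_bp"].to_numpy()
        idx = on[np.argmin(np.abs(pos - q.pos_bp))]
        g = genotypes.genotypes[:, idx].astype(float)
        g_sum += q.additive * (g - 1.0) + q.dominance * (g == 1)
    return g_sum


def simulate_phenotypes(genotypes: F2Genotypes, config: SimConfig) -> pd.DataFrame:
    """Simulate per-plant RAS/RT phenotypes for the F2.

    The modelled trait is log(RAS/RT):

        y = mean_log_ratio + block effect + sum_QTL [a (g - 1) + d 1{g=1}] + e

    The residual variance is chosen so that the genetic fraction of
    Var(genetic) + Var(residual) equals ``heritability_target`` (block effects
    are excluded from both sides, as in the broad-sense formula).  Individuals
    are assigned to blocks round-robin.  Returns a table with columns
    id, block, ras_g, rt_g (root-adhering soil and root tissue dry masses, g);
    RAS/RT is recovered downstream as ras_g / rt_g = exp(y).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = genotypes.n_individuals
    genetic = _genetic_values(genotypes, config)
    var_g = float(np.var(genetic))

    h2 = config.heritability_target
    if h2 is None:
        resid_sd = DEFAULT_RESIDUAL_SD if config.residual_sd is None else config.residual_sd
    elif h2 == 1.0:
        if config.residual_sd:
            raise ConfigError(
                "heritability_target=1 contradicts a nonzero residual_sd"
            )
        if var_g == 0:
            raise ConfigError("heritability_target=1 requires genetic variance > 0")
        resid_sd = 0.0
    elif h2 == 0.0:
        if var_g > 0:
            raise ConfigError(
                "heritability_target=0 is unattainable with QTLs of nonzero effect"
            )
        resid_sd = DEFAULT_RESIDUAL_SD if config.residual_sd is None else config.residual_sd
    else:
        if var_g == 0:
            raise ConfigError(
                "a heritability_target in (0,1) requires at least one QTL with effect"
            )
        resid_sd = float(np.sqrt(var_g * (1.0 - h2) / h2))

    block_idx = np.arange(n) % config.n_blocks
    block_effects = rng.normal(0.0, config.block_effect_sd, size=config.n_blocks)
    y = (
        config.mean_log_ratio
        + block_effects[block_idx]
        + genetic
        + rng.normal(0.0, resid_sd, size=n)
    )
    rt = rng.lognormal(mean=np.log(0.35), sigma=0.25, size=n)
    ratio = np.exp(y)
    return pd.DataFrame(
        {
            "id": genotypes.ids,
            "block": [f"B{b + 1}" for b in block_idx],
            "ras_g": ratio * rt,
            "rt_g": rt,
        }
    )


_BASES = np.array(list("ACGT"))


def simulate_bulk_reads(genotypes: F2Genotypes, low_ids, high_ids,
                        config: SimConfig) -> pd.DataFrame:
    """Pooled sequencing of the two bulks; returns a variant table.

    Per marker and bulk the true alternate-allele frequency is the mean
    genotype code over the bulk divided by 2.  Depth is gamma-Poisson
    (negative-binomial-like) around ``mean_depth`` with coefficient of
    variation sqrt(depth_dispersion) on the gamma multiplier; the alternate
    read count is Binomial(depth, frequency).  Missingness zeroes the depths
    of a bulk and sets its flag; multiallelic contamination diverts a small
    read fraction to a third allele and sets the shared flag.

    Columns: chrom, pos, ref, alt, alt2, ref_depth_low, alt_depth_low,
    alt2_depth_low, ref_depth_high, alt_depth_high, alt2_depth_high,
    missing_low, missing_high, multiallelic.
    """
    low_ids, high_ids = list(low_ids), list(high_ids)
    if not low_ids or not high_ids:
        raise ConfigError("both bulks must be non-empty")
    if set(low_ids) & set(high_ids):
        raise ConfigError("bulk id lists must be disjoint")
    index = {s: i for i, s in enumerate(genotypes.ids)}
    try:
        low_idx = np.array([index[s] for s in low_ids])
        high_idx = np.array([index[s] for s in high_ids])
    except KeyError as e:
        raise ConfigError(f"unknown individual id {e.args[0]!r} in a bulk") from None

    rng = np.random.default_rng([config.seed, 2])
    m = genotypes.n_markers
    out = {
        "chrom": genotypes.marker_map["chrom"].to_numpy(),
        "pos": genotypes.marker_map["pos_bp"].to_numpy().astype(np.int64),
    }

    # reference allele = low-parent allele; alternate = high-parent allele
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    alt2_i = np.full(m, -1)
    multi = rng.random(m) < config.multiallelic_rate
    if multi.any():
        cand = (alt_i + rng.integers(1, 4, size=m)) % 4
        cand[cand == ref_i] = (cand[cand == ref_i] + 1) % 4
        alt2_i[multi] = cand[multi]
    out["ref"] = _BASES[ref_i]
    out["alt"] = _BASES[alt_i]
    out["alt2"] = np.where(multi, _BASES[np.maximum(alt2_i, 0)], "")
    out["multiallelic"] = multi

    for tag, idx in (("low", low_idx), ("high", high_idx)):
        freq = genotypes.genotypes[idx].mean(axis=0) / 2.0
        if config.depth_dispersion > 0:
            shape = 1.0 / config.depth_dispersion
            lam = config.mean_depth * rng.gamma(shape, 1.0 / shape, size=m)
        else:
            lam = np.full(m, config.mean_depth)
        depth = rng.poisson(lam)
        alt_d = rng.binomial(depth, freq)
        ref_d = depth - alt_d
        alt2_d = np.zeros(m, dtype=np.int64)
        if multi.any():
            alt2_d[multi] = rng.binomial(ref_d[multi], 0.05)
            ref_d = ref_d - alt2_d
        missing = rng.random(m) < config.missing_rate
        for arr in (ref_d, alt_d, alt2_d):
            arr[missing] = 0
        out[f"ref_depth_{tag}"] = ref_d
        out[f"alt_depth_{tag}"] = alt_d
        out[f"alt2_depth_{tag}"] = alt2_d
        out[f"missing_{tag}"] = missing

    cols = [
        "chrom", "pos", "ref", "alt", "alt2",
        "ref_depth_low", "alt_depth_low", "alt2_depth_low",
        "ref_depth_high", "alt_depth_high", "alt2_depth_high",
        "missing_low", "missing_high", "multiallelic",
    ]
    return pd.DataFrame(out)[cols]


def simulate_inbred_panel(n_lines: int = 181, n_plants: int = 1408,
                          var_line: float = 1.0, var_res: float = 3.0,
                          mean: float = 18.0, seed: int = 0) -> pd.DataFrame:
    """Line-replicate phenotyping trial with random line effects.

    value = mean + line effect (N(0, var_line)) + residual (N(0, var_res));
    plants are spread round-robin over lines, so group sizes differ by at most
    one.  Returns columns line, value — the input shape the heritability
    estimator expects.
    """
    if n_lines < 2 or n_plants < n_lines:
        raise ConfigError("need >= 2 lines and at least one plant per line")
    rng = np.random.default_rng(seed)
    line_idx = np.arange(n_plants) % n_lines
    line_eff = rng.normal(0.0, np.sqrt(var_line), size=n_lines)
    value = mean + line_eff[line_idx] + rng.normal(0.0, np.sqrt(var_res), size=n_plants)
    return pd.DataFrame({"line": [f"L{i + 1:03d}" for i in line_idx], "value": value})
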