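"""Phenotype-side statistics: RAS/RT ratio, block ANOVA and bulk selection,
broad-sense heritability, trait correlations, and mycorrhizal colonization
scores.

The rhizosheath-size phenotype is the ratio of root-adhering soil dry mass
(RAS, g) to root tissue dry mass (RT, g).  Analysis of variance is run on the
natural log of the ratio; the residuals of the block model rank the F2
individuals for bulk selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InvalidSampleError


def ras_rt_ratio(ras_g, rt_g):
    """RAS/RT: root-adhering soil mass over root tissue mass.

    Accepts scalars or arrays; every root-tissue mass must be positive.
    """
    rt = np.asarray(rt_g, dtype=float)
    if np.any(rt <= 0):
        raise InvalidSampleError("root tissue mass must be > 0")
    out = np.asarray(ras_g, dtype=float) / rt
    return float(out) if out.ndim == 0 else out


@dataclass
class BlockModel:
    """One-way fixed-effect ANOVA of log(RAS/RT) on phenotyping block."""

    table: pd.DataFrame          # input rows + ratio, log_ratio, residual
    block_effects: pd.Series     # per-block mean of log(ratio)
    f_stat: float                # nan when the F statistic is undefined
    p_value: float
    n_excluded: int              # rows dropped for nonpositive ratio


def fit_block_model(table: pd.DataFrame, block_col: str = "block",
                    ras_col: str = "ras_g", rt_col: str = "rt_g") -> BlockModel:
    """Fit block means to log(RAS/RT) and attach residuals.

    Rows with nonpositive ratio cannot be log-transformed; they are excluded
    and counted.  Residuals are log(ratio) minus the fitted block mean, so
    they sum to zero within each block.  With all observations identical the
    F statistic is undefined and reported as NaN.
    """
    t = table.copy()
    if t[block_col].nunique() < 2:
        raise ConfigError("block model needs >= 2 blocks")
    t["ratio"] = np.asarray(t[ras_col], dtype=float) / np.asarray(t[rt_col], dtype=float)
    ok = (t["ratio"] > 0) & np.isfinite(t["ratio"])
    n_excluded = int((~ok).sum())
    t = t[ok].copy()
    if (t.groupby(block_col).size() < 1).any() or t[block_col].nunique() < 2:
        raise ConfigError("every block must retain at least one usable row")
    t["log_ratio"] = np.log(t["ratio"])
    means = t.groupby(block_col)["log_ratio"].mean()
    t["residual"] = t["log_ratio"] - t[block_col].map(means)
    groups = [g.to_numpy() for _, g in t.groupby(block_col)["log_ratio"]]
    if all(np.ptp(g) == 0 for g in groups) and np.ptp(t["log_ratio"]) == 0:
        f, p = float("nan"), float("nan")
    else:
        with np.errstate(invalid="ignore"):
            f, p = stats.f_oneway(*groups)
    return BlockModel(table=t, block_effects=means, f_stat=float(f),
                      p_value=float(p), n_excluded=n_excluded)


def select_bulks(table: pd.DataFrame, tail_fraction: float = 0.10,
                 residual_col: str = "residual", id_col: str = "id"):
    """Pick the two phenotypic-extreme bulks from block-model residuals.

    k = round(tail_fraction * n) ids with the smallest residuals form the low
    bulk and the k largest the high bulk (547 rows at the default 10% tail
    give bulks of 55).  Ties are broken by id order, so the selection is
    deterministic.  Returns (low_ids, high_ids).
    """
    if not (0.0 < tail_fraction < 0.5):
        raise ConfigError("tail_fraction must lie in (0, 0.5)")
    if residual_col not in table:
        raise ConfigError("residuals must be computed before bulk selection")
    n = len(table)
    k = int(np.rint(tail_fraction * n))
    if k == 0:
        raise ConfigError(f"tail of {tail_fraction} on {n} rows selects nobody")
    if 2 * k > n:
        raise ConfigError("bulks would overlap; reduce tail_fraction")
    order = table.sort_values([residual_col, id_col], kind="mergesort")
    low = order[id_col].head(k).tolist()
    high = order[id_col].tail(k).tolist()
    return low, high


@dataclass
class HeritabilityResult:
    """Variance components and broad-sense heritability.

    h2 = Var(line) / (Var(line) + Var(res) / n_plant_per_line), with
    n_plant_per_line the average number of plants measured per line.
    """

    var_line: float
    var_res: float
    n_plant_per_line: float
    h2: float
    method: str = "anova"


def heritability(table: pd.DataFrame, line_col: str = "line",
                 value_col: str = "value", method: str = "anova") -> HeritabilityResult:
    """Estimate broad-sense heritability from a line-replicate trial.

    The one-way random-effects model value = mu + line + residual is fitted
    either by the ANOVA method of moments (default; negative line variance is
    truncated to zero, and the standard effective replicate number
    n0 = (N - sum n_i^2 / N) / (k - 1) handles unbalanced designs) or by REML
    through ``statsmodels`` MixedLM (``method="reml"``).  h2 then follows the
    plug-in formula with the *average* plants-per-line in the denominator.
    """
    groups = table.groupby(line_col)[value_col]
    sizes = groups.size()
    k = len(sizes)
    if k < 2:
        raise ConfigError("heritability needs >= 2 lines")
    N = int(sizes.sum())
    if N <= k:
        raise ConfigError("residual variance inestimable with one plant per line")
    n_bar = N / k

    if method == "anova":
        y = table[value_col].to_numpy(dtype=float)
        grand = y.mean()
        means = groups.mean()
        ssb = float((sizes * (means - grand) ** 2).sum())
        ssw = float(((table[value_col] - table[line_col].map(means)) ** 2).sum())
        msb = ssb / (k - 1)
        msw = ssw / (N - k)
        n0 = (N - float((sizes ** 2).sum()) / N) / (k - 1)
        var_line = max((msb - msw) / n0, 0.0)
        var_res = msw
    elif method == "reml":
        import statsmodels.formula.api as smf

        df = table[[line_col, value_col]].rename(
            columns={line_col: "line", value_col: "value"}
        )
        fit = smf.mixedlm("value ~ 1", df, groups=df["line"]).fit(reml=True)
        var_line = float(fit.cov_re.iloc[0, 0])
        var_res = float(fit.scale)
    else:
        raise ConfigError(f"unknown heritability method {method!r}")

    denom = var_line + var_res / n_bar
    h2 = var_line / denom if denom > 0 else 0.0
    return HeritabilityResult(var_line=var_line, var_res=var_res,
                              n_plant_per_line=n_bar, h2=h2, method=method)


@dataclass
class CorrelationResult:
    """Pairwise trait correlations with p-values and squared coefficients."""

    corr: pd.DataFrame
    p_values: pd.DataFrame
    r2: pd.DataFrame
    method: str


def trait_correlations(matrix: pd.DataFrame, method: str = "spearman") -> CorrelationResult:
    """Pairwise correlation matrix over per-line trait means.

    Spearman (rank) correlation is the default; Pearson is available for
    comparison with adjusted-mean analyses.  Each pair uses its complete
    cases and needs at least 3 of them; a constant trait has no defined
    correlation and is reported as NaN.  r2 is the elementwise square.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigError(f"unknown correlation method {method!r}")
    cols = list(matrix.columns)
    p = len(cols)
    corr = np.full((p, p), np.nan)
    pval = np.full((p, p), np.nan)
    test = stats.spearmanr if method == "spearman" else stats.pearsonr
    for i in range(p):
        for j in range(i, p):
            x = matrix[cols[i]].to_numpy(dtype=float)
            y = matrix[cols[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
                continue
            if i == j:
                corr[i, j], pval[i, j] = 1.0, 0.0
                continue
            r, pv = test(x[ok], y[ok])
            corr[i, j] = corr[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(pv)
    corr_df = pd.DataFrame(corr, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    return CorrelationResult(corr=corr_df, p_values=p_df, r2=corr_df ** 2, method=method)


def adjusted_line_means(table: pd.DataFrame, line_col: str, group_col: str,
                        value_col: str) -> pd.Series:
    """Least-square (adjusted) mean per line across experiments.

    Fits the two-way fixed-effect model value ~ line + group and averages the
    fitted values for each line over *all* groups, which removes the
    experiment effect from unbalanced designs.
    """
    import statsmodels.formula.api as smf

    df = table[[line_col, group_col, value_col]].dropna().rename(
        columns={line_col: "line", group_col: "grp", value_col: "value"}
    )
    fit = smf.ols("value ~ C(line) + C(grp)", df).fit()
    lines = sorted(df["line"].unique())
    grps = sorted(df["grp"].unique())
    grid = pd.DataFrame(
        [(l, g) for l in lines for g in grps], columns=["line", "grp"]
    )
    grid["pred"] = fit.predict(grid)
    out = grid.groupby("line")["pred"].mean()
    out.name = value_col
    return out


@dataclass(frozen=True)
class MycorrhizaCounts:
    """Scored root fragments for arbuscular-mycorrhizal colonization.

    ``n1``..``n5`` count fragments with colonization score 1-5 (rising
    proportion of colonized cortex), ``n_mycorrhizal`` counts fragments
    showing any mycorrhizae, and ``n_total`` is the number observed.
    """

    n1: int = 0
    n2: int = 0
    n3: int = 0
    n4: int = 0
    n5: int = 0
    n_mycorrhizal: int = 0
    n_total: int = 0

    def __post_init__(self):
        vals = (self.n1, self.n2, self.n3, self.n4, self.n5,
                self.n_mycorrhizal, self.n_total)
        if any(v < 0 for v in vals):
            raise ConfigError("fragment counts must be >= 0")
        if self.n_total == 0:
            raise ConfigError("no observed fragments (N = 0)")
        if self.n_mycorrhizal > self.n_total:
            raise ConfigError("mycorrhizal fragments exceed observed fragments")
        if self.n1 + self.n2 + self.n3 + self.n4 + self.n5 > self.n_total:
            raise ConfigError("scored fragments exceed observed fragments")


def mycorrhiza_scores(counts: MycorrhizaCounts) -> tuple[float, float]:
    """Frequency and intensity of root colonization, both in percent.

    F = n / N * 100 and I = (95 n5 + 70 n4 + 30 n3 + 5 n2 + n1) / N, where n
    is the number of fragments showing mycorrhizae out of N observed.
    """
    c = counts
    f = c.n_mycorrhizal / c.n_total * 100.0
    i = (95 * c.n5 + 70 * c.n4 + 30 * c.n3 + 5 * c.n2 + c.n1) / c.n_total
    return f, i
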