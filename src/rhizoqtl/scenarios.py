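"""Canned validation scenarios: desk-scale end-to-end runs of the pipeline.

These drive the full simulate -> phenotype -> bulks -> reads -> filter ->
scan -> threshold -> regions chain at sizes a workstation handles in seconds,
and summarize operating characteristics (QTL localization, family-wise
false-positive calibration, heritability recovery).  The desk-scale genome is
two 40 Mbp chromosomes of 2,000 markers each at 1 cM/Mbp — roughly the
average pearl-millet recombination rate — with a single additive QTL
mid-chromosome 1 and pooled depth 200X.
"""

from __future__ import annotations

import numpy as np

from . import filtering, phenotype, regions as regions_mod, scan, simulate

DESK_QTL_POS = 20_000_000
DESK_QTL_CHROM = "chr1"


def desk_scale_config(seed: int, qtl_effect: float = 1.0,
                      h2: float = 0.25) -> simulate.SimConfig:
    """Desk-scale one-QTL design: 547 F2, 2 x 40 Mbp x 2,000 markers, 200X."""
    return simulate.SimConfig(
        n_chromosomes=2,
        chrom_lengths_bp=(40e6, 40e6),
        map_lengths_morgans=(0.4, 0.4),
        n_markers_per_chrom=2000,
        n_f2=547,
        qtls=[(1, DESK_QTL_POS, qtl_effect, 0.0)],
        heritability_target=h2,
        mean_depth=200,
        depth_dispersion=0.0,
        missing_rate=0.0,
        multiallelic_rate=0.0,
        seed=seed,
    )


def run_bsa_once(config: simulate.SimConfig, threshold_seed: int,
                 n_null_sims: int = 200, alpha: float = 0.05) -> dict:
    """One full BSA pass; returns peak location, regions and QTL coverage."""
    geno = simulate.simulate_f2(config)
    pheno = simulate.simulate_phenotypes(geno, config)
    model = phenotype.fit_block_model(pheno)
    low, high = phenotype.select_bulks(model.table)
    reads = simulate.simulate_bulk_reads(geno, low, high, config)
    filtered, _ = filtering.filter_cascade(reads)
    prof = scan.ed_profile(filtered)
    dl = (filtered["ref_depth_low"] + filtered["alt_depth_low"]).to_numpy()
    dh = (filtered["ref_depth_high"] + filtered["alt_depth_high"]).to_numpy()
    thr = scan.significance_threshold(
        filtered["chrom"].to_numpy(), dl, dh, bulk_size=len(low),
        n_sims=n_null_sims, alpha=alpha, seed=threshold_seed,
    )
    prof = scan.mark_significant(prof, thr)
    called = regions_mod.call_regions(prof)
    peak_row = prof.loc[prof["ed4"].idxmax()]
    covered = any(
        r.chrom == DESK_QTL_CHROM and r.start_bp <= DESK_QTL_POS <= r.end_bp
        for r in called
    )
    peak_dist = (
        abs(int(peak_row["pos"]) - DESK_QTL_POS)
        if peak_row["chrom"] == DESK_QTL_CHROM
        else np.inf
    )
    return {
        "regions": called,
        "qtl_covered": covered,
        "peak_chrom": peak_row["chrom"],
        "peak_dist_bp": peak_dist,
        "threshold": thr.value,
        "bulk_size": len(low),
    }


def qtl_recovery(n_runs: int = 100, seed: int = 0) -> dict:
    """Repeat the desk-scale one-QTL scan; rates of QTL coverage and of the
    global peak landing within 2 Mbp of the truth, in percent."""
    covered = 0
    near_peak = 0
    for i in range(n_runs):
        cfg = desk_scale_config(seed=seed * n_runs + i)
        out = run_bsa_once(cfg, threshold_seed=seed * n_runs + i + 10_000)
        covered += out["qtl_covered"]
        near_peak += out["peak_dist_bp"] <= 2_000_000
    return {
        "n_runs": n_runs,
        "coverage_pct": 100.0 * covered / n_runs,
        "peak_within_2mbp_pct": 100.0 * near_peak / n_runs,
    }


def fwer_calibration(seed: int = 0, n_threshold_sims: int = 1000,
                     n_eval_genomes: int = 200, n_markers_per_chrom: int = 2000,
                     n_chromosomes: int = 2, depth: int = 200,
                     bulk_size: int = 55, alpha: float = 0.05) -> dict:
    """Family-wise false-positive rate of the genome-max threshold on fresh
    no-QTL genomes drawn from the same marker-by-marker null, in percent."""
    chroms = np.repeat([f"chr{i + 1}" for i in range(n_chromosomes)],
                       n_markers_per_chrom)
    d = np.full(chroms.size, depth)
    thr = scan.significance_threshold(
        chroms, d, d, bulk_size=bulk_size, n_sims=n_threshold_sims,
        alpha=alpha, seed=seed,
    )
    fresh = scan.simulate_null_maxima(
        chroms, d, d, bulk_size=bulk_size, n_sims=n_eval_genomes,
        seed=seed + 1,
    )
    return {
        "n_eval_genomes": n_eval_genomes,
        "threshold": thr.value,
        "fwer_pct": 100.0 * float(np.mean(fresh >= thr.value)),
    }


def heritability_recovery(n_reps: int = 200, seed: int = 0,
                          n_lines: int = 181, n_plants: int = 1408,
                          var_line: float = 1.0, var_res: float = 3.0) -> dict:
    """Mean broad-sense heritability estimate over replicate line trials.

    The defaults generate H2 = 1 / (1 + var_res / (n_plants / n_lines)) = 0.72
    at the published design scale (181 lines, 1,408 plants).
    """
    estimates = [
        phenotype.heritability(
            simulate.simulate_inbred_panel(
                n_lines, n_plants, var_line, var_res, seed=seed * n_reps + i
            )
        ).h2
        for i in range(n_reps)
    ]
    n_bar = n_plants / n_lines
    return {
        "n_reps": n_reps,
        "generating_h2": var_line / (var_line + var_res / n_bar),
        "mean_h2": float(np.mean(estimates)),
        "sd_h2": float(np.std(estimates)),
    }
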