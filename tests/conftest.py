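import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import rhizoqtl as rq

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Tiny two-chromosome design that runs in well under a second."""
    return rq.SimConfig(
        n_chromosomes=2,
        chrom_lengths_bp=(40e6, 40e6),
        map_lengths_morgans=(0.4, 0.4),
        n_markers_per_chrom=300,
        n_f2=200,
        qtls=[(1, 20_000_000, 0.6, 0.0)],
        heritability_target=0.4,
        mean_depth=200,
        depth_dispersion=0.1,
        missing_rate=0.02,
        multiallelic_rate=0.02,
        seed=11,
    )


def _site(chrom="chr1", pos=1000, ref="A", alt="C", rl=50, al=50, rh=50, ah=50,
          missing_low=False, missing_high=False, multiallelic=False, alt2=""):
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt, "alt2": alt2,
        "ref_depth_low": rl, "alt_depth_low": al, "alt2_depth_low": 0,
        "ref_depth_high": rh, "alt_depth_high": ah, "alt2_depth_high": 0,
        "missing_low": missing_low, "missing_high": missing_high,
        "multiallelic": multiallelic,
    }


@pytest.fixture
def make_site():
    return _site


@pytest.fixture
def toy_cascade_table():
    """Ten sites, one violation per filter rule; exactly 3 clean sites.

    Layout: 2 multiallelic, 1 low pooled alternate frequency, 1 low-depth and
    1 high-depth outlier, 1 site missing in one bulk, 1 rare-MAF site, and
    3 clean sites of total depth 200 each.
    """
    rows = [
        _site(pos=1000, multiallelic=True, alt2="G"),
        _site(pos=2000, multiallelic=True, alt2="T"),
        _site(pos=3000, rl=90, al=10, rh=90, ah=10),            # pooled alt 0.10
        _site(pos=4000, rl=5, al=5, rh=5, ah=5),                # total depth 20
        _site(pos=5000, rl=2500, al=2500, rh=2500, ah=2500),    # total depth 10000
        _site(pos=6000, rl=0, al=0, rh=100, ah=100, missing_low=True),
        _site(pos=7000, rl=2, al=98, rh=2, ah=98),              # pooled MAF 0.02
        _site(pos=8000),
        _site(pos=9000),
        _site(pos=10000),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def flat_marker_map():
    """Builder for a hand-specified marker map."""

    def build(pos_bp, pos_morgans, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "pos_bp": np.asarray(pos_bp, dtype=np.int64),
             "pos_morgans": np.asarray(pos_morgans, dtype=float)}
        )

    return build
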