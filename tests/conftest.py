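import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from mutaflux import (
    FilterConfig,
    SignatureCatalog,
    VariantRecord,
    bundled_signature_catalog,
)
from mutaflux.fluctuation import FluctuationExperiment, ld_pmf


@pytest.fixture(scope="session")
def signature_catalog() -> SignatureCatalog:
    return bundled_signature_catalog()


def make_variant(pos, ref="C", alt="A", tumor=40, normal=30, vaf=0.5, flags=(),
                 chrom="chr1"):
    return VariantRecord(
        chrom=chrom, pos=pos, ref_base=ref, alt_base=alt,
        tumor_depth=tumor, normal_depth=normal, vaf=vaf,
        db_flags=frozenset(flags),
    )


@pytest.fixture
def ten_record_fixture():
    """10 exome records: 3 low-depth, 2 database-flagged, 1 low-VAF, 4 clean."""
    return [
        make_variant(100, tumor=29, normal=30),           # tumor depth below 30
        make_variant(200, tumor=40, normal=19),           # normal depth below 20
        make_variant(300, tumor=10, normal=10),           # both below
        make_variant(400, flags=("DBSNP",)),              # database member
        make_variant(500, flags=("KG", "ESP")),           # database member
        make_variant(600, vaf=0.03),                      # below 5% VAF floor
        make_variant(700),
        make_variant(800, ref="T", alt="G"),
        make_variant(900, ref="G", alt="T"),
        make_variant(1000, ref="A", alt="C"),
    ]


def grid_argmax_m(experiment: FluctuationExperiment, grid=None) -> float:
    """Brute-force MSS likelihood maximizer over an m grid (step 0.001).

    Independent oracle for the MLE: evaluates the pmf recursion for every
    grid value directly and returns the argmax of the log-likelihood,
    breaking ties toward smaller m.
    """
    if grid is None:
        grid = np.arange(0.001, 10.0 + 1e-12, 0.001)
    counts = np.asarray(experiment.culture_counts)
    censored = experiment.censored_mask()
    k_max = int(counts.max(initial=0))
    n_m = len(grid)
    # pmf for all grid m values at once: p[j, k]
    p = np.zeros((n_m, k_max + 1))
    p[:, 0] = np.exp(-grid)
    inv = 1.0 / np.arange(1, k_max + 2)
    for k in range(1, k_max + 1):
        p[:, k] = (grid / k) * (p[:, :k] @ inv[k:0:-1])
    p = np.clip(p, 1e-300, None)
    ll = np.log(p[:, counts[~censored]]).sum(axis=1)
    if censored.any():
        cap = experiment.censor_cap
        tail = np.clip(1.0 - p[:, :cap].sum(axis=1), 1e-300, None)
        ll = ll + censored.sum() * np.log(tail)
    return float(grid[np.argmax(ll)])
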