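import numpy as np
import pytest

from varforest.io import MISSING, Pedigree, Sex, VariantRecord
from varforest.simulate import SimulationConfig, simulate_cohort


def make_record(genotypes, chrom="1", pos=100, ref="A", alts=("G",),
                dp=None, gq=None, ad=None):
    """Build a VariantRecord from compact genotype tuples.

    ``genotypes`` is a list of (a, b) allele-index pairs; None means a
    fully missing genotype.  dp/gq are per-sample ints (None -> missing),
    ad a list of per-sample allele-count tuples (None -> missing row).
    """
    n = len(genotypes)
    gts = np.full((n, 2), MISSING, dtype=np.int16)
    for i, g in enumerate(genotypes):
        if g is not None:
            gts[i] = g
    n_alleles = 1 + len(alts)

    def _vec(vals):
        out = np.full(n, MISSING, dtype=np.int32)
        if vals is not None:
            for i, v in enumerate(vals):
                if v is not None:
                    out[i] = v
        return out

    ad_arr = None
    if ad is not None:
        ad_arr = np.full((n, n_alleles), MISSING, dtype=np.int32)
        for i, row in enumerate(ad):
            if row is not None:
                ad_arr[i] = row
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=list(alts),
                         genotypes=gts, dp=_vec(dp), gq=_vec(gq), ad=ad_arr)


def make_trio_pedigree(n_trios=1):
    """Pedigree of n_trios families; sample order fa, mo, ch per family."""
    individuals = []
    for f in range(n_trios):
        individuals += [
            (f"fa{f}", None, None, Sex.MALE),
            (f"mo{f}", None, None, Sex.FEMALE),
            (f"ch{f}", f"fa{f}", f"mo{f}", Sex.MALE),
        ]
    return Pedigree(individuals)


@pytest.fixture
def trio_ped():
    return make_trio_pedigree(1)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact but fully featured synthetic cohort, shared per session."""
    out = tmp_path_factory.mktemp("cohort")
    cfg = SimulationConfig(n_variants=600, n_families=12,
                           chrom_length=200_000, seed=11)
    paths = simulate_cohort(cfg, out)
    return cfg, paths
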