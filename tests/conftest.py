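import numpy as np
import pytest

import famcensor as fc
from famcensor.family_data import (
    CensoredPhenotype,
    CohortDataset,
    GenotypeMatrix,
    Pedigree,
    PedigreeRecord,
    ROLE_FATHER,
    ROLE_MOTHER,
    ROLE_OFFSPRING,
)

import pandas as pd


def make_trio_cohort(scores_father, scores_mother, scores_off, times=None, events=None,
                     population_maf=None):
    """Build a trio cohort from per-family genotype rows (lists of k-vectors)."""
    n = len(scores_off)
    k = len(scores_off[0])
    records, subj_ids, rows = [], [], []
    for i in range(n):
        fid, f, m, o = f"F{i}", f"F{i}_P", f"F{i}_M", f"F{i}_O"
        records += [
            PedigreeRecord(fid, f, None, None, 1, ROLE_FATHER),
            PedigreeRecord(fid, m, None, None, 2, ROLE_MOTHER),
            PedigreeRecord(fid, o, f, m, 0, ROLE_OFFSPRING),
        ]
        subj_ids += [f, m, o]
        rows += [scores_father[i], scores_mother[i], scores_off[i]]
    vids = [f"v{j}" for j in range(k)]
    maf = population_maf if population_maf is not None else np.full(k, 0.005)
    meta = pd.DataFrame(
        {"position": np.arange(1, k + 1), "minor_allele": "T", "ref": "A",
         "alt": "T", "minor_is_alt": True, "population_maf": maf, "chrom": "1"},
        index=vids,
    )
    geno = GenotypeMatrix(subj_ids, vids, np.array(rows, dtype=float), meta)
    pheno = None
    if times is not None:
        off_ids = [f"F{i}_O" for i in range(n)]
        pheno = CensoredPhenotype(off_ids, np.asarray(times, float),
                                  np.asarray(events, int), np.empty((n, 0)))
    return CohortDataset(Pedigree(records), geno, pheno)


def make_sibship_cohort(sib_scores, times=None, events=None):
    """Parentless sibships: sib_scores is a list of (n_i x k) arrays."""
    records, subj_ids, rows = [], [], []
    for i, fam in enumerate(sib_scores):
        for j, row in enumerate(fam):
            iid = f"F{i}_S{j}"
            records.append(PedigreeRecord(f"F{i}", iid, None, None, 0, ROLE_OFFSPRING))
            subj_ids.append(iid)
            rows.append(row)
    k = len(rows[0])
    vids = [f"v{j}" for j in range(k)]
    meta = pd.DataFrame(
        {"position": np.arange(1, k + 1), "minor_allele": "T", "ref": "A",
         "alt": "T", "minor_is_alt": True, "population_maf": np.full(k, 0.005),
         "chrom": "1"},
        index=vids,
    )
    geno = GenotypeMatrix(subj_ids, vids, np.array(rows, dtype=float), meta)
    pheno = None
    if times is not None:
        pheno = CensoredPhenotype(list(subj_ids), np.asarray(times, float),
                                  np.asarray(events, int),
                                  np.empty((len(subj_ids), 0)))
    return CohortDataset(Pedigree(records), geno, pheno)


@pytest.fixture(scope="session")
def small_pool():
    """A small haplotype pool for fast unit tests."""
    return fc.generate_haplotype_pool(
        n_haplotypes=2000, n_segments=20, n_exons=5, sites_per_segment_mean=6,
        seed=101,
    )


@pytest.fixture(scope="session")
def null_trio_cohort(small_pool):
    """300 trios with null censored traits attached."""
    cohort = fc.sample_trio_cohort(small_pool, 300, seed=5)
    mafs = cohort.genotypes.variant_meta["population_maf"].to_numpy(float)
    cfg = fc.SimulationConfig(n_trios=300, censoring_rate=0.3)
    cohort.phenotypes = fc.simulate_traits(cohort, mafs, cfg, "null", seed=6)
    return cohort


@pytest.fixture(scope="session")
def common_variant_cohort(small_pool):
    """400 trios keeping all (also common) sites: enough minor-allele
    carriers for asymptotic (CLT-regime) calibration checks."""
    cohort = fc.sample_trio_cohort(small_pool, 400, seed=15, rare_maf_threshold=0.5)
    mafs = cohort.genotypes.variant_meta["population_maf"].to_numpy(float)
    cfg = fc.SimulationConfig(n_trios=400, censoring_rate=0.3)
    cohort.phenotypes = fc.simulate_traits(cohort, mafs, cfg, "null", seed=16)
    return cohort
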