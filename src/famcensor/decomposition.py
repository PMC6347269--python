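"""Orthogonal between/within-family decomposition of offspring genotypes.

Following the Fulker/Abecasis construction, each offspring genotype score
splits into a between-family component ``G_b`` (the parental mean when both
parents are genotyped, else the sibship mean) and a within-family component
``G_w = G - G_b``.  ``G_b`` carries population-level allele-frequency
variation (and hence any stratification); ``G_w`` reflects Mendelian
transmission only, so association tests built on it are robust to
population structure.

Missing data rule: a family with any missing parent/offspring call at a
variant is excluded from that variant (both components set missing) —
the decomposition formulas assume complete data within the family.
Mendelian-inconsistent cells are likewise excluded, with a warning.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .family_data import CohortDataset

logger = logging.getLogger(__name__)

RULE_PARENTAL = "parental_mean"
RULE_SIBSHIP = "sibship_mean"


@dataclass
class DecomposedGenotypes:
    """Between- and within-family score matrices over offspring.

    ``G_b + G_w`` reconstructs the raw offspring score wherever defined;
    within a family all ``G_b`` rows are identical, and under the sibship
    rule the ``G_w`` rows of a family sum to zero per variant.
    """

    offspring_ids: list[str]
    variant_ids: list[str]
    G_b: np.ndarray  # N_off x k, NaN where excluded
    G_w: np.ndarray  # N_off x k
    family_index: np.ndarray  # int family index per offspring row
    rule_used: dict[str, str]  # family_id -> rule

    @property
    def n_families(self) -> int:
        return int(self.family_index.max()) + 1 if len(self.family_index) else 0

    def family_between(self) -> np.ndarray:
        """One G_b row per family (n_families x k)."""
        first = np.zeros(self.n_families, dtype=int)
        seen = np.zeros(self.n_families, dtype=bool)
        for row, fam in enumerate(self.family_index):
            if not seen[fam]:
                first[fam] = row
                seen[fam] = True
        return self.G_b[first]


def _mendel_consistent(gf: np.ndarray, gm: np.ndarray, go: np.ndarray) -> np.ndarray:
    """Elementwise check that offspring minor-allele count is attainable
    from the parents: each parent transmits 0 (g=0), 0/1 (g=1) or 1 (g=2)."""
    lo = (gf == 2).astype(float) + (gm == 2).astype(float)
    hi = (gf > 0).astype(float) + (gm > 0).astype(float)
    return (go >= lo) & (go <= hi)


def decompose(cohort: CohortDataset) -> DecomposedGenotypes:
    """Split offspring scores into ``G_b`` and ``G_w`` per family.

    Families must have either both parents genotyped or neither; a single
    genotyped parent is rejected (no half-imputation).
    """
    ped = cohort.pedigree
    geno = cohort.genotypes
    off_ids = ped.offspring_ids
    k = len(geno.variant_ids)
    n_off = len(off_ids)
    G_b = np.full((n_off, k), np.nan)
    G_w = np.full((n_off, k), np.nan)
    fam_index = cohort.family_of_offspring()
    rule_used: dict[str, str] = {}
    n_mendel = 0

    row_of = {s: i for i, s in enumerate(off_ids)}
    for fid in ped.family_ids:
        par = ped.parents(fid)
        f_geno = par["father"] is not None and geno.has_subject(par["father"])
        m_geno = par["mother"] is not None and geno.has_subject(par["mother"])
        rows = np.array([row_of[r.individual_id] for r in ped.offspring(fid)])
        G_off = np.vstack([geno.row(off_ids[r]) for r in rows])
        if f_geno != m_geno:
            raise ValueError(
                f"family {fid}: exactly one parent genotyped; decomposition "
                "requires both parents or neither"
            )
        if f_geno:
            rule_used[fid] = RULE_PARENTAL
            gf = geno.row(par["father"])
            gm = geno.row(par["mother"])
            ok = ~np.isnan(gf) & ~np.isnan(gm) & ~np.isnan(G_off).any(axis=0)
            consistent = np.ones(k, dtype=bool)
            with np.errstate(invalid="ignore"):
                cons_mat = _mendel_consistent(gf[None, :], gm[None, :], G_off)
            consistent[ok] = cons_mat[:, ok].all(axis=0)
            bad = ok & ~consistent
            if bad.any():
                n_mendel += int(bad.sum())
                ok &= consistent
            gb = np.where(ok, (gf + gm) / 2.0, np.nan)
            G_b[rows] = gb
            G_w[rows] = G_off - gb
        else:
            rule_used[fid] = RULE_SIBSHIP
            ok = ~np.isnan(G_off).any(axis=0)
            gb = np.where(ok, G_off.mean(axis=0), np.nan)
            G_b[rows] = gb
            G_w[rows] = G_off - gb
    if n_mendel:
        logger.warning(
            "excluded %d family-variant cell(s) with Mendelian inconsistencies",
            n_mendel,
        )
    return DecomposedGenotypes(
        offspring_ids=list(off_ids),
        variant_ids=list(geno.variant_ids),
        G_b=G_b,
        G_w=G_w,
        family_index=fam_index,
        rule_used=rule_used,
    )


def sample_maf_from_between(decomp: DecomposedGenotypes) -> np.ndarray:
    """Sample MAF estimated from the between-family component:
    ``p_hat_m = sum_i G_bi,m / (2 n)`` over families with data, clamped to
    ``[eps, 1 - eps]`` with ``eps = 1/(4 n)`` so weight functions stay finite.
    """
    fam_gb = decomp.family_between()  # n_fam x k
    n_fam = fam_gb.shape[0]
    n_obs = np.sum(~np.isnan(fam_gb), axis=0)
    if np.any(n_obs == 0):
        bad = [decomp.variant_ids[j] for j in np.flatnonzero(n_obs == 0)]
        raise ValueError(f"variant(s) missing in all families: {bad[:5]}")
    p_hat = np.nansum(fam_gb, axis=0) / (2.0 * n_obs)
    eps = 1.0 / (4.0 * n_fam)
    return np.clip(p_hat, eps, 1.0 - eps)
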