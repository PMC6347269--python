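"""Variant weights, the FamBAC burden test and the FamKAC kernel test.

FamBAC collapses weighted efficient scores within subject first::

    T = (sum_i sum_m w_m S_wim)^2 / sum_i (sum_m w_m S_wim)^2  ~  chi2(1)

FamKAC sums squared per-variant aggregates::

    T = sum_m w_m^2 (sum_i S_wim)^2  ~  sum_m lambda_m chi2(1)

with ``lambda`` the eigenvalues of ``n W C W`` (``C`` the sample covariance
of the rows of ``S_w``; the symmetric form has the same spectrum as
``n W^2 C`` for diagonal ``W`` and better numerics).  FamKAC p-values come
from the mixture tail (Davies-style inversion) or from gene-drop
permutation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from .decomposition import RULE_PARENTAL, DecomposedGenotypes
from .efficient_scores import (
    EfficientScoreMatrix,
    efficient_score_matrix,
    score_components,
)
from .family_data import CohortDataset
from .frailty_null import NullFrailtyFit
from .quadform import davies_pvalue
from .riskset import SurvivalContext

logger = logging.getLogger(__name__)

EIGEN_TRUNC = 1e-10  # relative eigenvalue cutoff before the mixture tail


@dataclass(frozen=True)
class WeightSpec:
    """Variant weighting scheme.  Weights never use phenotypes."""

    scheme: str = "none"  # none | madsen_browning | beta
    maf_source: str = "population"  # population | sample
    beta_params: tuple[float, float] = (1.0, 25.0)

    def __post_init__(self):
        if self.scheme not in ("none", "madsen_browning", "beta"):
            raise ValueError(f"unknown weight scheme {self.scheme!r}")
        if self.maf_source not in ("population", "sample"):
            raise ValueError(f"unknown maf_source {self.maf_source!r}")
        if min(self.beta_params) <= 0:
            raise ValueError("beta_params must be positive")

    @property
    def label(self) -> str:
        tag = {"none": "w0", "madsen_browning": "wMB", "beta": "wBeta"}[self.scheme]
        if self.scheme == "none":
            return tag
        return f"{tag}[{'pop' if self.maf_source == 'population' else 'hat'}]"


@dataclass
class TestResult:
    method: str  # FamBAC | FamKAC
    statistic: float
    p_value: float
    pvalue_method: str  # chi2 | davies | permutation
    df_or_eigenvalues: object = None
    n_families: Optional[int] = None
    n_variants: Optional[int] = None
    weight: Optional[WeightSpec] = None
    warnings: list = field(default_factory=list)


def compute_weights(maf: np.ndarray, spec: WeightSpec) -> np.ndarray:
    """Evaluate the weight function at per-variant MAFs in (0, 1).

    none -> 1; madsen_browning -> 1/sqrt(p(1-p));
    beta -> Beta(a, b) density at p (default Beta(1, 25) = 25 (1-p)^24).
    """
    p = np.asarray(maf, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("MAF values must lie strictly in (0, 1)")
    if spec.scheme == "none":
        return np.ones_like(p)
    if spec.scheme == "madsen_browning":
        return 1.0 / np.sqrt(p * (1.0 - p))
    a, b = spec.beta_params
    return beta_dist.pdf(p, a, b)


def fambac(esm: EfficientScoreMatrix, w: np.ndarray, **meta) -> TestResult:
    """Burden test; chi-square(1) p-value."""
    w = np.asarray(w, float)
    if len(w) != esm.n_variants:
        raise ValueError("weight vector length mismatch")
    if esm.n_offspring < 2:
        raise ValueError("need at least 2 offspring")
    burden = esm.S_w @ w
    denom = float(np.sum(burden**2))
    warns = []
    if denom == 0.0:
        warns.append("all per-subject burdens are zero; statistic undefined")
        t, p = 0.0, 1.0
    else:
        t = float(np.sum(burden) ** 2 / denom)
        p = float(chi2.sf(t, df=1))
    return TestResult(
        method="FamBAC",
        statistic=t,
        p_value=p,
        pvalue_method="chi2",
        df_or_eigenvalues=1,
        n_variants=esm.n_variants,
        warnings=warns,
        **meta,
    )


def famkac_eigenvalues(esm: EfficientScoreMatrix, w: np.ndarray) -> np.ndarray:
    """Eigenvalues of ``n W C W`` with C the centered covariance of S_w rows."""
    n = esm.n_offspring
    c = np.atleast_2d(np.cov(esm.S_w, rowvar=False, ddof=1))
    m = n * (w[:, None] * c * w[None, :])
    lam = np.linalg.eigvalsh(m)
    lam = lam[lam > EIGEN_TRUNC * max(lam.max(), 0.0)] if lam.size else lam
    return lam


def famkac(
    esm: EfficientScoreMatrix, w: np.ndarray, pvalue_method: str = "davies", **meta
) -> TestResult:
    """Kernel (variance-component) test; mixture-of-chi-square p-value."""
    w = np.asarray(w, float)
    if len(w) != esm.n_variants:
        raise ValueError("weight vector length mismatch")
    if esm.n_offspring < 2:
        raise ValueError("need at least 2 offspring")
    col = esm.S_w.sum(axis=0)
    t = float(np.sum(w**2 * col**2))
    lam = famkac_eigenvalues(esm, w)
    warns = []
    if lam.size == 0:
        warns.append("null covariance is zero; p-value set to 1")
        p = 1.0
    else:
        p = davies_pvalue(t, lam)
    return TestResult(
        method="FamKAC",
        statistic=t,
        p_value=p,
        pvalue_method=pvalue_method,
        df_or_eigenvalues=lam,
        n_variants=esm.n_variants,
        warnings=warns,
        **meta,
    )


# ---------------------------------------------------------------------------
# gene-drop permutation
# ---------------------------------------------------------------------------

class GeneDropper:
    """Regenerate offspring genotypes under the family-based null.

    Parent-genotyped families: Mendelian re-transmission conditional on the
    parents — whole-haplotype when phased parental haplotypes are attached to
    the cohort (preserves LD), else per-variant Bernoulli(g/2) transmission
    (exact marginally).  Parentless sibships: permute offspring rows within
    the family.  Singletons without parents cannot be permuted and keep
    their observed genotypes (warned once).
    """

    def __init__(self, cohort: CohortDataset, decomp: DecomposedGenotypes):
        self.decomp = decomp
        self.g_b = decomp.G_b
        n, k = decomp.G_w.shape
        self.shape = (n, k)
        ped = cohort.pedigree
        geno = cohort.genotypes
        row_of = {s: i for i, s in enumerate(decomp.offspring_ids)}
        self.parental_rows: list[int] = []
        father_rows, mother_rows = [], []
        self.sib_groups: list[np.ndarray] = []
        n_singleton = 0
        for fid in ped.family_ids:
            rows = np.array([row_of[r.individual_id] for r in ped.offspring(fid)])
            if decomp.rule_used[fid] == RULE_PARENTAL:
                par = ped.parents(fid)
                gf = geno.row(par["father"])
                gm = geno.row(par["mother"])
                for r in rows:
                    self.parental_rows.append(r)
                    father_rows.append(gf)
                    mother_rows.append(gm)
            elif len(rows) > 1:
                self.sib_groups.append(rows)
            else:
                n_singleton += 1
        if n_singleton:
            logger.warning(
                "%d parentless singleton(s) cannot be gene-dropped; their "
                "observed genotypes are kept in every permutation",
                n_singleton,
            )
        self.parental_rows = np.asarray(self.parental_rows, dtype=int)
        self.father = np.vstack(father_rows) if father_rows else np.empty((0, k))
        self.mother = np.vstack(mother_rows) if mother_rows else np.empty((0, k))
        self.haplotypes = cohort.parent_haplotypes
        self.nan_mask = np.isnan(decomp.G_w)

    def drop(self, rng: np.random.Generator) -> np.ndarray:
        """Return a new within-family component matrix G_w."""
        g_w = self.decomp.G_w.copy()
        nr = len(self.parental_rows)
        if nr:
            if self.haplotypes is not None and nr == self.shape[0]:
                fh = self.haplotypes["father"]
                mh = self.haplotypes["mother"]
                pick_f = rng.integers(2, size=nr)
                pick_m = rng.integers(2, size=nr)
                g_new = (
                    np.where(pick_f[:, None] == 0, fh[0], fh[1])
                    + np.where(pick_m[:, None] == 0, mh[0], mh[1])
                ).astype(float)
            else:
                g_new = (rng.random(self.father.shape) < self.father / 2.0).astype(
                    float
                ) + (rng.random(self.mother.shape) < self.mother / 2.0)
            g_w[self.parental_rows] = g_new - self.g_b[self.parental_rows]
        for rows in self.sib_groups:
            g_w[rows] = g_w[rows[rng.permutation(len(rows))]]
        g_w[self.nan_mask] = np.nan
        return g_w


def _statistic_from_gw(
    g_w: np.ndarray,
    g_b: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    theta: np.ndarray,
    ctx: SurvivalContext,
    w: np.ndarray,
    statistic: str,
) -> float:
    c = score_components(g_w, g_b, time, event, theta, ctx=ctx)
    esm = efficient_score_matrix(c["U_w"], c["U_b"], c["I_wb"], c["I_bb"])
    if statistic == "FamBAC":
        burden = esm.S_w @ w
        denom = np.sum(burden**2)
        return float(np.sum(burden) ** 2 / denom) if denom > 0 else 0.0
    col = esm.S_w.sum(axis=0)
    return float(np.sum(w**2 * col**2))


def permutation_pvalue(
    cohort: CohortDataset,
    decomp: DecomposedGenotypes,
    fit: NullFrailtyFit,
    statistic: str,
    w: np.ndarray,
    n_permutations: int,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Empirical p-value from gene-drop permutations.

    The null fit (and hence ``theta`` and the risk sets) is held fixed;
    each permutation redraws the Mendelian transmissions, recomputes ``G_w``
    (``G_b`` is invariant under the parental-mean rule) and the statistic.
    ``p = (1 + #{T_perm >= T_obs}) / (1 + B)``.
    """
    if statistic not in ("FamBAC", "FamKAC"):
        raise ValueError("statistic must be 'FamBAC' or 'FamKAC'")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    pheno = cohort.phenotypes
    w = np.asarray(w, float)
    ctx = SurvivalContext(pheno.time, pheno.event, fit.theta)
    t_obs = _statistic_from_gw(
        decomp.G_w, decomp.G_b, pheno.time, pheno.event, fit.theta, ctx, w, statistic
    )
    dropper = GeneDropper(cohort, decomp)
    rng = np.random.default_rng(seed)
    t_perm = np.empty(n_permutations)
    complete = not np.isnan(decomp.G_w).any()
    if complete:
        # between-family quantities are invariant under gene-drop; only the
        # within-family score and the I_wb block need recomputation
        theta = fit.theta
        s0 = ctx.S0[:, None]
        ev = ctx.event_subjects
        g_b = decomp.G_b
        mean_b = ctx.event_suffix_sum(theta[:, None] * g_b) / s0
        u_b_ev = g_b[ev] - mean_b
        c_bb = ctx.event_suffix_sum(theta[:, None] * g_b * g_b)
        i_bb = np.sum(c_bb / s0 - mean_b**2, axis=0)

        def fast_stat(g_w):
            th_gw = theta[:, None] * g_w
            mean_w = ctx.event_suffix_sum(th_gw) / s0
            u_w_ev = g_w[ev] - mean_w
            c_wb = ctx.event_suffix_sum(th_gw * g_b)
            i_wb = np.sum(c_wb / s0 - mean_w * mean_b, axis=0)
            ratio = np.divide(i_wb, i_bb, out=np.zeros_like(i_wb), where=i_bb > 0)
            s_ev = u_w_ev - ratio[None, :] * u_b_ev
            if statistic == "FamBAC":
                burden = s_ev @ w
                denom = np.sum(burden**2)
                return float(np.sum(burden) ** 2 / denom) if denom > 0 else 0.0
            return float(np.sum(w**2 * s_ev.sum(axis=0) ** 2))

        for b in range(n_permutations):
            t_perm[b] = fast_stat(dropper.drop(rng))
    else:
        for b in range(n_permutations):
            t_perm[b] = _statistic_from_gw(
                dropper.drop(rng), decomp.G_b, pheno.time, pheno.event,
                fit.theta, ctx, w, statistic,
            )
    p = (1.0 + np.sum(t_perm >= t_obs)) / (1.0 + n_permutations)
    return float(p), t_perm
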