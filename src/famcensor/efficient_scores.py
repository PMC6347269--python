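"""Per-variant score statistics and the subject-level efficient score matrix.

For each variant ``m`` the within- and between-family score contributions
under the null (``gamma = 0``, risk scores ``theta`` from the null frailty
fit) are, for an event subject ``i`` with risk set ``R_i``::

    U_wim = G_wim - sum_{l in R_i} G_wlm theta_l / sum_{l in R_i} theta_l

and analogously ``U_bim`` with ``G_b``.  The observed-information blocks
are the usual Cox quantities accumulated over events::

    I_ab,m = sum_i [ S_ab/S_0 - (S_a/S_0)(S_b/S_0) ],   a, b in {G_w, G_b}

The efficient score projects the between-family (ancestry-bearing) direction
out of the within-family score using the aggregate information ratio::

    S_wim = U_wim - (I_wb,m / I_bb,m) * U_bim

Non-event subjects carry rows of zeros; summing ``S_w`` over subjects
recovers the textbook aggregate efficient score exactly.  Variants with
missing family cells are handled by excluding the affected subjects from
that variant's risk sets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .decomposition import DecomposedGenotypes
from .family_data import CensoredPhenotype
from .frailty_null import NullFrailtyFit
from .riskset import SurvivalContext


@dataclass
class EfficientScoreMatrix:
    """Subject-by-variant efficient scores plus per-variant summaries.

    ``column sums of S_w == U_w - (I_wb / I_bb) U_b`` holds by construction.
    """

    S_w: np.ndarray  # N_off x k
    U_w: np.ndarray  # length k aggregates
    U_b: np.ndarray
    I_ww: np.ndarray
    I_wb: np.ndarray
    I_bb: np.ndarray
    offspring_ids: list[str]
    variant_ids: list[str]
    subject_event_index: np.ndarray  # original-order indices of event rows

    @property
    def n_offspring(self) -> int:
        return self.S_w.shape[0]

    @property
    def n_variants(self) -> int:
        return self.S_w.shape[1]


def _components_complete(
    g_w: np.ndarray, g_b: np.ndarray, ctx: SurvivalContext
) -> dict:
    """Scores and information blocks for complete (NaN-free) matrices."""
    n, k = g_w.shape
    th = ctx.theta[:, None]
    s0 = ctx.S0[:, None]
    c_w = ctx.event_suffix_sum(th * g_w)
    c_b = ctx.event_suffix_sum(th * g_b)
    mean_w = c_w / s0
    mean_b = c_b / s0
    ev = ctx.event_subjects
    u_w = np.zeros((n, k))
    u_b = np.zeros((n, k))
    # accumulate over tied events sharing a subject is impossible (one row
    # per subject), so direct assignment is safe
    u_w[ev] = g_w[ev] - mean_w
    u_b[ev] = g_b[ev] - mean_b
    c_ww = ctx.event_suffix_sum(th * g_w * g_w)
    c_bb = ctx.event_suffix_sum(th * g_b * g_b)
    c_wb = ctx.event_suffix_sum(th * g_w * g_b)
    i_ww = np.sum(c_ww / s0 - mean_w**2, axis=0)
    i_bb = np.sum(c_bb / s0 - mean_b**2, axis=0)
    i_wb = np.sum(c_wb / s0 - mean_w * mean_b, axis=0)
    return {
        "U_w": u_w,
        "U_b": u_b,
        "I_ww": i_ww,
        "I_wb": i_wb,
        "I_bb": i_bb,
        "event_index": ev,
    }


def score_components(
    g_w: np.ndarray,
    g_b: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    theta: np.ndarray,
    ctx: Optional[SurvivalContext] = None,
) -> dict:
    """Scores and information blocks; NaN cells exclude their subjects from
    that variant's risk sets (the missing-family rule of the decomposition)."""
    g_w = np.asarray(g_w, float)
    g_b = np.asarray(g_b, float)
    n, k = g_w.shape
    if ctx is None:
        ctx = SurvivalContext(time, event, theta)
    nan_cols = np.flatnonzero(np.isnan(g_w).any(axis=0))
    if np.isnan(g_w).all(axis=0).any():
        bad = np.flatnonzero(np.isnan(g_w).all(axis=0))
        raise ValueError(f"variant column(s) missing in every family: {bad[:5]}")
    out = _components_complete(np.nan_to_num(g_w), np.nan_to_num(g_b), ctx)
    # redo incomplete variants on the observed-subject subset
    for j in nan_cols:
        obs = ~np.isnan(g_w[:, j])
        sub_ctx = SurvivalContext(time[obs], event[obs], theta[obs])
        sub = _components_complete(
            g_w[obs, j : j + 1], g_b[obs, j : j + 1], sub_ctx
        )
        for key in ("U_w", "U_b"):
            col = np.zeros(n)
            col[np.flatnonzero(obs)] = sub[key][:, 0]
            out[key][:, j] = col
        for key in ("I_ww", "I_wb", "I_bb"):
            out[key][j] = sub[key][0]
    out["ctx"] = ctx
    return out


def _components(
    decomp: DecomposedGenotypes,
    fit: NullFrailtyFit,
    pheno: CensoredPhenotype,
    ctx: Optional[SurvivalContext] = None,
) -> dict:
    if len(pheno.subject_ids) != decomp.G_w.shape[0]:
        raise ValueError("phenotype/decomposition subject count mismatch")
    return score_components(
        decomp.G_w, decomp.G_b, pheno.time, pheno.event, fit.theta, ctx=ctx
    )


def variant_scores(
    decomp: DecomposedGenotypes, fit: NullFrailtyFit, pheno: CensoredPhenotype
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject score contributions ``(U_w, U_b)`` (zeros for non-events)."""
    c = _components(decomp, fit, pheno)
    return c["U_w"], c["U_b"]


def observed_information(
    decomp: DecomposedGenotypes, fit: NullFrailtyFit, pheno: CensoredPhenotype
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant observed-information blocks ``(I_ww, I_wb, I_bb)``."""
    c = _components(decomp, fit, pheno)
    return c["I_ww"], c["I_wb"], c["I_bb"]


def efficient_score_matrix(
    u_w_subj: np.ndarray,
    u_b_subj: np.ndarray,
    i_wb: np.ndarray,
    i_bb: np.ndarray,
    i_ww: Optional[np.ndarray] = None,
    offspring_ids: Optional[list] = None,
    variant_ids: Optional[list] = None,
) -> EfficientScoreMatrix:
    """Project the between-family direction out of the within-family scores.

    Where ``I_bb = 0`` (no between-family information) the correction term
    vanishes and ``S_w = U_w``.
    """
    u_w_subj = np.asarray(u_w_subj, float)
    u_b_subj = np.asarray(u_b_subj, float)
    if u_w_subj.shape != u_b_subj.shape or u_w_subj.shape[1] != len(i_bb):
        raise ValueError("score/information dimension mismatch")
    ratio = np.divide(
        i_wb, i_bb, out=np.zeros_like(np.asarray(i_wb, float)), where=i_bb > 0
    )
    s_w = u_w_subj - ratio[None, :] * u_b_subj
    event_rows = np.flatnonzero(np.any(u_w_subj != 0, axis=1) | np.any(u_b_subj != 0, axis=1))
    n, k = s_w.shape
    return EfficientScoreMatrix(
        S_w=s_w,
        U_w=u_w_subj.sum(axis=0),
        U_b=u_b_subj.sum(axis=0),
        I_ww=np.asarray(i_ww, float) if i_ww is not None else np.full(k, np.nan),
        I_wb=np.asarray(i_wb, float),
        I_bb=np.asarray(i_bb, float),
        offspring_ids=list(offspring_ids) if offspring_ids else [str(i) for i in range(n)],
        variant_ids=list(variant_ids) if variant_ids else [f"v{j}" for j in range(k)],
        subject_event_index=event_rows,
    )


def compute_efficient_scores(
    decomp: DecomposedGenotypes,
    fit: NullFrailtyFit,
    pheno: CensoredPhenotype,
    ctx: Optional[SurvivalContext] = None,
) -> EfficientScoreMatrix:
    """One-call pipeline: scores, information blocks, efficient projection."""
    c = _components(decomp, fit, pheno, ctx=ctx)
    esm = efficient_score_matrix(
        c["U_w"],
        c["U_b"],
        c["I_wb"],
        c["I_bb"],
        i_ww=c["I_ww"],
        offspring_ids=decomp.offspring_ids,
        variant_ids=decomp.variant_ids,
    )
    esm.subject_event_index = c["event_index"]
    return esm
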