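"""Breslow risk-set machinery shared by the null fit and the score tests.

Subjects are sorted by observed time once; every risk-set sum
(``sum over {l : Y_l >= Y_i}``) then becomes a suffix cumulative sum, so a
full pass over events costs O(N log N + N k).  Tied event times share the
risk set that starts at the first member of the tie group (Breslow).
"""
from __future__ import annotations

import numpy as np


class SurvivalContext:
    """Precomputed sort order, risk-set denominators and cumulative-hazard
    weights for fixed ``(Y, delta, theta)``."""

    def __init__(self, time: np.ndarray, event: np.ndarray, theta: np.ndarray):
        time = np.asarray(time, float)
        event = np.asarray(event, int)
        theta = np.asarray(theta, float)
        n = len(time)
        if not (len(event) == len(theta) == n):
            raise ValueError("time/event/theta length mismatch")
        if event.sum() == 0:
            raise ValueError("no events (delta = 1) in the data")
        self.n = n
        self.time = time
        self.event = event
        self.theta = theta
        self.order = np.argsort(time, kind="stable")
        self.inv_order = np.empty(n, dtype=int)
        self.inv_order[self.order] = np.arange(n)
        self.time_s = time[self.order]
        self.event_s = event[self.order]
        self.theta_s = theta[self.order]
        # events in sorted (ascending-time) order
        self.event_pos = np.flatnonzero(self.event_s == 1)
        # first index of each event's tie group = start of its risk set
        self.gs = np.searchsorted(self.time_s, self.time_s[self.event_pos], side="left")
        c0 = np.cumsum(self.theta_s[::-1])[::-1]
        self.S0 = c0[self.gs]
        # per-position cumulative-hazard weights: A_j = sum_{e: gs_e <= j} 1/S0_e
        inc_a = np.zeros(n)
        inc_b = np.zeros(n)
        np.add.at(inc_a, self.gs, 1.0 / self.S0)
        np.add.at(inc_b, self.gs, 1.0 / self.S0**2)
        self.cumhaz_s = np.cumsum(inc_a)
        self._bcum_s = np.cumsum(inc_b)
        # original-order subject indices of the events, in sorted order
        self.event_subjects = self.order[self.event_pos]

    # -- suffix sums -------------------------------------------------------
    def event_suffix_sum(self, values: np.ndarray) -> np.ndarray:
        """For each event i, ``sum_{l: Y_l >= Y_i} values_l`` (values in
        original subject order; trailing axes preserved)."""
        v = np.asarray(values, float)[self.order]
        c = np.cumsum(v[::-1], axis=0)[::-1]
        return c[self.gs]

    def partial_loglik(self, eta: np.ndarray) -> float:
        """Breslow partial log-likelihood at linear predictor ``eta``
        (must satisfy theta = exp(eta))."""
        return float(np.sum(eta[self.event_subjects]) - np.sum(np.log(self.S0)))

    # -- derivatives in eta-space ------------------------------------------
    def score_eta(self) -> np.ndarray:
        """d loglik / d eta_j = delta_j - theta_j * Lambda_j (original order)."""
        return self.event - self.theta * self.cumhaz_s[self.inv_order]

    def information_dense(self) -> np.ndarray:
        """Observed information matrix -d2 loglik / d eta d eta' (N x N,
        original order).  O(N^2) memory; intended for moderate cohorts."""
        th = self.theta_s
        a = th * self.cumhaz_s
        idx = np.arange(self.n)
        bmin = self._bcum_s[np.minimum.outer(idx, idx)]
        h = -np.outer(th, th) * bmin
        h[idx, idx] += a
        return h[np.ix_(self.inv_order, self.inv_order)]

    def information_proj(self, x: np.ndarray) -> np.ndarray:
        """x' H x for a design matrix x (N x p), without forming H:
        ``sum_e [S2_e/S0_e - (S1_e/S0_e)(S1_e/S0_e)']`` over events."""
        x = np.atleast_2d(np.asarray(x, float))
        if x.shape[0] != self.n:
            x = x.T
        p = x.shape[1]
        tx = self.theta[:, None] * x
        s1 = self.event_suffix_sum(tx)  # n_events x p
        out = np.zeros((p, p))
        mu = s1 / self.S0[:, None]
        # second-moment term
        txx = tx[:, :, None] * x[:, None, :]
        s2 = self.event_suffix_sum(txx.reshape(self.n, -1)).reshape(-1, p, p)
        out = np.einsum("epq->pq", s2 / self.S0[:, None, None])
        out -= np.einsum("ep,eq->pq", mu, s1 / self.S0[:, None])
        return out
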