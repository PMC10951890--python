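"""Similarity-regularised nonnegative matrix factorisation (linear features).

Factorises the circRNA-disease association matrix H into nonnegative latent
factors C (circRNAs) and D (diseases), fitting only the observed/training
cells marked by an indicator matrix W, with Tikhonov shrinkage and a penalty
tying the factor Gram matrices to the integrated similarity matrices:

    min_{C,D >= 0}  ||W o (H - C D^T)||_F^2
                    + alpha (||C||_F^2 + ||D||_F^2)
                    + lam (||SC - C C^T||_F^2 + ||SD - D D^T||_F^2)

Optimisation is alternating multiplicative updates in numerator/denominator
form (which preserve nonnegativity), with a per-factor backtracking exponent
so the objective trace is nonincreasing on every instance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

_EPS = 1e-12


def mf_objective(H, W, C, D, SC=None, SD=None, alpha: float = 0.0, lam: float = 0.0) -> float:
    """Evaluate the factorisation objective at (C, D)."""
    if alpha < 0 or lam < 0:
        raise ValueError("alpha and lam must be nonnegative")
    H, W, C, D = (np.asarray(x, dtype=float) for x in (H, W, C, D))
    if not np.isin(W, (0, 1)).all():
        raise ValueError("indicator matrix W must be binary")
    val = float(((W * (H - C @ D.T)) ** 2).sum())
    val += alpha * (float((C ** 2).sum()) + float((D ** 2).sum()))
    if lam > 0:
        if SC is None or SD is None:
            raise ValueError("similarity matrices required when lam > 0")
        val += lam * float(((np.asarray(SC) - C @ C.T) ** 2).sum())
        val += lam * float(((np.asarray(SD) - D @ D.T) ** 2).sum())
    return val


def _split(S) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(S, dtype=float)
    return np.maximum(S, 0.0), np.maximum(-S, 0.0)


class SimilarityRegularizedNMF(BaseEstimator):
    """Nonnegative factorisation of the association matrix with similarity ties.

    Parameters
    ----------
    rank : latent dimension r; clipped to min(m, n) - 1 on small matrices.
    alpha : Tikhonov weight on ||C||^2 + ||D||^2.
    lam : weight of the ||S - FF^T||^2 similarity-regularisation terms.
    max_iter, tol : stop when the relative objective change drops below tol.
    random_state : seed for the nonnegative Gaussian initialisation.

    Attributes
    ----------
    C_, D_ : fitted nonnegative factors (m x r and n x r).
    objective_trace_ : objective value per iteration (nonincreasing).
    rank_ : effective rank after clipping.
    """

    def __init__(self, rank: int = 64, alpha: float = 0.01, lam: float = 0.1,
                 max_iter: int = 500, tol: float = 1e-6, random_state: int = 0):
        self.rank = rank
        self.alpha = alpha
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, H, W=None, SC=None, SD=None):
        H = np.asarray(H, dtype=float)
        if (H < 0).any():
            raise ValueError("association matrix H must be nonnegative")
        m, n = H.shape
        if self.alpha < 0 or self.lam < 0:
            raise ValueError("alpha and lam must be nonnegative")
        r = min(self.rank, min(m, n) - 1)
        if r < 1:
            raise ValueError(f"rank {self.rank} infeasible for a {m}x{n} matrix")
        W = np.ones_like(H) if W is None else np.asarray(W, dtype=float)
        if not np.isin(W, (0, 1)).all():
            raise ValueError("indicator matrix W must be binary")
        lam = self.lam
        if lam > 0 and (SC is None or SD is None):
            raise ValueError("similarity matrices SC and SD required when lam > 0")
        SCp, SCn = _split(SC) if SC is not None else (None, None)
        SDp, SDn = _split(SD) if SD is not None else (None, None)

        rng = np.random.default_rng(self.random_state)
        mean_obs = H[W > 0].mean() if (W > 0).any() else 1.0
        scale = np.sqrt(max(mean_obs, _EPS) / r)
        C = np.abs(rng.standard_normal((m, r))) * scale
        D = np.abs(rng.standard_normal((n, r))) * scale

        def objective(Cm, Dm):
            return mf_objective(H, W, Cm, Dm, SC, SD, self.alpha, lam)

        WH = W * H
        obj = objective(C, D)
        trace = [obj]
        for _ in range(self.max_iter):
            C, obj = self._update(C, D, WH, W, SCp, SCn, lam,
                                  lambda Cm: objective(Cm, D), obj)
            D, obj = self._update(D, C, WH.T, W.T, SDp, SDn, lam,
                                  lambda Dm: objective(C, Dm), obj)
            trace.append(obj)
            prev = trace[-2]
            if obj > prev + 1e-9 * max(prev, 1.0):
                raise RuntimeError(
                    f"objective increased from {prev:.6g} to {obj:.6g}")
            if prev - obj <= self.tol * max(prev, _EPS):
                break
        self.C_, self.D_ = C, D
        self.rank_ = r
        self.objective_trace_ = np.asarray(trace)
        return self

    def _update(self, F, G, WH, W, Sp, Sn, lam, objective, current):
        """One multiplicative update of F, backtracked until nonincreasing.

        The gradient of the objective in F splits into nonnegative parts
        grad = den - num; the multiplicative step F <- F * num/den is damped
        by an exponent gamma in (0, 1] halved until the objective does not
        increase (gamma -> 0 recovers the current iterate).
        """
        num = WH @ G
        den = (W * (F @ G.T)) @ G + self.alpha * F
        if lam > 0:
            num = num + 2.0 * lam * (Sp @ F)
            den = den + 2.0 * lam * (F @ (F.T @ F) + Sn @ F)
        ratio = num / (den + _EPS)
        gamma = 1.0
        for _ in range(40):
            cand = F * ratio ** gamma
            val = objective(cand)
            if val <= current + 1e-12 * max(current, 1.0):
                return cand, val
            gamma *= 0.5
        return F, current

    def transform(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the fitted embedding blocks (circRNA rows, disease rows)."""
        return self.C_, self.D_
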