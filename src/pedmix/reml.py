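"""Restricted maximum likelihood for linear-covariance mixed models.

The engine fits models of the form

    y = X b + eps,   Cov(eps) = V(theta) = sum_q theta_q * D_q

where the ``D_q`` are known symmetric matrices (relationship matrices,
group-share matrices, the identity for the residual, or Kronecker-type
blocks in the bivariate case) and ``theta`` is estimated by REML with
average-information (AI) updates and an EM/gradient fallback when an AI
step leaves the parameter space or decreases the likelihood.

Family cohorts give block-diagonal ``D_q``; the engine partitions the
observations into independent blocks (connected components of the union
sparsity pattern), groups blocks of equal size, and evaluates all REML
quantities with batched dense linear algebra over each size group.  This
makes a cohort of thousands of small families cheap to fit repeatedly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["REMLResult", "BlockedREML", "connected_blocks"]


class DesignError(ValueError):
    """Fixed-effects design matrix is singular or otherwise unusable."""


def connected_blocks(mats: list[sp.spmatrix]) -> list[np.ndarray]:
    """Independent observation blocks: connected components of the union
    of the matrices' off-diagonal sparsity patterns."""
    n = mats[0].shape[0]
    union = sp.csr_matrix((n, n))
    for m in mats:
        union = union + abs(m.tocsr())
    ncomp, labels = sp.csgraph.connected_components(union, directed=False)
    order = np.argsort(labels, kind="stable")
    bounds = np.searchsorted(labels[order], np.arange(ncomp + 1))
    return [order[bounds[i]:bounds[i + 1]] for i in range(ncomp)]


@dataclass
class REMLResult:
    theta: np.ndarray                 # covariance parameters at optimum
    theta_cov: np.ndarray             # asymptotic covariance (inverse AI)
    log_likelihood: float             # REML log-likelihood (up to constant)
    beta: np.ndarray                  # GLS fixed-effect estimates
    beta_cov: np.ndarray              # (X' V^-1 X)^-1
    converged: bool
    n_iter: int
    n_used: int
    param_names: list[str] = field(default_factory=list)

    @property
    def theta_se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.theta_cov), 0.0, None))


class _SizeGroup:
    """Stacked data for all blocks of one size: Y (nb,s), X (nb,s,p),
    D (nb,q,s,s), plus the flat observation indices for bookkeeping."""

    __slots__ = ("Y", "X", "D", "idx")

    def __init__(self, Y, X, D, idx):
        self.Y, self.X, self.D, self.idx = Y, X, D, idx


class BlockedREML:
    """REML problem over blocked observations.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effects design (must be full column rank)
    derivs : list of (n, n) symmetric scipy sparse matrices, one per
        covariance parameter (``dV/dtheta_q``)
    blocks : optional explicit block index lists; computed from the union
        sparsity pattern when omitted
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        derivs: list[sp.spmatrix],
        blocks: list[np.ndarray] | None = None,
        param_names: list[str] | None = None,
    ):
        y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n = y.shape[0]
        if X.shape[0] != n:
            raise ValueError("X and y have different numbers of rows")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("fixed-effects design matrix is rank deficient")
        self.n, self.p = n, X.shape[1]
        self.q = len(derivs)
        self.param_names = param_names or [f"theta{k}" for k in range(self.q)]
        derivs = [sp.csr_matrix(d) for d in derivs]
        if blocks is None:
            blocks = connected_blocks(derivs)
        # permute to block order so each block is a contiguous slice,
        # then group blocks of equal size and stack them
        by_size: dict[int, list[np.ndarray]] = {}
        for b in blocks:
            by_size.setdefault(len(b), []).append(np.asarray(b))
        order = np.concatenate([b for s in sorted(by_size) for b in by_size[s]])
        y_perm, X_perm = y[order], X[order]
        # block boundaries in permuted coordinates
        sizes = np.array([s for s in sorted(by_size) for _ in by_size[s]])
        bounds = np.concatenate([[0], np.cumsum(sizes)])
        pos = np.empty(n, dtype=np.int64)
        pos[order] = np.arange(n)
        # scatter each derivative's entries into the stacked group arrays
        group_sizes = sorted(by_size)
        group_first = {}
        k0 = 0
        for s in group_sizes:
            group_first[s] = k0
            k0 += len(by_size[s])
        self.groups = []
        stacks = {}
        off = 0
        for s in group_sizes:
            nb = len(by_size[s])
            Y = y_perm[off:off + nb * s].reshape(nb, s)
            Xg = X_perm[off:off + nb * s].reshape(nb, s, self.p)
            D = np.zeros((nb, self.q, s, s))
            stacks[s] = D
            self.groups.append(_SizeGroup(Y, Xg, D, by_size[s]))
            off += nb * s
        size_of_block = sizes
        for qq, d in enumerate(derivs):
            coo = d.tocoo()
            rr = pos[coo.row]
            cc = pos[coo.col]
            b_idx = np.searchsorted(bounds, rr, side="right") - 1
            s_arr = size_of_block[b_idx]
            lr = rr - bounds[b_idx]
            lc = cc - bounds[b_idx]
            for s in group_sizes:
                m = s_arr == s
                if not m.any():
                    continue
                local_block = b_idx[m] - group_first[s]
                stacks[s][local_block, qq, lr[m], lc[m]] = coo.data[m]

    # -- single evaluation of logL, score, AI at theta ----------------

    def _evaluate(self, theta: np.ndarray):
        p, q = self.p, self.q
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        logdetV = 0.0
        cache = []
        for g in self.groups:
            V = np.einsum("q,nqij->nij", theta, g.D)
            sign, ld = np.linalg.slogdet(V)
            if not np.all(sign > 0):
                return None
            Vinv = np.linalg.inv(V)
            logdetV += float(ld.sum())
            ViX = np.einsum("nij,njp->nip", Vinv, g.X)
            XtViX += np.einsum("nip,niq->pq", g.X, ViX)
            XtViy += np.einsum("nip,ni->p", ViX, g.Y)
            cache.append((Vinv, ViX))
        sign_x, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign_x <= 0:
            return None
        beta = np.linalg.solve(XtViX, XtViy)
        XtViX_inv = np.linalg.inv(XtViX)

        ypy = 0.0
        trVD = np.zeros(q)
        quad = np.zeros(q)
        G = np.zeros((q, p, p))          # X' Vi D Vi X per parameter
        M = np.zeros((q, p))             # X' Vi D P y
        WU = np.zeros((q, q))
        for g, (Vinv, ViX) in zip(self.groups, cache):
            r = g.Y - np.einsum("nsp,p->ns", g.X, beta)
            Pr = np.einsum("nij,nj->ni", Vinv, r)
            ypy += float(np.einsum("ni,ni->", r, Pr))
            W = np.einsum("nqij,nj->nqi", g.D, Pr)
            U = np.einsum("nij,nqj->nqi", Vinv, W)
            quad += np.einsum("nqi,ni->q", W, Pr)
            trVD += np.einsum("nij,nqji->q", Vinv, g.D)
            DVX = np.einsum("nqij,njb->nqib", g.D, ViX)
            G += np.einsum("nia,nqib->qab", ViX, DVX)
            M += np.einsum("nip,nqi->qp", ViX, W)
            WU += np.einsum("nqi,nri->qr", W, U)
        trPD = trVD - np.einsum("ab,qba->q", XtViX_inv, G)
        score = -0.5 * (trPD - quad)
        AI = 0.5 * (WU - M @ XtViX_inv @ M.T)
        logL = -0.5 * (logdetV + logdet_xvx + ypy)
        return {
            "logL": logL, "score": score, "AI": AI, "beta": beta,
            "beta_cov": XtViX_inv, "quad": quad, "trPD": trPD,
        }

    # -- optimisation --------------------------------------------------

    def fit(
        self,
        theta0: np.ndarray,
        lower: np.ndarray | None = None,
        free: np.ndarray | None = None,
        max_iter: int = 100,
        tol: float = 1e-6,
    ) -> REMLResult:
        """Maximise the REML likelihood from ``theta0``.

        ``lower`` gives per-parameter lower bounds (default 0; use -inf
        for covariance parameters).  ``free`` masks parameters held fixed
        at their starting value (used for constrained null fits).
        """
        theta = np.asarray(theta0, dtype=float).copy()
        if lower is None:
            lower = np.zeros(self.q)
        lower = np.asarray(lower, dtype=float)
        if free is None:
            free = np.ones(self.q, dtype=bool)
        free = np.asarray(free, dtype=bool)

        ev = self._evaluate(theta)
        if ev is None:
            # nudge away from a singular start
            theta = np.where(free & (theta <= lower), lower + 1e-6, theta)
            ev = self._evaluate(theta)
            if ev is None:
                raise ValueError("starting covariance parameters give a singular V")
        converged = False
        it = 0
        eps_bound = 1e-10
        for it in range(1, max_iter + 1):
            score = ev["score"][free]
            AI = ev["AI"][np.ix_(free, free)]
            try:
                delta_free = np.linalg.solve(AI + 1e-12 * np.eye(AI.shape[0]), score)
            except np.linalg.LinAlgError:
                delta_free = score / (np.abs(np.diag(AI)) + 1e-8)
            delta = np.zeros(self.q)
            delta[free] = delta_free

            accepted = None
            step = 1.0
            for _ in range(20):
                cand = theta + step * delta
                cand = np.maximum(cand, np.where(free, lower, theta))
                cand[~free] = theta[~free]
                ev_new = self._evaluate(cand)
                if ev_new is not None and ev_new["logL"] >= ev["logL"] - 1e-10:
                    accepted = (cand, ev_new)
                    break
                step *= 0.5
            if accepted is None:
                # EM-style fallback for parameters with a variance role,
                # then a scaled-score sweep if that too fails
                cand = theta.copy()
                em = theta + theta**2 * (ev["quad"] - ev["trPD"]) / self.n
                grad_step = ev["score"] / (np.abs(np.diag(ev["AI"])) + 1e-8)
                use_em = theta > eps_bound
                cand[free] = np.where(use_em, em, theta + 0.1 * grad_step)[free]
                cand = np.maximum(cand, np.where(free, lower, theta))
                ev_new = self._evaluate(cand)
                if ev_new is not None and ev_new["logL"] >= ev["logL"] - 1e-8:
                    accepted = (cand, ev_new)
                else:
                    norm = np.linalg.norm(ev["score"][free]) + 1e-300
                    base = np.zeros(self.q)
                    base[free] = ev["score"][free] / norm
                    scale = max(np.abs(theta).max(), 1e-3)
                    for mag in (1e-1, 1e-2, 1e-3, 1e-4, 1e-5, 1e-6):
                        cand = theta + mag * scale * base
                        cand = np.maximum(cand, np.where(free, lower, theta))
                        ev_new = self._evaluate(cand)
                        if ev_new is not None and ev_new["logL"] > ev["logL"] + 1e-12:
                            accepted = (cand, ev_new)
                            break
                    if accepted is None:
                        break  # cannot improve; stop where we are
            new_theta, new_ev = accepted
            dll = new_ev["logL"] - ev["logL"]
            theta, ev = new_theta, new_ev
            if abs(dll) < tol:
                converged = True
                break

        AI_free = ev["AI"][np.ix_(free, free)]
        theta_cov = np.zeros((self.q, self.q))
        try:
            theta_cov[np.ix_(free, free)] = np.linalg.inv(AI_free)
        except np.linalg.LinAlgError:
            theta_cov[np.ix_(free, free)] = np.linalg.pinv(AI_free)
        return REMLResult(
            theta=theta,
            theta_cov=theta_cov,
            log_likelihood=float(ev["logL"]),
            beta=ev["beta"],
            beta_cov=ev["beta_cov"],
            converged=converged,
            n_iter=it,
            n_used=self.n,
            param_names=list(self.param_names),
        )
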