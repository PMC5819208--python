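"""Batched per-SNP ordinal-logistic and logistic regression.

A genome-wide scan fits the same tiny model (one genotype covariate) at
tens of thousands of SNPs, so the fits are run as batched Newton-Raphson
over SNP chunks: parameters live in (n_snps, n_params) arrays, gradients
and Hessians are accumulated with dense numpy ops per outcome category, and
each 4x4 (ordinal) or 2x2 (logistic) system is solved per SNP.  Standard
errors come from the observed information at the optimum.

Model conventions match ordinal logistic regression as usually reported:
P(Y <= j | x) = sigmoid(alpha_j - beta x), so beta is the log-odds of
exceeding any grade per effect-allele copy (positive beta = more severe
pathology with more copies).

SNPs that fail to converge, or drift to |beta| beyond a separation guard,
are flagged rather than raised — a genome scan must survive individual
degenerate SNPs.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InputError

__all__ = ["BatchFitResult", "fit_logistic_batch", "fit_proportional_odds_batch"]

_MAX_ITER = 50
_GRAD_TOL = 1e-8
_BETA_GUARD = 15.0  # |log-odds| beyond this is treated as separation
_CHUNK = 512


@dataclasses.dataclass
class BatchFitResult:
    """Per-SNP slope estimates from a batched fit."""

    beta: np.ndarray
    se: np.ndarray
    converged: np.ndarray  # bool per SNP
    n_iter: np.ndarray

    @property
    def n_failed(self) -> int:
        return int((~self.converged).sum())


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_logistic_batch(X: np.ndarray, y: np.ndarray) -> BatchFitResult:
    """Logistic regression of binary ``y`` on each column of ``X`` separately.

    Each SNP's model is intercept + slope; returns the slope and its SE.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("dosage matrix and outcome length mismatch")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError("binary outcome must be coded 0/1")
    if len(np.unique(y)) < 2:
        raise InputError("binary outcome is constant")
    n, M = X.shape
    beta = np.zeros(M)
    se = np.full(M, np.nan)
    conv = np.zeros(M, dtype=bool)
    iters = np.zeros(M, dtype=int)
    ybar = y.mean()

    for lo in range(0, M, _CHUNK):
        hi = min(lo + _CHUNK, M)
        Xc = X[:, lo:hi]
        m = hi - lo
        b0 = np.full(m, np.log(ybar / (1 - ybar)))
        b1 = np.zeros(m)
        active = np.ones(m, dtype=bool)
        failed = np.zeros(m, dtype=bool)
        it = np.zeros(m, dtype=int)
        for _ in range(_MAX_ITER):
            if not active.any():
                break
            eta = b0[None, :] + Xc * b1[None, :]
            mu = _sigmoid(eta)
            r = y[:, None] - mu
            g0 = r.sum(axis=0)
            g1 = (Xc * r).sum(axis=0)
            w = mu * (1.0 - mu)
            h00 = w.sum(axis=0)
            h01 = (w * Xc).sum(axis=0)
            h11 = (w * Xc * Xc).sum(axis=0)
            det = h00 * h11 - h01 * h01
            bad = ~np.isfinite(det) | (det <= 1e-12)
            step0 = np.where(bad, 0.0, (h11 * g0 - h01 * g1) / np.where(det == 0, 1, det))
            step1 = np.where(bad, 0.0, (-h01 * g0 + h00 * g1) / np.where(det == 0, 1, det))
            b0 = np.where(active, b0 + step0, b0)
            b1 = np.where(active, b1 + step1, b1)
            it += active
            done = active & (np.maximum(np.abs(g0), np.abs(g1)) < _GRAD_TOL * n)
            blown = active & (bad | (np.abs(b1) > _BETA_GUARD) | ~np.isfinite(b1))
            failed |= blown
            active &= ~(done | blown)
        # final information for SE at the optimum
        eta = b0[None, :] + Xc * b1[None, :]
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        h00 = w.sum(axis=0)
        h01 = (w * Xc).sum(axis=0)
        h11 = (w * Xc * Xc).sum(axis=0)
        det = h00 * h11 - h01 * h01
        ok = ~active & ~failed & np.isfinite(b1) & (det > 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            se_c = np.sqrt(h00 / det)
        beta[lo:hi] = b1
        se[lo:hi] = np.where(ok, se_c, np.nan)
        conv[lo:hi] = ok
        iters[lo:hi] = it
    return BatchFitResult(beta, se, conv, iters)


def _start_cutpoints(y: np.ndarray, J: int) -> np.ndarray:
    """Cumulative-logit cutpoints of the marginal outcome distribution."""
    cum = np.cumsum(np.bincount(y, minlength=J)[:-1]) / y.size
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return np.log(cum / (1 - cum))


def fit_proportional_odds_batch(X: np.ndarray, y: np.ndarray) -> BatchFitResult:
    """Proportional-odds regression of an ordinal ``y`` on each column of ``X``.

    Outcome levels must be coded 0..J-1 with every level observed.  Per SNP
    the parameters are J-1 ordered cutpoints plus one slope; the full
    (J, J) Newton system is assembled analytically per outcome category and
    solved per SNP in the batch.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("dosage matrix and outcome length mismatch")
    levels = np.unique(y)
    J = int(levels.max()) + 1
    if J < 2 or not np.array_equal(levels, np.arange(J)):
        raise InputError(
            f"ordinal outcome must take every level 0..J-1, observed levels {levels.tolist()}"
        )
    if J == 2:  # degenerate ordinal is plain logistic
        return fit_logistic_batch(X, y.astype(float))
    n, M = X.shape
    P = J  # (J-1) cutpoints + slope
    alpha0 = _start_cutpoints(y, J)
    groups = [np.flatnonzero(y == c) for c in range(J)]

    beta = np.zeros(M)
    se = np.full(M, np.nan)
    conv = np.zeros(M, dtype=bool)
    iters = np.zeros(M, dtype=int)

    for lo in range(0, M, _CHUNK):
        hi = min(lo + _CHUNK, M)
        Xc = X[:, lo:hi]
        m = hi - lo
        theta = np.tile(np.append(alpha0, 0.0), (m, 1))  # (m, P)
        active = np.ones(m, dtype=bool)
        it = np.zeros(m, dtype=int)
        H = np.zeros((m, P, P))
        g = np.zeros((m, P))
        for _ in range(_MAX_ITER):
            if not active.any():
                break
            H[:] = 0.0
            g[:] = 0.0
            b = theta[:, -1]
            ok_theta = np.isfinite(theta).all(axis=1) & (np.diff(theta[:, :-1], axis=1) > 0).all(axis=1)
            for c in range(J):
                rows = groups[c]
                x = Xc[rows, :]  # (nc, m)
                # upper boundary F_c (c < J-1), lower F_{c-1} (c > 0)
                if c < J - 1:
                    Fu = _sigmoid(theta[:, c][None, :] - b[None, :] * x)
                    fu = Fu * (1 - Fu)
                else:
                    Fu = np.ones_like(x)
                    fu = np.zeros_like(x)
                if c > 0:
                    Fl = _sigmoid(theta[:, c - 1][None, :] - b[None, :] * x)
                    fl = Fl * (1 - Fl)
                else:
                    Fl = np.zeros_like(x)
                    fl = np.zeros_like(x)
                p = np.clip(Fu - Fl, 1e-300, None)
                du = fu / p  # d log p / d alpha_c
                dl = -fl / p  # d log p / d alpha_{c-1}
                # first derivatives
                if c < J - 1:
                    g[:, c] += du.sum(axis=0)
                if c > 0:
                    g[:, c - 1] += dl.sum(axis=0)
                g[:, -1] += (-x * (fu - fl) / p).sum(axis=0)
                # second derivatives (observed Hessian)
                ku = fu * (1 - 2 * Fu)  # d fu / d alpha_c
                kl = fl * (1 - 2 * Fl)
                if c < J - 1:
                    H[:, c, c] += (ku / p - du * du).sum(axis=0)
                if c > 0:
                    H[:, c - 1, c - 1] += (-kl / p - dl * dl).sum(axis=0)
                if 0 < c < J - 1:
                    cross = (-du * dl).sum(axis=0)
                    H[:, c, c - 1] += cross
                    H[:, c - 1, c] += cross
                gb = -x * (fu - fl) / p
                H[:, -1, -1] += (x * x * (ku - kl) / p - gb * gb).sum(axis=0)
                if c < J - 1:
                    hb = (-x * ku / p - du * gb).sum(axis=0)
                    H[:, c, -1] += hb
                    H[:, -1, c] += hb
                if c > 0:
                    hb = (x * kl / p - dl * gb).sum(axis=0)
                    H[:, c - 1, -1] += hb
                    H[:, -1, c - 1] += hb
            step = np.zeros_like(theta)
            solvable = ok_theta & np.isfinite(H).reshape(m, -1).all(axis=1)
            if solvable.any():
                try:
                    step[solvable] = np.linalg.solve(
                        -H[solvable], g[solvable][..., None]
                    )[..., 0]
                except np.linalg.LinAlgError:
                    for i in np.flatnonzero(solvable):
                        try:
                            step[i] = np.linalg.solve(-H[i], g[i])
                        except np.linalg.LinAlgError:
                            solvable[i] = False
            # damp huge steps to keep cutpoints ordered
            norm = np.abs(step).max(axis=1)
            scale = np.where(norm > 5.0, 5.0 / np.where(norm == 0, 1, norm), 1.0)
            theta = np.where((active & solvable)[:, None], theta + step * scale[:, None], theta)
            it += active
            done = active & solvable & (np.abs(g).max(axis=1) < _GRAD_TOL * n)
            blown = active & (
                ~solvable
                | (np.abs(theta[:, -1]) > _BETA_GUARD)
                | ~np.isfinite(theta).all(axis=1)
            )
            active &= ~(done | blown)

        b = theta[:, -1]
        ok = (
            ~active
            & np.isfinite(b)
            & (np.abs(b) <= _BETA_GUARD)
            & (it < _MAX_ITER)
            & (np.diff(theta[:, :-1], axis=1) > 0).all(axis=1)
        )
        se_c = np.full(m, np.nan)
        if ok.any():
            info = -H[ok]
            try:
                cov = np.linalg.inv(info)
                se_c[ok] = np.sqrt(np.clip(cov[:, -1, -1], 0, None))
            except np.linalg.LinAlgError:
                ok[ok] = False
        beta[lo:hi] = b
        se[lo:hi] = se_c
        conv[lo:hi] = ok & np.isfinite(se_c) & (se_c > 0)
        iters[lo:hi] = it
    return BatchFitResult(beta, se, conv, iters)
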