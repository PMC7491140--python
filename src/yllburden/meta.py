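"""Second-stage pooling: multivariate random-effects meta-analysis.

Location-specific reduced coefficient vectors theta_i (with within-location
covariances V_i) are pooled under

    theta_i ~ N(mu, Psi + V_i)

where Psi is the between-location covariance.  Psi is estimated by REML,
maximised over a Cholesky factor so positive semidefiniteness is enforced
by construction.  Best linear unbiased predictions (BLUPs) shrink each
location's curve toward the pooled mean in proportion to its imprecision.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["MVMeta", "MVMetaResults", "blup_single"]


def _vech_to_chol(params: np.ndarray, p: int) -> np.ndarray:
    L = np.zeros((p, p))
    L[np.tril_indices(p)] = params
    return L


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-8) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(mat)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"{name} is not positive semidefinite (min eigenvalue {w.min():.3g})")


class MVMeta:
    """Intercept-only multivariate random-effects meta-analysis model.

    Parameters
    ----------
    estimates : sequence of (theta_i, V_i)
        Per-study coefficient vectors and their covariance matrices, all
        of a common dimension.
    """

    def __init__(self, estimates):
        thetas, vcovs = zip(*estimates)
        self.thetas = np.asarray(thetas, dtype=float)
        if self.thetas.ndim == 1:
            self.thetas = self.thetas[:, None]
        self.vcovs = np.asarray(
            [np.atleast_2d(np.asarray(v, dtype=float)) for v in vcovs]
        )
        self.n_studies, self.dim = self.thetas.shape
        if self.n_studies < 2:
            raise ValueError("need at least 2 studies")
        for i, v in enumerate(self.vcovs):
            if v.shape != (self.dim, self.dim):
                raise ValueError(f"V_{i} has wrong shape {v.shape}")
            _check_psd(v, f"V_{i}")

    # ---- REML machinery -------------------------------------------------

    def _gls(self, psi: np.ndarray):
        """Weighted mean and its covariance for a given Psi."""
        weights = [np.linalg.inv(psi + v) for v in self.vcovs]
        U = np.sum(weights, axis=0)
        vcov_mu = np.linalg.inv(U)
        mu = vcov_mu @ np.sum(
            [w @ t for w, t in zip(weights, self.thetas)], axis=0
        )
        return mu, vcov_mu, weights

    def _neg2_reml(self, psi: np.ndarray) -> float:
        mu, vcov_mu, weights = self._gls(psi)
        val = 0.0
        for w, t, v in zip(weights, self.thetas, self.vcovs):
            _, logdet = np.linalg.slogdet(psi + v)
            r = t - mu
            val += logdet + float(r @ w @ r)
        _, logdet_u = np.linalg.slogdet(np.linalg.inv(vcov_mu))
        return val + logdet_u

    def _mom_start(self) -> np.ndarray:
        """Method-of-moments starting value for Psi (projected to PSD)."""
        resid = self.thetas - self.thetas.mean(axis=0)
        raw = resid.T @ resid / max(self.n_studies - 1, 1) - self.vcovs.mean(axis=0)
        w, q = np.linalg.eigh((raw + raw.T) / 2)
        return (q * np.clip(w, 0.0, None)) @ q.T

    def fit(self, maxiter: int = 200, tol: float = 1e-10) -> "MVMetaResults":
        p = self.dim
        start = self._mom_start()
        # jitter keeps the Cholesky well-defined at a zero start
        L0 = np.linalg.cholesky(start + 1e-6 * np.eye(p))
        x0 = L0[np.tril_indices(p)]

        def objective(x):
            psi = (lambda L: L @ L.T)(_vech_to_chol(x, p))
            return self._neg2_reml(psi)

        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10},
        )
        if not res.success and "ABNORMAL" in str(res.message).upper():
            raise RuntimeError(f"REML optimisation failed: {res.message}")
        L = _vech_to_chol(res.x, p)
        psi = L @ L.T
        # snap numerically-zero heterogeneity to exactly zero
        if np.abs(psi).max() < 1e-10:
            psi = np.zeros_like(psi)
        mu, vcov_mu, _ = self._gls(psi)
        return MVMetaResults(self, mu, vcov_mu, psi, loglik=-0.5 * res.fun)


class MVMetaResults:
    """Pooled estimates, between-study covariance, and BLUPs."""

    def __init__(self, model: MVMeta, mu, vcov_mu, psi, loglik):
        self.model = model
        self.mu = np.asarray(mu)
        self.vcov_mu = np.asarray(vcov_mu)
        self.psi = np.asarray(psi)
        self.loglik = loglik
        _check_psd(self.psi, "Psi")

    def blups(self):
        """Per-study BLUPs: (theta_blup_i, vcov_blup_i) for every study.

        theta_blup_i = mu + Psi (Psi + V_i)^-1 (theta_i - mu).
        The covariance is the conditional variance of the random effect
        plus the propagated uncertainty of mu-hat:
        Psi - Psi (Psi + V_i)^-1 Psi + A_i vcov_mu A_i',
        with A_i = I - Psi (Psi + V_i)^-1.
        """
        out = []
        eye = np.eye(self.model.dim)
        for theta, v in zip(self.model.thetas, self.model.vcovs):
            shrink = self.psi @ np.linalg.inv(self.psi + v)
            t_blup = self.mu + shrink @ (theta - self.mu)
            a = eye - shrink
            v_blup = self.psi - shrink @ self.psi + a @ self.vcov_mu @ a.T
            v_blup = (v_blup + v_blup.T) / 2
            out.append((t_blup, v_blup))
        return out

    def i2(self) -> np.ndarray:
        """Per-coefficient I^2 heterogeneity (%): Psi_jj / (Psi_jj + mean V_jj)."""
        within = np.mean([np.diag(v) for v in self.model.vcovs], axis=0)
        between = np.diag(self.psi)
        return 100.0 * between / np.where(between + within > 0, between + within, 1.0)

    def save(self, path) -> None:
        """Serialize mu, Psi, and BLUPs to a JSON text file."""
        import json

        payload = {
            "mu": self.mu.tolist(),
            "vcov_mu": self.vcov_mu.tolist(),
            "psi": self.psi.tolist(),
            "loglik": self.loglik,
            "blups": [
                {"theta": t.tolist(), "vcov": v.tolist()} for t, v in self.blups()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load(path) -> dict:
        """Load a serialized result; arrays come back as ndarrays."""
        import json

        with open(path) as fh:
            payload = json.load(fh)
        payload["mu"] = np.asarray(payload["mu"])
        payload["vcov_mu"] = np.asarray(payload["vcov_mu"])
        payload["psi"] = np.asarray(payload["psi"])
        payload["blups"] = [
            (np.asarray(b["theta"]), np.asarray(b["vcov"])) for b in payload["blups"]
        ]
        return payload

    def summary(self) -> str:
        lines = [
            "Multivariate random-effects meta-analysis (REML)",
            "=" * 55,
            f"studies:            {self.model.n_studies}",
            f"dimension:          {self.model.dim}",
            f"restricted loglik:  {self.loglik:.4f}",
            "pooled mu:          " + ", ".join(f"{m:.4g}" for m in self.mu),
            "mu SE:              "
            + ", ".join(f"{s:.4g}" for s in np.sqrt(np.diag(self.vcov_mu))),
            "I^2 (%):            " + ", ".join(f"{v:.1f}" for v in self.i2()),
        ]
        return "\n".join(lines)


def blup_single(mu, psi, theta, v):
    """Scalar/matrix BLUP helper: mu + Psi (Psi+V)^-1 (theta - mu)."""
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    v = np.atleast_2d(np.asarray(v, dtype=float))
    return mu + psi @ np.linalg.inv(psi + v) @ (theta - mu)
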