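"""Linked independent component analysis of multiple modality matrices.

Model
-----
Each standardized modality ``X_k`` (features x subjects) is factorized as::

    X_k = A_k H + E_k,      A_k = S_k diag(lambda_k)

with ONE subject-loading matrix ``H`` (components x subjects) shared by all
modalities, per-modality source maps ``S_k`` (unit-norm columns), weights
``lambda_k >= 0`` and isotropic Gaussian noise of precision ``beta_k``.
Source entries carry a sparsity-inducing mixture-of-Gaussians prior: a
narrow "spike" component for (near-)zero entries and a wide "slab"
component for active ones, with mixing weight and both variances estimated
per (modality, component).  The non-Gaussianity of this prior is what
resolves the rotational ambiguity of a plain SVD and makes the
decomposition an ICA; the per-(modality, component) mixture parameters act
as automatic relevance determination, letting a component's weight
collapse toward zero in modalities it does not explain.

Estimation is variational expectation-maximization in two phases sharing
one objective.  Phase 1 constrains ``H`` to orthonormal rows, under which
the source posterior factorizes over entries of ``W_k = X_k H^T`` and the
marginal likelihood is available in closed form (the M-step for ``H`` is
an orthogonal Procrustes solve on the pooled, noise-precision weighted
cross-products); Jacobi sweeps over Givens rotations of the loading rows,
with the mixture parameters profiled per candidate angle, break the
rotational near-degeneracy that plain EM escapes only slowly.  Phase 2
releases the orthonormality constraint -- real subject loadings need not
be mutually orthogonal -- and continues mean-field coordinate ascent on
the evidence lower bound, which coincides with the phase-1 marginal
likelihood at orthonormal ``H``; the concatenated objective trace is
therefore monotone non-decreasing.

Conventions: components are ordered by total explained variance
``sum_k lambda_k,c^2`` descending, and each loading row's sign is fixed so
its largest-magnitude entry is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import log_expit, logsumexp

from .errors import ConvergenceError, DimensionError, ParameterError

__all__ = [
    "LicaInput",
    "LicaModel",
    "ContributionMatrix",
    "standardize_modalities",
    "fit_lica",
    "contribution_fractions",
    "reconstruct",
]

_PI_CLIP = 1e-4         # mixing weight kept in [clip, 1-clip]
_V1_FLOOR_REL = 1e-8    # slab variance floor, relative to modality mean square
# Spike variance floor.  A free spike variance lets the mixture absorb small
# leakage entries (imperfect rotations, oblique loadings); the floor keeps
# exactly-zero entries from earning unbounded density rewards that would
# otherwise favour mixed solutions on noiseless data.
_V0_FLOOR_REL = 1e-4
_TAU2_FLOOR_REL = 1e-6  # noise variance floor (caps beta on noiseless data)


@dataclass
class LicaInput:
    """Standardized modalities sharing one subject axis."""

    modalities: list[np.ndarray]       # K arrays (F_k, N)
    modality_names: list[str]
    subject_ids: list[str]
    scales: np.ndarray                 # (K,) multiplicative standardization factors
    row_means: list[np.ndarray]        # per modality (F_k,) original feature means

    def __post_init__(self) -> None:
        if len(self.modalities) == 0:
            raise ParameterError("need at least one modality")
        n = len(self.subject_ids)
        for name, X in zip(self.modality_names, self.modalities):
            X = np.asarray(X, dtype=float)
            if X.ndim != 2 or X.shape[1] != n:
                raise DimensionError(
                    f"modality {name!r}: expected (features, {n}), got {X.shape}"
                )
            if X.shape[0] < 2:
                raise ParameterError(f"modality {name!r} needs >= 2 features")
            if not np.all(np.isfinite(X)):
                raise ParameterError(f"modality {name!r} contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def inverse_transform(self, k: int, X_std: np.ndarray) -> np.ndarray:
        """Map a standardized-scale matrix of modality ``k`` back to raw units."""
        return X_std / self.scales[k] + self.row_means[k][:, None]


def standardize_modalities(raw: list[np.ndarray],
                           modality_names: list[str] | None = None,
                           subject_ids: list[str] | None = None) -> LicaInput:
    """Center each feature across subjects and rescale each modality.

    After centering, every modality is globally rescaled to unit mean-square
    value (computed over its non-constant feature rows), so modalities with
    vastly different feature counts contribute on a comparable scale.
    """
    if len(raw) == 0:
        raise ParameterError("need at least one modality")
    n = np.asarray(raw[0]).shape[1]
    if modality_names is None:
        modality_names = [f"modality{k}" for k in range(len(raw))]
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(n)]
    if any(np.asarray(X).shape[1] != n for X in raw):
        shapes = [np.asarray(X).shape for X in raw]
        raise DimensionError(f"inconsistent subject counts across modalities: {shapes}")
    out, scales, means = [], [], []
    for name, X in zip(modality_names, raw):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ParameterError(f"modality {name!r} contains missing/non-finite values")
        mu = X.mean(axis=1)
        Xc = X - mu[:, None]
        active = Xc.var(axis=1) > 0
        if not np.any(active):
            raise ParameterError(f"modality {name!r} has zero variance")
        ms = float(np.mean(Xc[active] ** 2))
        c = 1.0 / np.sqrt(ms)
        out.append(Xc * c)
        scales.append(c)
        means.append(mu)
    return LicaInput(
        modalities=out,
        modality_names=list(modality_names),
        subject_ids=list(subject_ids),
        scales=np.asarray(scales),
        row_means=means,
    )


@dataclass
class LicaModel:
    """Fitted linked factorization."""

    H: np.ndarray                      # (C, N), unit-norm rows
    sources: list[np.ndarray]          # K arrays (F_k, C), unit-norm columns (or 0)
    lambdas: np.ndarray                # (K, C) >= 0, standardized scale
    betas: np.ndarray                  # (K,) noise precisions
    modality_names: list[str]
    subject_ids: list[str]
    scales: np.ndarray
    row_means: list[np.ndarray] = field(repr=False, default_factory=list)
    mixture_pi: np.ndarray | None = None      # (K, C) slab mixing weights
    mixture_var: np.ndarray | None = None     # (K, C) slab variances
    mixture_var0: np.ndarray | None = None    # (K, C) spike variances
    n_iter: int = 0
    converged: bool = True
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0

    @property
    def n_components(self) -> int:
        return self.H.shape[0]

    def modality_index(self, name_or_index) -> int:
        if isinstance(name_or_index, str):
            try:
                return self.modality_names.index(name_or_index)
            except ValueError:
                raise ParameterError(f"unknown modality {name_or_index!r}") from None
        k = int(name_or_index)
        if not 0 <= k < len(self.sources):
            raise ParameterError(f"modality index {k} out of range")
        return k


@dataclass
class ContributionMatrix:
    """Per-component explained-variance fractions by modality (columns sum to 1)."""

    P: np.ndarray                      # (K, C)
    modality_names: list[str]
    degenerate: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise ParameterError("contribution fractions must lie in [0, 1]")
        if not np.allclose(self.P.sum(axis=0), 1.0, atol=1e-9):
            raise ParameterError("contribution columns must sum to 1")


def _svd_init(Xs: list[np.ndarray], C: int) -> np.ndarray:
    stacked = np.vstack(Xs)
    _, _, Vt = sla.svd(stacked, full_matrices=False)
    H0 = Vt[:C]
    # deterministic sign: largest-|.| entry of each row positive
    for c in range(C):
        j = int(np.argmax(np.abs(H0[c])))
        if H0[c, j] < 0:
            H0[c] = -H0[c]
    return H0


def _mix_logpdf(W, pi, v1, v0, tau2):
    """Entrywise log density of the two-Gaussian marginal of W columns."""
    slab = -0.5 * (np.log(2 * np.pi * (v1 + tau2)) + W**2 / (v1 + tau2))
    spike = -0.5 * (np.log(2 * np.pi * (v0 + tau2)) + W**2 / (v0 + tau2))
    return logsumexp(np.stack([np.log(pi) + slab, np.log1p(-pi) + spike]), axis=0)


def _marginal_loglik(Xs, norm2, H, betas, pis, v1s, v0s) -> float:
    """Exact marginal log likelihood for orthonormal loading rows."""
    C = H.shape[0]
    total = 0.0
    for k, X in enumerate(Xs):
        F, N = X.shape
        tau2 = 1.0 / betas[k]
        W = X @ H.T
        total += float(_mix_logpdf(W, pis[k], v1s[k], v0s[k], tau2).sum())
        r2 = max(norm2[k] - float(np.sum(W**2)), 0.0)
        total += 0.5 * F * (N - C) * (np.log(betas[k]) - np.log(2 * np.pi)) \
            - 0.5 * betas[k] * r2
    return total


def _posterior_moments(W, pi, v1, v0, tau2):
    """Exact entrywise posterior of source entries given W = A + noise.

    Returns (responsibility of the slab, E[a], E[a^2], slab-conditional
    E[a^2], spike-conditional E[a^2]).
    """
    s1, s0 = v1 + tau2, v0 + tau2
    log_odds = (np.log(pi) - np.log1p(-pi)
                + 0.5 * (np.log(s0) - np.log(s1))
                + 0.5 * W**2 * (1.0 / s0 - 1.0 / s1))
    r = np.exp(log_expit(log_odds))
    k1, k0 = v1 / s1, v0 / s0
    ea2_1 = k1 * tau2 + (k1 * W) ** 2
    ea2_0 = k0 * tau2 + (k0 * W) ** 2
    EA = (r * k1 + (1 - r) * k0) * W
    EA2 = r * ea2_1 + (1 - r) * ea2_0
    return r, EA, EA2, ea2_1, ea2_0


def _update_mixture(r, ea2_1, ea2_0, F, v1_floor, v0_floor):
    """Closed-form M-step for (pi, v1, v0) with slab kept the wider one."""
    rc = r.sum(axis=0)
    pi = np.clip(rc / F, _PI_CLIP, 1 - _PI_CLIP)
    v1 = np.maximum((r * ea2_1).sum(axis=0) / np.maximum(rc, 1e-300), v1_floor)
    v0 = np.maximum(((1 - r) * ea2_0).sum(axis=0) / np.maximum(F - rc, 1e-300),
                    v0_floor)
    swap = v0 > v1
    if np.any(swap):
        v1_s, v0_s = np.where(swap, v0, v1), np.where(swap, v1, v0)
        pi = np.where(swap, 1 - pi, pi)
        v1, v0 = v1_s, np.maximum(v0_s, v0_floor)
    return pi, v1, v0


def _profile_column(W, pi0, v10, v00, tau2, v1_floor, v0_floor, n_em: int = 4):
    """Profile the mixture log-likelihood of candidate columns over (pi, v1, v0).

    ``W`` is (F, n_cand) -- one candidate column per grid angle; a few
    vectorized EM updates per candidate re-estimate the mixture parameters
    from the warm start.  Returns the profiled log likelihood and the
    parameters per candidate.
    """
    F, n_cand = W.shape
    pi = np.full(n_cand, pi0)
    v1 = np.full(n_cand, v10)
    v0 = np.full(n_cand, v00)
    for _ in range(n_em):
        r, _, _, ea2_1, ea2_0 = _posterior_moments(W, pi, v1, v0, tau2)
        pi, v1, v0 = _update_mixture(r, ea2_1, ea2_0, F, v1_floor, v0_floor)
    ll = _mix_logpdf(W, pi[None, :], v1[None, :], v0[None, :], tau2).sum(axis=0)
    return ll, pi, v1, v0


def _rotation_sweep(Ws, H, betas, pis, v1s, v0s, v1_floor, v0_floor,
                    n_grid: int = 33):
    """Jacobi sweep over component pairs: accept Givens rotations of the
    loading rows that increase the exact marginal likelihood.

    Rotations leave the residual term invariant (column energies are
    preserved), so only the source-mixture term matters; it is profiled
    over each column's mixture parameters so the search is a joint
    coordinate ascent over (rotation, mixture parameters).
    """
    C = H.shape[0]
    K = len(Ws)
    improved = False

    def evaluate(a, b, thetas):
        cos, sin = np.cos(thetas), np.sin(thetas)
        vals = np.zeros(len(thetas))
        prof = []
        for k in range(K):
            tau2 = 1.0 / betas[k]
            wa, wb = Ws[k][:, a], Ws[k][:, b]
            Wa = wa[:, None] * cos + wb[:, None] * sin       # (F, n_theta)
            Wb = -wa[:, None] * sin + wb[:, None] * cos
            ll_a, pi_a, v1_a, v0_a = _profile_column(
                Wa, pis[k][a], v1s[k][a], v0s[k][a], tau2, v1_floor[k], v0_floor[k])
            ll_b, pi_b, v1_b, v0_b = _profile_column(
                Wb, pis[k][b], v1s[k][b], v0s[k][b], tau2, v1_floor[k], v0_floor[k])
            vals += ll_a + ll_b
            prof.append((pi_a, v1_a, v0_a, pi_b, v1_b, v0_b))
        return vals, prof

    def apply(a, b, theta, prof, j):
        for k, (pi_a, v1_a, v0_a, pi_b, v1_b, v0_b) in enumerate(prof):
            pis[k][a], v1s[k][a], v0s[k][a] = pi_a[j], v1_a[j], v0_a[j]
            pis[k][b], v1s[k][b], v0s[k][b] = pi_b[j], v1_b[j], v0_b[j]
        if theta == 0.0:
            return
        c_j, s_j = np.cos(theta), np.sin(theta)
        ha, hb = H[a].copy(), H[b].copy()
        H[a], H[b] = c_j * ha + s_j * hb, -s_j * ha + c_j * hb
        for k in range(K):
            wa, wb = Ws[k][:, a].copy(), Ws[k][:, b].copy()
            Ws[k][:, a] = c_j * wa + s_j * wb
            Ws[k][:, b] = -s_j * wa + c_j * wb

    for a in range(C):
        for b in range(a + 1, C):
            # inner-converge this pair: coarse grid, then one zoom level
            for _ in range(20):
                thetas = np.linspace(-np.pi / 4, np.pi / 4, n_grid)
                vals, prof = evaluate(a, b, thetas)
                mid = (n_grid - 1) // 2
                j = int(np.argmax(vals))
                if vals[j] <= vals[mid] + 1e-10:
                    apply(a, b, 0.0, prof, mid)
                    break
                step = thetas[1] - thetas[0]
                fine = np.linspace(thetas[j] - step, thetas[j] + step, n_grid)
                fvals, fprof = evaluate(a, b, fine)
                jf = int(np.argmax(fvals))
                if fvals[jf] > vals[j]:
                    apply(a, b, fine[jf], fprof, jf)
                else:
                    apply(a, b, thetas[j], prof, j)
                improved = True
    return improved


def _elbo_oblique(Xs, norm2, H, betas, pis, v1s, v0s, state):
    """Evidence lower bound of the mean-field mixture posterior.

    Exact (equal to the marginal likelihood) whenever the loading rows are
    orthonormal; a proper lower bound for general oblique rows.
    """
    G = H @ H.T
    total = 0.0
    for k, X in enumerate(Xs):
        F, N = X.shape
        EA, EA2, r, mu1, mu0, s1, s0 = (state[k][key] for key in
                                        ("EA", "EA2", "r", "mu1", "mu0", "s1", "s0"))
        M = EA.T @ EA
        np.fill_diagonal(M, EA2.sum(axis=0))
        e2 = norm2[k] - 2.0 * float(np.sum(EA * (X @ H.T))) + float(np.sum(G * M))
        total += 0.5 * F * N * (np.log(betas[k]) - np.log(2 * np.pi)) \
            - 0.5 * betas[k] * e2
        with np.errstate(divide="ignore", invalid="ignore"):
            rlogr = np.where(r > 0, r * np.log(np.maximum(r, 1e-300)), 0.0)
            q0log = np.where(r < 1, (1 - r) * np.log(np.maximum(1 - r, 1e-300)), 0.0)
        m2_1 = 1.0 / s1 + mu1**2          # slab-conditional second moment
        m2_0 = 1.0 / s0 + mu0**2
        prior = (r * (np.log(pis[k]) - 0.5 * np.log(2 * np.pi * v1s[k])
                      - 0.5 * m2_1 / v1s[k])
                 + (1 - r) * (np.log1p(-pis[k]) - 0.5 * np.log(2 * np.pi * v0s[k])
                              - 0.5 * m2_0 / v0s[k]))
        entropy = (-rlogr - q0log
                   + 0.5 * r * np.log(2 * np.pi * np.e / s1)
                   + 0.5 * (1 - r) * np.log(2 * np.pi * np.e / s0))
        total += float(prior.sum() + entropy.sum())
    return total


def _refine_oblique(Xs, norm2, H, betas, pis, v1s, v0s, max_iter, tol,
                    v1_floor, v0_floor, tau2_floor):
    """Mean-field VB refinement with unconstrained (oblique) loading rows.

    Coordinate ascent over per-entry mixture posteriors (all rows of one
    component jointly), closed-form updates for the mixture parameters,
    noise precisions and the shared loading matrix.  Every step is
    non-decreasing in the ELBO.
    """
    K = len(Xs)
    C, N = H.shape
    state = [
        {"EA": np.zeros((X.shape[0], C)), "EA2": np.zeros((X.shape[0], C)),
         "r": np.zeros((X.shape[0], C)), "mu1": np.zeros((X.shape[0], C)),
         "mu0": np.zeros((X.shape[0], C)), "s1": np.ones(C), "s0": np.ones(C)}
        for X in Xs
    ]
    trace = []
    converged = False
    for it in range(int(max_iter)):
        G = H @ H.T
        for k, X in enumerate(Xs):
            F = X.shape[0]
            beta = betas[k]
            st = state[k]
            XhT = X @ H.T                          # (F, C)
            for c in range(C):
                rho = beta * (XhT[:, c] - st["EA"] @ G[:, c]
                              + st["EA"][:, c] * G[c, c])
                s1 = beta * G[c, c] + 1.0 / v1s[k][c]
                s0 = beta * G[c, c] + 1.0 / v0s[k][c]
                mu1, mu0 = rho / s1, rho / s0
                log_odds = (np.log(pis[k][c]) - np.log1p(-pis[k][c])
                            + 0.5 * np.log((v0s[k][c] * s0) / (v1s[k][c] * s1))
                            + 0.5 * (mu1**2 * s1 - mu0**2 * s0))
                r = np.exp(log_expit(log_odds))
                st["EA"][:, c] = r * mu1 + (1 - r) * mu0
                st["EA2"][:, c] = r * (1.0 / s1 + mu1**2) + (1 - r) * (1.0 / s0 + mu0**2)
                st["r"][:, c] = r
                st["mu1"][:, c] = mu1
                st["mu0"][:, c] = mu0
                st["s1"][c] = s1
                st["s0"][c] = s0
            # mixture parameter updates (slab/spike-conditional moments)
            m2_1 = 1.0 / st["s1"][None, :] + st["mu1"]**2
            m2_0 = 1.0 / st["s0"][None, :] + st["mu0"]**2
            rc = st["r"].sum(axis=0)
            pis[k] = np.clip(rc / F, _PI_CLIP, 1 - _PI_CLIP)
            v1s[k] = np.maximum((st["r"] * m2_1).sum(axis=0)
                                / np.maximum(rc, 1e-300), v1_floor[k])
            v0s[k] = np.clip(((1 - st["r"]) * m2_0).sum(axis=0)
                             / np.maximum(F - rc, 1e-300), v0_floor[k], v1s[k])
        # shared loading update: pooled normal equations over all modalities
        Mtot = np.zeros((C, C))
        Btot = np.zeros((C, N))
        for k, X in enumerate(Xs):
            M = state[k]["EA"].T @ state[k]["EA"]
            np.fill_diagonal(M, state[k]["EA2"].sum(axis=0))
            Mtot += betas[k] * M
            Btot += betas[k] * (state[k]["EA"].T @ X)
        try:
            H = np.linalg.solve(Mtot, Btot)
        except np.linalg.LinAlgError:
            H = np.linalg.pinv(Mtot) @ Btot
        G = H @ H.T
        for k, X in enumerate(Xs):
            F = X.shape[0]
            M = state[k]["EA"].T @ state[k]["EA"]
            np.fill_diagonal(M, state[k]["EA2"].sum(axis=0))
            e2 = norm2[k] - 2.0 * float(np.sum(state[k]["EA"] * (X @ H.T))) \
                + float(np.sum(G * M))
            betas[k] = F * N / max(e2, F * N * tau2_floor[k])
        ll = _elbo_oblique(Xs, norm2, H, betas, pis, v1s, v0s, state)
        if not np.isfinite(ll):
            raise ConvergenceError(f"non-finite objective in refinement iteration {it}")
        trace.append(ll)
        if it > 0 and abs(ll - trace[-2]) <= tol * (1.0 + abs(trace[-2])):
            converged = True
            break
    EAs = [state[k]["EA"] for k in range(K)]
    return H, EAs, betas, pis, v1s, v0s, np.asarray(trace), converged


def _fit_once(Xs, C, max_iter, tol, H0):
    K = len(Xs)
    ms = np.array([float(np.mean(X**2)) for X in Xs])
    norm2 = np.array([float(np.sum(X**2)) for X in Xs])
    N = Xs[0].shape[1]
    tau2_floor = _TAU2_FLOOR_REL * ms
    v1_floor = _V1_FLOOR_REL * ms
    v0_floor = _V0_FLOOR_REL * ms

    H = H0.copy()
    # initial noise precisions from the residual off the initial subspace
    betas = np.empty(K)
    pis = np.full((K, C), 0.5)
    v1s = np.empty((K, C))
    v0s = np.empty((K, C))
    for k, X in enumerate(Xs):
        F, _ = X.shape
        W = X @ H.T
        r2 = max(norm2[k] - float(np.sum(W**2)), 0.0)
        betas[k] = F * N / max(r2, F * N * tau2_floor[k])
        v1s[k] = np.maximum(np.mean(W**2, axis=0) - 1.0 / betas[k], 1e-3 * ms[k])
        v0s[k] = np.full(C, max(1.0 / betas[k], v0_floor[k]))

    trace = []
    last_sweep = -10
    EAs = [np.zeros((X.shape[0], C)) for X in Xs]
    for it in range(int(max_iter)):
        # E-step: exact source posterior per entry of W_k = X_k H^T
        G = np.zeros((C, N))
        ea2_tot = np.empty(K)
        for k, X in enumerate(Xs):
            F, _ = X.shape
            tau2 = 1.0 / betas[k]
            W = X @ H.T
            r, EA, EA2, ea2_1, ea2_0 = _posterior_moments(
                W, pis[k], v1s[k], v0s[k], tau2)
            EAs[k] = EA
            pis[k], v1s[k], v0s[k] = _update_mixture(
                r, ea2_1, ea2_0, F, v1_floor[k], v0_floor[k])
            G += betas[k] * (EA.T @ X)
            ea2_tot[k] = float(EA2.sum())
        # M-step, shared loadings: orthogonal Procrustes on pooled cross-products
        U, _, Vt = sla.svd(G, full_matrices=False)
        H = U @ Vt
        # M-step, noise precisions (expected residual with the new H)
        for k, X in enumerate(Xs):
            F, _ = X.shape
            cross = float(np.sum(EAs[k] * (X @ H.T)))
            e2 = norm2[k] - 2.0 * cross + ea2_tot[k]
            betas[k] = F * N / max(e2, F * N * tau2_floor[k])
        # Givens rotation sweeps are comparatively costly, so they run early
        # (to break the initial rotational degeneracy) and whenever plain EM
        # stalls; convergence additionally requires a quiescent sweep.
        ll = _marginal_loglik(Xs, norm2, H, betas, pis, v1s, v0s)
        if not np.isfinite(ll):
            raise ConvergenceError(f"non-finite objective at iteration {it}")
        rel = abs(ll - trace[-1]) / (1.0 + abs(trace[-1])) if it > 0 else np.inf
        stalled = rel <= tol
        slowing = rel <= max(tol, 1e-6)
        if it < 3 or stalled or (slowing and it - last_sweep >= 5):
            last_sweep = it
            Ws = [X @ H.T for X in Xs]
            rotated = _rotation_sweep(Ws, H, betas, pis, v1s, v0s,
                                      v1_floor, v0_floor)
            if rotated:
                ll = _marginal_loglik(Xs, norm2, H, betas, pis, v1s, v0s)
            trace.append(ll)
            if stalled and not rotated:
                break
        else:
            trace.append(ll)

    # oblique refinement: drop the orthonormality constraint on the loading
    # rows and continue coordinate ascent on the same variational objective
    H, EAs, betas, pis, v1s, v0s, trace2, converged = _refine_oblique(
        Xs, norm2, H, betas, pis, v1s, v0s, max_iter, tol,
        v1_floor, v0_floor, tau2_floor,
    )
    full_trace = np.concatenate([np.asarray(trace), trace2])
    return H, EAs, betas, pis, v1s, v0s, full_trace, converged


def fit_lica(input: LicaInput, n_components: int = 10, max_iter: int = 4000,
             tol: float = 1e-9, seed: int = 0, n_restarts: int = 0) -> LicaModel:
    """Fit the linked factorization by variational expectation-maximization.

    Initialization is a deterministic SVD of the row-stacked standardized
    modalities; ``n_restarts`` adds that many seeded random rotations of the
    initial subspace, keeping the solution with the best final objective.
    ``max_iter`` caps each of the two optimization phases.
    """
    C = int(n_components)
    N = input.n_subjects
    if C < 1:
        raise ParameterError("n_components must be >= 1")
    if C > N:
        raise ParameterError(f"n_components={C} exceeds subject count {N}")
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    Xs = [np.asarray(X, dtype=float) for X in input.modalities]

    H_svd = _svd_init(Xs, C)
    inits = [H_svd]
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(17,)))
    for _ in range(int(n_restarts)):
        Q, _ = np.linalg.qr(rng.standard_normal((C, C)))
        inits.append(Q @ H_svd)

    best = None
    for H0 in inits:
        result = _fit_once(Xs, C, max_iter, tol, H0)
        if best is None or result[6][-1] > best[6][-1]:
            best = result
    H, EAs, betas, pis, v1s, v0s, trace, converged = best

    # fold loading-row norms into the weights so H rows are unit-norm
    H = H.copy()
    row_norms = np.linalg.norm(H, axis=1)
    for c in np.flatnonzero(row_norms == 0):
        H[c, c % N] = 1.0          # dead component: arbitrary unit row, zero weight
        row_norms[c] = 1.0
    H /= row_norms[:, None]
    lambdas = np.stack([np.linalg.norm(EA, axis=0) for EA in EAs]) * row_norms  # (K, C)
    sources = []
    for EA in EAs:
        lam = np.linalg.norm(EA, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(lam > 0, EA / np.where(lam > 0, lam, 1.0), 0.0)
        sources.append(S)

    # order components by total explained variance, fix loading-row signs
    order = np.argsort(-np.sum(lambdas**2, axis=0), kind="stable")
    H = H[order]
    lambdas = lambdas[:, order]
    pis = pis[:, order]
    v1s = v1s[:, order]
    v0s = v0s[:, order]
    sources = [S[:, order] for S in sources]
    for c in range(C):
        j = int(np.argmax(np.abs(H[c])))
        if H[c, j] < 0:
            H[c] = -H[c]
            for S in sources:
                S[:, c] = -S[:, c]

    return LicaModel(
        H=H,
        sources=sources,
        lambdas=lambdas,
        betas=betas,
        modality_names=list(input.modality_names),
        subject_ids=list(input.subject_ids),
        scales=np.asarray(input.scales),
        row_means=[m.copy() for m in input.row_means],
        mixture_pi=pis,
        mixture_var=v1s,
        mixture_var0=v0s,
        n_iter=len(trace),
        converged=converged,
        objective_trace=trace,
        seed=int(seed),
    )


def contribution_fractions(model: LicaModel) -> ContributionMatrix:
    """P[k, c] = lambda_k,c^2 / sum_k' lambda_k',c^2 on the standardized scale.

    With unit-norm source columns and loading rows, lambda^2 is the variance
    a component explains in a modality, so columns of P are the modality
    shares of each component's explained variance.  Components with zero
    weight everywhere get a uniform column and are flagged degenerate.
    """
    lam2 = model.lambdas**2
    totals = lam2.sum(axis=0)
    K = lam2.shape[0]
    degenerate = [int(c) for c in np.flatnonzero(totals == 0)]
    safe = np.where(totals > 0, totals, 1.0)
    P = np.where(totals > 0, lam2 / safe, 1.0 / K)
    return ContributionMatrix(P=P, modality_names=list(model.modality_names),
                              degenerate=degenerate)


def reconstruct(model: LicaModel, modality, components=None,
                destandardize: bool = False) -> np.ndarray:
    """Sum of S_k[:, c] * lambda_k,c * H[c, :] over a component subset.

    An empty subset returns a zero matrix.  ``destandardize`` maps the
    result back to the raw feature scale of the fitted input.
    """
    k = model.modality_index(modality)
    C = model.n_components
    if components is None:
        components = range(C)
    comps = [int(c) for c in components]
    if any(not 0 <= c < C for c in comps):
        raise ParameterError(f"component subset {comps} out of range")
    S = model.sources[k]
    X = np.zeros((S.shape[0], model.H.shape[1]))
    for c in comps:
        X += np.outer(S[:, c] * model.lambdas[k, c], model.H[c])
    if destandardize:
        X = X / model.scales[k] + model.row_means[k][:, None]
    return X
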