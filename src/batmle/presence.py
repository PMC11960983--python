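"""Maximum-likelihood presence testing from classified call counts.

The statistical question: given a night's classified file counts and a
classifier whose misclassification rates are known, is there evidence
that species *s* was actually recorded, beyond what misclassification
of the other species would produce?

Model. Condition on the files that received a species label. Each such
file's label is drawn from the mixture ``P(label j) = sum_i pi_i *
theta'[i, j]`` where ``pi`` is the (unknown) true species composition
of the night and ``theta'`` is the confusion matrix with the NOID
column removed and rows renormalised. The composition is estimated by
maximum likelihood on the simplex via EM, and presence of species *s*
is a likelihood-ratio test of ``H0: pi_s = 0`` against the
unconstrained alternative.

Because H0 pins ``pi_s`` to the boundary of the simplex, the usual
chi-square(1) reference distribution is replaced by the boundary
mixture ``0.5*delta_0 + 0.5*chi2_1``; a parametric bootstrap of the
statistic is available as a reference method. A p-value at or below
``alpha`` (0.05 by convention in survey guidance) declares acoustic
presence for the night.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .classifier import ClassifiedNight, ConfusionMatrix
from .species import species_index

EM_TOL = 1e-10
EM_MAX_ITER = 10_000

_TINY = 1e-300


class DegenerateNightError(ValueError):
    """Raised when a night has no classified files to test."""


@dataclass(frozen=True)
class CompositionFit:
    """Maximum-likelihood estimate of a night's true species mix."""

    pi_hat: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    species: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, map(float, self.pi_hat)))


@dataclass(frozen=True)
class PresenceResult:
    """Per-species presence p-values for one night at a threshold."""

    pvalues: dict[str, float]
    alpha: float
    method: str

    @property
    def present(self) -> dict[str, bool]:
        return {s: p <= self.alpha for s, p in self.pvalues.items()}


def _loglik(C: np.ndarray, pi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Row log-likelihoods for counts C (N,k) under compositions pi (N,k)."""
    M = np.clip(pi @ theta, _TINY, None)
    return np.einsum("nj,nj->n", C, np.log(M))


def em_batch(
    C: np.ndarray,
    theta: np.ndarray,
    active: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    pi0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM on many nights at once.

    Parameters
    ----------
    C : (N, k) nonnegative counts (fractional allowed).
    theta : (k, k) row-stochastic conditional confusion matrix.
    active : (N, k) bool; species forced to zero are inactive.
    pi0 : optional explicit start; defaults to uniform over active.

    Returns ``(pi, loglik, n_iter, converged)``. The EM update for
    mixture weights guarantees a nondecreasing log-likelihood; rows stop
    iterating once their gain drops below ``tol``.
    """
    C = np.asarray(C, dtype=float)
    N, k = C.shape
    totals = C.sum(axis=1)
    if np.any(totals <= 0):
        raise DegenerateNightError("night with no classified files")
    if pi0 is None:
        pi = active / active.sum(axis=1, keepdims=True)
    else:
        pi = np.where(active, pi0, 0.0)
        pi = pi / np.clip(pi.sum(axis=1, keepdims=True), _TINY, None)
    ll = _loglik(C, pi, theta)
    n_iter = np.zeros(N, dtype=int)
    running = np.ones(N, dtype=bool)
    for _ in range(max_iter):
        idx = np.flatnonzero(running)
        if idx.size == 0:
            break
        p = pi[idx]
        M = np.clip(p @ theta, _TINY, None)
        # E+M step for mixture weights: pi_i <- pi_i * sum_j c_j theta_ij / M_j / n
        p_new = p * ((C[idx] / M) @ theta.T) / totals[idx, None]
        p_new = np.where(active[idx], p_new, 0.0)
        sums = p_new.sum(axis=1, keepdims=True)
        # if the active species give (numerically) zero mass to every
        # observed label, the update collapses: keep the current point,
        # whose clipped log-likelihood already reflects impossibility
        stuck = sums[:, 0] <= 0
        if stuck.any():
            p_new[stuck] = p[stuck]
            sums[stuck] = 1.0
        p_new /= sums
        ll_new = _loglik(C[idx], p_new, theta)
        pi[idx] = p_new
        gain = ll_new - ll[idx]
        ll[idx] = ll_new
        n_iter[idx] += 1
        still = gain >= tol
        running[idx] = still
    converged = ~running
    return pi, ll, n_iter, converged


def _check_night(night: ClassifiedNight, cm: ConfusionMatrix) -> np.ndarray:
    if night.species != cm.species:
        raise ValueError("night and confusion matrix cover different species")
    if night.total_classified <= 0:
        raise DegenerateNightError("night has zero classified files")
    return cm.conditional()


def fit_composition(
    night: ClassifiedNight,
    cm: ConfusionMatrix,
    zero_species: Iterable[str] = (),
    n_restarts: int = 0,
    seed: int = 0,
) -> CompositionFit:
    """Estimate the night's true species proportions by EM.

    ``zero_species`` lists species whose proportion is pinned to zero
    (the constrained fit of the presence test). EM starts from the
    uniform composition; optional seeded random restarts guard against
    flat likelihoods, keeping the best final log-likelihood.
    """
    theta = _check_night(night, cm)
    k = cm.n_species
    zero = set(zero_species)
    active = np.ones((1, k), dtype=bool)
    for s in zero:
        active[0, species_index(s, cm.species)] = False
    if not active.any():
        raise ValueError("cannot zero out every species")
    C = night.counts[None, :]
    pi, ll, it, conv = em_batch(C, theta, active)
    best = (pi[0], float(ll[0]), int(it[0]), bool(conv[0]))
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            start = np.where(active, rng.dirichlet(np.ones(k))[None, :], 0.0)
            p, l2, i2, c2 = em_batch(C, theta, active, pi0=start)
            if l2[0] > best[1]:
                best = (p[0], float(l2[0]), int(i2[0]), bool(c2[0]))
    return CompositionFit(
        pi_hat=best[0], loglik=best[1], n_iter=best[2], converged=best[3],
        species=cm.species,
    )


def _lrt_pvalue(lam: float | np.ndarray) -> float | np.ndarray:
    """Boundary-mixture p-value: P(0.5*delta_0 + 0.5*chi2_1 >= lam)."""
    lam = np.asarray(lam, dtype=float)
    p = np.where(lam <= 0, 1.0, 0.5 * stats.chi2.sf(lam, df=1))
    return float(p) if p.ndim == 0 else p


def lr_statistic(
    night: ClassifiedNight, cm: ConfusionMatrix, species: str
) -> tuple[float, CompositionFit, CompositionFit]:
    """Likelihood-ratio statistic for H0: pi_species = 0."""
    full = fit_composition(night, cm)
    null = fit_composition(night, cm, zero_species=[species])
    lam = max(2.0 * (full.loglik - null.loglik), 0.0)
    return lam, full, null


def presence_pvalue(
    night: ClassifiedNight,
    cm: ConfusionMatrix,
    species: str,
    method: str = "lrt",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Presence p-value for one species on one night.

    ``lrt`` uses the boundary-mixture reference distribution and is
    deterministic. ``bootstrap`` simulates ``n_boot`` nights of the same
    total from the constrained (species-absent) fit, recomputes the
    statistic on each, and returns the add-one-smoothed tail proportion;
    it requires an (effectively) integer night total.
    """
    lam, full, null = lr_statistic(night, cm, species)
    if method == "lrt":
        return float(_lrt_pvalue(lam)) if lam > 0 else 1.0
    if method != "bootstrap":
        raise ValueError(f"method must be 'lrt' or 'bootstrap', got {method!r}")

    total = night.total_classified
    n = int(round(total))
    if abs(total - n) > 1e-9:
        raise ValueError("bootstrap requires an integer number of classified files")
    theta = cm.conditional()
    k = cm.n_species
    s_idx = species_index(species, cm.species)
    q = null.pi_hat @ theta
    rng = np.random.default_rng(seed)
    Cb = rng.multinomial(n, q, size=n_boot).astype(float)
    # degenerate draws (all mass on one label) are still valid nights
    act_full = np.ones((n_boot, k), dtype=bool)
    act_null = act_full.copy()
    act_null[:, s_idx] = False
    _, ll_f, _, _ = em_batch(Cb, theta, act_full)
    _, ll_0, _, _ = em_batch(Cb, theta, act_null)
    lam_b = np.maximum(2.0 * (ll_f - ll_0), 0.0)
    return float((1 + np.sum(lam_b >= lam - 1e-12)) / (n_boot + 1))


def pvalues_matrix(
    C: np.ndarray, cm: ConfusionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """LRT p-values for every species on every night, vectorised.

    ``C`` is an (N, k) matrix of classified counts. Returns
    ``(pvalues, lam)`` both (N, k): one full EM fit per night plus one
    constrained fit per species, all batched.
    """
    theta = cm.conditional()
    C = np.asarray(C, dtype=float)
    N, k = C.shape
    lam = np.zeros((N, k))
    ok = C.sum(axis=1) > 0  # empty nights carry no evidence: lam = 0, p = 1
    if ok.any():
        Cok = C[ok]
        act = np.ones((Cok.shape[0], k), dtype=bool)
        _, ll_full, _, _ = em_batch(Cok, theta, act)
        lam_ok = np.empty((Cok.shape[0], k))
        for s in range(k):
            a = act.copy()
            a[:, s] = False
            _, ll0, _, _ = em_batch(Cok, theta, a)
            lam_ok[:, s] = np.maximum(2.0 * (ll_full - ll0), 0.0)
        lam[ok] = lam_ok
    return _lrt_pvalue(lam), lam


def night_presence(
    night: ClassifiedNight,
    cm: ConfusionMatrix,
    alpha: float = 0.05,
    method: str = "lrt",
    n_boot: int = 1000,
    seed: int = 0,
) -> PresenceResult:
    """Presence p-values for all species on one night."""
    if method == "lrt":
        _check_night(night, cm)
        p, _ = pvalues_matrix(night.counts[None, :], cm)
        pvalues = dict(zip(cm.species, map(float, p[0])))
    else:
        pvalues = {
            s: presence_pvalue(night, cm, s, method=method, n_boot=n_boot,
                               seed=seed + i)
            for i, s in enumerate(cm.species)
        }
    return PresenceResult(pvalues=pvalues, alpha=alpha, method=method)


def grid_oracle(
    night: ClassifiedNight,
    cm: ConfusionMatrix,
    step: float = 1e-3,
    active_species: Sequence[str] | None = None,
) -> CompositionFit:
    """Exhaustive simplex-grid likelihood maximisation (test oracle).

    Enumerates compositions on a grid of resolution ``step`` over at
    most 3 active species (the rest pinned to zero) and returns the
    best. Deliberately brute force and independent of the EM code path;
    intended for verifying fits in tests, not for production use.
    """
    theta = _check_night(night, cm)
    k = cm.n_species
    if active_species is None:
        active_species = list(cm.species)
    idx = [species_index(s, cm.species) for s in active_species]
    if len(idx) > 3:
        raise ValueError("grid oracle supports at most 3 active species")
    m = int(round(1.0 / step))
    g = np.arange(m + 1) / m
    if len(idx) == 1:
        P = np.array([[1.0]])
    elif len(idx) == 2:
        P = np.column_stack([g, 1.0 - g])
    else:
        a, b = np.meshgrid(g, g, indexing="ij")
        keep = a + b <= 1.0 + 1e-12
        P = np.column_stack([a[keep], b[keep], 1.0 - a[keep] - b[keep]])
    pi_full = np.zeros((P.shape[0], k))
    pi_full[:, idx] = P
    ll = _loglik(np.broadcast_to(night.counts, pi_full.shape), pi_full, theta)
    best = int(np.argmax(ll))
    return CompositionFit(
        pi_hat=pi_full[best], loglik=float(ll[best]), n_iter=0, converged=True,
        species=cm.species,
    )
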