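"""Univariate Gaussian mixtures, BIC model selection, and the modality call.

A CpG[o/e] distribution that resolves into two well-separated components —
a low-mean (historically methylated) and a high-mean (historically
unmethylated) class — is the classic sequence signature of germ-line DNA
methylation; a single component indicates its absence. This module fits
K-component univariate Gaussian mixtures by expectation-maximization under
two variance families (equal variance across components and unequal — the
"E" and "V" families of classical model-based clustering), ranks the
candidate models by the Bayesian information
criterion, and turns the ranking into a conservative bimodal/unimodal call.

BIC convention: minimized, BIC = -2*logL + p*ln(n). Printed values are
comparable only within this package; rank order matches the maximized form.

Permutation invariance: fitted parameters are exactly independent of input
order. Values are sorted internally before EM, and random restarts perturb
the fit only through quantiles of the data (order statistics), never through
per-row assignments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

EQUAL = "equal"
UNEQUAL = "unequal"
BIMODAL = "bimodal_methylation_signature"
UNIMODAL = "unimodal_no_signature"

_LOG_2PI = math.log(2.0 * math.pi)


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested fit (e.g. constant
    values with K >= 2)."""


@dataclass(frozen=True)
class MixtureFit:
    """A fitted K-component univariate Gaussian mixture.

    Components are sorted by ascending mean. ``n_params`` counts K-1 weights,
    K means, and K (unequal) or 1 (equal) variances; ``bic`` is the minimized
    convention -2*logL + n_params*ln(n_obs).
    """

    k: int
    weights: tuple[float, ...]
    means: tuple[float, ...]
    variances: tuple[float, ...]
    variance_family: str
    loglik: float
    n_params: int
    bic: float
    n_obs: int
    converged: bool
    n_iter: int
    loglik_trace: tuple[float, ...] = field(repr=False, default=())

    @property
    def sds(self) -> tuple[float, ...]:
        return tuple(math.sqrt(v) for v in self.variances)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": list(self.weights),
            "means": list(self.means),
            "variances": list(self.variances),
            "variance_family": self.variance_family,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def bic_of(loglik: float, n_params: int, n_obs: int) -> float:
    """Bayesian information criterion, minimized convention: -2*logL + p*ln(n)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    return -2.0 * loglik + n_params * math.log(n_obs)


def _n_params(k: int, family: str) -> int:
    return (2 * k - 1) + (k if family == UNEQUAL else 1)


def _log_density(x: np.ndarray, weights, means, variances) -> np.ndarray:
    """Per-observation log mixture density terms, shape (n, k)."""
    log_w = np.log(weights)
    return log_w - 0.5 * (
        _LOG_2PI + np.log(variances) + (x[:, None] - means) ** 2 / variances
    )


def _em_single(
    x: np.ndarray,
    k: int,
    family: str,
    means0: np.ndarray,
    var0: np.ndarray,
    weights0: np.ndarray,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int, list[float]]:
    """One EM run from a given starting point.

    The log-likelihood is non-decreasing across iterations (EM guarantee);
    convergence is declared when the improvement drops below ``tol``.
    """
    n = x.size
    xc = x[:, None]
    weights = weights0.astype(float).copy()
    means = means0.astype(float).copy()
    variances = np.maximum(var0.astype(float), var_floor)
    trace: list[float] = []
    converged = False
    n_iter = 0
    prev_ll = -np.inf
    for n_iter in range(1, max_iter + 1):
        const = np.log(weights) - 0.5 * (_LOG_2PI + np.log(variances))
        log_comp = const - (xc - means) ** 2 / (2.0 * variances)
        peak = log_comp.max(axis=1)
        resp = np.exp(log_comp - peak[:, None])
        norm = resp.sum(axis=1)
        ll = float(np.log(norm).sum() + peak.sum())
        trace.append(ll)
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        resp /= norm[:, None]
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-10):
            raise DegenerateDataError(
                f"component collapsed to zero weight during EM (K={k})"
            )
        weights = nk / n
        means = x @ resp / nk
        sq = (xc - means) ** 2
        if family == UNEQUAL:
            variances = np.einsum("nk,nk->k", resp, sq) / nk
        else:
            shared = float(np.einsum("nk,nk->", resp, sq)) / n
            variances = np.full(k, shared)
        variances = np.maximum(variances, var_floor)
    return weights, means, variances, trace[-1], converged, n_iter, trace


def fit_gmm(
    values: Sequence[float] | np.ndarray,
    k: int,
    variance_family: str = UNEQUAL,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a K-component univariate Gaussian mixture by best-of-``n_starts`` EM.

    The first start places means at K evenly spaced quantiles of the data;
    the remaining starts place them at K quantiles drawn at random levels.
    Deterministic given ``seed``; exactly invariant to input order.
    """
    if variance_family not in {EQUAL, UNEQUAL}:
        raise ValueError(f"variance_family must be '{EQUAL}' or '{UNEQUAL}'")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("values must be non-empty and finite")
    if x.size < 5 * k:
        raise ValueError(f"need at least 5*K={5 * k} observations, got {x.size}")
    sample_var = float(np.var(x))
    if x[0] == x[-1] and k >= 2:  # x is sorted: constant data
        raise DegenerateDataError("all values identical: cannot fit K >= 2")
    var_floor = max(1e-6, 1e-4 * sample_var)
    rng = np.random.default_rng(seed)

    spread = x[-1] - x[0]
    jitter = (np.arange(k) - (k - 1) / 2) * max(spread, 1.0) * 1e-8
    # Each start runs a short burn-in; only the best burn-in solution is
    # polished to full convergence. K=1 needs no restarts (EM reaches the
    # closed-form MLE from any start).
    effective_starts = 1 if k == 1 else max(1, n_starts)
    burn_iter = max_iter if effective_starts == 1 else min(50, max_iter)
    best: tuple | None = None
    for start in range(effective_starts):
        if start == 0:
            levels = (np.arange(k) + 1.0) / (k + 1.0)
        else:
            levels = np.sort(rng.random(k))
        means0 = np.quantile(x, levels) + jitter
        var0 = np.full(k, max(sample_var / max(k, 1), var_floor))
        weights0 = np.full(k, 1.0 / k)
        try:
            result = _em_single(
                x, k, variance_family, means0, var0, weights0, tol, burn_iter, var_floor
            )
        except DegenerateDataError:
            continue
        if best is None or result[3] > best[3]:
            best = result
    if best is None:
        raise DegenerateDataError(f"all EM starts degenerated (K={k})")
    weights, means, variances, loglik, converged, n_iter, trace = best
    if not converged and n_iter < max_iter:
        weights, means, variances, loglik, converged, more_iter, more_trace = _em_single(
            x,
            k,
            variance_family,
            means,
            variances,
            weights,
            tol,
            max_iter - n_iter,
            var_floor,
        )
        n_iter += more_iter
        trace = trace + more_trace
    order = np.argsort(means)
    p = _n_params(k, variance_family)
    return MixtureFit(
        k=k,
        weights=tuple(float(w) for w in weights[order]),
        means=tuple(float(m) for m in means[order]),
        variances=tuple(float(v) for v in variances[order]),
        variance_family=variance_family,
        loglik=loglik,
        n_params=p,
        bic=bic_of(loglik, p, x.size),
        n_obs=int(x.size),
        converged=converged,
        n_iter=n_iter,
        loglik_trace=tuple(trace),
    )


def select_model(
    values: Sequence[float] | np.ndarray,
    k_max: int = 4,
    families: Sequence[str] = (EQUAL, UNEQUAL),
    seed: int = 0,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> list[MixtureFit]:
    """Fit every (K, variance family) candidate for K=1..k_max and rank by BIC.

    Returns fits sorted by ascending BIC, ties broken toward smaller K and
    then the equal-variance family. Degenerate candidates are dropped with a
    warning provided a K=1 fit succeeds.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    fits: list[MixtureFit] = []
    for k in range(1, k_max + 1):
        for family in families:
            try:
                fits.append(
                    fit_gmm(
                        values,
                        k,
                        variance_family=family,
                        n_starts=n_starts,
                        seed=seed + 7919 * k,
                        tol=tol,
                        max_iter=max_iter,
                    )
                )
            except DegenerateDataError as exc:
                logger.warning("dropping degenerate candidate K=%d/%s: %s", k, family, exc)
            except ValueError:
                raise
    if not any(f.k == 1 for f in fits):
        raise DegenerateDataError("no candidate model could be fitted (K=1 failed)")
    fits.sort(key=lambda f: (f.bic, f.k, 0 if f.variance_family == EQUAL else 1))
    return fits


def classify(
    values: Sequence[float] | np.ndarray, fit: MixtureFit
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior component responsibilities and hard labels under a fit.

    Components are in ascending-mean order, so with K=2 label 1 is the
    low-mean ("historically methylated-like") class. Returns (posteriors of
    shape (n, K), 1-based hard labels of shape (n,)).
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    log_comp = _log_density(
        x, np.asarray(fit.weights), np.asarray(fit.means), np.asarray(fit.variances)
    )
    post = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
    labels = post.argmax(axis=1) + 1
    return post, labels


@dataclass(frozen=True)
class MethylationCall:
    """The modality decision with its evidence.

    ``delta_bic`` is BIC(best K=1 candidate) - BIC(best candidate overall);
    ``separation`` is the closest adjacent-component pair's |mu_i - mu_j| over
    the pooled sd sqrt((var_i + var_j)/2) (NaN for a K=1 best fit).
    """

    verdict: str
    best_fit: MixtureFit
    ranked_fits: tuple[MixtureFit, ...]
    runner_up_bic: float
    delta_bic: float
    separation: float
    overall_mean: float

    def as_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "best_fit": self.best_fit.as_dict(),
            "runner_up_bic": self.runner_up_bic,
            "delta_bic": self.delta_bic,
            "separation": self.separation,
            "overall_mean": self.overall_mean,
        }


def component_separation(fit: MixtureFit) -> float:
    """Minimum adjacent-pair separation |mu_i+1 - mu_i| / pooled sd."""
    if fit.k < 2:
        return math.nan
    means = np.asarray(fit.means)
    variances = np.asarray(fit.variances)
    pooled = np.sqrt((variances[:-1] + variances[1:]) / 2.0)
    return float(np.min(np.diff(means) / pooled))


def call_methylation_signature(
    values: Sequence[float] | np.ndarray,
    delta_bic_min: float = 6.0,
    separation_min: float = 2.0,
    k_max: int = 4,
    seed: int = 0,
    families: Sequence[str] = (EQUAL, UNEQUAL),
    n_starts: int = 10,
) -> MethylationCall:
    """Call presence/absence of a historical-methylation signature.

    The verdict is bimodal only when the BIC-best model has K >= 2 AND the
    evidence over the best single-component model is strong (delta BIC >=
    ``delta_bic_min``, "strong" on the Kass-Raftery scale at the default 6)
    AND every adjacent component pair is separated by at least
    ``separation_min`` pooled standard deviations. Otherwise unimodal.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 50:
        raise ValueError(
            f"insufficient observations for modality call (need >= 50, got {x.size})"
        )
    fits = select_model(x, k_max=k_max, families=families, seed=seed, n_starts=n_starts)
    best = fits[0]
    bic_k1 = min(f.bic for f in fits if f.k == 1)
    delta_bic = bic_k1 - best.bic
    separation = component_separation(best)
    bimodal = (
        best.k >= 2 and delta_bic >= delta_bic_min and separation >= separation_min
    )
    return MethylationCall(
        verdict=BIMODAL if bimodal else UNIMODAL,
        best_fit=best,
        ranked_fits=tuple(fits),
        runner_up_bic=fits[1].bic if len(fits) > 1 else math.nan,
        delta_bic=delta_bic,
        separation=separation,
        overall_mean=float(np.mean(x)),
    )
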