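"""Gaussian-mixture models with a Poisson count likelihood for rating histograms.

A rating histogram gives counts :math:`y_i` over the Likert bins
:math:`x_i \\in \\{1..7\\}`.  Each bin count is modelled as an independent
Poisson draw with intensity

.. math::

    \\lambda(x_i) = c \\sum_{j=1}^{k} A_j f(x_i; \\mu_j, \\sigma),

where :math:`f` is the Gaussian density, the component weights satisfy
:math:`\\sum_j A_j = 1` with :math:`A_j \\in [0,1]`, the shared width
:math:`\\sigma` is held fixed during fitting (default 1.43, the average
SD of a low-variance reference quartet), and the count scale :math:`c`
defaults to the histogram total :math:`N` so that intensities live on
the scale of raw counts.  Setting ``count_scale=1`` recovers the
unit-area form for count-normalized histograms.

With the sum constraint eliminating the last weight, the one-, two- and
three-component variants carry 1, 3 and 5 free parameters.  Models are
compared by :math:`\\mathrm{BIC} = p \\ln n + 2\\,\\mathrm{NLL}` (lower is
better); a difference of at least 4 counts as positive evidence.  A
unimodal rating distribution favours one component, a contested image
whose ratings pile up at both ends favours two.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .data import LIKERT_MAX, LIKERT_MIN, RatingHistogram

DEFAULT_SIGMA = 1.43
#: free parameters per component count under the sum-to-one constraint
FREE_PARAMS = {1: 1, 2: 3, 3: 5}
#: BIC margin treated as positive evidence for the lower-BIC model
POSITIVE_EVIDENCE_DELTA = 4.0

_MU_START_POOL = (2.0, 3.0, 4.0, 5.0, 6.0)


def gaussian_density(x, mu: float, sigma: float):
    """Gaussian probability density, the mixture's component kernel."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    out = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MixtureSpec:
    """Parameter set of one mixture variant (weights, means, shared sigma)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sigma: float = DEFAULT_SIGMA
    count_scale: float | None = None  # None -> use the histogram's N_total

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.means):
            raise ValueError("weights and means must have equal length")
        if not 1 <= len(self.means) <= 3:
            raise ValueError("1 to 3 components supported")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(w < -1e-9 or w > 1 + 1e-9 for w in self.weights):
            raise ValueError("weights must lie in [0, 1]")
        if abs(sum(self.weights) - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")
        if any(m < LIKERT_MIN or m > LIKERT_MAX for m in self.means):
            raise ValueError("means must lie on the Likert scale [1, 7]")

    @property
    def k(self) -> int:
        return len(self.means)

    @property
    def n_free_params(self) -> int:
        return FREE_PARAMS[self.k]


def mixture_intensity(x, spec: MixtureSpec, n_total: int | None = None):
    """Poisson intensity lambda(x) = count_scale * sum_j A_j f_j(x).

    ``count_scale`` falls back to ``n_total`` (the histogram total) when
    the spec leaves it unset.
    """
    scale = spec.count_scale
    if scale is None:
        if n_total is None:
            raise ValueError("count_scale unset and no n_total supplied")
        scale = float(n_total)
    x = np.asarray(x, dtype=float)
    lam = np.zeros_like(x)
    for w, mu in zip(spec.weights, spec.means):
        lam += w * gaussian_density(x, mu, spec.sigma)
    out = scale * lam
    return out if out.ndim else float(out)


def negative_log_likelihood(hist: RatingHistogram, spec: MixtureSpec) -> float:
    """Negative log of the product of per-bin Poisson pmfs.

    NLL = sum_i [lambda_i - y_i ln(lambda_i) + ln(y_i!)], with ln(y!)
    via log-gamma so non-integer (count-normalized) histograms work too.
    A zero intensity under a positive count yields +inf, never an
    exception.
    """
    x, y = hist.as_arrays()
    lam = np.asarray(mixture_intensity(x, spec, hist.n_total), dtype=float)
    terms = np.where(y > 0,
                     lam - y * np.log(np.where(lam > 0, lam, 1.0)) + gammaln(y + 1.0),
                     lam)
    if np.any((lam <= 0) & (y > 0)):
        return float("inf")
    return float(np.sum(terms))


class HistogramGaussianMixture(BaseEstimator):
    """Constrained Gaussian mixture fitted to binned counts by Poisson ML.

    scikit-learn-style estimator: hyperparameters in ``__init__``, fitted
    values in trailing-underscore attributes after :meth:`fit`.

    Parameters
    ----------
    n_components : int
        Number of Gaussian components, 1-3.
    sigma : float
        Shared component SD, held fixed (not estimated).
    count_scale : float or None
        Intensity scale; ``None`` uses the histogram total so intensities
        are on the raw-count scale, ``1.0`` gives the unit-area form.
    bic_sample_size : {"bins", "total"}
        The n in the BIC penalty ``p ln n``: the number of histogram bins
        (default; the Poisson likelihood has one observation per bin) or
        the total rating count.
    tol : float
        Convergence tolerance on the NLL.

    Attributes
    ----------
    weights_ : ndarray of shape (n_components,)
        Fitted mixture weights, summing to 1.
    means_ : ndarray of shape (n_components,)
        Fitted component means in ascending order.
    nll_ : float
        Minimized negative log-likelihood.
    bic_ : float
        ``n_free_params * ln(n) + 2 * nll_``.
    converged_ : bool
    n_starts_used_ : int
    """

    def __init__(self, n_components: int = 1, sigma: float = DEFAULT_SIGMA,
                 count_scale: float | None = None,
                 bic_sample_size: Literal["bins", "total"] = "bins",
                 tol: float = 1e-8):
        self.n_components = n_components
        self.sigma = sigma
        self.count_scale = count_scale
        self.bic_sample_size = bic_sample_size
        self.tol = tol

    # -- internals ---------------------------------------------------------
    def _unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """theta = (mu_1..mu_k, A_1..A_{k-1}); last weight by elimination.

        Returns (weights, means, penalty); the penalty is positive when
        the eliminated weight strays outside [0, 1], keeping the
        objective finite and smooth for the box-constrained optimizer.
        """
        k = self.n_components
        mus = np.asarray(theta[:k], dtype=float)
        free_w = np.asarray(theta[k:], dtype=float)
        last = 1.0 - free_w.sum()
        penalty = 0.0
        if last < 0.0:
            penalty = 1e4 * last * last
            last = 0.0
        weights = np.append(free_w, last)
        total = weights.sum()
        if total > 0:
            weights = weights / total
        return weights, mus, penalty

    def _objective(self, theta: np.ndarray, hist: RatingHistogram) -> float:
        weights, mus, penalty = self._unpack(theta)
        spec = MixtureSpec(tuple(weights), tuple(np.clip(mus, LIKERT_MIN, LIKERT_MAX)),
                           sigma=self.sigma, count_scale=self.count_scale)
        nll = negative_log_likelihood(hist, spec)
        return nll + penalty

    def _starts(self) -> list[np.ndarray]:
        """Deterministic multi-start grid: all k-subsets of {2..6} for the
        means, uniform free weights."""
        k = self.n_components
        uniform = np.full(k - 1, 1.0 / k)
        return [np.concatenate([np.asarray(mus, float), uniform])
                for mus in itertools.combinations(_MU_START_POOL, k)]

    # -- estimator API -----------------------------------------------------
    def fit(self, hist: RatingHistogram | Sequence[int], y=None) -> "HistogramGaussianMixture":
        """Minimize the Poisson-count NLL over means and free weights.

        Bounded (L-BFGS-B) minimization from every start on the grid;
        the best NLL wins, ties broken by grid order.  Accepts a
        :class:`RatingHistogram` or a bare 7-vector of counts.
        """
        if self.n_components not in FREE_PARAMS:
            raise ValueError(f"n_components must be in {sorted(FREE_PARAMS)}")
        if not isinstance(hist, RatingHistogram):
            hist = RatingHistogram(counts=tuple(int(v) for v in np.asarray(hist).ravel()))
        if hist.n_total <= 0 and self.count_scale is None:
            raise ValueError("histogram has no counts")

        k = self.n_components
        bounds = [(LIKERT_MIN, LIKERT_MAX)] * k + [(0.0, 1.0)] * (k - 1)
        best = None
        any_converged = False
        n_starts = 0
        for x0 in self._starts():
            n_starts += 1
            res = minimize(self._objective, x0, args=(hist,), method="L-BFGS-B",
                           bounds=bounds, options={"ftol": self.tol, "maxiter": 500})
            any_converged = any_converged or bool(res.success)
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        assert best is not None

        weights, mus, _ = self._unpack(best.x)
        order = np.argsort(mus)  # ascending means remove label switching
        self.means_ = np.clip(mus[order], LIKERT_MIN, LIKERT_MAX)
        self.weights_ = weights[order]
        self.nll_ = float(best.fun)
        self.converged_ = any_converged and math.isfinite(self.nll_)
        self.n_starts_used_ = n_starts
        n = hist.n_bins if self.bic_sample_size == "bins" else hist.n_total
        self.bic_ = FREE_PARAMS[k] * math.log(n) + 2.0 * self.nll_
        self.n_total_ = hist.n_total
        self.hist_ = hist
        return self

    @property
    def spec_(self) -> MixtureSpec:
        return MixtureSpec(tuple(self.weights_), tuple(self.means_),
                           sigma=self.sigma, count_scale=self.count_scale)

    def intensity(self, x) -> np.ndarray:
        """Fitted Poisson intensity evaluated at x (rating-scale units)."""
        return mixture_intensity(x, self.spec_, self.n_total_)

    def score(self, hist: RatingHistogram | None = None, y=None) -> float:
        """Log-likelihood (higher is better) on ``hist`` or the training data."""
        h = hist if hist is not None else self.hist_
        if not isinstance(h, RatingHistogram):
            h = RatingHistogram(counts=tuple(int(v) for v in np.asarray(h).ravel()))
        return -negative_log_likelihood(h, self.spec_)


@dataclass(frozen=True)
class MixtureFit:
    """Frozen result of one fitted mixture variant."""

    spec: MixtureSpec
    nll: float
    bic: float
    converged: bool
    n_starts_used: int
    n_total: int

    @property
    def k(self) -> int:
        return self.spec.k

    @property
    def n_free_params(self) -> int:
        return self.spec.n_free_params


def fit_mixture(hist: RatingHistogram, k: int, sigma: float = DEFAULT_SIGMA,
                count_scale: float | None = None,
                bic_sample_size: Literal["bins", "total"] = "bins") -> MixtureFit:
    """Fit the k-component mixture to a histogram; thin estimator wrapper."""
    est = HistogramGaussianMixture(n_components=k, sigma=sigma,
                                   count_scale=count_scale,
                                   bic_sample_size=bic_sample_size).fit(hist)
    return MixtureFit(spec=est.spec_, nll=est.nll_, bic=est.bic_,
                      converged=est.converged_, n_starts_used=est.n_starts_used_,
                      n_total=est.n_total_)


def bic(nll: float, k: int, n: int) -> float:
    """BIC = p ln(n) + 2 NLL with p the free-parameter count for k components."""
    return FREE_PARAMS[k] * math.log(n) + 2.0 * nll


@dataclass(frozen=True)
class ModelComparison:
    """Best model by BIC with the evidence margin over the runner-up."""

    best: MixtureFit
    delta_bic: float
    evidence: str  # "positive" | "weak" | "tie"
    fits: tuple[MixtureFit, ...]

    @property
    def best_k(self) -> int:
        return self.best.k


def compare_models(fits: Sequence[MixtureFit]) -> ModelComparison:
    """Rank fitted variants by BIC (ties toward fewer parameters).

    The margin between the two best BICs is labelled "positive" at or
    above 4, "weak" below, "tie" at exactly zero.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    if len({f.k for f in fits}) != len(fits):
        raise ValueError("fits must have distinct component counts")
    if len({f.n_total for f in fits}) != 1:
        raise ValueError("fits compare different histograms")
    ranked = sorted(fits, key=lambda f: (f.bic, f.n_free_params))
    delta = ranked[1].bic - ranked[0].bic
    if delta == 0:
        evidence = "tie"
    elif delta >= POSITIVE_EVIDENCE_DELTA:
        evidence = "positive"
    else:
        evidence = "weak"
    return ModelComparison(best=ranked[0], delta_bic=float(delta),
                           evidence=evidence, fits=tuple(ranked))


def fit_and_compare(hist: RatingHistogram, ks: Sequence[int] = (1, 2, 3),
                    sigma: float = DEFAULT_SIGMA,
                    count_scale: float | None = None,
                    bic_sample_size: Literal["bins", "total"] = "bins") -> ModelComparison:
    """Fit every requested variant to one histogram and compare by BIC."""
    return compare_models([fit_mixture(hist, k, sigma=sigma, count_scale=count_scale,
                                       bic_sample_size=bic_sample_size) for k in ks])


def average_reference_sigma(summaries) -> float:
    """Mean per-image beauty SD — recomputes the fixed sigma from data."""
    sds = [s.beauty_sd for s in summaries if math.isfinite(s.beauty_sd)]
    if not sds:
        raise ValueError("no finite SDs to average")
    return float(np.mean(sds))
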