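"""Robust univariable MR: constrained-ML estimation with invalid-IV selection.

For one exposure -> outcome pair with m independent instruments, the model is

    beta_out_k = theta * b_k + r_k + noise(se_out_k)
    beta_exp_k = b_k + noise(se_exp_k)

where ``b_k`` is the latent true instrument-exposure effect and ``r_k`` a
direct (pleiotropic) instrument-outcome effect.  With exactly ``k`` nonzero
``r_k`` allowed, the constrained maximum-likelihood fit minimizes

    sum_k (beta_out_k - theta b_k - r_k)^2 / se_out_k^2
        + (beta_exp_k - b_k)^2 / se_exp_k^2 .

The number of invalid instruments is selected by BIC with a
``log(min(n_exposure, n_outcome))`` penalty per invalid instrument.  Under
the plurality condition (valid instruments form the largest group sharing a
ratio estimand) the selected support is consistent; when plurality is
violated -- e.g. a dominant group of instruments acting through a shared
upstream trait -- the estimate is biased, which is exactly the failure mode
the network-aware screening in :mod:`mrgraph.screening` guards against.

Implementation notes
--------------------
Coordinate descent with exact block updates:

* given theta, the optimal support is the ``k`` instruments with the
  largest standardized profile residuals
  ``(beta_out - theta beta_exp)^2 / (se_out^2 + theta^2 se_exp^2)``
  (invalid instruments zero out their objective contribution via free r);
* ``b`` has a closed-form weighted-average update;
* theta is a weighted-least-squares update.

Each full cycle is non-increasing in the objective.  Fits are warm-started
across k during BIC selection; no random restarts.  The inner loop is
numba-compiled: the perturbation bootstrap calls it millions of times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data import IVAssignment, PairSummary, SummaryPanel, pair_from_panel
from .exceptions import InsufficientInstrumentsError
from .network import MREffectNetwork

MAX_ITER = 200
TOL = 1e-8


@njit(cache=True)
def _cml_descent(bx, by, sx2, sy2, k, theta0, max_iter, tol):
    """Coordinate descent for the constrained-ML objective at fixed k.

    Returns (theta, r, b, objective, converged, n_iter).
    """
    m = bx.shape[0]
    theta = theta0
    r = np.zeros(m)
    b = bx.copy()
    invalid = np.empty(k, dtype=np.int64)
    prev = np.inf
    obj = np.inf
    converged = False
    it = 0
    for it in range(max_iter):
        # exact (support, b, r) update given theta
        denom = 1.0 / sx2 + theta * theta / sy2
        b = (bx / sx2 + theta * by / sy2) / denom
        r[:] = 0.0
        if k > 0:
            score = (by - theta * bx) ** 2 / (sy2 + theta * theta * sx2)
            order = np.argsort(score)
            invalid = order[m - k :]
            for idx in invalid:
                b[idx] = bx[idx]
                r[idx] = by[idx] - theta * bx[idx]
        # weighted-least-squares theta update given b, r
        num = 0.0
        den = 0.0
        for i in range(m):
            num += b[i] * (by[i] - r[i]) / sy2[i]
            den += b[i] * b[i] / sy2[i]
        if den <= 0.0:
            break
        theta = num / den
        obj = 0.0
        for i in range(m):
            obj += (by[i] - theta * b[i] - r[i]) ** 2 / sy2[i]
            obj += (bx[i] - b[i]) ** 2 / sx2[i]
        if np.abs(prev - obj) < tol:
            converged = True
            break
        prev = obj
    # final consistent state at the converged theta
    denom = 1.0 / sx2 + theta * theta / sy2
    b = (bx / sx2 + theta * by / sy2) / denom
    r[:] = 0.0
    if k > 0:
        score = (by - theta * bx) ** 2 / (sy2 + theta * theta * sx2)
        order = np.argsort(score)
        for idx in order[m - k :]:
            b[idx] = bx[idx]
            r[idx] = by[idx] - theta * bx[idx]
    obj = 0.0
    for i in range(m):
        obj += (by[i] - theta * b[i] - r[i]) ** 2 / sy2[i]
        obj += (bx[i] - b[i]) ** 2 / sx2[i]
    return theta, r, b, obj, converged, it + 1


@njit(cache=True)
def _cml_select_kernel(bx, by, sx2, sy2, k_max, log_n, extra_starts, max_iter, tol):
    """BIC selection over k = 0..k_max, multi-start descent at each k.

    Start set per k: the warm start (best theta from k-1), plus
    ``extra_starts`` (0, IVW, ratio quantiles).  Returns
    (theta, k_sel, nll, r, converged, bic_path).
    """
    m = bx.shape[0]
    bic_path = np.empty(k_max + 1)
    best_bic = np.inf
    best_theta = 0.0
    best_k = 0
    best_nll = np.inf
    best_r = np.zeros(m)
    best_conv = False
    warm = np.nan
    for k in range(k_max + 1):
        k_theta = 0.0
        k_obj = np.inf
        k_r = np.zeros(m)
        k_conv = False
        n_starts = extra_starts.shape[0] + (0 if np.isnan(warm) else 1)
        for s in range(n_starts):
            if s < extra_starts.shape[0]:
                start = extra_starts[s]
            else:
                start = warm
            theta, r, b, obj, converged, it = _cml_descent(
                bx, by, sx2, sy2, k, start, max_iter, tol
            )
            if obj < k_obj:
                k_obj = obj
                k_theta = theta
                k_r = r
                k_conv = converged
        warm = k_theta
        bic = k_obj + log_n * k  # objective == 2 * nll
        bic_path[k] = bic
        if bic < best_bic:
            best_bic = bic
            best_theta = k_theta
            best_k = k
            best_nll = 0.5 * k_obj
            best_r = k_r
            best_conv = k_conv
    return best_theta, best_k, best_nll, best_r, best_conv, bic_path


def _ivw_start(bx, by, sy2) -> float:
    den = float(np.sum(bx * bx / sy2))
    if den <= 0:
        return 0.0
    return float(np.sum(bx * by / sy2)) / den


RATIO_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)


def _start_set(bx, by, sy2, theta0=None) -> np.ndarray:
    """Deterministic descent starts: warm/IVW, zero, and ratio quantiles."""
    starts = {0.0, float(_ivw_start(bx, by, sy2) if theta0 is None else theta0)}
    nz = np.abs(bx) > 0
    if nz.any():
        ratios = by[nz] / bx[nz]
        starts.update(float(q) for q in np.quantile(ratios, RATIO_QUANTILES))
    return np.array(sorted(starts))


@dataclass
class CmlFit:
    """Constrained-ML fit at a fixed number of invalid instruments."""

    theta: float
    pleiotropy: np.ndarray  # r, zero for valid instruments
    nll: float  # negative log-likelihood (objective / 2, constants dropped)
    k: int
    converged: bool
    n_iter: int

    @property
    def invalid_set(self) -> np.ndarray:
        return np.flatnonzero(self.pleiotropy != 0.0)


@dataclass
class UvmrFit:
    """BIC-selected fit for one ordered trait pair."""

    theta_hat: float
    invalid_set: np.ndarray
    k_selected: int
    converged: bool
    bic: float
    nll: float
    bic_path: np.ndarray = field(default_factory=lambda: np.empty(0))


def cml_fit(pair: PairSummary, k: int, theta0: float | None = None) -> CmlFit:
    """Fit the constrained-ML model with exactly ``k`` invalid instruments.

    The objective is non-convex in theta under heavy contamination, so the
    descent is run from a small deterministic set of starts -- the
    caller-supplied warm start (IVW when none), theta = 0, and quantiles of
    the per-instrument ratio estimates beta_out/beta_exp -- keeping the
    lowest optimum.  Ratio-quantile starts cover the basins induced by
    instrument groups sharing a common ratio, which is what random restarts
    are for in stock implementations; here the start set is seed-free.
    """
    m = pair.n_ivs
    if m < 2:
        raise InsufficientInstrumentsError(
            f"need at least 2 instruments, got {m}"
        )
    if not 0 <= k <= m - 2:
        raise ValueError(f"k must satisfy 0 <= k <= m - 2 = {m - 2}, got {k}")
    bx = pair.beta_exposure
    by = pair.beta_outcome
    sx2 = pair.se_exposure**2
    sy2 = pair.se_outcome**2
    starts = _start_set(bx, by, sy2, theta0)
    best = None
    for start in starts:
        theta, r, _b, obj, converged, n_iter = _cml_descent(
            bx, by, sx2, sy2, k, start, MAX_ITER, TOL
        )
        if best is None or obj < best[3]:
            best = (theta, r, _b, obj, converged, n_iter)
    theta, r, _b, obj, converged, n_iter = best
    return CmlFit(
        theta=float(theta),
        pleiotropy=r,
        nll=0.5 * float(obj),
        k=k,
        converged=bool(converged),
        n_iter=int(n_iter),
    )


def cml_select(pair: PairSummary, k_max: int | None = None) -> UvmrFit:
    """Run :func:`cml_fit` over k = 0..k_max and pick the BIC minimizer.

    BIC = 2 * nll + log(min(n_exposure, n_outcome)) * k.  The default k_max,
    floor(m/2) - 1, honors the plurality condition (a majority of
    instruments must remain valid).  Fits are warm-started from the
    previous k's theta.
    """
    m = pair.n_ivs
    if m < 2:
        raise InsufficientInstrumentsError(f"need at least 2 instruments, got {m}")
    if k_max is None:
        k_max = m // 2 - 1
    k_max = int(min(max(k_max, 0), m - 2))
    bx = pair.beta_exposure
    by = pair.beta_outcome
    sx2 = pair.se_exposure**2
    sy2 = pair.se_outcome**2
    log_n = float(np.log(min(pair.n_exposure, pair.n_outcome)))
    extra_starts = _start_set(bx, by, sy2)
    theta, k_sel, nll, r, converged, bic_path = _cml_select_kernel(
        bx, by, sx2, sy2, k_max, log_n, extra_starts, MAX_ITER, TOL
    )
    return UvmrFit(
        theta_hat=float(theta),
        invalid_set=np.flatnonzero(r != 0.0),
        k_selected=int(k_sel),
        converged=bool(converged),
        bic=float(bic_path[k_sel]),
        nll=float(nll),
        bic_path=bic_path,
    )


def estimate_mr_network(
    panel: SummaryPanel, assignment: IVAssignment
) -> MREffectNetwork:
    """Bidirectional robust MR over all ordered trait pairs.

    ``Theta[i, j]`` is the BIC-selected constrained-ML estimate of the MR
    effect of trait j on trait i using the instruments assigned to the
    ordered pair (exposure j, outcome i).  Pairs with fewer than two
    instruments are set to 0 and flagged in the ``missing`` mask; per-pair
    fits are attached as ``fits[(j, i)]``.
    """
    T = panel.n_traits
    Theta = np.eye(T)
    missing = np.zeros((T, T), dtype=bool)
    fits: dict = {}
    for j in range(T):  # exposure
        for i in range(T):  # outcome
            if i == j:
                continue
            snps = assignment.sets.get((j, i), np.empty(0, dtype=int))
            if len(snps) < 2:
                missing[i, j] = True
                Theta[i, j] = 0.0
                continue
            pair = pair_from_panel(panel, exposure=j, outcome=i, snps=snps)
            fit = cml_select(pair)
            fits[(j, i)] = fit
            Theta[i, j] = fit.theta_hat
    net = MREffectNetwork(Theta, list(panel.trait_names), missing=missing)
    net.fits = fits
    return net
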