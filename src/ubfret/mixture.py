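"""Gaussian-mixture decomposition of burst FRET-efficiency distributions.

A population of molecules fluctuating among K conformational states yields a
burst-efficiency histogram that is a weighted sum of K overlapping Gaussian
peaks.  This module fits that mixture by expectation-maximization on the
*burst-level samples* (not on a binned histogram), selects K with BIC/AIC,
scores fits against the histogram with R² as a secondary diagnostic, and
averages replicate measurements into a species summary.

Model: p(e) = Σ_j w_j N(e | μ_j, σ_j²), with free parameters the K centers,
K widths and K−1 independent weights, so k_params = 3K − 1 and

    BIC = k_params·ln(n) − 2·lnL        AIC = 2·k_params − 2·lnL

both minimised over K.  Components are always reported sorted by center
descending, i.e. the high-FRET species first.

Numerical choices: efficiencies outside [0, 1] (possible under additive
noise) are clipped before fitting and the count recorded; component widths
are floored at 0.01 efficiency units to prevent variance collapse onto a
single sample; the E-step uses log-sum-exp; each fit runs several seeded
restarts (quantile-spaced initial centers, then jittered) and keeps the
best-likelihood solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MixtureFit",
    "SpeciesSummary",
    "em_fit",
    "select_k",
    "histogram_r2",
    "replicate_summary",
    "mixture_pdf",
    "WIDTH_FLOOR",
]

WIDTH_FLOOR = 0.01  # efficiency units; prevents variance collapse


@dataclass
class MixtureFit:
    """Result of one EM fit.  Components sorted by center descending."""

    k: int
    centers: np.ndarray
    widths: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float
    aic: float
    n_samples: int
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(repr=False, default=None)
    r_squared: float | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")


@dataclass(frozen=True)
class SpeciesSummary:
    """Replicate-averaged species parameters (mean ± SD over fits)."""

    centers_mean: np.ndarray
    centers_sd: np.ndarray
    populations_mean: np.ndarray
    populations_sd: np.ndarray
    n_replicates: int


def mixture_pdf(x, centers, widths, weights):
    """Mixture density Σ w_j N(x | μ_j, σ_j²); vectorised over ``x``."""
    x = np.asarray(x, dtype=float)[..., None]
    c = np.asarray(centers, dtype=float)
    s = np.asarray(widths, dtype=float)
    w = np.asarray(weights, dtype=float)
    z = (x - c) / s
    return np.sum(w / (s * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * z * z), axis=-1)


def _em_batch(x, centers, widths, weights, tol, max_iter, width_floor, fix_widths):
    """Run EM on ``R`` parameter sets simultaneously.

    ``centers``/``widths``/``weights`` have shape (R, k); ``x`` has shape
    (n,).  Restarts whose log-likelihood gain drops below ``tol`` are frozen
    in place while the rest continue.  Returns final parameters plus the
    per-restart log-likelihood paths.
    """
    n = x.size
    R = centers.shape[0]
    xc = x[None, :, None]  # (1, n, 1)
    widths = np.maximum(widths, width_floor)
    weights = weights / weights.sum(axis=1, keepdims=True)
    paths: list[list[float]] = [[] for _ in range(R)]
    lnl_prev = np.full(R, -np.inf)
    active = np.ones(R, dtype=bool)
    converged = np.zeros(R, dtype=bool)
    for it in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        c, s, w = centers[idx][:, None, :], widths[idx][:, None, :], weights[idx][:, None, :]
        z = (xc - c) / s
        # joint densities; width floor keeps |z| bounded so the density sum
        # only underflows in pathological collapse, floored below
        joint = (w / (s * np.sqrt(2.0 * np.pi))) * np.exp(-0.5 * z * z)  # (r, n, k)
        norm = np.maximum(joint.sum(axis=2), 1e-300)  # (r, n)
        lnl = np.log(norm).sum(axis=1)  # (r,)
        for j, r in enumerate(idx):
            paths[r].append(float(lnl[j]))
        done = (lnl - lnl_prev[idx]) < tol
        done &= np.array([len(paths[r]) > 1 for r in idx])
        lnl_prev[idx] = lnl
        if done.any():
            converged[idx[done]] = True
            active[idx[done]] = False
            keep = ~done
            idx = idx[keep]
            if idx.size == 0:
                break
            joint, norm = joint[keep], norm[keep]
        resp = joint / norm[:, :, None]  # (r, n, k)
        nk = np.maximum(resp.sum(axis=1), 1e-300)  # (r, k)
        weights[idx] = nk / n
        centers[idx] = (resp * xc).sum(axis=1) / nk
        if fix_widths is None:
            dev = xc - centers[idx][:, None, :]
            var = (resp * dev * dev).sum(axis=1) / nk
            widths[idx] = np.maximum(np.sqrt(var), width_floor)
    return centers, widths, weights, paths, converged


def em_fit(
    efficiencies,
    k: int,
    *,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    restarts: int = 10,
    width_floor: float = WIDTH_FLOOR,
    fix_widths=None,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture to burst efficiencies by EM.

    Parameters
    ----------
    efficiencies
        Per-burst FRET efficiencies.  Values outside [0, 1] are clipped and
        counted in ``n_clipped``.
    k
        Number of components; requires at least ``10*k`` samples.
    restarts
        Number of EM starts; the first uses quantile-spaced centers with
        equal weights and pooled SD, subsequent starts jitter that guess
        with the seeded generator.  Best final likelihood wins.
    fix_widths
        Optional array of per-component SDs held fixed (used for
        constrained comparisons against enumeration oracles).

    The log-likelihood trajectory is stored in ``loglik_path``; EM theory
    guarantees it is nondecreasing and the tests assert it.
    """
    x = np.asarray(efficiencies, dtype=float).ravel()
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} samples to fit k={k}, got {x.size}")
    if k < 1:
        raise ValueError("k must be >= 1")
    n_clipped = int(np.sum((x < 0) | (x > 1)))
    x = np.clip(x, 0.0, 1.0)

    rng = np.random.default_rng(seed)
    pooled_sd = max(float(np.std(x)), width_floor)
    base_centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    if fix_widths is not None:
        fix_widths = np.asarray(fix_widths, dtype=float)
        if fix_widths.shape != (k,):
            raise ValueError("fix_widths must have length k")

    R = max(1, restarts)
    centers0 = np.empty((R, k))
    centers0[0] = base_centers
    if R > 1:
        centers0[1:] = np.clip(
            base_centers[None, :] + rng.normal(0, pooled_sd / 2, size=(R - 1, k)), 0, 1
        )
    if fix_widths is not None:
        widths0 = np.tile(fix_widths, (R, 1))
    else:
        widths0 = np.full((R, k), pooled_sd / max(k, 1) + width_floor)
    weights0 = np.full((R, k), 1.0 / k)

    all_centers, all_widths, all_weights, paths, conv = _em_batch(
        x, centers0, widths0, weights0, tol, max_iter, width_floor, fix_widths
    )
    final_lnl = np.array([p[-1] for p in paths])
    win = int(np.argmax(final_lnl))
    centers, widths, weights = all_centers[win], all_widths[win], all_weights[win]
    path, converged, n_iter = paths[win], bool(conv[win]), len(paths[win])

    order = np.argsort(-centers)
    centers, widths, weights = centers[order], widths[order], weights[order]
    weights = weights / weights.sum()
    lnl = path[-1]
    k_params = 3 * k - 1
    n = x.size
    return MixtureFit(
        k=k,
        centers=centers,
        widths=widths,
        weights=weights,
        log_likelihood=lnl,
        bic=k_params * np.log(n) - 2.0 * lnl,
        aic=2.0 * k_params - 2.0 * lnl,
        n_samples=n,
        converged=converged,
        n_iter=n_iter,
        loglik_path=np.asarray(path),
        n_clipped=n_clipped,
    )


def select_k(
    efficiencies,
    k_range=range(1, 6),
    criterion: str = "bic",
    seed: int = 0,
    **em_kwargs,
) -> tuple[int, list[MixtureFit]]:
    """Fit every K in ``k_range`` and pick the one minimising BIC or AIC.

    Ties (within 1e-9) break toward the smaller K.  All per-K fits are
    returned so the criterion landscape can be inspected.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    if criterion not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    fits = [em_fit(efficiencies, k, seed=seed, **em_kwargs) for k in ks]
    scores = np.array([getattr(f, criterion) for f in fits])
    best_idx = int(np.argmin(scores))
    # prefer smaller k on ties
    for i in range(best_idx):
        if scores[i] <= scores[best_idx] + 1e-9:
            best_idx = i
            break
    return fits[best_idx].k, fits


def histogram_r2(fit: MixtureFit, efficiencies, n_bins: int = 30) -> float:
    """R² between the binned empirical density and the fitted mixture
    density at the bin centers — the secondary, histogram-level diagnostic
    reported alongside BIC/AIC.  In (−∞, 1]; negative means worse than a
    flat fit at the mean density."""
    x = np.clip(np.asarray(efficiencies, dtype=float).ravel(), 0.0, 1.0)
    if x.size == 0:
        raise ValueError("empty sample")
    if n_bins < 5:
        raise ValueError("need at least 5 bins")
    hist, edges = np.histogram(x, bins=n_bins, range=(0.0, 1.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = mixture_pdf(centers, fit.centers, fit.widths, fit.weights)
    ss_res = float(np.sum((hist - model) ** 2))
    ss_tot = float(np.sum((hist - hist.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def replicate_summary(fits: list[MixtureFit]) -> SpeciesSummary:
    """Average independent replicate fits into per-species mean ± SD.

    All fits must share K; components are matched by their sorted (center
    descending) order, so the summary is invariant to the input order of
    components within each fit.
    """
    if not fits:
        raise ValueError("no fits to summarise")
    k = fits[0].k
    if any(f.k != k for f in fits):
        raise ValueError("replicate fits have mismatched component counts")
    # match species by center order regardless of how components were stored
    orders = [np.argsort(-np.asarray(f.centers)) for f in fits]
    centers = np.stack([np.asarray(f.centers)[o] for f, o in zip(fits, orders)])
    weights = np.stack([np.asarray(f.weights)[o] for f, o in zip(fits, orders)])
    ddof = 1 if len(fits) > 1 else 0
    return SpeciesSummary(
        centers_mean=centers.mean(axis=0),
        centers_sd=centers.std(axis=0, ddof=ddof),
        populations_mean=weights.mean(axis=0),
        populations_sd=weights.std(axis=0, ddof=ddof),
        n_replicates=len(fits),
    )
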