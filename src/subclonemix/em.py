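"""Expectation-Maximization fitting of the subclonal mixture model.

The latent variables are the per-segment subclone label Z_j and allelic
configuration H_j; the genotype sum stays inside the objective, which keeps
the M-step exact for the categorical parameters and reduces the prevalence
update to K independent one-dimensional maximizations.

E-step
    gamma_j(k, h) proportional to pi_k * rho_jh * P(segment j | h, phi_k),
    normalized per segment in log space.

M-step
    pi_k   = (1/J) sum_j sum_h gamma_j(k, h)
    rho_jh = sum_k gamma_j(k, h)          (single-observation categorical MLE)
    phi_k  = argmax of sum_j sum_h gamma_j(k, h) * loglik(j, h, phi),
             found on a fixed grid over [phi_min, phi_max] followed by a
             bounded 1-D refinement around the best grid point.  The
             previous phi_k is always kept as a candidate, so the EM
             objective never decreases.

Initialization is data driven: each segment votes for the prevalence that
best explains it (the argmax over the phi grid of its own profile), and
the modes of the vote histogram seed the first restart; later restarts
alternate between resampled votes and uniform random draws.  With segment
read totals in the millions the likelihood basins in phi are extremely
narrow, so purely random starts rarely converge to the global optimum.

Prevalences are reported sorted ascending with pi and the responsibilities
permuted to match; ties everywhere break to the lowest index, making runs
reproducible given a seed.  The per-(grid point, segment, configuration)
log-likelihood table is precomputed once per fit and reused across
iterations, which is what makes grid search affordable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .config_space import ConfigSpace
from .data_model import Dataset
from .likelihood import (
    DEFAULT_PHI_MAX,
    DEFAULT_PHI_MIN,
    BaselineScale,
    ModelParams,
    PackedData,
    segment_loglik_matrix,
)

__all__ = ["EMOptions", "FitResult", "e_step", "m_step", "fit"]


@dataclass
class EMOptions:
    max_iter: int = 100
    rel_tol: float = 1e-6
    restarts: int = 10
    seed: int = 0
    phi_grid: int = 100
    phi_min: float = DEFAULT_PHI_MIN
    phi_max: float = DEFAULT_PHI_MAX
    refine_xatol: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_iter < 1 or self.restarts < 1:
            raise ValueError("max_iter and restarts must be >= 1")
        if not 0.0 < self.phi_min < self.phi_max < 1.0:
            raise ValueError("require 0 < phi_min < phi_max < 1")


@dataclass
class FitResult:
    """Fitted parameters plus per-segment MAP summaries."""

    params: ModelParams
    loglik: float
    loglik_trace: list[float]
    responsibilities: np.ndarray  # (J, K, |H|)
    map_subclone: np.ndarray  # (J,) index into params.phi
    map_config: np.ndarray  # (J,) index into space.configs
    map_config_labels: list[str]
    segment_prevalence: np.ndarray  # (J,) phi of the MAP subclone
    segment_copy_number: np.ndarray  # (J,) copy number of the MAP config
    converged: bool
    segment_ids: list[str] = field(default_factory=list)


def e_step(
    packed: PackedData,
    params: ModelParams,
    baseline: BaselineScale,
    space: ConfigSpace,
) -> tuple[np.ndarray, float]:
    """Responsibilities gamma (J, K, |H|) and the current log-likelihood."""
    ll = segment_loglik_matrix(packed, params.phi, baseline, space)  # (K, J, H)
    with np.errstate(divide="ignore"):
        log_joint = (
            np.log(params.pi)[:, None, None] + np.log(params.rho)[None, :, :] + ll
        )  # (K, J, H)
    log_joint = np.moveaxis(log_joint, 0, 1)  # (J, K, H)
    per_segment = logsumexp(log_joint, axis=(1, 2))  # (J,)
    if not np.all(np.isfinite(per_segment)):
        raise RuntimeError("non-finite segment evidence in the E-step")
    gamma = np.exp(log_joint - per_segment[:, None, None])
    return gamma, float(per_segment.sum())


def _optimize_phi(
    packed: PackedData,
    weights: np.ndarray,  # (J, H) responsibilities of one subclone
    phi_old: float,
    grid: np.ndarray,
    grid_ll: np.ndarray,  # (G, J, H) precomputed log-liks on the grid
    baseline: BaselineScale,
    space: ConfigSpace,
    options: EMOptions,
) -> float:
    """Maximize the weighted expected log-likelihood of one prevalence."""

    def value(phi: float) -> float:
        ll = segment_loglik_matrix(packed, np.array([phi]), baseline, space)[0]
        return float(np.sum(weights * ll))

    grid_scores = np.einsum("gjh,jh->g", grid_ll, weights)
    best = int(np.argmax(grid_scores))  # first max: lowest grid point on ties
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    candidates = [(grid_scores[best], float(grid[best]))]
    if hi > lo:
        res = minimize_scalar(
            lambda p: -value(p),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": options.refine_xatol},
        )
        candidates.append((-res.fun, float(res.x)))
    candidates.append((value(phi_old), float(phi_old)))
    best_score = max(c[0] for c in candidates)
    for score, phi in candidates:  # order: grid, refined, old — ties keep grid
        if score == best_score:
            return phi
    return phi_old  # pragma: no cover


def m_step(
    packed: PackedData,
    gamma: np.ndarray,
    params: ModelParams,
    baseline: BaselineScale,
    space: ConfigSpace,
    options: EMOptions,
    grid: np.ndarray,
    grid_ll: np.ndarray,
) -> tuple[ModelParams, np.ndarray]:
    """Update (pi, rho, phi) from responsibilities; returns the new params
    and gamma with subclone columns permuted into ascending-phi order."""
    J = packed.J
    pi = gamma.sum(axis=(0, 2)) / J  # (K,)
    rho = gamma.sum(axis=1)  # (J, H)
    phi = np.array(
        [
            _optimize_phi(
                packed,
                gamma[:, k, :],
                float(params.phi[k]),
                grid,
                grid_ll,
                baseline,
                space,
                options,
            )
            for k in range(len(params.phi))
        ]
    )
    order = np.argsort(phi, kind="stable")
    return (
        ModelParams(phi=phi[order], pi=pi[order], rho=rho),
        gamma[:, order, :],
    )


_VOTE_MIN_RANGE = 2.0  # nats: a flatter per-segment profile carries no signal


def _prevalence_votes(
    grid: np.ndarray, grid_ll: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-segment preferred prevalences (the initialization votes).

    For each segment the one-segment profile logsumexp_h of the grid
    log-likelihood table is maximized over the phi grid.  Each vote is
    weighted by the segment's profile range (how strongly it prefers its
    phi): diploid-like segments, whose profile is nearly flat, then
    contribute almost nothing, while SCNA segments — whose profiles span
    thousands of nats at whole-genome depths — dominate.  With deep data
    the likelihood basins in phi are extremely narrow, so blind random
    initialization almost never finds the optimum; the weighted vote
    histogram concentrates at the prevalences of the subclones present.

    Returns (votes, weights, pooled_peak) where pooled_peak is the argmax
    of the summed profile — the best single shared prevalence.
    """
    prof = logsumexp(grid_ll - np.log(grid_ll.shape[2]), axis=2)  # (G, J)
    ranges = prof.max(axis=0) - prof.min(axis=0)  # (J,)
    pooled_peak = float(grid[np.argmax(prof.sum(axis=1))])
    keep = ranges > _VOTE_MIN_RANGE
    if not keep.any():
        return np.empty(0), np.empty(0), pooled_peak
    votes = grid[np.argmax(prof[:, keep], axis=0)]
    return votes, ranges[keep], pooled_peak


def _vote_centers(
    votes: np.ndarray, weights: np.ndarray, grid: np.ndarray, K: int
) -> np.ndarray:
    """Greedy mode-seeking over the weighted vote histogram: repeatedly
    take the heaviest grid value and suppress its 2-grid-step neighborhood."""
    if len(votes) == 0:
        return np.empty(0)
    step = grid[1] - grid[0] if len(grid) > 1 else 1.0
    remaining, w = votes.copy(), weights.copy()
    centers: list[float] = []
    while len(centers) < K and len(remaining) > 0:
        vals = np.unique(remaining)
        mass = np.array([w[remaining == v].sum() for v in vals])
        c = float(vals[np.argmax(mass)])
        centers.append(c)
        far = np.abs(remaining - c) > 2.0 * step
        remaining, w = remaining[far], w[far]
    return np.array(centers)


def _initial_phi(
    K: int,
    restart: int,
    votes: np.ndarray,
    weights: np.ndarray,
    pooled_peak: float,
    grid: np.ndarray,
    rng: np.random.Generator,
    options: EMOptions,
) -> np.ndarray:
    """Initial prevalences for one restart.

    restart 0: the top-K weighted vote centers; restart 1: all components
    at the pooled-profile peak (the best shared prevalence — the natural
    K=1 start); later restarts alternate weight-proportional vote
    resampling with uniform draws (pure exploration).  Short vectors are
    padded with uniform draws.
    """
    phi0: list[float]
    if restart == 0 and len(votes) > 0:
        phi0 = list(_vote_centers(votes, weights, grid, K)[:K])
    elif restart == 1:
        phi0 = [pooled_peak] * K
    elif restart % 2 == 0 and len(votes) > 0:
        p = weights / weights.sum()
        phi0 = list(np.unique(rng.choice(votes, size=K, p=p)))[:K]
    else:
        phi0 = []
    n_extra = K - len(phi0)
    if n_extra > 0:
        phi0 += list(rng.uniform(options.phi_min, options.phi_max, n_extra))
    return np.sort(np.asarray(phi0, dtype=float))


def _single_run(
    packed: PackedData,
    K: int,
    baseline: BaselineScale,
    space: ConfigSpace,
    options: EMOptions,
    rng: np.random.Generator,
    grid: np.ndarray,
    grid_ll: np.ndarray,
    phi0: np.ndarray,
) -> tuple[ModelParams, np.ndarray, list[float], bool]:
    n_h = len(space.configs)
    params = ModelParams(
        phi=phi0,
        pi=np.full(K, 1.0 / K),
        rho=np.full((packed.J, n_h), 1.0 / n_h),
    )
    trace: list[float] = []
    converged = False
    gamma, ll = e_step(packed, params, baseline, space)
    trace.append(ll)
    for _ in range(options.max_iter):
        params, gamma = m_step(
            packed, gamma, params, baseline, space, options, grid, grid_ll
        )
        gamma, ll = e_step(packed, params, baseline, space)
        trace.append(ll)
        if len(trace) >= 2:
            prev = trace[-2]
            if abs(ll - prev) <= options.rel_tol * abs(prev):
                converged = True
                break
    return params, gamma, trace, converged


def fit(
    dataset: Dataset,
    K: int,
    baseline: BaselineScale,
    space: ConfigSpace,
    options: EMOptions | None = None,
    warm_starts: list[np.ndarray] | None = None,
) -> FitResult:
    """Best-of-restarts EM fit with K subclones.

    ``warm_starts`` supplies extra initial prevalence vectors (each length
    K), run as additional restarts; :func:`subclonemix.selection.run_selection`
    uses this to seed each K from the previous K's solution.
    """
    options = options or EMOptions()
    if K < 1:
        raise ValueError("K must be >= 1")
    packed = PackedData.from_dataset(dataset)
    if K > packed.J:
        warnings.warn(
            f"K={K} exceeds the number of segments J={packed.J}; the fit "
            "will be degenerate",
            stacklevel=2,
        )
    grid = np.linspace(options.phi_min, options.phi_max, options.phi_grid)
    grid_ll = segment_loglik_matrix(packed, grid, baseline, space)
    votes, weights, pooled_peak = _prevalence_votes(grid, grid_ll)

    inits: list[np.ndarray] = []
    for r in range(options.restarts):
        rng = np.random.default_rng([options.seed, r])
        inits.append(
            _initial_phi(K, r, votes, weights, pooled_peak, grid, rng, options)
        )
    for w in warm_starts or []:
        w = np.sort(np.clip(np.asarray(w, dtype=float),
                            options.phi_min, options.phi_max))
        if len(w) != K:
            raise ValueError(f"warm start has length {len(w)}, expected K={K}")
        inits.append(w)

    best: tuple[ModelParams, np.ndarray, list[float], bool] | None = None
    for r, phi0 in enumerate(inits):
        rng = np.random.default_rng([options.seed, r])
        run = _single_run(
            packed, K, baseline, space, options, rng, grid, grid_ll, phi0
        )
        if best is None or run[2][-1] > best[2][-1]:
            best = run
    assert best is not None
    params, gamma, trace, converged = best

    flat = gamma.reshape(packed.J, -1)
    flat_idx = flat.argmax(axis=1)  # first max: lowest (k, h) index on ties
    n_h = len(space.configs)
    map_k = flat_idx // n_h
    map_h = flat_idx % n_h
    copy_numbers = np.array([space.configs[h].copy_number for h in map_h])
    return FitResult(
        params=params,
        loglik=trace[-1],
        loglik_trace=trace,
        responsibilities=gamma,
        map_subclone=map_k,
        map_config=map_h,
        map_config_labels=[space.configs[h].label for h in map_h],
        segment_prevalence=params.phi[map_k],
        segment_copy_number=copy_numbers,
        converged=converged,
        segment_ids=list(packed.segment_ids),
    )
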