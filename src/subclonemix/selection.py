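"""Choosing the number of subclonal populations K.

The mixture is fitted for K = 1..K_max (default 5) and the number of
subclones is read off the growth of the maximized log-likelihood:

    Delta   = L_Kmax - L_1
    ratio   = |Delta / L_1|
    delta_i = |L_i - L_1| / Delta        for i = 2..K_max

If ratio < 0.01 the likelihood is essentially flat in K — no subclonal
event — and K = 1 is chosen.  Otherwise the chosen K is the smallest i with
delta_i >= 0.9 (delta_1 is defined as 0, so this is exactly "delta_i >= 0.9
and delta_{i-1} < 0.9").  The criterion depends on the *absolute* value of
L_1, hence the likelihood convention of including all normalization
constants.

This rule is a heuristic guide: on real data it should be weighed together
with external evidence (purity estimates, known driver events), and the
full list of fits is returned so alternatives can be inspected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config_space import ConfigSpace
from .data_model import Dataset
from .em import EMOptions, FitResult, fit
from .likelihood import BaselineScale

__all__ = ["SelectionResult", "select_K", "run_selection"]

RATIO_THRESHOLD = 0.01
DELTA_THRESHOLD = 0.9


@dataclass
class SelectionResult:
    logliks: list[float]  # L_K for K = 1..K_max
    delta: float  # L_Kmax - L_1
    ratio: float  # |delta / L_1|
    deltas_i: list[float]  # delta_i for i = 2..K_max
    chosen_K: int
    ratio_threshold: float = RATIO_THRESHOLD
    delta_threshold: float = DELTA_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "logliks": self.logliks,
            "delta": self.delta,
            "ratio": self.ratio,
            "deltas_i": self.deltas_i,
            "chosen_K": self.chosen_K,
            "ratio_threshold": self.ratio_threshold,
            "delta_threshold": self.delta_threshold,
            "note": (
                "log-likelihood-increase criterion; treat the chosen K as a "
                "heuristic guide and weigh it against external evidence"
            ),
        }


def select_K(
    logliks: list[float],
    ratio_threshold: float = RATIO_THRESHOLD,
    delta_threshold: float = DELTA_THRESHOLD,
) -> SelectionResult:
    """Apply the log-likelihood-increase criterion to L_1..L_Kmax."""
    if len(logliks) < 2:
        raise ValueError("need log-likelihoods for at least two values of K")
    L = np.asarray(logliks, dtype=float)
    if L[0] == 0.0:
        raise ValueError("L_1 must be nonzero to form the ratio |Delta/L_1|")
    delta = float(L[-1] - L[0])
    ratio = abs(delta / L[0])
    if delta != 0.0:
        deltas_i = [float(abs(L[i] - L[0]) / delta) for i in range(1, len(L))]
    else:
        deltas_i = [0.0] * (len(L) - 1)
    if delta < 0:
        warnings.warn(
            "L_Kmax < L_1: the larger models fitted worse than K=1, which "
            "indicates an optimization failure; selecting K=1",
            stacklevel=2,
        )
        chosen = 1
    elif ratio < ratio_threshold:
        chosen = 1
    else:
        chosen = len(L)  # delta_Kmax = 1 >= threshold always holds
        for i, d in enumerate(deltas_i, start=2):
            if d >= delta_threshold:
                chosen = i
                break
    return SelectionResult(
        logliks=[float(x) for x in L],
        delta=delta,
        ratio=ratio,
        deltas_i=deltas_i,
        chosen_K=chosen,
        ratio_threshold=ratio_threshold,
        delta_threshold=delta_threshold,
    )


def run_selection(
    dataset: Dataset,
    baseline: BaselineScale,
    space: ConfigSpace,
    K_range: range | list[int] | None = None,
    options: EMOptions | None = None,
    ratio_threshold: float = RATIO_THRESHOLD,
    delta_threshold: float = DELTA_THRESHOLD,
) -> tuple[list[FitResult], SelectionResult]:
    """Fit every K in K_range (default 1..5) with shared options and select."""
    Ks = list(K_range) if K_range is not None else list(range(1, 6))
    if Ks != sorted(Ks) or Ks[0] < 1:
        raise ValueError("K_range must be an ascending list of integers >= 1")
    options = options or EMOptions()
    fits: list[FitResult] = []
    prev: FitResult | None = None
    for K in Ks:
        warm = None
        if prev is not None and K == prev.params.K + 1:
            # seed from the previous K: duplicate the heaviest component,
            # and alternatively split it slightly, so L_K starts from L_{K-1}
            phi_prev = prev.params.phi
            heavy = float(phi_prev[int(np.argmax(prev.params.pi))])
            warm = [
                np.append(phi_prev, heavy),
                np.append(phi_prev, min(heavy + 0.05, 0.99)),
                np.append(phi_prev, max(heavy - 0.05, 0.01)),
            ]
        prev = fit(dataset, K, baseline, space, options, warm_starts=warm)
        fits.append(prev)
    logliks = [f.loglik for f in fits]
    for prev, cur, K in zip(logliks, logliks[1:], Ks[1:]):
        if cur < prev - 1e-6:
            warnings.warn(
                f"L_{K} < L_{K - 1}: EM likely found a poor local optimum "
                f"for K={K}; consider more restarts",
                stacklevel=2,
            )
    return fits, select_K(logliks, ratio_threshold, delta_threshold)
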