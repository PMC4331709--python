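"""Independent brute-force reference computations for the mixture model.

Everything here re-derives the probabilities directly from the model
definition with scipy.stats pmfs and explicit enumeration, deliberately
sharing no code with the package's likelihood engine.
"""

from __future__ import annotations

import itertools
import math

from scipy import stats


def mubar(phi: float, mu_g: float, n_h: int, mu0: float = 0.5) -> float:
    num = phi * n_h * mu_g + (1.0 - phi) * 2.0 * mu0
    den = phi * n_h + (1.0 - phi) * 2.0
    return mu0 if den == 0 else num / den


def lam(phi: float, n_h: int, reads_normal: int, scale: float) -> float:
    cbar = phi * n_h + (1.0 - phi) * 2.0
    return max(0.5 * cbar * reads_normal * scale, 1e-10)


def segment_prob_exhaustive(segment, h_index, phi, scale, space) -> float:
    """P(D_T, {b_i} | h, phi) by enumerating every genotype tuple."""
    h = space.configs[h_index]
    p_depth = stats.poisson.pmf(
        segment.reads_tumor, lam(phi, h.copy_number, segment.reads_normal, scale)
    )
    sites = segment.sites
    total_site = 0.0
    if not sites:
        return float(p_depth)
    for g_tuple in itertools.product(range(len(space.genotypes)), repeat=len(sites)):
        prob = 1.0
        for site, gi in zip(sites, g_tuple):
            mu = mubar(phi, space.genotypes[gi].baf, h.copy_number)
            prob *= space.Q[h_index, gi] * stats.binom.pmf(
                site.b_tumor, site.d_tumor, mu
            )
        total_site += prob
    return float(p_depth * total_site)


def total_loglik_exhaustive(dataset, params, scale, space) -> float:
    """Observed-data log-likelihood by direct enumeration over (Z, H, G)."""
    out = 0.0
    for j, seg in enumerate(dataset.segments):
        seg_prob = 0.0
        for k in range(len(params.phi)):
            for hi in range(len(space.configs)):
                seg_prob += (
                    params.pi[k]
                    * params.rho[j, hi]
                    * segment_prob_exhaustive(
                        seg, hi, float(params.phi[k]), scale, space
                    )
                )
        out += math.log(seg_prob)
    return out


def site_loglik_direct(b, d, h_index, phi, space) -> float:
    """log sum_g Q Binom without log-space tricks."""
    total = 0.0
    for gi, g in enumerate(space.genotypes):
        mu = mubar(phi, g.baf, space.configs[h_index].copy_number)
        total += space.Q[h_index, gi] * stats.binom.pmf(b, d, mu)
    return math.log(total)


def posterior_direct(dataset, params, scale, space):
    """Per-segment Bayes posterior over (k, h) by direct enumeration."""
    import numpy as np

    J = dataset.n_segments
    K = len(params.phi)
    H = len(space.configs)
    gamma = np.zeros((J, K, H))
    for j, seg in enumerate(dataset.segments):
        for k in range(K):
            for hi in range(H):
                gamma[j, k, hi] = (
                    params.pi[k]
                    * params.rho[j, hi]
                    * segment_prob_exhaustive(
                        seg, hi, float(params.phi[k]), scale, space
                    )
                )
        gamma[j] /= gamma[j].sum()
    return gamma
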