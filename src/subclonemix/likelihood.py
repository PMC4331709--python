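"""Joint Poisson-binomial likelihood of segment depths and SNP allele counts.

Model
-----
Each segment j carries a latent subclonal label Z_j in {1..K} (subclone k
has cellular prevalence phi_k) and a latent allelic configuration H_j with
copy number n_h.  The *average* copy number of the segment across the cell
mixture is

    Cbar_j = phi_k * n_h + (1 - phi_k) * 2,

the diploid background contributing 2 copies.  The expected tumor read
count is anchored on a curated set S of diploid heterozygous "baseline"
segments: with mappability ratios taken from the normal sample
(theta_x / theta_y = D_x^N / D_y^N) the expectation reduces to

    lambda_j = (Cbar_j / 2) * D_j^N * B,   B = (1/|S|) sum_{s in S} D_s^T / D_s^N,

and the tumor segment depth is D_j^T ~ Poisson(lambda_j).

At a SNP site heterozygous in the normal genome, with tumor genotype g
(BAF mu_g) the mixture-average BAF is

    mubar = (phi * n_h * mu_g + (1 - phi) * 2 * mu0) / (phi * n_h + (1 - phi) * 2),

mu0 = 1/2, and the tumor B-allele count is b ~ Binomial(d, mubar).  The
genotype is marginalized under the consistency table Q of the configuration
space, giving the joint segment likelihood

    P(D_j^T, {b_ij} | h, k) = Poisson(D_j^T; lambda_j)
                              * prod_i sum_g Q_gh Binomial(b_ij; d_ij, mubar).

Normalization constants (binomial coefficients, the Poisson factorial) are
included in reported log-likelihoods: the model-selection criterion depends
on absolute values of L, so the convention matters and is fixed here.

All mixture sums run in log space.  ``segment_loglik_matrix`` is the
vectorized engine used by the EM fitter: it evaluates log P(segment | h,
phi) for a whole vector of prevalences at once over flattened site arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .config_space import ConfigSpace
from .data_model import Dataset, SegmentRecord

__all__ = [
    "BaselineScale",
    "ModelParams",
    "LikelihoodConstants",
    "PackedData",
    "compute_baseline_scale",
    "avg_copy_number",
    "expected_depth",
    "avg_baf",
    "site_loglik",
    "segment_loglik",
    "segment_loglik_matrix",
    "total_loglik",
]

MU0 = 0.5  # BAF of a heterozygous site in the normal sample
LAMBDA_FLOOR = 1e-10  # keeps Poisson finite at copy number 0, phi -> 1
DEFAULT_PHI_MIN = 0.01
DEFAULT_PHI_MAX = 0.99


@dataclass
class LikelihoodConstants:
    mu0: float = MU0
    include_normalizers: bool = True


@dataclass
class BaselineScale:
    """Tumor/normal depth ratio averaged over the baseline segments S."""

    scale: float
    source_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("baseline scale must be positive")
        if len(self.source_ids) < 1:
            raise ValueError("baseline set must contain at least one segment")


def compute_baseline_scale(dataset: Dataset, baseline_ids: set[str]) -> BaselineScale:
    """B = (1/|S|) sum_{s in S} reads_tumor(s) / reads_normal(s)."""
    ratios = []
    ids = []
    for seg in dataset.segments:
        if seg.segment_id in baseline_ids:
            if seg.reads_normal <= 0:
                raise ValueError(
                    f"baseline segment {seg.segment_id!r} has zero normal depth"
                )
            ratios.append(seg.reads_tumor / seg.reads_normal)
            ids.append(seg.segment_id)
    if not ids:
        raise ValueError("no baseline segment ids found in dataset")
    return BaselineScale(scale=float(np.mean(ratios)), source_ids=tuple(ids))


@dataclass
class ModelParams:
    """Mixture parameters Theta = (phi, pi, rho).

    phi : (K,) subclone cellular prevalences, ascending.
    pi : (K,) mixing weights over subclones.
    rho : (J, |H|) per-segment categorical over allelic configurations.
    """

    phi: np.ndarray
    pi: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.phi.shape != self.pi.shape:
            raise ValueError("phi and pi must have the same length K")
        if not np.all(np.diff(self.phi) >= 0):
            raise ValueError("phi must be sorted ascending (canonical labels)")
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.rho.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each rho row must sum to 1")

    @property
    def K(self) -> int:
        return len(self.phi)


def avg_copy_number(phi, n_h):
    """Average copy number across the cell mixture: phi*n_h + (1-phi)*2."""
    phi = np.asarray(phi, dtype=float)
    n_h = np.asarray(n_h, dtype=float)
    return phi * n_h + (1.0 - phi) * 2.0


def expected_depth(
    segment: SegmentRecord,
    phi: float,
    n_h: float,
    baseline: BaselineScale,
    lambda_floor: float = LAMBDA_FLOOR,
) -> float:
    """Expected tumor read count lambda_j = (Cbar/2) * D_j^N * B, floored."""
    if segment.reads_normal <= 0:
        raise ValueError(
            f"segment {segment.segment_id!r} has zero normal depth; cannot "
            "form the expected tumor depth"
        )
    lam = 0.5 * avg_copy_number(phi, n_h) * segment.reads_normal * baseline.scale
    return float(max(lam, lambda_floor))


def avg_baf(phi, mu_g, n_h, mu0: float = MU0):
    """Mixture-average BAF; returns mu0 when the copy-mass denominator is 0."""
    phi = np.asarray(phi, dtype=float)
    mu_g = np.asarray(mu_g, dtype=float)
    n_h = np.asarray(n_h, dtype=float)
    num = phi * n_h * mu_g + (1.0 - phi) * 2.0 * mu0
    den = phi * n_h + (1.0 - phi) * 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), mu0)
    if out.ndim == 0:
        return float(out)
    return out


def _binom_logpmf(b, d, p, include_normalizer: bool = True):
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    p = np.asarray(p, dtype=float)
    out = b * np.log(p) + (d - b) * np.log1p(-p)
    if include_normalizer:
        out = out + gammaln(d + 1) - gammaln(b + 1) - gammaln(d - b + 1)
    return out


def _poisson_logpmf(k, lam, include_normalizer: bool = True):
    k = np.asarray(k, dtype=float)
    lam = np.asarray(lam, dtype=float)
    out = k * np.log(lam) - lam
    if include_normalizer:
        out = out - gammaln(k + 1)
    return out


def site_loglik(
    b: int,
    d: int,
    h_index: int,
    phi: float,
    space: ConfigSpace,
    constants: LikelihoodConstants | None = None,
) -> float:
    """log sum_g Q_gh Binomial(b; d, mubar(phi, g, h)) for one SNP site."""
    if not 0 <= b <= d:
        raise ValueError("require 0 <= b <= d")
    if d == 0:
        return 0.0
    constants = constants or LikelihoodConstants()
    n_h = space.configs[h_index].copy_number
    mubar = avg_baf(phi, space.mu_g, n_h, constants.mu0)  # (|G|,)
    terms = space.log_Q[h_index] + _binom_logpmf(
        b, d, mubar, constants.include_normalizers
    )
    return float(logsumexp(terms))


def segment_loglik(
    segment: SegmentRecord,
    h_index: int,
    phi: float,
    baseline: BaselineScale,
    space: ConfigSpace,
    constants: LikelihoodConstants | None = None,
) -> float:
    """Poisson depth term plus the sum of site terms for one (h, phi)."""
    constants = constants or LikelihoodConstants()
    n_h = space.configs[h_index].copy_number
    lam = expected_depth(segment, phi, n_h, baseline)
    total = float(
        _poisson_logpmf(segment.reads_tumor, lam, constants.include_normalizers)
    )
    for site in segment.sites:
        total += site_loglik(
            site.b_tumor, site.d_tumor, h_index, phi, space, constants
        )
    return total


@dataclass
class PackedData:
    """Dataset flattened to arrays for the vectorized likelihood engine.

    Sites are concatenated in segment order; ``site_offsets`` gives the
    start index of each segment's site block (length J + 1).
    """

    segment_ids: list[str]
    D_N: np.ndarray  # (J,) normal segment read totals
    D_T: np.ndarray  # (J,) tumor segment read totals
    site_b: np.ndarray  # (S,) tumor B-allele counts
    site_d: np.ndarray  # (S,) tumor depths
    site_offsets: np.ndarray  # (J+1,)
    log_dt_factorial: np.ndarray = field(init=False)
    site_log_binom_coeff_sum: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.log_dt_factorial = gammaln(self.D_T + 1.0)
        coeff = (
            gammaln(self.site_d + 1.0)
            - gammaln(self.site_b + 1.0)
            - gammaln(self.site_d - self.site_b + 1.0)
        )
        # per-segment sum of binomial coefficients (constant in phi and h)
        self.site_log_binom_coeff_sum = np.add.reduceat(
            np.concatenate([coeff, [0.0]]), self.site_offsets[:-1]
        ) * (np.diff(self.site_offsets) > 0)

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "PackedData":
        ids, dn, dt, b, d, offsets = [], [], [], [], [], [0]
        for seg in dataset.segments:
            ids.append(seg.segment_id)
            dn.append(seg.reads_normal)
            dt.append(seg.reads_tumor)
            for site in seg.sites:
                b.append(site.b_tumor)
                d.append(site.d_tumor)
            offsets.append(len(b))
        return cls(
            segment_ids=ids,
            D_N=np.asarray(dn, dtype=float),
            D_T=np.asarray(dt, dtype=float),
            site_b=np.asarray(b, dtype=float),
            site_d=np.asarray(d, dtype=float),
            site_offsets=np.asarray(offsets, dtype=int),
        )

    @property
    def J(self) -> int:
        return len(self.segment_ids)


def segment_loglik_matrix(
    packed: PackedData,
    phi_values: np.ndarray,
    baseline: BaselineScale,
    space: ConfigSpace,
    include_normalizers: bool = True,
    chunk: int = 16,
) -> np.ndarray:
    """log P(segment j | H_j = h, prevalence phi) for every (phi, j, h).

    Returns an array of shape (len(phi_values), J, |H|).  Evaluation is
    chunked over phi to bound the peak (phi, sites, |H|, |G|) intermediate.
    """
    phi_values = np.atleast_1d(np.asarray(phi_values, dtype=float))
    n_h = space.n_h  # (H,)
    mu_g = space.mu_g  # (G,)
    log_Q = space.log_Q  # (H, G)
    out = np.empty((len(phi_values), packed.J, len(n_h)))

    for lo in range(0, len(phi_values), chunk):
        phi = phi_values[lo : lo + chunk]  # (P,)
        cbar = avg_copy_number(phi[:, None], n_h[None, :])  # (P, H)
        lam = np.maximum(
            0.5 * cbar[:, None, :] * packed.D_N[None, :, None] * baseline.scale,
            LAMBDA_FLOOR,
        )  # (P, J, H)
        depth_ll = packed.D_T[None, :, None] * np.log(lam) - lam
        if include_normalizers:
            depth_ll = depth_ll - packed.log_dt_factorial[None, :, None]

        block = depth_ll
        if len(packed.site_b) > 0:
            mubar = avg_baf(
                phi[:, None, None], mu_g[None, None, :], n_h[None, :, None]
            )  # (P, H, G)
            log_mu = np.log(mubar)
            log_1mu = np.log1p(-mubar)
            # (P, S, H, G): per-site log Q_gh + b log mu + (d-b) log(1-mu)
            terms = (
                log_Q[None, None, :, :]
                + packed.site_b[None, :, None, None] * log_mu[:, None, :, :]
                + (packed.site_d - packed.site_b)[None, :, None, None]
                * log_1mu[:, None, :, :]
            )
            site_ll = logsumexp(terms, axis=-1)  # (P, S, H)
            # aggregate sites into their segments
            padded = np.concatenate(
                [site_ll, np.zeros((site_ll.shape[0], 1, site_ll.shape[2]))], axis=1
            )
            seg_site_ll = np.add.reduceat(padded, packed.site_offsets[:-1], axis=1)
            seg_site_ll *= (np.diff(packed.site_offsets) > 0)[None, :, None]
            if include_normalizers:
                seg_site_ll = (
                    seg_site_ll + packed.site_log_binom_coeff_sum[None, :, None]
                )
            block = block + seg_site_ll
        out[lo : lo + chunk] = block
    return out


def total_loglik(
    dataset: Dataset,
    params: ModelParams,
    baseline: BaselineScale,
    space: ConfigSpace,
    include_normalizers: bool = True,
    packed: PackedData | None = None,
) -> float:
    """Observed-data log-likelihood: sum_j logsumexp_{k,h} of
    log pi_k + log rho_jh + log P(segment j | h, phi_k)."""
    packed = packed or PackedData.from_dataset(dataset)
    if params.rho.shape != (packed.J, len(space.configs)):
        raise ValueError(
            f"rho has shape {params.rho.shape}, expected "
            f"({packed.J}, {len(space.configs)})"
        )
    ll = segment_loglik_matrix(
        packed, params.phi, baseline, space, include_normalizers
    )  # (K, J, H)
    with np.errstate(divide="ignore"):
        joint = (
            np.log(params.pi)[:, None, None] + np.log(params.rho)[None, :, :] + ll
        )
    per_segment = logsumexp(joint, axis=(0, 2))  # (J,)
    return float(per_segment.sum())
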