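"""Forward simulator for paired normal-tumor count data with known truth.

The simulator draws directly from the generative model the fitter assumes:
segment lengths and normal read totals, latent subclone labels and allelic
configurations, then tumor segment depths Poisson(lambda_j) and per-site
tumor B-allele counts Binomial(d, mubar).  It operates at the *count*
level — no reads, no aligner — so parameter-recovery experiments test the
inference machinery in isolation.

Defaults emulate a whole-genome 60X experiment on a large chromosome:
segments of 2-10 Mb, normal segment read totals at ~60X with 150 bp reads,
SNP sites at mean depth 60.  Copy-neutral LOH (PP/MM) is included in the
default configuration distribution since it is invisible to depth-only
methods but resolvable here through the allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config_space import ConfigSpace
from .data_model import Dataset, SegmentRecord, SNPSiteRecord
from .likelihood import avg_baf, avg_copy_number

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "score_against_truth"]


def _default_config_distribution() -> dict[str, float]:
    # weights over non-diploid configurations (max copy number 3 state space)
    return {"P/M": 0.3, "PP/MM": 0.2, "PPP/MMM": 0.2, "PPM/PMM": 0.3}


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``phi_true`` holds the cellular prevalence of each subclone.  A
    ``diploid_fraction`` of segments is forced to configuration PM (these
    are the ground-truth baseline); the rest draw a configuration from
    ``config_distribution`` and a subclone by a shuffled balanced
    assignment, so every subclone carries SCNA signal.
    """

    J: int = 40
    phi_true: tuple[float, ...] = (0.2, 0.8)
    segment_length_range: tuple[int, int] = (2_000_000, 10_000_000)
    diploid_fraction: float = 0.5
    config_distribution: dict[str, float] = field(
        default_factory=_default_config_distribution
    )
    snp_per_segment: float = 20.0
    normal_coverage_per_segment: float = 2_400_000.0  # ~60X / 150 bp at 6 Mb
    snp_depth_mean: float = 60.0
    tumor_normal_ratio: float = 1.0
    max_copy_number: int = 3
    epsilon: float = 0.01
    seed: int = 0

    @property
    def K(self) -> int:
        return len(self.phi_true)

    def __post_init__(self) -> None:
        if len(set(self.phi_true)) != len(self.phi_true):
            raise ValueError("phi_true values must be distinct")
        if not all(0.0 < p < 1.0 for p in self.phi_true):
            raise ValueError("phi_true values must lie in (0, 1)")
        if self.K > self.J:
            raise ValueError("more subclones than segments")
        total = sum(self.config_distribution.values())
        if total <= 0:
            raise ValueError("config_distribution weights must be positive")
        self.config_distribution = {
            k: v / total for k, v in self.config_distribution.items()
        }


@dataclass
class GroundTruth:
    """Latent state used to generate a dataset."""

    phi_true: tuple[float, ...]
    z_true: np.ndarray  # (J,) subclone index per segment
    h_true_labels: list[str]  # (J,) configuration label per segment
    is_baseline_true: np.ndarray  # (J,) diploid-PM truth flags


def simulate_dataset(
    config: SimConfig, space: ConfigSpace | None = None
) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset and its ground truth; deterministic given the seed."""
    space = space or ConfigSpace.build(
        config.max_copy_number, epsilon=config.epsilon
    )
    labels = space.config_labels
    for lab in config.config_distribution:
        if lab not in labels:
            raise ValueError(f"unknown configuration label {lab!r} in distribution")
        if lab == "PM":
            raise ValueError("config_distribution covers non-diploid states only")

    rng = np.random.default_rng(config.seed)
    J = config.J

    n_diploid = int(round(config.diploid_fraction * J))
    if J - n_diploid == 0 and config.K > 1:
        raise ValueError("all segments diploid but more than one subclone requested")

    # latent assignments: diploid segments are PM; non-diploid segments draw a
    # configuration and get subclones round-robin after a shuffle, so each
    # subclone is represented about equally
    is_diploid = np.zeros(J, dtype=bool)
    is_diploid[rng.choice(J, size=n_diploid, replace=False)] = True
    z_true = rng.integers(0, config.K, size=J)
    non_diploid_idx = np.flatnonzero(~is_diploid)
    rng.shuffle(non_diploid_idx)
    z_true[non_diploid_idx] = np.arange(len(non_diploid_idx)) % config.K

    cfg_labels = list(config.config_distribution)
    cfg_weights = np.array([config.config_distribution[c] for c in cfg_labels])
    h_true_labels = []
    for j in range(J):
        if is_diploid[j]:
            h_true_labels.append("PM")
        else:
            h_true_labels.append(cfg_labels[rng.choice(len(cfg_labels), p=cfg_weights)])

    lengths = rng.integers(
        config.segment_length_range[0], config.segment_length_range[1] + 1, size=J
    )
    mean_length = float(np.mean(config.segment_length_range))
    rate_per_bp = config.normal_coverage_per_segment / mean_length

    segments: list[SegmentRecord] = []
    start = 0
    phi_arr = np.array(config.phi_true)
    for j in range(J):
        h_idx = space.config_index(h_true_labels[j])
        h = space.configs[h_idx]
        phi = phi_arr[z_true[j]]
        D_N = int(rng.poisson(rate_per_bp * lengths[j]))
        D_N = max(D_N, 1)
        cbar = float(avg_copy_number(phi, h.copy_number))
        lam = max(0.5 * cbar * D_N * config.tumor_normal_ratio, 1e-10)
        D_T = int(rng.poisson(lam))

        n_sites = int(rng.poisson(config.snp_per_segment))
        positions = np.sort(
            np.unique(rng.integers(0, lengths[j], size=min(n_sites, lengths[j])))
        )
        # genotypes consistent with h: uniform over the 1-2 compatible states
        compat = np.flatnonzero(space.Q[h_idx] == space.Q[h_idx].max())
        sites = []
        for pos in positions:
            g_idx = int(rng.choice(compat))
            mu = float(
                avg_baf(phi, space.genotypes[g_idx].baf, h.copy_number)
            )
            d_n = int(rng.poisson(config.snp_depth_mean))
            d_t = int(rng.poisson(config.snp_depth_mean))
            b_n = int(rng.binomial(d_n, 0.5)) if d_n > 0 else 0
            b_t = int(rng.binomial(d_t, mu)) if d_t > 0 else 0
            sites.append(
                SNPSiteRecord(
                    position=start + int(pos),
                    b_normal=b_n,
                    d_normal=d_n,
                    b_tumor=b_t,
                    d_tumor=d_t,
                )
            )
        segments.append(
            SegmentRecord(
                chrom="chrSim",
                start=start,
                end=start + int(lengths[j]),
                segment_id=f"seg{j:04d}",
                reads_normal=D_N,
                reads_tumor=D_T,
                sites=sites,
                is_baseline=bool(is_diploid[j]),
            )
        )
        start += int(lengths[j])

    dataset = Dataset(
        segments=segments,
        metadata={
            "simulated": True,
            "seed": config.seed,
            "phi_true": list(config.phi_true),
            "max_copy_number": config.max_copy_number,
        },
    )
    truth = GroundTruth(
        phi_true=config.phi_true,
        z_true=z_true,
        h_true_labels=h_true_labels,
        is_baseline_true=is_diploid,
    )
    return dataset, truth


def score_against_truth(
    phi_hat: np.ndarray,
    map_subclone: np.ndarray,
    map_config_labels: list[str],
    truth: GroundTruth,
) -> dict:
    """Compare a fit with the generating truth.

    Fitted subclone labels are matched to true subclones by the assignment
    minimizing total |phi_hat - phi_true| (optimal over permutations).
    Assignment and configuration accuracy are reported on the non-diploid
    segments, where the data carry subclonal signal.
    """
    from scipy.optimize import linear_sum_assignment

    phi_hat = np.asarray(phi_hat, dtype=float)
    phi_true = np.asarray(truth.phi_true, dtype=float)
    cost = np.abs(phi_hat[:, None] - phi_true[None, :])
    rows, cols = linear_sum_assignment(cost)
    prevalence_mae = float(cost[rows, cols].mean())
    fitted_to_true = dict(zip(rows.tolist(), cols.tolist()))

    non_diploid = ~truth.is_baseline_true
    if non_diploid.any():
        mapped = np.array(
            [fitted_to_true.get(int(k), -1) for k in map_subclone]
        )
        assignment_accuracy = float(
            np.mean(mapped[non_diploid] == truth.z_true[non_diploid])
        )
        config_accuracy = float(
            np.mean(
                [
                    lab == true_lab
                    for lab, true_lab, nd in zip(
                        map_config_labels, truth.h_true_labels, non_diploid
                    )
                    if nd
                ]
            )
        )
    else:
        assignment_accuracy = float("nan")
        config_accuracy = float("nan")
    return {
        "prevalence_mae": prevalence_mae,
        "assignment_accuracy": assignment_accuracy,
        "config_accuracy": config_accuracy,
    }
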