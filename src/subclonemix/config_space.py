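"""Allele-specific state spaces for segment copy number and SNP genotypes.

A segment's *allelic configuration* describes how many copies of each
parental haplotype (P = paternal, M = maternal) the tumor carries, e.g.
``PM`` (normal diploid heterozygous), ``PP/MM`` (copy-neutral LOH) or
``PPM/PMM`` (single-copy gain).  Because short-read data cannot phase the
reference genome, mirror-image states (PP vs MM) are indistinguishable and
are stored once as a merged class.

A SNP site's *tumor genotype* is a multiset over the reference (A) and
alternative (B) allele, e.g. ``AB`` or ``AAB``.  Each genotype has a
B-allele frequency (BAF); homozygous BAFs of exactly 0 or 1 are clamped to
``epsilon`` / ``1 - epsilon`` to absorb sequencing error (``epsilon = 0.01``
corresponds to a Phred base quality of 20).

Genotypes are tied to configurations through the consistency table ``Q``:
for a site that is heterozygous in the matched normal genome, a genotype is
consistent with a configuration when its allele counts match the
configuration's haplotype counts.  Inconsistent genotypes keep a small leak
probability ``sigma`` so the likelihood never vanishes on noisy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AllelicConfig",
    "Genotype",
    "ConfigSpace",
    "enumerate_configs",
    "enumerate_genotypes",
    "is_compatible",
    "build_Q",
]

DEFAULT_MAX_COPY_NUMBER = 6
DEFAULT_EPSILON = 0.01
DEFAULT_SIGMA = 0.01

EMPTY_LABEL = "EMPTY"


@dataclass(frozen=True)
class AllelicConfig:
    """Allele-specific copy-number state of a segment.

    ``allele_multiset`` is the unordered pair of haplotype copy counts,
    stored as a sorted (descending) tuple; e.g. PM -> (1, 1),
    PPM/PMM -> (2, 1), EMPTY -> (0, 0).
    """

    label: str
    copy_number: int
    allele_multiset: tuple[int, int]

    def __post_init__(self) -> None:
        if self.copy_number != sum(self.allele_multiset):
            raise ValueError(
                f"copy_number {self.copy_number} does not match allele counts "
                f"{self.allele_multiset}"
            )


@dataclass(frozen=True)
class Genotype:
    """Tumor genotype of a SNP site: a multiset over alleles A and B."""

    label: str
    b_count: int
    copy_number: int
    baf: float

    def __post_init__(self) -> None:
        if self.b_count > self.copy_number:
            raise ValueError("b_count exceeds copy_number")


def _config_label(counts: tuple[int, int]) -> str:
    a, b = counts  # a >= b
    if a == 0:
        return EMPTY_LABEL
    primary = "P" * a + "M" * b
    mirror = "P" * b + "M" * a
    return primary if primary == mirror else f"{primary}/{mirror}"


def enumerate_configs(max_copy_number: int) -> list[AllelicConfig]:
    """Enumerate allelic configurations up to ``max_copy_number`` total copies.

    One entry per unordered pair of haplotype counts {a, b} with
    a + b <= max_copy_number, mirror classes merged.  Balanced states other
    than PM (e.g. PPMM) are excluded: with both alleles at equal dosage they
    are indistinguishable from the diploid baseline and are not modeled.
    Order is (copy number ascending, then the more-imbalanced class first),
    which at max copy 3 yields EMPTY, P/M, PP/MM, PM, PPP/MMM, PPM/PMM.
    """
    if max_copy_number < 1:
        raise ValueError(f"max_copy_number must be >= 1, got {max_copy_number}")
    configs: list[AllelicConfig] = []
    for total in range(max_copy_number + 1):
        # larger major-allele count first: PP/MM before PM, etc.
        for minor in range(total // 2 + 1):
            major = total - minor
            if minor == major and total not in (0, 2):
                continue  # balanced non-PM states (PPMM, ...) not modeled
            counts = (major, minor)
            configs.append(
                AllelicConfig(
                    label=_config_label(counts),
                    copy_number=total,
                    allele_multiset=counts,
                )
            )
    return configs


def enumerate_genotypes(
    max_copy_number: int, epsilon: float = DEFAULT_EPSILON
) -> list[Genotype]:
    """Enumerate tumor genotypes up to ``max_copy_number`` copies.

    One genotype per (copy number c, B-allele count 0..c), plus the EMPTY
    genotype (homozygous deletion), whose BAF is fixed to 1/2.  BAFs of 0
    and 1 are clamped to epsilon and 1 - epsilon respectively.
    """
    if max_copy_number < 1:
        raise ValueError(f"max_copy_number must be >= 1, got {max_copy_number}")
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    genotypes = [Genotype(EMPTY_LABEL, 0, 0, 0.5)]
    for c in range(1, max_copy_number + 1):
        for b in range(c + 1):
            baf = b / c
            if baf == 0.0:
                baf = epsilon
            elif baf == 1.0:
                baf = 1.0 - epsilon
            genotypes.append(Genotype("A" * (c - b) + "B" * b, b, c, baf))
    return genotypes


def is_compatible(g: Genotype, h: AllelicConfig) -> bool:
    """Can genotype ``g`` arise from configuration ``h`` at a site that is
    heterozygous (A on one homolog, B on the other) in the normal genome?

    True iff the copy numbers agree and the genotype's allele counts
    {b_count, copy_number - b_count} match the configuration's haplotype
    counts.  EMPTY is compatible only with EMPTY.
    """
    if g.copy_number != h.copy_number:
        return False
    counts = (max(g.b_count, g.copy_number - g.b_count),
              min(g.b_count, g.copy_number - g.b_count))
    return counts == h.allele_multiset


def build_Q(
    configs: list[AllelicConfig],
    genotypes: list[Genotype],
    sigma: float = DEFAULT_SIGMA,
) -> np.ndarray:
    """Genotype-given-configuration consistency table, shape (|H|, |G|).

    Row h: inconsistent genotypes get probability ``sigma``; the remaining
    mass is split equally among the consistent genotypes, so each row sums
    to one.
    """
    n_g = len(genotypes)
    if not 0.0 <= sigma < 1.0 / n_g:
        raise ValueError(
            f"sigma must satisfy 0 <= sigma < 1/|G| = {1.0 / n_g:.4g}, got {sigma}"
        )
    Q = np.empty((len(configs), n_g))
    for hi, h in enumerate(configs):
        compat = np.array([is_compatible(g, h) for g in genotypes], dtype=bool)
        n_compat = int(compat.sum())
        if n_compat == 0:
            raise ValueError(f"configuration {h.label} has no compatible genotype")
        mass = 1.0 - sigma * (n_g - n_compat)
        if mass <= 0.0:
            raise ValueError(
                f"sigma={sigma} leaves non-positive mass for configuration {h.label}"
            )
        Q[hi] = sigma
        Q[hi, compat] = mass / n_compat
    return Q


@dataclass
class ConfigSpace:
    """Joint enumeration of configurations, genotypes and their coupling.

    Attributes
    ----------
    configs, genotypes : the ordered state spaces H and G.
    Q : (|H|, |G|) consistency probabilities, rows summing to 1.
    n_h, mu_g : copy-number and BAF vectors aligned with the enumerations.
    """

    max_copy_number: int = DEFAULT_MAX_COPY_NUMBER
    epsilon: float = DEFAULT_EPSILON
    sigma: float = DEFAULT_SIGMA
    configs: list[AllelicConfig] = field(default_factory=list)
    genotypes: list[Genotype] = field(default_factory=list)
    Q: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    @classmethod
    def build(
        cls,
        max_copy_number: int = DEFAULT_MAX_COPY_NUMBER,
        epsilon: float = DEFAULT_EPSILON,
        sigma: float = DEFAULT_SIGMA,
    ) -> "ConfigSpace":
        configs = enumerate_configs(max_copy_number)
        genotypes = enumerate_genotypes(max_copy_number, epsilon)
        Q = build_Q(configs, genotypes, sigma)
        return cls(max_copy_number, epsilon, sigma, configs, genotypes, Q)

    @property
    def n_h(self) -> np.ndarray:
        return np.array([h.copy_number for h in self.configs], dtype=float)

    @property
    def mu_g(self) -> np.ndarray:
        return np.array([g.baf for g in self.genotypes], dtype=float)

    @property
    def config_labels(self) -> list[str]:
        return [h.label for h in self.configs]

    @property
    def log_Q(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.Q)

    def config_index(self, label: str) -> int:
        return self.config_labels.index(label)

    def genotype_index(self, label: str) -> int:
        return [g.label for g in self.genotypes].index(label)


def phred_quality(error_probability: float) -> float:
    """Phred scale of an error probability: -10 log10(p)."""
    return -10.0 * math.log10(error_probability)
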