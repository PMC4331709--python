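"""From pileup-level allele counts to a model-ready dataset.

Three steps:

1. *Heterozygous-site calling* in the normal sample: a site is kept when its
   normal depth clears a floor and its normal BAF sits inside a symmetric
   band around 1/2.  A window rule (rather than a genotype-likelihood model)
   keeps the policy transparent and configurable.
2. *Aggregation*: read totals and the retained het sites are attached to
   their segments.
3. *Baseline curation*: segments that show no loss of heterozygosity in the
   tumor (few sites with extreme tumor BAF) and whose tumor/normal depth
   ratio sits near the genome-wide median are declared diploid "baseline"
   segments; they anchor the absolute expected depth.  The two filters
   catch, respectively, allelic imbalance (including copy-neutral LOH) and
   balanced amplifications (e.g. a 4-copy PPMM-like segment keeps BAF 0.5
   but doubles its depth ratio).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import Dataset, FormatError, SegmentRecord, SNPSiteRecord

__all__ = [
    "PileupSite",
    "HetCallPolicy",
    "BaselinePolicy",
    "BaselineCurationError",
    "read_pileup",
    "call_het_sites",
    "aggregate_segments",
    "curate_baseline",
]

logger = logging.getLogger(__name__)


@dataclass
class PileupSite:
    """Raw allele counts at one candidate SNP position (A = reference)."""

    chrom: str
    position: int
    ref_count_normal: int
    alt_count_normal: int
    ref_count_tumor: int
    alt_count_tumor: int

    @property
    def d_normal(self) -> int:
        return self.ref_count_normal + self.alt_count_normal

    @property
    def d_tumor(self) -> int:
        return self.ref_count_tumor + self.alt_count_tumor


@dataclass
class HetCallPolicy:
    """Window rule for calling a site heterozygous in the normal sample."""

    min_depth_normal: int = 10
    baf_lower: float = 0.3
    baf_upper: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.baf_lower < self.baf_upper <= 1.0:
            raise ValueError("require 0 <= baf_lower < baf_upper <= 1")


@dataclass
class BaselinePolicy:
    """Thresholds for curating the diploid baseline segment set.

    ``loh_baf_lower/upper`` bound the tumor-BAF band considered balanced;
    a site outside it counts as LOH-like.  A segment passes the LOH filter
    when it has at least ``min_sites`` het sites and at most
    ``max_loh_fraction`` of them are LOH-like.  The depth filter then keeps
    segments whose tumor/normal ratio lies within
    [ratio_tol_lower, ratio_tol_upper] x median ratio AND within
    ``mad_multiplier`` scaled median absolute deviations of the median:
    at whole-genome depths the diploid ratio cluster is tight to a fraction
    of a percent, and the adaptive band rejects shallow SCNAs (e.g. a
    single-copy loss carried by a 20%-prevalence subclone shifts the ratio
    by only 10%) that a fixed band would admit and that would otherwise
    bias the baseline scale.
    """

    min_sites: int = 10
    loh_baf_lower: float = 0.35
    loh_baf_upper: float = 0.65
    max_loh_fraction: float = 0.2
    ratio_tol_lower: float = 0.8
    ratio_tol_upper: float = 1.2
    mad_multiplier: float = 5.0

    def __post_init__(self) -> None:
        for name in ("loh_baf_lower", "loh_baf_upper", "max_loh_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.loh_baf_lower >= self.loh_baf_upper:
            raise ValueError("require loh_baf_lower < loh_baf_upper")
        if not 0.0 < self.ratio_tol_lower <= 1.0 <= self.ratio_tol_upper:
            raise ValueError("require ratio_tol_lower <= 1 <= ratio_tol_upper")


class BaselineCurationError(RuntimeError):
    """No segment survived baseline curation."""


_PILEUP_COLS = [
    "chrom",
    "position",
    "ref_count_normal",
    "alt_count_normal",
    "ref_count_tumor",
    "alt_count_tumor",
]


def read_pileup(path: str | Path) -> list[PileupSite]:
    """Read the optional pileup TSV (columns as in ``_PILEUP_COLS``)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _PILEUP_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return [
        PileupSite(
            str(r.chrom),
            int(r.position),
            int(r.ref_count_normal),
            int(r.alt_count_normal),
            int(r.ref_count_tumor),
            int(r.alt_count_tumor),
        )
        for r in df.itertuples(index=False)
    ]


def call_het_sites(
    sites: list[PileupSite], policy: HetCallPolicy | None = None
) -> list[bool]:
    """Flag sites heterozygous in the normal sample under the window rule:
    normal depth >= floor and normal BAF within [baf_lower, baf_upper]."""
    policy = policy or HetCallPolicy()
    flags = []
    for site in sites:
        d = site.d_normal
        if d < policy.min_depth_normal:
            flags.append(False)
            continue
        baf = site.alt_count_normal / d
        flags.append(policy.baf_lower <= baf <= policy.baf_upper)
    return flags


def aggregate_segments(
    segments: list[tuple[str, int, int, str]],
    pileup: list[PileupSite],
    read_totals: dict[str, tuple[int, int]],
    het_policy: HetCallPolicy | None = None,
) -> Dataset:
    """Assemble a Dataset from segment definitions, pileup sites and
    per-segment read totals (segment_id -> (reads_normal, reads_tumor)).

    Sites are assigned to segments by half-open interval membership; sites
    covered by no segment are dropped with a warning, overlapping segment
    definitions are an error.  Only sites passing the het policy are kept.
    """
    het_policy = het_policy or HetCallPolicy()
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, seg_id in segments:
        by_chrom.setdefault(chrom, []).append((start, end, seg_id))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, id1), (s2, e2, id2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise FormatError(
                    f"segments {id1!r} and {id2!r} overlap on {chrom}"
                )

    records = {
        seg_id: SegmentRecord(
            chrom=chrom,
            start=start,
            end=end,
            segment_id=seg_id,
            reads_normal=read_totals.get(seg_id, (0, 0))[0],
            reads_tumor=read_totals.get(seg_id, (0, 0))[1],
        )
        for chrom, start, end, seg_id in segments
    }

    flags = call_het_sites(pileup, het_policy)
    n_dropped = 0
    for site, is_het in zip(pileup, flags):
        if not is_het:
            continue
        home = None
        for start, end, seg_id in by_chrom.get(site.chrom, []):
            if start <= site.position < end:
                home = seg_id
                break
        if home is None:
            n_dropped += 1
            continue
        records[home].sites.append(
            SNPSiteRecord(
                position=site.position,
                b_normal=site.alt_count_normal,
                d_normal=site.d_normal,
                b_tumor=site.alt_count_tumor,
                d_tumor=site.d_tumor,
            )
        )
    if n_dropped:
        logger.warning("%d het sites fell outside every segment; dropped", n_dropped)
    for rec in records.values():
        rec.sites.sort(key=lambda s: s.position)
        if rec.reads_normal <= 0:
            logger.warning("segment %s has zero normal reads", rec.segment_id)
    return Dataset(segments=list(records.values()))


def curate_baseline(
    dataset: Dataset, policy: BaselinePolicy | None = None
) -> set[str]:
    """Curate the diploid-heterozygous baseline segment set S.

    Step 1 keeps segments with enough het sites and a low fraction of
    LOH-like tumor BAFs; step 2 removes depth-ratio outliers relative to
    the median tumor/normal ratio of the step-1 survivors.  All members of
    S are treated downstream as configuration PM with copy number 2.
    """
    policy = policy or BaselinePolicy()
    step1: list[SegmentRecord] = []
    for seg in dataset.segments:
        if seg.n_sites < policy.min_sites or seg.reads_normal <= 0:
            continue
        bafs = np.array(
            [s.b_tumor / s.d_tumor for s in seg.sites if s.d_tumor > 0]
        )
        if len(bafs) < policy.min_sites:
            continue
        loh_frac = np.mean(
            (bafs < policy.loh_baf_lower) | (bafs > policy.loh_baf_upper)
        )
        if loh_frac <= policy.max_loh_fraction:
            step1.append(seg)
    if not step1:
        raise BaselineCurationError(
            "no segment passed the LOH filter; relax the baseline policy or "
            "provide is_baseline flags in segments.tsv"
        )
    # step 2 iterates to a fixed point so that curating the returned set
    # again changes nothing (the median is recomputed on the survivors)
    kept = list(step1)
    while True:
        ratios = np.array([s.reads_tumor / s.reads_normal for s in kept])
        med = float(np.median(ratios))
        mad = 1.4826 * float(np.median(np.abs(ratios - med)))  # scaled MAD
        lo = policy.ratio_tol_lower * med
        hi = policy.ratio_tol_upper * med
        if mad > 0:
            lo = max(lo, med - policy.mad_multiplier * mad)
            hi = min(hi, med + policy.mad_multiplier * mad)
        survivors = [
            seg for seg, r in zip(kept, ratios) if lo <= r <= hi
        ]
        if not survivors:
            raise BaselineCurationError(
                "all LOH-free segments were depth-ratio outliers; relax the "
                "baseline policy or provide is_baseline flags"
            )
        if len(survivors) == len(kept):
            return {seg.segment_id for seg in kept}
        kept = survivors
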