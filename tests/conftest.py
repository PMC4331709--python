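import numpy as np
import pytest

from subclonemix import (
    BaselineScale,
    ConfigSpace,
    Dataset,
    ModelParams,
    SegmentRecord,
    SNPSiteRecord,
)


@pytest.fixture(scope="session")
def space3() -> ConfigSpace:
    """Default-epsilon state space at max copy number 3 (|H|=6, |G|=10)."""
    return ConfigSpace.build(3)


@pytest.fixture(scope="session")
def space2() -> ConfigSpace:
    """Small state space at max copy number 2 for exhaustive oracles."""
    return ConfigSpace.build(2)


def make_segment(
    seg_id: str,
    reads_normal: int,
    reads_tumor: int,
    site_counts: list[tuple[int, int]],
    start: int = 0,
    length: int = 10_000,
) -> SegmentRecord:
    """Small hand-built segment; site_counts holds (b_tumor, d_tumor)."""
    sites = [
        SNPSiteRecord(
            position=start + 10 * (i + 1),
            b_normal=5,
            d_normal=10,
            b_tumor=b,
            d_tumor=d,
        )
        for i, (b, d) in enumerate(site_counts)
    ]
    return SegmentRecord(
        chrom="chrT",
        start=start,
        end=start + length,
        segment_id=seg_id,
        reads_normal=reads_normal,
        reads_tumor=reads_tumor,
        sites=sites,
    )


@pytest.fixture()
def tiny_dataset() -> Dataset:
    """Two small segments with site depths <= 4: exhaustively enumerable."""
    return Dataset(
        segments=[
            make_segment("s1", 100, 110, [(1, 3), (2, 4)], start=0),
            make_segment("s2", 80, 60, [(0, 2)], start=10_000),
        ]
    )


@pytest.fixture()
def tiny_params_k2(space2) -> ModelParams:
    rho = np.full((2, len(space2.configs)), 1.0 / len(space2.configs))
    return ModelParams(
        phi=np.array([0.3, 0.7]), pi=np.array([0.4, 0.6]), rho=rho
    )


@pytest.fixture()
def unit_baseline() -> BaselineScale:
    return BaselineScale(scale=1.1, source_ids=("s1",))
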