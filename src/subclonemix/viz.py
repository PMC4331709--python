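"""Diagnostic plots: prevalence vs copy number, likelihood vs K, BAF QC."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .data_model import Dataset
from .em import FitResult
from .selection import SelectionResult

__all__ = ["plot_results"]

logger = logging.getLogger(__name__)

_MAX_BAF_PANELS = 24


def _save(fig, out_dir: Path, stem: str) -> list[Path]:
    paths = []
    for ext in ("png", "svg"):
        p = out_dir / f"{stem}.{ext}"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        paths.append(p)
    plt.close(fig)
    return paths


def plot_results(
    fit: FitResult | None,
    selection: SelectionResult | None,
    out_dir: str | Path,
    dataset: Dataset | None = None,
) -> list[Path]:
    """Write the three result figures (PNG + SVG each) into ``out_dir``.

    1. prevalence-vs-copy-number scatter, one dot per segment;
    2. log-likelihood against the number of subclones K;
    3. per-segment tumor BAF histograms (QC; needs the dataset).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if fit is not None:
        if len(fit.segment_prevalence) == 0:
            logger.warning("fit has no segments; prevalence plot will be empty")
        figure, ax = plt.subplots(figsize=(5, 4))
        jitter = np.linspace(-0.08, 0.08, max(len(fit.segment_copy_number), 1))
        ax.scatter(
            fit.segment_copy_number + jitter,
            fit.segment_prevalence,
            s=18,
            alpha=0.7,
            color="tab:blue",
        )
        ax.set_xlabel("estimated absolute copy number")
        ax.set_ylabel("estimated cellular prevalence")
        ax.set_ylim(0, 1)
        ax.set_title("segments: prevalence vs copy number")
        written += _save(figure, out_dir, "prevalence_vs_copy_number")

    if selection is not None:
        figure, ax = plt.subplots(figsize=(5, 4))
        Ks = np.arange(1, len(selection.logliks) + 1)
        ax.plot(Ks, selection.logliks, "o-", color="tab:red")
        ax.axvline(selection.chosen_K, ls="--", color="gray", lw=1)
        ax.set_xticks(Ks)
        ax.set_xlabel("number of subclonal populations K")
        ax.set_ylabel("log-likelihood")
        ax.set_title(f"model selection (chosen K = {selection.chosen_K})")
        written += _save(figure, out_dir, "loglik_vs_K")

    if dataset is not None:
        with_sites = [s for s in dataset.segments if s.n_sites > 0]
        skipped = dataset.n_segments - len(with_sites)
        if skipped:
            logger.info("%d segments without SNP sites omitted from BAF panel",
                        skipped)
        panel = with_sites[:_MAX_BAF_PANELS]
        if panel:
            ncol = 4
            nrow = int(np.ceil(len(panel) / ncol))
            figure, axes = plt.subplots(
                nrow, ncol, figsize=(3 * ncol, 2.2 * nrow), squeeze=False
            )
            for ax in axes.flat:
                ax.set_axis_off()
            for ax, seg in zip(axes.flat, panel):
                bafs = [
                    s.b_tumor / s.d_tumor for s in seg.sites if s.d_tumor > 0
                ]
                ax.set_axis_on()
                ax.hist(bafs, bins=np.linspace(0, 1, 21), color="tab:green")
                ax.set_xlim(0, 1)
                ax.set_title(seg.segment_id, fontsize=8)
            figure.suptitle("tumor BAF by segment")
            written += _save(figure, out_dir, "baf_by_segment")
        else:
            logger.warning("no segment has SNP sites; BAF panel skipped")
    return written
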