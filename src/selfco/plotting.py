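"""Diagnostic plots: per-sample zygosity tracks and cohort summaries."""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .co_caller import COEvent, SampleCallResult, SegState  # noqa: E402
from .summaries import BinProfile, COSummary  # noqa: E402
from .variant_io import ChromTable  # noqa: E402

HET_COLOR = "#2c6fbb"   # heterozygous: blue
HOM_COLOR = "#8c8c8c"   # homozygous: grey


def plot_zygosity_track(result: SampleCallResult, chroms: ChromTable,
                        path: str) -> None:
    """One panel per chromosome: raw calls coloured by observed state, with
    smoothed segment spans overdrawn and called crossovers marked."""
    names = chroms.names
    fig, axes = plt.subplots(len(names), 1, figsize=(10, 1.2 * len(names) + 1),
                             sharex=False, squeeze=False)
    for ax, chrom in zip(axes[:, 0], names):
        res = result.chroms.get(chrom)
        ax.set_ylim(-0.5, 1.5)
        ax.set_yticks([0, 1], ["hom", "het"])
        ax.set_xlim(0, chroms.length(chrom) / 1e6)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
        if res is None:
            continue
        for seg in res.segments:
            if seg.state is SegState.NO_CALL:
                continue
            y = 1 if seg.state is SegState.HET else 0
            color = HET_COLOR if y else HOM_COLOR
            ax.plot([seg.start / 1e6, seg.end / 1e6], [y, y], lw=4,
                    color=color, alpha=0.5, solid_capstyle="butt")
        for e in res.events:
            ax.axvline(e.midpoint / 1e6, color="crimson", lw=0.8, ls="--")
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle(f"{result.sample}: smoothed zygosity and called crossovers")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bin_profile(profiles: Mapping[str, BinProfile], path: str) -> None:
    """Mean crossovers per individual per 2% physical-length bin."""
    fig, ax = plt.subplots(figsize=(8, 4))
    for label, prof in profiles.items():
        mean = prof.mean_per_individual()
        x = (np.arange(prof.n_bins) + 0.5) * 100 / prof.n_bins
        ax.plot(x, mean, marker="o", ms=3, label=label)
    ax.set_xlabel("relative position along chromosome (%)")
    ax.set_ylabel("mean CO per individual per bin")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_summary(summary: COSummary, path: str) -> None:
    """Per-chromosome CO distribution and per-individual totals."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    ks = sorted(summary.distribution)
    ax1.bar(ks, [summary.distribution[k] for k in ks], color=HET_COLOR)
    ax1.set_xlabel("CO per chromosome")
    ax1.set_ylabel("number of chromosomes")
    totals = sorted(summary.per_individual.values())
    ax2.hist(totals, bins=range(0, max(totals) + 2), color=HOM_COLOR,
             edgecolor="white")
    ax2.axvline(summary.mean, color="crimson", ls="--",
                label=f"mean {summary.mean:.2f} ± {summary.sd:.1f}")
    ax2.set_xlabel("CO per individual")
    ax2.set_ylabel("individuals")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
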