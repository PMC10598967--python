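"""Positional nucleotide-composition comparison between positive and
negative window sets (two-sample-logo style): per-cell frequency
differences with two-proportion z-tests and multiple-testing correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .sequence_io import Label, LabeledDataset

__all__ = ["FrequencyTable", "EnrichmentCell", "positional_frequencies",
           "enrichment_table", "plot_enrichment"]

BASES = "ACGU"


@dataclass(frozen=True)
class FrequencyTable:
    values: np.ndarray   # (L, 4), rows sum to 1
    n: int

    @property
    def window_length(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EnrichmentCell:
    position: int        # 0-based window position
    base: str
    difference: float    # pos - neg frequency
    p_value: float
    significant: bool
    informative: bool    # False on the forced-A center row


def positional_frequencies(dataset: LabeledDataset,
                           label: Label | str) -> FrequencyTable:
    label = Label(label)
    seqs = [w.window for w in dataset if w.label == label]
    if not seqs:
        raise ValueError(f"no windows labeled {label.value!r}")
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(-1, L)
    counts = np.zeros((L, 4), dtype=float)
    for b_idx, base in enumerate(BASES):
        counts[:, b_idx] = (arr == ord(base)).sum(axis=0)
    return FrequencyTable(values=counts / len(seqs), n=len(seqs))


def _two_proportion_p(p1, p2, n1, n2):
    """Two-sided two-proportion z-test p-values, elementwise."""
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (p1 - p2) / np.where(se > 0, se, 1.0), 0.0)
    return 2.0 * norm.sf(np.abs(z))


def enrichment_table(pos: FrequencyTable, neg: FrequencyTable,
                     alpha: float = 0.05, correction: str = "bonferroni",
                     center: int | None = None) -> list[EnrichmentCell]:
    """Per-cell difference, p-value and significance flag.

    `center` marks the forced-A row as uninformative; defaults to the middle
    position of an odd-length window.
    """
    if pos.window_length != neg.window_length:
        raise ValueError(
            f"window length mismatch: {pos.window_length} vs {neg.window_length}")
    L = pos.window_length
    if center is None and L % 2 == 1:
        center = L // 2
    diff = pos.values - neg.values
    pvals = _two_proportion_p(pos.values, neg.values, pos.n, neg.n)
    n_cells = L * 4
    if correction == "bonferroni":
        threshold = alpha / n_cells
    elif correction == "none":
        threshold = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    cells = []
    for i in range(L):
        informative = i != center
        for b_idx, base in enumerate(BASES):
            cells.append(EnrichmentCell(
                position=i, base=base,
                difference=float(diff[i, b_idx]),
                p_value=float(pvals[i, b_idx]),
                significant=bool(informative and pvals[i, b_idx] < threshold),
                informative=informative))
    return cells


def plot_enrichment(cells: list[EnrichmentCell], path: str,
                    delta: int | None = None) -> None:
    """Bar chart of per-position frequency differences (logo-style sketch)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    L = max(c.position for c in cells) + 1
    offsets = np.arange(L) - (delta if delta is not None else L // 2)
    fig, ax = plt.subplots(figsize=(max(6, L / 4), 3))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    for base in BASES:
        vals = np.zeros(L)
        for c in cells:
            if c.base == base:
                vals[c.position] = c.difference
        ax.bar(offsets, vals, width=0.2, label=base, color=colors[base],
               align="edge")
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("offset from center")
    ax.set_ylabel("freq(pos) - freq(neg)")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
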