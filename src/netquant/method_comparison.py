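"""Bland-Altman agreement between by-eye and automated NET percentages.

For n paired measurements, the bias is the mean of the per-pair
differences, and the 95% limits of agreement are bias +/- 1.96 times the
sample SD of the differences. The multiplier is fixed at 1.96 (not 2.0).

Differences are oriented method1 - method2. For validating the automated
counter against visual counting, pass the by-eye value first so a
positive bias reads "the automated method undercounts".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientPairsError

LOA_MULTIPLIER = 1.96


@dataclass
class BlandAltmanResult:
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray        # per-pair (m1 + m2) / 2, for plotting
    differences: np.ndarray  # per-pair m1 - m2
    n_dropped: int = 0       # incomplete pairs removed


def loa_from_summary(bias: float, sd_diff: float) -> tuple[float, float]:
    """95% limits of agreement from a (bias, SD of differences) summary."""
    return (bias - LOA_MULTIPLIER * sd_diff, bias + LOA_MULTIPLIER * sd_diff)


def bland_altman(pairs) -> BlandAltmanResult:
    """Bland-Altman statistics for a sequence of (method1, method2) pairs.

    Pairs with a missing value are dropped (their count is recorded on the
    result). Fewer than two complete pairs is an error.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise InsufficientPairsError("Bland-Altman needs >= 2 complete pairs, got 0")
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) pairs, got shape {arr.shape}")
    complete = arr[~np.isnan(arr).any(axis=1)]
    n_dropped = len(arr) - len(complete)
    n = len(complete)
    if n < 2:
        raise InsufficientPairsError(
            f"Bland-Altman needs >= 2 complete pairs, got {n}")
    diffs = complete[:, 0] - complete[:, 1]
    means = complete.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    low, high = loa_from_summary(bias, sd)
    return BlandAltmanResult(n=n, bias=bias, sd_diff=sd, loa_low=low,
                             loa_high=high, means=means, differences=diffs,
                             n_dropped=n_dropped)


def bland_altman_plot(
    result: BlandAltmanResult,
    out_path,
    method1: str = "by eye",
    method2: str = "automated",
):
    """Scatter of per-pair mean vs difference with bias and limit lines.

    Returns the matplotlib figure after saving it to ``out_path``.
    """
    if result.n < 2:
        raise InsufficientPairsError("cannot plot fewer than 2 pairs")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.differences, color="#1f77b4", zorder=3)
    ax.axhline(result.bias, color="black", label=f"bias = {result.bias:.2f}")
    for value, style in ((result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(value, color="gray", linestyle=style)
    ax.set_xlabel(f"mean of {method1} and {method2} NET%")
    ax.set_ylabel(f"{method1} - {method2} NET%")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return fig
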