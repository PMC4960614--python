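"""Binned-means figure summarization: fitted lines at +/-1 score SD and
per-score-sign binned means across birth-year rank bins."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .trend import TrendFit

__all__ = ["BinnedSummary", "binned_means", "fitted_lines", "plot_figure"]


@dataclasses.dataclass
class BinnedSummary:
    """One score-sign group's binned (mean birth year, mean response)."""

    label: str
    mean_birth_year: np.ndarray
    mean_response: np.ndarray
    bin_sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.label,
                "bin": np.arange(len(self.bin_sizes)),
                "mean_birth_year": self.mean_birth_year,
                "mean_response": self.mean_response,
                "n": self.bin_sizes,
            }
        )


def _group_bins(
    birth_year: np.ndarray, response: np.ndarray, n_bins: int, label: str
) -> BinnedSummary:
    # contiguous rank blocks, remainder spread over the earliest bins;
    # birth-year ties broken by response so output is row-order invariant
    order = np.lexsort((response, birth_year))
    blocks = np.array_split(order, n_bins)
    return BinnedSummary(
        label=label,
        mean_birth_year=np.array([birth_year[b].mean() for b in blocks]),
        mean_response=np.array([response[b].mean() for b in blocks]),
        bin_sizes=np.array([len(b) for b in blocks]),
    )


def binned_means(
    score: np.ndarray,
    birth_year: np.ndarray,
    response: np.ndarray,
    n_bins: int = 20,
) -> tuple[BinnedSummary, BinnedSummary]:
    """Split at score 0 (exact zeros go to the below group) and, within each
    group, cut birth years into ``n_bins`` near-equal rank blocks."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    score = np.asarray(score, dtype=float)
    birth_year = np.asarray(birth_year, dtype=float)
    response = np.asarray(response, dtype=float)
    keep = np.isfinite(score) & np.isfinite(birth_year) & np.isfinite(response)
    score, birth_year, response = score[keep], birth_year[keep], response[keep]
    below = score <= 0.0
    for mask, label in ((below, "below"), (~below, "above")):
        if mask.sum() < n_bins:
            raise ValueError(
                f"group {label!r} has {int(mask.sum())} observations, "
                f"fewer than n_bins={n_bins}"
            )
    return (
        _group_bins(birth_year[below], response[below], n_bins, "below"),
        _group_bins(birth_year[~below], response[~below], n_bins, "above"),
    )


def fitted_lines(
    fit: TrendFit, birth_year_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted response at standardized score -1 and +1 over the grid.

    The vertical gap at centered year c is exactly
    ``2 * (b_pgs + b_interaction * c)``.
    """
    grid = np.asarray(birth_year_grid, dtype=float)
    minus = fit.predict(np.full_like(grid, -1.0), grid)
    plus = fit.predict(np.full_like(grid, 1.0), grid)
    return minus, plus


def plot_figure(
    fit: TrendFit,
    score: np.ndarray,
    birth_year: np.ndarray,
    response: np.ndarray,
    out_path: str,
    n_bins: int = 20,
    title: str | None = None,
) -> tuple[BinnedSummary, BinnedSummary]:
    """Render the two-line / two-point-cloud summary to ``out_path`` and
    return the binned summaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    below, above = binned_means(score, birth_year, response, n_bins)
    grid = np.linspace(np.min(birth_year), np.max(birth_year), 100)
    minus, plus = fitted_lines(fit, grid)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(grid, minus, color="black", label="fitted, score = -1 SD")
    ax.plot(grid, plus, color="gray", label="fitted, score = +1 SD")
    ax.scatter(
        below.mean_birth_year, below.mean_response, color="black", s=14,
        label="binned means, score < 0",
    )
    ax.scatter(
        above.mean_birth_year, above.mean_response, color="dimgray", s=14,
        marker="s", label="binned means, score > 0",
    )
    ax.set_xlabel("birth year")
    ax.set_ylabel("response")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return below, above
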