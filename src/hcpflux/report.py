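"""Summary matrices and distributions: row z-scores, ratio histograms, heatmaps.

The visual summaries of a clearance experiment are driven by two small
transforms: a per-row z-score (center each protein's profile, scale to unit
standard deviation) for heatmap display, and a fixed-width histogram of
protein ratios. Both are emitted as data tables; image rendering is an
optional layer on top so that tests and downstream tooling assert on numbers,
not pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ChannelDesign
from .quant import ProteinQuant, quants_to_frame

__all__ = ["row_zscore", "ratio_histogram", "RatioHistogram", "heatmap_matrix"]


def row_zscore(m: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-score: subtract the row mean, divide by the row sd (n-1).

    Constant rows have no scale and map to all-zero rows (with a warning).

    Raises
    ------
    ValueError
        If the matrix has fewer than two columns (a single column admits no
        row scale).
    """
    if m.shape[1] < 2:
        raise ValueError("row z-score needs at least 2 columns")
    values = m.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant row(s) mapped to zeros", stacklevel=2)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=m.index, columns=m.columns)


@dataclass(frozen=True)
class RatioHistogram:
    """Fixed-width histogram of ratios; infinities are tallied separately."""

    bins: tuple[tuple[float, int], ...]  # (bin_start, count), half-open [start, start+width)
    bin_width: float
    n_infinite: int

    @property
    def total_finite(self) -> int:
        return sum(c for _, c in self.bins)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["bin_start", "count"])


def ratio_histogram(ratios: Sequence[float], bin_width: float = 0.2) -> RatioHistogram:
    """Bin ratios into half-open intervals ``[i*w, (i+1)*w)`` anchored at 0.

    Counts over the contiguous bin range covering the finite data sum to the
    number of finite inputs; infinite ratios are counted separately; NaNs are
    ignored.
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(list(ratios), dtype=float)
    n_inf = int(np.isinf(arr).sum())
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        return RatioHistogram(bins=(), bin_width=bin_width, n_infinite=n_inf)
    idx = np.floor(finite / bin_width).astype(int)
    lo, hi = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    bins = tuple((float(i * bin_width), int(c)) for i, c in zip(range(lo, hi + 1), counts))
    return RatioHistogram(bins=bins, bin_width=bin_width, n_infinite=n_inf)


def heatmap_matrix(
    quants: Sequence[ProteinQuant],
    design: ChannelDesign,
    cluster: bool = False,
) -> pd.DataFrame:
    """Row z-scored log2 protein-ratio matrix for heatmap display.

    Rows are quantifiable proteins (product chains included); columns the
    sample labels. Values are log2 of the per-label protein ratio, then
    row z-scored, so red/green symmetry of a heatmap corresponds to
    symmetric fold changes. Proteins with any non-positive or undefined
    ratio carry no complete log profile and are dropped. Default row order
    is descending total signal; ``cluster=True`` orders rows by hierarchical
    clustering (correlation distance, average linkage), deterministic for a
    fixed input order.
    """
    usable = [q for q in quants if q.quantifiable]
    ratios = quants_to_frame(usable, "ratio") if usable else pd.DataFrame()
    if ratios.empty:
        return pd.DataFrame(columns=list(design.sample_labels))
    ratios = ratios[list(design.sample_labels)]
    complete = ratios.gt(0).all(axis=1) & ratios.notna().all(axis=1)
    ratios = ratios.loc[complete]
    if ratios.empty:
        return pd.DataFrame(columns=list(design.sample_labels))
    totals = {q.accession: sum(q.signal.values()) for q in usable}
    ratios = ratios.loc[sorted(ratios.index, key=lambda a: (-totals[a], a))]
    z = row_zscore(np.log2(ratios))
    if cluster and len(z) > 2:
        from scipy.cluster.hierarchy import average, leaves_list
        from scipy.spatial.distance import pdist

        with np.errstate(invalid="ignore"):
            dist = pdist(z.to_numpy(), metric="correlation")
        dist = np.nan_to_num(dist, nan=1.0)
        order = leaves_list(average(dist))
        z = z.iloc[order]
    return z


def render_heatmap(z: pd.DataFrame, path) -> None:
    """Optional image rendering of a z-score matrix (green-black-red)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, z.shape[1]), max(4, min(12, z.shape[0] / 10))))
    lim = float(np.nanmax(np.abs(z.to_numpy()))) if z.size else 1.0
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-lim, vmax=lim)
    ax.set_xticks(range(z.shape[1]), labels=list(z.columns), rotation=90)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row z-score of log2 ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
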