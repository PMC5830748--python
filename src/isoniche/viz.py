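"""Optional plots: isotope bi-plot with standard ellipses and SEA_B
posterior density strips.  Numeric exports, not figures, are the
pipeline's contract; these are convenience views."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from isoniche.niche import PosteriorSeaDraws  # noqa: E402


def _ellipse_path(xy: np.ndarray, n: int = 200) -> np.ndarray:
    """Boundary of the standard ellipse (semi-axes = sqrt eigenvalues)."""
    mean = xy.mean(axis=0)
    cov = np.cov(xy, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    t = np.linspace(0, 2 * np.pi, n)
    circle = np.stack([np.cos(t), np.sin(t)])
    return (vecs @ (np.sqrt(np.clip(vals, 0, None))[:, None] * circle)).T + mean


def biplot(prepared: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, sub in prepared.groupby("treatment", sort=False):
        xy = sub[["d13c_corr", "d15n"]].to_numpy(float)
        pts = ax.scatter(xy[:, 0], xy[:, 1], s=12, alpha=0.6, label=label)
        if len(xy) >= 3:
            ell = _ellipse_path(xy)
            ax.plot(ell[:, 0], ell[:, 1], color=pts.get_facecolor()[0], lw=1.2)
    ax.set_xlabel(r"$\delta^{13}$C (‰)")
    ax.set_ylabel(r"$\delta^{15}$N (‰)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def sea_density_plot(posteriors: Sequence[PosteriorSeaDraws], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for i, p in enumerate(posteriors):
        for level, width in zip((95, 75, 50), (0.2, 0.45, 0.7)):
            lo, hi = p.intervals[level]
            ax.fill_between([i - width / 2, i + width / 2], lo, hi, color="C0",
                            alpha=0.35)
        ax.plot(i, p.mean, "ko", ms=4)
    ax.set_xticks(range(len(posteriors)))
    ax.set_xticklabels([p.label for p in posteriors], rotation=30, ha="right",
                       fontsize=8)
    ax.set_ylabel(r"SEA$_B$ (‰$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
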