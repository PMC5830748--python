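"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the hull oracle tests
every point pair for edge extremality instead of calling a hull library;
the Levene oracle is the one-way-ANOVA-on-absolute-deviations closed form;
the AUC oracle is the rank-based normalised Mann-Whitney U.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import rankdata


def hull_area_bruteforce(xy: np.ndarray) -> float:
    """Convex hull area via pairwise extremality testing + shoelace.

    A directed edge i->j is on the hull iff every other point lies
    (weakly) to its left.  Assumes points in general position (random
    floats); collinear/degenerate inputs return 0.
    """
    xy = np.asarray(xy, float)
    n = len(xy)
    if n < 3:
        return 0.0
    verts: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = xy[j] - xy[i]
            rel = xy - xy[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            mask = np.ones(n, bool)
            mask[[i, j]] = False
            if np.all(cross[mask] >= -1e-12):
                verts.update((i, j))
    if len(verts) < 3:
        return 0.0
    pts = xy[sorted(verts)]
    centre = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0]))
    p = pts[order]
    x, y = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def levene_anova_oracle(groups: list[np.ndarray], center: str = "mean"):
    """Levene W as a one-way ANOVA F on |deviations from the group centre|."""
    centre = np.mean if center == "mean" else np.median
    z = [np.abs(np.asarray(g, float) - centre(g)) for g in groups]
    k = len(z)
    n_i = np.array([len(g) for g in z])
    n = n_i.sum()
    zbar_i = np.array([g.mean() for g in z])
    zbar = np.concatenate(z).mean()
    ss_between = np.sum(n_i * (zbar_i - zbar) ** 2)
    ss_within = sum(((g - gb) ** 2).sum() for g, gb in zip(z, zbar_i))
    w = ((n - k) / (k - 1)) * ss_between / ss_within
    p = f_dist.sf(w, k - 1, n - k)
    return float(w), float(p)


def auc_mannwhitney_oracle(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U of scores between classes."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    ranks = rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u1 = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n1 * n0))
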