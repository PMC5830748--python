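"""Bivariate isotopic-niche metrics.

For one group of (d13C, d15N) points this module computes

* the six Layman metrics — NR (d15N range), CR (d13C range), TA (convex
  hull area), CD (mean distance to centroid), MNND and SDNND (mean and sd
  of nearest-neighbour distances);
* the standard ellipse area SEA = pi * sqrt(det(S)) with S the sample
  covariance (equivalently pi * sqrt(lambda1 * lambda2) over its
  eigenvalues; the ellipse semi-axes are the square roots of the
  eigenvalues, no chi-square scaling) and its small-sample correction
  SEAc = SEA * (n - 1) / (n - 2);
* bootstrap comparisons of groups with unequal sizes, resampling every
  group at the minimum group size;
* Bayesian posterior draws of the ellipse area (SEA_B) from a conjugate
  Normal-Inverse-Wishart model, with pairwise exceedance probabilities
  between groups.

Areas are permil squared; distances are permil.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from scipy.stats import invwishart

LAYMAN_NAMES = ("NR", "CR", "TA", "CD", "MNND", "SDNND")
INTERVAL_LEVELS = (50, 75, 95)


@dataclass
class NicheMetrics:
    """Niche metrics for one group of bivariate points."""

    n: int
    nr: float
    cr: float
    ta: float
    cd: float
    mnnd: float
    sdnnd: float
    sea: float = float("nan")
    seac: float = float("nan")
    degenerate_hull: bool = False
    degenerate_ellipse: bool = False

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "NR": self.nr,
            "CR": self.cr,
            "TA": self.ta,
            "CD": self.cd,
            "MNND": self.mnnd,
            "SDNND": self.sdnnd,
            "SEA": self.sea,
            "SEAc": self.seac,
        }


@dataclass
class BootstrapSummary:
    """Resampled draws of one metric for one group, with nested intervals."""

    metric: str
    resample_n: int
    reps: int
    draws: np.ndarray
    mean: float
    intervals: dict[int, tuple[float, float]]


@dataclass
class PosteriorSeaDraws:
    """Posterior samples of the population standard ellipse area (SEA_B)."""

    label: str
    draws: np.ndarray
    mean: float
    intervals: dict[int, tuple[float, float]]

    @property
    def n_draws(self) -> int:
        return len(self.draws)


@dataclass
class SeaComparison:
    """P(SEA_B of group a exceeds group b) and a two-sided call at `level`."""

    label_a: str
    label_b: str
    p_exceed: float
    level: float = 0.95
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        tail = (1.0 - self.level) / 2.0
        self.significant = self.p_exceed >= 1.0 - tail or self.p_exceed <= tail


@dataclass(frozen=True)
class NiwPrior:
    """Vague conjugate Normal-Inverse-Wishart prior for a 2x2 covariance.

    nu0 = 3 (= dimension + 1) is the smallest proper degrees of freedom;
    the scale matrix is eps * I with small eps; the mean prior is centred
    on the sample mean (mu0=None) with weak precision kappa0, so the
    posterior is dominated by the data scatter.
    """

    nu0: float = 3.0
    scale_eps: float = 1e-3
    kappa0: float = 1e-3
    mu0: tuple[float, float] | None = None


def _as_points(points) -> np.ndarray:
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13c, d15n)")
    if not np.all(np.isfinite(xy)):
        raise ValueError("points contain non-finite values")
    return xy


def hull_area(points) -> tuple[float, bool]:
    """Convex hull area of 2-D points; (0.0, True) when degenerate."""
    xy = _as_points(points)
    if len(np.unique(xy, axis=0)) < 3:
        return 0.0, True
    try:
        hull = ConvexHull(xy)
    except QhullError:  # collinear or otherwise flat
        return 0.0, True
    return float(hull.volume), False  # .volume is the area in 2-D


def layman_metrics(points) -> NicheMetrics:
    """The six Layman metrics for one group (n >= 2).

    TA needs n >= 3 non-collinear points and is reported as 0 with the
    degenerate flag otherwise.
    """
    xy = _as_points(points)
    n = len(xy)
    if n < 2:
        raise ValueError("layman_metrics requires at least 2 points")
    nr = float(xy[:, 1].max() - xy[:, 1].min())
    cr = float(xy[:, 0].max() - xy[:, 0].min())
    ta, degenerate = hull_area(xy)
    centroid = xy.mean(axis=0)
    cd = float(np.hypot(*(xy - centroid).T).mean())
    dist = squareform(pdist(xy))
    np.fill_diagonal(dist, np.inf)
    nnd = dist.min(axis=1)
    mnnd = float(nnd.mean())
    sdnnd = float(nnd.std(ddof=1)) if n > 1 else 0.0
    return NicheMetrics(
        n=n, nr=nr, cr=cr, ta=ta, cd=cd, mnnd=mnnd, sdnnd=sdnnd,
        degenerate_hull=degenerate,
    )


def standard_ellipse(points) -> tuple[float, float]:
    """(SEA, SEAc) of one group; (0, 0) with no error when singular.

    SEA = pi * sqrt(det(S)), S the sample covariance (denominator n - 1);
    SEAc = SEA * (n - 1) / (n - 2).
    """
    xy = _as_points(points)
    n = len(xy)
    if n < 3:
        raise ValueError("standard_ellipse requires at least 3 points")
    s = np.cov(xy, rowvar=False, ddof=1)
    det = float(np.linalg.det(s))
    if det <= 0:
        return 0.0, 0.0
    sea = float(np.pi * np.sqrt(det))
    return sea, sea * (n - 1) / (n - 2)


def niche_metrics(points) -> NicheMetrics:
    """Layman metrics plus SEA/SEAc in one :class:`NicheMetrics`."""
    m = layman_metrics(points)
    if m.n >= 3:
        m.sea, m.seac = standard_ellipse(points)
        m.degenerate_ellipse = m.sea == 0.0
    else:
        m.degenerate_ellipse = True
    return m


def _percentile_intervals(draws: np.ndarray) -> dict[int, tuple[float, float]]:
    out = {}
    for level in INTERVAL_LEVELS:
        tail = (100 - level) / 2
        lo, hi = np.percentile(draws, [tail, 100 - tail])
        out[level] = (float(lo), float(hi))
    return out


def _hdr_intervals(draws: np.ndarray) -> dict[int, tuple[float, float]]:
    """Shortest (highest-density) interval per level; optional alternative."""
    x = np.sort(draws)
    n = len(x)
    out = {}
    for level in INTERVAL_LEVELS:
        k = max(1, int(np.ceil(level / 100 * n)))
        widths = x[k - 1:] - x[: n - k + 1]
        i = int(np.argmin(widths))
        out[level] = (float(x[i]), float(x[i + k - 1]))
    return out


def bootstrap_metrics(
    groups: Mapping[str, np.ndarray],
    reps: int = 2000,
    resample_n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> dict[str, dict[str, BootstrapSummary]]:
    """Bootstrap the Layman metrics across groups of unequal size.

    Every group is resampled with replacement at ``resample_n`` points per
    replicate (default: the minimum group size across ``groups``), so that
    group summaries are comparable despite unequal n.  Percentile
    intervals at 50/75/95% are nested by construction.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    arrays = {label: _as_points(p) for label, p in groups.items()}
    if not arrays:
        raise ValueError("no groups supplied")
    if resample_n is None:
        resample_n = min(len(p) for p in arrays.values())
    if resample_n < 3:
        raise ValueError("resample_n must be >= 3 to compute hull metrics")
    rng = np.random.default_rng(rng)
    out: dict[str, dict[str, BootstrapSummary]] = {}
    for label, xy in arrays.items():
        draws = np.empty((reps, len(LAYMAN_NAMES)))
        for r in range(reps):
            idx = rng.integers(0, len(xy), size=resample_n)
            m = layman_metrics(xy[idx])
            draws[r] = (m.nr, m.cr, m.ta, m.cd, m.mnnd, m.sdnnd)
        out[label] = {
            name: BootstrapSummary(
                metric=name,
                resample_n=resample_n,
                reps=reps,
                draws=draws[:, j].copy(),
                mean=float(draws[:, j].mean()),
                intervals=_percentile_intervals(draws[:, j]),
            )
            for j, name in enumerate(LAYMAN_NAMES)
        }
    return out


def bayesian_sea(
    points,
    n_draws: int = 10_000,
    prior: NiwPrior | None = None,
    rng: np.random.Generator | int | None = None,
    label: str = "",
    hdr: bool = False,
) -> PosteriorSeaDraws:
    """Posterior draws of the population standard ellipse area (SEA_B).

    The population covariance Sigma gets a conjugate Normal-Inverse-Wishart
    prior (see :class:`NiwPrior`); the posterior over Sigma is then
    Inverse-Wishart with

        nu_n     = nu0 + n
        Lambda_n = Lambda0 + scatter + kappa0*n/(kappa0+n) * d d'

    where ``scatter`` is the centred sum of squares and d = xbar - mu0
    (zero under the default data-centred mean prior).  Each draw maps to an
    area SEA_B = pi * sqrt(det(Sigma)).  As n grows the posterior mean
    approaches SEAc.
    """
    xy = _as_points(points)
    n = len(xy)
    if n < 3:
        raise ValueError("bayesian_sea requires at least 3 points")
    prior = prior or NiwPrior()
    rng = np.random.default_rng(rng)
    xbar = xy.mean(axis=0)
    centred = xy - xbar
    scatter = centred.T @ centred
    mu0 = xbar if prior.mu0 is None else np.asarray(prior.mu0, float)
    d = (xbar - mu0)[:, None]
    lambda_n = (
        prior.scale_eps * np.eye(2)
        + scatter
        + (prior.kappa0 * n / (prior.kappa0 + n)) * (d @ d.T)
    )
    nu_n = prior.nu0 + n
    sigma = invwishart.rvs(df=nu_n, scale=lambda_n, size=n_draws, random_state=rng)
    dets = np.linalg.det(sigma)
    draws = np.pi * np.sqrt(dets)
    intervals = _hdr_intervals(draws) if hdr else _percentile_intervals(draws)
    return PosteriorSeaDraws(
        label=label,
        draws=draws,
        mean=float(draws.mean()),
        intervals=intervals,
    )


def compare_sea(
    a: PosteriorSeaDraws, b: PosteriorSeaDraws, level: float = 0.95
) -> SeaComparison:
    """Fraction of paired posterior draws with a's SEA_B above b's.

    Draw sets of unequal length are cycled; exact ties split evenly, so
    P(a>b) + P(b>a) = 1.  The significance call is two-sided at ``level``:
    the groups are flagged different when P(a>b) falls outside the central
    ``level`` probability band.
    """
    da, db = np.asarray(a.draws, float), np.asarray(b.draws, float)
    if da.size == 0 or db.size == 0:
        raise ValueError("empty posterior draw set")
    m = max(da.size, db.size)
    da, db = np.resize(da, m), np.resize(db, m)
    p = float(np.mean(da > db) + 0.5 * np.mean(da == db))
    return SeaComparison(label_a=a.label, label_b=b.label, p_exceed=p, level=level)


def pairwise_sea(
    posteriors: Sequence[PosteriorSeaDraws], level: float = 0.95
) -> list[SeaComparison]:
    """All ordered-pair comparisons among a set of group posteriors."""
    out = []
    for i, a in enumerate(posteriors):
        for b in posteriors[i + 1:]:
            out.append(compare_sea(a, b, level=level))
    return out
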