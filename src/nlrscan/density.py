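"""Gene/repeat density landscape and its two-component Gaussian mixture.

Densities are computed in a fixed window (default 250 kb) centred on each
gene's midpoint, restricted to the gene's parent superscaffold: genes whose
window would extend beyond the scaffold are omitted (spacer regions between
placed scaffolds do not reflect real separation).  Gene density counts gene
midpoints in the window per Mb; repeat density is the fraction of the window
covered by the union of repeat intervals.  The genome-wide landscape is
binned into a 200 x 200 2-D histogram and a two-component Gaussian mixture
is fitted to the binned frequencies; NB-LRRs whose mixture density falls
below the contour enclosing a target probability mass are flagged as lying
outside the bulk distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.mixture import GaussianMixture


@dataclass
class DensityPoint:
    gene_id: str
    gene_density: float  # genes per Mb
    repeat_density: float  # covered fraction of the window, in [0, 1]
    window: int


def union_coverage(intervals: list[tuple[int, int]], lo: int, hi: int) -> int:
    """Total bases of [lo, hi) covered by the union of the intervals."""
    clipped = sorted((max(s, lo), min(e, hi)) for s, e in intervals
                     if s < hi and e > lo)
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def densities(
    gene_mid: int,
    scaffold_length: int,
    gene_midpoints: np.ndarray,
    repeats: list[tuple[int, int]],
    window: int = 250_000,
    repeat_measure: str = "coverage",
) -> tuple[float, float] | None:
    """Window densities for one gene, or None when the window leaves the scaffold.

    ``repeat_measure`` selects the repeat statistic: "coverage" (fraction of
    the window covered by the union of repeat intervals, the default) or
    "count" (number of overlapping repeat features per Mb).
    """
    half = window // 2
    lo, hi = gene_mid - half, gene_mid + half
    if lo < 0 or hi > scaffold_length:
        return None
    count = int(np.searchsorted(gene_midpoints, hi)
                - np.searchsorted(gene_midpoints, lo))
    gene_density = count / (window / 1e6)
    if repeat_measure == "coverage":
        repeat_density = union_coverage(repeats, lo, hi) / window
    elif repeat_measure == "count":
        n = sum(1 for s, e in repeats if s < hi and e > lo)
        repeat_density = n / (window / 1e6)
    else:
        raise ValueError(f"unknown repeat_measure {repeat_measure!r}")
    return gene_density, repeat_density


def density_table(
    genes: dict,  # gene_id -> GeneModel
    repeats: dict[str, list[tuple[int, int]]],
    scaffold_lengths: dict[str, int],
    window: int = 250_000,
    repeat_measure: str = "coverage",
) -> pd.DataFrame:
    """Per-gene density table with an ``omitted`` flag."""
    mids_by_scaffold: dict[str, np.ndarray] = {}
    for g in genes.values():
        mids_by_scaffold.setdefault(g.scaffold_id, [])
        mids_by_scaffold[g.scaffold_id].append((g.start + g.end) // 2)
    mids_by_scaffold = {k: np.sort(np.array(v))
                        for k, v in mids_by_scaffold.items()}
    rows = []
    for gid in sorted(genes):
        g = genes[gid]
        mid = (g.start + g.end) // 2
        res = densities(mid, scaffold_lengths[g.scaffold_id],
                        mids_by_scaffold[g.scaffold_id],
                        repeats.get(g.scaffold_id, []), window,
                        repeat_measure)
        rows.append({
            "gene_id": gid, "window": window,
            "gene_density": res[0] if res else np.nan,
            "repeat_density": res[1] if res else np.nan,
            "omitted": res is None,
        })
    return pd.DataFrame(rows)


@dataclass
class Histogram2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def histogram2d(points: np.ndarray, bins: int = 200) -> Histogram2D:
    """2-D histogram of (gene density, repeat density) points."""
    counts, xe, ye = np.histogram2d(points[:, 0], points[:, 1], bins=bins)
    return Histogram2D(x_edges=xe, y_edges=ye, counts=counts)


@dataclass
class GmmModel:
    weights: np.ndarray  # (k,) positive, sums to 1
    means: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2) symmetric positive-definite
    log_likelihood: float = float("nan")

    def pdf(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        out = np.zeros(len(pts))
        for w, mu, cov in zip(self.weights, self.means, self.covariances):
            out += w * multivariate_normal.pdf(pts, mean=mu, cov=cov)
        return out

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        out = np.empty((n, 2))
        for k in range(len(self.weights)):
            mask = comp == k
            if mask.any():
                out[mask] = rng.multivariate_normal(
                    self.means[k], self.covariances[k], size=int(mask.sum()))
        return out


def fit_gmm(
    hist: Histogram2D,
    components: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> GmmModel:
    """Fit a Gaussian mixture to binned frequencies by EM.

    Observations are the bin centres weighted by their counts (realised by
    count-repetition); the best of ``n_init`` seeded restarts by
    log-likelihood is returned.  Deterministic given the seed.
    """
    nonempty = int((hist.counts > 0).sum())
    if nonempty < 2:
        raise ValueError(
            f"only {nonempty} non-empty bins; too degenerate for a "
            f"{components}-component mixture — use fewer components")
    xc = 0.5 * (hist.x_edges[:-1] + hist.x_edges[1:])
    yc = 0.5 * (hist.y_edges[:-1] + hist.y_edges[1:])
    ix, iy = np.nonzero(hist.counts)
    reps = hist.counts[ix, iy].astype(int)
    pts = np.repeat(np.column_stack([xc[ix], yc[iy]]), reps, axis=0)
    gm = GaussianMixture(
        n_components=components, covariance_type="full",
        n_init=n_init, tol=1e-6, max_iter=500, reg_covar=1e-9,
        random_state=int(seed) % (2**32),
    ).fit(pts)
    return GmmModel(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        covariances=gm.covariances_.copy(),
        log_likelihood=float(gm.score(pts) * len(pts)),
    )


def density_threshold(model: GmmModel, mass_level: float, seed: int = 0,
                      n_mc: int = 100_000) -> float:
    """Mixture-density value whose superlevel set encloses ``mass_level`` mass.

    Monte-Carlo quantile of the mixture density under the model (seeded).
    """
    rng = np.random.default_rng(seed)
    draws = model.sample(n_mc, rng)
    dens = model.pdf(draws)
    return float(np.quantile(dens, 1.0 - mass_level))


def flag_outliers(
    points: pd.DataFrame,  # columns gene_id, gene_density, repeat_density
    model: GmmModel,
    mass_level: float = 0.99,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag points whose mixture density falls below the mass-level contour.

    Returns the input with ``mixture_density``, ``outlier`` and
    ``repeat_rich_side`` columns.  mass_level >= 1 flags nothing by
    convention.
    """
    pts = points[["gene_density", "repeat_density"]].to_numpy(float)
    dens = model.pdf(pts)
    if mass_level >= 1.0:
        outlier = np.zeros(len(pts), dtype=bool)
    else:
        thr = density_threshold(model, mass_level, seed)
        outlier = dens < thr
    mean_repeat = float(np.dot(model.weights, model.means[:, 1]))
    out = points.copy()
    out["mixture_density"] = dens
    out["outlier"] = outlier
    out["repeat_rich_side"] = pts[:, 1] > mean_repeat
    return out
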