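"""Sammon projection, maximum-variance axes, and the Texture Index.

The Sammon mapping embeds a pairwise distance matrix into 2D by minimizing

    E = (1 / sum_{i<j} D_ij) * sum_{i<j} (D_ij - d_ij)^2 / D_ij

which, unlike classical MDS, weights small distances up — local structure is
preserved preferentially.  The optimizer is gradient descent with step
halving from a classical-MDS initialization, so the recorded stress sequence
is non-increasing by construction.

The Texture Index (TI) of a query group relative to a reference group is the
displacement of the query's center of gravity along the maximum-variance
axis (MVP) of the pooled embedded cloud.  Tracked over a timecourse it
summarizes progressive texture change as a single signed scalar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sstats

from .types import ValidationError

__all__ = [
    "SammonEmbedding",
    "TextureIndexSeries",
    "sammon_project",
    "texture_index",
    "cog_with_ci",
    "timecourse_texture_index",
]

EPS_DIST = 1e-12


@dataclass
class SammonEmbedding:
    points: np.ndarray  # (n, 2)
    stress: float
    stress_history: List[float]
    mvp_axis: np.ndarray  # unit 2-vector, maximum-variance direction
    svp_axis: np.ndarray
    iterations_run: int

    def coords_mvp(self) -> np.ndarray:
        c = self.points - self.points.mean(axis=0)
        return c @ self.mvp_axis

    def coords_svp(self) -> np.ndarray:
        c = self.points - self.points.mean(axis=0)
        return c @ self.svp_axis


@dataclass
class TextureIndexSeries:
    timepoints: List[float]
    ti: List[float]
    ci_halfwidth: List[float]
    reference_class: str
    p_values: List[float] = field(default_factory=list)  # Welch t vs reference


def _stress(D: np.ndarray, d: np.ndarray, iu: Tuple[np.ndarray, np.ndarray], c: float) -> float:
    diff = D[iu] - d[iu]
    return float(np.sum(diff * diff / np.maximum(D[iu], EPS_DIST)) / c)


def _classical_mds_init(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:ndim]
    w_top = np.maximum(w[order], 0.0)
    return V[:, order] * np.sqrt(w_top)[None, :]


def sammon_project(
    D: np.ndarray,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
    init: Optional[np.ndarray] = None,
) -> SammonEmbedding:
    """Embed a symmetric distance matrix into 2D by Sammon stress descent."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("D must be symmetric")
    if np.any(D < 0) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValidationError("D must be nonnegative with a zero diagonal")
    D = np.maximum(D, 0.0)
    iu = np.triu_indices(n, 1)
    Dsafe = np.maximum(D, EPS_DIST)
    c = float(np.sum(Dsafe[iu]))
    if init is None:
        Y = _classical_mds_init(D)
        if not np.isfinite(Y).all() or np.allclose(Y, 0):
            rng = np.random.default_rng(seed)
            Y = rng.standard_normal((n, 2)) * max(D.max(), 1.0) / np.sqrt(n)
    else:
        Y = np.array(init, dtype=float)
        if Y.shape != (n, 2):
            raise ValidationError("init must have shape (n, 2)")

    def pair_d(Y: np.ndarray) -> np.ndarray:
        diff = Y[:, None, :] - Y[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    d = pair_d(Y)
    history = [_stress(D, d, iu, c)]
    step = 0.3
    it = 0
    for it in range(1, max_iter + 1):
        dd = np.maximum(d, EPS_DIST)
        # gradient of the Sammon stress wrt Y
        W = np.zeros_like(D)
        off = ~np.eye(n, dtype=bool)
        W[off] = (D[off] - d[off]) / (Dsafe[off] * dd[off])
        diff = Y[:, None, :] - Y[None, :, :]
        grad = (-2.0 / c) * (W[:, :, None] * diff).sum(axis=1)
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-15:
            break
        improved = False
        cur = history[-1]
        for _ in range(30):  # step halving
            Ynew = Y - step * grad
            dnew = pair_d(Ynew)
            snew = _stress(D, dnew, iu, c)
            if snew < cur:
                Y, d = Ynew, dnew
                history.append(snew)
                improved = True
                step *= 1.3  # gentle growth after success
                break
            step *= 0.5
        if not improved or cur - history[-1] < tol * max(cur, 1e-30):
            break
    pts = Y - Y.mean(axis=0)
    C = np.cov(pts.T) if n > 1 else np.eye(2)
    w, V = np.linalg.eigh(np.atleast_2d(C))
    order = np.argsort(w)[::-1]
    mvp, svp = V[:, order[0]], V[:, order[1]]
    return SammonEmbedding(
        points=Y,
        stress=history[-1],
        stress_history=history,
        mvp_axis=mvp,
        svp_axis=svp,
        iterations_run=it,
    )


def texture_index(
    embedding: SammonEmbedding,
    reference_rows: Sequence[int],
    query_rows: Sequence[int],
    orientation: float = 1.0,
) -> float:
    """Displacement of the query COG from the reference COG along the MVP axis.

    ``orientation`` (+1/-1) fixes the sign convention; callers orient it so
    the final-timepoint class scores nonnegative.
    """
    reference_rows = np.asarray(reference_rows, dtype=int)
    query_rows = np.asarray(query_rows, dtype=int)
    if reference_rows.size == 0 or query_rows.size == 0:
        raise ValidationError("row sets must be nonempty")
    mvp = embedding.coords_mvp()
    return float(orientation * (mvp[query_rows].mean() - mvp[reference_rows].mean()))


def cog_with_ci(distances: Sequence[float], level: float = 0.95) -> Tuple[float, float]:
    """Center of gravity with a normal-theory confidence half-width.

    Returns (mean, Z * s / sqrt(N)) with Z the standard-normal upper critical
    value at the given level (1.96 at 95%) and s the sample standard
    deviation (N-1 denominator).
    """
    x = np.asarray(distances, dtype=float)
    if x.size < 2:
        raise ValidationError("need at least 2 points for a confidence interval")
    z = float(sstats.norm.ppf(0.5 + level / 2.0))
    s = float(np.std(x, ddof=1))
    return float(x.mean()), z * s / np.sqrt(x.size)


def timecourse_texture_index(
    D: np.ndarray,
    timepoints: Sequence[float],
    reference_timepoint: Optional[float] = None,
    seed: int = 0,
    level: float = 0.95,
) -> Tuple[TextureIndexSeries, SammonEmbedding]:
    """Embed all rows jointly, then track TI per timepoint vs the reference.

    The reference defaults to the earliest timepoint.  The TI sign is
    oriented so the final timepoint is nonnegative.  Per-timepoint confidence
    half-widths come from the normal-theory interval on per-image MVP
    coordinates; p-values are Welch two-sample t-tests of each timepoint's
    MVP coordinates against the reference's.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    emb = sammon_project(D, seed=seed)
    tps = sorted(set(timepoints.tolist()))
    ref_tp = tps[0] if reference_timepoint is None else float(reference_timepoint)
    ref_rows = np.flatnonzero(timepoints == ref_tp)
    if ref_rows.size == 0:
        raise ValidationError(f"no rows at reference timepoint {ref_tp}")
    mvp = emb.coords_mvp()
    last_rows = np.flatnonzero(timepoints == tps[-1])
    raw_last = mvp[last_rows].mean() - mvp[ref_rows].mean()
    orient = 1.0 if raw_last >= 0 else -1.0
    ti, ci, pv = [], [], []
    for tp in tps:
        rows = np.flatnonzero(timepoints == tp)
        ti.append(texture_index(emb, ref_rows, rows, orientation=orient))
        if rows.size >= 2:
            _, half = cog_with_ci(orient * mvp[rows], level=level)
        else:
            half = 0.0
        ci.append(half)
        if tp == ref_tp or rows.size < 2 or ref_rows.size < 2:
            pv.append(1.0)
        else:
            pv.append(float(sstats.ttest_ind(mvp[rows], mvp[ref_rows], equal_var=False).pvalue))
    series = TextureIndexSeries(
        timepoints=[float(t) for t in tps],
        ti=ti,
        ci_halfwidth=ci,
        reference_class=f"t={ref_tp:g}",
        p_values=pv,
    )
    return series, emb
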