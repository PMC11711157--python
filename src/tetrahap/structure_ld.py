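"""Population structure (PCA, simplified DAPC) and LD-decay fitting.

LD between biallelic target SNPs is measured as the squared Pearson
correlation of allele dosages (0-4), the composite-LD analogue that
needs no phasing.  Decay with physical distance is summarised by fitting
the Hill-Weir drift-recombination expectation

    E(r^2) = [(10+C) / ((2+C)(11+C))] *
             [1 + ((3+C)(12+12C+C^2)) / (n(2+C)(11+C))]

with C = 4*a*d, where ``a`` is the fitted per-bp coefficient, ``d`` the
distance in bp and ``n`` the sample size.  A circulating variant of the
formula with ``(12+4C+C^2)`` and ``n(2+C(11+C))`` in the second factor
is exposed as ``formula="as_printed"`` so both can be compared; the
standard form is the default.

The DAPC here is deliberately simple: PCA retaining a target variance
fraction, k-means over a candidate k range scored by a Gaussian-model
BIC ``n ln(WSS/n) + k d ln(n)`` (``d`` = retained PCs, so the penalty
counts every centroid coordinate), then a linear-discriminant
projection onto k-1 axes with nearest-centroid membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from tetrahap.madc_io import LocusCoordinate


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, n_components)
    percent_variance: np.ndarray
    loadings: np.ndarray  # (n_markers, n_components)
    mean: np.ndarray
    scale: np.ndarray | None
    labels: list[str] = field(default_factory=list)


@dataclass
class DAPCResult:
    n_clusters: int
    membership: np.ndarray
    n_retained_pcs: int
    discriminant_scores: np.ndarray
    bic_trace: dict[int, float]


@dataclass
class LDFit:
    a: float
    n: int
    threshold: float
    decay_distance_bp: float
    formula: str
    n_pairs: int


def pca(matrix: np.ndarray, scale: bool = False, labels=None) -> PCAResult:
    """Column-centered (optionally unit-scaled) SVD principal components.

    Deterministic up to component sign.  Raises on an all-constant
    matrix.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    if not np.any(Xc != 0):
        raise ValueError("matrix has no variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    pct = 100.0 * var / var.sum()
    return PCAResult(
        scores=U * S,
        percent_variance=pct,
        loadings=Vt.T,
        mean=mean,
        scale=sd,
        labels=list(labels) if labels is not None else [],
    )


def population_pca(
    freqs: dict[str, dict[str, tuple[np.ndarray, int]]], scale: bool = False
) -> PCAResult:
    """PCA of the population x allele-frequency matrix built from the
    mapping returned by :func:`tetrahap.diversity.allele_frequencies`."""
    pops = list(freqs)
    if len(pops) < 3:
        raise ValueError("need >= 3 populations")
    loci = sorted(set().union(*[set(freqs[p]) for p in pops]))
    cols = []
    for locus in loci:
        a = max(len(freqs[p][locus][0]) for p in pops if locus in freqs[p])
        block = np.full((len(pops), a), np.nan)
        for i, p in enumerate(pops):
            if locus in freqs[p]:
                block[i] = freqs[p][locus][0]
        if np.isnan(block).any():
            continue  # only loci typed in every population
        cols.append(block)
    X = np.hstack(cols)
    return pca(X, scale=scale, labels=pops)


def dapc(
    matrix: np.ndarray,
    k_range=range(1, 9),
    variance_retained: float = 0.80,
    seed: int = 0,
    n_kmeans_starts: int = 10,
) -> DAPCResult:
    """Cluster search on retained PCs (k-means, BIC) followed by a
    linear discriminant step."""
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range is empty")
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if n < max(k_range):
        raise ValueError("fewer samples than the largest candidate k")
    res = pca(X)
    cum = np.cumsum(res.percent_variance) / 100.0
    if variance_retained >= 1.0:
        npc = len(res.percent_variance)
    else:
        npc = int(np.searchsorted(cum, variance_retained) + 1)
    npc = min(npc, res.scores.shape[1])
    Z = res.scores[:, :npc]

    bic_trace: dict[int, float] = {}
    assign: dict[int, np.ndarray] = {}
    for k in k_range:
        if k == 1:
            wss = float(((Z - Z.mean(axis=0)) ** 2).sum())
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=n_kmeans_starts, random_state=seed
            ).fit(Z)
            wss = float(km.inertia_)
            labels = km.labels_
        bic_trace[k] = n * np.log(max(wss, 1e-12) / n) + k * npc * np.log(n)
        assign[k] = labels
    best_k = min(bic_trace, key=bic_trace.get)
    labels = assign[best_k]

    if best_k == 1:
        scores = np.zeros((n, 0))
        membership = labels
    else:
        lda = LinearDiscriminantAnalysis(
            n_components=min(best_k - 1, Z.shape[1])
        )
        scores = lda.fit_transform(Z, labels)
        centroids = np.stack(
            [scores[labels == g].mean(axis=0) for g in range(best_k)]
        )
        d = ((scores[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        membership = d.argmin(axis=1)
    return DAPCResult(best_k, membership, npc, scores, bic_trace)


def ld_pairs(
    dosages: np.ndarray,
    coords: list[LocusCoordinate],
    maf_min: float = 0.05,
    max_distance: int = 1_000_000,
    ploidy: int = 4,
) -> pd.DataFrame:
    """Same-chromosome r^2 between dosage columns.

    ``dosages`` is samples x markers with values 0..ploidy (NaN =
    missing); r^2 is the squared Pearson correlation over
    pairwise-complete samples.  Markers below ``maf_min`` minor allele
    frequency are excluded before pairing.
    """
    X = np.asarray(dosages, dtype=float)
    freqs = np.nanmean(X, axis=0) / ploidy
    maf = np.minimum(freqs, 1 - freqs)
    keep = np.where(maf >= maf_min)[0]
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for i in keep:
        by_chrom.setdefault(coords[i].chromosome, []).append(i)
    for chrom, idx in by_chrom.items():
        idx = sorted(idx, key=lambda i: coords[i].position)
        for ai in range(len(idx)):
            for bi in range(ai + 1, len(idx)):
                i, j = idx[ai], idx[bi]
                d = coords[j].position - coords[i].position
                if d > max_distance:
                    break
                xi, xj = X[:, i], X[:, j]
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() < 3:
                    continue
                a, b = xi[ok], xj[ok]
                if a.std() == 0 or b.std() == 0:
                    continue
                r = np.corrcoef(a, b)[0, 1]
                rows.append(
                    {
                        "chrom": chrom,
                        "pos1": coords[i].position,
                        "pos2": coords[j].position,
                        "distance": d,
                        "r2": r * r,
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "distance", "r2"])


def expected_r2(C, n: int, formula: str = "standard"):
    """Hill-Weir expected r^2 at scaled distance ``C`` for sample size
    ``n``; vectorised over ``C``."""
    C = np.asarray(C, dtype=float)
    first = (10 + C) / ((2 + C) * (11 + C))
    if formula == "standard":
        second = 1 + ((3 + C) * (12 + 12 * C + C**2)) / (n * (2 + C) * (11 + C))
    elif formula == "as_printed":
        second = 1 + ((3 + C) * (12 + 4 * C + C**2)) / (n * (2 + C * (11 + C)))
    else:
        raise ValueError("formula must be 'standard' or 'as_printed'")
    out = first * second
    return float(out) if out.ndim == 0 else out


def fit_ld_decay(
    pairs: pd.DataFrame,
    n: int,
    threshold: float = 0.1,
    formula: str = "standard",
    min_pairs: int = 100,
) -> LDFit:
    """Nonlinear least squares of observed r^2 against
    ``expected_r2(4 a d, n)`` over the single coefficient ``a``, plus the
    distance where the fitted curve crosses ``threshold``.

    The start value is grid-seeded (best of a log-spaced grid of ``a``
    candidates) so the fit is deterministic.
    """
    if len(pairs) < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs, got {len(pairs)}")
    d = pairs["distance"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)

    def resid(log_a):
        return expected_r2(4 * np.exp(log_a[0]) * d, n, formula) - r2

    grid = np.log(np.logspace(-8, -2, 25))
    sse = [float((resid([g]) ** 2).sum()) for g in grid]
    start = grid[int(np.argmin(sse))]
    sol = least_squares(resid, x0=[start], method="lm")
    if not sol.success:
        raise RuntimeError(f"LD fit did not converge: {sol.message}")
    a = float(np.exp(sol.x[0]))

    floor = expected_r2(np.array(1e12), n, formula)
    if threshold <= floor:
        decay = float("inf")
    else:
        f = lambda dd: expected_r2(4 * a * dd, n, formula) - threshold
        hi = 1.0
        while f(hi) > 0:
            hi *= 10
            if hi > 1e15:
                break
        decay = float(brentq(f, 1e-9, hi))
    return LDFit(a, n, threshold, decay, formula, len(pairs))
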