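"""Community-environment statistics.

Supporting multivariate layer for the functional-group pipeline:

* pairwise distances (Bray-Curtis for community data, Euclidean for
  standardized environmental data);
* PCA with variance fractions computed as eigenvalue over the total
  eigenvalue sum;
* the permutation Mantel test for correlation between two distance
  matrices;
* PERMDISP — permutation test for homogeneity of multivariate
  dispersions, measured as distances to group centroids in
  principal-coordinate space;
* hierarchical partitioning (Chevan-Sutherland) of the RDA explained
  variance of a transformed community matrix over environmental
  predictors.

All permutation p-values use the +1 correction
p = (#{permuted statistic >= observed} + 1) / (n_perm + 1) and take an
explicit integer seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .functional_groups import BiomassMatrix, round_half_up
from .io_core import EnvTable, ValidationError, align_samples

logger = logging.getLogger("phytofg")

METRICS = ("bray_curtis", "euclidean")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample labels."""

    labels: list
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise ValidationError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (condensed) vector, scipy ordering."""
        return squareform(self.d, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def distance(matrix: np.ndarray, metric: str = "bray_curtis",
             labels: list | None = None) -> DistanceMatrix:
    """Pairwise Bray-Curtis or Euclidean distances between sample rows."""
    X = np.asarray(matrix, dtype=float)
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; use one of {METRICS}")
    if labels is None:
        labels = list(range(X.shape[0]))
    if metric == "bray_curtis":
        if np.any(X < 0):
            raise ValidationError("Bray-Curtis requires non-negative data")
        if np.any(X.sum(axis=1) == 0):
            rows = np.flatnonzero(X.sum(axis=1) == 0).tolist()
            raise ValidationError(
                f"all-zero sample row(s) {rows} undefined under Bray-Curtis")
        d = squareform(pdist(X, metric="braycurtis"))
    else:
        d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(labels=list(labels), d=d, metric=metric)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    components: np.ndarray        # n_components x n_features loadings
    eigenvalues: np.ndarray       # covariance eigenvalues, descending
    explained: np.ndarray         # eigenvalue / sum(eigenvalues)
    scores: np.ndarray            # n_samples x n_components


def pca(matrix: np.ndarray, scale: bool = False,
        feature_names: list[str] | None = None) -> PCAResult:
    """Centered (optionally z-scored) PCA via SVD.

    Variance-explained fractions are each eigenvalue divided by the
    total eigenvalue sum, so they sum to 1. With ``scale=True`` a
    constant feature is an error (its z-score is undefined).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples and >= 2 features")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        const = [names[j] for j in np.flatnonzero(sd == 0)]
        if const:
            raise ValidationError(
                f"constant feature(s) cannot be scaled: {const}")
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s ** 2 / (X.shape[0] - 1)
    total = eig.sum()
    explained = eig / total if total > 0 else np.zeros_like(eig)
    return PCAResult(components=vt, eigenvalues=eig, explained=explained,
                     scores=u * s)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    seed: int
    method: str


def _rankdata(v: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    return rankdata(v)


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0, method: str = "pearson") -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    r is the Pearson (or Spearman, by flag) correlation of the
    vectorized upper triangles; the one-sided p-value permutes the
    row/column order of ``d2`` jointly,
    p = (#{r_perm >= r_obs} + 1) / (n_perm + 1).
    """
    if d1.labels != d2.labels:
        raise ValidationError("distance matrices have different labels/order")
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99")
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    n = d1.n
    iu = np.triu_indices(n, k=1)
    v1 = d1.d[iu]
    if method == "spearman":
        v1 = _rankdata(v1)
    v1 = v1 - v1.mean()
    s1 = math.sqrt((v1 ** 2).sum())

    def corr_with(mat: np.ndarray) -> float:
        v2 = mat[iu]
        if method == "spearman":
            v2 = _rankdata(v2)
        v2 = v2 - v2.mean()
        s2 = math.sqrt((v2 ** 2).sum())
        if s1 == 0 or s2 == 0:
            raise ValidationError("zero variance among distances")
        return float((v1 * v2).sum() / (s1 * s2))

    r_obs = corr_with(d2.d)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr_with(d2.d[np.ix_(idx, idx)]) >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, seed=seed, method=method)


# ---------------------------------------------------------------------------
# PERMDISP
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    group_means: dict            # group -> mean distance to centroid
    f_stat: float
    p: float
    n_perm: int
    seed: int
    distances: np.ndarray        # per-sample distance to own centroid
    group_labels: np.ndarray


def _pcoa_coords(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding; returns (real-part, imaginary-part)
    coordinate blocks for the positive and negative eigenvalues."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-10 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F on a vector given integer group codes."""
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        m = v.mean()
        ss_between += v.size * (m - grand) ** 2
        ss_within += ((v - m) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within == 0:
        return math.inf if ss_between > 0 else 0.0
    return float((ss_between / df_b) / (ss_within / df_w))


def permdisp(d: DistanceMatrix, groups: dict | list, n_perm: int = 999,
             seed: int = 0) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Samples are embedded by principal-coordinate analysis (negative
    eigenvalues handled by the standard imaginary-part correction:
    squared distances to centroids subtract the negative-axis part);
    each sample's distance to its own group centroid is compared across
    groups with a one-way ANOVA F, and significance comes from
    permuting group labels of the distance vector.
    """
    if isinstance(groups, dict):
        labels = np.array([groups[l] for l in d.labels])
    else:
        labels = np.asarray(groups)
        if labels.size != d.n:
            raise ValidationError("group labels length mismatch")
    uniq = np.unique(labels)
    codes = np.searchsorted(uniq, labels)
    if uniq.size < 2:
        raise ValidationError("need >= 2 groups")
    counts = np.bincount(codes, minlength=uniq.size)
    single = [str(uniq[g]) for g in np.flatnonzero(counts < 2)]
    if single:
        raise ValidationError(f"singleton group(s): {single}")

    real, imag = _pcoa_coords(d.d)
    dist2 = np.zeros(d.n)
    for g in range(uniq.size):
        mask = codes == g
        cr = real[mask].mean(axis=0)
        ci = imag[mask].mean(axis=0) if imag.size else np.zeros(0)
        part = ((real[mask] - cr) ** 2).sum(axis=1)
        if imag.size:
            part = part - ((imag[mask] - ci) ** 2).sum(axis=1)
        dist2[mask] = part
    z = np.sqrt(np.clip(dist2, 0.0, None))

    f_obs = _anova_f(z, codes, uniq.size)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(z, perm, uniq.size) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    group_means = {str(uniq[g]): float(z[codes == g].mean())
                   for g in range(uniq.size)}
    return DispersionResult(group_means=group_means, f_stat=f_obs, p=p,
                            n_perm=n_perm, seed=seed, distances=z,
                            group_labels=labels)


# ---------------------------------------------------------------------------
# hierarchical partitioning of RDA explained variance
# ---------------------------------------------------------------------------

TRANSFORMS = ("hellinger", "log1p", "none")


def transform_community(Y: np.ndarray, transform: str = "hellinger") -> np.ndarray:
    """Community-matrix transformation ahead of RDA."""
    Y = np.asarray(Y, dtype=float)
    if transform == "hellinger":
        if np.any(Y < 0):
            raise ValidationError("Hellinger transform needs non-negative data")
        totals = Y.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValidationError("all-zero rows cannot be Hellinger-transformed")
        return np.sqrt(Y / totals)
    if transform == "log1p":
        return np.log1p(Y)
    if transform == "none":
        return Y
    raise ValidationError(f"unknown transform {transform!r}; use {TRANSFORMS}")


@dataclass
class HierPartResult:
    predictors: list[str]
    total_r2: float
    individual: dict[str, float]
    joint: dict[str, float]
    subset_r2: dict[frozenset, float]

    @property
    def residual(self) -> float:
        return 1.0 - self.total_r2

    def negative_individuals(self) -> list[str]:
        return [p for p, v in self.individual.items() if v < 0]


def _rda_r2(Yc: np.ndarray, X: np.ndarray, ss_total: float) -> float:
    """RDA explained variance: trace of fitted SS over total SS."""
    if X.shape[1] == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    coef, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ coef
    return float((fitted ** 2).sum() / ss_total)


def hierarchical_partition(response: np.ndarray, predictors: pd.DataFrame,
                           transform: str = "hellinger") -> HierPartResult:
    """Chevan-Sutherland hierarchical partitioning of RDA R².

    For every subset S of predictors, R²(S) is the explained-variance
    fraction of the multivariate linear model of the (transformed,
    centered) community matrix on S. Each predictor's *individual*
    contribution averages its R² increment over all orderings of entry
    (equivalently, Shapley weights over subsets); the individual
    contributions sum exactly to R²(all). *Joint* contribution is the
    marginal single-predictor R² minus the individual share; negative
    individual values are retained and flagged, never truncated.
    """
    names = list(predictors.columns)
    p = len(names)
    if p == 0:
        raise ValidationError("no predictors given")
    if p > 12:
        raise ValidationError(f"{p} predictors; all-subsets limited to 12")
    X_all = predictors.to_numpy(float)
    Y = np.asarray(response, dtype=float)
    if np.isnan(X_all).any() or np.isnan(Y).any():
        raise ValidationError("complete cases required (drop missing first)")
    if X_all.shape[0] != Y.shape[0]:
        raise ValidationError("response and predictors differ in sample count")

    Xc = X_all - X_all.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        # name a minimal aliased set: greedily find columns not raising rank
        aliased = []
        kept: list[int] = []
        for j in range(p):
            trial = Xc[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept):
                aliased.append(names[j])
            else:
                kept.append(j)
        raise ValidationError(f"collinear (aliased) predictor(s): {aliased}")

    Yt = transform_community(Y, transform)
    Yc = Yt - Yt.mean(axis=0)
    ss_total = float((Yc ** 2).sum())
    if ss_total == 0:
        raise ValidationError("response has zero variance")

    subset_r2: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, p + 1):
        for combo in itertools.combinations(range(p), r):
            subset_r2[frozenset(combo)] = _rda_r2(
                Yc, X_all[:, list(combo)], ss_total)

    fact = [math.factorial(i) for i in range(p + 1)]
    individual = {}
    for j in range(p):
        total = 0.0
        for S in subset_r2:
            if j in S:
                continue
            w = fact[len(S)] * fact[p - len(S) - 1] / fact[p]
            total += w * (subset_r2[frozenset(S | {j})] - subset_r2[S])
        individual[names[j]] = total
    total_r2 = subset_r2[frozenset(range(p))]
    joint = {names[j]: subset_r2[frozenset({j})] - individual[names[j]]
             for j in range(p)}
    neg = [nm for nm, v in individual.items() if v < 0]
    if neg:
        logger.info("negative individual contribution(s) retained: %s", neg)
    return HierPartResult(predictors=names, total_r2=total_r2,
                          individual=individual, joint=joint,
                          subset_r2=subset_r2)


def contribution_share_percent(rates: list[float], total: float) -> float:
    """Share of a total interpretation rate held by selected factors, in %.

    The report arithmetic used when quoting, e.g., the top-three
    factors' combined share of an RDA interpretation rate; 2-decimal
    half-up rounding.
    """
    if total <= 0:
        raise ValidationError("total interpretation rate must be positive")
    return round_half_up(100.0 * sum(rates) / total)


# ---------------------------------------------------------------------------
# prepared tables for external ML / SEM tooling
# ---------------------------------------------------------------------------

def prepare_community_env(bm: BiomassMatrix, env: EnvTable,
                          transform: str = "hellinger"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned (community, environment) tables for off-the-shelf tools.

    Returns the transformed sample-by-group community DataFrame and the
    complete-case environmental DataFrame on the shared samples — the
    hook for external variable-importance or SEM analyses, which this
    package does not implement.
    """
    from .io_core import AbundanceTable  # avoid cycle at import time

    keys_env = {k: i for i, k in enumerate(env.samples)}
    shared = [(i, keys_env[k]) for i, k in enumerate(bm.samples)
              if k in keys_env]
    if not shared:
        raise ValidationError("no shared samples between biomass and environment")
    ib, ie = zip(*shared)
    env_sub = env.subset_samples(list(ie)).data
    complete = ~env_sub.isna().any(axis=1)
    if (~complete).any():
        logger.info("dropping %d incomplete sample(s)", int((~complete).sum()))
    rows_b = [ib[i] for i in np.flatnonzero(complete.to_numpy())]
    rows_e = np.flatnonzero(complete.to_numpy())
    Yt = transform_community(bm.biomass[rows_b], transform)
    idx = pd.MultiIndex.from_tuples([bm.samples[i] for i in rows_b],
                                    names=["site", "date"])
    Ydf = pd.DataFrame(Yt, index=idx, columns=bm.groups)
    Xdf = pd.DataFrame(env_sub.iloc[rows_e].to_numpy(float), index=idx,
                       columns=env_sub.columns)
    return Ydf, Xdf
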