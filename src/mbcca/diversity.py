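"""Alpha diversity, Bray-Curtis beta diversity, PCoA, and ANOSIM.

Alpha indices follow the classical definitions on relative abundances
p_i = x_i / sum(x): Shannon entropy -sum p_i log p_i (natural log by
default, base exposed), Gini-Simpson 1 - sum p_i^2, inverse Simpson
1 / sum p_i^2, bias-corrected Chao1, and observed richness. Beta
diversity is Bray-Curtis; ordination is classical metric scaling (PCoA);
group separation is tested with rank-based ANOSIM using a seeded
add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .datamodel import FeatureTable, GroupDesign, ValidationError


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValidationError("counts must be one-dimensional")
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValidationError("counts must be finite and non-negative")
    return x


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over positive proportions.

    Natural log by default; pass ``base`` (e.g. 2) for other conventions.
    """
    x = _as_counts(counts)
    total = x.sum()
    if total == 0:
        raise ValidationError("Shannon undefined for an all-zero vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson_family(counts, variant: str = "gini_simpson") -> float:
    """Simpson concentration D = sum p_i^2; returns 1-D or 1/D per variant."""
    x = _as_counts(counts)
    total = x.sum()
    if total == 0:
        raise ValidationError("Simpson undefined for an all-zero vector")
    d = float(((x / total) ** 2).sum())
    if variant == "gini_simpson":
        return 1.0 - d
    if variant == "inverse_simpson":
        return 1.0 / d
    raise ValidationError(f"unknown Simpson variant {variant!r}")


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    F1/F2 are singleton/doubleton counts; the +1 in the denominator keeps
    the estimator defined when no doubletons are observed. Requires
    integer counts (singletons are literal count-1 observations).
    """
    x = _as_counts(counts)
    if not np.all(x == np.round(x)):
        raise ValidationError("Chao1 requires integer counts")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def observed_species(counts) -> int:
    """Number of features with strictly positive count."""
    return int((_as_counts(counts) > 0).sum())


def alpha_diversity_table(table: FeatureTable) -> pd.DataFrame:
    """Per-sample table of all alpha indices used in the analysis."""
    rows = {}
    for s in table.sample_ids:
        x = table.data.loc[s].to_numpy()
        row = {"observed_species": observed_species(x)}
        if x.sum() > 0:
            row["shannon"] = shannon(x)
            row["gini_simpson"] = simpson_family(x, "gini_simpson")
            row["inverse_simpson"] = simpson_family(x, "inverse_simpson")
        else:
            row.update(shannon=np.nan, gini_simpson=np.nan, inverse_simpson=np.nan)
        try:
            row["chao1"] = chao1(x)
        except ValidationError:
            row["chao1"] = np.nan
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distance matrix with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v).

    Pairs of all-zero samples (undefined ratio) are assigned distance 0.
    """
    if table.n_samples < 2:
        raise ValidationError("Bray-Curtis needs at least two samples")
    with np.errstate(invalid="ignore"):
        d = pdist(table.values, metric="braycurtis")
    d = np.nan_to_num(d, nan=0.0)  # all-zero sample pairs
    return DistanceMatrix(table.sample_ids, squareform(d))


@dataclass
class OrdinationResult:
    """Classical-scaling ordination: coordinates plus the eigen-spectrum."""

    sample_ids: list[str]
    coordinates: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # all n, descending; negatives retained
    proportion_explained: np.ndarray  # aligned with eigenvalues

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dist: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (classical metric scaling).

    Eigen-decomposes the double-centered -d^2/2 matrix. Negative
    eigenvalues (non-Euclidean distances) are retained in the spectrum
    report but excluded from coordinates; proportions are relative to the
    positive part of the spectrum.
    """
    n = len(dist.sample_ids)
    if k is None:
        k = n - 1
    if k > n - 1:
        raise ValidationError(f"k={k} exceeds n-1={n - 1}")
    d2 = dist.values ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos_sum = evals[evals > 0].sum()
    proportions = np.where(evals > 0, evals, 0.0) / pos_sum if pos_sum > 0 else np.zeros(n)
    coords = np.zeros((n, k))
    for i in range(k):
        if evals[i] > 1e-12 * max(abs(evals[0]), 1.0):
            coords[:, i] = evecs[:, i] * np.sqrt(evals[i])
    return OrdinationResult(list(dist.sample_ids), coords, evals, proportions)


@dataclass
class AnosimResult:
    """ANOSIM statistic and its seeded permutation p-value."""

    r: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValidationError(f"ANOSIM R out of bounds: {self.r}")


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray) -> float:
    m = ranks.size
    r_within = ranks[same_group].mean()
    r_between = ranks[~same_group].mean()
    return float((r_between - r_within) / (m / 2.0))


def anosim(
    dist: DistanceMatrix,
    design: GroupDesign,
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """ANOSIM: are between-group distances larger than within-group ones?

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with average ranks. The
    p-value uses the add-one permutation estimator
    (1 + #{permuted R >= observed R}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = design.labels_for(dist.sample_ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise ValidationError(f"groups with fewer than two samples: {small}")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(dist.condensed())
    same = labels[iu] == labels[ju]
    r_obs = _anosim_r(ranks, same)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] == perm[ju]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return AnosimResult(r_obs, p, n_perm, seed)


def pairwise_anosim(
    dist: DistanceMatrix,
    design: GroupDesign,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """ANOSIM for every group pair, with raw and BH-adjusted p-values."""
    from .differential import bh_adjust

    groups = design.groups()
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            ids = design.samples(a) + design.samples(b)
            keep = [s for s in dist.sample_ids if s in set(ids)]
            idx = [dist.sample_ids.index(s) for s in keep]
            sub = DistanceMatrix(keep, dist.values[np.ix_(idx, idx)])
            res = anosim(sub, design, n_perm, int(rng.integers(2**31 - 1)))
            rows.append({"group_a": a, "group_b": b, "R": res.r, "p": res.p_value})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
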