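"""Bray-Curtis dissimilarity, ANOSIM, SIMPER breakdowns and nMDS ordination.

All dissimilarities/similarities use the 0-100 scale.  ANOSIM is the
rank-based statistic

    R = (rB - rW) / c,    c = n(n-1)/4

where rB and rW are the mean midranks of between- and within-group pairwise
dissimilarities.  Significance is reported as

    sig% = 100 * (n_ge_observed + 1) / (n_permutations + 1)

the convention under which 44 of 999 permuted statistics at or above the
observed one prints as 4.5%.

SIMPER decomposes within-group Bray-Curtis similarity (and between-group
dissimilarity) into additive per-feature contributions whose sum equals the
group mean similarity (dissimilarity) exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .feature_matrix import PeakMatrix

logger = logging.getLogger(__name__)

#: Sentinel for pairwise permutation counts above 1e9, mirroring how very
#: large possible-permutation counts are usually printed.
VERY_LARGE = "Very large"

_PERM_LIMIT = 10 ** 9


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities on the 0-100 scale."""

    samples: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.samples)
        if self.d.shape != (n, n):
            raise ValueError("dissimilarity matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("dissimilarity diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 100 + 1e-9):
            raise ValueError("dissimilarities must lie in [0, 100]")

    @property
    def n(self) -> int:
        return len(self.samples)

    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)

    def subset(self, sample_ids) -> "DissimilarityMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return DissimilarityMatrix(
            samples=list(sample_ids), d=self.d[np.ix_(idx, idx)]
        )


@dataclass
class AnosimResult:
    """ANOSIM statistic with permutation provenance."""

    R: float
    sig_percent: float
    n_permutations: int
    n_ge_observed: int
    possible_perms: int | str
    groups: tuple[str, ...] | str = "global"
    rB: float = float("nan")
    rW: float = float("nan")
    c: float = float("nan")
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups) if isinstance(self.groups, tuple)
            else self.groups,
            "R": self.R,
            "sig_percent": self.sig_percent,
            "n_permutations": self.n_permutations,
            "n_ge_observed": self.n_ge_observed,
            "possible_perms": self.possible_perms,
            "n": self.n,
        }


@dataclass
class SimperResult:
    """Per-feature contribution breakdown for one group or group pair.

    ``table`` columns: feature_mz, contribution, contribution_pct,
    cumulative_pct, ratio (contribution / across-pair SD, inf where SD = 0);
    rows sorted by contribution descending, ties by ascending m/z.
    """

    scope: str | tuple[str, str]
    kind: str  # "similarity" or "dissimilarity"
    average_score: float
    table: pd.DataFrame = field(repr=False)
    n_pairs: int = 0


@dataclass
class NmdsResult:
    coordinates: np.ndarray
    stress: float
    converged: bool
    seed: int | None
    samples: list[str] = field(default_factory=list)


def _group_vector(dis_samples, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.reindex(dis_samples).to_numpy()
    if isinstance(labels, dict):
        return np.array([labels[s] for s in dis_samples], dtype=object)
    arr = np.asarray(labels, dtype=object)
    if len(arr) != len(dis_samples):
        raise ValueError("labels length does not match samples")
    return arr


def bray_curtis(matrix: PeakMatrix) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis dissimilarity, 0-100 scale.

    d(i,j) = 100 * sum_f |x_if - x_jf| / sum_f (x_if + x_jf); the similarity
    quoted alongside SIMPER results is 100 - d.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    row_sums = matrix.values.sum(axis=1)
    if np.any(row_sums == 0):
        bad = [s for s, t in zip(matrix.samples, row_sums) if t == 0]
        raise ValueError(f"all-zero samples have undefined dissimilarity: {bad}")
    d = squareform(pdist(matrix.values, metric="braycurtis")) * 100.0
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(samples=list(matrix.samples), d=d)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> tuple[float, ...]:
    c = n * (n - 1) / 4.0
    rW = ranks[within].mean()
    rB = ranks[~within].mean()
    return (rB - rW) / c, rB, rW, c


def _within_mask(groups: np.ndarray) -> np.ndarray:
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    return groups[iu[0]] == groups[iu[1]]


def anosim(
    dis: DissimilarityMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    groups_name: tuple[str, ...] | str = "global",
) -> AnosimResult:
    """Global ANOSIM with permutation significance.

    Labels are permuted uniformly (identity rearrangement excluded) and the
    observed R is compared against the permuted distribution.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    groups = _group_vector(dis.samples, labels)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if np.any(counts < 2):
        bad = uniq[counts < 2]
        raise ValueError(f"groups with a single sample: {list(bad)}")

    n = dis.n
    cond = dis.condensed()
    within = _within_mask(groups)
    if np.all(cond == cond[0]):
        logger.warning("all dissimilarities equal; ANOSIM R is 0 by convention")
        observed, rB, rW, c = 0.0, np.nan, np.nan, n * (n - 1) / 4.0
    else:
        ranks = rankdata(cond)  # midranks for ties
        observed, rB, rW, c = _anosim_r(ranks, within, n)

    ranks = rankdata(cond)
    rng = np.random.default_rng(seed)
    identity = np.arange(n)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        while np.array_equal(perm, identity):
            perm = rng.permutation(n)
        r_perm, *_ = _anosim_r(ranks, _within_mask(groups[perm]), n)
        if r_perm >= observed - 1e-12:
            n_ge += 1
    sig = significance_percent(n_ge, n_permutations)
    return AnosimResult(
        R=float(observed), sig_percent=sig, n_permutations=n_permutations,
        n_ge_observed=n_ge, possible_perms=_possible_perms(counts),
        groups=groups_name, rB=float(rB), rW=float(rW), c=float(c), n=n,
    )


def anosim_r(dis: DissimilarityMatrix, labels) -> float:
    """The ANOSIM R statistic alone (no permutation test)."""
    groups = _group_vector(dis.samples, labels)
    cond = dis.condensed()
    if np.all(cond == cond[0]):
        return 0.0
    r, *_ = _anosim_r(rankdata(cond), _within_mask(groups), dis.n)
    return float(r)


def significance_percent(n_ge_observed: int, n_permutations: int) -> float:
    """Permutation significance on the percent scale.

    sig% = 100 * (n_ge_observed + 1) / (n_permutations + 1); the observed
    statistic counts as one of the permutations.
    """
    if n_permutations < 1 or not 0 <= n_ge_observed <= n_permutations:
        raise ValueError("need 0 <= n_ge_observed <= n_permutations, >= 1")
    return 100.0 * (n_ge_observed + 1) / (n_permutations + 1)


def _possible_perms(counts) -> int | str:
    total = math.factorial(int(sum(counts)))
    for c in counts:
        total //= math.factorial(int(c))
    return total if total <= _PERM_LIMIT else VERY_LARGE


def pairwise_anosim(
    dis: DissimilarityMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> list[AnosimResult]:
    """One ANOSIM per unordered group pair, on that pair's sub-matrix."""
    groups = _group_vector(dis.samples, labels)
    uniq = sorted(set(groups))
    results = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(uniq, 2):
        ids = [s for s, g in zip(dis.samples, groups) if g in (a, b)]
        sub = dis.subset(ids)
        sub_labels = {s: g for s, g in zip(dis.samples, groups) if g in (a, b)}
        res = anosim(
            sub, sub_labels, n_permutations=n_permutations,
            seed=int(rng.integers(2 ** 63)), groups_name=(a, b),
        )
        results.append(res)
    return results


def _simper_pair_table(
    features: np.ndarray, per_pair: np.ndarray, scope, kind: str
) -> SimperResult:
    contribution = per_pair.mean(axis=0)
    if per_pair.shape[0] > 1:
        sd = per_pair.std(axis=0, ddof=1)
    else:
        sd = np.zeros(per_pair.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd > 0, contribution / np.where(sd > 0, sd, 1.0), np.inf)
    average_score = float(contribution.sum())
    order = np.lexsort((features, -contribution))
    contribution = contribution[order]
    total = contribution.sum()
    pct = contribution / total * 100.0 if total > 0 else np.zeros_like(contribution)
    table = pd.DataFrame(
        {
            "feature_mz": features[order],
            "contribution": contribution,
            "contribution_pct": pct,
            "cumulative_pct": np.cumsum(pct),
            "ratio": ratio[order],
        }
    )
    return SimperResult(
        scope=scope, kind=kind, average_score=average_score, table=table,
        n_pairs=per_pair.shape[0],
    )


def simper_within(matrix: PeakMatrix, labels=None, level: str = "family"
                  ) -> list[SimperResult]:
    """SIMPER similarity breakdown per group.

    For each within-group sample pair (j, k) feature i contributes
    100 * 2 min(x_ij, x_ik) / sum_f (x_fj + x_fk); the per-feature mean over
    pairs sums to the group's mean Bray-Curtis similarity.
    """
    groups = _labels_for(matrix, labels, level)
    results = []
    for g in sorted(set(groups)):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            logger.warning("group %s has < 2 samples; skipped in SIMPER", g)
            continue
        rows = []
        for j, k in itertools.combinations(idx, 2):
            xj, xk = matrix.values[j], matrix.values[k]
            denom = xj.sum() + xk.sum()
            rows.append(100.0 * 2.0 * np.minimum(xj, xk) / denom)
        results.append(
            _simper_pair_table(matrix.features, np.array(rows), g, "similarity")
        )
    return results


def simper_between(matrix: PeakMatrix, labels=None, level: str = "family"
                   ) -> list[SimperResult]:
    """SIMPER dissimilarity breakdown per group pair.

    Feature i contributes 100 * |x_ij - x_ik| / sum_f (x_fj + x_fk) per
    cross-group pair; means sum to the pair's average Bray-Curtis
    dissimilarity.
    """
    groups = _labels_for(matrix, labels, level)
    results = []
    for a, b in itertools.combinations(sorted(set(groups)), 2):
        ia = np.flatnonzero(groups == a)
        ib = np.flatnonzero(groups == b)
        rows = []
        for j in ia:
            for k in ib:
                xj, xk = matrix.values[j], matrix.values[k]
                denom = xj.sum() + xk.sum()
                rows.append(100.0 * np.abs(xj - xk) / denom)
        results.append(
            _simper_pair_table(
                matrix.features, np.array(rows), (a, b), "dissimilarity"
            )
        )
    return results


def _labels_for(matrix: PeakMatrix, labels, level: str) -> np.ndarray:
    if labels is None:
        return matrix.label_series(level).to_numpy()
    return _group_vector(matrix.samples, labels)


def top_contributors(result: SimperResult, cutoff_percent: float) -> pd.DataFrame:
    """Minimal prefix of features whose cumulative contribution % >= cutoff."""
    if not 0 < cutoff_percent <= 100:
        raise ValueError("cutoff_percent must lie in (0, 100]")
    cum = result.table["cumulative_pct"].to_numpy()
    stop = int(np.searchsorted(cum, cutoff_percent - 1e-9)) + 1
    return result.table.iloc[:stop].copy()


def kruskal_stress(dis: DissimilarityMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of an embedding: monotone-regressed disparities."""
    dhat_target = dis.condensed()
    emb = pdist(coords)
    iso = IsotonicRegression(increasing=True)
    disparities = iso.fit_transform(dhat_target, emb)
    denom = float(np.sum(emb ** 2))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((emb - disparities) ** 2)) / denom)


def nmds(
    dis: DissimilarityMatrix,
    k: int = 2,
    n_restarts: int = 50,
    seed: int | None = None,
    max_iter: int = 300,
) -> NmdsResult:
    """Non-metric MDS via SMACOF with monotone regression; stress-1 reported."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if dis.n < k + 1:
        raise ValueError("need at least k+1 samples")
    if not np.all(np.isfinite(dis.d)):
        raise ValueError("non-finite dissimilarities")
    mds = MDS(
        n_components=k, metric_mds=False, metric="precomputed",
        n_init=n_restarts, init="random", random_state=seed,
        max_iter=max_iter, eps=1e-6, normalized_stress=True,
    )
    coords = mds.fit_transform(dis.d)
    coords = coords - coords.mean(axis=0, keepdims=True)
    stress = kruskal_stress(dis, coords)
    converged = bool(getattr(mds, "n_iter_", max_iter) < max_iter)
    return NmdsResult(
        coordinates=coords, stress=stress, converged=converged, seed=seed,
        samples=list(dis.samples),
    )
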