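"""Sequence-level divergence metrics and their link to fingerprint statistics.

Covers pairwise identity/count-difference on pre-aligned sequences, linear
rate-based predicted amino-acid change from divergence time, per-family mean
ANOSIM R summaries, simple linear fits and Welch's t-test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

GAP = "-"

#: Relative amino-acid substitution rates of the three collagen(I) chains.
CHAIN_RATES = {"COL1A1": 0.7, "COL1A2": 0.9, "COL1A3": 1.0}


@dataclass(frozen=True)
class SequencePair:
    taxon_a: str
    taxon_b: str
    aligned_a: str
    aligned_b: str
    count_difference: int
    identity_percent: float
    compared_positions: int


@dataclass(frozen=True)
class DivergenceRecord:
    """Pairwise divergence with a rate-predicted amino-acid change."""

    taxon_a: str
    taxon_b: str
    ed_mya: float
    chain: str
    rate: float
    time_scale: float
    predicted_change: float


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    n: int


def identity_metrics(
    aligned_a: str, aligned_b: str, taxon_a: str = "a", taxon_b: str = "b",
    gap: str = GAP,
) -> SequencePair:
    """Count difference and % identity over comparable aligned positions.

    Positions gapped in both sequences are skipped; a position gapped in only
    one counts as a difference.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    compared = matches = diffs = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x == gap and y == gap:
            continue
        compared += 1
        if x == gap or y == gap or x != y:
            diffs += 1
        else:
            matches += 1
    if compared == 0:
        raise ValueError("no comparable (non-double-gap) positions")
    return SequencePair(
        taxon_a=taxon_a, taxon_b=taxon_b, aligned_a=aligned_a,
        aligned_b=aligned_b, count_difference=diffs,
        identity_percent=100.0 * matches / compared,
        compared_positions=compared,
    )


def pairwise_identity(sequences: dict[str, str]) -> list[SequencePair]:
    """identity_metrics over every unordered pair of a name->sequence dict."""
    return [
        identity_metrics(sequences[a], sequences[b], a, b)
        for a, b in itertools.combinations(sorted(sequences), 2)
    ]


def predicted_change(
    ed_mya: float, chain: str, time_scale: float = 1.0,
    taxon_a: str = "", taxon_b: str = "",
) -> DivergenceRecord:
    """Predicted amino-acid change = chain rate x divergence time x scale."""
    if ed_mya <= 0:
        raise ValueError("ed_mya must be positive")
    if chain not in CHAIN_RATES:
        raise ValueError(f"unknown chain {chain!r}; expected one of "
                         f"{sorted(CHAIN_RATES)}")
    rate = CHAIN_RATES[chain]
    return DivergenceRecord(
        taxon_a=taxon_a, taxon_b=taxon_b, ed_mya=float(ed_mya), chain=chain,
        rate=rate, time_scale=float(time_scale),
        predicted_change=rate * ed_mya * time_scale,
    )


def mean_family_R(pairwise_results, family: str) -> float:
    """Mean ANOSIM R over every pair involving ``family``."""
    rs = [
        res.R for res in pairwise_results
        if isinstance(res.groups, tuple) and family in res.groups
    ]
    if not rs:
        raise ValueError(f"family {family!r} appears in no pairwise result")
    return float(np.mean(rs))


def group_mean_R(pairwise_results) -> tuple[float, float, dict[str, float]]:
    """Per-family mean R plus the grand mean +/- SD across families."""
    families = sorted(
        {g for res in pairwise_results if isinstance(res.groups, tuple)
         for g in res.groups}
    )
    per_family = {f: mean_family_R(pairwise_results, f) for f in families}
    vals = np.array(list(per_family.values()))
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd, per_family


def fit_linear(x, y) -> FitResult:
    """Ordinary least-squares line with Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least three points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return FitResult(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue), r_squared=float(res.rvalue ** 2),
        n=len(x),
    )


def filter_by_ed(records, max_ed: float):
    """Keep records with ed_mya <= max_ed; returns (kept, n_kept, n_removed)."""
    if max_ed <= 0:
        raise ValueError("max_ed must be positive")
    records = list(records)
    kept = [r for r in records if r.ed_mya <= max_ed]
    removed = len(records) - len(kept)
    if not kept:
        logger.warning("ED filter at %.1f Mya removed every record", max_ed)
    return kept, len(kept), removed


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch two-sample t-test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("degenerate (zero) variance")
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def toy_align(a: str, b: str, match: int = 1, mismatch: int = -1,
              gap: int = -2) -> tuple[str, str]:
    """Needleman-Wunsch global alignment for toy inputs only.

    Not a substitute for curated alignments of real collagen sequences.
    """
    na, nb = len(a), len(b)
    score = np.zeros((na + 1, nb + 1))
    score[:, 0] = gap * np.arange(na + 1)
    score[0, :] = gap * np.arange(nb + 1)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1]
                                          else mismatch)
            score[i, j] = max(diag, score[i - 1, j] + gap, score[i, j - 1] + gap)
    out_a, out_b = [], []
    i, j = na, nb
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
                match if a[i - 1] == b[j - 1] else mismatch):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_b.append(b[j - 1]); out_a.append(GAP); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))
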