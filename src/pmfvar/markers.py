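"""Entropy-based diagnostic-peak selection and one-vs-rest classification.

Markers are chosen per taxon by ID3-style information gain on a binary
presence/absence matrix: a feature is informative when splitting the samples
on its presence reduces the entropy of the taxon-vs-rest labelling.  A sample
is assigned to a taxon only when it agrees with enough of that taxon's
markers and with no other taxon's; anything else is Unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_matrix import BINARY, PeakMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "Unclassified"


def entropy(labels) -> float:
    """Shannon entropy (bits) of a class vector; 0 log 0 is 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(feature, labels) -> float:
    """Reduction in label entropy from splitting on a binary feature."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels must have equal length")
    n = len(labels)
    h = entropy(labels)
    for v in np.unique(feature):
        mask = feature == v
        h -= mask.sum() / n * entropy(labels[mask])
    return float(h)


@dataclass
class MarkerSet:
    """Diagnostic peaks for one taxon.

    ``markers`` rows are (feature m/z, expected presence 0/1, gain in bits),
    sorted by gain descending; every gain >= ``gain_threshold`` and at most
    ``max_markers`` rows are kept.
    """

    taxon: str
    markers: list[tuple[float, int, float]]
    gain_threshold: float
    max_markers: int

    def to_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "gain_threshold": self.gain_threshold,
            "max_markers": self.max_markers,
            "markers": [
                {"feature_mz": mz, "expected_present": exp, "gain_bits": g}
                for mz, exp, g in self.markers
            ],
        }


@dataclass
class ClassificationReport:
    """Per-taxon TP/FP/FN counts and sensitivities (TP / (TP + FN))."""

    counts: pd.DataFrame  # index taxon; columns tp, fp, fn, sensitivity
    mean_sensitivity: float
    sd_sensitivity: float
    predictions: pd.Series = field(repr=False, default=None)


def taxon_gains(matrix: PeakMatrix, taxon: str, level: str = "family"
                ) -> np.ndarray:
    """One-vs-rest information gain of every feature for ``taxon``."""
    if matrix.mode != BINARY:
        raise ValueError("marker identification requires a binary matrix")
    y = (matrix.label_series(level).to_numpy() == taxon)
    return np.array(
        [information_gain(matrix.values[:, j], y) for j in range(matrix.n_features)]
    )


def identify_markers(
    matrix: PeakMatrix,
    level: str = "family",
    gain_threshold: float = 0.3,
    max_markers: int = 10,
) -> list[MarkerSet]:
    """Select top information-gain features per taxon (one-vs-rest).

    Taxa with fewer than two samples are skipped with a warning.  The
    expected presence flag is the feature state enriched within the taxon.
    """
    if matrix.mode != BINARY:
        raise ValueError("marker identification requires a binary matrix")
    groups = matrix.label_series(level).to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two taxa at the chosen level")
    out = []
    for taxon, cnt in zip(uniq, counts):
        if cnt < 2:
            logger.warning("taxon %s has < 2 samples; skipped", taxon)
            continue
        gains = taxon_gains(matrix, taxon, level)
        inside = groups == taxon
        rows = []
        for j in np.flatnonzero(gains >= gain_threshold):
            p_in = matrix.values[inside, j].mean()
            p_out = matrix.values[~inside, j].mean()
            expected = 1 if p_in >= p_out else 0
            rows.append((float(matrix.features[j]), expected, float(gains[j])))
        rows.sort(key=lambda r: (-r[2], r[0]))
        rows = rows[:max_markers]
        if not rows:
            logger.warning("no feature reached gain %.3f for taxon %s",
                           gain_threshold, taxon)
        out.append(MarkerSet(taxon=taxon, markers=rows,
                             gain_threshold=gain_threshold,
                             max_markers=max_markers))
    return out


def _marker_agreement(values: np.ndarray, features: np.ndarray,
                      marker_set: MarkerSet) -> float:
    if not marker_set.markers:
        return 0.0
    agree = 0
    for mz, expected, _ in marker_set.markers:
        j = int(np.argmin(np.abs(features - mz)))
        if abs(features[j] - mz) > 1e-6:
            continue  # marker feature absent from this matrix
        if int(values[j] > 0) == expected:
            agree += 1
    return agree / len(marker_set.markers)


def classify(
    sample_values,
    features,
    marker_sets: list[MarkerSet],
    match_fraction: float = 0.8,
) -> str:
    """Assign a sample to a taxon, or Unclassified.

    The sample matches a taxon when at least ``match_fraction`` of that
    taxon's markers show their expected state.  Exactly one match wins; zero
    or several matches return Unclassified (ambiguities are logged).
    """
    if not marker_sets:
        raise ValueError("no marker sets supplied")
    values = np.asarray(sample_values, dtype=float)
    features = np.asarray(features, dtype=float)
    matches = [
        ms.taxon for ms in sorted(marker_sets, key=lambda m: m.taxon)
        if ms.markers and _marker_agreement(values, features, ms)
        >= match_fraction - 1e-12
    ]
    if len(matches) == 1:
        return matches[0]
    if len(matches) > 1:
        logger.info("ambiguous classification (%s); returning %s",
                    ", ".join(matches), UNCLASSIFIED)
    return UNCLASSIFIED


def classify_matrix(matrix: PeakMatrix, marker_sets: list[MarkerSet],
                    match_fraction: float = 0.8) -> pd.Series:
    """Classify every sample of a binary matrix."""
    preds = {
        sid: classify(matrix.values[i], matrix.features, marker_sets,
                      match_fraction)
        for i, sid in enumerate(matrix.samples)
    }
    return pd.Series(preds, name="prediction")


def evaluate(predictions: pd.Series, truth: pd.Series) -> ClassificationReport:
    """Confusion counts and sensitivity per taxon.

    From a taxon's perspective: TP = correctly assigned samples of that
    taxon; FN = its samples assigned elsewhere or Unclassified; FP = other
    taxa's samples assigned to it.
    """
    predictions = pd.Series(predictions)
    truth = pd.Series(truth)
    if set(predictions.index) != set(truth.index):
        raise ValueError("predictions and truth must cover the same samples")
    predictions = predictions.reindex(truth.index)
    taxa = sorted(set(truth))
    rows = {}
    for t in taxa:
        is_t = truth == t
        tp = int(((predictions == t) & is_t).sum())
        fn = int(((predictions != t) & is_t).sum())
        fp = int(((predictions == t) & ~is_t).sum())
        sens = tp / (tp + fn) if tp + fn else float("nan")
        rows[t] = {"tp": tp, "fp": fp, "fn": fn, "sensitivity": sens}
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "taxon"
    sens = counts["sensitivity"].dropna()
    return ClassificationReport(
        counts=counts,
        mean_sensitivity=float(sens.mean()) if len(sens) else float("nan"),
        sd_sensitivity=float(sens.std(ddof=1)) if len(sens) > 1 else 0.0,
        predictions=predictions,
    )
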