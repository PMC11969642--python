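"""Sample x peak feature matrices: transforms, binarization and contaminant filtering.

The :class:`PeakMatrix` is the central exchange format of the pipeline: rows are
samples, columns are aligned peak features identified by their reference m/z.
Matrices exist in one of two modes, ``intensity`` (non-negative reals) or
``binary`` (0/1 presence calls).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ("family", "genus", "dataset")

INTENSITY = "intensity"
BINARY = "binary"

#: Average mass-defect slope of tryptic peptides (Da of defect per Da of mass).
PEPTIDE_DEFECT_SLOPE = 4.95e-4


@dataclass
class PeakMatrix:
    """Samples x aligned-peak-features grid with taxon labels.

    Parameters
    ----------
    features : array of float
        Reference m/z of each feature, strictly increasing.
    samples : list of str
        Sample identifiers, one per row.
    values : 2-D array
        ``(n_samples, n_features)`` non-negative values (0/1 in binary mode).
    mode : {"intensity", "binary"}
    labels : pandas.DataFrame
        Indexed by sample id with columns ``family``, ``genus``, ``dataset``.
    """

    features: np.ndarray
    samples: list[str]
    values: np.ndarray
    mode: str = INTENSITY
    labels: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = [str(s) for s in self.samples]
        if self.values.shape != (len(self.samples), len(self.features)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids in matrix")
        if np.any(np.diff(self.features) <= 0):
            raise ValueError("feature m/z must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("matrix values must be non-negative")
        if self.mode not in (INTENSITY, BINARY):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == BINARY and not np.all(np.isin(self.values, (0.0, 1.0))):
            raise ValueError("binary matrix may only contain 0/1 values")
        if self.values.size and np.any(self.values.sum(axis=0) == 0):
            raise ValueError("matrix contains an all-zero feature column")
        if self.labels is None:
            self.labels = pd.DataFrame(
                "", index=pd.Index(self.samples, name="sample_id"),
                columns=list(LABEL_COLUMNS),
            )
        else:
            self.labels = self.labels.reindex(self.samples).fillna("")
            for col in LABEL_COLUMNS:
                if col not in self.labels.columns:
                    self.labels[col] = ""
            self.labels = self.labels[list(LABEL_COLUMNS)]
            self.labels.index.name = "sample_id"

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def label_series(self, level: str) -> pd.Series:
        """Return the per-sample labels for ``level`` (family/genus/dataset)."""
        if level not in LABEL_COLUMNS:
            raise ValueError(f"unknown label level {level!r}")
        return self.labels[level]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{mz:.2f}" for mz in self.features]
        df = pd.DataFrame(self.values, index=self.labels.index, columns=cols)
        return pd.concat([self.labels, df], axis=1)

    def to_csv(self, path) -> None:
        """Write the matrix as CSV with a ``# mode=`` header comment."""
        with open(path, "w") as fh:
            fh.write(f"# mode={self.mode}\n")
            self.to_frame().to_csv(fh)


def read_matrix_csv(path) -> PeakMatrix:
    """Round-trip reader for :meth:`PeakMatrix.to_csv` output."""
    with open(path) as fh:
        first = fh.readline().strip()
        mode = INTENSITY
        if first.startswith("#"):
            key, _, val = first.lstrip("# ").partition("=")
            if key == "mode":
                mode = val.strip()
            df = pd.read_csv(fh, index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, index_col=0)
    label_cols = [c for c in LABEL_COLUMNS if c in df.columns]
    labels = df[label_cols].astype(object).where(df[label_cols].notna(), "")
    feat_cols = [c for c in df.columns if c not in LABEL_COLUMNS]
    features = np.array([float(c) for c in feat_cols])
    return PeakMatrix(
        features=features,
        samples=list(df.index.astype(str)),
        values=df[feat_cols].to_numpy(dtype=float),
        mode=mode,
        labels=labels.set_axis(df.index.astype(str)),
    )


@dataclass(frozen=True)
class FilterRule:
    """Non-biological peak removal rule.

    ``min_mz`` discards low-mass (matrix-dominated) features outright;
    features elsewhere are kept only when their fractional mass lies within
    ``defect_tolerance`` of the expected peptide mass defect
    ``defect_slope * m/z (mod 1)``.  Matrix/chemical-noise peaks carry
    near-integer masses and fail this test.
    """

    min_mz: float = 900.0
    defect_slope: float = PEPTIDE_DEFECT_SLOPE
    defect_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if self.min_mz <= 0:
            raise ValueError("min_mz must be positive")
        if not 0 < self.defect_tolerance < 0.5:
            raise ValueError("defect_tolerance must lie in (0, 0.5)")


def defect_deviation(mz, slope: float = PEPTIDE_DEFECT_SLOPE):
    """Circular distance between observed and expected fractional mass."""
    mz = np.asarray(mz, dtype=float)
    observed = np.mod(mz, 1.0)
    expected = np.mod(slope * mz, 1.0)
    d = np.abs(observed - expected)
    return np.minimum(d, 1.0 - d)


def sqrt_transform(matrix: PeakMatrix) -> PeakMatrix:
    """Square-root transform an intensity matrix (variance stabilisation)."""
    if matrix.mode != INTENSITY:
        raise ValueError("sqrt_transform requires an intensity-mode matrix")
    return replace(matrix, values=np.sqrt(matrix.values), labels=matrix.labels.copy())


def binarize(matrix: PeakMatrix) -> PeakMatrix:
    """Reduce values to 0/1 presence calls."""
    values = (matrix.values > 0).astype(float)
    zero_rows = [s for s, row in zip(matrix.samples, values) if not row.any()]
    for s in zero_rows:
        logger.warning("sample %s has no peaks after binarization", s)
    return replace(matrix, values=values, mode=BINARY, labels=matrix.labels.copy())


def normalize_total(matrix: PeakMatrix, total: float = 100.0) -> PeakMatrix:
    """Scale each sample to a fixed total intensity (relative intensities)."""
    if matrix.mode != INTENSITY:
        raise ValueError("normalize_total requires an intensity-mode matrix")
    sums = matrix.values.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        bad = [s for s, t in zip(matrix.samples, sums[:, 0]) if t == 0]
        raise ValueError(f"cannot normalize all-zero samples: {bad}")
    return replace(
        matrix, values=matrix.values / sums * total, labels=matrix.labels.copy()
    )


def filter_nonbiological(
    matrix: PeakMatrix, rule: FilterRule | None = None
) -> tuple[PeakMatrix, pd.DataFrame]:
    """Drop features judged non-biological; return (matrix, removal report).

    Two rules apply, in order: features below ``rule.min_mz`` are removed,
    then features whose mass defect deviates from the peptide expectation by
    more than ``rule.defect_tolerance``.  The report has one row per removed
    feature with the rule that triggered.  Samples left with no peaks are
    dropped with a warning.
    """
    rule = rule or FilterRule()
    reasons: list[tuple[float, str]] = []
    keep = np.ones(matrix.n_features, dtype=bool)
    dev = defect_deviation(matrix.features, rule.defect_slope)
    for i, mz in enumerate(matrix.features):
        if mz < rule.min_mz:
            keep[i] = False
            reasons.append((mz, "below_min_mz"))
        elif dev[i] > rule.defect_tolerance:
            keep[i] = False
            reasons.append((mz, "mass_defect"))
    report = pd.DataFrame(reasons, columns=["feature_mz", "rule"])
    values = matrix.values[:, keep]
    row_ok = values.sum(axis=1) > 0
    if not row_ok.all():
        dropped = [s for s, ok in zip(matrix.samples, row_ok) if not ok]
        logger.warning("dropping all-zero samples after filtering: %s", dropped)
    samples = [s for s, ok in zip(matrix.samples, row_ok) if ok]
    values = values[row_ok]
    features = matrix.features[keep]
    # dropping samples can orphan a column; keep the no-all-zero invariant
    col_ok = values.sum(axis=0) > 0
    if not col_ok.all():
        logger.warning(
            "dropping %d features orphaned by sample removal", int((~col_ok).sum())
        )
    filtered = PeakMatrix(
        features=features[col_ok],
        samples=samples,
        values=values[:, col_ok],
        mode=matrix.mode,
        labels=matrix.labels.loc[samples].copy(),
    )
    return filtered, report
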