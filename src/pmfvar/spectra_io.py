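"""Peak-list input, peak picking on profile traces and cross-sample alignment.

Pre-picked MALDI-ToF peak lists arrive as two-column (m/z, intensity) text
files.  Profile traces can be peak-picked with a MALDIquant-style workflow:
moving-average smoothing, SNIP baseline subtraction, MAD noise estimation and
an SNR threshold on local maxima.  Aligned peaks across samples become a
:class:`~pmfvar.feature_matrix.PeakMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks
from scipy.stats import median_abs_deviation

from .feature_matrix import PeakMatrix

logger = logging.getLogger(__name__)


@dataclass
class Spectrum:
    """One sample's picked peak list plus taxon metadata.

    ``mz`` is kept strictly increasing; ``intensity`` is non-negative and the
    same length.
    """

    sample_id: str
    mz: np.ndarray
    intensity: np.ndarray
    family: str = ""
    genus: str = ""
    dataset: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError(
                f"{self.sample_id}: mz and intensity must be 1-D and equal length"
            )
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError(f"{self.sample_id}: duplicate m/z values in peak list")
        if np.any(self.intensity < 0):
            raise ValueError(f"{self.sample_id}: negative intensity")

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class PeakPickingParams:
    """Knobs for :func:`pick_peaks`; all strictly positive."""

    half_window: int = 20
    snr: float = 3.0
    baseline_iterations: int = 100
    align_tolerance: float = 0.3

    def __post_init__(self) -> None:
        for name in ("half_window", "snr", "baseline_iterations", "align_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _parse_two_column(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mz, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1:
                try:
                    [float(p) for p in parts[:2]]
                except ValueError:
                    continue  # header row
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not mz:
        raise ValueError(f"{path}: empty peak list")
    return np.asarray(mz), np.asarray(inten)


def read_metadata(path) -> pd.DataFrame:
    """Read a sample metadata CSV (sample_id, family, genus, dataset)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs a 'sample_id' column")
    return df.set_index("sample_id")


def read_peak_lists(paths, metadata: pd.DataFrame | None = None) -> list[Spectrum]:
    """Read two-column peak-list files into Spectrum objects.

    Sample ids are file stems; labels are joined from ``metadata`` (a frame
    indexed by sample_id with family/genus/dataset columns).  Samples absent
    from the metadata carry empty labels and a warning is logged.
    """
    spectra: list[Spectrum] = []
    seen: set[str] = set()
    for path in map(Path, paths):
        sample_id = path.stem
        if sample_id in seen:
            raise ValueError(f"duplicate sample id {sample_id!r} from {path}")
        seen.add(sample_id)
        mz, inten = _parse_two_column(path)
        labels = {}
        if metadata is not None and sample_id in metadata.index:
            row = metadata.loc[sample_id]
            labels = {
                k: str(row.get(k, "")) for k in ("family", "genus", "dataset")
            }
        elif metadata is not None:
            logger.warning("sample %s absent from metadata; labels left empty",
                           sample_id)
        spectra.append(Spectrum(sample_id=sample_id, mz=mz, intensity=inten, **labels))
    return spectra


def snip_baseline(y: np.ndarray, iterations: int = 100) -> np.ndarray:
    """SNIP baseline estimate: iterative symmetric min-clipping."""
    b = np.asarray(y, dtype=float).copy()
    n = len(b)
    for m in range(1, min(iterations, (n - 1) // 2) + 1):
        avg = 0.5 * (b[: n - 2 * m] + b[2 * m:])
        mid = b[m: n - m]
        b[m: n - m] = np.minimum(mid, avg)
    return b


def pick_peaks(profile: Spectrum, params: PeakPickingParams | None = None) -> Spectrum:
    """Pick peaks from a profile trace.

    Smooth with a moving average of radius ``half_window``, subtract a SNIP
    baseline, estimate noise as the (normal-scaled) median absolute deviation
    of the baseline-corrected raw trace, and keep windowed local maxima of
    height >= ``snr`` x noise.
    """
    params = params or PeakPickingParams()
    n = len(profile.mz)
    if n < 2 * params.half_window + 1:
        raise ValueError(
            f"{profile.sample_id}: trace of {n} points shorter than the "
            f"smoothing window ({2 * params.half_window + 1})"
        )
    raw = profile.intensity.astype(float)
    smoothed = uniform_filter1d(raw, size=2 * params.half_window + 1,
                                mode="nearest")
    baseline = snip_baseline(smoothed, params.baseline_iterations)
    corrected = np.clip(smoothed - baseline, 0.0, None)
    # noise from the unsmoothed corrected trace: smoothing would deflate it
    noise = median_abs_deviation(raw - baseline, scale="normal")
    threshold = params.snr * noise
    idx, _ = find_peaks(
        corrected, height=max(threshold, np.finfo(float).tiny),
        distance=params.half_window + 1,
    )
    return Spectrum(
        sample_id=profile.sample_id,
        mz=profile.mz[idx],
        intensity=corrected[idx],
        family=profile.family,
        genus=profile.genus,
        dataset=profile.dataset,
    )


def align_peaks(spectra, tolerance: float = 0.3) -> PeakMatrix:
    """Merge peaks within ``tolerance`` Da across samples into shared features.

    Greedy single pass in ascending m/z: a peak opens a new feature when it
    lies more than ``tolerance`` above the current feature's intensity-
    weighted mean m/z.  Adjacent features whose references still fall within
    tolerance afterwards are merged, so re-aligning the matrix is a no-op.
    A sample contributing several peaks to one feature has their intensities
    summed (total intensity is conserved).
    """
    spectra = list(spectra)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if len(spectra) < 2:
        raise ValueError("need at least two spectra to align")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among spectra")

    rows = []
    for si, s in enumerate(spectra):
        for mz, inten in zip(s.mz, s.intensity):
            rows.append((mz, inten, si))
    rows.sort(key=lambda r: r[0])

    clusters: list[list[tuple[float, float, int]]] = []
    ref_num = ref_den = 0.0
    for mz, inten, si in rows:
        w = inten if inten > 0 else np.finfo(float).tiny
        if clusters and mz - ref_num / ref_den <= tolerance:
            clusters[-1].append((mz, inten, si))
            ref_num += w * mz
            ref_den += w
        else:
            clusters.append([(mz, inten, si)])
            ref_num, ref_den = w * mz, w

    def ref(cluster):
        ws = np.array([i if i > 0 else np.finfo(float).tiny for _, i, _ in cluster])
        ms = np.array([m for m, _, _ in cluster])
        return float(np.average(ms, weights=ws))

    refs = [ref(c) for c in clusters]
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        out, out_refs = [clusters[0]], [refs[0]]
        for c, r in zip(clusters[1:], refs[1:]):
            if r - out_refs[-1] <= tolerance:
                out[-1] = out[-1] + c
                out_refs[-1] = ref(out[-1])
                merged = True
            else:
                out.append(c)
                out_refs.append(r)
        clusters, refs = out, out_refs

    values = np.zeros((len(spectra), len(clusters)))
    for fi, cluster in enumerate(clusters):
        for _, inten, si in cluster:
            values[si, fi] += inten
    labels = pd.DataFrame(
        {
            "family": [s.family for s in spectra],
            "genus": [s.genus for s in spectra],
            "dataset": [s.dataset for s in spectra],
        },
        index=pd.Index(ids, name="sample_id"),
    )
    keep = values.sum(axis=0) > 0
    return PeakMatrix(
        features=np.asarray(refs)[keep],
        samples=ids,
        values=values[:, keep],
        mode="intensity",
        labels=labels,
    )


def matrix_to_spectra(matrix: PeakMatrix) -> list[Spectrum]:
    """Reconstruct per-sample peak lists from a matrix (inverse of align)."""
    out = []
    for i, sid in enumerate(matrix.samples):
        present = matrix.values[i] > 0
        lab = matrix.labels.loc[sid]
        out.append(
            Spectrum(
                sample_id=sid,
                mz=matrix.features[present],
                intensity=matrix.values[i][present],
                family=lab["family"],
                genus=lab["genus"],
                dataset=lab["dataset"],
            )
        )
    return out
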