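"""Feature-to-lipid identification filters.

In supercritical-fluid chromatography lipids elute by head group, so each
class occupies a narrow retention-time window; combined with an m/z range
this assigns features to classes.  Individual species are then accepted on
mass accuracy (ppm error below threshold) and isotope-envelope similarity.
Peak picking, adducts and fragment interpretation are upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

PPM_THRESHOLD_DEFAULT = 5.0
SIMILARITY_THRESHOLD_DEFAULT = 80.0


class WindowConfigError(ValueError):
    """Raised when class windows overlap or are malformed."""


@dataclass(frozen=True)
class FeatureRecord:
    """An MS feature: observed m/z, retention time and isotope envelope."""

    observed_mz: float
    retention_time: float
    isotope_envelope: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.observed_mz <= 0:
            raise ValueError("observed m/z must be positive")
        if self.retention_time < 0:
            raise ValueError("retention time must be non-negative")
        if self.isotope_envelope and not all(0 <= v <= 1 for v in self.isotope_envelope):
            raise ValueError("envelope intensities must lie in [0, 1]")


@dataclass(frozen=True)
class ClassWindow:
    """Closed retention-time x m/z rectangle assigned to one lipid class."""

    lipid_class: str
    rt_min: float
    rt_max: float
    mz_min: float
    mz_max: float

    def __post_init__(self) -> None:
        if not (self.rt_min < self.rt_max and self.mz_min < self.mz_max):
            raise WindowConfigError(
                f"window for {self.lipid_class!r} has empty rt or m/z interval"
            )

    def contains(self, feature: FeatureRecord) -> bool:
        return (
            self.rt_min <= feature.retention_time <= self.rt_max
            and self.mz_min <= feature.observed_mz <= self.mz_max
        )


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Absolute mass error in parts per million.

    ``|observed - theoretical| / theoretical * 1e6``; scale-invariant and
    symmetric in sign by construction.
    """
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("masses must be positive")
    return abs(observed_mz - theoretical_mz) / theoretical_mz * 1e6


def isotope_similarity(observed: Sequence[float], theoretical: Sequence[float]) -> float:
    """Cosine similarity of two isotope envelopes, as a percentage in [0, 100].

    The workflow's acceptance threshold is conventionally 80%.  Cosine is the
    standard envelope comparison; swap in another metric at the call site if
    a vendor-specific score is required.
    """
    obs = np.asarray(observed, dtype=float)
    theo = np.asarray(theoretical, dtype=float)
    if obs.shape != theo.shape:
        raise ValueError(f"envelope length mismatch: {obs.shape} vs {theo.shape}")
    if obs.size < 2:
        raise ValueError("envelopes need at least 2 isotope peaks")
    denom = np.linalg.norm(obs) * np.linalg.norm(theo)
    if denom == 0:
        raise ValueError("zero envelope has no direction")
    cos = float(np.dot(obs, theo) / denom)
    return 100.0 * min(max(cos, 0.0), 1.0)


def validate_windows(windows: Sequence[ClassWindow]) -> None:
    """Reject window sets whose closed rectangles intersect.

    Rectangles sharing even an edge are rejected: a boundary feature would
    otherwise sit in two windows and have no unique class.
    """
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            rt_overlap = a.rt_min <= b.rt_max and b.rt_min <= a.rt_max
            mz_overlap = a.mz_min <= b.mz_max and b.mz_min <= a.mz_max
            if rt_overlap and mz_overlap:
                raise WindowConfigError(
                    f"windows for {a.lipid_class!r} and {b.lipid_class!r} overlap "
                    "in rt x m/z space"
                )


def assign_class_by_window(
    feature: FeatureRecord, windows: Sequence[ClassWindow]
) -> str | None:
    """Return the class whose window contains the feature, else ``None``.

    Windows are validated as non-overlapping, so at most one can match.
    Interval bounds are closed: a feature exactly on a window edge is
    assigned rather than silently dropped.
    """
    validate_windows(windows)
    for w in windows:
        if w.contains(feature):
            return w.lipid_class
    return None


def load_class_windows(path: str | Path) -> list[ClassWindow]:
    """Load class windows from delimited text with columns
    class, rt_min, rt_max, mz_min, mz_max; validates non-overlap."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"class", "rt_min", "rt_max", "mz_min", "mz_max"}
    missing = required - set(df.columns)
    if missing:
        raise WindowConfigError(f"window table missing columns: {sorted(missing)}")
    windows = [
        ClassWindow(str(row["class"]), float(row["rt_min"]), float(row["rt_max"]),
                    float(row["mz_min"]), float(row["mz_max"]))
        for _, row in df.iterrows()
    ]
    validate_windows(windows)
    return windows


def passes_identification(
    feature: FeatureRecord,
    theoretical_mz: float,
    theoretical_envelope: Sequence[float] | None = None,
    ppm_threshold: float = PPM_THRESHOLD_DEFAULT,
    similarity_threshold: float = SIMILARITY_THRESHOLD_DEFAULT,
) -> bool:
    """Apply the mass-accuracy and (optionally) isotope-similarity gates."""
    if ppm_error(feature.observed_mz, theoretical_mz) >= ppm_threshold:
        return False
    if theoretical_envelope is not None:
        sim = isotope_similarity(feature.isotope_envelope, theoretical_envelope)
        if sim <= similarity_threshold:
            return False
    return True
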