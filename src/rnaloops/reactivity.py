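"""Normalization, classification, merging and MaP-rate computation.

These are the standard chemical-probing post-processing steps: box-plot
normalization with outlier removal, reactivity-class thresholds for SHAPE
(3 classes) and hydroxyl-radical footprinting (4 classes), averaging of
overlapping primer reads, slope-through-origin scaling between samples,
windowed reagent differencing, and mutational-profiling (MaP) rate
computation from modified/untreated counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DataError,
    FormatError,
    NormalizationError,
    ParameterError,
    ScalingError,
    StateError,
)
from .profiles import NORMALIZED, RAW, SCALED, ReactivityProfile


# ---------------------------------------------------------------------------
# Classification schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered reactivity class boundaries and labels.

    Boundary membership: intervals are closed on the left, and the top class
    is strictly above the last boundary. Hence for the SHAPE scheme a value of
    exactly 0.40 is "moderately reactive" and 0.85 is still "moderately
    reactive" (only values > 0.85 are "very reactive").
    """

    name: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ParameterError("boundaries must be strictly increasing")
        if len(self.labels) != len(self.boundaries) + 1:
            raise ParameterError("need exactly one more label than boundaries")

    def classify_value(self, value: float) -> str | None:
        if not np.isfinite(value):
            return None
        idx = int(np.searchsorted(self.boundaries, value, side="right"))
        if idx == len(self.boundaries) and value <= self.boundaries[-1]:
            idx -= 1  # exact top boundary stays in the class below
        return self.labels[idx]


SHAPE3 = ClassificationScheme(
    name="shape3",
    boundaries=(0.40, 0.85),
    labels=("not reactive", "moderately reactive", "very reactive"),
)

HRF4 = ClassificationScheme(
    name="hrf4",
    boundaries=(0.29, 0.58, 0.86),
    labels=(
        "not reactive",
        "poorly reactive",
        "moderately reactive",
        "very reactive",
    ),
)


def classify(profile: ReactivityProfile, scheme: ClassificationScheme = SHAPE3):
    """Per-position class labels (``None`` for NODATA). Requires a normalized profile."""
    if profile.state == RAW:
        raise StateError("classify requires a normalized (or scaled) profile")
    return [scheme.classify_value(v) for v in profile.values]


# ---------------------------------------------------------------------------
# Box-plot normalization
# ---------------------------------------------------------------------------

def normalize_boxplot(
    profile: ReactivityProfile,
    outlier_cap_fraction: float = 0.10,
    method: str = "boxplot",
) -> tuple[ReactivityProfile, float]:
    """Box-plot normalization with outlier removal.

    Outliers (values above Q3 + 1.5 IQR, capped at ``outlier_cap_fraction`` of
    the finite values) are excluded, the normalization factor is the mean of
    the top decile of the remaining values, and every finite value is divided
    by that factor. NODATA positions are preserved. With
    ``method="percentile_2_8"`` the factor is instead the mean of the values
    between the 2nd and 10th percentile from the top (the alternative SHAPE
    convention), with no IQR step.
    """
    finite = np.sort(profile.finite_values)
    n = finite.size
    if n < 10:
        raise NormalizationError(f"need >= 10 finite values, got {n}")

    if method == "boxplot":
        q1, q3 = np.percentile(finite, [25, 75])
        cutoff = q3 + 1.5 * (q3 - q1)
        n_out = int((finite > cutoff).sum())
        n_out = min(n_out, int(np.floor(outlier_cap_fraction * n)))
        survivors = finite[: n - n_out] if n_out else finite
        k = max(1, int(np.ceil(0.10 * survivors.size)))
        factor = float(survivors[-k:].mean())
    elif method == "percentile_2_8":
        lo = n - int(np.floor(0.10 * n))
        hi = n - int(np.floor(0.02 * n))
        if hi <= lo:
            raise NormalizationError("too few values for 2%/8% normalization")
        factor = float(finite[lo:hi].mean())
    else:
        raise ParameterError(f"unknown normalization method {method!r}")

    if not np.isfinite(factor) or factor <= 0:
        raise NormalizationError(f"non-positive normalization factor {factor}")
    out = profile.with_values(profile.values / factor, state=NORMALIZED)
    return out, factor


# ---------------------------------------------------------------------------
# Merging, scaling, differencing
# ---------------------------------------------------------------------------

def merge_primer_reads(
    profiles, offsets=None, length: int | None = None
) -> ReactivityProfile:
    """Average overlapping primer reads on a common coordinate system.

    Each profile covers positions ``offset + 1 .. offset + len(profile)``.
    Overlap positions take the arithmetic mean of the contributing finite
    values; positions covered once pass through; positions where every
    contribution is NODATA stay NODATA. The result is invariant to the order
    of the inputs.
    """
    profiles = list(profiles)
    if not profiles:
        raise DataError("no profiles to merge")
    if offsets is None:
        offsets = [0] * len(profiles)
    offsets = list(offsets)
    if len(offsets) != len(profiles):
        raise DataError("one offset per profile required")
    if any(o < 0 for o in offsets):
        raise DataError("offsets must be non-negative")
    total = length or max(o + p.length for o, p in zip(offsets, profiles))
    acc = np.zeros(total)
    cnt = np.zeros(total, dtype=np.int64)
    for profile, off in zip(profiles, offsets):
        vals = profile.values
        mask = np.isfinite(vals)
        sl = slice(off, off + profile.length)
        acc[sl][mask] += vals[mask]
        cnt[sl][mask] += 1
    merged = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return profiles[0].with_values(merged)


def scale_to_reference(
    target: ReactivityProfile, reference: ReactivityProfile
) -> tuple[ReactivityProfile, float]:
    """Scale ``target`` onto ``reference`` by a slope-through-origin factor.

    The factor minimizes ``sum((factor * t - r)^2)`` over positions finite in
    both profiles: ``factor = sum(t * r) / sum(t^2)``.
    """
    if target.length != reference.length:
        raise DataError("profiles must have equal length for scaling")
    common = target.finite_mask & reference.finite_mask
    if common.sum() < 10:
        raise ScalingError(f"only {int(common.sum())} common finite positions (< 10)")
    t = target.values[common]
    r = reference.values[common]
    denom = float((t * t).sum())
    if denom <= 0:
        raise ScalingError("target has zero norm on common positions")
    factor = float((t * r).sum() / denom)
    return target.with_values(target.values * factor, state=SCALED), factor


def smooth_centered(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean over finite values; NaN where no finite value in window."""
    if window < 1 or window % 2 == 0:
        raise ParameterError("window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(finite.astype(float), kernel, mode="same")
    return np.where(counts > 0.5, sums / np.maximum(counts, 1), np.nan)


def diff_by_window(
    a: ReactivityProfile, b: ReactivityProfile, window: int = 3
) -> ReactivityProfile:
    """Centered-window mean of (a - b), the standard reagent-differencing step."""
    if a.length != b.length:
        raise DataError("profiles must have equal length")
    diff = a.values - b.values
    return a.with_values(smooth_centered(diff, window), reagent=f"{a.reagent}-{b.reagent}")


# ---------------------------------------------------------------------------
# Mutational profiling (MaP)
# ---------------------------------------------------------------------------

@dataclass
class MapCounts:
    """Per-position mutation counts and read depths for modified and untreated channels."""

    modified_mutations: np.ndarray
    modified_depth: np.ndarray
    untreated_mutations: np.ndarray
    untreated_depth: np.ndarray

    def __post_init__(self):
        arrays = [
            np.asarray(a, dtype=np.int64)
            for a in (
                self.modified_mutations,
                self.modified_depth,
                self.untreated_mutations,
                self.untreated_depth,
            )
        ]
        lengths = {a.size for a in arrays}
        if len(lengths) != 1:
            raise FormatError("count arrays must share one length")
        if any((a < 0).any() for a in arrays):
            raise FormatError("counts and depths must be non-negative")
        if (arrays[0] > arrays[1]).any() or (arrays[2] > arrays[3]).any():
            raise FormatError("mutation counts cannot exceed depths")
        (
            self.modified_mutations,
            self.modified_depth,
            self.untreated_mutations,
            self.untreated_depth,
        ) = arrays

    @property
    def length(self) -> int:
        return self.modified_mutations.size

    def to_table(self) -> str:
        lines = ["# pos\tmod_mut\tmod_depth\tunt_mut\tunt_depth"]
        for i in range(self.length):
            lines.append(
                f"{i + 1}\t{self.modified_mutations[i]}\t{self.modified_depth[i]}"
                f"\t{self.untreated_mutations[i]}\t{self.untreated_depth[i]}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "MapCounts":
        rows = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise FormatError(f"line {lineno}: expected 5 columns")
            try:
                rows.append([int(f) for f in fields[:5]])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer count") from exc
        if not rows:
            raise FormatError("empty MaP count table")
        arr = np.asarray(rows, dtype=np.int64)
        order = np.argsort(arr[:, 0])
        arr = arr[order]
        return cls(arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])


def map_reactivity(
    counts: MapCounts, min_depth: int = 1000, reagent: str = "1M7"
) -> ReactivityProfile:
    """Raw MaP reactivity: modified mutation rate minus untreated mutation rate.

    Positions where either channel's depth is below ``min_depth`` become
    NODATA. Negative raw values (untreated rate above modified rate) are
    retained; they are removed or rescaled only at the normalization step.
    """
    if min_depth <= 0:
        raise ParameterError("min_depth must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_mod = counts.modified_mutations / np.maximum(counts.modified_depth, 1)
        rate_unt = counts.untreated_mutations / np.maximum(counts.untreated_depth, 1)
    raw = rate_mod - rate_unt
    low = (counts.modified_depth < min_depth) | (counts.untreated_depth < min_depth)
    raw = np.where(low, np.nan, raw)
    return ReactivityProfile(raw, reagent=reagent, state=RAW)
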