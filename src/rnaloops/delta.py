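"""In vivo vs ex vivo differential reactivity calling.

Implements a deltaSHAPE-style caller: both profiles are smoothed with a
centered window, the smoothed difference is screened by a Z-factor (which
requires the difference to exceed its combined measurement error) and by a
standard score (which requires the difference to stand out from the
transcript-wide distribution), and a site-level rule demands a minimum number
of passing positions within a window before any position is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError
from .profiles import ReactivityProfile
from .reactivity import smooth_centered

PROTECTED = "protected_in_vivo"
ENHANCED = "enhanced_in_vivo"


@dataclass(frozen=True)
class DeltaParams:
    """Constants of the differential caller.

    smoothing_window : centered mean window applied to both profiles (odd).
    site_window : window for the minimum-hit site rule (odd).
    min_hits : passing positions required within ``site_window``.
    z_multiplier : error multiplier in the Z-factor (1.96 ~ 95% confidence).
    score_cutoff : minimum |standard score| of the smoothed difference.
    """

    smoothing_window: int = 3
    site_window: int = 5
    min_hits: int = 3
    z_multiplier: float = 1.96
    score_cutoff: float = 1.0

    def __post_init__(self):
        for w in (self.smoothing_window, self.site_window):
            if w < 1 or w % 2 == 0:
                raise ParameterError("windows must be odd and >= 1")
        if self.min_hits > self.site_window:
            raise ParameterError("min_hits cannot exceed the site window")


@dataclass(frozen=True)
class DeltaCall:
    """One called position: difference, Z-factor, standard score, direction."""

    position: int
    delta: float
    z_factor: float
    standard_score: float
    direction: str


def smooth(profile: ReactivityProfile, window: int = 3) -> ReactivityProfile:
    """Centered moving mean over finite values (NODATA-aware)."""
    return profile.with_values(smooth_centered(profile.values, window))


def delta_call(
    ex_vivo: ReactivityProfile,
    in_vivo: ReactivityProfile,
    err_ex: np.ndarray,
    err_in: np.ndarray,
    params: DeltaParams | None = None,
) -> list[DeltaCall]:
    """Call protected/enhanced sites from an ex vivo / in vivo profile pair.

    For each position i, with smoothed profiles: ``delta_i = smooth(ex)_i -
    smooth(in)_i``; ``z_factor_i = 1 - z_multiplier * (err_ex_i + err_in_i) /
    |delta_i|``; ``standard_score_i = (delta_i - mean(delta)) / sd(delta)``.
    A position is called when its own Z-factor is positive and |standard
    score| >= cutoff, and at least ``min_hits`` positions within the centered
    site window also pass both criteria. ``delta > 0`` (more reactive ex
    vivo, i.e. after protein removal) is reported as protection in vivo.
    """
    params = params or DeltaParams()
    if ex_vivo.length != in_vivo.length:
        raise DataError("profiles must have equal length")
    err_ex = np.asarray(err_ex, dtype=float)
    err_in = np.asarray(err_in, dtype=float)
    if err_ex.size != ex_vivo.length or err_in.size != in_vivo.length:
        raise DataError("error arrays must match profile length")

    sm_ex = smooth_centered(ex_vivo.values, params.smoothing_window)
    sm_in = smooth_centered(in_vivo.values, params.smoothing_window)
    delta = sm_ex - sm_in

    finite = np.isfinite(delta)
    if finite.sum() == 0:
        raise DataError("no overlapping finite positions")
    sd = float(np.std(delta[finite]))
    if sd == 0:
        warnings.warn("zero variance of the difference profile; no calls made")
        return []
    mean = float(np.mean(delta[finite]))
    score = (delta - mean) / sd

    with np.errstate(divide="ignore", invalid="ignore"):
        z = 1.0 - params.z_multiplier * (err_ex + err_in) / np.abs(delta)
    passing = finite & (z > 0) & (np.abs(score) >= params.score_cutoff)

    kernel = np.ones(params.site_window)
    hits = np.convolve(passing.astype(float), kernel, mode="same")
    called = passing & (hits >= params.min_hits)

    calls = [
        DeltaCall(
            position=int(i) + 1,
            delta=float(delta[i]),
            z_factor=float(z[i]),
            standard_score=float(score[i]),
            direction=PROTECTED if delta[i] > 0 else ENHANCED,
        )
        for i in np.nonzero(called)[0]
    ]
    return calls


def calls_to_table(calls) -> str:
    lines = ["# position\tdelta\tz_factor\tstandard_score\tdirection"]
    for c in calls:
        lines.append(
            f"{c.position}\t{c.delta:.6g}\t{c.z_factor:.6g}"
            f"\t{c.standard_score:.6g}\t{c.direction}"
        )
    return "\n".join(lines) + "\n"


def merge_call_regions(calls, max_gap: int = 1) -> list[tuple[int, int, str]]:
    """Merge called positions into 1-based inclusive intervals per direction."""
    regions: list[tuple[int, int, str]] = []
    for direction in (PROTECTED, ENHANCED):
        positions = sorted(c.position for c in calls if c.direction == direction)
        start = prev = None
        for pos in positions:
            if start is None:
                start = prev = pos
            elif pos - prev <= max_gap:
                prev = pos
            else:
                regions.append((start, prev, direction))
                start = prev = pos
        if start is not None:
            regions.append((start, prev, direction))
    return sorted(regions)
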