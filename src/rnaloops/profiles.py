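"""Per-nucleotide probing profiles with an explicit no-data sentinel.

Values live in a float array with NaN marking NODATA internally, so arithmetic
can never silently use a missing value; on disk NODATA is encoded as -999, the
common convention of probing pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError

NODATA_SENTINEL = -999.0

RAW = "raw"
NORMALIZED = "normalized"
SCALED = "scaled"


@dataclass
class ReactivityProfile:
    """Per-position probing values for one transcript.

    Parameters
    ----------
    values : array of float
        One value per nucleotide (1-based position k stored at index k - 1);
        NaN marks NODATA.
    reagent : str
        Probing reagent label (1M7, 1M6, NMIA, DMS, HRF, ...).
    state : {"raw", "normalized", "scaled"}
        Processing state; normalized values are unitless.
    """

    values: np.ndarray
    reagent: str = "1M7"
    state: str = RAW
    replicates: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).copy()
        if self.values.ndim != 1:
            raise FormatError("profile values must be one-dimensional")
        if self.state not in (RAW, NORMALIZED, SCALED):
            raise FormatError(f"unknown profile state {self.state!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def length(self) -> int:
        return self.values.size

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def finite_values(self) -> np.ndarray:
        return self.values[self.finite_mask]

    def value_at(self, pos: int) -> float:
        """1-based access; returns NaN for NODATA."""
        return float(self.values[pos - 1])

    def with_values(self, values: np.ndarray, **kwargs) -> "ReactivityProfile":
        out = replace(self, **kwargs)
        out.values = np.asarray(values, dtype=float).copy()
        return out

    def mean(self) -> float:
        """Mean over finite positions (NODATA excluded from all statistics)."""
        finite = self.finite_values
        return float(finite.mean()) if finite.size else float("nan")


def read_reactivity_table(text: str, reagent: str = "1M7", state: str = RAW) -> ReactivityProfile:
    """Parse a two-column position/value table (``#`` comments allowed).

    Positions need not be contiguous: gaps are filled with NODATA. Duplicate
    positions and non-numeric values raise :class:`FormatError`.
    """
    entries: dict[int, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.replace(",", "\t").split()
        if len(fields) < 2:
            raise FormatError(f"line {lineno}: expected 'position value'")
        try:
            pos = int(fields[0])
            val = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric entry in {line!r}") from exc
        if pos < 1:
            raise FormatError(f"line {lineno}: positions are 1-based, got {pos}")
        if pos in entries:
            raise FormatError(f"line {lineno}: duplicate position {pos}")
        entries[pos] = val
    if not entries:
        raise FormatError("empty reactivity table")
    length = max(entries)
    values = np.full(length, np.nan)
    for pos, val in entries.items():
        values[pos - 1] = np.nan if val == NODATA_SENTINEL else val
    return ReactivityProfile(values, reagent=reagent, state=state)


def write_reactivity_table(profile: ReactivityProfile) -> str:
    lines = [f"# reagent={profile.reagent} state={profile.state}"]
    for pos, val in enumerate(profile.values, start=1):
        out = NODATA_SENTINEL if not np.isfinite(val) else val
        lines.append(f"{pos}\t{out:.6g}")
    return "\n".join(lines) + "\n"


def load_reactivity_table(path, **kwargs) -> ReactivityProfile:
    with open(path) as fh:
        return read_reactivity_table(fh.read(), **kwargs)


def save_reactivity_table(profile: ReactivityProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_reactivity_table(profile))


def replicate_stats(profiles) -> tuple[ReactivityProfile, np.ndarray]:
    """Position-wise mean profile and standard error across replicates.

    NODATA values are excluded position-wise; a position missing in every
    replicate stays NODATA (standard error NaN there).
    """
    profiles = list(profiles)
    if not profiles:
        raise FormatError("no replicates given")
    lengths = {p.length for p in profiles}
    if len(lengths) != 1:
        raise FormatError("replicates must share one length")
    stack = np.vstack([p.values for p in profiles])
    finite = np.isfinite(stack)
    n = finite.sum(axis=0)
    filled = np.where(finite, stack, 0.0)
    mean = np.where(n > 0, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    dev2 = np.where(finite, (stack - mean) ** 2, 0.0).sum(axis=0)
    sd = np.sqrt(np.where(n > 1, dev2 / np.maximum(n - 1, 1), 0.0))
    stderr = np.where(n > 0, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    out = profiles[0].with_values(mean)
    out.replicates = tuple(p.reagent for p in profiles)
    return out, stderr
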