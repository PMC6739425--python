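"""Single-particle AFM topography analytics.

Square height-map crops around individual particles are reduced to a
row-wise one-dimensional power spectral density (PSD), averaged over rows and
particles. Auto-affine regions of the averaged spectrum — ranges where
``PSD(f) = a0 * f**-gamma`` — are fitted by (optionally weighted) least
squares in log-log space, and the intersection of the low- and
high-frequency fits marks a characteristic spatial frequency f*; its inverse
is the characteristic length of the particle population.

Frequency convention: cycles/nm, so the characteristic length is L = 1/f*.
The angular (2*pi/k) convention is selectable and is recorded on the result,
since the two differ by a factor 2*pi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, FitError, ParameterError


@dataclass
class HeightMap:
    """A square AFM crop: heights in nm on a grid of known pixel size."""

    heights: np.ndarray
    pixel_size_nm: float

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise DataError("height map must be two-dimensional")
        if self.heights.shape[0] != self.heights.shape[1]:
            raise DataError("height-map crops must be square")
        if self.pixel_size_nm <= 0:
            raise ParameterError("pixel size must be positive")
        if not np.isfinite(self.heights).all():
            raise DataError("heights must be finite")

    @property
    def n_pixels(self) -> int:
        return self.heights.shape[0]

    @property
    def crop_nm(self) -> float:
        return self.n_pixels * self.pixel_size_nm

    def to_text(self) -> str:
        lines = [f"# pixel_size_nm: {self.pixel_size_nm}"]
        for row in self.heights:
            lines.append(" ".join(f"{v:.5g}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HeightMap":
        pixel = None
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "pixel_size_nm" in line:
                    pixel = float(line.split(":")[-1])
                continue
            rows.append([float(v) for v in line.split()])
        if pixel is None:
            raise DataError("missing '# pixel_size_nm:' header")
        return cls(np.asarray(rows), pixel)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path,
            self.heights.astype(np.float32),
            resolution=(1.0 / self.pixel_size_nm, 1.0 / self.pixel_size_nm),
        )

    @classmethod
    def from_tiff(cls, path, pixel_size_nm: float) -> "HeightMap":
        import tifffile

        return cls(tifffile.imread(path), pixel_size_nm)


@dataclass
class Spectrum:
    """Averaged one-sided PSD: frequency (cycles/nm) -> power (nm^2).

    Scaling: the power values over f > 0 sum to the mean per-row variance
    (discrete Parseval identity after per-row mean detrending).
    """

    frequency: np.ndarray
    power: np.ndarray

    def to_table(self) -> str:
        lines = ["# frequency_cycles_per_nm\tpower_nm2"]
        for f, p in zip(self.frequency, self.power):
            lines.append(f"{f:.8g}\t{p:.8g}")
        return "\n".join(lines) + "\n"


def compute_psd(maps, axis: str = "x") -> Spectrum:
    """Row-wise mean-detrended periodogram averaged over rows and particles.

    ``axis="x"`` analyses matrix rows (the fast scanning axis); ``axis="y"``
    analyses columns. All maps must share one pixel size.
    """
    maps = list(maps)
    if not maps:
        raise DataError("no height maps given")
    pixel_sizes = {m.pixel_size_nm for m in maps}
    if len(pixel_sizes) != 1:
        raise DataError(f"mixed pixel sizes: {sorted(pixel_sizes)}")
    if axis not in ("x", "y"):
        raise ParameterError("axis must be 'x' or 'y'")
    pixel = maps[0].pixel_size_nm
    n = maps[0].n_pixels
    if any(m.n_pixels != n for m in maps):
        raise DataError("all maps must share one raster size")

    freqs = np.fft.rfftfreq(n, d=pixel)
    accum = np.zeros(freqs.size)
    total_rows = 0
    for m in maps:
        data = m.heights if axis == "x" else m.heights.T
        rows = data - data.mean(axis=1, keepdims=True)
        spec = np.abs(np.fft.rfft(rows, axis=1)) ** 2 / n**2
        # one-sided scaling: double interior bins so sum over f>0 = row variance
        spec[:, 1:] *= 2.0
        if n % 2 == 0:
            spec[:, -1] /= 2.0
        accum += spec.sum(axis=0)
        total_rows += rows.shape[0]
    return Spectrum(frequency=freqs, power=accum / total_rows)


@dataclass
class PowerLawFit:
    """Weighted log-log fit of PSD(f) = a0 * f**-gamma over one frequency range."""

    amplitude: float
    gamma: float
    f_range: tuple[float, float]
    weighted_residual: float
    n_points: int

    def log10_at(self, log10_f: float) -> float:
        return np.log10(self.amplitude) - self.gamma * log10_f


@dataclass
class CharacteristicScale:
    """Crossover frequency of two auto-affine fits and its length scale."""

    crossover_frequency: float  # cycles/nm
    length_nm: float
    convention: str = "cycles (L = 1/f)"


def fit_power_law(
    spectrum: Spectrum, f_range: tuple[float, float], weights: np.ndarray | None = None
) -> PowerLawFit:
    """Least-squares line in log10-log10 space over ``f_range`` (inclusive)."""
    f, p = spectrum.frequency, spectrum.power
    mask = (f >= f_range[0]) & (f <= f_range[1]) & (f > 0) & (p > 0)
    if mask.sum() < 4:
        raise FitError(f"fit range {f_range} contains {int(mask.sum())} usable points (< 4)")
    x = np.log10(f[mask])
    y = np.log10(p[mask])
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)[mask]
    coeffs = np.polyfit(x, y, 1, w=np.sqrt(w))
    slope, intercept = coeffs[0], coeffs[1]
    resid = float((w * (y - (slope * x + intercept)) ** 2).sum())
    return PowerLawFit(
        amplitude=10**intercept,
        gamma=-slope,
        f_range=(float(f_range[0]), float(f_range[1])),
        weighted_residual=resid,
        n_points=int(mask.sum()),
    )


def crossover(low: PowerLawFit, high: PowerLawFit, convention: str = "cycles") -> CharacteristicScale:
    """Analytic intersection of two log-log lines -> characteristic scale."""
    dgamma = high.gamma - low.gamma
    if abs(dgamma) < 1e-6:
        raise FitError("fits are parallel; no crossover frequency")
    log_f = (np.log10(high.amplitude) - np.log10(low.amplitude)) / dgamma
    f_star = float(10**log_f)
    if convention == "cycles":
        return CharacteristicScale(f_star, 1.0 / f_star, "cycles (L = 1/f)")
    if convention == "angular":
        return CharacteristicScale(f_star, 2.0 * np.pi / f_star, "angular (L = 2*pi/k)")
    raise ParameterError("convention must be 'cycles' or 'angular'")


def estimate_noise_floor(spectrum: Spectrum) -> float:
    """White-noise floor level: median power of the top-quartile frequencies."""
    p = spectrum.power[spectrum.frequency > 0]
    return float(np.median(p[int(0.75 * p.size):]))


def subtract_floor(spectrum: Spectrum, guard: float = 0.2) -> Spectrum:
    """Floor-corrected spectrum: the additive white-noise level is estimated
    from the high-frequency tail and subtracted; bins within ``guard`` of the
    floor are dropped (set non-positive, hence excluded from log-log fits)."""
    floor = estimate_noise_floor(spectrum)
    corrected = spectrum.power - floor
    corrected[corrected <= guard * floor] = 0.0
    return Spectrum(spectrum.frequency, corrected)


def auto_fit_ranges(
    spectrum: Spectrum,
    plateau_drop: float = 10**-0.5,
    flank_hi: float = 1e-1,
    flank_lo: float = 1e-3,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Default fit ranges for a (floor-corrected) particle-population spectrum.

    The low-frequency (plateau) range covers frequencies whose power stays
    within ``plateau_drop`` of the plateau level; the high-frequency (flank)
    range covers the decade band ``[flank_lo, flank_hi]`` of power relative
    to the plateau.
    """
    pos = (spectrum.frequency > 0) & (spectrum.power > 0)
    f, p = spectrum.frequency[pos], spectrum.power[pos]
    if f.size < 8:
        raise FitError("spectrum has too few usable points")
    plateau = float(np.median(p[: max(3, int(0.02 * p.size))]))
    rel = p / plateau
    low_mask = rel >= plateau_drop
    first_break = int(np.argmin(low_mask)) if not low_mask.all() else low_mask.size
    low_range = (float(f[0]), float(f[max(first_break - 1, 3)]))
    flank_mask = (rel <= flank_hi) & (rel >= flank_lo)
    idx = np.nonzero(flank_mask)[0]
    if idx.size:
        # first contiguous stretch of the flank band, widened to >= 4 points
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        stop = int(idx[breaks[0]] if breaks.size else idx[-1])
        start = int(idx[0])
    else:
        start = stop = int(np.argmin(np.abs(rel - np.sqrt(flank_lo * flank_hi))))
    while stop - start + 1 < 4:
        if start > first_break:
            start -= 1
        elif stop < f.size - 1:
            stop += 1
        else:  # pragma: no cover
            break
    high_range = (float(f[start]), float(f[stop]))
    return low_range, high_range


def fit_autoaffine(
    spectrum: Spectrum,
    low_range: tuple[float, float] | None = None,
    high_range: tuple[float, float] | None = None,
    weights: np.ndarray | None = None,
    convention: str = "cycles",
    correct_floor: bool = True,
) -> tuple[PowerLawFit, PowerLawFit, CharacteristicScale]:
    """Fit the two auto-affine regions and report their crossover scale.

    By default the additive white-noise floor is subtracted first (see
    :func:`subtract_floor`). When ranges are omitted they are chosen by
    :func:`auto_fit_ranges` on the corrected spectrum. The fit x-ranges are
    part of the result (``f_range``) because the analysis is sensitive to
    them and they must be reported alongside any length.
    """
    work = subtract_floor(spectrum) if correct_floor else spectrum
    if low_range is None or high_range is None:
        auto_low, auto_high = auto_fit_ranges(work)
        low_range = low_range or auto_low
        high_range = high_range or auto_high
    low = fit_power_law(work, low_range, weights)
    high = fit_power_law(work, high_range, weights)
    scale = crossover(low, high, convention)
    return low, high, scale


def characteristic_length(maps, axis: str = "x", **kwargs) -> CharacteristicScale:
    """PSD -> auto-affine fits -> characteristic length, in one call."""
    spectrum = compute_psd(maps, axis=axis)
    _, _, scale = fit_autoaffine(spectrum, **kwargs)
    return scale


def percent_compaction(length_before: float, length_after: float) -> float:
    """Percent reduction of a characteristic length: 100*(L0 - L1)/L0."""
    if length_before <= 0 or length_after <= 0:
        raise ParameterError("lengths must be positive")
    return 100.0 * (length_before - length_after) / length_before
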