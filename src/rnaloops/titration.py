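"""Hill-type Mg2+ titration analysis of hydration radii.

RNA tertiary folding is driven by Mg2+; sedimentation experiments report the
hydration (Stokes) radius R_h as a function of Mg2+ concentration. The
folding isotherm is modelled by the Hill form

    R_h(c) = R_inf + (R_0 - R_inf) / (1 + (c / C_half)**n)

where R_0 is the extended-state radius at low Mg2+, R_inf the compact-state
radius at saturation, C_half the folding-transition midpoint (the
concentration where R_h is exactly halfway), and n the Hill coefficient
(cooperativity). Percent compaction is 100*(R_0 - R_inf)/R_0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

from .errors import FitError, ParameterError


@dataclass
class TitrationCurve:
    """R_h (nm) measured over a series of Mg2+ concentrations (mM)."""

    concentrations_mM: np.ndarray
    radii_nm: np.ndarray

    def __post_init__(self):
        self.concentrations_mM = np.asarray(self.concentrations_mM, dtype=float)
        self.radii_nm = np.asarray(self.radii_nm, dtype=float)
        if self.concentrations_mM.size == 0:
            raise ParameterError("empty concentration list")
        if self.concentrations_mM.size != self.radii_nm.size:
            raise ParameterError("concentration/radius arrays must match")
        if (self.concentrations_mM <= 0).any():
            raise ParameterError("concentrations must be positive (log-scale data)")

    def to_table(self) -> str:
        lines = ["# concentration_mM\tR_h_nm"]
        for c, r in zip(self.concentrations_mM, self.radii_nm):
            lines.append(f"{c:.6g}\t{r:.6g}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_table(cls, text: str) -> "TitrationCurve":
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, r = line.split()[:2]
            rows.append((float(c), float(r)))
        arr = np.asarray(rows)
        return cls(arr[:, 0], arr[:, 1])


def hill_radius(c, r0, r_inf, c_half, n):
    """The Hill folding isotherm for R_h(c)."""
    c = np.asarray(c, dtype=float)
    return r_inf + (r0 - r_inf) / (1.0 + (c / c_half) ** n)


@dataclass
class HillFit:
    """Results of a Hill-isotherm fit.

    Carries the four parameter estimates, their standard errors (from the
    fit covariance), the derived percent compaction, and diagnostic flags.
    """

    r0: float
    r_inf: float
    c_half_mM: float
    n_hill: float
    stderr: dict = field(default_factory=dict)
    residual_sd: float = 0.0
    direction: str = "compaction"
    c_half_in_range: bool = True
    curve: TitrationCurve | None = None

    @property
    def percent_compaction(self) -> float:
        return 100.0 * (self.r0 - self.r_inf) / self.r0

    def predict(self, concentrations) -> np.ndarray:
        return hill_radius(concentrations, self.r0, self.r_inf, self.c_half_mM, self.n_hill)

    def summary(self) -> str:
        lines = [
            "Hill titration fit",
            "------------------",
            f"R_h,0        : {self.r0:8.3f} nm  (se {self.stderr.get('r0', float('nan')):.3f})",
            f"R_h,inf      : {self.r_inf:8.3f} nm  (se {self.stderr.get('r_inf', float('nan')):.3f})",
            f"C_Mg1/2      : {self.c_half_mM:8.4f} mM  (se {self.stderr.get('c_half', float('nan')):.4f})",
            f"Hill n       : {self.n_hill:8.3f}     (se {self.stderr.get('n', float('nan')):.3f})",
            f"compaction   : {self.percent_compaction:8.2f} %",
            f"direction    : {self.direction}",
            f"midpoint in data range: {self.c_half_in_range}",
            f"residual sd  : {self.residual_sd:.4f} nm",
        ]
        return "\n".join(lines)


def fit_hill(curve: TitrationCurve, p0: dict | None = None) -> HillFit:
    """Nonlinear least-squares fit of the Hill isotherm to a titration curve.

    Requires at least 5 concentration points. A rising trend (expansion
    rather than compaction) is flagged but still fitted. The midpoint is
    flagged when it falls outside the measured concentration range.
    """
    c = curve.concentrations_mM
    r = curve.radii_nm
    if c.size < 5:
        raise ParameterError(f"need >= 5 concentration points, got {c.size}")
    order = np.argsort(c)
    c, r = c[order], r[order]

    lo, hi = float(r.min()), float(r.max())
    if hi - lo < 1e-12:
        raise FitError("degenerate titration: radii do not change")
    rho = spearmanr(c, r).statistic
    direction = "expansion" if rho > 0 else "compaction"
    mid = 0.5 * (lo + hi)
    guess_c = float(c[np.argmin(np.abs(r - mid))])
    defaults = {
        "r0": float(r[0]),
        "r_inf": float(r[-1]),
        "c_half": guess_c,
        "n": 1.0,
    }
    if p0:
        defaults.update(p0)
    start = [defaults["r0"], defaults["r_inf"], defaults["c_half"], defaults["n"]]
    try:
        popt, pcov = curve_fit(
            hill_radius,
            c,
            r,
            p0=start,
            maxfev=20000,
            bounds=([0, 0, 1e-9, 0.05], [np.inf, np.inf, np.inf, 20.0]),
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    resid = r - hill_radius(c, *popt)
    dof = max(c.size - 4, 1)
    return HillFit(
        r0=float(popt[0]),
        r_inf=float(popt[1]),
        c_half_mM=float(popt[2]),
        n_hill=float(popt[3]),
        stderr={
            "r0": float(perr[0]),
            "r_inf": float(perr[1]),
            "c_half": float(perr[2]),
            "n": float(perr[3]),
        },
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
        direction=direction,
        c_half_in_range=bool(c.min() <= popt[2] <= c.max()),
        curve=curve,
    )


def compare_constructs(fit_a: HillFit, fit_b: HillFit) -> float:
    """Saturation-radius difference of b relative to a, in percent.

    Positive means construct b stays larger at saturation, i.e. compacts
    less than construct a (the sign convention used for mutant-vs-wild-type
    comparisons). Antisymmetric under swapping a and b only up to the change
    of reference; exact antisymmetry holds for the log-ratio at small
    differences.
    """
    return 100.0 * (fit_b.r_inf - fit_a.r_inf) / fit_a.r_inf
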