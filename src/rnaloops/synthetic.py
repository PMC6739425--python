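"""Seeded generators for every input class the pipeline consumes.

The generators emulate the statistical structure the analysis assumes — a
structured transcript with a hairpin-loop motif and distal complementary
tandem repeats, structure-conditioned probing reactivities, binomial
mutational-profiling counts, in vivo / ex vivo profile pairs with planted
protection windows, star-phylogeny alignments with planted covariation,
single-particle AFM topographies in three folding states, and Hill-shaped
Mg2+ titration curves — so that every stage of the pipeline is testable
without experimental data. All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .afm import HeightMap
from .errors import LayoutError, ParameterError
from .profiles import NORMALIZED, ReactivityProfile
from .pseudoknot import (
    KissingRegister,
    count_motif_repeats,
    find_hairpin_loops,
    pair_type,
)
from .reactivity import MapCounts
from .structure import SecondaryStructure
from .titration import TitrationCurve, hill_radius
from .transcript import _COMPLEMENT

_BASES = np.array(list("ACGU"))


# ---------------------------------------------------------------------------
# Core transcript generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoreLayout:
    """Blueprint of a synthetic structured core.

    ``stems`` are ((s1, e1), (s2, e2)) pairs of 1-based inclusive intervals
    paired antiparallel (s1..e1 with e2..s2). The loop motif sits inside a
    hairpin loop; ``n_repeats`` copies of its wobble-aware reverse complement
    are planted back-to-back (``repeat_spacing`` spacer nucleotides apart)
    at the start of the single-stranded ``repeat_region``. ``wobble_at``
    lists 0-based motif offsets whose planted partner uses a G.U wobble
    instead of the Watson-Crick base.
    """

    total_length: int = 320
    stems: tuple = (
        ((31, 42), (51, 62)),
        ((80, 87), (92, 99)),
        ((230, 237), (242, 249)),
    )
    loop_motif: str = "GUGAG"
    motif_position: int = 44
    n_repeats: int = 6
    repeat_region: tuple[int, int] = (170, 199)
    repeat_spacing: int = 0
    wobble_at: tuple[int, ...] = ()

    def __post_init__(self):
        n = self.total_length
        occupied = np.zeros(n + 1, dtype=bool)
        for (s1, e1), (s2, e2) in self.stems:
            if not (1 <= s1 <= e1 < s2 <= e2 <= n):
                raise LayoutError(f"stem ({s1},{e1})/({s2},{e2}) out of order or bounds")
            if e1 - s1 != e2 - s2:
                raise LayoutError("stem sides must have equal length")
            for a, b in ((s1, e1), (s2, e2)):
                if occupied[a : b + 1].any():
                    raise LayoutError("stems overlap")
                occupied[a : b + 1] = True
        k = len(self.loop_motif)
        ms, me = self.motif_position, self.motif_position + k - 1
        if not self._motif_in_hairpin_loop():
            raise LayoutError("loop motif must lie inside a hairpin loop of the plan")
        rs, re = self.repeat_region
        if not (1 <= rs <= re <= n):
            raise LayoutError("repeat region out of bounds")
        if occupied[rs : re + 1].any():
            raise LayoutError("repeat region must be single-stranded in the plan")
        if self.n_repeats < 0:
            raise LayoutError("n_repeats must be >= 0")
        needed = self.n_repeats * k + max(self.n_repeats - 1, 0) * self.repeat_spacing
        if needed > re - rs + 1:
            raise LayoutError(
                f"repeat region too short: need {needed} nt, have {re - rs + 1}"
            )
        if any(not 0 <= w < k for w in self.wobble_at):
            raise LayoutError("wobble offsets must index into the motif")
        if any(self.loop_motif[w] not in "GU" for w in self.wobble_at):
            raise LayoutError("wobble offsets must sit on G or U motif bases")

    def _motif_in_hairpin_loop(self) -> bool:
        k = len(self.loop_motif)
        ms, me = self.motif_position, self.motif_position + k - 1
        for (s1, e1), (s2, e2) in self.stems:
            loop_lo, loop_hi = e1 + 1, s2 - 1
            if loop_lo <= ms and me <= loop_hi:
                # hairpin: no other stem inside the loop
                inside = any(
                    loop_lo <= a1 and b2 <= loop_hi
                    for (a1, b1), (a2, b2) in self.stems
                    if ((a1, b1), (a2, b2)) != ((s1, e1), (s2, e2))
                )
                return not inside
        return False

    @property
    def motif_interval(self) -> tuple[int, int]:
        return (self.motif_position, self.motif_position + len(self.loop_motif) - 1)

    def hairpin_loop_interval(self) -> tuple[int, int]:
        k = len(self.loop_motif)
        ms, me = self.motif_position, self.motif_position + k - 1
        for (s1, e1), (s2, e2) in self.stems:
            if e1 + 1 <= ms and me <= s2 - 1:
                return (e1 + 1, s2 - 1)
        raise LayoutError("motif not inside any loop")  # pragma: no cover

    def repeat_unit(self) -> str:
        """Wobble-aware reverse complement of the loop motif (the planted TR)."""
        k = len(self.loop_motif)
        unit = [""] * k
        for t, base in enumerate(self.loop_motif):
            partner = _COMPLEMENT[base]
            if t in self.wobble_at:
                partner = "U" if base == "G" else "G"
            unit[k - 1 - t] = partner
        return "".join(unit)

    def repeat_starts(self) -> list[int]:
        k = len(self.loop_motif)
        rs = self.repeat_region[0]
        return [rs + i * (k + self.repeat_spacing) for i in range(self.n_repeats)]


def meg3_like_layout() -> CoreLayout:
    """A 1,595-nt layout mirroring the published repeat architecture:

    a hairpin whose loop (nt 366-373) carries GUGAG at 368-372, and six
    tandem repeats starting at nt 857 in a distal single-stranded region.
    """
    return CoreLayout(
        total_length=1595,
        stems=(
            ((240, 250), (255, 265)),
            ((356, 365), (374, 383)),
            ((480, 492), (497, 509)),
            ((700, 710), (715, 725)),
            ((1000, 1012), (1017, 1029)),
        ),
        loop_motif="GUGAG",
        motif_position=368,
        n_repeats=6,
        repeat_region=(857, 886),
        repeat_spacing=0,
    )


def _plan_structure(layout: CoreLayout) -> SecondaryStructure:
    pairs = set()
    for (s1, e1), (s2, e2) in layout.stems:
        for off in range(e1 - s1 + 1):
            pairs.add((s1 + off, e2 - off))
    return SecondaryStructure(layout.total_length, pairs)


def _ground_truth_registers(layout: CoreLayout) -> list[KissingRegister]:
    k = len(layout.loop_motif)
    ms = layout.motif_position
    registers = []
    for idx, rs in enumerate(layout.repeat_starts()):
        pairs = []
        for t in range(k):
            typ = "wobble" if t in layout.wobble_at else "WC"
            pairs.append((ms + t, rs + k - 1 - t, typ))
        registers.append(
            KissingRegister(
                loop_interval=(ms, ms + k - 1),
                repeat_interval=(rs, rs + k - 1),
                pairs=tuple(pairs),
                label=f"TR{idx + 1}",
                group=0,
            )
        )
    return registers


def _matches_window(seq: list[str], motif: str, start0: int, allow_wobble=True) -> bool:
    k = len(motif)
    for t in range(k):
        if pair_type(motif[t], seq[start0 + k - 1 - t], allow_wobble) is None:
            return False
    return True


def gen_core(
    layout: CoreLayout | None = None, seed: int = 0
) -> tuple[str, SecondaryStructure, list[KissingRegister]]:
    """Generate (sequence, ground-truth structure, planted registers).

    The random background is scrubbed so that no *accidental* single-stranded
    window is complementary to any hairpin-loop window: the only kissing-loop
    registers present are the planted ones.
    """
    layout = layout or CoreLayout()
    rng = np.random.default_rng(seed)
    n = layout.total_length
    seq = list(rng.choice(_BASES, n))
    structure = _plan_structure(layout)

    # enforce stem complementarity (3' side = reverse complement of 5' side)
    for (s1, e1), (s2, e2) in layout.stems:
        for off in range(e1 - s1 + 1):
            seq[e2 - 1 - off] = _COMPLEMENT[seq[s1 - 1 + off]]

    # plant the loop motif
    for t, base in enumerate(layout.loop_motif):
        seq[layout.motif_position - 1 + t] = base

    # plant the repeats
    unit = layout.repeat_unit()
    k = len(unit)
    planted_windows = set()
    for rs in layout.repeat_starts():
        for t, base in enumerate(unit):
            seq[rs - 1 + t] = base
        planted_windows.add(rs)

    # scrub accidental complementary windows against every loop window
    table = structure.pair_table()
    unpaired = table[1:] == 0
    loop_windows = []
    for lo, hi in find_hairpin_loops(structure):
        for s in range(lo, hi - k + 2):
            loop_windows.append(s)
    motif_lo, motif_hi = layout.motif_interval
    protected = np.zeros(n, dtype=bool)  # positions the scrub must not touch
    for (s1, e1), (s2, e2) in layout.stems:
        protected[s1 - 1 : e1] = True
        protected[s2 - 1 : e2] = True
    protected[motif_lo - 1 : motif_hi] = True
    for rs in layout.repeat_starts():
        protected[rs - 1 : rs + k - 1] = True

    for _ in range(400):
        dirty = False
        for ls in loop_windows:
            motif_win = "".join(seq[ls - 1 : ls + k - 1])
            for s in range(1, n - k + 2):
                if not unpaired[s - 1 : s + k - 1].all():
                    continue
                if ls == motif_lo and s in planted_windows:
                    continue
                if abs(s - ls) < k:  # self-overlap
                    continue
                if _matches_window(seq, motif_win, s - 1):
                    free = [
                        q for q in range(s - 1, s + k - 1) if not protected[q]
                    ]
                    if not free:
                        free = [
                            q
                            for q in range(ls - 1, ls + k - 1)
                            if not protected[q]
                        ]
                    if not free:
                        raise LayoutError(
                            "cannot scrub accidental complement: all positions fixed"
                        )
                    q = free[int(rng.integers(len(free)))]
                    choices = [b for b in "ACGU" if b != seq[q]]
                    seq[q] = choices[int(rng.integers(3))]
                    dirty = True
        if not dirty:
            break
    else:  # pragma: no cover
        raise LayoutError("scrub did not converge")

    registers = _ground_truth_registers(layout)
    return "".join(seq), structure, registers


# ---------------------------------------------------------------------------
# Reactivity and MaP-count simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Structure-conditioned reactivity noise.

    Paired positions draw from an exponential with mean ``paired_mean``;
    unpaired positions from a gamma with ``unpaired_shape``/``unpaired_scale``
    (mean = shape*scale). Either can be switched to a noiseless constant at
    its mean. Values are clipped at ``clip`` and a ``nodata_fraction`` of
    positions is masked NODATA.
    """

    paired_mean: float = 0.15
    unpaired_shape: float = 2.0
    unpaired_scale: float = 0.5
    paired_model: str = "exponential"
    unpaired_model: str = "gamma"
    nodata_fraction: float = 0.05
    clip: float = 4.0
    seed: int = 0

    @property
    def unpaired_mean(self) -> float:
        return self.unpaired_shape * self.unpaired_scale

    def __post_init__(self):
        if not 0 <= self.nodata_fraction < 1:
            raise ParameterError("nodata_fraction must be in [0, 1)")
        if self.unpaired_mean <= self.paired_mean:
            raise ParameterError("expected unpaired value must exceed paired value")
        for m in (self.paired_model, self.unpaired_model):
            if m not in ("exponential", "gamma", "constant"):
                raise ParameterError(f"unknown noise model {m!r}")


def simulate_reactivity(
    structure: SecondaryStructure,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> ReactivityProfile:
    """Structure-conditioned reactivity profile (non-negative, clipped)."""
    noise = noise or NoiseModel()
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    n = structure.length
    paired = structure.pair_table()[1:] > 0
    values = np.empty(n)

    def draw(model, mean, shape, scale, size):
        if model == "constant":
            return np.full(size, mean)
        if model == "exponential":
            return rng.exponential(mean, size)
        return rng.gamma(shape, scale, size)

    values[paired] = draw(
        noise.paired_model, noise.paired_mean, 1.0, noise.paired_mean, int(paired.sum())
    )
    values[~paired] = draw(
        noise.unpaired_model,
        noise.unpaired_mean,
        noise.unpaired_shape,
        noise.unpaired_scale,
        int((~paired).sum()),
    )
    values = np.clip(values, 0.0, noise.clip)
    if noise.nodata_fraction > 0:
        values[rng.random(n) < noise.nodata_fraction] = np.nan
    return ReactivityProfile(values, reagent="1M7", state=NORMALIZED)


def simulate_map_counts(
    profile: ReactivityProfile,
    depth: int = 100_000,
    background: float = 0.002,
    slope: float = 0.02,
    seed: int = 0,
) -> MapCounts:
    """Binomial MaP counts from a reactivity profile.

    The modified-channel mutation rate is ``background + slope * reactivity``
    (background alone at NODATA positions); the untreated channel mutates at
    the background rate. Both channels are sequenced to ``depth``.
    """
    if depth < 0:
        raise ParameterError("depth must be >= 0")
    rates = background + slope * np.where(profile.finite_mask, profile.values, 0.0)
    if (rates < 0).any() or (rates > 0.5).any():
        raise ParameterError("mutation rates must stay within [0, 0.5]")
    rng = np.random.default_rng(seed)
    n = profile.length
    depths = np.full(n, depth, dtype=np.int64)
    mod = rng.binomial(depths, rates)
    unt = rng.binomial(depths, np.full(n, background))
    return MapCounts(mod, depths, unt, depths.copy())


def simulate_protection_pair(
    base: ReactivityProfile | int,
    windows=((0, 0, 0.0),),
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """An (ex vivo, in vivo) profile pair with planted protection windows.

    ``windows`` holds (start, end, delta) 1-based inclusive intervals: the ex
    vivo profile (probed after protein removal) gains ``delta`` there,
    emulating sites protected by protein in vivo. Returns
    (ex_profile, in_profile, err_ex, err_in) with constant per-position
    standard errors equal to ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(base, ReactivityProfile):
        base_values = base.values.copy()
    else:
        base_values = rng.uniform(0.1, 1.0, int(base))
    n = base_values.size
    ex = base_values.copy()
    for start, end, delta in windows:
        if start < 1 or end > n:
            raise ParameterError(f"window ({start},{end}) outside 1..{n}")
        ex[start - 1 : end] += delta
    iv = base_values + rng.normal(0.0, noise_sd, n)
    ex = ex + rng.normal(0.0, noise_sd, n)
    ex = np.clip(ex, 0.0, None)
    iv = np.clip(iv, 0.0, None)
    err = np.full(n, noise_sd)
    return (
        ReactivityProfile(ex, reagent="1M7", state=NORMALIZED),
        ReactivityProfile(iv, reagent="1M7", state=NORMALIZED),
        err,
        err.copy(),
    )


# ---------------------------------------------------------------------------
# Star-phylogeny alignment with planted covariation
# ---------------------------------------------------------------------------

_CANONICAL_LIST = ["AU", "UA", "GC", "CG", "GU", "UG"]


def simulate_alignment(
    core,
    n_species: int = 41,
    sub_prob: float = 0.10,
    covary_prob: float = 0.90,
    repeat_count_range: tuple[int, int] = (3, 6),
    seed: int = 0,
):
    """Star-phylogeny alignment around a generated core.

    Each species descends independently from the core sequence. Paired
    columns substitute with probability ``sub_prob``; a substituted pair
    co-substitutes to a new canonical pair with probability ``covary_prob``
    (otherwise only the 5' partner changes, breaking the pair). Unpaired,
    unconstrained columns substitute independently. The loop motif is kept
    invariant, and each species keeps a number of tandem repeats drawn from
    ``repeat_count_range`` (remaining repeat copies are scrambled).

    Returns (MultipleSeqAlignment with an SS_cons annotation, metadata dict
    with per-species repeat counts).
    """
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .structure import write_dotbracket

    sequence, structure, registers = core
    if n_species < 2:
        raise ParameterError("need at least 2 species")
    lo, hi = repeat_count_range
    if lo < 1 or hi < lo:
        raise ParameterError("repeat_count_range must satisfy 1 <= min <= max")
    if hi > len(registers):
        raise ParameterError("repeat_count_range exceeds the planted repeat count")
    rng = np.random.default_rng(seed)
    n = len(sequence)
    nested = sorted(structure.nested_pairs())
    paired_cols = {i for p in nested for i in p}
    motif_cols = set()
    repeat_cols_by_register = []
    for reg in registers:
        motif_cols.update(range(reg.loop_interval[0], reg.loop_interval[1] + 1))
        repeat_cols_by_register.append(
            list(range(reg.repeat_interval[0], reg.repeat_interval[1] + 1))
        )

    records = []
    repeat_counts = {}
    for s in range(n_species):
        row = list(sequence)
        # paired-column evolution
        for i, j in nested:
            if rng.random() < sub_prob:
                current = row[i - 1] + row[j - 1]
                # a planted co-substitution replaces both partners, so the new
                # canonical pair must differ from the old one at both columns
                options = [
                    p
                    for p in _CANONICAL_LIST
                    if p[0] != current[0] and p[1] != current[1]
                ]
                new = options[int(rng.integers(len(options)))]
                if rng.random() < covary_prob:
                    row[i - 1], row[j - 1] = new[0], new[1]
                else:
                    row[i - 1] = new[0]
        # unpaired, unconstrained columns
        all_repeat_cols = {c for cols in repeat_cols_by_register for c in cols}
        for col in range(1, n + 1):
            if col in paired_cols or col in motif_cols or col in all_repeat_cols:
                continue
            if rng.random() < sub_prob:
                choices = [b for b in "ACGU" if b != row[col - 1]]
                row[col - 1] = choices[int(rng.integers(3))]
        # repeat-count variation: keep the first r repeats, scramble the rest
        r = int(rng.integers(lo, hi + 1))
        for reg_cols in repeat_cols_by_register[r:]:
            for col in reg_cols:
                choices = [b for b in "ACGU" if b != row[col - 1]]
                row[col - 1] = choices[int(rng.integers(3))]
        # make sure scrambling did not recreate a repeat
        motif = sequence[
            registers[0].loop_interval[0] - 1 : registers[0].loop_interval[1]
        ]
        region_lo = min(c for cols in repeat_cols_by_register for c in cols)
        region_hi = max(c for cols in repeat_cols_by_register for c in cols)
        for _ in range(50):
            if count_motif_repeats("".join(row[region_lo - 1 : region_hi]), motif) <= r:
                break
            scram = [
                c - 1
                for cols in repeat_cols_by_register[r:]
                for c in cols
            ]
            q = scram[int(rng.integers(len(scram)))]
            choices = [b for b in "ACGU" if b != row[q]]
            row[q] = choices[int(rng.integers(3))]
        repeat_counts[f"species_{s + 1:02d}"] = r
        records.append(
            SeqRecord(Seq("".join(row)), id=f"species_{s + 1:02d}", description="")
        )
    alignment = MultipleSeqAlignment(records)
    alignment.column_annotations["secondary_structure"] = write_dotbracket(structure)
    return alignment, {"repeat_counts": repeat_counts}


# ---------------------------------------------------------------------------
# AFM topographies
# ---------------------------------------------------------------------------

def _stamp_dome(img, coords_nm, cx, cy, sigma, height):
    xx, yy = coords_nm
    img += height * np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2)) / (2 * sigma**2))


def simulate_heightmap(
    kind: str,
    pixel_size_nm: float = 0.98,
    crop_nm: float = 250.0,
    diameter_nm: float = 30.0,
    height_nm: float = 1.5,
    n_domes: int = 3,
    envelope_nm: float = 85.0,
    noise_sd_nm: float = 0.02,
    seed: int = 0,
) -> HeightMap:
    """Synthetic single-particle AFM crop.

    compact: one Gaussian dome; the particle diameter is its apparent
    footprint, defined as 5 sigma of the Gaussian (where the dome has decayed
    to ~4% of its peak, i.e. into the background). intermediate: a chain of
    ``n_domes`` domes of ``diameter_nm`` spread across an ``envelope_nm``
    envelope. denatured: a thin meandering filament. White pixel noise of
    ``noise_sd_nm`` is added.
    """
    npix = int(np.floor(crop_nm / pixel_size_nm))
    if npix < 64:
        raise ParameterError("crop must span at least 64 pixels")
    rng = np.random.default_rng(seed)
    axis = (np.arange(npix) + 0.5) * pixel_size_nm
    xx, yy = np.meshgrid(axis, axis)
    img = np.zeros((npix, npix))
    centre = crop_nm / 2.0
    sigma = diameter_nm / 5.0

    if kind == "compact":
        jitter = rng.uniform(-5, 5, 2)
        _stamp_dome(img, (xx, yy), centre + jitter[0], centre + jitter[1], sigma, height_nm)
    elif kind == "intermediate":
        if n_domes < 2:
            raise ParameterError("intermediate particles need >= 2 domes")
        angle = rng.uniform(0, np.pi)
        span = max(envelope_nm - diameter_nm, 1.0)
        offsets = np.linspace(-span / 2, span / 2, n_domes)
        for off in offsets:
            cx = centre + off * np.cos(angle) + rng.normal(0, 2)
            cy = centre + off * np.sin(angle) + rng.normal(0, 2)
            _stamp_dome(img, (xx, yy), cx, cy, sigma, height_nm * rng.uniform(0.8, 1.2))
    elif kind == "denatured":
        length_nm = 200.0
        step = 2.0
        n_steps = int(length_nm / step)
        heading = rng.uniform(0, 2 * np.pi)
        x, y = centre + rng.uniform(-30, 30), centre + rng.uniform(-30, 30)
        width_sigma = 3.0
        for _ in range(n_steps):
            heading += rng.normal(0, 0.25)
            x = np.clip(x + step * np.cos(heading), 10, crop_nm - 10)
            y = np.clip(y + step * np.sin(heading), 10, crop_nm - 10)
            _stamp_dome(img, (xx, yy), x, y, width_sigma, 0.12)
        img = np.clip(img, 0, 0.45)  # thin filament: low, flat-topped
    else:
        raise ParameterError(f"unknown particle kind {kind!r}")

    img += rng.normal(0.0, noise_sd_nm, img.shape)
    return HeightMap(img, pixel_size_nm)


# ---------------------------------------------------------------------------
# Titration curves
# ---------------------------------------------------------------------------

def simulate_titration(
    r0: float = 12.0,
    r_inf: float = 9.6,
    c_half: float = 1.0,
    n_hill: float = 2.0,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Hill-shaped R_h vs [Mg2+] curve over a log-spaced 0.01-100 mM grid."""
    if not (r0 > r_inf > 0):
        raise ParameterError("require R0 > Rinf > 0")
    if c_half <= 0:
        raise ParameterError("C_half must be positive")
    if concentrations is None:
        concentrations = np.logspace(-2, 2, 12)
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size == 0:
        raise ParameterError("empty concentration list")
    rng = np.random.default_rng(seed)
    values = hill_radius(concentrations, r0, r_inf, c_half, n_hill)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.size)
    return TitrationCurve(concentrations, values)
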