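"""Probing-directed secondary-structure prediction.

The energy model is a simplified nearest-neighbour scheme: a stacking-energy
table keyed by adjacent pair types, affine hairpin/bulge/internal-loop
penalties, an affine multiloop term, and an optional per-paired-nucleotide
pseudo-energy ``m*ln(S+1) + b`` derived from chemical-probing reactivities
(the Deigan-style restraint used by probing-directed folding software). The
same model drives three computations that must agree exactly:

* :func:`structure_energy` — the model definition, evaluated on an explicit
  pair set by loop decomposition;
* :func:`fold_mfe` — a Zuker-style dynamic program whose minimum equals the
  exhaustive minimum of :func:`structure_energy` over all nested structures;
* :func:`pair_probabilities` — a McCaskill-style partition function with an
  inside-outside pass yielding exact base-pair probabilities and
  per-nucleotide Shannon entropies (log base 10) under the same model.

The model is deliberately not the full Turner rule set: every term is a
replaceable parameter of :class:`FoldingParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, ParameterError, SequenceError
from .profiles import ReactivityProfile
from .structure import NESTED, SecondaryStructure
from .transcript import clean_rna

INF = float("inf")

CANONICAL = {"AU", "UA", "GC", "CG", "GU", "UG"}
WOBBLE = {"GU", "UG"}

_PAIR_STRENGTH = {"GC": 2.2, "CG": 2.2, "AU": 1.1, "UA": 1.1, "GU": 0.7, "UG": 0.7}


def default_stack_table() -> dict[tuple[str, str], float]:
    """Stacking energies (kcal/mol) for adjacent canonical pairs.

    Built from per-pair strengths so that GC-rich stacks are most stable;
    values are negative for every canonical stack.
    """
    table = {}
    for outer, s_out in _PAIR_STRENGTH.items():
        for inner, s_in in _PAIR_STRENGTH.items():
            table[(outer, inner)] = -0.5 * (s_out + s_in)
    return table


@dataclass
class FoldingParams:
    """Tunable terms of the simplified nearest-neighbour model (kcal/mol)."""

    stack: dict[tuple[str, str], float] = field(default_factory=default_stack_table)
    hairpin_base: float = 3.0
    hairpin_per_nt: float = 0.1
    bulge_base: float = 3.2
    bulge_per_nt: float = 0.3
    internal_base: float = 2.2
    internal_per_nt: float = 0.3
    multi_base: float = 3.4
    multi_branch: float = 0.4
    multi_unpaired: float = 0.1
    min_hairpin: int = 3
    max_internal: int = 30
    slope: float = 2.6       # pseudo-energy m
    intercept: float = -0.8  # pseudo-energy b
    kT: float = 0.6163       # temperature-equivalent scale for probabilities
    prob_length_cap: int = 2000

    def __post_init__(self):
        if self.min_hairpin < 3:
            raise ParameterError("min hairpin loop must be >= 3")
        if self.slope < 0:
            raise ParameterError("pseudo-energy slope m must be >= 0")
        if self.kT <= 0:
            raise ParameterError("kT must be positive")
        for key, value in self.stack.items():
            if key[0] in CANONICAL and key[1] in CANONICAL and value > 0:
                raise ParameterError(f"stacking energy for {key} must be <= 0")


def pseudo_energy(reactivity: float, params: FoldingParams | None = None) -> float:
    """Per-paired-nucleotide pseudo-energy ``m*ln(S+1) + b``; 0 for NODATA."""
    params = params or FoldingParams()
    if reactivity is None or (isinstance(reactivity, float) and math.isnan(reactivity)):
        return 0.0
    if reactivity < -0.3:
        raise DataError(f"reactivity {reactivity} below plausible noise floor (-0.3)")
    return params.slope * math.log(reactivity + 1.0) + params.intercept


def _pseudo_vector(n: int, profile: ReactivityProfile | None, params: FoldingParams):
    if profile is None:
        return np.zeros(n)
    if profile.length != n:
        raise DataError("profile length does not match sequence")
    return np.array([pseudo_energy(v, params) for v in profile.values])


def _pair_str(seq: str, i: int, j: int) -> str:
    return seq[i] + seq[j]


def _loop_children(pairs: list[tuple[int, int]]):
    """Map each pair (0-based) to its directly enclosed pairs; returns
    (children dict, exterior list). Input pairs must be non-crossing."""
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    exterior: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in sorted(pairs, key=lambda q: (q[0], -q[1])):
        while stack and stack[-1][1] < p[0]:
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            exterior.append(p)
        stack.append(p)
    return children, exterior


def structure_energy(
    sequence: str,
    pairs,
    params: FoldingParams | None = None,
    profile: ReactivityProfile | None = None,
) -> float:
    """Energy of an explicit nested structure under the model (kcal/mol).

    Returns +inf for structures the model forbids (non-canonical pairs or
    hairpin loops shorter than the minimum). Pairs are 1-based (i, j) tuples.
    """
    params = params or FoldingParams()
    seq = clean_rna(sequence)
    ps = _pseudo_vector(len(seq), profile, params)
    pairs0 = sorted((min(i, j) - 1, max(i, j) - 1) for i, j in pairs)
    for i, j in pairs0:
        if _pair_str(seq, i, j) not in CANONICAL or j - i - 1 < params.min_hairpin:
            return INF
    children, _ = _loop_children(pairs0)
    energy = 0.0
    for (i, j), ch in children.items():
        energy += ps[i] + ps[j]
        if not ch:
            energy += params.hairpin_base + params.hairpin_per_nt * (j - i - 1)
        elif len(ch) == 1:
            k, l = ch[0]
            l1, l2 = k - i - 1, j - l - 1
            if l1 == 0 and l2 == 0:
                energy += params.stack[(_pair_str(seq, i, j), _pair_str(seq, k, l))]
            elif l1 == 0 or l2 == 0:
                energy += params.bulge_base + params.bulge_per_nt * (l1 + l2)
            else:
                energy += params.internal_base + params.internal_per_nt * (l1 + l2)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in ch)
            energy += (
                params.multi_base
                + params.multi_branch * (len(ch) + 1)
                + params.multi_unpaired * unpaired
            )
    return float(energy)


# ---------------------------------------------------------------------------
# Zuker-style MFE dynamic program
# ---------------------------------------------------------------------------

class _Arrays:
    """Shared DP preparation: pairability mask and interior-loop penalties."""

    def __init__(self, sequence: str, profile, params: FoldingParams):
        self.params = params
        self.seq = clean_rna(sequence)
        self.n = len(self.seq)
        self.ps = _pseudo_vector(self.n, profile, params)
        n, p = self.n, params
        idx = np.array([{"A": 0, "C": 1, "G": 2, "U": 3}[b] for b in self.seq])
        canon = np.zeros((4, 4), dtype=bool)
        for pair in CANONICAL:
            canon[
                "ACGU".index(pair[0]), "ACGU".index(pair[1])
            ] = True
        self.pairable = canon[idx[:, None], idx[None, :]]
        span_ok = (np.arange(n)[None, :] - np.arange(n)[:, None]) > p.min_hairpin
        self.pairable &= span_ok
        cap = p.max_internal
        a = np.arange(cap + 1)
        total = a[:, None] + a[None, :]
        pen = np.where(
            (a[:, None] == 0) | (a[None, :] == 0),
            p.bulge_base + p.bulge_per_nt * total,
            p.internal_base + p.internal_per_nt * total,
        ).astype(float)
        pen[total > cap] = INF
        pen[0, 0] = INF  # the stack case is handled separately per pair type
        self.interior_pen = pen

    def stack_energy(self, i: int, j: int, k: int, l: int) -> float:
        return self.params.stack[(_pair_str(self.seq, i, j), _pair_str(self.seq, k, l))]


def _mfe_matrices(arr: _Arrays):
    n, p = arr.n, arr.params
    cap = p.max_internal
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    WM2 = np.full((n, n), INF)
    b, c = p.multi_branch, p.multi_unpaired
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            # --- V ---
            if arr.pairable[i, j]:
                best = p.hairpin_base + p.hairpin_per_nt * (j - i - 1)
                A = min(cap + 1, j - i - 1)
                if A > 0:
                    kmax = i + A          # k in i+1 .. i+A
                    block = V[i + 1 : kmax + 1, j - A : j][:, ::-1]
                    cand = block + arr.interior_pen[:A, :A]
                    m = cand.min() if cand.size else INF
                    if m < best:
                        best = m
                if arr.pairable[i + 1, j - 1] and V[i + 1, j - 1] < INF:
                    best = min(best, V[i + 1, j - 1] + arr.stack_energy(i, j, i + 1, j - 1))
                if j - 1 > i + 1 and WM2[i + 1, j - 1] < INF:
                    best = min(best, p.multi_base + b + WM2[i + 1, j - 1])
                V[i, j] = arr.ps[i] + arr.ps[j] + best
            # --- WM / WM2 ---
            wm = WM[i, j - 1] + c if j > i else INF
            ks = np.arange(i, j + 1)
            vcol = V[i : j + 1, j]
            prefix = np.empty(j - i + 1)
            prefix[0] = 0.0
            if j > i:
                prefix[1:] = np.minimum(WM[i, i : j], c * (ks[1:] - i))
            cand = prefix + vcol + b
            wm = min(wm, cand.min())
            WM[i, j] = wm
            wm2 = WM2[i, j - 1] + c if j > i else INF
            if j > i:
                cand2 = WM[i, i : j] + vcol[1:] + b
                m2 = cand2.min() if cand2.size else INF
                wm2 = min(wm2, m2)
            WM2[i, j] = wm2
    return V, WM, WM2


def _traceback(arr: _Arrays, V, WM, WM2, W) -> list[tuple[int, int]]:
    n, p = arr.n, arr.params
    cap = p.max_internal
    b, c = p.multi_branch, p.multi_unpaired
    tol = 1e-7
    pairs: list[tuple[int, int]] = []
    stack: list[tuple[str, int, int]] = [("W", 0, n - 1)]
    while stack:
        state, i, j = stack.pop()
        if state == "W":
            while j >= i:
                if j > i and abs(W[j] - W[j - 1]) < tol:
                    j -= 1
                    continue
                found = False
                for k in range(i, j + 1):
                    left = W[k - 1] if k > 0 else 0.0
                    if V[k, j] < INF and abs(left + V[k, j] - W[j]) < tol:
                        stack.append(("V", k, j))
                        j = k - 1
                        found = True
                        break
                if not found:
                    j -= 1
        elif state == "V":
            pairs.append((i, j))
            base = V[i, j] - arr.ps[i] - arr.ps[j]
            if abs(base - (p.hairpin_base + p.hairpin_per_nt * (j - i - 1))) < tol:
                continue
            if (
                arr.pairable[i + 1, j - 1]
                and V[i + 1, j - 1] < INF
                and abs(base - (V[i + 1, j - 1] + arr.stack_energy(i, j, i + 1, j - 1))) < tol
            ):
                stack.append(("V", i + 1, j - 1))
                continue
            done = False
            for l1 in range(0, min(cap, j - i - 2) + 1):
                k = i + 1 + l1
                for l2 in range(0 if l1 else 1, min(cap - l1, j - k - 1) + 1):
                    l = j - 1 - l2
                    if l <= k or V[k, l] >= INF:
                        continue
                    pen = arr.interior_pen[l1, l2]
                    if pen < INF and abs(base - (V[k, l] + pen)) < tol:
                        stack.append(("V", k, l))
                        done = True
                        break
                if done:
                    break
            if done:
                continue
            if j - 1 > i + 1 and abs(base - (p.multi_base + b + WM2[i + 1, j - 1])) < tol:
                stack.append(("WM2", i + 1, j - 1))
                continue
            raise AssertionError("traceback failed in V")  # pragma: no cover
        elif state in ("WM", "WM2"):
            M = WM if state == "WM" else WM2
            target = M[i, j]
            if j > i and abs(M[i, j - 1] + c - target) < tol:
                stack.append((state, i, j - 1))
                continue
            done = False
            kmin = i if state == "WM" else i + 1
            for k in range(kmin, j + 1):
                if V[k, j] >= INF:
                    continue
                # all-unpaired prefix (only admissible for WM)
                if state == "WM" and abs(c * (k - i) + V[k, j] + b - target) < tol:
                    stack.append(("V", k, j))
                    done = True
                    break
                if (
                    k > i
                    and WM[i, k - 1] < INF
                    and abs(WM[i, k - 1] + V[k, j] + b - target) < tol
                ):
                    stack.append(("V", k, j))
                    stack.append(("WM", i, k - 1))
                    done = True
                    break
            if not done:  # pragma: no cover
                raise AssertionError(f"traceback failed in {state}")
    return pairs


def fold_mfe(
    sequence: str,
    profile: ReactivityProfile | None = None,
    params: FoldingParams | None = None,
) -> tuple[SecondaryStructure, float]:
    """Minimum-free-energy nested structure under the simplified model.

    The returned energy equals the exhaustive minimum of
    :func:`structure_energy` over all nested structures (the empty structure,
    at energy 0, is always admissible).
    """
    params = params or FoldingParams()
    seq = clean_rna(sequence)
    if not seq:
        raise SequenceError("empty sequence")
    n = len(seq)
    if n < params.min_hairpin + 2:
        return SecondaryStructure(n), 0.0
    arr = _Arrays(seq, profile, params)
    V, WM, WM2 = _mfe_matrices(arr)
    W = np.zeros(n)
    for j in range(n):
        best = W[j - 1] if j > 0 else 0.0
        vcol = V[0 : j + 1, j]
        lefts = np.concatenate(([0.0], W[:j]))
        W[j] = min(best, float((lefts + vcol).min()))
    energy = float(W[n - 1])
    pairs0 = _traceback(arr, V, WM, WM2, W)
    pairs = {(i + 1, j + 1) for i, j in pairs0}
    structure = SecondaryStructure(n, pairs, {(i + 1, j + 1): NESTED for i, j in pairs0})
    return structure, energy


# ---------------------------------------------------------------------------
# McCaskill-style partition function and pair probabilities
# ---------------------------------------------------------------------------

@dataclass
class PairProbabilityMatrix:
    """Base-pair probabilities, unpaired probabilities and Shannon entropies.

    ``p[i, j]`` (0-based, i < j) is the probability that nucleotides i+1 and
    j+1 pair; ``p_unpaired[i] = 1 - sum_j p[i, j]``; ``entropy[i]`` is the
    Shannon entropy (log base 10) of position i+1 over the outcomes
    {each pairing partner, unpaired}.
    """

    p: np.ndarray
    p_unpaired: np.ndarray
    entropy: np.ndarray
    log_z: float

    @property
    def length(self) -> int:
        return self.p_unpaired.size

    def pair_probability(self, i: int, j: int) -> float:
        """1-based accessor."""
        a, b = min(i, j) - 1, max(i, j) - 1
        return float(self.p[a, b])

    def to_sparse_tsv(self, threshold: float = 1e-6) -> str:
        lines = ["# i\tj\tprobability"]
        n = self.length
        for i in range(n):
            for j in range(i + 1, n):
                if self.p[i, j] >= threshold:
                    lines.append(f"{i + 1}\t{j + 1}\t{self.p[i, j]:.8g}")
        return "\n".join(lines) + "\n"


def pair_probabilities(
    sequence: str,
    profile: ReactivityProfile | None = None,
    params: FoldingParams | None = None,
) -> PairProbabilityMatrix:
    """Exact Boltzmann pair probabilities under the same energy model as
    :func:`fold_mfe`, via an inside-outside computation."""
    params = params or FoldingParams()
    seq = clean_rna(sequence)
    n = len(seq)
    if n == 0:
        raise SequenceError("empty sequence")
    if n > params.prob_length_cap:
        raise ParameterError(
            f"sequence length {n} exceeds probability cap {params.prob_length_cap}"
        )
    arr = _Arrays(seq, profile, params)
    p = params
    kT = p.kT
    cap = p.max_internal

    def w(x: float) -> float:
        return math.exp(-x / kT)

    wb = w(p.multi_branch)
    wa = w(p.multi_base)
    u1 = w(p.multi_unpaired)
    wps = np.exp(-arr.ps / kT)
    w_interior = np.exp(
        -np.where(np.isinf(arr.interior_pen), np.inf, arr.interior_pen) / kT
    )  # exp(-inf) -> 0

    QB = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM2 = np.zeros((n, n))
    upow = u1 ** np.arange(n + 1)

    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            if arr.pairable[i, j]:
                total = w(p.hairpin_base + p.hairpin_per_nt * (j - i - 1))
                A = min(cap + 1, j - i - 1)
                if A > 0:
                    block = QB[i + 1 : i + 1 + A, j - A : j][:, ::-1]
                    total += float((block * w_interior[:A, :A]).sum())
                if arr.pairable[i + 1, j - 1]:
                    total += QB[i + 1, j - 1] * w(arr.stack_energy(i, j, i + 1, j - 1))
                if j - 1 > i + 1:
                    total += wa * wb * QM2[i + 1, j - 1]
                QB[i, j] = wps[i] * wps[j] * total
            # QM1(k, j) = sum_l QB[k, l] * wb * u^(j-l); build QM/QM2 from it
            ks = np.arange(i, j + 1)
            # vector of QM1[k][j] for k in i..j
            # computed on the fly: QM1[k][j] = sum over l of QB[k, l] u^{j-l} wb
            qm1 = np.zeros(j - i + 1)
            for t, k in enumerate(ks):
                row = QB[k, k : j + 1]
                if row.any():
                    qm1[t] = wb * float((row * upow[j - np.arange(k, j + 1)]).sum())
            prefix_unpaired = upow[ks - i]
            prefix_branch = np.zeros(j - i + 1)
            if j > i:
                prefix_branch[1:] = QM[i, i : j]
            QM[i, j] = float(((prefix_unpaired + prefix_branch) * qm1).sum())
            QM2[i, j] = float((prefix_branch * qm1).sum())

    Q = np.ones(n + 1)  # Q[t] = partition of prefix 1..t (Q[0] = 1)
    for j in range(n):
        total = Q[j]
        for i in range(j + 1):
            if QB[i, j] > 0:
                total += Q[i] * QB[i, j]
        Q[j + 1] = total
    Z = Q[n]

    Qrev = np.ones(n + 2)  # Qrev[t] = partition of suffix t..n (1-based t)
    for i in range(n - 1, -1, -1):
        total = Qrev[i + 2]
        for j in range(i, n):
            if QB[i, j] > 0:
                total += QB[i, j] * Qrev[j + 2]
        Qrev[i + 1] = total

    pairable_list = [
        (i, j) for i in range(n) for j in range(i + 1, n) if arr.pairable[i, j]
    ]
    pairable_list.sort(key=lambda q: q[1] - q[0], reverse=True)

    P = np.zeros((n, n))
    for i, j in pairable_list:
        if QB[i, j] == 0:
            continue
        total = Q[i] * QB[i, j] * Qrev[j + 2] / Z
        for h, l in pairable_list:
            if not (h < i and l > j) or QB[h, l] == 0 or P[h, l] == 0:
                continue
            coef = P[h, l] / QB[h, l] * wps[h] * wps[l]
            l1, l2 = i - h - 1, l - j - 1
            if l1 + l2 <= cap:
                if l1 == 0 and l2 == 0:
                    wint = w(arr.stack_energy(h, l, i, j))
                else:
                    wint = w_interior[l1, l2] if l1 <= cap and l2 <= cap else 0.0
                total += coef * wint * QB[i, j]
            left_u = upow[l1]
            right_u = upow[l2]
            left_m = QM[h + 1, i - 1] if i - 1 >= h + 1 else 0.0
            right_m = QM[j + 1, l - 1] if l - 1 >= j + 1 else 0.0
            ways = left_m * right_u + left_u * right_m + left_m * right_m
            total += coef * wa * wb * wb * QB[i, j] * ways
        P[i, j] = total

    p_unpaired = 1.0 - (P.sum(axis=1) + P.sum(axis=0))
    entropy = np.zeros(n)
    for i in range(n):
        probs = np.concatenate((P[i, :], P[:, i], [p_unpaired[i]]))
        probs = probs[probs > 0]
        entropy[i] = float(-(probs * np.log10(probs)).sum())
    return PairProbabilityMatrix(
        p=P, p_unpaired=p_unpaired, entropy=entropy, log_z=math.log(Z)
    )
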