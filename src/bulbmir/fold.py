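"""RNA hairpin folding and stem-loop validation.

Implements a deliberately simple, fully declared nearest-neighbour energy
model so that every fold is exactly reproducible and brute-force checkable:

* stacked pair (pair (i,j) with (i+1,j-1) also paired), keyed by the outer
  pair type: GC/CG -3.0, AU/UA -2.0, GU/UG -1.0 kcal/mol;
* isolated pair (no adjacent pair on either side): half its stack energy;
* hairpin loop: +4.0 initiation, +0.5 per unpaired nucleotide beyond 3;
* every other loop (bulge, internal, multibranch): +2.0 initiation,
  +0.3 per unpaired nucleotide;
* exterior unpaired nucleotides are free;
* minimum hairpin loop of 3 (every pair spans >= 4 nucleotides);
* no pseudoknots.

Energies are handled internally as integers in units of 0.1 kcal/mol, so
dynamic programming, re-scoring and exhaustive enumeration agree exactly.
The O(n^3) fill is compiled with numba; traceback runs in plain Python with
a fixed deterministic option order (minimum energy, then maximum pairs,
then a leftmost-pairing exploration order), making outputs bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .seqio import gc_percent as _gc_percent

MIN_FOLD_LEN = 10
MAX_FOLD_LEN = 2000
MIN_HAIRPIN_LOOP = 3

_INF = np.int32(10**8)

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# deci-kcal stack energies keyed by (5' base, 3' base) of the outer pair
_STACK = np.full((4, 4), 0, dtype=np.int32)
_STACK[_ENCODE["G"], _ENCODE["C"]] = -30
_STACK[_ENCODE["C"], _ENCODE["G"]] = -30
_STACK[_ENCODE["A"], _ENCODE["U"]] = -20
_STACK[_ENCODE["U"], _ENCODE["A"]] = -20
_STACK[_ENCODE["G"], _ENCODE["U"]] = -10
_STACK[_ENCODE["U"], _ENCODE["G"]] = -10

_CAN_PAIR = _STACK != 0

_HAIRPIN_INIT = 40
_HAIRPIN_PER_NT = 5  # per unpaired nt beyond MIN_HAIRPIN_LOOP
_LOOP_INIT = 20
_LOOP_PER_NT = 3


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[c] for c in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid residue {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True)
class HairpinFold:
    """A sequence with its minimum-energy structure in dot-bracket form."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure length must equal sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    def pair_partner(self) -> list[Optional[int]]:
        return _partners(self.structure)

    def as_text(self) -> str:
        return f"{self.sequence}\n{self.structure} ({self.mfe:.1f})"


@dataclass
class PrecursorCandidate:
    """An excised transcript window folded as a candidate pre-miRNA."""

    source_id: str
    window: tuple[int, int]  # 0-based half-open on the transcript
    fold: HairpinFold
    mature: tuple[int, int]  # window coordinates, half-open
    star: Optional[tuple[int, int]]
    amfe: float
    mfei: Optional[float]
    gc_percent: float

    @property
    def mature_sequence(self) -> str:
        return self.fold.sequence[self.mature[0]:self.mature[1]]


def _partners(structure: str) -> list[Optional[int]]:
    stack: list[int] = []
    partner: list[Optional[int]] = [None] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return partner


def pairs_to_dotbracket(pairs, length: int) -> str:
    s = ["."] * length
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def structure_energy(sequence: str, structure: str) -> float:
    """Score a given structure under the declared model.

    Serves as the consistency oracle for fold_mfe: the returned energy of the
    folder's own structure always equals its reported MFE.
    """
    enc = _encode(sequence)
    partner = _partners(structure)
    n = len(sequence)
    if len(partner) != n:
        raise ValueError("structure length must equal sequence length")

    pairs = [(i, j) for i, j in enumerate(partner) if j is not None and i < j]
    for i, j in pairs:
        if not _CAN_PAIR[enc[i], enc[j]]:
            raise ValueError(f"illegal pair {sequence[i]}:{sequence[j]} at ({i},{j})")
        if j - i < MIN_HAIRPIN_LOOP + 1:
            raise ValueError(f"hairpin loop below {MIN_HAIRPIN_LOOP} at ({i},{j})")

    energy = 0
    paired = {i for p in pairs for i in p}
    for i, j in pairs:
        stacked_inside = partner[i + 1] == j - 1 if i + 1 < j - 1 else False
        if stacked_inside:
            energy += int(_STACK[enc[i], enc[j]])
        stacked_outside = (
            i > 0 and j < n - 1 and partner[i - 1] == j + 1
        )
        if not stacked_inside and not stacked_outside:
            energy += int(_STACK[enc[i], enc[j]]) // 2
        # classify the loop closed by (i, j)
        branches = 0
        unpaired = 0
        k = i + 1
        while k < j:
            if partner[k] is not None:
                branches += 1
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if branches == 0:
            energy += _HAIRPIN_INIT + _HAIRPIN_PER_NT * max(0, unpaired - MIN_HAIRPIN_LOOP)
        elif branches == 1 and unpaired == 0:
            pass  # a stack, scored above
        else:
            energy += _LOOP_INIT + _LOOP_PER_NT * unpaired
    del paired
    return energy / 10.0


@njit(cache=True)
def _fill(enc, stack_tbl, can_pair):  # pragma: no cover - exercised via fold_mfe
    n = enc.shape[0]
    INF = 10**8
    e_out = np.full((n, n), INF, dtype=np.int64)
    p_out = np.zeros((n, n), dtype=np.int64)
    e_free = np.full((n, n), INF, dtype=np.int64)
    p_free = np.zeros((n, n), dtype=np.int64)
    e_wm = np.full((n, n), INF, dtype=np.int64)
    p_wm = np.zeros((n, n), dtype=np.int64)

    for span in range(4, n):
        for i in range(0, n - span):
            j = i + span
            if can_pair[enc[i], enc[j]]:
                st = stack_tbl[enc[i], enc[j]]
                iso = st // 2
                # hairpin
                u = j - i - 1
                eh = 40 + 5 * max(0, u - 3)
                ph = 1
                # stack on (i+1, j-1)
                es = INF
                ps = 0
                if j - 1 - (i + 1) >= 4 and can_pair[enc[i + 1], enc[j - 1]]:
                    if e_out[i + 1, j - 1] < INF:
                        es = st + e_out[i + 1, j - 1]
                        ps = 1 + p_out[i + 1, j - 1]
                # any other loop (bulge / internal / multibranch)
                el = INF
                pl = 0
                if e_wm[i + 1, j - 1] < INF:
                    el = 20 + e_wm[i + 1, j - 1]
                    pl = 1 + p_wm[i + 1, j - 1]
                # V_out: (i, j) stacked from outside -> never isolated
                be, bp = eh, ph
                if es < be or (es == be and ps > bp):
                    be, bp = es, ps
                if el < be or (el == be and pl > bp):
                    be, bp = el, pl
                e_out[i, j], p_out[i, j] = be, bp
                # V_free: isolated bonus unless the inner stack is chosen
                be, bp = eh + iso, ph
                if es < be or (es == be and ps > bp):
                    be, bp = es, ps
                eli = el + iso if el < INF else INF
                if eli < be or (eli == be and pl > bp):
                    be, bp = eli, pl
                e_free[i, j], p_free[i, j] = be, bp

            # WM: >=1 branch in [i..j], unpaired nucleotides at 0.3 each
            be, bp = INF, 0
            if e_free[i, j] < INF:
                be, bp = e_free[i, j], p_free[i, j]
            if e_wm[i + 1, j] < INF:
                e = e_wm[i + 1, j] + 3
                p = p_wm[i + 1, j]
                if e < be or (e == be and p > bp):
                    be, bp = e, p
            if e_wm[i, j - 1] < INF:
                e = e_wm[i, j - 1] + 3
                p = p_wm[i, j - 1]
                if e < be or (e == be and p > bp):
                    be, bp = e, p
            for k in range(i, j):
                if e_wm[i, k] < INF and e_wm[k + 1, j] < INF:
                    e = e_wm[i, k] + e_wm[k + 1, j]
                    p = p_wm[i, k] + p_wm[k + 1, j]
                    if e < be or (e == be and p > bp):
                        be, bp = e, p
            e_wm[i, j], p_wm[i, j] = be, bp

    # small spans: WM stays INF; fill WM for spans < 4 already INF by init
    e_w = np.zeros(n + 1, dtype=np.int64)  # exterior, e_w[t] over prefix [0..t-1]
    p_w = np.zeros(n + 1, dtype=np.int64)
    for t in range(1, n + 1):
        j = t - 1
        be, bp = e_w[t - 1], p_w[t - 1]  # j unpaired, free
        for i in range(0, j - 3):
            if e_free[i, j] < INF:
                e = e_w[i] + e_free[i, j]
                p = p_w[i] + p_free[i, j]
                if e < be or (e == be and p > bp):
                    be, bp = e, p
        e_w[t], p_w[t] = be, bp
    return e_out, p_out, e_free, p_free, e_wm, p_wm, e_w, p_w


class _Tracer:
    """Reconstructs one optimal structure from the filled DP tables."""

    def __init__(self, enc, tables):
        self.enc = enc
        (self.e_out, self.p_out, self.e_free, self.p_free,
         self.e_wm, self.p_wm, self.e_w, self.p_w) = tables
        self.n = enc.shape[0]
        self.pairs: list[tuple[int, int]] = []

    def _can(self, i, j):
        return j - i >= 4 and _CAN_PAIR[self.enc[i], self.enc[j]]

    def trace_w(self):
        t = self.n
        while t > 0:
            j = t - 1
            target = (self.e_w[t], self.p_w[t])
            chosen = False
            for i in range(0, j - 3):
                if self.e_free[i, j] < _INF:
                    cand = (self.e_w[i] + self.e_free[i, j],
                            self.p_w[i] + self.p_free[i, j])
                    if cand == target:
                        self.trace_v(i, j, stacked_outside=False)
                        t = i
                        chosen = True
                        break
            if not chosen:
                t -= 1  # j left unpaired

    def trace_v(self, i, j, stacked_outside):
        self.pairs.append((i, j))
        enc = self.enc
        st = int(_STACK[enc[i], enc[j]])
        iso = 0 if stacked_outside else st // 2
        e_tbl = self.e_out if stacked_outside else self.e_free
        p_tbl = self.p_out if stacked_outside else self.p_free
        target = (e_tbl[i, j], p_tbl[i, j])
        # option order: stack, loop, hairpin
        if self._can(i + 1, j - 1) and self.e_out[i + 1, j - 1] < _INF:
            cand = (st + self.e_out[i + 1, j - 1], 1 + self.p_out[i + 1, j - 1])
            if cand == target:
                self.trace_v(i + 1, j - 1, stacked_outside=True)
                return
        if self.e_wm[i + 1, j - 1] < _INF:
            cand = (20 + self.e_wm[i + 1, j - 1] + iso, 1 + self.p_wm[i + 1, j - 1])
            if cand == target:
                self.trace_wm(i + 1, j - 1)
                return
        u = j - i - 1
        cand = (40 + 5 * max(0, u - 3) + iso, 1)
        if cand == target:
            return  # hairpin loop, nothing inside
        raise AssertionError("traceback failed to match DP tables")

    def trace_wm(self, i, j):
        target = (self.e_wm[i, j], self.p_wm[i, j])
        if self.e_free[i, j] < _INF and \
                (self.e_free[i, j], self.p_free[i, j]) == target:
            self.trace_v(i, j, stacked_outside=False)
            return
        for k in range(i, j):
            if self.e_wm[i, k] < _INF and self.e_wm[k + 1, j] < _INF:
                cand = (self.e_wm[i, k] + self.e_wm[k + 1, j],
                        self.p_wm[i, k] + self.p_wm[k + 1, j])
                if cand == target:
                    self.trace_wm(i, k)
                    self.trace_wm(k + 1, j)
                    return
        if self.e_wm[i + 1, j] < _INF and \
                (self.e_wm[i + 1, j] + 3, self.p_wm[i + 1, j]) == target:
            self.trace_wm(i + 1, j)
            return
        if self.e_wm[i, j - 1] < _INF and \
                (self.e_wm[i, j - 1] + 3, self.p_wm[i, j - 1]) == target:
            self.trace_wm(i, j - 1)
            return
        raise AssertionError("traceback failed to match DP tables")


def fold_mfe(sequence: str) -> HairpinFold:
    """Fold a sequence to its minimum-energy non-crossing structure.

    Deterministic: ties are broken toward more pairs, then by a fixed
    leftmost-pairing traceback order.
    """
    n = len(sequence)
    if n < MIN_FOLD_LEN:
        raise ValueError("too short to fold")
    if n > MAX_FOLD_LEN:
        raise ValueError(f"sequence longer than {MAX_FOLD_LEN} nt")
    enc = _encode(sequence)
    tables = _fill(enc, _STACK, _CAN_PAIR)
    e_w = tables[6]
    tracer = _Tracer(enc, tables)
    tracer.trace_w()
    structure = pairs_to_dotbracket(tracer.pairs, n)
    mfe = e_w[n] / 10.0
    fold = HairpinFold(sequence=sequence, structure=structure, mfe=mfe)
    # internal consistency: the reported MFE re-scores exactly
    assert abs(structure_energy(sequence, structure) - mfe) < 1e-9
    return fold


def enumerate_structures(sequence: str):
    """Yield every legal non-crossing pair set for a short sequence.

    Brute-force reference for testing; exponential, keep sequences short.
    """
    enc = _encode(sequence)
    n = len(enc)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def region(i: int, j: int) -> tuple:
        if j - i < 4:
            return ((),)
        out = list(region(i + 1, j))  # i unpaired
        for k in range(i + 4, j + 1):
            if _CAN_PAIR[enc[i], enc[k]]:
                for inner in region(i + 1, k - 1):
                    for outer in region(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return tuple(out)

    yield from region(0, n - 1)


def amfe_mfei(fold: HairpinFold) -> tuple[float, Optional[float], float]:
    """Adjusted MFE (energy per 100 nt) and the minimal folding energy index.

    AMFE = (MFE / length) * 100; MFEI = AMFE / (G+C)% with GC on the 0-100
    scale. MFEI is None (undefined) for a GC-free sequence.
    """
    amfe = fold.mfe / len(fold) * 100.0
    gc = _gc_percent(fold.sequence)
    mfei = amfe / gc if gc > 0 else None
    return amfe, mfei, gc


#: maximum nucleotides a mature may reach past its last paired position into
#: the terminal loop before the star is considered undefined
MAX_LOOP_OVERLAP = 4


def star_of(fold: HairpinFold, mature: tuple[int, int]) -> Optional[tuple[int, int]]:
    """Derive the miRNA* interval from the duplex geometry of the fold.

    The star is the region pairing with the mature, shifted to leave the
    canonical 2-nt 3' overhang on each duplex strand. Absent when fewer than
    60% of mature positions are paired, when pairing partners fall on both
    sides of the mature (spanning the terminal loop), or when the mature
    runs more than 4 nt past its duplex into the terminal loop.
    """
    m0, m1 = mature
    n = len(fold)
    if not (0 <= m0 < m1 <= n):
        raise ValueError("mature interval outside fold")
    partner = fold.pair_partner()
    paired = [(i, partner[i]) for i in range(m0, m1) if partner[i] is not None]
    if len(paired) < 0.6 * (m1 - m0):
        return None
    partners = [q for _, q in paired]
    if all(q >= m1 for q in partners):
        on_five_prime_arm = True  # loop lies beyond the mature 3' end
    elif all(q < m0 for q in partners):
        on_five_prime_arm = False  # loop lies before the mature 5' end
    else:
        return None  # partners span the terminal loop

    p_out = min(i for i, _ in paired)  # paired position nearest the mature 5' end
    p_in = max(i for i, _ in paired)  # paired position nearest the mature 3' end
    loop_overlap = (m1 - 1) - p_in if on_five_prime_arm else p_out - m0
    if loop_overlap > MAX_LOOP_OVERLAP:
        return None

    # In a nested stem the partner index falls by one per mature position on
    # either arm, so extrapolate ideal partners from the nearest paired
    # position. The star 5' end pairs mature position m1-3 (2-nt mature 3'
    # overhang); the star 3' end runs 2 nt past the partner of m0.
    part = dict(paired)
    a0 = min(part, key=lambda p: (abs(p - (m1 - 3)), -p))
    a1 = min(part, key=lambda p: (abs(p - m0), p))
    s0 = part[a0] + (a0 - (m1 - 3))
    s1 = part[a1] + (a1 - m0) + 3
    s0, s1 = max(0, s0), min(n, s1)
    if s1 <= s0:
        return None
    return (s0, s1)


#: largest gap tolerated between consecutive pairing partners (bulge budget)
#: before the opposite-arm block is considered non-contiguous
MAX_PARTNER_GAP = 6


def validate_stemloop(
    candidate: PrecursorCandidate,
    max_mature_unpaired: int = 8,
    require_one_arm: bool = True,
) -> tuple[bool, list[str]]:
    """Decide whether a folded candidate is an acceptable miRNA stem-loop.

    Accepts iff (a) the mature lies entirely on one arm, (b) at most
    max_mature_unpaired mature nucleotides are unpaired, (c) all mature
    pairing partners form a contiguous opposite-arm block, and (d) the fold
    is stabilising (MFE < 0). Every violated clause is reported.
    """
    reasons: list[str] = []
    fold = candidate.fold
    m0, m1 = candidate.mature
    partner = fold.pair_partner()
    paired = [(i, partner[i]) for i in range(m0, m1) if partner[i] is not None]
    partners = sorted(q for _, q in paired)

    one_arm = bool(partners) and (
        all(q >= m1 for q in partners) or all(q < m0 for q in partners)
    )
    if require_one_arm and not one_arm:
        reasons.append("mature straddles the terminal loop or is unpaired")

    unpaired = (m1 - m0) - len(paired)
    if unpaired > max_mature_unpaired:
        reasons.append(
            f"{unpaired} unpaired mature nucleotides exceeds {max_mature_unpaired}"
        )

    if partners:
        max_gap = max(
            (b - a for a, b in zip(partners, partners[1:])), default=1
        )
        if max_gap - 1 > MAX_PARTNER_GAP:
            reasons.append("mature pairing partners are not a contiguous block")
    else:
        reasons.append("mature has no pairing partners")

    if not fold.mfe < 0:
        reasons.append("fold is not stabilising (MFE >= 0)")

    return (not reasons), reasons
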