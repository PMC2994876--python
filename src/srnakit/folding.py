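"""Minimum-free-energy RNA secondary structure by dynamic programming.

Nested (pseudoknot-free) structures over Watson-Crick and GU wobble pairs are
scored with a simplified nearest-neighbour model: a stacking-energy table for
adjacent pairs plus length-dependent hairpin / bulge / internal-loop penalties
and an affine multiloop cost.  The recursion is the classic Zuker scheme
(V / WM / W matrices); the fill is numba-compiled, traceback is plain Python.

``score_structure`` evaluates the same energy model on an explicit pair set,
so any structure the fold emits can be re-scored (and the DP cross-checked
against exhaustive enumeration on short sequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

INF = 1e9
MIN_HAIRPIN = 3          # minimum unpaired bases closed by a pair
MAX_INTERIOR = 30        # max total unpaired bases in a bulge/internal loop

# multiloop: ML_CLOSE + ML_BRANCH per branch (closing helix included) +
# ML_UNPAIRED per unpaired base inside the loop
ML_CLOSE = 3.4
ML_BRANCH = 0.4
ML_UNPAIRED = 0.1

_BASES = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair indices: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5 (first base is 5' side)
_PAIR_IDX = -np.ones((4, 4), dtype=np.int64)
_PAIR_IDX[0, 3] = 0
_PAIR_IDX[3, 0] = 1
_PAIR_IDX[1, 2] = 2
_PAIR_IDX[2, 1] = 3
_PAIR_IDX[2, 3] = 4
_PAIR_IDX[3, 2] = 5

# stacking energies, kcal/mol: STACK[outer pair, inner pair] for the motif
# 5'-i, i+1-3' over 3'-j, j-1-5' with (i,j) outer and (i+1,j-1) inner.
_STACK = np.array(
    [
        #  AU     UA     CG     GC     GU     UG     (inner)
        [-0.9, -1.1, -2.1, -2.2, -0.6, -1.4],  # outer AU
        [-1.3, -0.9, -2.1, -2.4, -1.0, -1.3],  # outer UA
        [-2.1, -2.1, -2.4, -3.3, -1.4, -2.1],  # outer CG
        [-2.4, -2.2, -3.3, -3.4, -1.5, -2.5],  # outer GC
        [-1.3, -1.4, -2.1, -2.5, -0.5, -1.3],  # outer GU
        [-1.0, -0.6, -1.4, -1.5, -0.3, -0.5],  # outer UG
    ]
)

_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_INIT = {2: 4.1, 3: 5.1, 4: 4.9, 5: 5.3, 6: 5.7}
_LOOP_EXTRAP = 1.08  # Jacobson-Stockmayer-style ln extrapolation slope


def hairpin_energy(n_unpaired: int) -> float:
    """Penalty for a hairpin loop of ``n_unpaired`` bases (>= MIN_HAIRPIN)."""
    if n_unpaired < MIN_HAIRPIN:
        return INF
    if n_unpaired <= 9:
        return _HAIRPIN_INIT[n_unpaired]
    return _HAIRPIN_INIT[9] + _LOOP_EXTRAP * math.log(n_unpaired / 9.0)


def bulge_energy(n_unpaired: int) -> float:
    if n_unpaired < 1 or n_unpaired > MAX_INTERIOR:
        return INF
    if n_unpaired <= 6:
        return _BULGE_INIT[n_unpaired]
    return _BULGE_INIT[6] + _LOOP_EXTRAP * math.log(n_unpaired / 6.0)


def internal_energy(n_unpaired: int) -> float:
    if n_unpaired < 2 or n_unpaired > MAX_INTERIOR:
        return INF
    if n_unpaired <= 6:
        return _INTERNAL_INIT[n_unpaired]
    return _INTERNAL_INIT[6] + _LOOP_EXTRAP * math.log(n_unpaired / 6.0)


def _loop_tables(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hp = np.array([hairpin_energy(k) if k >= MIN_HAIRPIN else INF for k in range(n + 1)])
    bu = np.array([bulge_energy(k) if 1 <= k <= MAX_INTERIOR else INF for k in range(n + 1)])
    it = np.array([internal_energy(k) if 2 <= k <= MAX_INTERIOR else INF for k in range(n + 1)])
    return hp, bu, it


def encode(seq: str) -> np.ndarray:
    """Encode an RNA/DNA sequence (T read as U) to integer codes."""
    try:
        return np.array([_BASES[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGU/T character in sequence: {exc.args[0]!r}") from None


@njit(cache=False)
def _fill(s, pair_idx, stack, hp, bu, it, max_interior):  # pragma: no cover - jitted
    n = s.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for i in range(n - 2, -1, -1):
        for j in range(i + 1, n):
            p = pair_idx[s[i], s[j]]
            if p >= 0 and j - i - 1 >= MIN_HAIRPIN:
                best = hp[j - i - 1]
                # two-loop cases: stack, bulge, internal (inner pair (k, l))
                kmax = min(i + max_interior + 2, j - 1)
                for k in range(i + 1, kmax + 1):
                    l1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (max_interior - l1))
                    for l in range(j - 1, lmin - 1, -1):
                        if V[k, l] >= INF:
                            continue
                        l2 = j - l - 1
                        q = pair_idx[s[k], s[l]]
                        if l1 == 0 and l2 == 0:
                            e = stack[p, q] + V[k, l]
                        elif l1 == 0 or l2 == 0:
                            e = bu[l1 + l2] + V[k, l]
                        else:
                            e = it[l1 + l2] + V[k, l]
                        if e < best:
                            best = e
                # multiloop: split interior into two non-empty branch regions
                for k in range(i + 2, j - 2):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ML_CLOSE + ML_BRANCH + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: >=1 branch in [i, j] with multiloop per-base/branch costs
            w = INF
            if V[i, j] < INF:
                w = V[i, j] + ML_BRANCH
            if i + 1 <= j and WM[i + 1, j] + ML_UNPAIRED < w:
                w = WM[i + 1, j] + ML_UNPAIRED
            if j - 1 >= i and WM[i, j - 1] + ML_UNPAIRED < w:
                w = WM[i, j - 1] + ML_UNPAIRED
            for k in range(i + 2, j + 1):
                if WM[i, k - 1] < INF and V[k, j] < INF:
                    e = WM[i, k - 1] + V[k, j] + ML_BRANCH
                    if e < w:
                        w = e
            WM[i, j] = w
    # exterior loop
    W = np.zeros(n + 1)  # W[j+1] = best energy of prefix s[0..j]
    for j in range(n):
        best = W[j]
        for k in range(0, j + 1):
            if V[k, j] < INF:
                e = W[k] + V[k, j]
                if e < best:
                    best = e
        W[j + 1] = best
    return V, WM, W


@dataclass
class FoldResult:
    """MFE structure: dot-bracket string, energy (kcal/mol), sorted pair list."""

    structure: str
    mfe: float
    pairs: list[tuple[int, int]] = field(default_factory=list)


_EPS = 1e-6


def _traceback(s, V, WM, W) -> list[tuple[int, int]]:
    pair_idx, stack = _PAIR_IDX, _STACK
    n = s.shape[0]
    hp, bu, it = _loop_tables(n)
    pairs: list[tuple[int, int]] = []
    stack_v: list[tuple[str, int, int]] = []
    # exterior
    j = n - 1
    while j >= 0:
        if abs(W[j + 1] - W[j]) < _EPS:
            j -= 1
            continue
        for k in range(j + 1):
            if V[k, j] < INF and abs(W[j + 1] - (W[k] + V[k, j])) < _EPS:
                stack_v.append(("V", k, j))
                j = k - 1
                break
        else:  # numerical safety: treat as unpaired
            j -= 1
    while stack_v:
        kind, i, j = stack_v.pop()
        if kind == "V":
            pairs.append((i, j))
            p = pair_idx[s[i], s[j]]
            if abs(V[i, j] - hp[j - i - 1]) < _EPS:
                continue
            found = False
            kmax = min(i + MAX_INTERIOR + 2, j - 1)
            for k in range(i + 1, kmax + 1):
                l1 = k - i - 1
                lmin = max(k + 1, j - 1 - (MAX_INTERIOR - l1))
                for l in range(j - 1, lmin - 1, -1):
                    if V[k, l] >= INF:
                        continue
                    l2 = j - l - 1
                    q = pair_idx[s[k], s[l]]
                    if l1 == 0 and l2 == 0:
                        e = stack[p, q] + V[k, l]
                    elif l1 == 0 or l2 == 0:
                        e = bu[l1 + l2] + V[k, l]
                    else:
                        e = it[l1 + l2] + V[k, l]
                    if abs(V[i, j] - e) < _EPS:
                        stack_v.append(("V", k, l))
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 2):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                    e = ML_CLOSE + ML_BRANCH + WM[i + 1, k] + WM[k + 1, j - 1]
                    if abs(V[i, j] - e) < _EPS:
                        stack_v.append(("WM", i + 1, k))
                        stack_v.append(("WM", k + 1, j - 1))
                        found = True
                        break
            if not found:  # should not happen; drop silently
                continue
        else:  # WM
            if V[i, j] < INF and abs(WM[i, j] - (V[i, j] + ML_BRANCH)) < _EPS:
                stack_v.append(("V", i, j))
                continue
            if i + 1 <= j and abs(WM[i, j] - (WM[i + 1, j] + ML_UNPAIRED)) < _EPS:
                stack_v.append(("WM", i + 1, j))
                continue
            if j - 1 >= i and abs(WM[i, j] - (WM[i, j - 1] + ML_UNPAIRED)) < _EPS:
                stack_v.append(("WM", i, j - 1))
                continue
            for k in range(i + 2, j + 1):
                if WM[i, k - 1] < INF and V[k, j] < INF:
                    if abs(WM[i, j] - (WM[i, k - 1] + V[k, j] + ML_BRANCH)) < _EPS:
                        stack_v.append(("WM", i, k - 1))
                        stack_v.append(("V", k, j))
                        break
    return sorted(pairs)


def fold_mfe(seq: str) -> FoldResult:
    """Fold ``seq`` (RNA or DNA alphabet) to its MFE nested structure.

    Returns the empty structure with MFE 0 when no negative-energy structure
    exists, so ``mfe == 0`` iff no pairs are reported.
    """
    s = encode(seq)
    n = len(s)
    if n < MIN_HAIRPIN + 2:
        return FoldResult("." * n, 0.0, [])
    hp, bu, it = _loop_tables(n)
    V, WM, W = _fill(s, _PAIR_IDX, _STACK, hp, bu, it, MAX_INTERIOR)
    mfe = float(W[n])
    if mfe >= -_EPS:
        return FoldResult("." * n, 0.0, [])
    pairs = _traceback(s, V, WM, W)
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return FoldResult("".join(db), round(mfe, 6), pairs)


def score_structure(seq: str, pairs: list[tuple[int, int]]) -> float:
    """Energy of an explicit nested pair set under the same model.

    Returns INF for disallowed pairs, hairpin loops shorter than 3, or
    interior loops above the size cap.  Used by the hairpin validator and by
    the enumeration oracle in the test suite.
    """
    s = encode(seq)
    pairs = sorted(pairs)
    partner = {}
    for i, j in pairs:
        if not (0 <= i < j < len(s)):
            raise ValueError("pair out of range")
        if i in partner or j in partner:
            raise ValueError("base in two pairs")
        partner[i] = j
        partner[j] = i
    # nestedness check
    open_stack: list[int] = []
    for k in range(len(s)):
        if k in partner and partner[k] > k:
            open_stack.append(partner[k])
        elif k in partner:
            if not open_stack or open_stack[-1] != k:
                raise ValueError("pseudoknotted pair set")
            open_stack.pop()
    total = 0.0
    for i, j in pairs:
        p = _PAIR_IDX[s[i], s[j]]
        if p < 0:
            return INF
        # children: pairs directly accessible from (i, j)
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        unpaired = (j - i - 1) - sum(cj - ci + 1 for ci, cj in children)
        if not children:
            e = hairpin_energy(unpaired)
        elif len(children) == 1:
            (ci, cj), q = children[0], _PAIR_IDX[s[children[0][0]], s[children[0][1]]]
            if q < 0:
                return INF
            l1, l2 = ci - i - 1, j - cj - 1
            if l1 == 0 and l2 == 0:
                e = float(_STACK[p, q])
            elif l1 == 0 or l2 == 0:
                e = bulge_energy(l1 + l2)
            else:
                e = internal_energy(l1 + l2)
        else:
            e = ML_CLOSE + ML_BRANCH * (len(children) + 1) + ML_UNPAIRED * unpaired
        if e >= INF:
            return INF
        total += e
    return total
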