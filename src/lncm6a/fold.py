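"""Maximum base-pairing RNA secondary structure (Nussinov dynamic program).

Provides the two coarse structure descriptors used as genomic features:
whether the site's base is paired, and the paired fraction of its window.
Pairing rules: Watson-Crick (AU, GC) plus the GU wobble; hairpin loops
must contain at least 3 unpaired bases.  Traceback is deterministic,
preferring to leave the 5'-most base unpaired and otherwise pairing it
with the 5'-most compatible partner, so identical inputs always yield
identical dot-bracket strings.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_FOLD_LENGTH = 200
MIN_LOOP = 3

_PAIR_OK = np.zeros((4, 4), dtype=np.bool_)
for a, b in ("AU", "UA", "GC", "CG", "GU", "UG"):
    _PAIR_OK["ACGU".index(a), "ACGU".index(b)] = True

_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


@njit(cache=False)
def _fill(codes, pair_ok, min_loop):  # pragma: no cover - jitted
    n = codes.shape[0]
    N = np.zeros((n + 1, n + 1), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if pair_ok[codes[i], codes[k]]:
                    cand = N[i + 1, k - 1] + 1 + N[k + 1, j]
                    if cand > best:
                        best = cand
            N[i, j] = best
    return N


def _traceback(codes: np.ndarray, N: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    stack = [(0, len(codes) - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i, j] == 0:
            continue
        if N[i + 1, j] == N[i, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (_PAIR_OK[codes[i], codes[k]]
                    and N[i + 1, k - 1] + 1 + N[k + 1, j] == N[i, j]):
                pairs.append((i, k))
                stack.append((i + 1, k - 1))
                stack.append((k + 1, j))
                break
    return pairs


def nussinov_fold(sequence: str) -> str:
    """Dot-bracket structure with the maximum number of base pairs.

    Raises for sequences longer than 200 nt (the cubic DP guard); longer
    windows should come from precomputed structure files.
    """
    from .seq import normalize_rna, _check_bases

    seq = normalize_rna(sequence)
    _check_bases(seq)
    n = len(seq)
    if n > MAX_FOLD_LENGTH:
        raise ValueError(
            f"sequence length {n} exceeds {MAX_FOLD_LENGTH}; "
            "supply precomputed dot-bracket structures instead"
        )
    if n == 0:
        return ""
    codes = np.array([_BASE_INDEX[b] for b in seq], dtype=np.int8)
    if n <= MIN_LOOP + 1:
        return "." * n
    N = _fill(codes, _PAIR_OK, MIN_LOOP)
    structure = ["."] * n
    for i, j in _traceback(codes, N):
        structure[i] = "("
        structure[j] = ")"
    return "".join(structure)


def pair_count(dot_bracket: str) -> int:
    return dot_bracket.count("(")


def paired_fraction(dot_bracket: str) -> float:
    if not dot_bracket:
        return 0.0
    return sum(c in "()" for c in dot_bracket) / len(dot_bracket)
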