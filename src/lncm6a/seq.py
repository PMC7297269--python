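"""Sequence-level encoding of candidate m6A sites.

Each nucleotide of a 21-nt window centered on a candidate adenosine is
represented by four numbers: three binary chemical-property indicators
(ring number, amino/keto group, hydrogen-bond strength) and the cumulative
frequency of that base within the window up to its position.  The window
therefore encodes to an 84-dimensional vector.

Candidate sites are adenosines under the DRACH consensus motif
(D = A/G/U, R = A/G, A methylated, C, H = A/C/U; 18 distinct 5-mers).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
from Bio import SeqIO

log = logging.getLogger(__name__)

RNA_BASES = "ACGU"

#: chemical-property triple (x, y, z):
#:  x = purine (two rings), y = amino group, z = weak hydrogen bonding
CHEMICAL_CODE: dict[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
}
_DECODE = {v: k for k, v in CHEMICAL_CODE.items()}

PAD = "N"
DEFAULT_WINDOW = 21

_D = frozenset("AGU")
_R = frozenset("AG")
_H = frozenset("ACU")


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert DNA T to RNA U."""
    return sequence.upper().replace("T", "U")


def _check_bases(sequence: str, allow_pad: bool = False) -> None:
    allowed = set(RNA_BASES) | ({PAD} if allow_pad else set())
    for i, b in enumerate(sequence, start=1):
        if b not in allowed:
            raise ValueError(f"invalid RNA base {b!r} at position {i}")


def chemical_code(base: str) -> tuple[int, int, int]:
    """Chemical-property triple for one base (T accepted as U).

    Raises ``ValueError`` for any other symbol, including N.
    """
    b = normalize_rna(base)
    if b not in CHEMICAL_CODE:
        raise ValueError(f"invalid RNA base {base!r} at position 1")
    return CHEMICAL_CODE[b]


def decode_chemical(triple: tuple[int, int, int]) -> str:
    """Inverse of :func:`chemical_code`."""
    try:
        return _DECODE[tuple(triple)]
    except KeyError:
        raise ValueError(f"{triple!r} is not a valid chemical code") from None


def cumulative_frequencies(sequence: str) -> list[float]:
    """Per-position cumulative base frequency f_i = d_i / i.

    d_i counts occurrences of the base found at position i within
    positions 1..i (1-based).  The first occurrence of any base is
    always 1/1 at position 1 terms: f_1 = 1.
    """
    seq = normalize_rna(sequence)
    if not seq:
        raise ValueError("empty sequence")
    _check_bases(seq)
    counts = {b: 0 for b in RNA_BASES}
    out = []
    for i, b in enumerate(seq, start=1):
        counts[b] += 1
        out.append(counts[b] / i)
    return out


def encode_window(window: str, window_length: int = DEFAULT_WINDOW) -> np.ndarray:
    """Encode a window into its 4 x window_length feature vector.

    Per position the entries are (x, y, z, f): the chemical triple and the
    cumulative frequency of that base within the window.  Pad characters
    'N' (windows truncated at transcript ends) encode as (0, 0, 0, 0);
    they still occupy a position, so the denominator of f stays the
    1-based position index.
    """
    seq = normalize_rna(window)
    if len(seq) != window_length:
        raise ValueError(
            f"window length {len(seq)} != expected {window_length}"
        )
    _check_bases(seq, allow_pad=True)
    counts = {b: 0 for b in RNA_BASES}
    values = np.zeros(4 * window_length, dtype=float)
    for i, b in enumerate(seq):
        if b == PAD:
            continue  # (0,0,0,0)
        counts[b] += 1
        x, y, z = CHEMICAL_CODE[b]
        values[4 * i : 4 * i + 4] = (x, y, z, counts[b] / (i + 1))
    return values


def is_drach(fivemer: str) -> bool:
    """True if the 5-mer matches DRACH (central A methylatable)."""
    s = normalize_rna(fivemer)
    if len(s) != 5:
        return False
    return (
        s[0] in _D and s[1] in _R and s[2] == "A" and s[3] == "C" and s[4] in _H
    )


def drach_motifs() -> list[str]:
    """The 18 DRACH 5-mers in lexicographic order (frozen catalog order)."""
    return sorted(
        d + r + "AC" + h for d in sorted(_D) for r in sorted(_R) for h in sorted(_H)
    )


_MOTIF_INDEX = {m: i for i, m in enumerate(drach_motifs())}


def motif_identity(fivemer: str) -> int:
    """Index of a DRACH 5-mer in the lexicographically sorted motif list."""
    s = normalize_rna(fivemer)
    if s not in _MOTIF_INDEX:
        raise ValueError(f"{fivemer!r} is not a DRACH 5-mer")
    return _MOTIF_INDEX[s]


def scan_drach(sequence: str) -> list[int]:
    """1-based positions of every DRACH central A on the sense strand."""
    seq = normalize_rna(sequence)
    hits = []
    for p in range(2, len(seq) - 2):
        if seq[p] == "A" and is_drach(seq[p - 2 : p + 3]):
            hits.append(p + 1)
    return hits


def window_around(sequence: str, center: int, flank: int = 10,
                  quiet: bool = False) -> str:
    """Window of ``2*flank+1`` nt around 1-based ``center``, N-padded at ends."""
    seq = normalize_rna(sequence)
    if not 1 <= center <= len(seq):
        raise ValueError(f"center {center} outside sequence of length {len(seq)}")
    lo = center - 1 - flank
    hi = center + flank
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    if left_pad or right_pad:
        log.log(
            logging.DEBUG if quiet else logging.WARNING,
            "window at position %d overruns sequence ends; padding %d+%d nt",
            center, left_pad, right_pad,
        )
    return PAD * left_pad + seq[max(0, lo) : min(len(seq), hi)] + PAD * right_pad


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record, wrapped) FASTA into {id: sense-strand sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
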