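"""Bit-packed boolean vectors for fast filter evaluation.

Filters are conjunctions of per-descriptor membership masks over the same
molecule set, so the hot path is AND + popcount over packed uint64 words.
"""

from __future__ import annotations

import math

import numpy as np

WORD = 64


def n_words(n: int) -> int:
    return (n + WORD - 1) // WORD


def pack_rows(mask: np.ndarray) -> np.ndarray:
    """Pack a boolean matrix (rows × n) into uint64 words (rows × n_words).

    Padding bits beyond n are zero, so popcounts are unaffected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == 1:
        mask = mask[None, :]
    rows, n = mask.shape
    w = n_words(n)
    padded = np.zeros((rows, w * WORD), dtype=bool)
    padded[:, :n] = mask
    packed = np.packbits(padded, axis=1, bitorder="little")
    return packed.view(np.uint64).reshape(rows, w)


def popcount(words: np.ndarray) -> np.ndarray:
    """Number of set bits per row."""
    return np.bitwise_count(words).sum(axis=-1, dtype=np.int64)


def exact_mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation from integer counts, zero denominator → 0.

    Products are taken in exact integer arithmetic before the square root
    so equal confusion tables always yield bit-identical values.
    """
    num = tp * tn - fp * fn
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den2 == 0:
        return 0.0
    return num / math.sqrt(den2)


def confusion_batch(
    filter_words: np.ndarray, active_words: np.ndarray, n_active: int, n_total: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Confusion counts for a batch of packed filter pass-vectors.

    filter_words: (m, W) packed pass masks; active_words: (W,) packed labels.
    Returns (tp, fp, tn, fn) as int64 arrays of length m.
    """
    tp = popcount(filter_words & active_words)
    passed = popcount(filter_words)
    fp = passed - tp
    fn = n_active - tp
    tn = (n_total - n_active) - fp
    return tp, fp, tn, fn


def mcc_batch(tp, fp, tn, fn) -> np.ndarray:
    """Vectorised MCC in float64; exact to ~1e-15 for counts below ~1e6."""
    tp = tp.astype(np.float64)
    fp = fp.astype(np.float64)
    tn = tn.astype(np.float64)
    fn = fn.astype(np.float64)
    num = tp * tn - fp * fn
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out = np.zeros_like(num)
    ok = den2 > 0
    out[ok] = num[ok] / np.sqrt(den2[ok])
    return out
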