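"""Low-complexity masking of query sequences (SEG-style).

Repetitive query segments would otherwise dominate seed scores, so
positions inside low-entropy regions contribute zero during seed
scoring.  The implementation follows the trigger-and-extend scheme of
the classic SEG method: a sliding window whose Shannon entropy falls
below ``locut`` triggers a low-complexity segment, which is then
extended across all adjacent windows whose entropy stays below
``hicut``.  SEG's second refinement stage (minimal-probability
subsequence trimming) is intentionally omitted; it only adjusts segment
margins.  Database sequences are never masked.
"""

from __future__ import annotations

import numpy as np

#: Canonical SEG defaults: 12-residue window, trigger 2.2 bits, extend 2.5.
DEFAULT_WINDOW = 12
DEFAULT_LOCUT = 2.2
DEFAULT_HICUT = 2.5


def window_entropies(seq: str, window: int) -> np.ndarray:
    """Shannon entropy (bits) of each length-``window`` subsequence."""
    n = len(seq)
    if n < window:
        return np.empty(0, dtype=float)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    ent = np.empty(n - window + 1, dtype=float)
    counts = np.zeros(128, dtype=np.int64)
    for c in codes[:window]:
        counts[c] += 1
    for start in range(n - window + 1):
        p = counts[counts > 0] / window
        ent[start] = float(-(p * np.log2(p)).sum())
        if start + window < n:
            counts[codes[start]] -= 1
            counts[codes[start + window]] += 1
    return ent


def seg_mask(
    seq: str,
    window: int = DEFAULT_WINDOW,
    locut: float = DEFAULT_LOCUT,
    hicut: float = DEFAULT_HICUT,
) -> np.ndarray:
    """Boolean mask (True = low complexity) per residue of ``seq``.

    Sequences shorter than ``window`` are never masked.  A maximal run of
    consecutive windows with entropy < ``hicut`` is masked in full iff it
    contains at least one trigger window with entropy < ``locut``.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if locut > hicut:
        raise ValueError("locut must be <= hicut")
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    if n < window:
        return mask
    ent = window_entropies(seq, window)
    below_hi = ent < hicut
    below_lo = ent < locut
    i = 0
    m = len(ent)
    while i < m:
        if not below_hi[i]:
            i += 1
            continue
        j = i
        while j < m and below_hi[j]:
            j += 1
        if below_lo[i:j].any():
            mask[i : j - 1 + window] = True
        i = j
    return mask
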