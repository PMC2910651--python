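"""Numba hot path for batch motif-cluster scoring.

The cluster score of a region is the best additive segment score

    max over windows  [ sum of selected non-overlapping site log-odds
                        - gap_penalty * (#non-site bases inside the window) ]

floored at 0, where a selectable site is any offset/strand with positive
log2-odds under the motif model.  The recurrence below is a Kadane-style
sweep: ``E[i]`` is the best score of a window ending at base ``i``; a site of
width ``w`` ending at ``i`` may either extend a window open at its start
(``E[i-w]``) or open a fresh window (contribution 0).

Sequences are int8-encoded (A=0 C=1 G=2 T=3, anything else=4); code 4 breaks
sites but still costs gap penalty inside a window, and ragged batches may be
padded with 4 on the right without changing any score.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18


@njit(cache=True)
def cluster_scores_batch(codes, lodds_f, lodds_r, widths, gap_penalty):
    """Best cluster score per region for a multi-motif (OR) model.

    Parameters
    ----------
    codes : int8[n_regions, L]
    lodds_f, lodds_r : float64[n_motifs, w_max, 4]
        Forward and reverse-complement log2-odds, row-padded per motif.
    widths : int64[n_motifs]
    gap_penalty : float
        Bits charged per non-site base inside a window.

    Returns
    -------
    float64[n_regions] of scores floored at 0.
    """
    n_regions, seq_len = codes.shape
    n_motifs = widths.shape[0]
    out = np.zeros(n_regions)
    E = np.empty(seq_len + 1)
    for r in range(n_regions):
        E[0] = NEG
        best = 0.0
        for i in range(1, seq_len + 1):
            e = E[i - 1] - gap_penalty
            for m in range(n_motifs):
                w = widths[m]
                if i < w:
                    continue
                o = i - w
                sf = 0.0
                sr = 0.0
                ok = True
                for j in range(w):
                    b = codes[r, o + j]
                    if b > 3:
                        ok = False
                        break
                    sf += lodds_f[m, j, b]
                    sr += lodds_r[m, j, b]
                if not ok:
                    continue
                s = sf if sf > sr else sr
                if s > 0.0:
                    prev = E[o] if E[o] > 0.0 else 0.0
                    cand = s + prev
                    if cand > e:
                        e = cand
            E[i] = e
            if e > best:
                best = e
        out[r] = best
    return out


@njit(cache=True)
def site_scores_batch(codes, lodds, width):
    """Per-offset site log2-odds for one strand orientation.

    Returns float64[n_regions, L - width + 1]; offsets containing a non-ACGT
    code get ``NEG`` (no site).
    """
    n_regions, seq_len = codes.shape
    n_off = seq_len - width + 1
    out = np.full((n_regions, max(n_off, 0)), NEG)
    for r in range(n_regions):
        for o in range(n_off):
            s = 0.0
            ok = True
            for j in range(width):
                b = codes[r, o + j]
                if b > 3:
                    ok = False
                    break
                s += lodds[j, b]
            if ok:
                out[r, o] = s
    return out
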