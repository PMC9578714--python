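"""Brute-force affine-gap Smith-Waterman oracle (numpy dynamic programming).

Independent of the package's aligner: scores every read against every
reference by filling the full DP matrix (match +2, mismatch -6, gap of
length k costs 5 + 3k), vectorised across references.  The within-row
gap recurrence is resolved exactly by prefix-max iteration to a fixpoint.
"""

from __future__ import annotations

import numpy as np

MATCH = 2
MISMATCH = -6
GAP_FIRST = 8   # cost of a length-1 gap
GAP_EXT = 3

_ENC = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}


def _encode(seq: str) -> np.ndarray:
    return np.array([_ENC.get(c, 5) for c in seq.upper()], dtype=np.int64)


def sw_scores(read: str, refs: list[str]) -> np.ndarray:
    """Optimal local alignment score of ``read`` vs each reference."""
    q = _encode(read)
    n_ref = len(refs)
    lr = max(len(r) for r in refs)
    ref_mat = np.zeros((n_ref, lr), dtype=np.int64)  # 0 pad never matches
    for i, r in enumerate(refs):
        ref_mat[i, : len(r)] = _encode(r)
    valid = ref_mat > 0

    neg = np.int64(-(10 ** 9))
    h_prev = np.zeros((n_ref, lr), dtype=np.int64)
    u_prev = np.full((n_ref, lr), neg)
    best = np.zeros(n_ref, dtype=np.int64)
    j_cost = 3 * np.arange(lr, dtype=np.int64)

    for i in range(len(q)):
        sub = np.where(ref_mat == q[i], MATCH, MISMATCH)
        diag = np.zeros((n_ref, lr), dtype=np.int64)
        diag[:, 1:] = h_prev[:, :-1]
        diag = diag + sub
        u = np.maximum(h_prev - GAP_FIRST, u_prev - GAP_EXT)
        h = np.maximum.reduce([np.zeros_like(diag), diag, u])
        # left-gap (gap in read) term: F[j] = max_{k<j} H[k] - 5 - 3(j-k)
        while True:
            g = h + j_cost
            p = np.maximum.accumulate(g, axis=1)
            f = np.full_like(h, neg)
            f[:, 1:] = p[:, :-1] - 5 - j_cost[1:][None, :]
            h_new = np.maximum(h, f)
            if (h_new == h).all():
                break
            h = h_new
        h_prev, u_prev = h, u
        best = np.maximum(best, np.where(valid, h, neg).max(axis=1))
    return best


def best_pair_gene(
    r1: str, r2s: str, names: list[str], seqs: list[str], isos: list[str]
) -> tuple[float, list[str], bool]:
    """(best summed pair score, tied gene names, cross-isodecoder tie?)."""
    s1 = sw_scores(r1, seqs)
    s2 = sw_scores(r2s, seqs)
    totals = s1 + s2
    best = totals.max()
    tied = [i for i in range(len(seqs)) if totals[i] == best]
    cross = len({isos[i] for i in tied}) > 1
    return float(best), sorted(names[i] for i in tied), cross
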