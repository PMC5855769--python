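"""Independent oracles used by the test suite.

These deliberately avoid the package's own alignment code paths:

* ``sw_oracle`` — optimal local alignment via Bio.Align.PairwiseAligner
  (an established, independent Smith-Waterman implementation) with the same
  scoring scheme (+1/-2, gap of length k costs 5+2k, N mismatches all).
* ``exact_repeat_pairs`` — seed-free O(n^2) diagonal scan enumerating all
  maximal exact repeated pairs (direct and inverted) of a sequence.
* ``ols_normal_equations`` — closed-form least squares.
"""

from __future__ import annotations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices


def make_sw_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            mat[a, b] = 1.0 if (a == b and a != "N") else -2.0
    aligner.substitution_matrix = mat
    aligner.mode = "local"
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -2.0
    return aligner


def sw_oracle(query: str, target: str, aligner: Align.PairwiseAligner | None = None):
    """(score, q0, q1, t0, t1, matches, has_word_seed) of the optimal local alignment.

    ``has_word_seed`` reports whether the optimal alignment contains a run of
    >= 11 consecutive exact matches (the default seed requirement).
    """
    aligner = aligner or make_sw_aligner()
    res = aligner.align(query, target)
    score = int(res.score)
    aln = res[0]
    qa, ta = aln[0], aln[1]
    run = 0
    best_run = 0
    matches = 0
    for a, b in zip(qa, ta):
        if a == b and a != "-" and a != "N":
            matches += 1
            run += 1
            best_run = max(best_run, run)
        else:
            run = 0
    (q0, q1), (t0, t1) = aln.aligned[0][[0, -1]][[0, 1], [0, 1]], aln.aligned[1][[0, -1]][[0, 1], [0, 1]]
    return score, int(q0), int(q1), int(t0), int(t1), matches, best_run >= 11


def _maximal_runs(eq: np.ndarray, min_len: int):
    """(start, end) of maximal True runs of length >= min_len."""
    if eq.size == 0:
        return
    padded = np.concatenate([[False], eq, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            yield int(s), int(e)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def exact_repeat_pairs(seq: str, min_len: int) -> set[tuple[int, int, int, int, str]]:
    """All maximal exact repeated pairs >= min_len, canonical (a <= b), seed-free.

    Direct pairs come from comparing the sequence to itself at every shift;
    inverted pairs from comparing it to its reverse complement at every
    diagonal.  The trivial zero-shift self match is excluded.
    """
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = len(codes)
    rc = np.frombuffer(
        "".join(_COMP[c] for c in reversed(seq)).encode("ascii"), dtype=np.uint8
    )
    pairs: set[tuple[int, int, int, int, str]] = set()
    for d in range(1, n - min_len + 1):
        eq = codes[: n - d] == codes[d:]
        for s, e in _maximal_runs(eq, min_len):
            pairs.add((s, e, s + d, e + d, "direct"))
    # seq[i] vs rc[j] with j - i = d; a run [s, e) on i maps to
    # A = (s, e) and B = (n - (s + d) - (e - s), n - (s + d)) on the forward strand
    for d in range(-(n - 1), n - min_len + 1):
        i0 = max(0, -d)
        i1 = min(n, n - d)
        if i1 - i0 < min_len:
            continue
        eq = codes[i0:i1] == rc[i0 + d: i1 + d]
        for s_off, e_off in _maximal_runs(eq, min_len):
            s, e = i0 + s_off, i0 + e_off
            b1 = n - (s + d)
            b0 = b1 - (e - s)
            a, b = (s, e), (b0, b1)
            if a == b:
                continue   # a perfect palindrome aligned onto itself
            if b < a:
                a, b = b, a
            pairs.add((a[0], a[1], b[0], b[1], "inverted"))
    return pairs


def ols_normal_equations(points):
    """Closed-form OLS slope/intercept/R^2 via the normal equations."""
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    X = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(beta[0]), float(beta[1]), r2
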