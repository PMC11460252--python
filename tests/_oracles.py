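"""Independent oracles: brute-force implementations used only to check the
package, never sharing code with it."""

from __future__ import annotations

from itertools import combinations

import numba as nb
import numpy as np
from scipy import stats as sps


def sw_local_python(a: str, b: str, match=1, mismatch=-1, gap=-2):
    """Plain-loop linear-gap Smith-Waterman. Small inputs only.

    Returns (score, a_start, a_end, b_start, b_end) of the best local
    alignment (first-found on ties, scanning row-major).
    """
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = max(0, H[i - 1][j - 1] + s, H[i - 1][j] + gap, H[i][j - 1] + gap)
            H[i][j] = h
            if h > best:
                best, bi, bj = h, i, j
    # traceback for start coordinates
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i][j] == H[i - 1][j - 1] + s:
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
    return best, i, bi, j, bj


_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i


def enc(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


def rc(arr: np.ndarray) -> np.ndarray:
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[arr[::-1]]


@nb.njit(cache=False)
def _sw_best_ends(read, ref, match, mismatch, gap, ends_out):
    """Full SW of read vs ref; returns (best_score, n_ends) and fills
    ends_out with every ref end-column attaining the best score."""
    n = read.shape[0]
    m = ref.shape[0]
    prev = np.zeros(m + 1, np.int32)
    cur = np.zeros(m + 1, np.int32)
    best = 0
    n_ends = 0
    for i in range(1, n + 1):
        cur[0] = 0
        for j in range(1, m + 1):
            s = match if (read[i - 1] <= 3 and read[i - 1] == ref[j - 1]) else mismatch
            h = prev[j - 1] + s
            if prev[j] + gap > h:
                h = prev[j] + gap
            if cur[j - 1] + gap > h:
                h = cur[j - 1] + gap
            if h < 0:
                h = 0
            cur[j] = h
            if h > best:
                best = h
                n_ends = 0
                ends_out[n_ends] = j
                n_ends += 1
            elif h == best and best > 0 and n_ends < ends_out.shape[0]:
                ends_out[n_ends] = j
                n_ends += 1
        prev, cur = cur, prev
    return best, n_ends


def sw_scan_best_positions(read_seq: str, refs: dict[str, str], match=1, mismatch=-4, gap=-7):
    """Exhaustive SW of a read against every reference, both strands.

    Returns (best_score, set of (ref_id, ref_end)) over all co-optimal local
    alignments; ref_end is the 1-based end column on the forward reference
    (for a reverse-strand alignment the coordinate is converted back).
    """
    arr = enc(read_seq)
    ends_buf = np.empty(64, np.int64)
    best = 0
    hits: set[tuple[str, int]] = set()
    for ref_id, ref_seq in refs.items():
        ref_arr = enc(ref_seq)
        L = ref_arr.shape[0]
        for strand, oriented in (("+", arr), ("-", rc(arr))):
            sc, n_ends = _sw_best_ends(oriented, ref_arr, match, mismatch, gap, ends_buf)
            if sc < best or sc == 0:
                continue
            if sc > best:
                best = sc
                hits = set()
            for e in ends_buf[:n_ends].tolist():
                hits.add((ref_id, int(e)))
    return best, hits


def ols_normal_equations(x, y):
    """Closed-form simple OLS via normal equations, with the slope t-test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    intercept, slope = beta
    resid = y - X @ beta
    rss = float(resid @ resid)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = np.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2 * sps.t.sf(abs(t), n - 2)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - rss / tss if tss > 0 else 1.0
    return {"slope": slope, "intercept": intercept, "r_squared": r2,
            "p_value": float(p), "slope_se": float(se)}


def exact_permutation_pvalue(a, b):
    """Exhaustive two-sided permutation p-value on the Welch t statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = a.size

    def welch_t(x, y):
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        denom = np.sqrt(vx / x.size + vy / y.size)
        if denom == 0:
            return 0.0
        return (x.mean() - y.mean()) / denom

    t_obs = abs(welch_t(a, b))
    count = 0
    total = 0
    for idx in combinations(range(pooled.size), na):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        t = abs(welch_t(pooled[mask], pooled[~mask]))
        if t >= t_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def coverage_stabbing_oracle(spans, ref_len):
    """Naive per-base interval-stabbing count."""
    raw = np.zeros(ref_len, dtype=np.int64)
    for start, seg in spans:
        length = seg if isinstance(seg, (int, np.integer)) else len(seg)
        for i in range(max(0, start), min(ref_len, start + length)):
            raw[i] += 1
    return raw


def find_homology_oracle(target: str, source: str, min_len: int, min_identity: float):
    """Exhaustive high-identity local-alignment intervals on ``target``.

    Iterated Smith-Waterman (mismatch penalized so windows below the identity
    threshold score negative), both strands of ``source``; each found
    interval is blanked on the target and the scan repeats.
    """
    # mismatch penalty chosen so identity >= min_identity <=> positive score
    pen = -int(round(min_identity / (1 - min_identity)))
    t = list(target)
    intervals = []
    sources = [source, _revcomp_str(source)]
    while True:
        best = None
        for s in sources:
            score, a0, a1, _b0, _b1 = sw_local_python(
                "".join(t), s, match=1, mismatch=pen, gap=pen
            )
            if a1 - a0 >= min_len and (best is None or score > best[0]):
                best = (score, a0, a1)
        if best is None:
            break
        _, a0, a1 = best
        intervals.append((a0, a1))
        for i in range(a0, a1):
            t[i] = "x"
    intervals.sort()
    return intervals


def _revcomp_str(s: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(s))
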