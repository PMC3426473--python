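"""Independent quadratic-time local-alignment reference.

Plain-Python Gotoh dynamic programming, score only, written directly from
the recurrences: H (match state), E (gap in target), F (gap in query),
with an affine gap of length L costing ``gap_open + L * gap_extend`` and
N never scoring as a match. Deliberately shares no code with the
package's aligner so the two can cross-check each other.
"""

NEG = float("-inf")


def gotoh_local_score(
    q: str,
    t: str,
    match: int = 2,
    mismatch: int = 3,
    gap_open: int = 5,
    gap_extend: int = 2,
) -> float:
    n, m = len(q), len(t)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend,
                E[i - 1][j] - gap_extend,
            )
            F[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend,
                F[i][j - 1] - gap_extend,
            )
            same = q[i - 1] == t[j - 1] and q[i - 1] != "N" and t[j - 1] != "N"
            s = match if same else -mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
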