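"""Independent brute-force oracles, kept deliberately naive.

These implement the textbook definitions directly (full O(nm) dynamic
programming with explicit matrices, a lookup-table reverse complement) and
share no code with the package under test.
"""

NEG = float("-inf")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc_oracle(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def sw_score_oracle(
    q: str, r: str, match: int = 2, mismatch: int = 3, gap_open: int = 5, gap_extend: int = 2
) -> int:
    """Best affine-gap Smith-Waterman score on the given strand only.

    Gap of length k costs gap_open + k * gap_extend. N never matches.
    """
    n, m = len(q), len(r)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            if q[i - 1] == r[j - 1] and q[i - 1] != "N":
                s = match
            else:
                s = -mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def sw_score_oracle_both_strands(q: str, r: str, **scoring) -> int:
    return max(sw_score_oracle(q, r, **scoring), sw_score_oracle(rc_oracle(q), r, **scoring))
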