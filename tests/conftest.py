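import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20160518)


def naive_global_identity(a: str, b: str) -> tuple[float, int]:
    """Independent full-matrix Needleman-Wunsch oracle (pure Python).

    Match +1, mismatch -1 (N never matches), gap -2 linear; traceback prefers
    diagonal, then gap-in-b, then gap-in-a; the lexicographically smaller
    sequence is taken first so the reported identity is order-invariant;
    identity = matches / columns.
    """
    if b < a:
        a, b = b, a
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        H[i][0] = -2 * i
    for j in range(n + 1):
        H[0][j] = -2 * j
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = 1 if (ai == b[j - 1] and ai != "N") else -1
            H[i][j] = max(H[i - 1][j - 1] + s, H[i - 1][j] - 2, H[i][j - 1] - 2)
    i, j, matches, cols = m, n, 0, 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = 1 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else -1
            if H[i][j] == H[i - 1][j - 1] + s:
                matches += s == 1
                i, j = i - 1, j - 1
                cols += 1
                continue
        if i > 0 and H[i][j] == H[i - 1][j] - 2:
            i -= 1
        else:
            j -= 1
        cols += 1
    return round(100.0 * matches / cols, 2), cols
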