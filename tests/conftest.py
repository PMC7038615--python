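import numpy as np
import pytest

from tdnascope.simulate import make_cassette, make_host_genome


@pytest.fixture(scope="session")
def small_genome():
    return make_host_genome(1, [20_000], 0.35, seed=11)


@pytest.fixture(scope="session")
def cassette():
    return make_cassette(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sw_oracle(read: str, ref: str, scoring=(1, 6, 5, 2)):
    """Independent quadratic affine-gap local-alignment oracle (pure Python).

    Returns (score, (read_start, read_end), (ref_start, ref_end),
    n_optimal_cells). Tie-break matches the production convention: the first
    best cell in row-major order wins.
    """
    match, mis, go, ge = scoring
    n, m = len(read), len(ref)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj, n_best = 0, 0, 0, 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go - ge)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go - ge)
            s = match if read[i - 1] == ref[j - 1] else -mis
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best, bi, bj, n_best = h, i, j, 1
            elif h == best and h > 0:
                n_best += 1
    # traceback (same state machine as the production kernel)
    i, j, state = bi, bj, 0
    while i > 0 and j > 0:
        if state == 0:
            if H[i][j] == 0:
                break
            s = match if read[i - 1] == ref[j - 1] else -mis
            if H[i][j] == H[i - 1][j - 1] + s:
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if E[i][j] == H[i][j - 1] - go - ge:
                state = 0
            j -= 1
        else:
            if F[i][j] == H[i - 1][j] - go - ge:
                state = 0
            i -= 1
    return best, (i, bi), (j, bj), n_best
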