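import numpy as np
import pytest

from domcert.conductance import DPMatrix
from domcert.io_formats import WinLossMatrix
from domcert.synth import default_ids


def random_winloss(rng: np.random.Generator, n: int, max_count: int = 5,
                   zero_fraction: float = 0.3) -> WinLossMatrix:
    """Random count matrix with a controllable share of silent dyads."""
    counts = rng.integers(0, max_count + 1, size=(n, n))
    silent_dyads = rng.random((n, n)) < zero_fraction
    silent_dyads |= silent_dyads.T  # silence both directions of the dyad
    counts[silent_dyads] = 0
    np.fill_diagonal(counts, 0)
    return WinLossMatrix(default_ids(n), counts)


def random_dp(rng: np.random.Generator, n: int) -> DPMatrix:
    """Random valid dominance-probability matrix (rows+cols normalised)."""
    a = rng.random((n, n)) + 1e-6
    dp = a / (a + a.T)
    np.fill_diagonal(dp, np.nan)
    return DPMatrix(default_ids(n), dp)


def block_dp(n_per_block: int = 3, within: float = 0.5, between: float = 0.95) -> DPMatrix:
    """Two-tier dp matrix: ambiguous within blocks, decided between them."""
    n = 2 * n_per_block
    dp = np.full((n, n), within)
    dp[:n_per_block, n_per_block:] = between
    dp[n_per_block:, :n_per_block] = 1.0 - between
    np.fill_diagonal(dp, np.nan)
    return DPMatrix(default_ids(n), dp)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
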