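import numpy as np
import pytest

from contactcalls import GeneratorConfig, build_model_data, simulate_model_level


def dtw_brute_force(a, b, normalize=True):
    """Exhaustive enumeration of all admissible warping paths.

    Independent of the DP implementation: recursively walks every monotone
    path from (0,0) to (n-1,m-1); a diagonal step contributes twice the local
    cost, horizontal/vertical steps once, and the start cell contributes once.
    Only feasible for short sequences.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        if cost >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = cost
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, cost + 2.0 * abs(a[i + 1] - b[j + 1]))
        if i + 1 < n:
            walk(i + 1, j, cost + abs(a[i + 1] - b[j]))
        if j + 1 < m:
            walk(i, j + 1, cost + abs(a[i] - b[j + 1]))

    walk(0, 0, abs(a[0] - b[0]))
    return best[0] / (n + m) if normalize else best[0]


@pytest.fixture(scope="session")
def recovery_config():
    """The realistic-regime design used for parameter recovery."""
    return GeneratorConfig(
        n_cities=8,
        parks_per_city=5,
        inds_per_park=8,
        calls_per_ind=10,
        sigma_city=0.4,
        sigma_park=0.2,
        sigma_ind=0.5,
        sigma_obs=0.5,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_model_data():
    """A small dataset with true IDs, reused by model tests."""
    cfg = GeneratorConfig(
        n_cities=3, parks_per_city=2, inds_per_park=3, calls_per_ind=6,
        sigma_city=0.5, sigma_park=0.3, sigma_ind=0.5, sigma_obs=0.5, seed=11,
    )
    md, truth = simulate_model_level(cfg)
    md = md.copy()
    md["individual"] = md["call_id"].map(truth.call_to_individual)
    return build_model_data(md, md["y"].to_numpy()), truth
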