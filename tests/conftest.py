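import warnings

import numpy as np
import pytest

from hdxresolve.model import Instance, Interval
from hdxresolve.simulate import SyntheticSpec, benchmark_suite, generate_instance

SUITE_SEED = 20260920


@pytest.fixture(autouse=True)
def _silence_requirement_warnings():
    # noisy requirement rows legitimately violate the sum==length heuristic
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def random_instance(rng, n_max=12, K=3, f_max=6, noisy=True):
    """Ad-hoc random instance, independent of the synthetic generator."""
    n = int(rng.integers(3, n_max + 1))
    nf = int(rng.integers(1, f_max + 1))
    frs = [
        Interval(int(s), int(e))
        for s, e in (sorted(rng.integers(1, n + 1, 2).tolist()) for _ in range(nf))
    ]
    req = np.array([rng.multinomial(len(f), [1.0 / K] * K) for f in frs])
    if noisy:
        req = np.maximum(req + rng.integers(-1, 2, size=req.shape), 0)
    return Instance(n=n, fragments=frs, requirements=req,
                    color_names=tuple("abcd")[:K])


@pytest.fixture(scope="session")
def tiny_cases():
    """Oracle tier of the fixed benchmark battery (n <= 12, <= 6 fragments)."""
    return [c for c in benchmark_suite(SUITE_SEED, n_tiny=60, n_scale=0)]


@pytest.fixture(scope="session")
def scale_cases():
    """Digest-scale tier (n in [74, 152], 18-49 fragments)."""
    return [c for c in benchmark_suite(SUITE_SEED, n_tiny=0, n_scale=6)]


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture
def fig1_fragment():
    """A fragment with counts (5, 2, 1) on residues 12..19 of a 28-mer."""
    return Instance(
        n=28,
        fragments=[Interval(12, 19)],
        requirements=np.array([[5, 2, 1]]),
    )
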