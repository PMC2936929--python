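"""Synthetic fragment-overlap instances with planted colorings.

No fragment-level HDX class-count datasets are publicly deposited, so every
solver and score in this package is exercised on generated instances that
emulate the shape of real digests: a protein of n residues is cut into
consecutive peptic fragments with a controllable mean length, several
independent digests can be overlaid (emulating multiple proteases or
combined datasets, which is what creates the crucial fragment overlaps),
and requirements are counted exactly from a planted residue coloring.
Optional integer noise then moves single counts between classes of a
fragment -- the smallest physically meaningful corruption of discretized
class counts, and one a real deconvolution step plausibly commits.

Noise-free instances are satisfiable by construction (optimum 0, the
planted coloring among the optima); ``noise_moves = m`` changes at most 2m
requirement entries by one each, so the planted coloring's error -- and a
fortiori the optimum -- is at most 2m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import Instance, Interval, ResidueAssignment, ValidationError

__all__ = ["SyntheticSpec", "generate_instance", "benchmark_suite"]

#: default class frequencies for slow / medium / fast planted colorings
DEFAULT_CLASS_FREQUENCIES = (0.4, 0.3, 0.3)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic instance.

    ``coverage`` overlays that many independent digests; ``noise_moves``
    unit count-swaps corrupt the requirements after exact counting.  The
    same spec and seed always produce the same instance.
    """

    n: int
    K: int = 3
    mean_fragment_length: float = 8.0
    min_fragment_length: int = 2
    coverage: int = 2
    noise_moves: int = 0
    class_frequencies: tuple[float, ...] | None = None
    planted: np.ndarray | None = None
    drop_fragment_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if self.K < 2:
            raise ValidationError("K must be >= 2")
        if self.noise_moves < 0:
            raise ValidationError("noise_moves must be >= 0")
        if self.mean_fragment_length > self.n:
            raise ValidationError("mean fragment length exceeds protein length")
        if self.min_fragment_length < 1:
            raise ValidationError("min fragment length must be >= 1")


def _digest(rng: np.random.Generator, spec: SyntheticSpec) -> list[Interval]:
    """One protease pass: cut 1..n into consecutive fragments."""
    fragments = []
    start = 1
    while start <= spec.n:
        length = max(
            spec.min_fragment_length,
            int(rng.poisson(max(spec.mean_fragment_length - spec.min_fragment_length, 0.1)))
            + spec.min_fragment_length,
        )
        end = min(start + length - 1, spec.n)
        fragments.append(Interval(start, end))
        start = end + 1
    return fragments


def generate_instance(spec: SyntheticSpec) -> tuple[Instance, ResidueAssignment]:
    """Generate ``(instance, planted_coloring)`` from a spec.

    Requirements are exact counts of the planted coloring inside each
    fragment; each noise move then shifts one unit of count between two
    classes of a random fragment.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.planted is not None:
        colors = np.asarray(spec.planted, dtype=np.int64)
        if len(colors) != spec.n or colors.min() < 1 or colors.max() > spec.K:
            raise ValidationError("planted coloring inconsistent with n, K")
    else:
        freqs = spec.class_frequencies
        if freqs is None:
            freqs = DEFAULT_CLASS_FREQUENCIES if spec.K == 3 else (1.0 / spec.K,) * spec.K
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        colors = rng.choice(np.arange(1, spec.K + 1), size=spec.n, p=freqs)

    fragments: list[Interval] = []
    for _ in range(spec.coverage):
        for frag in _digest(rng, spec):
            if spec.drop_fragment_prob and rng.random() < spec.drop_fragment_prob:
                continue
            fragments.append(frag)
    fragments.sort()

    req = np.zeros((len(fragments), spec.K), dtype=np.int64)
    for fi, f in enumerate(fragments):
        inside = colors[f.start - 1 : f.end]
        for k in range(spec.K):
            req[fi, k] = int((inside == k + 1).sum())

    sizes = np.array([len(f) for f in fragments])
    for _ in range(spec.noise_moves):
        if not len(fragments):
            break
        fi = int(rng.integers(len(fragments)))
        src, dst = rng.choice(spec.K, size=2, replace=False)
        if req[fi, src] > 0 and req[fi, dst] < sizes[fi]:
            req[fi, src] -= 1
            req[fi, dst] += 1

    covered = np.zeros(spec.n, dtype=bool)
    for f in fragments:
        covered[f.start - 1 : f.end] = True
    planted = colors.copy()
    planted[~covered] = 0

    if spec.K == 3:
        names = ("slow", "medium", "fast")
    elif spec.K == 2:
        names = ("slow", "fast")
    else:
        names = tuple(f"class{k}" for k in range(1, spec.K + 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        instance = Instance(n=spec.n, fragments=fragments, requirements=req,
                            color_names=names)
    return instance, ResidueAssignment(planted)


@dataclass
class BenchmarkCase:
    instance: Instance
    planted: ResidueAssignment
    spec: SyntheticSpec
    tier: str


def benchmark_suite(
    seed: int,
    n_tiny: int = 200,
    n_scale: int = 12,
) -> list[BenchmarkCase]:
    """The fixed two-tier benchmark battery.

    Tier "tiny" (oracle tier): ``n_tiny`` instances with n <= 12, K = 3 and
    at most 6 fragments, small enough for exhaustive 3^n cross-checks.
    Tier "scale": ``n_scale`` instances with n in [74, 152] and 18-49
    fragments (the size range of real digest datasets), mixed noise.
    Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    cases: list[BenchmarkCase] = []
    for i in range(n_tiny):
        n = int(rng.integers(4, 13))
        spec = SyntheticSpec(
            n=n,
            K=3,
            mean_fragment_length=float(rng.uniform(2.5, max(3.0, n / 2))),
            min_fragment_length=1,
            coverage=2,
            noise_moves=int(rng.integers(0, 4)),
            drop_fragment_prob=0.35,
            seed=int(rng.integers(2**31)),
        )
        inst, planted = generate_instance(spec)
        while inst.n_fragments == 0 or inst.n_fragments > 6:
            spec.seed = int(rng.integers(2**31))
            inst, planted = generate_instance(spec)
        cases.append(BenchmarkCase(inst, planted, spec, "tiny"))
    for i in range(n_scale):
        n = int(rng.integers(74, 153))
        spec = SyntheticSpec(
            n=n,
            K=3,
            mean_fragment_length=float(rng.uniform(7.0, 11.0)),
            min_fragment_length=2,
            coverage=2,
            noise_moves=int(rng.integers(0, 13)),
            drop_fragment_prob=0.25,
            seed=int(rng.integers(2**31)),
        )
        inst, planted = generate_instance(spec)
        while not (18 <= inst.n_fragments <= 49):
            spec.seed = int(rng.integers(2**31))
            inst, planted = generate_instance(spec)
        cases.append(BenchmarkCase(inst, planted, spec, "scale"))
    return cases
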