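"""Null model for convergent lineage recruitment across independent C4
origins.

Under the null, each of ``n_species`` independent C4 origins recruits one
of a family's ``k`` lineages uniformly at random.  The number of families
in which all origins pick the same lineage is then a sum of independent
Bernoulli indicators with success probability k^(1 - n_species) (1/k**2
for three origins): a Poisson-binomial variable.  The tail probability of
the observed convergent count is estimated two ways: by seeded
Monte-Carlo resampling (the resampling scheme of the original analysis,
100,000 replicates by default) and exactly, by dynamic-programming
convolution of the per-family success probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NullModelSpec",
    "ConvergenceResult",
    "prob_all_same",
    "mc_null",
    "mc_pvalue",
    "exact_tail",
    "run_convergence_test",
]


@dataclass
class NullModelSpec:
    """Family sizes (multi-lineage families only), number of independent
    C4 origins, and Monte-Carlo settings."""

    family_sizes: list[int]
    n_species: int = 3
    n_replicates: int = 100_000
    seed: int = 0
    include_single: bool = False

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        sizes = [int(k) for k in self.family_sizes]
        if any(k < 1 for k in sizes):
            raise ValueError("family sizes must be >= 1")
        if not self.include_single:
            sizes = [k for k in sizes if k >= 2]
        if not sizes:
            raise ValueError("no multi-lineage families left after exclusion")
        self.family_sizes = sizes


def prob_all_same(k: int, n_species: int = 3) -> float:
    """Probability that ``n_species`` independent uniform draws from ``k``
    lineages all coincide: k^(1 - n_species)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    return float(k) ** (1 - n_species)


def mc_null(spec: NullModelSpec) -> np.ndarray:
    """Monte-Carlo null histogram of the convergent-family count.

    Returns an integer array ``hist`` with ``hist[c]`` = number of
    replicates in which exactly ``c`` families had all species draw the
    same lineage; ``len(hist) == len(family_sizes) + 1`` and the entries
    sum to ``n_replicates``.  Uses one PCG64 stream seeded from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.family_sizes)
    counts = np.zeros(spec.n_replicates, dtype=np.int64)
    for k in spec.family_sizes:
        draws = rng.integers(0, k, size=(spec.n_replicates, spec.n_species))
        counts += np.all(draws == draws[:, :1], axis=1)
    return np.bincount(counts, minlength=m + 1)


def mc_pvalue(histogram: np.ndarray, observed: int) -> tuple[float, float]:
    """Upper-tail Monte-Carlo p-value and its binomial standard error.

    ``p = (#replicates with count >= observed) / n``; the standard error
    is ``sqrt(p_hat * (1 - p_hat) / n)`` with ``p_hat`` the conservative
    ``(r + 1) / (n + 1)`` estimate so that it stays positive when no
    replicate reaches the observed value.
    """
    if observed < 0:
        raise ValueError("observed must be >= 0")
    hist = np.asarray(histogram)
    n = int(hist.sum())
    if n == 0:
        raise ValueError("empty histogram")
    r = int(hist[min(observed, len(hist)) :].sum()) if observed < len(hist) else 0
    p = r / n
    p_hat = (r + 1) / (n + 1)
    se = math.sqrt(p_hat * (1.0 - p_hat) / n)
    return p, se


def exact_tail(
    family_sizes: Sequence[int], n_species: int = 3, observed: int = 0
) -> float:
    """Exact Poisson-binomial upper tail P(X >= observed).

    The pmf of the convergent-family count is built by dynamic-programming
    convolution of the per-family Bernoulli(k^(1-n_species)) successes;
    stable for thousands of families.
    """
    probs = [prob_all_same(int(k), n_species) for k in family_sizes]
    pmf = np.zeros(len(probs) + 1)
    pmf[0] = 1.0
    for p in probs:
        pmf[1:] = pmf[1:] * (1.0 - p) + pmf[:-1] * p
        pmf[0] *= 1.0 - p
    if observed <= 0:
        return 1.0
    if observed > len(probs):
        return 0.0
    return float(pmf[observed:].sum())


@dataclass
class ConvergenceResult:
    """Observed convergent count with its simulated null and tail
    probabilities."""

    observed: int
    histogram: dict[int, int]
    p_mc: float
    p_mc_se: float
    p_mc_conservative: float
    p_exact: float
    per_family_p_same: list[float]
    n_replicates: int
    seed: int
    family_sizes: list[int] = field(default_factory=list)
    n_species: int = 3
    rng: str = "numpy PCG64 (default_rng)"

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "histogram": {str(k): v for k, v in self.histogram.items()},
            "p_mc": self.p_mc,
            "p_mc_se": self.p_mc_se,
            "p_mc_conservative": self.p_mc_conservative,
            "p_exact": self.p_exact,
            "per_family_p_same": self.per_family_p_same,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "family_sizes": self.family_sizes,
            "n_species": self.n_species,
            "rng": self.rng,
        }


def run_convergence_test(
    family_sizes: Sequence[int],
    observed: int,
    n_species: int = 3,
    n_replicates: int = 100_000,
    seed: int = 0,
    include_single: bool = False,
) -> ConvergenceResult:
    """Full randomness test: Monte-Carlo resampling plus the exact tail."""
    spec = NullModelSpec(
        family_sizes=list(family_sizes),
        n_species=n_species,
        n_replicates=n_replicates,
        seed=seed,
        include_single=include_single,
    )
    hist = mc_null(spec)
    p_mc, se = mc_pvalue(hist, observed)
    r = int(hist[min(observed, len(hist)) :].sum()) if observed < len(hist) else 0
    p_cons = (r + 1) / (spec.n_replicates + 1)
    p_ex = exact_tail(spec.family_sizes, spec.n_species, observed)
    return ConvergenceResult(
        observed=observed,
        histogram={i: int(c) for i, c in enumerate(hist)},
        p_mc=p_mc,
        p_mc_se=se,
        p_mc_conservative=p_cons,
        p_exact=p_ex,
        per_family_p_same=[
            prob_all_same(k, spec.n_species) for k in spec.family_sizes
        ],
        n_replicates=spec.n_replicates,
        seed=spec.seed,
        family_sizes=spec.family_sizes,
        n_species=spec.n_species,
    )
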