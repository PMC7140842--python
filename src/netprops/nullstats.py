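"""Random-gene-set null distributions and significance tests.

The null model draws uniform without-replacement gene samples of a fixed
size (default: 1000 draws of 120 genes) from a supplied gene universe, maps
each through the network, and evaluates one of the set-level measures.
Observed values are compared to the null via a one-sided two-sample
Kolmogorov-Smirnov test or a permutation rank test with add-one smoothing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from netprops.genesets import GeneSet, MappedGeneSet, map_to_network
from netprops.modules_gdm import ModulePartition, gdm
from netprops.network_io import Network
from netprops.setmetrics import (
    SPMatrix,
    inter_set_distance,
    intra_set_distance,
    set_clustering_coefficient,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "TestResult",
    "sample_random_sets",
    "null_distribution",
    "ks_one_sided",
    "permutation_p",
]

MEASURES = ("cc", "iad", "ied", "gdm")


@dataclass(frozen=True)
class NullDistribution:
    """Measure values over random gene sets (undefined evaluations dropped)."""

    measure: str
    b: int
    set_size: int
    values: tuple[float, ...]
    seed: int | None
    n_dropped: int = 0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    alternative: str
    method: str


def sample_random_sets(
    universe: Sequence[str], set_size: int = 120, b: int = 1000, seed: int | None = None
) -> list[GeneSet]:
    """Draw ``b`` uniform without-replacement samples of ``set_size`` symbols."""
    pool = sorted(set(universe))
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds universe size {len(pool)}")
    if set_size < 1 or b < 1:
        raise ValueError("set_size and b must be >= 1")
    rng = np.random.default_rng(seed)
    arr = np.array(pool, dtype=object)
    out = []
    for i in range(b):
        picked = rng.choice(arr, size=set_size, replace=False)
        out.append(GeneSet(name=f"random_{i:04d}", genes=frozenset(picked.tolist())))
    return out


def evaluate_measure(
    net: Network,
    sp: SPMatrix | None,
    part: ModulePartition | None,
    mapped: MappedGeneSet,
    measure: str,
    reference: MappedGeneSet | None = None,
    cc_mode: str = "node_average",
    gdm_mode: str = "incident",
) -> float | None:
    """Evaluate one set-level measure; ``None`` when undefined for this set."""
    if measure == "cc":
        if not mapped.in_network:
            return None
        return set_clustering_coefficient(net, mapped, mode=cc_mode)
    if measure == "iad":
        if len(mapped.in_network) < 2:
            return None
        return intra_set_distance(sp, mapped).iad
    if measure == "ied":
        if reference is None:
            raise ValueError("measure 'ied' needs a reference set")
        if not mapped.in_network or not reference.in_network:
            return None
        return inter_set_distance(sp, mapped, reference).ied
    if measure == "gdm":
        if part is None:
            raise ValueError("measure 'gdm' needs a module partition")
        if not mapped.in_network:
            return None
        return gdm(net, part, mapped, mode=gdm_mode).gdm
    raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")


def null_distribution(
    net: Network,
    sp: SPMatrix | None,
    part: ModulePartition | None,
    random_sets: list[GeneSet],
    measure: str,
    reference: MappedGeneSet | None = None,
    cc_mode: str = "node_average",
    gdm_mode: str = "incident",
    seed: int | None = None,
) -> NullDistribution:
    """Map each random set onto the network and evaluate the measure.

    Undefined evaluations (e.g. the module statistic with no qualifying
    edge, or the intra-set distance of a set with <2 mapped genes) are
    dropped; their count is recorded, and logged.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    values: list[float] = []
    dropped = 0
    set_sizes = {s.size for s in random_sets}
    for s in random_sets:
        mapped = map_to_network(s, net)
        v = evaluate_measure(net, sp, part, mapped, measure, reference=reference, cc_mode=cc_mode, gdm_mode=gdm_mode)
        if v is None:
            dropped += 1
        else:
            values.append(v)
    if not values:
        raise ValueError(f"all {len(random_sets)} null evaluations of {measure!r} were undefined")
    if dropped:
        logger.info("null %s: dropped %d/%d undefined evaluations", measure, dropped, len(random_sets))
    return NullDistribution(
        measure=measure,
        b=len(random_sets),
        set_size=max(set_sizes) if set_sizes else 0,
        values=tuple(values),
        seed=seed,
        n_dropped=dropped,
    )


def ks_one_sided(
    sample_a: Sequence[float], sample_b: Sequence[float], alternative: str = "less"
) -> TestResult:
    """One-sided two-sample Kolmogorov-Smirnov test.

    ``alternative='less'`` tests whether sample A is stochastically smaller
    than sample B (statistic D+ = max over x of ECDF_a(x) - ECDF_b(x));
    ``'greater'`` is the mirror image. The p-value is the asymptotic
    one-sided bound exp(-2 m n D^2 / (m + n)), capped at 1.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples need at least one value")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / a.size
    fb = np.searchsorted(b, grid, side="right") / b.size
    diff = fa - fb if alternative == "less" else fb - fa
    d = float(max(diff.max(), 0.0))
    m, n = a.size, b.size
    p = min(1.0, math.exp(-2.0 * m * n * d * d / (m + n)))
    return TestResult(statistic=d, p=p, alternative=alternative, method="ks_one_sided")


def permutation_p(observed: float, null: NullDistribution, alternative: str = "less") -> TestResult:
    """Permutation rank p-value with add-one smoothing (never exactly 0).

    p = (1 + #{null values at least as extreme as the observation}) /
    (1 + number of null values).
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    vals = np.asarray(null.values, dtype=float)
    if vals.size == 0:
        raise ValueError("null distribution is empty")
    if alternative == "less":
        extreme = int(np.sum(vals <= observed))
    else:
        extreme = int(np.sum(vals >= observed))
    p = (1 + extreme) / (1 + vals.size)
    return TestResult(statistic=float(observed), p=p, alternative=alternative, method="permutation")
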