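"""Alpha diversity and permutation rarefaction for isolate OTU tables.

Implements the indices used to characterise the isolate collection: observed
richness, the bias-corrected Chao1 estimator, Shannon entropy (natural log),
Pielou evenness, Faith's phylogenetic diversity over an iOTU tree, and
richness rarefaction by repeated subsampling without replacement.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import skbio


def _as_counts(counts: Iterable[float]) -> np.ndarray:
    v = np.asarray(list(counts), dtype=float)
    if v.size == 0 or v.sum() <= 0:
        raise ValueError("abundance vector must have a positive total")
    if (v < 0).any():
        raise ValueError("abundance vector must be non-negative")
    return v


def observed_richness(counts: Iterable[float]) -> int:
    v = _as_counts(counts)
    return int((v > 0).sum())


def chao1(counts: Iterable[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    The bias-corrected form is used unconditionally (it is defined when there
    are no doubletons), so chao1 >= S_obs always and equals S_obs exactly
    when there are no singletons.
    """
    v = _as_counts(counts)
    s_obs = (v > 0).sum()
    f1 = (v == 1).sum()
    f2 = (v == 2).sum()
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon(counts: Iterable[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log) over nonzero taxa."""
    v = _as_counts(counts)
    p = v[v > 0] / v.sum()
    return float(-(p * np.log(p)).sum())


def pielou(counts: Iterable[float]) -> float:
    """Pielou evenness J = H / ln(S_obs); NaN when only one taxon is present."""
    v = _as_counts(counts)
    s_obs = (v > 0).sum()
    if s_obs <= 1:
        return float("nan")
    return shannon(v) / float(np.log(s_obs))


def faith_pd(tree: skbio.TreeNode, observed: Iterable[str]) -> float:
    """Faith's phylogenetic diversity of a tip set on a rooted tree.

    Sum of the branch lengths of the minimal subtree connecting the observed
    tips to the root, each branch counted once; the root's own edge counts if
    it has a length.  Raises on tip names absent from the tree.
    """
    observed = set(observed)
    if not observed:
        return 0.0
    tip_index = {t.name: t for t in tree.tips()}
    unknown = observed - set(tip_index)
    if unknown:
        raise ValueError(f"tip ids not in tree: {sorted(unknown)[:5]}")
    seen: set[int] = set()
    total = 0.0
    for name in observed:
        node = tip_index[name]
        while node is not None:
            if id(node) in seen:
                break
            seen.add(id(node))
            if node.length is not None:
                total += node.length
            node = node.parent
    return float(total)


def _subseed(seed: int, depth: int) -> np.random.Generator:
    # per-depth sub-seed derived deterministically from (seed, depth)
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(depth)]))


def rarefy_group(
    counts: Iterable[float],
    depth: int,
    permutations: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean ± sd richness over permuted subsamples without replacement.

    Draws ``permutations`` independent multivariate-hypergeometric subsamples
    of ``depth`` individuals and averages the number of taxa observed.
    Reproducible for a fixed seed.  Raises if depth exceeds the total count.
    """
    v = _as_counts(counts)
    iv = v.astype(np.int64)
    if not np.array_equal(iv, v):
        raise ValueError("rarefaction requires integer counts")
    total = int(iv.sum())
    if not 0 < depth <= total:
        raise ValueError(f"depth must be in [1, {total}], got {depth}")
    if depth == total:
        return float((iv > 0).sum()), 0.0
    rng = _subseed(seed, depth)
    draws = rng.multivariate_hypergeometric(iv, depth, size=permutations)
    richness = (draws > 0).sum(axis=1)
    return float(richness.mean()), float(richness.std(ddof=1))


@dataclasses.dataclass
class RarefactionCurve:
    depths: list[int]
    mean_richness: list[float]
    sd_richness: list[float]
    permutations: int
    seed: int


def rarefaction_curve(
    counts: Iterable[float],
    depths: Sequence[int],
    permutations: int = 1000,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefaction curve over sorted depths (per-depth derived sub-seeds)."""
    v = _as_counts(counts)
    depths = list(depths)
    if depths != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    if depths and depths[-1] > int(v.sum()):
        raise ValueError("maximum depth exceeds the vector total")
    means, sds = [], []
    for d in depths:
        m, s = rarefy_group(v, d, permutations=permutations, seed=seed)
        means.append(m)
        sds.append(s)
    return RarefactionCurve(
        depths=depths,
        mean_richness=means,
        sd_richness=sds,
        permutations=permutations,
        seed=seed,
    )


def expected_rarefied_richness(counts: Iterable[float], depth: int) -> float:
    """Analytic (hypergeometric) expectation of rarefied richness.

    E[S] = sum_i [1 - C(N - N_i, n) / C(N, n)] — the closed form the
    permutation estimate converges to.
    """
    from scipy.special import gammaln

    v = _as_counts(counts).astype(np.int64)
    n_total = int(v.sum())

    def log_comb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    denom = log_comb(n_total, depth)
    probs = []
    for ni in v[v > 0]:
        if n_total - ni < depth:
            probs.append(1.0)
        else:
            probs.append(1.0 - float(np.exp(log_comb(n_total - ni, depth) - denom)))
    return float(np.sum(probs))
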