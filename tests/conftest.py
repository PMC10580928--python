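"""Shared fixtures: a small fully ground-truthed synthetic experiment.

The session-scoped fixture keeps the alignment work (the expensive part at
full gene length) to one simulation shared by the crossmap/novelty/pipeline
tests; module-specific fixtures build their own tiny inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from isoamp.cluster import greedy_cluster
from isoamp.simulate import SimParams, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """One-season microcosm: 14 taxa (8 novelty-planted), 10 isolates/group."""
    params = SimParams(
        seed=2,
        n_taxa=14,
        seasons=("summer",),
        isolate_effort=10,
        reads_per_sample=4000,
    )
    truth, table, isolates, plates = simulate_all(params)
    return params, truth, table, isolates, plates


@pytest.fixture(scope="session")
def small_sim_clusters(small_sim):
    _, _, _, isolates, _ = small_sim
    seqs = {r.isolate_id: r.sequence for r in isolates}
    ziotus = greedy_cluster(seqs, 1.0, level_label="ziOTU")
    iotus = greedy_cluster(seqs, 0.99, level_label="iOTU")
    return seqs, iotus, ziotus


PIPELINE_CONFIG = {
    "seed": 5,
    "simulate": {
        "n_taxa": 12,
        "seasons": ("summer",),
        "isolate_effort": 8,
        "reads_per_sample": 3000,
        "novelty_plan": ((0.96, 0.96, 1), (0.93, 0.92, 1)),
        "n_decoy_taxa": 1,
    },
    "rarefaction_permutations": 200,
}


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The same small pipeline config run twice under one seed."""
    from isoamp.pipeline import run_pipeline

    results = []
    for name in ("run_a", "run_b"):
        outdir = tmp_path_factory.mktemp(name)
        results.append(run_pipeline(PIPELINE_CONFIG, outdir, make_plots=False))
    return results


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in rng.choice(len(seq), size=n_subs, replace=False):
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def make_planted_fixture(seed: int = 42, n_groups: int = 6, members: int = 5):
    """Sequences from planted centroids, separable at the 99% threshold.

    Within-group: one substitution on 200 nt (identity 0.995).  Between-group:
    independent ~12% divergence from a shared template (identity well under
    0.99).  Returns (id -> sequence, group -> member ids).
    """
    rng = np.random.default_rng(seed)
    template = random_seq(rng, 200)
    seqs: dict[str, str] = {}
    groups: dict[int, list[str]] = {}
    for g in range(n_groups):
        centroid = mutate(template, 24, rng)
        variants = [centroid] + [mutate(centroid, 1, rng) for _ in range(members - 1)]
        for k, s in enumerate(variants):
            sid = f"g{g}m{k}"
            seqs[sid] = s
            groups.setdefault(g, []).append(sid)
    return seqs, groups
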