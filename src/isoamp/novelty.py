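"""Taxonomic novelty screening of ziOTUs by dual identity thresholds.

Each ziOTU centroid is compared against two reference sets — cultured taxa
(CCM, closest cultured match) and environmental/uncultured taxa (CEM) — and
classified by the best-hit identities:

* ccm >= 97%                          -> known (a cultured relative exists)
* ccm < 97% and cem >= 97%            -> novel_to_culture (seen in nature,
                                         never cultured)
* 94.5% <= max(ccm, cem) < 97%        -> putative_novel_species
* max(ccm, cem) < 94.5%               -> putative_novel_genus

Thresholds are strict "less than" for novelty: equality at 97% or 94.5% is
not novel at that level.  Candidate isolates in the species band re-clustered
at 97% give the putative novel species count; genus-band candidates clustered
at 94.5% give the novel genus count.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from .cluster import greedy_cluster, pairwise_identity

SPECIES_THRESHOLD = 0.97
GENUS_THRESHOLD = 0.945

CATEGORIES = (
    "known",
    "novel_to_culture",
    "putative_novel_species",
    "putative_novel_genus",
)

NOVEL_CATEGORIES = CATEGORIES[1:]


def best_match_identity(
    query: str, refs: Mapping[str, str]
) -> tuple[str, float]:
    """Best-hit (reference id, identity) of ``query`` over a reference set.

    Uses the clustering module's semi-global identity; ties between equally
    good references are broken by ascending reference id.  Raises on an empty
    reference set.
    """
    if not refs:
        raise ValueError("best_match_identity requires a non-empty reference set")
    best_id: str | None = None
    best = -1.0
    for ref_id in sorted(refs):
        ident = pairwise_identity(query, refs[ref_id])
        if ident > best:
            best, best_id = ident, ref_id
    assert best_id is not None
    return best_id, best


def classify_novelty(
    ccm_id: float,
    cem_id: float,
    species_thr: float = SPECIES_THRESHOLD,
    genus_thr: float = GENUS_THRESHOLD,
) -> str:
    """Categorise one (CCM identity, CEM identity) pair.

    The species/genus bands are defined on max(ccm, cem); the asymmetric case
    ccm < 94.5% <= cem < 97% therefore lands in putative_novel_species.
    """
    for name, v in (("ccm_id", ccm_id), ("cem_id", cem_id)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if not genus_thr < species_thr <= 1.0:
        raise ValueError("need genus threshold < species threshold <= 1")
    if ccm_id >= species_thr:
        return "known"
    if cem_id >= species_thr:
        return "novel_to_culture"
    top = max(ccm_id, cem_id)
    if top >= genus_thr:
        return "putative_novel_species"
    return "putative_novel_genus"


@dataclasses.dataclass
class NoveltyCall:
    ziotu_id: str
    ccm_ref: str
    ccm_id: float
    cem_ref: str
    cem_id: float
    category: str


def screen_ziotus(
    ziotu_sequences: Mapping[str, str],
    ccm_refs: Mapping[str, str],
    cem_refs: Mapping[str, str],
    species_thr: float = SPECIES_THRESHOLD,
    genus_thr: float = GENUS_THRESHOLD,
) -> list[NoveltyCall]:
    """Best-hit scan of every ziOTU against the CCM and CEM sets."""
    calls = []
    for zid in ziotu_sequences:
        ccm_ref, ccm_id = best_match_identity(ziotu_sequences[zid], ccm_refs)
        cem_ref, cem_id = best_match_identity(ziotu_sequences[zid], cem_refs)
        calls.append(
            NoveltyCall(
                ziotu_id=zid,
                ccm_ref=ccm_ref,
                ccm_id=ccm_id,
                cem_ref=cem_ref,
                cem_id=cem_id,
                category=classify_novelty(ccm_id, cem_id, species_thr, genus_thr),
            )
        )
    return calls


def count_novel_taxa(
    species_candidates: Mapping[str, str],
    genus_candidates: Mapping[str, str],
) -> tuple[int, int]:
    """Cluster candidate sequences to count distinct novel species and genera.

    Species-band candidates are clustered at 97% identity and genus-band
    candidates at 94.5%; the cluster counts are the putative novel species
    and genus counts.  Empty candidate sets yield 0, not an error.
    """
    n_species = (
        greedy_cluster(species_candidates, SPECIES_THRESHOLD).n_clusters
        if species_candidates
        else 0
    )
    n_genera = (
        greedy_cluster(genus_candidates, GENUS_THRESHOLD).n_clusters
        if genus_candidates
        else 0
    )
    return n_species, n_genera


@dataclasses.dataclass
class NoveltyLedger:
    """Novelty calls with collection-level counts and percentages."""

    calls: list[NoveltyCall]
    n_novel_isolates: int
    n_novel_iotus: int
    n_novel_ziotus: int
    pct_of_isolates: float
    pct_of_iotus: float
    pct_of_ziotus: float
    n_novel_species: int
    n_novel_genera: int


def novelty_summary(
    calls: Sequence[NoveltyCall],
    ziotu_members: Mapping[str, Sequence[str]],
    iotu_of_isolate: Mapping[str, str],
    n_isolates: int,
    ziotu_sequences: Mapping[str, str] | None = None,
) -> NoveltyLedger:
    """Aggregate novelty calls at the isolate, iOTU and ziOTU levels.

    ``ziotu_members`` maps each ziOTU centroid to its member isolate ids;
    ``iotu_of_isolate`` maps isolates to their iOTU centroid.  A ziOTU is
    novel when its CCM identity is below the species threshold (any category
    other than "known"); an iOTU is novel when any of its member isolates
    belongs to a novel ziOTU.  Percentages are relative to the collection
    totals.  When ``ziotu_sequences`` is given, the species/genus band
    candidates are re-clustered to count distinct novel species and genera.
    """
    n_iotus = len(set(iotu_of_isolate.values()))
    n_ziotus = len(ziotu_members)
    if not (n_isolates and n_iotus and n_ziotus):
        raise ValueError("collection totals must be positive")

    novel_z = [c.ziotu_id for c in calls if c.category != "known"]
    novel_isolates = {m for z in novel_z for m in ziotu_members[z]}
    novel_iotus = {iotu_of_isolate[m] for m in novel_isolates}

    n_species = n_genera = 0
    if ziotu_sequences is not None:
        species_band = {
            c.ziotu_id: ziotu_sequences[c.ziotu_id]
            for c in calls
            if c.category == "putative_novel_species"
        }
        genus_band = {
            c.ziotu_id: ziotu_sequences[c.ziotu_id]
            for c in calls
            if c.category == "putative_novel_genus"
        }
        n_species, n_genera = count_novel_taxa(species_band, genus_band)

    return NoveltyLedger(
        calls=list(calls),
        n_novel_isolates=len(novel_isolates),
        n_novel_iotus=len(novel_iotus),
        n_novel_ziotus=len(novel_z),
        pct_of_isolates=100.0 * len(novel_isolates) / n_isolates,
        pct_of_iotus=100.0 * len(novel_iotus) / n_iotus,
        pct_of_ziotus=100.0 * len(novel_z) / n_ziotus,
        n_novel_species=n_species,
        n_novel_genera=n_genera,
    )
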