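"""Cross-map isolate ziOTUs onto amplicon ASVs and derive cultured fractions.

An ASV is "cultured" when its exact sequence (or its reverse complement)
occurs as a substring of at least one ziOTU centroid: for a short amplicon
against a near-full-length 16S gene this is exactly what 100% identity means,
and exact substring search avoids any alignment ambiguity.  From the match
set we compute the statistics the integration is about: the percentage of
community reads that belong to cultured ASVs, per (season, treatment, time)
group (replicate mean ± sd), both raw and corrected for 16S rRNA gene copy
number; plate-count culturability (CFU/DAPI); rank-abundance overlays;
composition tables and culture-media overlap of iOTUs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterSet
from .io import (
    AmpliconTable,
    CopyNumberTable,
    FormatError,
    IsolateRecord,
    PlateCountTable,
    reverse_complement,
)

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


@dataclasses.dataclass
class CrossmapResult:
    """ziOTU <-> ASV matches and derived cultured-read fractions."""

    matches: dict[str, list[str]]  # asv_id -> matching ziOTU centroid ids
    cultured_flag: dict[str, bool]
    n_asvs_cultured: int
    n_ziotus_matched: int
    n_ziotus_total: int
    per_group_fraction_raw: pd.DataFrame | None = None
    per_group_fraction_corrected: pd.DataFrame | None = None

    @property
    def pct_ziotus_matched(self) -> float:
        return 100.0 * self.n_ziotus_matched / self.n_ziotus_total

    def matched_ziotus(self) -> set[str]:
        return {z for zs in self.matches.values() for z in zs}


def match_ziotus_to_asvs(
    ziotus: ClusterSet,
    ziotu_sequences: Mapping[str, str],
    asvs: AmpliconTable,
) -> CrossmapResult:
    """Match every ASV against every ziOTU centroid at 100% identity.

    The ASV sequence or its reverse complement must occur as an exact
    substring of the centroid's (longer) gene sequence; ambiguity codes never
    match, so an ASV containing any non-ACGT character is unmatchable.
    All matching ziOTUs are recorded per ASV.
    """
    centroids = {}
    for c in ziotus.clusters:
        try:
            centroids[c.centroid_id] = ziotu_sequences[c.centroid_id]
        except KeyError:
            raise FormatError(f"no sequence for ziOTU centroid {c.centroid_id!r}") from None

    matches: dict[str, list[str]] = {}
    for asv_id in asvs.asv_ids:
        seq = asvs.asv_sequences[asv_id]
        if not seq:
            raise FormatError(f"ASV {asv_id!r} has an empty sequence")
        hit_ids: list[str] = []
        if _ACGT.issuperset(seq):
            rc = reverse_complement(seq)
            for zid, zseq in centroids.items():
                if seq in zseq or rc in zseq:
                    hit_ids.append(zid)
        matches[asv_id] = hit_ids

    cultured = {a: bool(m) for a, m in matches.items()}
    matched_z = {z for m in matches.values() for z in m}
    return CrossmapResult(
        matches=matches,
        cultured_flag=cultured,
        n_asvs_cultured=sum(cultured.values()),
        n_ziotus_matched=len(matched_z),
        n_ziotus_total=ziotus.n_clusters,
    )


def _group_fractions(
    counts: pd.DataFrame, cultured: Mapping[str, bool], asvs: AmpliconTable
) -> pd.DataFrame:
    """Replicate-mean cultured percentage per (season, treatment, time) group.

    Per replicate sample the fraction is 100 x cultured reads / total reads;
    per group the replicate mean and standard deviation (ddof=1; 0 for a
    single replicate) are reported.
    """
    mask = np.array([cultured.get(a, False) for a in counts.columns])
    vals = counts.to_numpy(dtype=float)
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.index[totals <= 0][0]
        raise FormatError(f"sample {bad!r} has zero total abundance")
    per_sample = 100.0 * vals[:, mask].sum(axis=1) / totals
    frac = pd.Series(per_sample, index=counts.index)
    rows = []
    for group, samples in asvs.groups().items():
        reps = frac.loc[[s for s in samples if s in frac.index]]
        sd = float(reps.std(ddof=1)) if len(reps) > 1 else 0.0
        rows.append(
            {
                "season": group[0],
                "treatment": group[1],
                "time": group[2],
                "n_replicates": len(reps),
                "cultured_pct_mean": float(reps.mean()),
                "cultured_pct_sd": sd,
            }
        )
    return pd.DataFrame(rows)


def correct_matrix(
    counts: pd.DataFrame,
    asv_class: Mapping[str, str],
    copies: CopyNumberTable,
) -> pd.DataFrame:
    """Divide each ASV column by its class mean 16S copy number.

    SAR11-labelled ASVs use the dedicated "SAR11" entry; ASVs with a missing
    or unmapped class fall back to ``default_copies`` with a logged warning.
    """
    divisors = np.empty(counts.shape[1], dtype=float)
    missing: list[str] = []
    for k, asv_id in enumerate(counts.columns):
        label = asv_class.get(asv_id)
        if label is None or (label not in copies.copies):
            missing.append(asv_id)
            divisors[k] = copies.default_copies
        else:
            divisors[k] = copies.copies[label]
    if missing:
        logger.warning(
            "%d ASVs without a resolvable class; using default copy number %.3g "
            "(first few: %s)",
            len(missing),
            copies.default_copies,
            missing[:5],
        )
    if (divisors <= 0).any():
        raise FormatError("copy numbers must be positive")
    return counts.astype(float) / divisors


def copy_number_correct(asvs: AmpliconTable, copies: CopyNumberTable) -> pd.DataFrame:
    """Copy-number-corrected abundance matrix, renormalised per sample."""
    corrected = correct_matrix(asvs.counts, asvs.asv_class, copies)
    vals = corrected.to_numpy()
    return pd.DataFrame(
        vals / vals.sum(axis=1, keepdims=True),
        index=corrected.index,
        columns=corrected.columns,
    )


def cultured_read_fraction(
    result: CrossmapResult,
    asvs: AmpliconTable,
    copies: CopyNumberTable | None = None,
) -> CrossmapResult:
    """Attach per-group cultured-read fractions (raw, and corrected if copies given).

    Returns the same result object with ``per_group_fraction_raw`` (and
    ``per_group_fraction_corrected``) populated.  Percentages are reported to
    full precision; round to 2 decimals for display.
    """
    result.per_group_fraction_raw = _group_fractions(
        asvs.counts, result.cultured_flag, asvs
    )
    if copies is not None:
        corrected = correct_matrix(asvs.counts, asvs.asv_class, copies)
        result.per_group_fraction_corrected = _group_fractions(
            corrected, result.cultured_flag, asvs
        )
    return result


def overall_cultured_fraction(
    result: CrossmapResult,
    asvs: AmpliconTable,
    copies: CopyNumberTable | None = None,
) -> float:
    """Percentage of all reads in the data set belonging to cultured ASVs."""
    counts = asvs.counts
    if copies is not None:
        counts = correct_matrix(asvs.counts, asvs.asv_class, copies)
    mask = np.array([result.cultured_flag.get(a, False) for a in counts.columns])
    vals = counts.to_numpy(dtype=float)
    return 100.0 * vals[:, mask].sum() / vals.sum()


# ---------------------------------------------------------------------------
# Culturability (CFU / DAPI)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CulturabilityRecord:
    sample_group: str
    medium: str
    cfu_per_mL: float
    dapi_per_mL: float

    @property
    def culturability_pct(self) -> float:
        return 100.0 * self.cfu_per_mL / self.dapi_per_mL


def culturability_ratio(plates: PlateCountTable) -> list[CulturabilityRecord]:
    """CFU/DAPI culturability per (sample group, medium).

    Each plate contributes CFU mL^-1 = colonies x dilution / plated volume;
    plates of a group/medium are averaged, and culturability is
    100 x CFU mL^-1 / DAPI mL^-1.
    """
    records = []
    df = plates.rows
    for (group, medium), sub in df.groupby(["sample_group", "medium"], sort=False):
        if group not in plates.dapi:
            raise FormatError(f"missing DAPI count for sample group {group!r}")
        cfu = (
            sub["colonies"].astype(float)
            * sub["dilution_factor"].astype(float)
            / sub["plated_volume_mL"].astype(float)
        ).mean()
        records.append(
            CulturabilityRecord(
                sample_group=str(group),
                medium=str(medium),
                cfu_per_mL=float(cfu),
                dapi_per_mL=float(plates.dapi[group]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Rank abundance
# ---------------------------------------------------------------------------

def rank_abundance_overlay(
    asvs: AmpliconTable,
    result: CrossmapResult,
    group: tuple[str, str, str],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank ASVs of one group by replicate-mean relative abundance.

    Returns columns (rank, asv_id, mean_relative_abundance_pct, cultured);
    ranks are 1..K without gaps, abundance non-increasing, ties broken by
    ascending asv_id.
    """
    samples = asvs.groups().get(group)
    if not samples:
        raise ValueError(f"no samples in group {group!r}")
    rel = asvs.relative_abundance().loc[samples]
    mean_rel = rel.mean(axis=0)
    order = sorted(mean_rel.index, key=lambda a: (-mean_rel[a], a))
    rows = []
    for rank, asv_id in enumerate(order, start=1):
        rows.append(
            {
                "rank": rank,
                "asv_id": asv_id,
                "mean_relative_abundance_pct": 100.0 * float(mean_rel[asv_id]),
                "cultured": bool(result.cultured_flag.get(asv_id, False)),
            }
        )
        if top_k is not None and rank >= top_k:
            break
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composition & media overlap
# ---------------------------------------------------------------------------

_FACETS = ("class_x_season", "class_x_treatment", "medium", "genus_x_treatment")


def composition_summary(
    isolates: Sequence[IsolateRecord],
    by: str,
    asvs: AmpliconTable | None = None,
) -> pd.DataFrame:
    """Percentage composition table of the isolate collection.

    Facets: ``class_x_season``, ``class_x_treatment``, ``medium``,
    ``genus_x_treatment``.  Per column, percentage = 100 x count / column
    total.  For the treatment facets, the ``t0`` category pools all
    treatments at the initial time and each other column is that treatment at
    final time.  For ``genus_x_treatment`` with an amplicon table supplied,
    a ``mean_abundance_pct:<treatment>`` block with the genus' mean ASV
    relative abundance is appended (requires ``asvs.asv_genus``).
    """
    if by not in _FACETS:
        raise ValueError(f"unknown facet {by!r}; choose from {_FACETS}")
    df = pd.DataFrame(
        {
            "class_label": [r.class_label or "unclassified" for r in isolates],
            "genus": [r.genus or "unclassified" for r in isolates],
            "season": [r.season for r in isolates],
            "treatment": [r.treatment for r in isolates],
            "time": [r.time for r in isolates],
            "medium": [r.medium for r in isolates],
        }
    )
    # treatment category: pool every initial-time sample under "t0"
    df["treatment_cat"] = np.where(df["time"] == "t0", "t0", df["treatment"])

    if by == "medium":
        counts = df.groupby("medium").size().to_frame("count")
        counts["pct"] = 100.0 * counts["count"] / counts["count"].sum()
        return counts.reset_index()

    row_key = "class_label" if by.startswith("class") else "genus"
    col_key = "season" if by == "class_x_season" else "treatment_cat"
    table = pd.crosstab(df[row_key], df[col_key])
    pct = 100.0 * table / table.sum(axis=0)
    pct.columns = [f"pct:{c}" for c in pct.columns]
    table.columns = [f"count:{c}" for c in table.columns]
    out = pd.concat([pct, table], axis=1).reset_index()

    if by == "genus_x_treatment" and asvs is not None and asvs.asv_genus:
        rel = asvs.relative_abundance()
        meta = asvs.sample_meta
        treat_cat = np.where(
            meta.loc[rel.index, "time"] == "t0",
            "t0",
            meta.loc[rel.index, "treatment"],
        )
        genus_of = pd.Series(
            [asvs.asv_genus.get(a, "unclassified") for a in rel.columns],
            index=rel.columns,
        )
        by_genus = rel.T.groupby(genus_of).sum().T  # samples x genus
        mean_by_cat = 100.0 * by_genus.groupby(treat_cat).mean()
        for cat in mean_by_cat.index:
            out[f"mean_abundance_pct:{cat}"] = (
                out["genus"].map(mean_by_cat.loc[cat]).fillna(0.0)
            )
    return out


def media_overlap(
    iotus: ClusterSet, isolates: Sequence[IsolateRecord]
) -> dict[str, float]:
    """Counts of iOTUs cultured only on MA, only on mR2A, or on both media."""
    medium_of = {r.isolate_id: r.medium for r in isolates}
    only_ma = only_mr2a = shared = 0
    for c in iotus.clusters:
        media = {medium_of[m] for m in c.member_ids if m in medium_of}
        if media == {"MA"}:
            only_ma += 1
        elif media == {"mR2A"}:
            only_mr2a += 1
        elif media == {"MA", "mR2A"}:
            shared += 1
    total = iotus.n_clusters
    return {
        "only_MA": only_ma,
        "only_mR2A": only_mr2a,
        "shared": shared,
        "total_iotus": total,
        "shared_pct": 100.0 * shared / total if total else 0.0,
    }
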