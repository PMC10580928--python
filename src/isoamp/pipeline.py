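"""End-to-end orchestration: simulate/load -> cluster -> crossmap -> novelty
-> diversity, with provenance-stamped TSV outputs.

Every output table carries a provenance header (package version, seed, config
hash) as '#'-prefixed lines above the TSV payload, and a fixed seed makes
re-runs byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cluster import ClusterSet, greedy_cluster, nest_check
from .crossmap import (
    CrossmapResult,
    composition_summary,
    cultured_read_fraction,
    culturability_ratio,
    match_ziotus_to_asvs,
    media_overlap,
    overall_cultured_fraction,
    rank_abundance_overlay,
)
from .diversity import chao1, pielou, rarefaction_curve, shannon
from .io import (
    AmpliconTable,
    CopyNumberTable,
    IsolateRecord,
    PlateCountTable,
    read_amplicon_table,
    read_asv_taxonomy,
    read_copy_numbers,
    read_isolates,
    read_plate_counts,
)
from .novelty import novelty_summary, screen_ziotus
from .simulate import SimParams, simulate_all, write_fixture

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"iotu": 0.99, "ziotu": 1.0, "species": 0.97, "genus": 0.945}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, header: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclasses.dataclass
class PipelineResult:
    """In-memory handles to everything a pipeline run produced."""

    outdir: Path
    isolates: list[IsolateRecord]
    asvs: AmpliconTable
    iotus: ClusterSet
    ziotus: ClusterSet
    crossmap: CrossmapResult
    overall_cultured_pct: float
    overall_cultured_pct_corrected: float | None
    media: dict[str, float]
    culturability: list
    novelty: Any | None
    diversity: pd.DataFrame


def ziotu_table(isolates: list[IsolateRecord], ziotus: ClusterSet) -> dict[str, list[str]]:
    """Member isolate ids per ziOTU centroid."""
    return {c.centroid_id: list(c.member_ids) for c in ziotus.clusters}


def iotu_abundance_by_treatment(
    isolates: list[IsolateRecord], iotus: ClusterSet
) -> pd.DataFrame:
    """iOTU x treatment-category count table (t0 pools all initial-time samples)."""
    assignment = iotus.assignment()
    rows = []
    for r in isolates:
        cat = "t0" if r.time == "t0" else r.treatment
        rows.append({"iotu": assignment[r.isolate_id], "category": cat})
    df = pd.DataFrame(rows)
    return pd.crosstab(df["iotu"], df["category"])


def run_pipeline(
    config: Mapping[str, Any],
    outdir: str | Path,
    *,
    make_plots: bool = True,
) -> PipelineResult:
    """Execute all stages in dependency order and write the report bundle.

    ``config`` either carries a ``simulate`` block (SimParams fields) or an
    ``inputs`` block with paths (isolates_fasta, isolates_meta, asv_counts,
    asv_fasta, sample_meta, and optionally asv_taxonomy, copy_numbers,
    ccm_fasta, cem_fasta, plate_counts, dapi).  Raises
    :class:`PipelineError` naming the failing stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    seed = int(config.get("seed", config.get("simulate", {}).get("seed", 0)))
    stamp = {"isoamp_version": __version__, "seed": seed, "config_hash": chash}
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    if not thresholds["genus"] < thresholds["species"]:
        raise PipelineError("config: species threshold must exceed genus threshold")

    # --- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        ccm_refs = cem_refs = None
        copies: CopyNumberTable | None = None
        plates: PlateCountTable | None = None
        if "simulate" in config:
            params = SimParams(**{**config["simulate"], "seed": seed})
            truth, asvs, isolates, plates = simulate_all(params)
            fixture_dir = outdir / "inputs"
            write_fixture(fixture_dir, truth, asvs, isolates, plates)
            ccm_refs, cem_refs = truth.ccm_refs, truth.cem_refs
            copies = truth.copy_table
        else:
            inputs = config["inputs"]
            isolates = read_isolates(inputs["isolates_fasta"], inputs["isolates_meta"])
            asvs = read_amplicon_table(
                inputs["asv_counts"], inputs["asv_fasta"], inputs["sample_meta"]
            )
            if inputs.get("asv_taxonomy"):
                asvs.asv_class, asvs.asv_genus = read_asv_taxonomy(
                    inputs["asv_taxonomy"]
                )
            if inputs.get("copy_numbers"):
                copies = read_copy_numbers(inputs["copy_numbers"])
            if inputs.get("ccm_fasta") and inputs.get("cem_fasta"):
                from .io import read_fasta

                ccm_refs = read_fasta(inputs["ccm_fasta"])
                cem_refs = read_fasta(inputs["cem_fasta"])
            if inputs.get("plate_counts") and inputs.get("dapi"):
                plates = read_plate_counts(inputs["plate_counts"], inputs["dapi"])
    except (KeyError, FileNotFoundError, ValueError) as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    seqs = {r.isolate_id: r.sequence for r in isolates}

    # --- stage: clustering -------------------------------------------------
    stage = "clustering"
    try:
        iotus = greedy_cluster(seqs, thresholds["iotu"], level_label="iOTU")
        ziotus = greedy_cluster(seqs, thresholds["ziotu"], level_label="ziOTU")
        ok, split_report = nest_check(ziotus, iotus)
        for level, cs in (("iotu", iotus), ("ziotu", ziotus)):
            rows = []
            for k, c in enumerate(cs.clusters):
                for m in c.member_ids:
                    rows.append(
                        {
                            "cluster_id": f"{cs.level_label}{k:04d}",
                            "centroid_id": c.centroid_id,
                            "member_id": m,
                            "identity_to_centroid": c.identities.get(m, float("nan")),
                        }
                    )
            _write_tsv(pd.DataFrame(rows), outdir / f"clusters_{level}.tsv", stamp)
        if not ok:
            logger.warning("ziOTU level has fewer clusters than iOTU level")
        if split_report:
            logger.info("%d ziOTUs split across iOTUs", len(split_report))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- stage: crossmap ---------------------------------------------------
    stage = "crossmap"
    try:
        ziotu_seqs = {c.centroid_id: seqs[c.centroid_id] for c in ziotus.clusters}
        result = match_ziotus_to_asvs(ziotus, ziotu_seqs, asvs)
        result = cultured_read_fraction(result, asvs, copies)
        overall = overall_cultured_fraction(result, asvs)
        overall_corr = (
            overall_cultured_fraction(result, asvs, copies) if copies else None
        )
        match_rows = [
            {"asv_id": a, "ziotu_ids": ",".join(z), "cultured": bool(z)}
            for a, z in result.matches.items()
        ]
        _write_tsv(pd.DataFrame(match_rows), outdir / "matches.tsv", stamp)
        frac = result.per_group_fraction_raw.copy()
        if result.per_group_fraction_corrected is not None:
            corr = result.per_group_fraction_corrected
            frac = frac.merge(
                corr.rename(
                    columns={
                        "cultured_pct_mean": "corrected_pct_mean",
                        "cultured_pct_sd": "corrected_pct_sd",
                    }
                ),
                on=["season", "treatment", "time", "n_replicates"],
            )
        _write_tsv(frac, outdir / "cultured_fractions.tsv", stamp)

        rank_frames = []
        for group in asvs.groups():
            ra = rank_abundance_overlay(asvs, result, group)
            ra.insert(0, "season", group[0])
            ra.insert(1, "treatment", group[1])
            ra.insert(2, "time", group[2])
            rank_frames.append(ra)
        _write_tsv(pd.concat(rank_frames), outdir / "rank_abundance.tsv", stamp)

        media = media_overlap(iotus, isolates)
        comp = composition_summary(isolates, "class_x_treatment")
        _write_tsv(comp, outdir / "composition_class_treatment.tsv", stamp)
        cults = culturability_ratio(plates) if plates is not None else []
        if cults:
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "sample_group": c.sample_group,
                            "medium": c.medium,
                            "cfu_per_mL": c.cfu_per_mL,
                            "dapi_per_mL": c.dapi_per_mL,
                            "culturability_pct": c.culturability_pct,
                        }
                        for c in cults
                    ]
                ),
                outdir / "culturability.tsv",
                stamp,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- stage: novelty ----------------------------------------------------
    stage = "novelty"
    novelty_ledger = None
    try:
        if ccm_refs and cem_refs:
            calls = screen_ziotus(
                ziotu_seqs,
                ccm_refs,
                cem_refs,
                species_thr=thresholds["species"],
                genus_thr=thresholds["genus"],
            )
            novelty_ledger = novelty_summary(
                calls,
                ziotu_table(isolates, ziotus),
                iotus.assignment(),
                n_isolates=len(isolates),
                ziotu_sequences=ziotu_seqs,
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "ziotu_id": c.ziotu_id,
                            "ccm_ref": c.ccm_ref,
                            "ccm_id": c.ccm_id,
                            "cem_ref": c.cem_ref,
                            "cem_id": c.cem_id,
                            "category": c.category,
                        }
                        for c in calls
                    ]
                ),
                outdir / "novelty_ledger.tsv",
                stamp,
            )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- stage: diversity --------------------------------------------------
    stage = "diversity"
    try:
        iotu_table = iotu_abundance_by_treatment(isolates, iotus)
        depth = int(iotu_table.sum(axis=0).min())
        rows = []
        for cat in iotu_table.columns:
            v = iotu_table[cat].to_numpy()
            curve = rarefaction_curve(
                v[v > 0],
                [depth],
                permutations=int(config.get("rarefaction_permutations", 1000)),
                seed=seed,
            )
            rows.append(
                {
                    "category": cat,
                    "n_isolates": int(v.sum()),
                    "richness": int((v > 0).sum()),
                    "chao1": chao1(v),
                    "shannon": shannon(v),
                    "pielou": pielou(v),
                    "rarefied_richness_mean": curve.mean_richness[0],
                    "rarefied_richness_sd": curve.sd_richness[0],
                    "rarefaction_depth": depth,
                }
            )
        diversity_df = pd.DataFrame(rows)
        _write_tsv(diversity_df, outdir / "diversity.tsv", stamp)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- stage: summary/plots ---------------------------------------------
    stage = "summary"
    try:
        summary = {
            "config_hash": chash,
            "seed": seed,
            "n_isolates": len(isolates),
            "n_iotus": iotus.n_clusters,
            "n_ziotus": ziotus.n_clusters,
            "n_asvs": len(asvs.asv_ids),
            "n_asvs_cultured": result.n_asvs_cultured,
            "pct_asvs_cultured": 100.0 * result.n_asvs_cultured / len(asvs.asv_ids),
            "pct_ziotus_matched": result.pct_ziotus_matched,
            "overall_cultured_reads_pct": overall,
            "overall_cultured_reads_pct_corrected": overall_corr,
            "media_overlap": media,
        }
        if novelty_ledger is not None:
            summary["novelty"] = {
                "n_novel_isolates": novelty_ledger.n_novel_isolates,
                "pct_of_isolates": novelty_ledger.pct_of_isolates,
                "n_novel_iotus": novelty_ledger.n_novel_iotus,
                "pct_of_iotus": novelty_ledger.pct_of_iotus,
                "n_novel_ziotus": novelty_ledger.n_novel_ziotus,
                "pct_of_ziotus": novelty_ledger.pct_of_ziotus,
                "n_novel_species": novelty_ledger.n_novel_species,
                "n_novel_genera": novelty_ledger.n_novel_genera,
            }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        if make_plots:
            _plots(outdir, result, asvs, novelty_ledger)
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    return PipelineResult(
        outdir=outdir,
        isolates=isolates,
        asvs=asvs,
        iotus=iotus,
        ziotus=ziotus,
        crossmap=result,
        overall_cultured_pct=overall,
        overall_cultured_pct_corrected=overall_corr,
        media=media,
        culturability=cults,
        novelty=novelty_ledger,
        diversity=diversity_df,
    )


def _plots(outdir: Path, result, asvs, novelty_ledger) -> None:
    """Cultured-fraction, rank-abundance and novelty-scatter figures."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = result.per_group_fraction_raw
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = frac["season"] + " " + frac["treatment"] + " " + frac["time"]
    ax.errorbar(
        range(len(frac)),
        frac["cultured_pct_mean"],
        yerr=frac["cultured_pct_sd"],
        fmt="o",
    )
    ax.set_xticks(range(len(frac)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("cultured reads (%)")
    fig.tight_layout()
    fig.savefig(outdir / "cultured_fractions.png", dpi=120)
    plt.close(fig)

    group = next(iter(asvs.groups()))
    ra = rank_abundance_overlay(asvs, result, group, top_k=60)
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = ["tab:red" if c else "0.7" for c in ra["cultured"]]
    ax.bar(ra["rank"], ra["mean_relative_abundance_pct"], color=colors)
    ax.set_yscale("log")
    ax.set_xlabel("rank")
    ax.set_ylabel("mean relative abundance (%)")
    ax.set_title(" ".join(group))
    fig.tight_layout()
    fig.savefig(outdir / "rank_abundance.png", dpi=120)
    plt.close(fig)

    if novelty_ledger is not None:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(
            [100 * c.cem_id for c in novelty_ledger.calls],
            [100 * c.ccm_id for c in novelty_ledger.calls],
            s=12,
        )
        for v, style in ((97.0, "k--"), (94.5, "--")):
            ax.axhline(v, ls="--", c="k" if v == 97 else "0.6", lw=0.8)
            ax.axvline(v, ls="--", c="k" if v == 97 else "0.6", lw=0.8)
        ax.set_xlabel("closest environmental match (%)")
        ax.set_ylabel("closest cultured match (%)")
        fig.tight_layout()
        fig.savefig(outdir / "novelty_scatter.png", dpi=120)
        plt.close(fig)
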