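"""Synthetic microcosm experiment generator with full ground truth.

Emulates the structure of the study data the pipeline was built for: a
seawater community sampled at the start of an experiment (t0) and after
manipulation treatments (controls CL/CD, predator-reduced PL/PD, diluted DL,
virus-reduced VL) in several seasons, sequenced both as near-full-length 16S
genes from plate isolates and as a V4-V5 amplicon ASV table, with
treatment-responsive copiotrophs, per-class 16S copy-number bias, planted
novelty-band taxa, and a dilution-plating series with DAPI totals.

Design notes:

* Taxon genes are generated by independently mutating one random ancestral
  template (default 12% per-site divergence).  Real 16S genes are homologous
  and end-to-end alignable; fully independent random sequences are not, and
  would not exercise the identity metric the way real data does.
* Sequencing noise is multinomial only (the analysis operates on denoised
  ASVs); the expected read share of a taxon is cells x copy number, which is
  exactly the bias the copy-number correction removes.
* Mutations planted for the novelty screen are substitution-only, so the
  planted identities are exact under the semi-global metric.
* Everything is deterministic under the seed: independent generator streams
  are derived for the community, the reads and the isolation stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import pandas as pd

from .cluster import pairwise_identity
from .io import (
    AmpliconTable,
    CopyNumberTable,
    IsolateRecord,
    PlateCountTable,
    write_amplicon_table,
    write_copy_numbers,
    write_fasta,
    write_isolates,
    write_plate_counts,
)

_BASES = np.array(list("ACGT"))

# class label -> (probability in the community, mean 16S copy number)
DEFAULT_CLASS_PROFILE: dict[str, tuple[float, float]] = {
    "Gammaproteobacteria": (0.30, 5.0),
    "Alphaproteobacteria": (0.25, 2.0),
    "Bacteroidia": (0.18, 3.0),
    "Bacilli": (0.07, 6.0),
    "Actinobacteria": (0.08, 3.0),
    "SAR11": (0.12, 1.0),
}

# multiplicative cell-abundance boost for copiotrophs at final time
DEFAULT_TREATMENT_EFFECTS: dict[str, float] = {
    "t0": 1.0,
    "CL": 2.0,
    "CD": 2.0,
    "PL": 5.0,
    "PD": 5.0,
    "DL": 15.0,
    "VL": 20.0,
}

# planted CFU/DAPI ratio per treatment for the plate-count series; the VL
# value prints as the 1.4% culturability maximum
DEFAULT_CULTURABILITY_TARGETS: dict[str, float] = {
    "t0": 0.001,
    "CL": 0.002,
    "CD": 0.002,
    "PL": 0.004,
    "PD": 0.004,
    "DL": 0.008,
    "VL": 0.014,
}


@dataclasses.dataclass
class SimParams:
    """Tunable generator parameters (defaults emulate the study conditions)."""

    seed: int = 0
    n_taxa: int = 200
    seasons: tuple[str, ...] = ("winter", "summer")
    treatments_tf: tuple[str, ...] = ("CL", "CD", "PL", "PD", "DL", "VL")
    n_replicates: int = 3
    reads_per_sample: int = 50_000
    gene_length: int = 1400
    template_divergence: float = 0.12
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    replicate_sigma: float = 0.2
    copiotroph_fraction: float = 0.25
    treatment_effects: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )
    class_profile: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROFILE)
    )
    amplicon_window: tuple[int, int] = (515, 888)  # 0-based half-open
    isolate_effort: int = 40  # isolates per (season, treatment, time) group
    strain_variant_rate: float = 0.3
    max_variant_subs: int = 3
    copiotroph_culturability: float = 1.0
    oligotroph_culturability: float = 0.02
    # (target CCM identity, target CEM identity, count) of planted candidates
    novelty_plan: tuple[tuple[float, float, int], ...] = (
        (0.99, 0.99, 3),
        (0.96, 0.96, 3),
        (0.93, 0.92, 2),
    )
    n_decoy_taxa: int = 2
    culturability_targets: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CULTURABILITY_TARGETS)
    )
    dapi_cells_per_mL: float = 1.0e6
    plated_volume_mL: float = 0.1
    dilution_factors: tuple[int, ...] = (1, 10, 100)

    def __post_init__(self) -> None:
        start, end = self.amplicon_window
        if not (0 <= start < end <= self.gene_length):
            raise ValueError("amplicon window must lie within the gene")
        if not 0 <= self.copiotroph_fraction <= 1:
            raise ValueError("copiotroph_fraction must be in [0, 1]")
        for ccm, cem, count in self.novelty_plan:
            for t in (ccm, cem):
                if not 0 < t <= 1:
                    raise ValueError(f"novelty identity target out of (0, 1]: {t}")
                if round(self.gene_length * (1 - t)) > self.gene_length:
                    raise ValueError("infeasible novelty identity target")

    def groups(self) -> list[tuple[str, str, str]]:
        out = []
        for season in self.seasons:
            out.append((season, "t0", "t0"))
            for t in self.treatments_tf:
                out.append((season, t, "tf"))
        return out


def _rng(seed: int, stream: str) -> np.random.Generator:
    key = sum(ord(c) for c in stream)
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def random_gene(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def mutate_sites(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def mutate_to_identity(
    seq: str, target: float, seed: int | np.random.Generator = 0
) -> str:
    """Substitution-only mutant at an exact identity target.

    Places round(L x (1 - target)) substitutions at distinct positions so
    the semi-global identity to the input equals the target (verified
    internally to +/- 0.2 percentage points).  Raises for infeasible targets.
    """
    if not 0 < target <= 1:
        raise ValueError(f"target identity must be in (0, 1], got {target}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = int(round(len(seq) * (1.0 - target)))
    if k > len(seq):
        raise ValueError("infeasible identity target for this sequence length")
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    out = mutate_sites(seq, positions, rng)
    achieved = pairwise_identity(seq, out)
    if abs(achieved - target) > 0.002:
        raise RuntimeError(
            f"mutate_to_identity overshoot: target {target}, achieved {achieved:.4f}"
        )
    return out


@dataclasses.dataclass
class CommunityTruth:
    """Everything the generator knows, for parameter-recovery tests."""

    params: SimParams
    taxa: pd.DataFrame  # index taxon_id; class/copies/copiotroph/cult coeff/...
    genes: dict[str, str]
    asv_sequence_of_taxon: dict[str, str]
    cell_fractions: pd.DataFrame  # samples x taxa (rows sum to 1)
    sample_meta: pd.DataFrame
    ccm_refs: dict[str, str]
    cem_refs: dict[str, str]
    copy_table: CopyNumberTable
    decoy_genes: dict[str, str] = dataclasses.field(default_factory=dict)
    # filled by simulate_amplicon_reads / simulate_isolation
    asv_taxa: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    asv_of_taxon: dict[str, str] = dataclasses.field(default_factory=dict)
    isolated_taxa: list[str] = dataclasses.field(default_factory=list)

    def group_samples(self) -> dict[tuple[str, str, str], list[str]]:
        out: dict[tuple[str, str, str], list[str]] = {}
        for s, row in self.sample_meta.iterrows():
            out.setdefault((row["season"], row["treatment"], row["time"]), []).append(s)
        return out

    def cultured_asv_ids(self) -> set[str]:
        """ASVs whose slice is carried by at least one isolated taxon."""
        isolated_slices = {self.asv_sequence_of_taxon[t] for t in self.isolated_taxa
                           if t in self.asv_sequence_of_taxon}
        return {
            a
            for a, taxa in self.asv_taxa.items()
            if any(self.asv_sequence_of_taxon[t] in isolated_slices for t in taxa)
        }

    def true_cultured_read_fraction(self, counts: pd.DataFrame) -> pd.Series:
        """Realised per-sample cultured-read percentage from the truth labels."""
        cultured = self.cultured_asv_ids()
        mask = np.array([a in cultured for a in counts.columns])
        vals = counts.to_numpy(dtype=float)
        return pd.Series(
            100.0 * vals[:, mask].sum(axis=1) / vals.sum(axis=1), index=counts.index
        )

    def true_cultured_cell_fraction(self) -> pd.Series:
        """Model cultured-cell percentage per sample (copy-bias free)."""
        cultured = self.cultured_asv_ids()
        cols = [
            t
            for t in self.cell_fractions.columns
            if self.asv_of_taxon.get(t) in cultured
        ]
        return 100.0 * self.cell_fractions[cols].sum(axis=1)


def simulate_community(params: SimParams) -> CommunityTruth:
    """Draw the taxa, their genes, classes, copy numbers and cell abundances."""
    rng = _rng(params.seed, "community")
    template = random_gene(params.gene_length, rng)

    n = params.n_taxa
    taxon_ids = [f"TAX{i:04d}" for i in range(n)]
    genes = {}
    for tid in taxon_ids:
        k = rng.binomial(params.gene_length, params.template_divergence)
        pos = rng.choice(params.gene_length, size=k, replace=False)
        genes[tid] = mutate_sites(template, pos, rng)

    labels = list(params.class_profile)
    probs = np.array([params.class_profile[c][0] for c in labels], dtype=float)
    probs = probs / probs.sum()
    classes = [labels[i] for i in rng.choice(len(labels), size=n, p=probs)]
    copies = [params.class_profile[c][1] for c in classes]
    copiotroph = [
        c != "SAR11" and rng.random() < params.copiotroph_fraction for c in classes
    ]
    cult_coeff = [
        0.0
        if c == "SAR11"
        else (
            params.copiotroph_culturability
            if is_cop
            else params.oligotroph_culturability
        )
        for c, is_cop in zip(classes, copiotroph)
    ]
    genus = [f"Genus{i % 40:03d}" for i in range(n)]

    novelty_category = ["" for _ in range(n)]
    novelty_ccm = [np.nan] * n
    novelty_cem = [np.nan] * n
    ccm_refs: dict[str, str] = {}
    cem_refs: dict[str, str] = {}

    # plant novelty-band taxa at the end of the taxon list: their references
    # sit at the target identities; everybody else gets a near-identical
    # cultured reference so the screen calls them known
    plan_slots: list[tuple[float, float]] = []
    for ccm_t, cem_t, count in params.novelty_plan:
        plan_slots.extend([(ccm_t, cem_t)] * count)
    if len(plan_slots) > n:
        raise ValueError("novelty plan larger than the community")
    planted = list(range(n - len(plan_slots), n))
    from .novelty import classify_novelty

    for idx, (ccm_t, cem_t) in zip(planted, plan_slots):
        tid = taxon_ids[idx]
        ccm_refs[f"CCM_{tid}"] = mutate_to_identity(genes[tid], ccm_t, rng)
        cem_refs[f"CEM_{tid}"] = mutate_to_identity(genes[tid], cem_t, rng)
        novelty_category[idx] = classify_novelty(ccm_t, cem_t)
        novelty_ccm[idx] = ccm_t
        novelty_cem[idx] = cem_t
        # make sure planted candidates are culturable so they reach the screen
        if cult_coeff[idx] == 0.0:
            cult_coeff[idx] = params.oligotroph_culturability
            classes[idx] = "Alphaproteobacteria"
            copies[idx] = params.class_profile["Alphaproteobacteria"][1]
            copiotroph[idx] = False
    for idx in range(n):
        if idx in planted:
            continue
        tid = taxon_ids[idx]
        ccm_refs[f"CCM_{tid}"] = mutate_to_identity(genes[tid], 0.995, rng)
        cem_refs[f"CEM_{tid}"] = mutate_to_identity(genes[tid], 0.99, rng)

    decoy_genes = {}
    for d in range(params.n_decoy_taxa):
        k = rng.binomial(params.gene_length, params.template_divergence)
        pos = rng.choice(params.gene_length, size=k, replace=False)
        tid = f"DECOY{d:02d}"
        decoy_genes[tid] = mutate_sites(template, pos, rng)
        ccm_refs[f"CCM_{tid}"] = mutate_to_identity(decoy_genes[tid], 0.995, rng)
        cem_refs[f"CEM_{tid}"] = mutate_to_identity(decoy_genes[tid], 0.99, rng)

    start, end = params.amplicon_window
    taxa = pd.DataFrame(
        {
            "class": classes,
            "copies": copies,
            "copiotroph": copiotroph,
            "culturability_coefficient": cult_coeff,
            "genus": genus,
            "novelty_category": novelty_category,
            "novelty_ccm_target": novelty_ccm,
            "novelty_cem_target": novelty_cem,
        },
        index=pd.Index(taxon_ids, name="taxon_id"),
    )

    # cell abundances: a lognormal base per taxon and season; copiotrophs get
    # the treatment boost at final time; light lognormal replicate jitter
    groups = params.groups()
    sample_ids = []
    meta_rows = []
    fractions = []
    base = {
        season: rng.lognormal(params.abundance_mu, params.abundance_sigma, size=n)
        for season in params.seasons
    }
    cop_mask = np.array(copiotroph, dtype=bool)
    for season, treatment, time in groups:
        boost = np.ones(n)
        if time == "tf":
            boost[cop_mask] = params.treatment_effects.get(treatment, 1.0)
        for rep in range(1, params.n_replicates + 1):
            jitter = rng.lognormal(0.0, params.replicate_sigma, size=n)
            cells = base[season] * boost * jitter
            sid = f"{season}_{treatment}_{time}_r{rep}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "season": season,
                    "treatment": treatment,
                    "time": time,
                    "replicate": str(rep),
                }
            )
            fractions.append(cells / cells.sum())

    cell_fractions = pd.DataFrame(
        fractions, index=pd.Index(sample_ids, name="sample_id"), columns=taxon_ids
    )
    sample_meta = pd.DataFrame(meta_rows, index=cell_fractions.index)

    copy_map = {c: params.class_profile[c][1] for c in params.class_profile}
    copy_map.setdefault("SAR11", 1.0)
    copy_table = CopyNumberTable(copies=copy_map, default_copies=1.0)

    return CommunityTruth(
        params=params,
        taxa=taxa,
        genes=genes,
        asv_sequence_of_taxon={t: genes[t][start:end] for t in taxon_ids},
        cell_fractions=cell_fractions,
        sample_meta=sample_meta,
        ccm_refs=ccm_refs,
        cem_refs=cem_refs,
        copy_table=copy_table,
        decoy_genes=decoy_genes,
    )


def simulate_amplicon_reads(
    truth: CommunityTruth, noise: bool = True
) -> AmpliconTable:
    """Multinomial amplicon reads with copy-number bias.

    Expected read share of a taxon is proportional to cells x copy number;
    taxa with identical amplicon-window slices collapse into one ASV (the
    truth records the many-to-one map).  With ``noise=False`` the expected
    counts are rounded to the nearest integer — useful only for sanity
    checks, as rounding breaks exactness at small depths.
    """
    params = truth.params
    rng = _rng(params.seed, "reads")

    # collapse identical slices into ASVs, ordered by first contributing taxon
    slice_to_asv: dict[str, str] = {}
    asv_taxa: dict[str, list[str]] = {}
    asv_seqs: dict[str, str] = {}
    for tid in truth.cell_fractions.columns:
        s = truth.asv_sequence_of_taxon[tid]
        if s not in slice_to_asv:
            aid = f"ASV{len(slice_to_asv):04d}"
            slice_to_asv[s] = aid
            asv_seqs[aid] = s
            asv_taxa[aid] = []
        asv_taxa[slice_to_asv[s]].append(tid)
    truth.asv_taxa = asv_taxa
    truth.asv_of_taxon = {
        t: slice_to_asv[truth.asv_sequence_of_taxon[t]]
        for t in truth.cell_fractions.columns
    }

    copies = truth.taxa["copies"].to_numpy(dtype=float)
    asv_ids = list(asv_seqs)
    taxon_idx = {t: k for k, t in enumerate(truth.cell_fractions.columns)}
    rows = []
    for sid in truth.cell_fractions.index:
        w = truth.cell_fractions.loc[sid].to_numpy() * copies
        p = w / w.sum()
        if noise:
            taxon_reads = rng.multinomial(params.reads_per_sample, p)
        else:
            taxon_reads = np.rint(p * params.reads_per_sample).astype(np.int64)
        asv_reads = np.zeros(len(asv_ids), dtype=np.int64)
        for aid_i, aid in enumerate(asv_ids):
            for t in asv_taxa[aid]:
                asv_reads[aid_i] += taxon_reads[taxon_idx[t]]
        rows.append(asv_reads)

    counts = pd.DataFrame(
        np.array(rows), index=truth.cell_fractions.index.copy(), columns=asv_ids
    )
    asv_class = {
        a: truth.taxa.loc[asv_taxa[a][0], "class"] for a in asv_ids
    }
    asv_genus = {
        a: truth.taxa.loc[asv_taxa[a][0], "genus"] for a in asv_ids
    }
    return AmpliconTable(
        counts=counts,
        asv_sequences=asv_seqs,
        sample_meta=truth.sample_meta.copy(),
        asv_class=asv_class,
        asv_genus=asv_genus,
    )


def simulate_isolation(
    truth: CommunityTruth,
) -> tuple[list[IsolateRecord], PlateCountTable]:
    """Colony picking plus the dilution-plating series.

    Isolates are drawn per group with probability proportional to
    cells x culturability coefficient; each isolate's emitted sequence is the
    taxon's full gene, optionally carrying a few "strain variant"
    substitutions placed outside the amplicon window (so the variant ziOTU
    still contains its ASV exactly).  Every planted novelty candidate and
    decoy taxon is guaranteed one isolate in the first t0 group.  Plate
    counts are integer-consistent across the dilution series so that
    culturability_ratio recovers the planted CFU/DAPI ratio exactly.
    """
    params = truth.params
    rng = _rng(params.seed, "isolation")
    start, end = params.amplicon_window
    gene_len = params.gene_length
    outside = np.array(
        [p for p in range(gene_len) if not (start <= p < end)], dtype=np.int64
    )

    coeff = truth.taxa["culturability_coefficient"].to_numpy(dtype=float)
    taxon_ids = list(truth.cell_fractions.columns)
    isolates: list[IsolateRecord] = []
    isolated: set[str] = set()
    counter = 0

    def emit(
        tid: str,
        gene: str,
        group: tuple[str, str, str],
        rep: str,
        allow_variant: bool = True,
    ) -> None:
        nonlocal counter
        seq = gene
        if (
            allow_variant
            and params.max_variant_subs > 0
            and rng.random() < params.strain_variant_rate
        ):
            k = int(rng.integers(1, params.max_variant_subs + 1))
            pos = rng.choice(outside, size=k, replace=False)
            seq = mutate_sites(gene, pos, rng)
        medium = "MA" if rng.random() < 0.5 else "mR2A"
        counter += 1
        row = truth.taxa.loc[tid] if tid in truth.taxa.index else None
        isolates.append(
            IsolateRecord(
                isolate_id=f"ISO{counter:05d}",
                sequence=seq,
                season=group[0],
                treatment=group[1],
                time=group[2],
                medium=medium,
                replicate=rep,
                genus=None if row is None else str(row["genus"]),
                class_label=None if row is None else str(row["class"]),
            )
        )
        isolated.add(tid)

    group_samples = truth.group_samples()
    for group, samples in group_samples.items():
        for k in range(params.isolate_effort):
            sid = samples[k % len(samples)]
            w = truth.cell_fractions.loc[sid].to_numpy() * coeff
            total = w.sum()
            if total <= 0:
                break  # no culturable biomass in this group; empty isolate list
            tid = taxon_ids[rng.choice(len(taxon_ids), p=w / total)]
            emit(tid, truth.genes[tid], group, rep=str(k % len(samples) + 1))

    first_t0 = (params.seasons[0], "t0", "t0")
    planted = truth.taxa.index[truth.taxa["novelty_category"] != ""]
    for tid in planted:
        if tid not in isolated:
            emit(tid, truth.genes[tid], first_t0, rep="1", allow_variant=False)
    for tid, gene in truth.decoy_genes.items():
        emit(tid, gene, first_t0, rep="1", allow_variant=False)

    truth.isolated_taxa = sorted(isolated)

    plate_rows = []
    dapi: dict[str, float] = {}
    for season, treatment, time in params.groups():
        group_id = f"{season}_{treatment}_{time}"
        target = params.culturability_targets.get(treatment, 0.001)
        dapi[group_id] = params.dapi_cells_per_mL
        cfu_per_mL = target * params.dapi_cells_per_mL
        for medium in ("MA", "mR2A"):
            for dilution in params.dilution_factors:
                colonies = cfu_per_mL * params.plated_volume_mL / dilution
                if abs(colonies - round(colonies)) > 1e-9:
                    raise ValueError(
                        "culturability target does not yield integer plate counts; "
                        "choose targets that are multiples of "
                        f"{max(params.dilution_factors) / (params.dapi_cells_per_mL * params.plated_volume_mL)}"
                    )
                for rep in range(1, params.n_replicates + 1):
                    plate_rows.append(
                        {
                            "sample_group": group_id,
                            "medium": medium,
                            "replicate": str(rep),
                            "colonies": int(round(colonies)),
                            "dilution_factor": int(dilution),
                            "plated_volume_mL": params.plated_volume_mL,
                        }
                    )

    plates = PlateCountTable(rows=pd.DataFrame(plate_rows), dapi=dapi)
    return isolates, plates


def simulate_all(
    params: SimParams,
) -> tuple[CommunityTruth, AmpliconTable, list[IsolateRecord], PlateCountTable]:
    """Run the three generator stages in order."""
    truth = simulate_community(params)
    table = simulate_amplicon_reads(truth)
    isolates, plates = simulate_isolation(truth)
    return truth, table, isolates, plates


def write_fixture(
    outdir: str | Path,
    truth: CommunityTruth,
    table: AmpliconTable,
    isolates: list[IsolateRecord],
    plates: PlateCountTable,
) -> dict[str, Path]:
    """Write the exact file set the pipeline consumes, plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "isolates_fasta": outdir / "isolates.fasta",
        "isolates_meta": outdir / "isolates.tsv",
        "asv_counts": outdir / "asv_counts.tsv",
        "asv_fasta": outdir / "asvs.fasta",
        "sample_meta": outdir / "samples.tsv",
        "asv_taxonomy": outdir / "asv_taxonomy.tsv",
        "copy_numbers": outdir / "copy_numbers.tsv",
        "ccm_fasta": outdir / "ccm.fasta",
        "cem_fasta": outdir / "cem.fasta",
        "plate_counts": outdir / "plate_counts.tsv",
        "dapi": outdir / "dapi.tsv",
        "truth": outdir / "truth.json",
    }
    write_isolates(paths["isolates_fasta"], paths["isolates_meta"], isolates)
    write_amplicon_table(
        table, paths["asv_counts"], paths["asv_fasta"], paths["sample_meta"]
    )
    pd.DataFrame(
        {
            "asv_id": table.asv_ids,
            "class": [table.asv_class.get(a, "") for a in table.asv_ids],
            "genus": [table.asv_genus.get(a, "") for a in table.asv_ids],
        }
    ).to_csv(paths["asv_taxonomy"], sep="\t", index=False)
    write_copy_numbers(paths["copy_numbers"], truth.copy_table)
    write_fasta(paths["ccm_fasta"], truth.ccm_refs)
    write_fasta(paths["cem_fasta"], truth.cem_refs)
    write_plate_counts(plates, paths["plate_counts"], paths["dapi"])

    frac = truth.true_cultured_read_fraction(table.counts)
    truth_doc = {
        "seed": truth.params.seed,
        "n_taxa": truth.params.n_taxa,
        "isolated_taxa": truth.isolated_taxa,
        "cultured_asvs": sorted(truth.cultured_asv_ids()),
        "per_sample_cultured_read_pct": {s: float(v) for s, v in frac.items()},
        "per_sample_cultured_cell_pct": {
            s: float(v) for s, v in truth.true_cultured_cell_fraction().items()
        },
        "novelty": {
            t: truth.taxa.loc[t, "novelty_category"]
            for t in truth.taxa.index
            if truth.taxa.loc[t, "novelty_category"]
        },
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return paths
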