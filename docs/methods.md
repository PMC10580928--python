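# Methods

This note documents the models, numerical choices and limitations behind
`isoamp`, in the spirit of a statistical-software methods appendix.

## Pairwise identity and clustering

The package's identity primitive is an optimal **semi-global alignment with
affine gaps**: global over both sequences but with free (unpenalised)
terminal gaps, scored match +5 / mismatch −4 / gap open −10 / gap extend −1
(a gap of length L costs 10 + (L − 1)). Identity is

```
identity = identical unambiguous columns / alignment columns
```

where the column count excludes terminal-gap columns and counts internal gap
columns as differences, and IUPAC ambiguity codes never count as matches —
not even against themselves — and score as mismatches. This is deliberately
conservative at the 99–100% thresholds, where a single column decides cluster
membership. Published isolate-clustering workflows typically name a
clustering program but not its alignment parameters; the contract above is
explicit and oracle-checkable (the test suite verifies the numba kernel against an
independent pure-Python dynamic program, against exhaustive alignment
enumeration on short sequences, and against Biopython's `PairwiseAligner`
scores).

Determinism: ties in the dynamic program are broken by a fixed traceback
preference (residue pair > gap-in-second > gap-in-first > fresh start) and a
fixed scan order of the boundary cells, and the input pair is canonically
ordered (longer first, then lexicographic) before alignment, so
`pairwise_identity` is a symmetric, deterministic function.

**Greedy clustering** processes sequences in decreasing length order (ties by
ascending id); a query joins the first centroid, in creation order, at or
above the threshold, else founds a new cluster. No k-mer accept/reject
heuristics: every query is compared against every centroid, which is exact
and affordable at collection scale (≤ a few thousand sequences). Exact
duplicate sequence strings are deduplicated internally — a duplicate provably
takes the same decision as its first occurrence — and at threshold 1.0 the
identity test reduces to exact, unambiguity-free substring containment of the
shorter sequence in the longer, which is applied directly. Cluster results
are invariant to input file order because the processing order is recomputed
internally.

*Known limitation*: with free end gaps, two short sequences that share only a
perfect suffix–prefix overlap can score identity 1.0 over a tiny core. This
cannot arise among near-full-length homologous 16S genes (whose end-to-end
alignment dominates the score by orders of magnitude) but means the metric
should not be applied to collections of mutually non-homologous short
fragments.

## Cross-mapping and cultured fractions

"100% similarity" of a short amplicon to a full-length gene is implemented as
**exact substring containment** of the ASV (or its reverse complement) in the
ziOTU centroid — at 100% the two notions coincide, and substring search is
exact and fast. An ASV matching several ziOTUs is flagged cultured once; a
ziOTU may match several ASVs. Per-replicate cultured-read fractions are
computed first and then averaged within a (season, treatment, time) group;
the replicate standard deviation (ddof = 1; 0 for singleton groups) is
reported alongside.

**Copy-number correction** divides each ASV's reads by the mean 16S copy
number of its class (SAR11 by its own entry; unmapped classes fall back to a
default with a logged warning rather than aborting), renormalises per sample,
and recomputes the fractions. If the weights are exact, the corrected
fraction is an unbiased-to-O(1/N) ratio estimator of the cultured *cell*
fraction; the acceptance suite checks it against generator ground truth
within three delta-method multinomial standard errors.

**Culturability** is `100 × CFU mL⁻¹ / DAPI mL⁻¹`, with per-plate
CFU mL⁻¹ = colonies × dilution / plated volume averaged over the plates of a
group/medium.

## Novelty screen

Best-hit identities against the cultured (CCM) and environmental (CEM)
reference sets use the same alignment identity (a global-style measure where
BLAST-style local percent identity is conventional; at near-full-length the
two coincide at the thresholds of interest, but partial-length references
would be penalised). Ties between equally good references go to the smaller
reference id. Thresholds are strict `<` for novelty (equality at 97% or 94.5%
is not novel). The species/genus bands are defined on max(CCM, CEM), so the
asymmetric corner CCM < 94.5% ≤ CEM < 97% is assigned to the species band —
a documented convention for a case the threshold scheme leaves open. Novel
species/genera counts re-cluster the band candidates at 97% / 94.5%.

## Diversity

Chao1 uses the bias-corrected form `S_obs + F₁(F₁−1)/(2(F₂+1))`
unconditionally — it is defined when F₂ = 0 and equals S_obs when F₁ = 0 —
diverging from the classical `F₁²/(2F₂)` form (documented; the two coincide
asymptotically). Shannon uses the natural log (base is configurable nowhere —
callers can rescale). Pielou is undefined (NaN) for single-taxon vectors.
Faith's PD sums the branch lengths of the union of root paths of the observed
tips, counting the root edge when it carries a length. Rarefaction draws
multivariate-hypergeometric subsamples (without replacement) with a seeded
`numpy` generator; per-depth sub-seeds are derived deterministically from
(seed, depth) so curves are reproducible piecewise; the grouped isolate table
is rarefied to the smallest group total, mirroring standard practice of
comparing richness at equal effort.

## Synthetic microcosms

The generator emulates the structure of a seawater manipulation experiment:
seasons × treatments {t0, CL, CD, PL, PD, DL, VL} (defaults: 2 seasons ×
(t0 + 6 final-time treatments) = 14 groups × 3 replicates = 42 samples),
copiotroph cell abundances multiplied at final time by per-treatment factors
(defaults DL/VL ≫ PL/PD > CL/CD > 1), lognormal base abundances (μ = 0,
σ = 1.5 — a generic skewed rank-abundance stand-in; parameters exposed), and
plate-based isolation biased by per-taxon culturability coefficients
(copiotrophs 1.0, oligotrophs 0.02, SAR11 0 — plates strongly favour
copiotrophs).

**Gene model.** Taxon genes (1,400 nt) are generated by independently
mutating one random ancestral template at 12% per-site divergence. Real 16S
genes are homologous and alignable end to end; fully independent random
sequences are not, and under a free-end-gap identity they can collide on
short perfect overlaps (see the clustering limitation above). The
shared-template model is therefore both the biologically faithful emulation
and the one under which the 99/100% thresholds behave as they do on real
collections. The amplicon is a fixed window of the gene (default 515–888,
0-based half-open, evoking a V4-V5 primer span); identical windows across
taxa collapse into one ASV and the truth records the many-to-one map.

**Read model.** Expected read share ∝ cells × copy number; reads are
multinomial per sample (no sequencing-error model — the analysis consumes
denoised ASVs). Copy numbers are per class (defaults between 1 and 6, SAR11
fixed at 1), so correcting by the class table recovers cell fractions exactly
in the noise-free limit.

**Isolation.** Isolates are drawn per group ∝ cells × culturability
coefficient; each emitted sequence is the taxon's full gene, optionally with
up to 3 "strain variant" substitutions placed outside the amplicon window
(creating extra ziOTUs whose ASV match is preserved). Novelty-band taxa
planted by `novelty_plan` (substitution-only mutants at exact identity
targets, verified internally to ±0.2 pp) and "decoy" taxa absent from the
community are each guaranteed one isolate. Plate counts are
integer-consistent across the 1×/10×/100× dilution series so the CFU/DAPI
ratio is recovered exactly; the default per-treatment targets rise from 0.1%
at t0 to 1.4% in VL.

**What passing tests do and do not show.** The generator exercises exact
cross-mapping, copy-bias removal, threshold classification and clustering
separability under a substitution-only, chimera-free, contaminant-free model
with perfectly known taxonomy. It does not emulate sequencing error, PCR
chimeras, intragenomic 16S polymorphism, partial-length Sanger reads, or
reference databases that lack a near neighbour — so green tests certify the
arithmetic and the algorithms, not robustness to those real-data pathologies.

## Problem sizes

Alignment work is quadratic in collection size, so the default verification
sizes are: the full default experiment (200 taxa / 42 samples / 50,000
reads per sample) wherever only exact matching is needed (cross-mapping,
fractions, correction); a 40-taxon experiment for 99% iOTU clustering, media
overlap and diversity; and a 20-taxon experiment for the all-ziOTU ×
all-reference novelty screen. `scripts/acceptance.py` states these sizes in
its output (`n` fields). The clustering/identity oracles run on 30-sequence
planted fixtures at 200 nt and on random pairs up to 100 nt.

## Error handling conventions

Readers reject malformed input (duplicate FASTA ids, non-integer counts with
the offending cell named, missing metadata — a strict join, since silently
dropped samples would bias cultured-fraction denominators) rather than
coercing. Sequences are canonicalised to uppercase DNA (U→T) on read;
treatment/season labels are case-normalised. Empty candidate sets in the
novelty counts yield (0, 0); a group with no culturable biomass yields an
empty isolate list with a warning; zero-read samples are errors.
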