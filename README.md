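# markerprof

Marker-gene taxonomic profiling of long metagenomic reads.

`markerprof` estimates, for a shotgun-sequenced microbial community,
(1) the **total number of prokaryotic genome copies** and (2) a
**species-level taxonomic abundance profile** — the fraction of cells,
not of reads, per species. It is aimed at microbiome researchers
working with long (e.g. nanopore) reads who need cell-fraction
abundances: for absolute quantification against spike-ins, for
abundance-aware diversity indices, or as the denominator for gene
abundances such as antibiotic-resistance-gene (ARG) copies per cell.

## Method in brief

Reads are first searched (frame-shift-aware blastx mode) against a
protein database of eight universal single-copy ribosomal protein
genes per prokaryotic domain. After a greedy overlap cull of the hits,
each marker sequence's coverage is summarized by a positional trimmed
mean over its central 50% of positions — with the default 75%
subject-cover cutoff this equals the number of mapped hits — and the
total genome copies is the mean coverage over the 8 markers:

    copies_total = (1/8) Σ_m cov(m)

so a single marker-containing read contributes exactly 1/8 genome
copies, the detection floor.

Marker-containing reads are then aligned to a nucleotide database of
10 kb marker-flanking windows. Alignments within tight ratios of each
read's best (AS > 0.99·max, MS > 0.99·max, or ID > 0.999·max) define a
binary read-species matrix x, and an EM loop estimates the species
mixture θ and per-read posteriors z:

    E: z_ij = x_ij θ_j / Σ_j x_ij θ_j        M: θ_j = Σ_i z_ij / n

iterated from θ_j = 1/k until the L1 change of θ is < 1e-5 (at most
100 iterations). Reads are hard-assigned by argmax z with a
deterministic tie-break, and genome copies are apportioned by assigned
read counts. See `docs/methods.md` for the full model, the
marker-screening statistics (universality, deviance, F0.5, genomic
distance clustering), the evaluation metrics, and the ARG
copies-per-cell layer.

## Worked example

Simulate a 4-species community with known truth, then profile it:

```sh
markerprof simulate --k 4 --reads-per-copy 8 --total-copies 20 \
    --ambiguity 0.1 --seed 7 --out-dir fix
markerprof profile --hits fix/protein_hits.tsv --paf fix/alignments.paf \
    --ref2species fix/ref2species.tsv --lineages fix/lineages.tsv \
    --out profile.tsv
```

which prints

```
161 reads -> fix/protein_hits.tsv
total genome copies: 20.1250
species detected: 4
```

The simulated community planted 20 genome copies at a depth of one
read per marker per copy; 161 marker reads / 8 markers = 20.125
estimated copies (the 0.125 excess is one read of rounding). The
profile (`profile.tsv`, rank columns abbreviated):

```
genus     species              copies   rel_abundance
Genus001  Genus001 species001  8        0.3975
Genus000  Genus000 species000  5.375    0.2671
Genus002  Genus002 species002  4.625    0.2298
Genus003  Genus003 species003  2.125    0.1056
```

against planted abundances (0.3830, 0.2844, 0.2160, 0.1166) — each
species' copies are its assigned read count / 8, and relative
abundances are copies over the classified total. `markerprof evaluate`
compares two such profiles (x/y ratio, precision/recall/F1, L1, L2,
Bray–Curtis, Jensen–Shannon); `markerprof arg-profile` divides
filtered ARG read counts by genome copies to report ARG copies per
cell; `markerprof build-db` and `markerprof select-markers` cover
reference-side window extraction and marker screening.

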