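# pelagiscope

Viral ecogenomics of phage isolate genomes in ocean viromes: who is where,
how abundant, and how their populations are structured.

`pelagiscope` is a Python toolkit for the analysis chain used to
characterise a phage isolate genome (the motivating case is a ~35 kb polar
pelagiphage) against global marine virome data:

- **Read recruitment** with the conservative virome standard: alignments are
  kept at ≥95% nucleotide identity over ≥90% of the read, reads are assigned
  competitively to their single best genome, and a genome counts as detected
  in a sample only when recruited reads cover ≥40% of its length (breadth
  filter against false positives). Abundance is reported as
  **RPKM** = reads / (genome kb) / (million sample reads).
- **Coverage profiling** with a hypervariable-region (HVR) caller — maximal
  runs of per-base depth below 20% of the genome-wide median, at least
  500 bp long — and **direct terminal repeat** (DTR) detection, both from
  the sequence (exact prefix = suffix) and from the ~2× terminal coverage
  that *pac*-type headful packaging leaves.
- **Comparative genomics**: fragment-based bidirectional **ANI**,
  single-linkage clustering at ICTV-style species (95%) and genus (60%)
  thresholds, upper-tail **hypergeometric** probabilities of shared protein
  clusters, and core-gene extraction from cluster tables.
- **SNV population profiling**: per-position departure-from-consensus
  (1 − consensus/coverage) with coverage ≥10× and departure ≥0.10 filters, a
  70% genome-breadth filter on samples, hierarchical clustering of the
  sample × position departure matrix, and a substitution-accumulation
  estimator (subs = μ · L · generations/yr · years).
- **Ecology**: absolute-latitude banding (Polar ≥66°, Temperate 33–66°,
  Tropical <33°), prevalence filtering (non-zero RPKM in ≥5 samples),
  per-genome RPKM ~ covariate OLS with Benjamini–Hochberg correction, and
  bootstrap difference-of-medians effect sizes.
- A **synthetic virome generator** that plants all of the above as ground
  truth — DTRs, divergent HVR intervals in a strain population,
  environment-driven community weights along a latitude/temperature
  gradient — and emits SAM/FASTA/TSV, so the whole pipeline is testable
  without downloading any data.

## Worked example

Simulate a 35,392 bp, 31.5% G+C phage genome; plant a 125 bp terminal
repeat and a strain population that is 30% divergent inside
[13,646, 15,713) and 1% divergent elsewhere; recruit ~200× of reads against
the reference and call the HVR:

```python
import pelagiscope as pg
from pelagiscope import synthetic as syn

ref = pg.plant_dtr(pg.simulate_genome(35392, 0.315, seed=1,
                                      genome_id="phage"), 125)
strains = pg.simulate_strains(ref, 10, 0.01, (13646, 15713), 0.30, seed=2)
community = pg.CommunityDesign("S1", {}, {"phage": 1.0})
reads, truth = syn.simulate_reads(community, {"phage": ref},
                                  {"phage": strains},
                                  n_reads=72_000, read_length=100,
                                  error_rate=0.005, seed=3)
kept = pg.filter_alignments(syn.reads_to_alignments(reads))
profile = pg.coverage_from_alignments(kept, len(ref))
print(pg.detect_dtr(ref.sequence))
print(pg.call_hvrs(profile)[0])
print(pg.substitution_accumulation(1e-6, 1e-4, len(ref)))
```

prints (seed 1):

```
DTRCall(length=125, method='prefix_suffix_repeat')
HVRCall(start=13641, end=15722, mean_depth_inside=0.485..., median_depth_genome=202.0)
SubstitutionEstimate(mu_low=1e-06, mu_high=0.0001, genome_length=35392,
                     generations_per_year=1.0, years=1.0,
                     subs_low=0.035392, subs_high=3.5392)
```

The DTR comes back at exactly the planted 125 bp. The HVR call overlaps the
planted interval almost perfectly: reads from the divergent region carry too
many mismatches to pass the 95% identity filter, so depth collapses below
20% of the genome median there. The substitution estimate says a genome of
this size accumulates ~0.04–3.5 substitutions per year across the
literature range of dsDNA-phage mutation rates (10⁻⁶–10⁻⁴ per site per
infection).

The same operations are available from the shell:

```sh
pelagiscope simulate --config sim.yaml --outdir demo --seed 1
pelagiscope recruit --genomes demo/genomes.fasta --sam demo/S001.sam ...
pelagiscope hvr --coverage coverage.tsv
pelagiscope dtr demo/genomes.fasta
pelagiscope run --config pipeline.yaml   # full pipeline, one config
```

## Layout

| module                      | contents                                             |
| --------------------------- | ---------------------------------------------------- |
| `pelagiscope.synthetic`     | genomes, strains, reads, SAM writer, env gradient    |
| `pelagiscope.recruit`       | identity/fraction filters, competitive assignment, RPKM, breadth |
| `pelagiscope.coverage_hvr`  | depth profiles, HVR caller, DTR detection            |
| `pelagiscope.comparative`   | ANI, taxon clustering, hypergeometric genes, core genes |
| `pelagiscope.popgen`        | pileups, SNV calling, departure matrix, clustering, substitutions |
| `pelagiscope.ecology`       | latitude bands, prevalence, regressions, bootstrap effect sizes |
| `pelagiscope.io`            | FASTA/SAM/TSV/BED/Newick I/O, pipeline driver        |
| `pelagiscope.cli`           | `pelagiscope` command                                |

See `docs/methods.md` for the models, parameter defaults and the design
decisions behind them.
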