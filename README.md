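# snofrag

Discovery, quantification and cohort screening of **snoRNA-derived RNAs
(sdRNAs)** from small RNA-seq data, with miRNA-like 3'UTR target scanning.

Small nucleolar RNAs are processed into specifically excised 16–36 nt
fragments that load into Argonaute and act like microRNAs. In tumor
cohorts, individual sdRNAs can be far more prevalent and abundant than in
matched normal tissue, which makes them candidate oncogenic regulators and
biomarkers. `snofrag` implements the full in-silico screen for such
fragments for researchers who have: a snoRNA reference (FASTA), small
RNA-seq libraries for a tumor/normal cohort (FASTQ), optionally an
Argonaute immunoprecipitation library, and 3'UTR sequences for candidate
targets.

## Method

1. **Ingest** — 3' adapter trimming (exact suffix/prefix match, TruSeq
   Small RNA RA3 by default), length QC, per-library read totals (the
   reads-per-million denominators).
2. **Alignment** — reads are placed on snoRNA precursors only as whole-read
   **perfect matches** (100% identity, ungapped, ≥ 20 nt), via a 6-mer word
   index; in this regime seed-and-extend equals exhaustive substring
   search, which the tests exploit as an oracle.
3. **Fragment calling** — per-precursor read coverage d(i) is scored with
   an unnormalized Haar step response
   `score(i) = mean(d[i:i+w]) − mean(d[i−w:i])`; local extrema above a
   robust threshold give rise/fall boundaries, paired into 16–36 nt
   fragments with minimum read support. Discovery runs on coverage pooled
   across the cohort; each library is then quantified against the shared
   catalogue in RPM = reads × 10⁶ / library total.
4. **Cohort screen** — per fragment: prevalence (fraction of samples with
   RPM ≥ 30), class mean RPM, pseudocounted fold change
   `(μ_T + 1)/(μ_N + 1)`. Candidates need fold change ≥ 2 and expression in
   ≥ 50% of tumors; final candidates additionally need tumor prevalence
   > 90%, normal prevalence < 50% and ≥ 1 Ago-IP read contained in the
   fragment.
5. **Target scanning** — every 3'UTR window of guide length is paired
   antiparallel against the sdRNA; positions are classed Watson–Crick
   (A:U, G:C), G:U wobble, or unpaired; sites are ranked by longest
   contiguous WC run and paired fraction, and rendered as three-line
   duplex text (`|` = WC, `:` = wobble).

A seed-deterministic synthetic-data module (`snofrag.simdata`) generates
every input the pipeline consumes — precursors with planted fragments,
adaptered FASTQ libraries with guaranteed-nonaligning background reads,
tumor/normal cohorts with Bernoulli prevalence and truncated-Gamma
expression, Ago libraries, and UTRs with planted (optionally wobbled)
target sites — together with machine-readable truth.

## Worked example

```bash
snofrag simulate --seed 5 --out study --n-tumor 8 --n-normal 4 --depth 20000
snofrag run-all study/config.yaml
```

prints

```
synthetic study written to study
called 2 fragments; 1 final candidates -> study/results
```

and writes `catalogue.tsv` (called fragments with support),
`rpm_matrix.tsv` (fragments × samples), `candidate_report.tsv` (per-
fragment prevalence, fold change, Ago support and pass/fail flags),
`final_candidates.tsv`, and a `manifest.json` with config and input
hashes. In this small study the two planted fragments are both recovered;
only one survives the final screen because, at 12 samples, the other's
realized normal prevalence lands above the 50% cut — at full cohort scale
both separate cleanly (see the reproduction script below).

The same run is available as a library call:

```python
from snofrag import simdata
from snofrag.pipeline import run_cohort_from_libraries

records, planted = simdata.simulate_reference(6, rng=1, fragments_per_precursor=(1, 2))
frags = simdata.default_cohort_fragments(records, planted)
libs, truth = simdata.simulate_cohort(records, frags, n_tumor=30, n_normal=10,
                                      mode="reads", depth=100_000, rng=2)
result = run_cohort_from_libraries(records, libs)
print(result.stats)        # prevalence, mean RPM, fold change per fragment
```

## Layout

| module | role |
| --- | --- |
| `snofrag.ingest` | FASTA/FASTQ reading, adapter trimming, QC |
| `snofrag.aligner` | perfect-match placement, word index, locus hits |
| `snofrag.fragcall` | coverage, Haar edge detection, fragment calls, RPM |
| `snofrag.cohort` | expression matrix, prevalence/fold filters, Ago support, selection |
| `snofrag.targetscan` | 3'UTR scanning, pair classes, duplex rendering |
| `snofrag.simdata` | seeded generators for every input + truth manifests |
| `snofrag.pipeline` / `snofrag.cli` | orchestration and the `snofrag` command |

See `docs/methods.md` for the model, parameter defaults and limitations.
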