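# exposig

Mutational-signature analysis for carcinogen-exposure clone experiments.

A common experimental design for studying mutagenesis in a tissue of
interest is to expose cultured cells to a candidate carcinogen, expand
single cells into clones so each clone's private somatic mutations are
detectable by whole-genome sequencing, and compare exposed clones
against unexposed control clones. `exposig` implements the downstream
computational analysis of such a design, starting from per-clone VCFs:

- **Catalogues** — classify every somatic variant into the canonical
  channel schemes: 96 single-base-substitution channels (six
  pyrimidine-centred classes C>A, C>G, C>T, T>A, T>C, T>G × 16 flanking
  dinucleotide contexts), 78 strand-agnostic doublet-substitution
  channels, and 83 indel channels (type × length × homopolymer/repeat
  context, with microhomology sub-classes), then tally per-sample
  count matrices and six-class percentage summaries with one-way
  ANOVA + Tukey HSD across classes.
- **Exposure signatures** — derive the exposure process's spectrum by
  normalising exposed clones against controls: per-channel mean excess,
  floored at zero, renormalised to a unit-sum profile
  (`w ∝ max(0, mean_exposed − mean_control)`).
- **Catalogue comparison** — cosine similarity ranking against any
  signature catalogue TSV (e.g. COSMIC-format files), and non-negative
  least-squares refitting `min_{w≥0} ‖q − Σᵢ wᵢ sᵢ‖₂`.
- **Selection statistics** — per-gene overmutation/protection tests
  under a uniform-placement null (`X ~ Poisson(λ)`,
  `λ = total · footprint / genome`, one-sided tails FDR-controlled by
  Benjamini–Hochberg), and OLS regression of binned mutation rate
  (per Mb) on gene expression level.
- **Simulator** — synthetic reference genomes and clone panels drawn
  from explicit background and exposure signatures, with
  channel-conditional site placement, per-mutation ground truth, gene
  models, and optional expression-coupled mutation rates. Everything
  is reproducible byte-for-byte from a single seed.

## Worked example

Simulate a 3-control / 4-exposed panel, build catalogues and derive the
exposure signature (full scripts under `examples/`):

```python
from exposig import *
from exposig.simulate import SimulationConfig, simulate_study, default_exposure_sbs96

study = simulate_study(SimulationConfig(seed=2, n_contigs=2, contig_length_bp=150_000,
                                        background_burden=800, exposure_burden=1500))
classified, _ = classify_records(study.all_records(), study.genome, "SBS96")
catalog = build_catalog(classified, "SBS96", sample_ids=list(study.groups))
summary = class_percentages(catalog.subset(study.exposed_samples))
profile = derive_exposure_signature(catalog.subset(study.exposed_samples),
                                    catalog.subset(study.control_samples))
print(cosine_similarity(profile.weights, default_exposure_sbs96()))
```

Running `examples/02_build_catalogs.py` prints:

```
control clones (n=3): C>A 6.3%±0.9, C>G 6.6%±1.1, C>T 42.0%±2.2, T>A 4.6%±1.0, T>C 32.4%±2.4, T>G 8.1%±0.6
  one-way ANOVA across classes: F=336.0, p=1.85e-12
exposed clones (n=4): C>A 51.2%±1.0, C>G 5.1%±0.3, C>T 21.1%±0.6, T>A 4.5%±0.3, T>C 13.3%±0.7, T>G 4.7%±0.2
```

Control clones are dominated by C>T/T>C transitions; exposure shifts
the spectrum to C>A transversions. `examples/03_derive_and_compare.py`
shows the derived profile matching the generating signature at cosine
0.998 and ranking it first among nine random decoys, with an NNLS
weight of ~1 on it.

## Command line

The same pipeline is available as subcommands for shell use:

```sh
exposig simulate --seed 1 --out study/
exposig catalog   --config run.json --out out/catalog
exposig signature --config run.json --out out/signature
exposig selection --config run.json --out out/selection
exposig all       --config run.json --out out/
```

`run.json` names the reference FASTA, a sample sheet TSV
(`sample  vcf  group` with groups `control`/`exposed`), and optional
signature-catalogue TSV, gene BED and expression TSV. Exit code 0 means
a clean run, 3 that some records were skipped with warnings.

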