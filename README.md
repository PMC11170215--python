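# linkread

Platform-agnostic linked-read processing: a unified barcoded-read
representation for 10x Genomics, stLFR, and TELL-seq libraries, plus the
computational core built on top of it.

## What it does

- **platform_io** — converts raw platform-specific FASTQ layouts (16-bp
  inline R1 prefix for 10x, 3×10-bp R2 tail for stLFR, 18-bp index read for
  TELL-seq) into one unified FASTQ whose headers carry a `BX:Z:<barcode>`
  token, and reads/writes BX-tagged SAM/BAM alignments.
- **barcode_correct** — barcode error correction against a whitelist
  (Hamming distance ≤ 1, ambiguous hits nulled) or, for whitelist-less
  platforms, by rescuing single-read barcodes onto unique distance-1
  multi-read neighbours; reports whitelist-match statistics.
- **simulator** — generates linked-read libraries from reference FASTA under
  the standard parameterization (fragment coverage `C_F`, per-fragment read
  coverage `C_R`, fragments per partition `N_F/P`, mean fragment length
  `mu_FL`), emitting unified FASTQ, a ground-truth SAM, and a truth-fragment
  table. Supports lognormal metagenome abundance profiles.
- **fragments** — reconstructs long DNA molecules from co-barcoded
  alignments (insert-size model, `mu + 3*sigma` pair filtering, greedy
  extension of co-barcoded seeds within 200 kb by default) and computes the
  five library statistics `C_R`, `C_F`, `N_F/P`, `mu_FL`, `W-mu_FL`.
- **metaquant** — tiered metagenomic quantification: first-pass genome
  screening (coverage rate > 40% and covered bases > 500 kb), 10-kb window
  read counting with multimapped reads split across hit genomes
  proportionally to unique-read support, extreme-window trimming, and
  relative abundances from mean window depth.
- **strainflow** — caller-aware metagenomic SNV filtering (depth ≥ 6, alt
  support ≥ 2, quality ≥ 15 for FreeBayes/SAMtools; inStrain untouched),
  cross-sample minor-allele-frequency matrices anchored on a reference
  sample, k-means clustering with Calinski–Harabasz model selection, and
  detection of clusters whose minor allele becomes the major allele.
- **reportqc** — MAG quality tiers (near-complete / high / medium / low)
  and machine-readable run summaries.

## CLI

One entry point with a subcommand per stage:

```bash
linkread fqconver --platform stlfr --r1 raw_R1.fq --r2 raw_R2.fq --out-prefix unified
linkread correct --fastq unified_R1.fq --fastq unified_R2.fq --whitelist wl.txt --out-prefix corr
linkread mkfq --config sim.json --out-dir simdir           # sim.json: SimConfig fields + "fasta"
linkread fragments --bam aln.bam --max-gap 200000 --out-prefix frags
linkread quant --bam1 pass1.bam --bam2 pass2.bam --ref-fai ref.fa.fai --out-prefix quant
linkread snv-filter --vcf sample.vcf --caller freebayes --out snvs.tsv
linkread strain --vcf S1=s1.vcf --vcf S5=s5.vcf --ref-sample S1 --pair S1,S5 \
    --genome sp1 --out events.tsv
linkread report --bins bins.tsv --out tiers.tsv
```

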