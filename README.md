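# ldscape

Linkage-disequilibrium characterization for diploid biallelic SNP panels —
the analysis a population geneticist runs to decide whether a marker panel
is dense enough for genomic selection or association mapping in a livestock
population.

Given genotypes (PLINK text .ped/.map or VCF) with a physical marker map,
`ldscape` provides:

* **Quality control** — sample/SNP call-rate, MAF and Hardy–Weinberg χ²
  filters with a per-chromosome audit report;
* **Two-locus LD** — maximum-likelihood (EM) haplotype frequencies from
  unphased genotypes, then D = ρ_AB − ρ_A ρ_B, |D′| = |D|/D_max and
  r² = D²/(ρ_A ρ_a ρ_B ρ_b), for adjacent or all within-chromosome pairs,
  plus profile-likelihood confidence limits on |D′|;
* **Summaries** — per-chromosome means, distance-binned decay tables,
  low/medium/high LD categories (r² ≤ 0.16 / interior / ≥ 0.70), metric
  correlations;
* **Effective population size** — the Sved relation E[r²] = 1/(1 + 4N_e c)
  inverted per recombination-distance bin,
  N_e(t) = (4c)⁻¹(E[r²|c]⁻¹ − α), with t = 1/(2c) generations back,
  harmonic means per chromosome, and the Hill–Robertson E(D²)–F relation;
* **Haplotype blocks** — Gabriel-style blocks from |D′| confidence-interval
  classes, block statistics, and a marker-density recommendation
  round(genome Mb / mean within-block spacing);
* **Inbreeding and relatedness** — excess-homozygosity
  F = (O − E)/(L − E) and the VanRaden genomic relationship matrix
  G = ZZ′/(2Σp(1−p));
* **A Wright–Fisher simulator** — forward neutral simulation with
  recombination and known ground truth (census size, haplotypes, pedigree),
  so every estimator above is verifiable without access data.

## Worked example

Recover a known effective population size from simulated LD decay
(`examples/03_ne_trajectory.py`):

```sh
$ python examples/03_ne_trajectory.py
 mean_dist_mb      c   t  n_pairs  mean_r2   adj_r2         ne
         0.25 0.0025 200      202 0.464937 0.454937 119.810623
         0.50 0.0050 100      191 0.356601 0.346601  94.258114

recent Ne = 94.3 at generation t = 100 (truth N = 100, error -5.7%)
```

A constant-size Wright–Fisher population (census 100) is simulated, QC'd,
and all within-chromosome pairwise r² is binned by distance.  Each bin's
mean r² (minus the 1/n sampling correction, column `adj_r2`) is inverted
through the Sved relation: pairs ~0.5 Mb apart (c = 0.005) read the
population about 100 generations back and give N_e ≈ 94 — within 6% of the
truth.  The other examples cover two-locus LD with confidence limits
(`01`), QC plus summary/category tables (`02`), inbreeding and half-sib
relatedness (`04`), and planted-block recovery with the density
recommendation (`05`).

The same pipeline runs from the shell:

```sh
ldscape simulate --config sim.yaml --out data/
ldscape run --config run.yaml          # QC -> LD -> summaries -> F/G -> Ne -> blocks
ldscape qc|ld|ne|blocks ...            # individual stages
```

`run` writes TSV report tables, a `summary.json` of headline scalars and a
`manifest.json` (config, package version, input checksums); identical input
and config produce byte-identical output.

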