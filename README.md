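# coaldrop

Simulation of sequence, SNP-chip, QTL and phenotype data for genomic
selection and GWAS studies, combining a coalescent simulator (ancestral
haplotypes) with a gene-drop simulator (recent pedigree).

A run proceeds in stages:

1. **demography / coalescent** — per-chromosome haplotype panels are
   simulated under a sequential Markovian coalescent (SMC′) with
   recombination, infinite-sites-style mutation and a piecewise-linear
   effective-population-size history.  ms-dialect haplotype files can be
   supplied instead of the internal simulator.
2. **pedigree / gene drop** — a discrete-generation mammalian-style
   pedigree (or an external pedigree file) is populated: founders sample
   their gametes from the haplotype panel with recombination, and later
   generations inherit Mendelianly with Poisson crossovers (1%/cM by
   default) and no mutation.  Gametes are stored bit-packed; crossovers
   operate directly on packed 64-bit words.
3. **markers / QTL** — SNP chips of configured densities are uniform
   samples of segregating sites; candidate-QTL sets are drawn
   unrestricted and with a minor-allele-frequency cap.
4. **traits** — four additive traits (PolyUnres, GammaUnres, PolyRes,
   GammaRes) with normal or signed-gamma allele-substitution effects;
   the residual variance is scaled against the base generation's genetic
   variance (a′a/(n−1)) so the configured heritability holds exactly.
5. **outputs** — pedigree, chip/QTL maps, genotype dosages, phased
   haplotypes, full sequence, trait tables, training/validation splits,
   optional VCF, plus a manifest with row/column counts and the master
   seed.  Runs are byte-reproducible from one master seed.

## CLI

```sh
coaldrop example-spec > scenario.txt    # default livestock scenario
coaldrop validate scenario.txt
coaldrop simulate scenario.txt -o out --seed 1 --scale 0.01
coaldrop stats out
```

The control file is a single key-value text file (see
`coaldrop example-spec` or the docstring of
`coaldrop/io_cli/specfile.py`).  `--scale` shrinks every chromosome's
physical length and the chip densities proportionally for desk-scale
runs; pedigree, QTL counts and traits are untouched.

The default scenario: 30 chromosomes of 100 cM / 10⁸ bp, mutation rate
2.5e-8, Ne declining from 43,500 (100k generations ago) to 100 (now)
with linear changes, 4000 base haplotypes, a 10-generation pedigree with
50 sires × 10 dams × 2 offspring (1000 individuals/generation), 60k and
300k SNP chips, 9000 candidate QTL (restricted variant capped at
MAF ≤ 0.30), four traits at h² = 0.25, training on the 4th–5th cohorts
and validation on 500 animals from each of the 6th, 8th and 10th.

## Layout

```
src/coaldrop/
  demography.py         Ne(t) trajectories, inhomogeneous waiting times
  coalescent.py         SMC(') simulator, ms-dialect I/O
  packed_haplotypes.py  bit-packed gametes, word-level recombination
  pedigree.py           generator / reader / validator
  gene_drop.py          base gametes, meiosis, pedigree drop
  markers_qtl.py        chip and candidate-QTL sampling, dosages
  traits.py             effects, breeding values, heritability scaling
  io_cli/               control-file parser, pipeline, writers, CLI
  sumstats.py           audit statistics recomputable from output files
```
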