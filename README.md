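# dupdiv

**Gene duplication–amplification–divergence dynamics under serial-dilution
evolution, with the measurements to read them out.**

When a bacterial population needs more expression of a gene, two very
different mutation routes compete: tandem duplication/amplification of the
locus (arising orders of magnitude more often than point mutations, but
genetically unstable — arrays collapse back to single copy at rates of
1e-3 to 1e-1 per cell per generation) and promoter point mutations (rare
but permanent). Because fitness saturates once expression meets the
environmental demand, the two routes are negatively epistatic: whichever
arrives first removes the benefit of the second. Frequent amplification
can therefore *hinder* the fixation of adaptive point mutations — and with
it, lasting sequence divergence.

`dupdiv` is a toolkit for studying this competition at desk scale, aimed at
experimental-evolution and population-genetics researchers:

- a seeded stochastic simulator of a 12-day serial-dilution experiment
  (daily 1:820 dilution ≈ 10 generations of regrowth to ~carrying
  capacity) over genotype classes `(k, m)` — `k` tandem copies, `m` of
  them carrying the adaptive promoter allele — with Poisson tau-leaped
  mutation flows and an exact multinomial bottleneck, plus a
  deterministic mean-field oracle;
- a virtual dual-fluorophore readout (YFP tracks total expression, CFP
  tracks copy number only) and the four-way population/event
  classification built on it (ancestral / YFP+ / YFP+CFP+ / mixed);
- the study-style measurement procedures: steepest 20-point sliding-window
  growth rate from log(OD), efficiency-corrected relative copy number
  (Pfaffl: `E_t^ΔCq_t / E_r^ΔCq_r`), and 39-bp-motif amplicon divergence
  counting with contaminant exclusion;
- synthetic-data generators for all four real data shapes (plate OD/
  fluorescence time series, flow-cytometry event tables, FASTQ amplicon
  reads, qPCR Cq tables) with known ground truth.

The model in one line: expression `E = (k−m)·β_anc + m·β_mut`, growth
`r = r0 + (rmax−r0)·min(E/D, 1) − c·(k−1)`, and the demand `D` decides the
regime — low demand makes copy-number and point mutations mutually
exclusive adaptive routes, high demand makes their combination necessary.

## Worked example

Simulate 8 replicate IS+ populations under low demand at desk scale, then
tabulate their phenotype fractions per day:

```
$ printf '[protocol]\ncarrying_capacity = 1e6\n' > low_demand.toml
$ dupdiv simulate --config low_demand.toml --replicates 8 --seed 1 --out run1
wrote run1/trajectories.csv (8 replicates, seeds 1..8)
$ dupdiv report --trajectories run1/trajectories.csv --demand low --strain IS+ --out fractions.csv
...
  default   12    ancestral      0
  default   12     yfp_plus      0
  default   12 yfp_cfp_plus      7
  default   12        mixed      1
```

By day 12, 7 of 8 replicates are classified YFP+CFP+ (adapted by
amplification: both channels elevated together, near the amplification
diagonal) and none by point mutation alone — the mutually exclusive,
amplification-dominated regime.

Copy number by simulated qPCR (noiseless fixture, a 4-copy clone):

```
$ dupdiv synth qpcr --copies 4 --noise 0 --out cq.csv
$ dupdiv assay pfaffl --cq cq.csv
4
```

Amplicon divergence from a population of pure `(k=4, m=1)` combination
cells (one mutant copy per four-copy array):

```
$ dupdiv synth amplicon --k 4 --m 1 --reads 20000 --seed 2 --out amp.fastq
$ dupdiv assay amplicon --fastq amp.fastq --motifs amp.motifs.tsv
{
  "counts": {
    "ancestral": 14403,
    "-37C>T": 9,
    "-30T>A": 9,
    "-37C>T,-30T>A": 4815,
    "control": 730
  },
  "excluded": 0,
  "unassigned": 34,
  "divergence_fractions": {
    "-37C>T": 0.0006,
    "-30T>A": 0.0006,
    "-37C>T,-30T>A": 0.3343
  }
}
```

The evolved/ancestral read fraction is ~1/3, not 1: each cell contributes
one evolved and three ancestral promoter templates. This dilution is kept
deliberately — a single SNP inside a four-copy array has only a 1-in-4
chance of surviving collapse back to single copy, so diluted divergence
reflects the biology, not a counting artefact. The handful of single-SNP
reads are sequencing errors on double-mutant templates, and "unassigned"
reads carry errors inside the scored windows (exact matching never
miscalls an allele).

## File formats

CSV is UTF-8, comma-separated, dot-decimal, header mandatory.

| file | columns |
|---|---|
| plate time series | `well, day, od, yfp, cfp` |
| event table | `event, yfp, cfp` |
| Cq table | `sample, channel, cq, dilution` |
| trajectories | `replicate, day, k, m, count` |
| motif set (TSV) | `name, sequence, role` |

FASTQ is 4-line records; qualities are read and ignored. Every
artifact-producing command writes a JSON manifest (version, config hash,
seeds, input checksums).

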