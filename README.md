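# mitopop

A mitochondrial-DNA phylogeography toolkit for multi-breed haplotype
datasets: diversity statistics, AMOVA and pairwise Phi_ST, metric MDS of
F_ST matrices, neighbour-joining trees with bootstrap and reference-based
lineage assignment, median-joining haplotype networks, and an approximate
Bayesian computation (ABC) engine for testing demographic colonization
scenarios with a built-in coalescent simulator.

## Test

```bash
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) and an acceptance
suite (`tests/test_acceptance.py`); the ABC scenario-recovery criterion
builds a 40,000-row reference table and takes several minutes on one CPU.

## Library overview

| module | contents |
| --- | --- |
| `mitopop.alignment` | aligned FASTA + metadata I/O, haplotype collapsing, polymorphic sites, windows |
| `mitopop.popgen` | Nei haplotype diversity (+SE), mean pairwise differences, mismatch distributions, 1/2-level AMOVA with permutation tests, pairwise Phi_ST |
| `mitopop.mds` | classical (Torgerson) and SMACOF multidimensional scaling of F_ST matrices |
| `mitopop.nj` | p/K2P/TN93/composite-likelihood distances, neighbour joining, site bootstrap, lineage assignment (rooted clade reading or nearest reference) |
| `mitopop.mjnet` | median-joining haplotype networks (minimum-spanning network + quasi-median vectors), GML/TSV export |
| `mitopop.abc` | scenario/prior DSL, structured-coalescent simulator with HKY mutations, DIYABC-style summary statistics, reference tables, PCA pre-evaluation, model choice by weighted polychotomous logistic regression (with 95% CIs and predictive error), local-linear parameter estimation with logit transform, RMAE, goodness-of-fit |
| `mitopop.synth` | synthetic multi-breed fixtures with known lineage ground truth; labelled reference panels |
| `mitopop.pipeline` / `mitopop.cli` | config-driven orchestration with a reproducible run manifest |

All effective sizes are haploid gene-copy counts (mtDNA), times are in
generations, and the mutation rate is per site per generation.

## CLI

Every stage is a subcommand of `mitopop` (see `mitopop --help`):

```bash
mitopop simulate-data --n-breeds 3 --samples-per-breed 20 --seed 1 --outdir demo/
mitopop diversity --fasta demo/synthetic.fasta --metadata demo/synthetic.meta.tsv
mitopop amova     --fasta demo/synthetic.fasta --metadata demo/synthetic.meta.tsv
mitopop fst       --fasta demo/synthetic.fasta --metadata demo/synthetic.meta.tsv --out fst.tsv
mitopop mds       --fst-tsv fst.tsv --out mds.tsv
mitopop tree      --fasta demo/synthetic.fasta --metadata demo/synthetic.meta.tsv \
                  --model mcl --bootstrap 2000 --seed 2 --out tree.nwk
mitopop network   --fasta demo/synthetic.fasta --metadata demo/synthetic.meta.tsv --out-prefix net
mitopop abc simulate --scenarios scenarios.txt --priors priors.txt \
                     --samples ME:20,MP:20,IS:20 --length 600 --seed 3 --out reftable.tsv
mitopop abc choose   --reference-table reftable.tsv --observed observed.tsv
mitopop run --config pipeline.yaml --outdir results/
```

Exit codes: 0 success, 2 config error, 3 data error, 4 numerical failure.
CLI coordinates (e.g. `--window 1:612`) are 1-based inclusive; the library
uses 0-based half-open coordinates throughout.

Scenario files are plain text (`split <derived> <source> @ <t>` events read
backwards in time, `constraint t1 > t2` ordering rules); priors files hold
`prior <symbol> uniform|loguniform <low> <high>` lines. Shipped presets are
in `mitopop.abc.scenario` (`lineage_a_scenarios`, `lineage_b_scenarios`,
`default_priors`).

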