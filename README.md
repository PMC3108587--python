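# parvapop

Population-genetic analysis of the European invasion of the topmouth gudgeon
(*Pseudorasbora parva*), a small East Asian cyprinid that spread across more
than 30 countries after a single 1960s introduction. The package implements
the full mitochondrial (cytochrome *b*, ~700 bp) analysis chain used to ask
three questions about such an invasion:

1. **Where did the invaders come from?** Haplotype collapsing, median-joining
   networks and NJ trees resolve the deeply diverged native lineages and show
   which of them the invasive haplotypes belong to.
2. **Were they admixed and/or bottlenecked?** Within-population diversity
   (haplotype diversity *H*, bootstrap-standardised *H₆*, nucleotide
   diversity π) is compared against a Kingman-coalescent mutation–drift
   equilibrium envelope: admixture of diverged sources inflates π relative to
   *H*, a founder bottleneck depresses both.
3. **How did they spread?** Hudson *F*ST / K2P *D*XY matrices, classical MDS,
   Mantel isolation-by-distance tests and distance-from-source regressions
   separate stepping-stone from long-distance (jump) spread, and approximate
   Bayesian computation (ABC) compares three explicit demographic scenarios
   for the introduction, including ghost populations and admixture events.

Every stage runs on synthetic data with a known ground truth
(`parvapop.synth`), so the whole pipeline is testable without downloads.

## Core statistics

- *H* = n/(n−1) · (1 − Σ p̂ᵢ²) (bias-corrected Nei haplotype diversity);
  standardised to the smallest sample size k by bootstrap, with closed form
  E[H_k] = (1 − 1/k) · H · (n−1)/n.
- π = mean pairwise p-distance per site; *D*XY = mean between-population K2P
  distance, d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q); *F*ST = 1 − H_w/H_b
  (Hudson).
- Equilibrium envelope: per θ = 2Nμ·L, simulate Kingman genealogies with
  infinite-sites mutation; record mean *H*, mean π and the 5–95% π band;
  classify observed (H, π) points by the conditional band at their observed
  *H*.
- ABC: structured-coalescent simulation of the three invasion scenarios,
  MAD-normalised summary statistics, rejection + multinomial logistic
  regression on the closest 1% for model choice, ridge-stabilised
  local-linear (Beaumont) adjustment for parameter posteriors.

## Worked example

```sh
python analysis/01_simulate_data.py   # synthetic native range + 3 invasions
python analysis/02_diversity.py       # Table-2-style diversity summary
python analysis/03_differentiation.py # FST/DXY matrices, MDS
python analysis/06_ibd.py             # Mantel IBD contrast
```

On the bundled long-distance invasion dataset (an admixed source pool, jump
dispersal, two bottlenecked satellite populations, one introgressed
haplotype) the drivers print, among other things:

```
29 haplotypes from 180 sequences; divergence screen flagged: ['H24']
median FST: native-native=0.8047, invasive-invasive=0.1659, native-invasive=0.4354
median DXY: native-native=0.0125, invasive-invasive=0.0090, native-invasive=0.0086
stepping_stone: Mantel r=-0.122 p=0.684 | without satellites r=0.659 p=0.011
long_distance:  Mantel r=-0.155 p=0.714 | without satellites r=-0.073 p=0.613
```

Reading: the flagged haplotype is the injected introgressed mitochondrion
(H24, ~5% diverged — the misidentified-congener signature). Invasive
populations are far less differentiated from each other than native ones
(median *F*ST 0.17 vs 0.80) while absolute divergence (*D*XY) stays
comparable — the signature of a shared, recently reshuffled source rather
than independent colonisations. The stepping-stone dataset shows significant
isolation by distance once the two bottleneck-distorted satellites are
removed; the long-distance dataset shows none, the contrast the Mantel test
is there to detect.

The same stages are exposed as a CLI (`parvapop simulate | diversity |
matrices | network | envelope | ibd | abc | run-all`) and as a single
config-driven pipeline (`parvapop.pipeline.run_pipeline`).

The study's deposited sequences (GenBank JF489575–JF489887) can be fetched
with `python scripts/fetch_accessions.py --out data/cytb.fasta` (network
required), aligned with mafft, and run through the same CLI; nothing in the
package depends on them.

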