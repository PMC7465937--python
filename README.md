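# hp1kit

Tools for analyzing the protein interactome and genomic territory of
*Drosophila* Heterochromatin Protein 1a (HP1a). The package bundles the
three computations such a study needs, each usable from Python or from a
thin command line:

1. **Motif scanning** (`hp1kit.motifs`) — locate the chromoshadow-domain
   (CSD) binding pentapeptide **P-x-V-x-L** (x = any amino acid) and its
   degenerate variants **L-x-V-x-L** and **C-x-V-x-L** in protein
   sequences, report the −1/+1 flanking residues, and summarize candidate
   interactor cohorts as "percent of proteins with ≥ 1 motif".
2. **Peak co-localization** (`hp1kit.coloc`) — the percentage of query
   ChIP-seq peaks intersecting a reference peak set (≥ 1 bp, half-open
   coordinates), with significance from a chromosome-aware randomization
   null: reference peaks are re-placed uniformly on their own chromosomes
   `n_perm` times, the empirical p is `(1 + b)/(n_perm + 1)`, and
   `z = (observed − null mean)/null sd` (z < 0 flags depletion).
3. **Epigenomic border calling** (`hp1kit.borders`) — the
   heterochromatin/euchromatin transition on a chromosome arm: take the
   genome-wide median of peak summit heights, bin summits every 0.5 Mb
   from the centromeric origin, and mark the border at the first bin whose
   median height decays strictly below the global median; multiple tracks
   combine into a consensus call.

`hp1kit.simulate` generates seeded synthetic inputs — proteomes with
planted motifs (rejection-sampled so the planted set is the exact truth),
peak pairs with an exactly controlled overlap fraction, and step-shaped
peak landscapes with a known border — so the whole pipeline is testable
without any external download. `hp1kit.io` handles FASTA, BED3/BED6,
ENCODE narrowPeak, chrom.sizes and TSV/JSON reports.

## Worked example

```sh
python examples/scan_motifs.py
```

builds a 13-protein synthetic cohort with motifs planted in 9 proteins and
prints, among other lines:

```
  prot_0   PxVxL @40   PEVKL  [D/Y]
  ...
cohort 'direct binders': 9 of 13 proteins carry a motif -> 69%
```

Each hit line gives the protein, motif class, 1-based start, the literal
pentapeptide and its −1/+1 flanking residues; the cohort percentage uses
nearest-integer rounding. Similarly:

```sh
python examples/colocalization.py
```

```
observed: 80/200 query peaks (40.0%) touch a reference peak
null (999 randomizations): mean 2.28 overlapping peaks, sd 1.59
z = 48.90, empirical p = 0.0010
```

Here 40% of query peaks were planted on reference peaks; random placement
would explain only ~2 of the 80 overlaps, so the co-localization is highly
significant. And `python examples/border_calling.py` generates a 25-Mb
arm with a heterochromatin block ending at 7.0 Mb and recovers the border
from the binned-median scan (within one 0.5-Mb bin).

The same analyses run from the shell:

```sh
hp1kit simulate landscape --seed 1 --out arm.narrowPeak --genome-out arm.sizes
hp1kit call-border --peaks arm.narrowPeak --genome arm.sizes \
    --chrom chr2R --origin 0 --direction increasing --out border.tsv
```

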