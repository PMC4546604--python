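# teadgrammar

Regulatory-grammar analysis of YAP1/TEAD ChIP-seq peaks.

YAP1, the transcriptional effector of Hippo signaling, has no DNA-binding
domain: it is recruited to chromatin by TEAD transcription factors, whose
consensus hexamer is CATTCC (reverse complement GGAATG). Given a peak set,
a genome, and expression data, this package answers the questions a
YAP1/TEAD regulatory analysis asks:

- **Motif grammar.** Mismatch-tolerant scanning of the TEAD consensus on
  both strands of 151-bp summit-centred windows; detection of homotypic
  same-orientation double motifs and their spacer spectrum (the 3-bp
  spacer being the functional configuration); exact hypergeometric
  enrichment against a chromosome-shuffle null,
  P = Σ_{j≥x} C(X,j)·C(N−X,n−j) / C(N,n), computed in log space.
- **Peaks and coverage.** Summit-anchored interval model with peakzilla /
  BED dialects, overlap fractions, width-preserving chromosome shuffles,
  150-bp read-extension pileups in reads-per-million, per-region density
  correlations between samples, summit meta-profiles, and conservation
  profiles from bedGraph/wiggle tracks.
- **Target genes.** Nearest-TSS assignment with signed distances and a
  2-kb proximal/distal split, genomic-feature classification, the
  four-comparison knockdown differential-expression rule (padj ≤ 1e−5 in
  all four, ≥2-fold in one, ≥1.2-fold in the rest), differential-binding
  thresholds, and gene-set hypergeometric enrichment.
- **Activity signature.** Ranksum (expression + copy-number) high/low
  labeling, a Gaussian naive-Bayes classifier over signature genes,
  repeated stratified 2/3 / 1/3 holdout with Mann–Whitney AUC, and
  standardized-mean-difference feature selection.
- **Synthetic data.** Generators for genomes with planted motifs (with a
  ground-truth ledger), summit-enriched read libraries, and two-class
  expression matrices, so every stage is testable without downloads.

## Worked example

Scan a reporter-style sequence carrying a minus-strand double motif
(GGAATG-CAG-GGAATG):

```python
from teadgrammar.motifs import ConsensusQuery, scan_consensus, find_pairs

query = ConsensusQuery("CATTCC", max_mismatch=0)
seq = "TTGGAATGCAGGGAATGTT"
matches = scan_consensus(seq, query)
pairs = find_pairs(matches, motif_len=6, max_spacer=30)
```

prints two minus-strand occurrences forming one 3-bp-spacer pair:

```
MotifMatch(offset=2, strand='-', n_mismatch=0)
MotifMatch(offset=11, strand='-', n_mismatch=0)
spacer: 3 strand: -
```

Full enrichment run on a synthetic genome with planted grammar (86%
single-motif windows, 18% spacer-3 doubles, 37% background rate):

```python
from teadgrammar.regions import ChromSizes
from teadgrammar.motifs import ConsensusQuery
from teadgrammar.enrichstats import motif_enrichment
from teadgrammar.synthdata import MotifPlantingConfig, gen_genome_with_peaks

sizes = ChromSizes({f"chr{i}": 15_000_000 for i in range(1, 5)})
config = MotifPlantingConfig()
genome, peaks, ledger = gen_genome_with_peaks(sizes, n_peaks=2500, config=config, seed=1)
query = ConsensusQuery(config.consensus, config.max_mismatch)
result = motif_enrichment(peaks, genome, query, sizes, seed=2)
```

```
observed: 2150/2500 windows with a TEAD site (86.0%)
control:  938/2500 (37.5%)
fold = 2.29, log10 P = -288
```

86.0% of peak windows carry a TEAD site versus 37.5% of shuffled
controls — a 2.3-fold enrichment whose exact upper-tail probability is
about 10^−288.

A command-line interface mirrors the library
(`teadgrammar regions|motifs|enrich|coverage|integrate|signature|simulate`,
see `teadgrammar --help`).

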