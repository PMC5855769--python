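# igtscan

Detection and analysis of **intergenomic gene transfer (IGT)** — the movement
of DNA between the nuclear, mitochondrial and chloroplast genomes of a plant.
The package implements the desk-scale analysis pipeline around organellar
transfer screens: finding transferred segments (*numts*, *nupts*, *mtpts*,
mt→cp inserts), classifying the fate of reference organellar genes, reading
the repair signature at insertion breakpoints, quantifying genomic repeats,
and summarising everything statistically.  A ground-truth simulator generates
genome trios with planted transfers so every stage can be scored against
known answers.

It is written for comparative-genomics work in Python: the public face is the
importable API (plus short narrative scripts in `examples/` and a thin
`igt-scan` CLI for the scanning commands).

## What it computes

**Transfer detection.** A seed-and-extend local aligner stands in for the
classic BLASTN screens, honouring the same detection gates: E-value ≤ 1e−5,
alignment identity ≥ 95%, minimum length 100 bp for nuclear insertions and
50 bp for organelle-to-organelle insertions.  Scoring is +1 match / −2
mismatch with affine gaps (a gap of length *k* costs 5 + 2*k*), and E-values
follow the ungapped Karlin–Altschul formula *E = K·m·n·e^(−λS)* with
*K* = 0.71, *λ* = 1.37.  Per-species transfer totals are the union of
recipient intervals, so overlapping hits count once.

**Gene fate.** Each reference gene *g* of a donor organelle is placed in one
of four mutually exclusive states for a species:

| state | donor genome | recipient genome |
|---|---|---|
| `lost` | no hit | — |
| `not_transferred` | hit | no hit |
| `intact_homolog` | hit | chained coverage ≥ 95% |
| `pseudogene` | hit | chained coverage < 95% |

where coverage is the query fraction covered by the best co-linear chain of
recipient hits.

**Junction repair signature.** For each insertion breakpoint the
micro-homology is the longest exact overlap (1–4 bp) between the recipient
flank and the insert edge at the fusion point; junctions without one are
blunt-end joins.  Cross-species intersection recovers clade-conserved
junction motifs.

**Repeats.** Self-alignment of a genome yields repeat pairs (direct and
inverted) summarised at the two standard tiers (> 1 kb, > 100 bp) plus union
repeat size; transferred segments are attributed to seven repeat classes
(copia, gypsy, low_complexity, LTR-retro, simple_repeat, TE, unspecified) by
best hit against a labelled library.

**Statistics.** Ratio tables rounded half-up to two decimals with a
below-threshold flag, OLS regressions with R², and two-tailed Welch t-tests
(e.g. spermatophytes vs bryophytes).  Two compiled published tables — nuclear
repeat/genome sizes and mitogenome repeat tiers for 22 land plants — ship as
package data and feed the worked examples.

## Worked example

```python
from igtscan import SimConfig, generate_trio, scan_transfers, total_transferred_bp

cfg = SimConfig(seed=1, species_id="demo", n_numts=10, n_mtpts=10,
                gene_transfer_fraction=0.0)
trio = generate_trio(cfg)
numts = scan_transfers(trio.mitochondrial, trio.nuclear)
print(len(numts), total_transferred_bp(numts))
```

Running `python examples/01_simulate_and_scan.py` prints:

```
genome sizes (bp): nuclear=95038 mt=56528 cp=20000
numts detected: 10 segments, union 5040 bp (planted 5038 bp)
mtpts detected: 10 segments, union 11525 bp
  numt_0000: recipient 5460..6444 (+) identity 0.983 E=0.00e+00
```

All ten planted mitochondrion→nucleus insertions are recovered; the detected
union (5040 bp) differs from the planted total (5038 bp) only by chance
flank matches at segment edges.  The other examples walk through gene-fate
classification (`02`), junction micro-homology and clade-conserved motifs
(`03`), and repeat tiers plus the published ratio table and Welch test
(`04`).

A small CLI covers the shell-friendly operations:

```bash
igt-scan simulate --seed 1 --out trio/
igt-scan search --donor trio/sim01_mitochondrial.fa \
                --recipient trio/sim01_nuclear.fa --mode numt --out numts.bed
igt-scan repeats --genome trio/sim01_mitochondrial.fa
```

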