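# chromdyn

Analysis of promoter-interaction dynamics during metabolic adaptation to
diet, rebuilt as a tested Python library: from binned chromatin-contact
matrices through A/B compartments, TADs, and loop calling, to
promoter-capture interaction scoring, differential testing, and the
classification of diet-responsive promoter–enhancer loops into *rewired*
(de novo) versus *preformed-activated* categories — exercised end-to-end on
synthetic data with planted, recoverable ground truth.

## Who this is for

Computational biologists who want the statistical machinery of a liver
Hi-C / promoter-capture Hi-C (PCHi-C) diet study as reusable, testable
components, without the original sequencing data: every input the pipeline
consumes can be simulated with known truth, so each stage's behaviour is
measurable.

## The model in brief

**Contacts.** Cis contact counts at 10-kb bins decay with genomic distance
(P(contact) ∝ d^-α, α = 1 by default), modulated by compartment preference
(checkerboard A/B blocks), topological domains (cross-boundary contacts
suppressed to a ratio of 0.2), and focal loops (pixels enriched 5× over
local background). A/B compartments are the sign of the leading eigenvector
(PC1) of the per-chromosome observed/expected correlation matrix at 50-kb
bins, sign-oriented by an activity track. TADs are insulation minima of a
multi-window diamond score, requiring a drop ≥ 0.1 below flanking maxima
and a BH-corrected rank test at 0.05. Loops are pixels with per-distance
z ≥ 6 within 1 Mb of the diagonal; aggregate peak analysis (APA) sums
21×21 submatrices around loops ≥ 300 kb from the diagonal and scales by
the mean of the four corner pixels.

**Capture interactions.** Bait (promoter fragment) × other-end counts are
scored as −log10 p under a negative-binomial background with a pooled
distance-decay mean and per-bait scaling; score ≥ 5 is significant. Trans
pairs and spans > 1 Mb are discarded.

**Dynamics.** Differential counts use an exact negative-binomial test with
a common method-of-moments dispersion (floored at 0.01) on library-size
normalised, per-condition pooled counts. Interactions are *rewired* when
the contact counts differ at p < 0.001; *preformed-activated* when contacts
are stable but a differential H3K27ac peak (FDR < 0.05, FC > 1.5) overlaps
the distal end; otherwise *static*. Genes are linked through their bait;
DEGs use FDR < 0.05 and FC > 1.2.

**Associations.** Mann–Whitney U tests (exact enumeration for n₁+n₂ ≤ 8)
relate expression (TPM bins 0, (0,1], (1,10], >10) to interaction counts
and distal-end acetylation; Monte-Carlo size-matched shuffling within an
enhancer universe tests peak-set overlap (empirical p = (r+1)/(n+1));
energy expenditure follows the calorimetry formula
EE (kcal/h) = 3.941·VO₂ + 1.106·VCO₂ (l/h).

## Worked example

```python
import chromdyn as cd
from chromdyn.loops import apa, call_loops, loop_zscores

truth = cd.make_genome(cd.SimulationConfig(seed=1))
mats = cd.simulate_contacts(truth)
merged = cd.merge_replicates([mats[("A", 0)], mats[("A", 1)]])
loops = call_loops(loop_zscores(merged))
res = apa(merged, loops)
print(len(loops), round(res.center_score, 2))
```

Running `python examples/02_loops_apa.py` (which adds the comparison with
the planted truth) prints:

```
37 loops called from 40 planted (recall 0.93, precision 1.00)
median called span: 680 kb
APA: centre score 5.46 from 37 loops (planted enrichment 5x)
```

37 of the 40 planted 5×-enriched pixels are recovered at z ≥ 6 with no
false calls, and the APA centre score (aggregate centre over corner
background) estimates the planted enrichment. The other scripts in
`examples/` walk through TAD/compartment recovery, capture scoring, the
rewired/preformed classification (98.3% agreement with planted labels at
the default configuration), and the association statistics; each prints a
short interpretation of its numbers.

## Layout

```
src/chromdyn/
  genome.py        coordinates, intervals, binning, BED/TSV I/O
  contacts.py      contact matrices: build, merge, balance, compare
  architecture.py  A/B compartments, insulation TADs
  loops.py         loop z-scores, loop calls, APA
  capture.py       capture interaction scoring and filtering
  dynamics.py      NB differential tests, loop-dynamics classification
  stats.py         association statistics, shuffle tests, calorimetry
  simulate.py      planted-truth synthetic data
docs/methods.md    model, parameter, and design notes
examples/          one narrative script per capability
```
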