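# delinmetrics

Measurement pipeline for **inter-observer agreement in brain-tumor
delineation studies**. When several observers — radiologists and
novices — outline tumorous tissue on the slices of an MR volume, how
consistently do they agree on what the tumor is, where its boundary
lies, and how do they inspect the stack? `delinmetrics` turns raw
stylus polylines and slice-visit logs into the standard quantitative
measures of such studies, and ships a synthetic study generator so the
whole pipeline is testable without access to (typically unshareable)
participant data.

It is aimed at researchers in medical image perception and
radiotherapy contouring variability who need reproducible, audited
agreement numbers rather than one-off scripts.

## Measures

For observers $A, B$ with delineated pixel sets $S_A, S_B$ on a slice:

* **Gross tumor volume / area.** GTV $= \sum_k |S^{(k)}|$, the total
  delineated pixels over a whole-brain stack (per-slice contours merged
  by union). For a set of independent single slices, GTA $=$ total
  pixels ÷ number of slices delineated.
* **Concordance rate.** Jaccard
  $J = 100\,\frac{|S_A \cap S_B|}{|S_A \cup S_B|}$ (default) or Dice
  $D = 100\,\frac{2|S_A \cap S_B|}{|S_A| + |S_B|}$, from 0 %
  (disjoint) to 100 % (identical). Slices where neither observer drew
  are excluded (0/0 undefined); where exactly one drew, the pair scores
  0 %. Each observer's score is the mean over same-group peers, then
  over slices — separately for **central** slices (the five slices most
  observers delineated) and **peripheral** ones (the rest, where the
  margin is faint).
* **Inspection-sequence similarity.** Slice-visit sequences are
  collapsed (consecutive repeats dropped), encoded as token strings,
  and globally aligned (Needleman–Wunsch) under the substitution score
  $s(i,j) = (n-1) - |i-j|$ with gap penalty 0; the raw score is
  normalized by $(n-1)\cdot\max(|a|,|b|)$, giving 1 for identical and
  0 for maximally dissimilar sequences.
* **Contour–saliency score.** A graph-based visual saliency map (Markov
  chain over a coarse feature grid, intensity + orientation channels)
  is computed per masked slice, scaled to $[0,1]$; a drawn boundary's
  score is $\sum_{p}\,\mathrm{saliency}(p)\,\mathbb{1}[p \in
  \mathrm{stroke}]$ — how much of the drawing lies on conspicuous
  image structure.

The synthetic generator emulates the standard study design: three
whole-brain stacks (~31 axial slices) plus one 16-stimulus set of
independent single slices (8 central, 8 peripheral), inspected by 8
experts and 12 novices whose boundary jitter, detection probability,
area bias and slice-revisit rate differ by group.

## Worked example

```python
import numpy as np
from delinmetrics import Delineation, pairwise_concordance, rasterize_filled

sq = np.array([[10, 10], [10, 40], [40, 40], [40, 10]], float)
a = rasterize_filled(Delineation("alice", "demo", 0, sq), 64, 64)
b = rasterize_filled(Delineation("bob", "demo", 0, sq + 5.0), 64, 64)
print(pairwise_concordance(a, b, "jaccard"), pairwise_concordance(a, b, "dice"))
```

prints `54.25 70.34`: two 961-pixel squares offset by 5 px overlap
on 676 pixels, so Jaccard gives 100·676/1246 ≈ 54 % and Dice
100·1352/1922 ≈ 70 %.

A small end-to-end study (`examples/02_synthetic_study.py`) prints,
among other tables:

```
inter-observer agreement (% concordance):
set_id   location  group      mean       sd
     2    central expert 64.459153 4.145856
     2    central novice 52.750114 2.179185
     2 peripheral expert 37.437755 4.372939
     2 peripheral novice 20.281418 5.822703
```

— agreement is much higher on central slices than peripheral ones in
both groups, and experts hold up better than novices peripherally,
the signature structure of expertise in these tasks.

Each script in `examples/` demonstrates one capability (rasterization
and concordance, synthetic studies, sequence similarity, saliency, the
full pipeline). The same pipeline is scriptable from a shell:

```bash
delinmetrics run --seed 42 --out results/
delinmetrics analyze --in mystudy/ --out results/   # your own data
```

Input layout for real data (`manifest.yaml`, `contours.csv`,
`sequences.csv`, PNG/NIfTI rasters) is documented in
`delinmetrics/io.py`.

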