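# exepi

Quantifying the co-localization of epigenetic reader proteins (LEDGF, BRD4,
…) with histone modifications (H3K36me3, H3K9/14ac, …) in multi-channel
(expansion-)microscopy z-stacks — and mapping where in the nucleus those
interactions happen.

Conventional voxel-correlation measures (Pearson's correlation coefficient)
fail on nuclear histone-mark stains: the marks are distributed
heterogeneously, so the marker channel fluctuates strongly whether or not a
reader protein actually sits on a marked nucleosome. `exepi` implements the
object-based alternative: detect individual reader spots, read the marker
intensity at each spot's exact 3D position, and compare it against marker
intensities at random locations inside the same nucleus.

## The statistic

For a spot at position **x** inside nucleus Ω with marker image *M*, draw
*n* random locations *u₁…uₙ* uniformly in Ω and compute the upper-tail
empirical p-value with the add-one permutation correction

```
p(x) = (1 + #{ i : M(u_i) ≥ M(x) }) / (1 + n)
```

The spot **co-localizes** when `p < α` (default α = 0.05, n = 10,000).
Per cell, results are summarized by the co-localization ratio

```
R = 100 · n_coloc / (n_total − n_coloc)
```

and the percentage `100 · n_coloc / n_total`. The statistic depends on the
marker only through intensity ranks, so it is invariant to any monotone
intensity rescaling. Two built-in controls quantify its operating range:

* **rotation control** — rotating the marker channel 180° destroys true
  correspondence and measures the false-positive floor (≈ α);
* **reversed analysis** — anchoring on marker spots and reading the reader
  channel, the same machinery with the channel roles exchanged.

Around the statistic, the package provides nuclear segmentation with
anisotropy-aware rim-distance maps, matched-filter 3D spot detection with
sub-pixel Gaussian localization (the locROI / chi2 / FWHM parameterization,
with presets for pre- and post-expansion sampling), distance-to-nuclear-rim
spatial analysis rescaled by the gel expansion factor (~3.5), one-way ANOVA
group comparison, and 4-parameter-logistic IC50 fitting for inhibitor
titrations. A synthetic-data generator produces ground-truthed stacks so
every stage is testable without microscope data.

## Worked example

```python
from exepi.colocalization import ColocParams, classify_spots
from exepi.detection import detect_spots
from exepi.fixtures import sparse_cell
from exepi.pipeline import SYNTHETIC_DETECTION
from exepi.segmentation import segment_nuclei

stack, truth = sparse_cell(seed=1, coloc_fraction=0.5, enrichment=10.0)
region = segment_nuclei(stack.channel("dapi"), stack.geometry)[0]
spots = detect_spots(stack.channel("reader"), region, SYNTHETIC_DETECTION)
result = classify_spots(spots, stack.channel("marker"), region,
                        ColocParams(alpha=0.05, n_random=10_000, seed=1))
```

Running `python examples/colocalization_basics.py` (the same code) prints:

```
detected spots          : 46 (planted emitters: 50)
co-localizing (p < 0.05): 25
flagged fraction        : 0.543 (planted fraction 0.5, chance floor 0.05)
co-localization ratio R : 119.0  (= 100 * coloc / non-coloc, the per-cell summary statistic)
```

Half the emitters were planted on marker-enriched loci; the flagged
fraction 0.543 ≈ 0.5 + α·0.5 recovers the planted half plus the expected
false positives among the rest. `examples/` contains similar short scripts
for the rotation control, IC50 fitting, and rim-distance analysis; the
`exepi` command-line tool (`exepi simulate | segment | detect | run |
stats`) drives the same stages on (OME-)TIFF stacks and CSV tables. As a
sanity check of the arithmetic on real data reported for dual-labelled
HIV-1 virions: 265 co-localizing particles of 287 give a percentage of
92% and a ratio R ≈ 1204.5.

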