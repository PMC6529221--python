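# lhoverlap

Quantitative analysis tools for neurogenetic dissection of the *Drosophila*
lateral horn (LH): binary-mask construction from registered confocal stacks,
a bidirectional voxel-overlap score used as a proxy for potential
connectivity, and the optogenetic behaviour metrics (quadrant preference
index, locomotion deltas, tethered-flight wingbeat responses) with their
screening statistics. A synthetic-data module generates registered volumes,
arena trajectories and wingbeat traces with exact ground truth, so every
stage of the pipeline is verifiable without any imaging data.

The package is aimed at researchers analysing split-GAL4 anatomy screens and
optogenetic activation experiments, or benchmarking mask-overlap methods
against known ground truth.

## The core quantities

**Mask construction.** For each cell type and compartment (axon, dendrite,
or "membrane" for local neurons), *n* = 3 registered example stacks are
overlaid, contrast-enhanced (percentile clip + linear rescale), Gaussian
blurred (σ = 1 voxel) and auto-thresholded with Otsu's method, giving a
binary mask on the common template grid (voxel size 0.56 × 0.56 × 1.0 µm).

**Overlap score.** For masks *A*, *B* on one grid,

    P1 = 100·|A ∩ B| / |A|,   P2 = 100·|A ∩ B| / |B|

and the reported score is (P1 + P2)/2 (max and min are available as
alternative combine rules). A score **strictly above 15%** counts as a
significant potential interaction. Score matrices between mask families are
clustered by hierarchical agglomerative clustering (Euclidean distance,
complete linkage); the relationship between a family's axonal and dendritic
overlap is summarised by ordinary least squares (R²).

**Quadrant preference index.** With the arena's four 90° sectors labelled so
Q2+Q3 and Q1+Q4 are the two illuminable pairs,

    PI = (n flies in Q2∪Q3 − n flies in Q1∪Q4) / total

per frame; the single-value PI averages the final 5 s of each of the two
light-ON epochs. Locomotion deltas compare the 5 s before onset with the
first 5 s of stimulation, restricted to flies that stayed in the lit pair,
normalised by the pre-stimulation mean.

**Tethered flight.** Yaw = left − right wingbeat amplitude, thrust = left +
right. Per trial, the 100 ms pre-onset mean is subtracted; the fly's
response is mean(stim trials) − mean(no-stim trials); groups are compared
per timepoint with a two-sided Wilcoxon rank-sum test at p < 0.05.

**Screen statistics.** Levene check for homoskedasticity, Kruskal–Wallis
followed by Dunn's post-hoc test of every line against the empty-split
control, Benjamini–Hochberg FDR control at 10% with significance at
adjusted p < 0.05 (Bonferroni for replication experiments).

## Worked example

```python
import lhoverlap as lh

# two cell types with a designed 50% directional overlap, three noisy
# replicate stacks each, pushed through the full mask pipeline
stacks_a, stacks_b, truth_a, truth_b, true_p1 = lh.generate_overlap_stacks(
    lh.OverlapStackDesign(target_p1=0.5, seed=0)
)
mask_a = lh.make_mask(stacks_a, metadata={"cell_type": "AV1a1", "compartment": "axon"})
mask_b = lh.make_mask(stacks_b, metadata={"cell_type": "PV5a1", "compartment": "dendrite"})
r = lh.overlap_score(mask_a, mask_b)
print(f"true P1 {true_p1:.1f}%  measured P1 {r.p1:.1f}%  mean score {r.mean_score:.1f}%")
```

prints

```
true P1 50.0%  measured P1 49.9%  mean score 49.9%
```

— the pipeline recovers the designed directional overlap of A in B to
within 0.1 percentage points despite the intensity noise, and because the
two ground-truth arbors have equal voxel counts the converse overlap P2 (and
hence the mean score) sits at the same value.

The same workflows are scriptable from the shell:

```sh
lh-overlap simulate quadrant --seed 7 --out sim/
lh-overlap behavior quadrant --track sim/track.csv --schedule sim/schedule.yaml --out out/
```

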