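# Methods

## Network family

All variants derive from one staged graph (the YOLOv10n layout): a
3×3/stride-2 stem, conv downsample into a C2f stage (repeats 3), conv
downsample into a C2f stage (6) tapped at stride 8, spatial-channel
decoupled downsampling (SCDown) into a C2f stage (6) tapped at stride
16, SCDown into a C2f stage (3), SPPF and a partial self-attention
block (PSA) at stride 32. Stage widths before scaling are
64/128/256/512/1024. The neck is PAN+FPN with C2f fusion blocks and a
compact-inverted-block (CIB) stage at the deepest level; the deepest
CIB uses a plain 3×3 depthwise mid-conv (no large-kernel
re-parameterised branch — this choice is what reconciles the whole
parameter ladder, see *Calibration*). The head is the dual-assignment
decoupled head: a one-to-many branch for dense training supervision
and a structurally identical one-to-one branch, fed detached features,
used for NMS-free inference. Box regression is distributional (DFL,
16 bins per side, expectation decode).

Scaling rules: `channels = ceil(min(base, 1024) * width / 8) * 8`,
`repeats = max(round(base * depth), 1)`. The ladder configs are
packaged as YAML (`yolov10n` 0.33/0.25; `model1`–`model5` and `kiwi`
at 0.33/0.125 with module toggles).

## HetConv and C2fDualHet

A HetConv filter gives K×K kernels to M/P input channels and 1×1 to
the remaining M − M/P. Cost model (MACs):

- standard: D_o² · M · N · K²
- K×K part: D_o² · M · N · K² / P
- 1×1 part: D_o² · N · (M − M/P)
- ratio: 1/P + (1 − 1/P)/K²

The layer realises the interleaved arrangement: filter f applies K×K
kernels to channels c with c ≡ f (mod P), so the filter bank jointly
covers every input channel spatially. Implementation groups filters by
residue class (P standard convs on strided channel subsets plus P
pointwise convs on the complements, then an index-permutation
reassembly), which makes the instrumented MAC count equal the cost
model by construction. A DualHetBlock chains two HetConv layers, each
followed by batch-norm + SiLU, with a residual add when input and
output widths match — exactly the bottleneck it replaces, with only
the convolution type changed. C2fDualHet substitutes DualHetBlocks for
the bottlenecks of the four *backbone* C2f stages only; neck C2f and
the CIB stage keep dense convolutions.

## Cross-scale fusion neck

The CCFM variant removes SPPF and PSA (hybrid-encoder style: the
deepest level enters the fusion module through a 1×1 entry projection)
and replaces the stock neck with:

- `reduce`: 1×1 conv+BN+SiLU taking the stride-32 backbone output to
  the fused width (256 through the width rule; 32 at width 0.125);
- `proj3`, `proj4`: 1×1 conv+BN+SiLU input projections for the
  stride-8/16 taps;
- `lat5`, `lat4`: bias-only 1×1 lateral convs (no normalisation or
  activation) on the top-down path, each followed by ×2
  nearest-neighbour upsampling;
- `down3`, `down4`: SCDown stride-2 downsamplers on the bottom-up path;
- fusion joins width-aligned streams by elementwise addition (no
  fusion blocks remain — the heavy per-level fusion stacks are what
  this neck removes).

The head then sees three equal-width levels at strides 8/16/32.

## Calibration of the open structural choices

Three things the source material leaves open were fixed by matching
the published parameter ladder exactly (counts are training-time, both
head branches, single class):

- deepest-stage CIB mid-conv: plain depthwise 3×3 (large-kernel branch
  would give 2.707M instead of the published 2.694M baseline);
- HetConv partition and substitution extent: P = 4, backbone-only
  (gives Model 2 = 917,934 = 0.917M; P = 2/8 give 0.944/0.904M, and
  extending to the neck gives 0.890M);
- fusion-neck layout: the structure above is the unique small-conv
  combination reaching Model 3 = 586,478 = 0.586M (12,352 neck
  parameters) and hence Model 5 = 505,838 = 0.505M and 2.02 MB at
  4 bytes/parameter.

Published tables truncate millions at three decimals (998,574 → 0.998;
917,934 → 0.917; 505,838 → 0.505); the profiler reports exact counts
and the acceptance script applies the same truncation.

## Profiling conventions

FLOPs are counted by instrumenting a real forward pass: every conv
(including each HetConv sub-conv) and attention matmul reports MACs;
the headline number is 2 FLOPs/MAC over the deploy forward (one-to-one
branch only). This convention was calibrated once against the
published baseline figure (6.6 GFLOPs at 640: we compute 6.578) and
then frozen. `full_ops=True` additionally counts pointwise work
(normalisation, activation, bias adds); `head_mode="dual"` profiles
the training-time forward. Serialized size is estimated as 4
bytes/parameter (fp32); the actual checkpoint is compressed and
reported separately.

Under the frozen convention the fusion-neck variants compute to 1.80
(Model 3) and 1.57 (full model) GFLOPs. The corresponding published
figures (2.32 / 2.1) cannot be produced by any uniform counting of
this architecture once the parameter ladder is matched: with the neck
and head pinned to 0.586M parameters there is no room for the ~0.5
GFLOPs the published numbers imply, and the published column is not
internally consistent either (the same backbone-only substitution
appears as a 0.5 GFLOP drop in one row pair and 0.22 in another; the
baseline itself is printed as both 5.5 and 6.6). We report what the
profiler measures.

## Losses

All six IoU-family losses (GIoU, DIoU, CIoU, EIoU, SIoU, MPDIoU) are
implemented on the autograd tensor type, reduce to 1 − IoU plus a
non-negative penalty, and are zero exactly on coincident boxes. MPDIoU
normalises the two squared corner distances by h² + w² of the network
input (640² by default during training — the letterboxed extent, a
documented constant). The corner terms use squared *differences* of
corresponding coordinates; a typeset variant with sums appears in
print but is not a distance and is not what the loss's own definition
describes. The training criterion is BCE classification against
task-aligned soft targets (alignment metric s^0.5 · IoU^6, top-10
candidates for the one-to-many branch, top-1 for one-to-one), the
selected IoU-family loss on decoded boxes, and a two-bin soft
cross-entropy DFL term, with component weights 7.5/0.5/1.5
(box/cls/dfl) summed over both branches.

## Synthetic orchard scenes

The generator emulates the qualitative profile of a trellised-orchard
kiwifruit dataset: 640×640 (configurable) scenes, a single class,
1–8 near-circular fruit per image (aspect ratio ~N(1, 0.08) clipped to
[0.75, 1.33], mirroring the ratio-clusters-at-1 profile), fruit
centres drawn from a Beta(2.5, 2.5) per-axis distribution (density
peaks in the central third), partial leaf occluders with probability
0.35, and three lighting modes (sunny / cloudy / night-flash)
modulating brightness, contrast and vignetting. Boxes annotate the
un-occluded fruit extent, as annotators box whole fruit. Scenes are
pure functions of (seed, index) via counter-based PCG64 streams, so
datasets regenerate bit-identically. The "easy" regime used by the
end-to-end smoke check is occlusion-free, high-contrast, 2–4 larger
fruit with overlap-free placement (bounded rejection sampling).

What the synthetic scenes do *not* model: real foliage texture and
colour statistics, perspective and trellis geometry, motion blur,
fruit clusters with heavy mutual occlusion. Passing the smoke check
therefore demonstrates that the training loop, assignment, losses and
NMS-free decoding work end to end — not field-level accuracy.

## Training

Defaults follow the reference recipe: SGD, momentum 0.937 (linear
warmup from 0.8 over 3 epochs), initial LR 0.01 with linear LR warmup
then cosine annealing to 1% of LR0, weight decay 5e-4 on weight
matrices only, batch 16, 150 epochs, input 640. Optional augmentation
(horizontal flips) and weight-EMA are off by default (EMA lags badly
in runs of only a few hundred steps and is useful only at full scale);
structural accounting is never affected by either. The smoke regime
used in the test suite is 64 scenes at 160 px, 30 epochs, batch 6 with
momentum 0.9: the smaller batch gives ~330 optimizer steps (batch 16
yields too few to converge on 64 images), and the reduced momentum
damps plateau oscillation of the epoch-averaged loss. The run takes
roughly three minutes on one CPU. All randomness (weights, batch
order, augmentation) derives from the run seed; CPU reruns are
bit-identical. A caveat measured during harness calibration: with
mini-batch SGD and batch normalisation at this problem size, *strict*
epoch-over-epoch loss decrease is seed-sensitive — sub-2% upticks near
the plateau appear in roughly half of seed draws for any configuration
that also clears mAP@50 0.9. The committed smoke run satisfies both
properties; a downward trend plus final-below-first is the robust
property across seeds.

## Evaluation

Greedy confidence-ordered one-to-one matching (ties broken by stable
rank), AP as the area under the precision envelope via 101-point
recall interpolation (an exact all-points integrator is available),
mAP@50 and mAP@50–95 over thresholds 0.50:0.05:0.95, and
operating-point precision/recall at a configurable confidence
threshold (default 0.25; the threshold behind published P/R tables is
not stated anywhere, so it is exposed as a parameter).

## Numerical and degenerate-input choices

Zero-area unions define IoU = 0. Box-loss kernels add 1e-9 to
denominators. Empty label files are valid negative images; an
assignment with no foreground anchors yields a classification-only
loss. Batch norm uses eps 1e-3, momentum 0.03; inference uses running
statistics. The DFL projection clamps target distances to
reg_max − 1.01 stride units. `split_dataset` uses a seeded PCG64
permutation with largest-remainder allocation (1280 files at 8:1:1 →
1024/128/128; the source data's printed 772/253/255 split of 1,280
images contradicts its own stated 8:1:1 ratio and is recorded, not
reconciled).

## Known limitations

- NumPy training is practical only at smoke scale; the 640-px,
  150-epoch reference recipe is supported by the code but not by CPU
  budgets.
- The one-to-one branch is trained with top-1 assignment from scratch;
  on harder synthetic regimes (occlusion, night-flash) 30-epoch runs
  do not saturate.
- Published GFLOPs for the fusion-neck rows are not reproducible from
  the published parameter counts (see *Profiling conventions*); the
  profiler's numbers are self-consistent and oracle-checked instead.
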