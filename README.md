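# vasctort

Quantification of retinal vascular tortuosity from binary vessel masks of
murine flat-mounts.

In the oxygen-induced retinopathy (OIR) mouse model — hyperoxia from
postnatal day P7 to P12, then room air — the retina develops
vaso-obliteration (VO), neovascularization (NV, peaking at P17), and
measurably tortuous large vessels.  NV and VO area fractions are routine
outcome measures; tortuosity usually is not, for lack of a standardized
computation.  `vasctort` provides one: it takes binary vessel-segmentation
masks (hand-traced or automated) plus optic-disc center coordinates, and
returns per-image tortuosity indices, inter-grader Dice agreement, NV/VO
area ratios, and group statistics with star annotations.

## Method in brief

Each mask is thinned to a unit-width skeleton, turned into a pixel-adjacency
graph, and decomposed into vessel segments between branch points and
endpoints (a configurable exclusion disc removes the confluence hub at the
optic disc; short spurs are pruned).  Each segment's chain is smoothed
(Savitzky–Golay, local quadratic) and resampled at equal arc length
(default 5 px); with interior turning angles θᵢ the per-segment metrics are

- **CTI** — cumulative tortuosity index: `L_arc / L_chord` (≥ 1; 1 for a
  straight vessel; scale-invariant),
- **IC** — integrated curvature: `Σ|θᵢ|` (rad),
- **OC** — overall curvature: `mean|θᵢ|` (rad),

averaged (unweighted) over segments to image level.  Two-group comparisons
use the classical unpaired Student t test, ≥ 3 groups one-way ANOVA, with
stars `*` p < 0.05, `**` p < 0.01, `***` p < 0.001, `****` p < 0.0001
(strict inequalities).  Inter-grader agreement is the Dice coefficient
`2|A∩B| / (|A|+|B|)` over all grader pairs.  See `docs/methods.md` for the
full model, parameter defaults and limitations.

A built-in phantom generator produces flat-mount-like masks — radial
vessels with sinusoidal perturbation of known amplitude — whose true
arc/chord ratios are computed by quadrature before rasterization, so the
whole pipeline is testable without any microscope data.

## Worked example

Generate a two-group synthetic cohort (low vs high sinusoid amplitude,
standing in for normoxic vs OIR retinas), measure tortuosity, and compare:

```sh
vasctort synth -o cohort --n-images 4 --seed 42 --group NOX=3 --group OIR=20
vasctort tortuosity cohort/masks cohort/disc_centers.csv -o results
vasctort compare results/tortuosity_per_image.csv cohort/groups.csv -o comparison.csv
```

which prints

```
wrote 8 masks -> cohort/masks
processed 8 images -> results (config 53be71086787)
cti: t_unpaired p=5.013e-13 **** -> comparison.csv
```

`results/tortuosity_per_image.csv` holds one row per image:

```
image_id,n_segments,cti,ic,oc,config_hash
NOX_000,8,1.008706625543391,2.5747860382944014,0.0390119096711273,53be71086787
NOX_001,8,1.0087477552914028,2.4462401791365633,0.037064245138432775,53be71086787
...
```

The NOX-like group sits at CTI ≈ 1.009 (nearly straight vessels; the
baseline is exactly 1) and the OIR-like group at ≈ 1.313; the comparison
table reports group means ± SD, the pooled-variance t statistic and
`****` significance.  The `config_hash` column fingerprints every tunable
parameter, so rows from different configurations can never be mixed
silently.

The same subcommands work on real data: a directory of TIFF/PNG masks, a
`disc_centers.csv` with columns `image_id,row,col` (add `--xy-order` if
your file is in x/y order), and a `groups.csv` with `image_id,condition`
(plus optional `timepoint`).  `vasctort dice` compares per-grader mask
directories; `vasctort ratios` converts NV/VO pathology masks to area
fractions with an optional expert-override CSV; `vasctort experiment` runs
everything and emits a tidy per-image table plus a comparison table per
metric and timepoint.

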