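# foldbias

Demonstrations of how **uneven vertex spacing** on cortical surface
meshes induces **spurious fMRI correlations** ("gyral bias"), built as a
tested, reusable pipeline on synthetic folded sheets.

Real surface meshes place vertices more densely in sulci than on gyral
crests. Two standard processing steps then turn spatially *independent*
noise into spatially *structured* surface signal:

1. **volume-to-surface upsampling** — neighbouring vertices sample the
   same (or interpolated) voxels where vertices are closer than the
   voxel grid;
2. **geodesic Gaussian smoothing** — a fixed-width kernel averages over
   more vertices where they are packed tightly.

Because vertex spacing tracks each individual's folding pattern,
anatomy leaks into "functional" data: noise-derived parcellations put
their borders on gyri, parcel means over-represent sulcal vertices, and
vertex-level functional connectivity of pure noise can identify
individuals ("fingerprinting") until near-neighbour pairs are removed.

## Package layout

| module | contents |
| --- | --- |
| `foldbias.mesh` | `TriangleMesh`, adjacency, inter-vertex distance, 1/3-triangle vertex areas, truncated edge-graph geodesics |
| `foldbias.synth` | folded/uniform toroidal sheet generators, cohorts, voxel grids, contiguous parcellations |
| `foldbias.signals` | surface/volume noise, trilinear & nearest projection, geodesic Gaussian smoothing kernels |
| `foldbias.local_stats` | local correlation (Fisher-averaged neighbour correlation), 15 mm normalisation, volumetric 6-neighbour control, autocorrelation-vs-distance, parcel time series |
| `foldbias.inference` | area-weighted Pearson, toroidal shift permutation test, t-tests with Cohen's d |
| `foldbias.parcellation` | connectivity-constrained Ward clustering, border-depth bias, matched/mismatched designs, parcel-mean bias |
| `foldbias.fingerprint` | FC matrices, vectorisation with distance thresholds, test–retest identification, threshold sweeps |
| `foldbias.experiments` | config-driven experiments E1–E8 + real-data diagnostics |
| `foldbias.io` | GIFTI surface/metric/label, NIfTI volume, plain-text fixtures |

## CLI

```sh
# run one experiment (E1..E8) with defaults, write a JSON summary
foldbias run E4 --out results/ --seed 0

# custom configuration
foldbias run E7 --config config.json --out results/

# diagnostics for external GIFTI data
foldbias diagnose --surface lh.surf.gii --depth lh.sulc.shape.gii \
    --series lh.func.gii
```

Experiments:

- **E1** normalised local correlation tracks the *own* depth map far
  more than the next participant's (individuality).
- **E2** inter-vertex spacing covaries with depth across a cohort.
- **E3** projecting voxel noise to the surface inflates local
  correlation where vertices are close (trilinear and nearest).
- **E4** smoothing surface noise does the same on folded meshes and not
  on uniform ones.
- **E5** controls: volumetric 6-neighbour correlations are unbiased;
  autocorrelation of smoothed noise decays with geodesic distance.
- **E6** Ward parcellation of smoothed noise puts borders on gyri,
  participant-specifically.
- **E7** fingerprinting: parcel-level FC of noise is at chance,
  within-parcel vertex-level FC is far above chance, and collapses once
  pairs closer than the largest inter-vertex distance are dropped.
- **E8** parcel means over-represent sulcal vertices; area-weighted
  averaging shrinks (but does not abolish) the bias.

## Synthetic model

Participants are periodic (toroidal) triangulated sheets. A smooth
sinusoidal "depth" field (positive = gyrus) drives an in-plane warp
whose divergence compresses vertices in sulci and stretches them on
gyri, plus an independent distortion field and an out-of-plane fold, so
the spacing–depth correlation lands in the range observed on real
participant meshes (~0.5) with spacing varying from about 1.5 mm in
sulci to 3.3 mm on crests. The toroidal domain makes cyclic translation
an exact autocorrelation-preserving permutation group — the synthetic
analogue of the spherical "spin test".
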