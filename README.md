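# asymparc

Connectivity-based parcellation and cross-species hemispheric-asymmetry
statistics for a seeded cortical region, with a synthetic-data generator
that makes the entire pipeline testable without any neuroimaging download.

## The problem

Comparative neuroanatomy asks whether a cortical region — here modeled on
the inferior parietal lobule (IPL) — is organized and lateralized the same
way in different primate species. The standard tractography workflow
answers this in four steps, each of which this package implements as a
tested library function:

1. **Connectivity-based parcellation.** Every seed vertex *i* of the
   region has a connectivity fingerprint: row *i* of an M×N matrix of
   connection strengths to N whole-brain targets. Pearson correlation of
   fingerprints gives an M×M similarity matrix; subject matrices are
   averaged into a group matrix and spectral clustering partitions the
   seeds into k subregions. k is scanned (2–12) and chosen as the largest
   value whose partitions stay consistent across hemispheres and species.
2. **Profile processing.** Raw tractography values are mapped through
   x → log(1+x), max-normalized to [0, 1], optionally smoothed over a
   seed-adjacency graph, averaged into population maps, and thresholded;
   the union of left and mirrored-right supports is the analysis mask.
3. **Asymmetry statistics.** For homotopic measurements L and R the
   asymmetry index is

       AI = 2 (R − L) / (R + L)   ∈ [−2, 2],

   negative = leftward dominance. Vertex-wise, per-subject AIs are tested
   against zero with one-sample t statistics whose null comes from
   sign-flip permutation (exhaustive over all 2ⁿ flips when 2ⁿ ≤ n_perm),
   corrected by Benjamini–Hochberg FDR across the mask and summarized by
   Cohen's d. Volumetric, ROI-wise and tract-wise AIs use two-sided
   Wilcoxon signed-rank tests (exact enumerated null for n ≤ 12) with
   Bonferroni correction.
4. **Allometric scaling.** Subregion volume V against total gray-matter
   volume G follows a power law V = b·Gᵃ, fitted as OLS of ln V on ln G
   pooled across species; a > 1 is positive allometry. Left/right slope
   equality is tested by the hemisphere × ln G interaction F-test
   (ANCOVA-style) in a stacked model.

The synthetic generator (`asymparc.synth`) plants all of this with known
ground truth: block-structured fingerprints, multiplicative right-
hemisphere connectional effects, volumetric AIs of either sign, and
power-law volume scaling with lognormal noise. Three presets mirror the
qualitative study conditions: a `macaque`-like null species (n=8), and
`chimp`-like (n=27) and `human`-like (n=40) species sharing an
anterior-leftward / posterior-rightward volumetric pattern, with the
human-like species carrying connectional effects on more targets.

## Worked example

```sh
asymparc run-all --seed 0 --out demo_run
asymparc report --run demo_run
```

prints (abridged):

```
selected cluster count k = 4 (consistency threshold reached: True)

significant asymmetries (corrected) by species and level:
  macaque    total=   0  (none)
  chimp      total=  47  (roi=6, tract=5, vertex=32, volumetric=4)
  human      total=  98  (roi=10, tract=8, vertex=76, volumetric=4)

allometric scaling slopes (pooled, species means):
  C1   L  slope=1.176  R2=1.000
  C1   R  slope=1.129  R2=1.000
  ...
```

Reading: the consistency scan recovered the planted four-subregion
organization; the null species shows no significant asymmetry anywhere;
both asymmetric species recover the planted volumetric sign pattern in
all four subregions (leftward C1–C2, rightward C3–C4, Bonferroni
p < 0.05); the human-like species shows about twice as many significant
connectional units as the chimp-like one, matching its wider planted
effects; and every fitted scaling exponent exceeds 1 (positive
allometry), near the planted 1.15–1.30.

The same stages are available piecemeal (`simulate`, `process`,
`parcellate`, `scan-k`, `asym`, `allometry`) and as library calls:

```python
import asymparc as ap

ds = ap.generate_dataset(ap.human_like(), seed=0)
sim, truth = ap.block_similarity(400, k=4, seed=0)
parc = ap.spectral_parcellate(sim, k=4, seed=0)
ap.asymmetry_index(3.0, 1.0)   # -1.0, leftward
```

All artifacts are plain TSV/JSON; re-running a config reproduces them
byte-identically.

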