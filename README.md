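# pelagia

Quantitative machinery for timing a pelagic fish radiation: biostratigraphic
confidence limits on times of evolutionary origin, MCMCTREE-style
truncated-Cauchy clock calibrations, paleontological-vs-molecular timescale
concordance, mitogenomic supermatrix coding, and maximum-likelihood
ancestral depth reconstruction.

## The problem

The open-ocean percomorph radiation nicknamed **Pelagia** — 15 families
including the tunas and mackerels (Scombridae) — poses a classic
calibration problem. Its molecular timescale is deliberately estimated
*without* any ingroup fossil calibrations, so that an independent
paleontological timescale, built from the clade's own fossil record, can be
compared against it. This package implements every quantitative step of
that comparison for anyone doing the same style of analysis:

1. **Fossil record → origin estimates** (`pelagia.fossilrec`). A family's
   fossil record is summarized by the ages of its distinct fossil-bearing
   horizons: the oldest (*y*, the first appearance datum), the youngest
   (*z*), the observed range *R = y − z*, and the horizon count *N_h*.
   Under uniform preservation potential, the classical range-extension
   confidence limit at level α and the unbiased ML point estimate of the
   origin time are

   ```
   CI_α  =  y + f·R·[(1 − α)^(−1/(N_h − 1)) − 1]          (f ≥ 1)
   t̂     =  y + (y − z)/(N_h − 1)
   ```

   where `f = 10` models preservation an order of magnitude higher within
   the observed range than before it (the `CI_0.5,10%` sensitivity check).

2. **Soft-bound calibrations** (`pelagia.calib`). An MCMCTREE minimum bound
   `L(t_min, p, c)` puts 2.5% of its mass below the soft minimum and a
   truncated Cauchy with location `t_min(1+p)` and scale `c·t_min` above
   it. Given a stated soft maximum `t_max`, the scale `c` is solved by a
   bracketed root search so that `t_max` falls at the 97.5% point; three
   published tail conventions are supported (see `docs/methods.md`).

3. **Timescale concordance** (`pelagia.concord`). Each estimable family's
   fossil-based `t̂` is paired with the molecular *stem* age of the same
   lineage (parent of the family's MRCA — the total-group origin in a
   sampled tree), and disagreement is the residual sum of squares from the
   1:1 line, `RSS = Σ (t_mol − t̂)²`.

4. **Supermatrix coding** (`pelagia.supermatrix`). The four standard
   mitogenomic data sets from per-gene alignments (ND6 excluded):
   `12n3rRTn` (RY-coded third positions), `123nRTn`, `12nRTn` (thirds
   dropped), `123aRTn` (vertebrate-mito amino acids) with 5/5/4/3
   partitions respectively.

5. **Ancestral depth ecology** (`pelagia.depthmap`). Species depths are the
   means of their reported minimum/maximum depths; ancestral states are the
   Brownian-motion ML estimates obtained by re-rooting the chronogram at
   each internal node and taking the contrasts (pruning) state at the root,
   with linear-in-time interpolation along branches and epipelagic
   (≤ 200 m) / mesopelagic zone labels.

`pelagia.synth` generates synthetic inputs with known ground truth for all
of the above, and `pelagia.demo` packages a deterministic synthetic
stand-in for the study's tables (15 families: 2 with no fossil record, 3
single-horizon, 10 estimable).

## Worked example

The numbered scripts under `analysis/` run the whole study on the packaged
synthetic data, writing tables under `results/`:

```
$ python analysis/02_fossil_confidence_intervals.py
estimability census: 2 families with no record, 3 single-horizon, 10 estimable
wrote results/ci_table.tsv: 10 families with numeric confidence ages
widest two-tailed upper limit: Caristiidae (FAD 33.0 Ma -> CI_0.975 83.8 Ma; sparse records stretch furthest)

$ python analysis/03_solve_calibrations.py
MRCA_Carangidae_Echeneoidea   bounds 56.0-93.9 Ma  solved c = 0.04175  published 0.04175
...
```

The census line is the estimability split of the 15-family fixture; the
calibration lines show the truncated-Cauchy scale re-solved from each
published bound pair, matching the published value (one published scale is
internally inconsistent by a factor of ten with its own bounds; the script
flags it). Script 04 prints the RSS of the fossil-only vs the older-biased
calibration scheme (the fossil-only scheme is the more concordant), and
script 06 reconstructs a mesopelagic (~400 m) ancestor for the synthetic
radiation with shallow-water shifts in several terminal lineages.

Equivalent functionality is exposed as a CLI (`pelagia synth|fossil|calib|
concord|matrix|depthmap|run`); `pelagia run --config cfg.yaml` drives all
stages from one YAML file and writes a JSON run manifest.

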