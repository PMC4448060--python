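# voxtype

Links gene cliques to cell types through voxel-based gene-expression
atlases. Given a voxel-by-gene expression-energy matrix and a panel of
cell-type transcriptomes, the pipeline:

1. **Deconvolution** — estimates a nonnegative spatial density for every
   cell type at every voxel by per-voxel nonnegative least squares
   (optionally L1-penalized).
2. **Clique scoring** — sums a gene clique's expression columns into a
   brain-wide profile and ranks cell types by cosine similarity between
   the profile and each density column; a threshold sweep over the
   L2-normalized profile locates the similarity peak per type.
3. **Monte Carlo significance** — simulates the null similarity
   distribution from random same-size gene sets (draw count sized by
   Hoeffding's inequality; default R = 27,000) and reports, per type, the
   fraction of draws strictly below the observed similarity.
4. **Pair fitting** — finds the optimal nonnegative combination of every
   pair of density columns in closed form, detects pairs that beat every
   single type, and assesses their significance with the same draws.
5. **Region similarity** — scores density columns against unit-norm
   region-mask indicators.

A synthetic-data module generates atlases with known ground truth
(marker-structured panels, disjoint slab territories, additive truncated
Gaussian noise, planted cliques), so the whole pipeline is testable
end-to-end without any external data.

## CLI

All stages are subcommands of `voxtype` (use `-v` for stage timings):

```sh
voxtype synth --outdir data --seed 0                      # synthetic inputs
voxtype deconvolve --atlas data/atlas.tsv --panel data/panel.tsv --out dens.tsv
voxtype cliquescore --atlas data/atlas.tsv --densities dens.tsv \
    --clique data/clique.txt --out score/
voxtype significance --atlas data/atlas.tsv --densities dens.tsv \
    --clique data/clique.txt --draws 27000 --seed 0 --out ranking.tsv
voxtype pairs --atlas data/atlas.tsv --densities dens.tsv \
    --clique data/clique.txt --out pairs/
voxtype regionscore --densities dens.tsv --mask data/mask_territory_type00.txt \
    --out region.tsv
voxtype run-all --seed 0 --outdir results/   # everything, incl. synthesis
```

`run-all` also accepts a YAML config (`--config cfg.yaml`) covering the
synthetic-data settings, draw counts, sweep steps, and the significance
reporting threshold. Runs are fully deterministic for a fixed seed; every
report is a TSV and a `manifest.json` records seeds and versions.

All file formats are plain text: matrices are TSV with a gene-identifier
header row and a leading label column (`x:y:z` voxel coordinates or type
labels), gene cliques are one symbol per line, region masks one voxel
index per line.

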