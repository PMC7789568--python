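# dmrscan

Window-based differential DNA methylation (MeDIP-seq-style) analysis.

The package tiles a genome into fixed 1-kb windows, counts aligned-read
intervals per window per sample, tests each window between case and control
groups with a common-dispersion negative-binomial exact test, merges adjacent
significant windows into DMRs (differential methylation regions), and
validates the DMR set with a label-permutation null, leave-one-out
cross-validation and PCA nearest-centroid classification of blinded samples.
A synthetic-data module generates complete desk-scale datasets (genome FASTA,
read BED, NB count matrices with planted differential regions), and a
clinical-statistics module reproduces the group summaries of the packaged
26-sample semen-analysis table.

## Library quick start

```python
from dmrscan import SimConfig, simulate_dataset, test_all, call_dmrs
from dmrscan.validate import permutation_test, cross_validate

cfg = SimConfig(n_chromosomes=2, chrom_length=1_000_000,
                n_planted_dmrs=50, effect_fold=2.5, seed=7)
sim = simulate_dataset(cfg)           # genome, window grid, truth, counts
results = test_all(sim.counts)        # per-window p, q, log2 fold change
dmrs = call_dmrs(results, sim.grid, p_threshold=1e-5)
null = permutation_test(sim.counts, sim.grid, n_permutations=50, seed=11)
cv = cross_validate(sim.counts, sim.grid)
print(len(dmrs), null.empirical_p, cv.accuracy)
```

## CLI

Every stage is also a `dmrscan` subcommand:

```bash
dmrscan simulate --out-dir sim --n-dmrs 20 --effect-fold 3 --seed 1 --write-reads
dmrscan count --genome sim/genome.fasta --reads sim/reads.bed \
              --sample-sheet sim/sample_sheet.tsv --out counts.tsv
dmrscan test --counts sim/counts.tsv --sample-sheet sim/sample_sheet.tsv --out results.tsv
dmrscan call-dmrs --results results.tsv --out dmrs.tsv \
                  --bed-out dmrs.bed --genome sim/genome.fasta
dmrscan annotate --dmrs dmrs.tsv --genes genes.bed --out annotated.tsv
dmrscan enrich --dmr-genes genes.txt --gene-set set.txt --universe 20000 --out enrich.tsv
dmrscan validate perm --counts sim/counts.tsv --sample-sheet sim/sample_sheet.tsv \
                      --n-perm 100 --seed 1 --out perm.tsv
dmrscan validate cv   --counts sim/counts.tsv --sample-sheet sim/sample_sheet.tsv --out cv.tsv
dmrscan classify --counts all_counts.tsv --sample-sheet sheet_with_blinded.tsv --out calls.tsv
dmrscan clinical-stats --out clinical.tsv
```

All coordinates are 0-based half-open (BED convention); window rows are
labelled `chrom:start-stop`. Count tables are TSV (windows x samples), sample
sheets are two-column TSV (`sample_id`, `group` in `case`/`control`/`blinded`).

## Layout

| module | responsibility |
| --- | --- |
| `dmrscan.simulate` | synthetic genomes, planted DMRs, NB count matrices, read intervals |
| `dmrscan.windows`  | window grids, read counting, RPKM, CpG counting |
| `dmrscan.difftest` | library-size equalization, common dispersion (conditional ML), NB exact test, BH |
| `dmrscan.dmr`      | DMR merging, threshold table, CpG/length features, gene association, gene-set overlap |
| `dmrscan.validate` | permutation null, PCA + nearest-centroid, LOO cross-validation, outlier-DMR removal |
| `dmrscan.clinical` | packaged semen table, group summaries, t-tests, 2-SD outlier re-analysis |
| `dmrscan.io`       | FASTA / BED / TSV readers and writers |
| `dmrscan.cli`      | `dmrscan` command-line entry point |
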