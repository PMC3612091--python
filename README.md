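# cismodules

Discovery and scoring of paired-motif cis-regulatory modules in gene
upstream regions.

Given upstream sequences (FASTA, one record per gene, 5'→3' on the gene's
strand with the last base abutting the translation start), `cismodules`:

1. **scans** both strands for IUPAC consensus motifs with an allowed
   mismatch budget (e.g. PAC = `GATGAG`, its single-nucleotide variant
   PAC2 = `GATAAG`, a user-supplied A/T-rich RRPE consensus);
2. **pairs** occurrences into *modules* — two motif instances in one
   region with an edge-to-edge gap up to `max_gap` (default 200 bp) — and
   labels each with its 5'→3' motif order and strand agreement;
3. **scores** every (gene set × module order) with five statistics
   combined into a weighted module score normalized to [0, 1]:
   * **Sig value** (bits): binomial-tail overrepresentation of each
     component motif, `Sig = -log2 P(X ≥ k)`, against an i.i.d. background
     estimated from a genome FASTA or the gene set itself;
   * **ABC score** in [−1, +1]: signed area between the empirical CDFs of
     actual vs shuffled-null inter-motif distances (null = same per-gene
     instance counts repositioned uniformly, non-overlapping, random
     strand; seedable);
   * **position score** in [0, 1]: Kolmogorov–Smirnov distance of module
     upstream positions from uniform;
   * **coverage**: fraction of genes with ≥ 1 module instance;
   * **orientation**: strand co-orientation preference `|2·f_same − 1|`;
4. runs the **downstream analyses**: upstream-distance quartile fractions,
   per-group attribute means (with ABC+1 and |upstream| display
   transforms), partition of genes by exclusive module orientation with
   exact hypergeometric term enrichment, and a greedy *extra-gene* search
   that adds genome genes which improve a motif's Sig value;
5. ships a **synthetic-data generator** that plants modules with known
   gap, order, strand relation, position bias and coverage, emitting exact
   ground-truth tables.

## CLI

All stages are subcommands of one entry point (`cismodules --help`):

```sh
cismodules scan      --fasta up.fasta --motifs motifs.yaml --out occ.tsv
cismodules modules   --occ occ.tsv --pair RRPE,PAC --max-gap 200 --out modules.tsv
cismodules score     --fasta up.fasta --occ occ.tsv --motifs motifs.yaml \
                     --pairs "RRPE,PAC" --replicates 1000 --seed 17 --out attrs.tsv
cismodules quartiles --occ occ.tsv -L 800 --out q.tsv
cismodules aggregate --attrs attrs.tsv --groups groups.tsv --out table.tsv
cismodules partition --modules modules.tsv --orders RRPE-PAC,PAC-RRPE --out-prefix part_
cismodules enrich    --subset part_RRPE-PAC.txt --universe genes.txt \
                     --annot annotations.tsv --alpha 1e-3 --out enrich.tsv
cismodules extra-genes --set set.fasta --candidates genome.fasta \
                     --motif PAC --motifs motifs.yaml --max-added 20 --out extra.tsv
cismodules simulate  --spec plant.yaml --out-prefix sim/
cismodules run       --config config.yaml --out-dir out/
```

`run` executes scan → modules → score → quartiles → aggregate and writes a
`manifest.json` (parameters, seed, input checksums, version, timestamp);
re-running with the same seed reproduces identical statistics tables.

A minimal `config.yaml`:

```yaml
fasta: upstream.fasta
motifs:
  RRPE: {consensus: AAAAWTTTT, max_mismatches: 1}
  PAC: GATGAG
pairs: ["RRPE,PAC"]
weights: {sig: 1, abc: 1, position: 1, coverage: 1, orientation: 1}
seed: 17
replicates: 1000
```

Motif occurrence tables are TSV with 0-based, end-exclusive coordinates on
the upstream string and strand relative to the gene; `distance_to_atg` is
`region_length − end`.

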