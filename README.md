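# barcodelim

**Single-locus species delimitation and congruence analysis for DNA barcodes.**

When a species-rich group (tropical chafers, say) is inventoried with COI
barcodes, different de novo delimitation methods applied to the *same*
sequences routinely return different numbers of molecular operational
taxonomic units (MOTUs), and none of them need agree with the morphospecies
a taxonomist would recognise from, e.g., male genital shape.  `barcodelim`
is a toolkit for quantifying exactly that: it implements five delimitation
engines, the *match ratio* congruence statistic between any two specimen
partitions, split/lump diagnostics per species, a method-similarity matrix,
and its PCoA ordination — plus a synthetic barcode-community generator with
known species boundaries so every stage can be validated without touching a
sequence archive.

## The core statistic

For a MOTU partition with $N_{mol}$ blocks and a reference (morphospecies)
partition with $N_{morph}$ blocks over the same specimens,

$$\mathrm{match\ ratio} = \frac{2\,N_{match}}{N_{mol} + N_{morph}},$$

where $N_{match}$ counts *exact* matches: specimen sets that appear as a
block in both partitions.  The ratio is 1 exactly when the partitions are
identical.  Each reference species is further classified as **match**,
**split** (spread over ≥ 2 MOTUs, all subsets), **lump** (inside one larger
MOTU), or **mixed**.

## Delimitation engines

| engine | input | idea |
|---|---|---|
| `threshold` | distance matrix | single-linkage components below a fixed cutoff (default 2.2%, a BIN proxy) |
| `tcs` | alignment | statistical-parsimony networks: haplotypes connected while the step count stays below the 95% non-homoplasy limit |
| `abgd` | distance matrix | barcode-gap discovery over a geometric grid of prior divergences, with recursive within-group re-splitting |
| `asap` | distance matrix | every single-linkage merge level scored by a panmixia probability and a relative gap width, candidates ranked |
| `ptp` | rooted tree | Poisson tree processes ML delimitation (single-rate, and multi-rate with AIC), exact on small trees, DP-assisted heuristic on large ones |

## Worked example

Simulate a 5-species community (4 specimens each, 658 bp, intraspecific
diversity θ = 0.005) in which one species pair shares a single haplotype
pool — morphologically distinct, mitochondrially indistinguishable — and
run the whole pipeline:

```python
import barcodelim as b
from barcodelim.pipeline import RunConfig, run_pipeline

cfg = RunConfig(
    outdir="demo_out", seed=11,
    simulate=b.CommunityConfig(n_species=5, n_per_species=4,
                               n_recent_pairs=1, seed=11),
)
result = run_pipeline(cfg)
print(result["table"].to_string())
```

```
             BIN-proxy   TCS  ABGD-p0.001  ABGD-p0.007906  ASAP-1st  ASAP-2nd  mlPTP  mPTP
N_match           3.00  3.00          2.0            3.00      3.00       0.0   3.00   3.0
N_MOTU            4.00  4.00          5.0            4.00      4.00      12.0   4.00   5.0
match_ratio       0.67  0.67          0.4            0.67      0.67       0.0   0.67   0.6
```

Read: the community truly has 5 species, but the cryptic pair is lumped by
essentially every engine — 4 MOTUs, 3 of which exactly match a true
species, hence a match ratio of 2·3/(4+5) = 0.67.  The output directory
also holds the per-species status table, the pairwise method-similarity
matrix and its PCoA coordinates, every per-method partition as TSV, and a
run log with seeds and input digests.

The same steps are available from the shell:

```sh
barcodelim simulate --seed 11 -o sim/
barcodelim dist sim/alignment.fasta -o dist.tsv
barcodelim delimit threshold --t 0.022 dist.tsv -o bin.tsv
barcodelim delimit ptp sim/genealogy.nwk -o ptp.tsv
barcodelim compare --ref sim/true_partition.tsv bin.tsv ptp.tsv -o congruence.json
```

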