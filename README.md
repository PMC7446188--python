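# redikit

RNA-editing site detection from coordinate-sorted RNA-seq alignments, built
around three ideas:

- **Single-load pileup traversal** — each alignment record is retrieved from
  the BAM exactly once per interval traversal (instead of once per covered
  position, as position-by-position `mpileup`-style engines do), with
  instrumentation to verify the contract (`loads/read == 1`, peak active-read
  buffer size).
- **Dynamic Interval Analysis (DIA)** — a greedy partitioner that splits the
  genome into intervals of approximately equal *estimated processing cost*,
  where per-position cost is `floor + scale * coverage**exponent` (cubic by
  default). This balances workloads dominated by coverage hotspots far better
  than equal-width tiling.
- **Coordinator/worker parallel driver** — intervals are dispatched to idle
  workers with `COMPUTE` messages, completions collected via `DONE`, workers
  released with `FINISH`; per-interval temporary tables are merged in plan
  order so the final output is byte-identical to a serial run regardless of
  worker count or completion order.

Candidate sites are emitted in a tab-separated table:

```
Region  Position  Reference  Strand  Coverage-q25  MeanQ  BaseCount[A,C,G,T]  AllSubs  Frequency
chr1    1521      A          2       39            38.00  [16, 0, 23, 0]      AG       0.59
```

Positions are 1-based in the table (0-based half-open internally); strand is
`1` plus, `0` minus, `2` undefined.

A synthetic-data module (`redikit.synthetic_data`) generates references,
truth tables of planted A→G (T→C on minus) editing sites, and
coordinate-sorted indexed BAMs with configurable coverage profiles,
hotspots, error rates and CIGAR features — every test fixture is built from
a seed at run time.

## CLI

```sh
# simulate a fixture (reference.fa, reads.bam, truth.tsv)
redikit simulate --chroms 2x100000 --depth 30 --sites 50 --freq 0.1:1.0 \
    --error 0.001 --seed 7 -o fixtures/

# serial analysis
redikit serial -f fixtures/reads.bam -r fixtures/reference.fa -o out.tsv \
    -q 25 -m 25 -c 10 -v 3 -n 0.1 --stats

# parallel analysis with DIA partitioning
redikit parallel -f fixtures/reads.bam -r fixtures/reference.fa -o out.tsv \
    -w 4 --dia --bin-size 1000 --scratch scratch/

# export an interval plan as BED (5th column = estimated cost)
redikit plan -f fixtures/reads.bam -n 8 -o plan.bed
```

Key options: `-q` minimum base quality (the `Coverage-q<Q>` column header
follows it), `-m` minimum mapping quality, `-c`/`-v`/`-n` caller thresholds
(coverage / alt reads / frequency), `-s` library strandedness, `--emit-all`
to report every covered position, `--load-intervals` for a user BED plan.

## Layout

| module | contents |
| --- | --- |
| `redikit.alignment_io` | BAM/FASTA access, read filters, intervals, BED/region parsing |
| `redikit.pileup_engine` | single-load traversal, per-position tallies, instrumentation |
| `redikit.editing_caller` | substitution frequencies, strand inference, table writer/reader/merge |
| `redikit.dia_partitioner` | coverage track, cost model + fitting, DIA and naive partitioners |
| `redikit.parallel_driver` | serial runner, COMPUTE/DONE/FINISH coordinator (in-process and multiprocess backends) |
| `redikit.synthetic_data` | reference/truth/BAM simulation |
| `redikit.cli` | `redikit` command group |

Known limitations (documented, configurable where sensible): overlapping
mate pairs are counted independently; reverse-strand records report bases on
the genome plus strand; CRAM and remote access are unsupported.
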