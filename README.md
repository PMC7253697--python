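# kmerpanel

Design taxon-specific k-mer panels from collections of organellar (or any)
genomes, and detect those taxa in shotgun sequencing reads without
alignment.

The workflow:

1. **Panel building** — a *genus* panel is the set of canonical 32-mers
   present in *every* target genome and in *no* non-target genome; a
   *species* panel is the set private to one genome after subtracting
   congeners and non-targets.
2. **Read-based filtering** — panel k-mers observed in confounder
   whole-genome read sets (at a configurable per-set frequency cutoff)
   are removed.
3. **Detection** — reads are 3'-quality-trimmed (threshold 35, minimum
   length 32), every read window is canonicalized and counted against the
   panel, and the number of *distinct* panel k-mers at or above a
   frequency cutoff (1 or 2) is compared with a presence threshold
   (inclusive `>=`).
4. **Sensitivity curves** — detected k-mers as a function of subsampled
   read depth, with nested (prefix-of-one-permutation) subsampling so
   curves are deterministically monotone.
5. **Simulation** — synthetic target clades, divergent background genomes
   and error-bearing read mixtures at a controllable target fraction, so
   the whole pipeline is testable offline.

All k-mer handling is strand-agnostic via canonical form (the
lexicographically smaller of a k-mer and its reverse complement), with
2-bit encoding into 64-bit words (k <= 32).

## Command line

```sh
kmerpanel build-genus  -t albus.fa -t luteus.fa -t westianus.fa \
                       -n nontargets.fa --taxon Lupinus -o genus.panel
kmerpanel filter-reads --panel genus.panel -r confounder1.fastq.gz \
                       -r confounder2.fastq.gz -o genus.filtered.panel
kmerpanel detect       --panel genus.filtered.panel -r sample.fastq.gz \
                       -o report.tsv
kmerpanel curve        --panel genus.filtered.panel -r sample.fastq.gz \
                       --sizes 1000,10000,100000 -o curve.tsv
kmerpanel screen       --panel genus.filtered.panel -f assembly.fa
kmerpanel call         --taxon Lupinus --detected 1700 --panel-size 31179
kmerpanel simulate     --outdir sim/ --target-fraction 0.005 \
                       --panel-out sim.panel
```

Also available: `build-species` and `trim`. FASTA/FASTQ inputs may be
gzip-compressed. Exit codes: 0 success, 1 usage error, 2 data/format
error. Built-in presence thresholds: genus *Lupinus* 1,500; *L. albus*
7,500; *L. luteus* 4,000; *L. westianus* 4,300 (all overridable with
`--threshold`); the frequency cutoff defaults to 1 (2 for the
*L. luteus* / *L. westianus* presets). Global flags: `--seed`,
`--threads` (throughput only), `-v`, `--config` (JSON overrides).

Panels are plain-text files: `#`-prefixed headers (k, taxon, rank,
provenance) followed by one sorted uppercase k-mer per line.

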