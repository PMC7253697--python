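"""Independent naive string-based oracles used to cross-check the package.

Everything here works on plain Python strings and sets, with no bit
encoding, so it shares no code path with the implementation under test.
"""

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def naive_rc(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def naive_canonical(s: str) -> str:
    return min(s, naive_rc(s))


def naive_windows(seq: str, k: int):
    """(1-based position, canonical window) for pure-ACGT windows."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if all(c in "ACGT" for c in window):
            out.append((i + 1, naive_canonical(window)))
    return out


def naive_genome_set(seqs, k: int) -> set:
    """Union of canonical k-mers over a list of sequence strings."""
    out = set()
    for seq in seqs:
        out.update(kmer for _, kmer in naive_windows(seq, k))
    return out


def naive_genus_panel(target_genomes, nontarget_genomes, k: int) -> set:
    """target_genomes: list of genomes, each a list of sequence strings."""
    panel = None
    for genome in target_genomes:
        gset = naive_genome_set(genome, k)
        panel = gset if panel is None else panel & gset
    for genome in nontarget_genomes:
        panel -= naive_genome_set(genome, k)
    return panel


def naive_species_panel(species_seqs, sibling_genomes, nontarget_genomes, k: int) -> set:
    panel = naive_genome_set(species_seqs, k)
    for genome in list(sibling_genomes) + list(nontarget_genomes):
        panel -= naive_genome_set(genome, k)
    return panel


def naive_count(panel_kmers, reads, k: int) -> dict:
    """Occurrences of each panel k-mer over reads (double-strand scan)."""
    panel_kmers = set(panel_kmers)
    counts = {}
    for read in reads:
        for _, kmer in naive_windows(read, k):
            if kmer in panel_kmers:
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def naive_detected(counts: dict, min_freq: int) -> int:
    return sum(1 for v in counts.values() if v >= min_freq)
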