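# Phage methylase family data

The published-value checks in `tests/test_acceptance.py` expect the phage
DNA-methylase protein family here (not redistributable with this package):

- `pham_106461.fasta` — the 17-member pham (unaligned)
- `pham_105558.fasta` — the 254-member pham (unaligned)
- `combined.fasta` — the 271 analysed methylases (unaligned)
- `compact_alignment.fasta` — MAFFT alignment of the combined set
  (globalpair, maxiterate 1000)
- `gappy_extein_subset.fasta` — gappy-alignment extein columns for the
  carrier-enriched subset used by the constrained-tree suite
- `metadata.tsv` — columns: phage, cluster, location

Sequences can be retrieved from PhagesDB (https://phagesdb.org) by pham
number; phages are identified as `<PhageName>_<ORF>`.
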