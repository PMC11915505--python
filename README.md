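# tmrna-curator

A curation toolkit for tmRNA gene candidates. It automates the triage and
quality-control pipeline used to build large curated tmRNA gene collections:

- **hit ingestion** — parsers for Infernal `tblout`, BLAST tabular
  (`-outfmt 6`), tRNAscan-SE v2 tabular, and a minimal Aragorn-style tab
  dialect; strong/weak hit designation; flanked region extraction; the
  tRNA-overlap, contig-end-truncation and intron size/score rejection rules;
  under-represented-taxon candidate selection (`tmrna_curator.hits`)
- **segment mapping & chunk alignment** — transfer of named gene-segment
  boundaries (tRNA-like-5′, CDS, tRNA-like-3′, CCA, IVS, intron) from a
  matched reference, plus the boundary-anchored "chunk alignment" in which
  every segment is center-padded with dashes to the longest instance
  (`tmrna_curator.chunks`)
- **automated QC** — ambiguous-base blocks, 7-bp acceptor-stem pairing with
  shift-based rescue, CCA-position presence, tag reading-frame validation
  with declared-frameshift support, comparative internal-deletion detection
  (`tmrna_curator.qc`)
- **group I intron handling** — boundary determination inside the TψC-loop
  under the −1U/P1-G and ω-G rules (with the C/A variant), insertion-subsite
  assignment (positions 1–8), sequence-logo matrices, homing-endonuclease
  (HEG) flagging from HMMER `domtblout` evidence or an ORF heuristic, and a
  seeded random-insertion robustness simulator (`tmrna_curator.introns`)
- **seed-alignment preparation** — pairwise fractional identity, greedy
  identity filtering, flagged-row add-back, Stockholm I/O preserving
  `#=GC SS_cons` (`tmrna_curator.seedprep`)
- **taxonomy assignment** — smallest-containing-clade lineage assignment on
  Newick reference trees with GTDB-style lineages, and the `__X<n>` labeling
  convention for genomes unresolved below species (`tmrna_curator.taxonomy`)
- **core model** — gene records with segment maps, deduplication, the
  `species.serial` naming scheme, the staged curation funnel, and a
  tab-separated flat-file dialect (`tmrna_curator.core`)
- **synthetic fixtures** — a fully seeded generator for genes of every form
  (standard, permuted, intron, CDS-less variants), targeted defect planting,
  tRNA decoys, and emulated tool-output files, so the entire pipeline is
  testable offline (`tmrna_curator.synth`)

## Command line

```sh
# generate a batch of clean synthetic records (flat-file dialect)
tmrna-curator synth --seed 5 --n 10 --out candidates.tsv

# run the curation funnel
tmrna-curator curate \
    --candidates candidates.tsv \
    --hits aragorn:hits.tsv --hits infernal_tblout:cm.tblout \
    --trna trnascan.tsv \
    --refs existing.tsv \
    --config thresholds.toml \
    --out accepted.tsv --report funnel.json

# dedup / naming utilities
tmrna-curator dedup --in accepted.tsv --out unique.tsv
tmrna-curator name --in unique.tsv --species-map species.tsv --out names.tsv
```

`--hits` takes `dialect:path` pairs; every rejection is logged to stderr
with its reason code and provenance. Thresholds (TOML) default to the
published cutoffs: strong-hit scores Aragorn >103 / Infernal >140 /
database-BLAST >90, tRNA rejection at >5 bp overlap by a tRNA scoring
>42 bits (with the permuted+strong exception), 250-bp flanks, and the
intron screen at ≥500 bp and ≥150 bits.

## Conventions

- In-memory coordinates are 0-based half-open; all serialized coordinates
  (flat file, hit tables, provenance strings) are 1-based inclusive.
- Sequences are compared case-insensitively with U folded onto T.
- The flat file is tab-separated with one row per unique sequence:
  id, form, species, sequence, segment boundaries, instance count, status,
  reject reasons, provenance list, JSON annotations. `read ∘ write` is the
  identity.
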