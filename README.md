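# chresonym

A toolkit for *contextual* taxonomic name-usage databases. Instead of
only cataloguing which scientific names appear in which publications, it
records the context of every use — a specimen, a geographic location, a
citation of an earlier usage, or no context at all — and uses those
contexts to work out which currently recognized species each author was
actually referring to.

The package provides:

- **Flat-file tables** (tab-delimited UTF-8, `.` for missing cells) for
  name-usage records, publications, spelling variants and accepted
  species, with lossless round-trip readers/writers and a JSON export
  (`chresonym.record_io`).
- **Name-key grammar**: each unique name in a publication gets an
  integer base key; multiple contextual uses get decimal suffixes
  (`3.1`, `3.2`). A citing record can address all contexts (`3`), one
  context (`3.1`), the publication in general (`0`), or a work not yet
  recorded (`.`). Keys are parsed as integer pairs, never floats, so
  `3.10` and `3.1` stay distinct (`chresonym.datamodel`).
- **Nomenclature utilities**: positional parsing of compound names
  (genus, subgenus, specific/subspecific epithets, qualifiers) and
  table-driven canonicalization of spelling, typographic and
  gender-agreement variants (`chresonym.nomenclature`).
- **The resolver** (`chresonym.resolver`): a single chronological pass
  that propagates accepted species through citation chains. For each
  compute-marked citation it pools the resolved species of all cited
  contexts and decides by unanimity, plurality, a spelling-variant
  match against the citing name, or first appearance — appending an
  "in part" flag whenever the cited contexts span more than one
  species. Editing one base record and re-running updates every
  downstream citation automatically.
- **Cross-reference indices** (`chresonym.crossref`): specific-name and
  binomial/compound-name indices, per-publication pages with
  name-citation "cited by" lists, and per-species pages whose
  publication lists are derived from resolved species rather than
  printed names.
- **Static site generation** (`chresonym.sitegen`): deterministic,
  wholly regenerated HTML with an internal link checker.
- **Synthetic data** (`chresonym.synthgen`): seeded literature networks
  with planted ground truth (species per record, expected citation
  resolutions, planted taxonomic splits that must surface as "in part"
  flags, registered misspellings), plus a brute-force fixed-point
  resolution oracle used to cross-check the single-pass resolver.

## Command line

```sh
chresonym synth --out data/ --seed 7            # generate a synthetic dataset
chresonym validate --data data/ [--strict]      # structural checks (TSV issue log)
chresonym resolve --data data/ --out resolved.tsv
chresonym crossref --data data/ --out xref.json
chresonym summarize --data data/
chresonym build-site --data data/ --out site/ --check-links
```

A dataset directory holds `usages.tsv`, `publications.tsv`,
`species.tsv` and `variants.tsv`; `chresonym synth` writes a valid one
(plus `ground_truth.json`) if you want an example of the layout. Exit
codes: 0 clean, 1 errors (warnings too under `--strict`), 2 usage
problems.

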