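# qsardb

A Python library and CLI for typed container/cargo archives holding QSAR
data sets and models. An archive bundles five kinds of containers —
Compounds, Properties, Descriptors, Models and Predictions — each carrying
document attachments ("cargos") such as SMILES structures, tab-separated
value tables, BibTeX databases, UCUM unit strings and PMML regression
models. Archives live either as plain directory trees or as `*.qdb.zip`
files; both use identical relative paths (`archive.xml`,
`compounds/compounds.xml`, `compounds/1/smiles`, ...).

Features:

- **schema** (`qsardb.schema`) — the container type system, registries with
  ordered id-unique members, strong-relationship enforcement
  (Property ← Model ← Prediction) and schema introspection.
- **storage** (`qsardb.storage`) — directory and ZIP backends with
  canonical, byte-reproducible serialization; unrecognized files are
  preserved verbatim as unofficial extensions.
- **codecs** (`qsardb.codecs`) — values/references TSV tables with
  normal/abnormal ("N/A") value semantics, BibTeX key resolution, BODO
  YAML records, UCUM unit strings, Chemical-MIME-derived structure cargo
  identifiers and qualified extension-identifier checks.
- **pmml** (`qsardb.pmml`) — a linear-regression PMML subset: strict
  writer, tolerant reader, registry-prefixed variable names
  (`properties/p1`, `descriptors/logp`) and per-compound evaluation that
  degrades missing/abnormal inputs to "N/A".
- **validation** (`qsardb.validation`) — CAS check-digit and standard-InChI
  checks plus ten archive-wide integrity rules (r1–r10) reported as
  findings, never exceptions.
- **conversion** (`qsardb.conversion`) — build archives from TSV/CSV tables
  via column mappings, optionally attaching a linear model and its training
  prediction from an equation such as `pLC50 = 1.2 + 0.5*logp`.
- **analytics** (`qsardb.analytics`) — on-demand goodness of fit (R²,
  RMSE, residuals = predicted − experimental), internal/external/mixed
  validation-set classification and boolean label queries
  (`train AND NOT outlier`).
- **synth** (`qsardb.synth`) — a deterministic synthetic-archive generator
  (checksum-correct CAS numbers, known linear model, optional noise) used
  throughout the tests.

## CLI

The `qdb` command groups thin wrappers over the library:

```sh
qdb synth demo --compounds 10 --sigma 0.1 --seed 1   # synthetic archive
qdb info demo                                        # container counts
qdb validate demo                                    # r1-r10 findings, exit 1 if any
qdb stats demo --prediction m1-training              # n / R^2 / RMSE
qdb predict demo --model m1 --id run2 --type validation
qdb query demo --expression "train AND NOT outlier"
qdb pack demo demo.qdb.zip && qdb unpack demo.qdb.zip demo2
qdb import --in table.tsv --map 0=id --map 1=cargo:smiles \
    --map 2=property:pLC50 --map 3=descriptor:logp \
    --equation "pLC50 = 1.2 + 0.5*logp" --out out.qdb.zip
qdb init empty --name "An empty archive"
```

Exit status: 0 success, 1 findings/content errors, 2 usage errors.

Mapping roles for `--map COL=ROLE[:ARG]`: `id`, `name`, `cas`, `inchi`,
`cargo:<format>`, `property:<id>`, `descriptor:<id>`, `refs:<id>`. `COL`
is a 0-based index or a header name; a header row is auto-detected (first
row non-numeric in a mapped values column) and can be forced with
`--header/--no-header`.

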