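# Mock genome spec file

`dastrack mock serve --spec genome.yaml` serves a synthetic genome
described by a YAML file. All keys are optional; missing keys fall back
to the built-in default genome (two chromosomes, four annotation
classes).

```yaml
seed: 42                      # RNG seed; identical seeds give identical genomes
title: my mock source         # advertised in the sources document
coordinate_system: MockAsm_1
segments:                     # [segment_id, length_bp]
  - [chr1, 1000000]
  - [chr2, 500000]
feature_classes:
  - type_id: gene             # DAS TYPE id
    count: 300                # features per segment
    min_len: 2000             # lengths are log-uniform on [min_len, max_len]
    max_len: 200000
    category: transcription   # optional DAS TYPE category
    method: simulation        # optional DAS METHOD
    stranded: true            # orientation uniform over +/- when true
    scored: false             # scores uniform in [0, 1] when true
    grouped_fraction: 0.0     # share of features given shared group ids
                              # in gene-like runs of 2-5 members
```

The generator consumes one RNG stream in a fixed order (per segment:
residues, then each class in declared order), so a fixed spec is fully
reproducible. Editing the spec (adding or reordering classes) shifts
later draws; cross-version stability is only promised for an unchanged
spec.
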