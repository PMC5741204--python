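# pathsense

Find short enzymatic routes that make a target compound detectable by a
genetically-encoded biosensor.

Many small molecules cannot be sensed directly by any known allosteric
transcription factor. `pathsense` searches for *sensing-enabling pathways*:
one- or two-step enzymatic transformations that convert a target compound
into a compound annotated as a transcription-factor effector. Compounds are
encoded as **molecular signatures** — multisets of canonical atom-environment
fragments at a configurable bond diameter (default 12) — and reactions as
**reaction signatures**, the signed difference of product and substrate
signatures. A query compound matches a reaction when it embeds the
signature's consumed fragments; adding the signature to the query yields a
putative product fragment multiset, which is accepted only if it resolves
exactly into known compounds. Lower diameters give coarser, more promiscuous
reaction rules. Candidate endpoints are annotated with hashed circular
fingerprints and Jaccard–Tanimoto similarity against the detectable-compound
registry.

## Knowledge bases

A knowledge base is a directory of UTF-8 tab-separated files:
`compounds.tsv` (id, structure, dialect, xrefs), `reactions.tsv`
(id, substrates — pipe-separated, primary first —, products, reversible,
xrefs), `detectables.tsv` (compound_id, effector, transcription_factors,
source) and `cofactors.tsv`. Structures may be InChI or SMILES; compounds
are normalized (aromatic form, charges neutralized, hydrogens implicit,
largest fragment kept, stereo retained) and deduplicated by canonical
structure key with cross-references merged.

Self-contained fixtures are bundled:

```bash
pathsense fixture cocaine   --out kb-cocaine    # esterase route to benzoate
pathsense fixture parathion --out kb-parathion  # PTE + monooxygenase routes
pathsense fixture random    --out kb-rnd --seed 1 --n-compounds 30
```

## Searching

```bash
pathsense search \
    --target "CCOP(=S)(OCC)Oc1ccc(cc1)[N+](=O)[O-]" \
    --kb kb-parathion --steps 2 \
    --out-pathways pathways.tsv --out-gml graph.gml --verbose
```

The target may be a knowledge-base compound id, an InChI or a SMILES. The
search writes a pathway table (TSV, one row per pathway step) and the whole
expansion graph as Graph Markup Language (GML). Finding zero pathways is a
successful run with an empty result; only unresolvable targets exit
non-zero. Other commands: `pathsense build-kb` (validate + cache a KB
directory, emit a rejection report), `pathsense encode` (print a compound's
signature and fingerprint).

Key options: `--diameter` (signature specificity), `--steps {1,2}`,
`--threshold` (detectable similarity cut-off, default 1.0 = exact match),
`--bidirectional/--forward-only` (reversible reaction handling), and
`--config FILE` for a `key: value` config overridden by flags.

## Layout

| module | contents |
| --- | --- |
| `pathsense.chemstruct` | structure parsing, normalization, canonical keys |
| `pathsense.signatures` | atomic/molecular/reaction signatures |
| `pathsense.oracle` | brute-force reference implementations for testing |
| `pathsense.matching` | embedding, signature application, product resolution |
| `pathsense.knowledgebase` | tabular registries, fragment index, caching |
| `pathsense.fixtures` | packaged and random fixture knowledge bases |
| `pathsense.pathways` | graph expansion, pathway extraction, GML/TSV export |
| `pathsense.similarity` | hashed fingerprints, Tanimoto, similarity tables |
| `pathsense.cli` | `pathsense` command-line entry point |
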