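# biotagger

Dictionary-based biomedical named entity recognition (NER) with
identifier normalization, usable as a Python library, a command-line
batch tagger, and a queue-managed asynchronous annotation web service.

It is built for people who need to find mentions of **genes, chemicals,
organisms, subcellular structures, tissues/organs, and diseases** in
titles and abstracts, and need each mention *grounded* to a database
identifier (a STRING-style locus id, a PubChem CID, an NCBI taxon id, a
GO/BTO/DOID term) rather than just highlighted. Matching is an
exhaustive lookup of a curated name→entity lexicon, so the tagger is
deterministic, auditable row by row, and fast: work per document is
O(tokens × longest-name-token-count) hash probes, independent of how
many names the dictionary holds.

Two ideas carry the design:

1. **Canonical-key matching.** A name and a text span match when they
   share a canonical key — full case-fold, with every run of whitespace,
   hyphens/dashes, underscores and slashes collapsed to one space. So
   `NF-kappa B`, `nf kappa  b` and `NF_KAPPA-B` all meet at the key
   `nf kappa b`. Matches respect token boundaries, overlaps resolve
   leftmost-longest, and an ambiguous name reports *all* of its
   identifiers.
2. **Staged queues with admission control.** The server moves each
   request through parse → download → tag → deliver stages, each with
   its own bounded worker pool, so many document fetches run in parallel
   while CPU-heavy tagging stays capped and status queries answer from a
   dedicated fast lane. Clients exceeding per-IP request or memory
   budgets are rejected up front with an HTTP 429/503.

The service speaks an asynchronous annotation protocol: a
`getAnnotations` request names documents by identifier and `source`; the
server fetches their text from the source's document server, tags it,
and POSTs the results to a callback URL. Both routes are configurable
per request (`custom_parameters.servers` and `custom_parameters.apiurl`),
never hardwired. Gene/protein mentions are annotated as `GENE`;
`PROTEIN` is rejected explicitly, because the gene lexicon is
locus-based and includes ncRNAs.

## Worked example

No downloads are needed: the `fixtures` subcommand emits a synthetic
dictionary and a corpus with entities planted at known offsets.

```sh
biotagger fixtures --seed 7 --out demo
biotagger tag --entities demo/entities.tsv --names demo/names.tsv \
              --documents demo/corpus.tsv | head -6
```

prints (one TSV row per annotation):

```
SYN7-0000	T	15	23	jkk-bjcf	TISSUE_AND_ORGAN	BTO:0000043
SYN7-0000	A	37	41	Ccac	CHEMICAL	CID000000018
SYN7-0000	A	65	69	ccac	CHEMICAL	CID000000018
SYN7-0000	A	78	85	addeamb	ORGANISM	10022
SYN7-0000	A	112	128	ICII HMC AMMCCCH	ORGANISM	10021
SYN7-0001	T	27	31	LKHH	TISSUE_AND_ORGAN	BTO:0000042;BTO:0000044
```

Columns: document id; section (`T` title, `A` abstract); 0-based
half-open character offsets into that section; the matched text exactly
as it appears; the entity type; and the `;`-joined database identifiers.
Note the normalization at work: `Ccac` and `ccac` are different spellings
of the same chemical and both ground to `CID000000018`, while `LKHH` is
an ambiguous tissue name and honestly reports both of its BTO
identifiers. On this strict-mode fixture the output equals the
generator's ground truth (`demo/ground_truth.tsv`) byte for byte.

The same lexicon files drive the server:

```sh
biotagger serve --entities demo/entities.tsv --names demo/names.tsv
```

which loads the dictionary into memory once, then opens the port and
answers `getStatus` immediately even while large batches tag. The
library API mirrors the CLI: `load_dictionary(...)` + `tag(doc, d)`
return `Annotation` objects with the same fields as the TSV rows.

Dictionary files are headerless TSV — entities
(`serial, type_code, identifier`), names (`serial, surface`), optional
blocked names — shape-compatible with publicly distributed tagger
dictionaries, so a production lexicon drops in unchanged.

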