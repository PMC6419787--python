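# Methods

## The problem

Dictionary-based named entity recognition (NER) locates mentions of
biomedical entities — genes, chemicals, organisms, subcellular
structures, tissues and organs, diseases — as character spans in text
and *normalizes* each mention to a database or ontology identifier
(STRING-style locus identifiers, PubChem compound ids, NCBI taxon ids,
GO/BTO/DOID terms). Unlike learned taggers, the method is an exhaustive
lookup of a curated name→entity lexicon, which makes it fast enough for
real-time services and large corpora, and makes every annotation
traceable to a dictionary row.

The package has two halves: the matching engine (`dictionary`, `text`,
`ner`) and a web service (`service`, `http_intake`, `protocol`) that
exposes the engine through an asynchronous annotation protocol in which
document text is fetched by identifier from document servers and results
are pushed to a callback URL.

## Entity model

Six entity types are supported. Gene/protein mentions are annotated as
`GENE`, never `PROTEIN`: the gene lexicon is locus-based (no splice
isoforms) and also contains ncRNAs, so a gene/protein distinction cannot
be made honestly at the dictionary level. Requests asking for `PROTEIN`
are rejected with an explicit unsupported-type error rather than being
silently remapped.

Internally an entity is `(serial, type_code, identifier)`. A positive
`type_code` is an NCBI taxon id naming the organism whose gene namespace
the entity belongs to (and maps to `GENE`); the non-gene classes use
fixed negative codes (`-1` CHEMICAL, `-2` ORGANISM, `-22`
SUBCELLULAR_STRUCTURE, `-25` TISSUE_AND_ORGAN, `-26` DISEASE), chosen to
match the conventions of publicly distributed tagger dictionaries so
those files remain a drop-in input. One surface name may map to several
serials; this ambiguity is preserved through to the output (an
annotation carries *every* identifier sharing the matched key).

## Matching

**Canonical keys.** Flexible matching is defined as equality of
canonical keys: full Unicode case-fold, then every maximal run of
separator characters (whitespace plus the hyphen class `- ‐ ‑ ‒ – — _ /`)
collapses to one space, with leading/trailing separators stripped. All
other characters (periods, apostrophes, digits, Greek letters) are
preserved. This captures case/hyphen/spacing variation — `NF-kappa B`,
`nf kappa  b` and `NF_KAPPA-B` share one key — without any fuzzy
matching whose behavior would be hard to reason about.

**Tokenization** splits on the same separator class and keeps exact
offsets, so token text never contains separators. That yields the
identity the fast path relies on: the canonical key of any token window
equals its case-folded tokens joined by single spaces (a property test
asserts this over arbitrary text). Matches must start and end on token
boundaries; `aspirin` inside `aspirinic` never matches.

**Lookup.** For each section the engine considers every window of
1..`max_key_tokens` tokens (`max_key_tokens` = token count of the
longest dictionary name, typically ≤ 5), builds the window key
incrementally, and probes the hash index. Work per document is
O(tokens × max_key_tokens) hash lookups — independent of the number of
names in the dictionary, which is the property that lets the same code
serve a millions-of-names lexicon and a reduced one at the same speed.
The dictionary is immutable after load and `tag()` is a pure function,
so one preloaded dictionary serves any number of threads with no
locking.

**Short-name guard.** Canonical keys shorter than `min_key_length`
(default 2 characters) match only when the source span equals one of the
dictionary's exact surface spellings for that key. Case-folding
one-letter symbols otherwise produces rampant false positives. The
threshold is configuration (`MatchConfig`), not a constant.

**Overlap resolution** is leftmost-longest per section: candidates are
ordered by (start, −length) and accepted greedily if they do not overlap
an accepted span. When several entity types share the winning span, one
annotation per type is emitted, each listing all of its type's
identifiers. Output is sorted by (section with title first, start).

**Blocked names.** An optional stopword file lists surfaces that are
never reported; they are canonicalized at load and filtered at candidate
stage. Default is an empty set.

**The oracle.** `oracle_tag()` is a deliberately naive reference: for
every dictionary key it slides a window of the key's width over the
tokens and compares `canonicalize(span)` to the key, then applies its own
copy of the resolution rule. It shares no lookup machinery with `tag()`
and is O(names × text), so it is only used on small inputs — but on
those it is ground truth, and the suite asserts element-wise equality
over hundreds of randomized dictionary/document pairs.

## Service architecture

**Staged queues.** A request is a task moving through ordered stages,
each with its own FIFO queue and fixed worker pool: `parse(2)` →
`status(2)` → `download(8)` → `tag(2)` → `deliver(4)` (workers
configurable via INI). Downloads are I/O-bound, so many run in parallel;
tagging is the CPU-heavy part and is capped low; status queries live in
a dedicated fast stage so they are never queued behind tagging work.
Tasks may skip stages but never move backward; a handler advancing
backward is a programming error that fails the task.

**Admission control** runs before a task exists: a client (source IP, or
a configurable header when behind a proxy) exceeding its simultaneous-
request count or memory budget is answered `429`, and a full entry queue
answers `503` (both codes configurable). Memory is accounted as request
body bytes plus a per-document estimate (default 10 KiB/document) added
when the parse stage learns the document count — an estimate, not a
measurement; the budget is a blunt overload guard, not an allocator.
Accounting is released exactly once when the task reaches `done` or
`failed`.

**Supervision.** Worker threads catch handler exceptions (task → failed,
client gets an error status, pool unaffected). A worker that dies
entirely is detected by a supervisor thread polling at 20 ms, the task
it held is failed with its accounting released, and a replacement thread
is started, restoring the configured pool size.

**Intake.** One event loop built on `selectors` owns the listening
socket and all connections: bytes accumulate per connection and the
application callback fires only when a complete HTTP request (headers +
`Content-Length` body) has arrived, so half-received requests never
create tasks; a connection closing early is discarded silently.
Responses produced on worker threads are handed back to the same loop
through a wake-up socket pair. The loop speaks a deliberate HTTP subset:
one request per connection, no chunked bodies — all the protocol needs.

## Protocol

JSON-over-POST with a `method` field. `getStatus` answers synchronously
from the fast stage. `getAnnotations` is acknowledged as soon as it
parses, then proceeds asynchronously: documents are fetched by id from
their `source`'s server (one POST per batch of 100 ids, configurable),
tagged, and delivered as a single callback POST. Two routing extensions
avoid hardwired endpoints: `custom_parameters.servers` maps source names
to document-server URLs per request (falling back to configured
defaults, never to built-in constants), and `custom_parameters.apiurl`
names the callback target. Callback delivery retries 3 times with
doubling backoff starting at 1 s (configurable).

Per-document fetch failures do not abort a batch: the affected documents
appear in the payload with `fetch_failed: true` and empty annotation
lists (partial delivery, flagged, rather than all-or-nothing). An
unresolvable source fails the whole request, and that failure is itself
reported to the callback with `state: "failed"`. The exact wire schema
is this package's own documented dialect (the upstream protocol bodies
vary); offsets are 0-based half-open by default with an
`inclusive_end` switch for dialects that want closed intervals.

## Synthetic data

`fixtures` generates everything tests need, from one `random.Random`
seeded per call — identical specs give byte-identical files. Dictionary
names are 1–3 tokens over the alphabet `a–m` with deliberate
case/hyphen/underscore variants and a configurable fraction of names
shared between two same-type serials (exercising ambiguity). Corpora are
decoy tokens with dictionary surfaces planted at recorded offsets; the
ground truth lists each planted span with the exact identifiers the
engine must report. In strict mode (the default) decoys draw on the
disjoint alphabet `n–z`, so no decoy window can canonicalize to a
dictionary key and the engine's output on such a corpus provably equals
the ground truth — which the suite asserts exactly.

What the generator does *not* emulate: real biomedical word statistics,
names whose canonical keys collide across types, non-Latin scripts, or
adversarial near-miss spellings. Passing strict-mode exactness therefore
demonstrates engine correctness (offsets, resolution, normalization),
not corpus-level precision/recall on real literature, which depends
entirely on dictionary quality.

## Problem sizes and numerical choices

The default verification sizes are: 200 randomized dictionary/document
pairs for engine/oracle agreement (≤ ~100 entities, ≤ 2,000-character
documents each); a seed-7 strict corpus of 60 entities and 20 documents
for exactness; a 100-document corpus timed against a ~1,000-name subset
versus the full ~108,000-name lexicon (3 repeats per document, median of
per-document minima, asserted as a ratio ≤ 2 rather than an absolute
time); a 500-task storm for queue caps; and a 1,000-document batch for
the responsiveness ordering check, with the mock document server
stalling each batch fetch by 50 ms so the batch is observably in flight
when the status query lands.

Determinism choices worth knowing: identifier lists within an annotation
are ordered by serial; annotations sort title-before-abstract, then by
start offset, then type label; dictionary writes emit rows in canonical
sort order so a written dictionary is byte-stable under rewrite.

## Limitations

- Matching is exact on canonical keys: no spelling correction, no
  morphological variants beyond the separator/case rules.
- One process, threads only; the GIL bounds tagging throughput — the cap
  on concurrent tag workers manages latency and memory, not total
  CPU parallelism.
- The intake loop's HTTP subset (no keep-alive, no chunked transfer) is
  adequate for the protocol but not a general web server.
- Document caching is deliberately absent: fetch time dominates
  end-to-end latency by design of the surrounding protocol, and callers
  who control the documents should run the tagger locally via the CLI.
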