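# Methods

This note records the model behind `orthoprop`, the choices made where
the design was genuinely open, and what the synthetic test bed does and
does not establish about real data.

## Orthology model

Orthologs are operationalized as bidirectional best hits (BBH) over the
two proteomes. "Best" is the minimal E-value per query; equality is
tested on the parsed floating-point values with no epsilon, because
alignment tools print coarse E-values and exact ties are real — exact
gene duplications produce identical scores, and retaining all ties is
part of the method (a source protein may legitimately have several
target orthologs, e.g. both copies of a recent duplication). The
E-value cutoff (default `1e-3`) is strict (`<`). Paralogs are not
computed, and genes without protein products (RNA genes) never enter the
search.

Two hit backends exist behind one interface:

* **tabular** — any aligner emitting the common 12-column tabular format
  (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
  evalue bitscore). Multiple HSPs per (query, subject) are reduced to
  the row with minimal E-value, ties broken by maximal bitscore. This is
  the fidelity path for real proteomes.
* **builtin** — all-vs-all Smith–Waterman (Biopython `PairwiseAligner`,
  local mode, BLOSUM62, gap open 11 / extend 1), with raw scores mapped
  to E-values via the Karlin–Altschul form `E = K·m·n·exp(−λS)` using
  the standard gapped BLOSUM62 parameters `λ = 0.267`, `K = 0.041`,
  where `m` is the query length and `n` the total residue count of the
  searched proteome. Because the raw score is symmetric, the two
  directions are computed in a single pass and differ only in `(m, n)`.
  This backend promises the same *ranking* as a production aligner, not
  numerically identical E-values; it is intended for desk-scale
  proteomes (hundreds of proteins) and for fully self-contained tests.

The pair's P-value is defined as the arithmetic mean of its two
E-values and is consumed only by the P-value filter.

## Disambiguation

When a target gene T maps to several source candidates the resolver
applies synteny first: candidate S passes if the product of either gene
directly adjacent to S (in its replicon's `gene_order`; circular
replicons wrap, linear ends yield one neighbour, strand is ignored,
productless neighbours are skipped) is an ortholog of the product of
either gene directly adjacent to T. Exactly one syntenic candidate
wins. Only when *no* candidate is syntenic are gene names consulted:
exactly one candidate whose primary gene name equals T's (exact,
case-sensitive; synonyms deliberately ignored as too noisy) wins.
Every other outcome rejects T.

Open choices resolved here:

* **Two syntenic candidates reject** rather than falling through to
  names. Names are defined as a fallback for the zero-synteny case
  only, and a multi-way synteny pass offers no principled
  discriminator; rejection is the conservative reading of a method
  whose stated bias is to not propagate rather than risk overwriting.
* **A nameless target cannot be name-resolved** (vacuously zero
  matches → rejection).
* Adjacency is computed from `gene_order`, not coordinates, so
  overlapping genes still have a defined order; genes on different
  replicons are never adjacent. Only the ±1-gene neighbourhood is
  examined — no global synteny blocks.

## Quality filters

All five filters are evaluated for every resolved pair, even after an
early failure, so single- vs multi-filter failure statistics are exact.

1. *Target evidence*: T's gene, product and GO annotations must carry no
   experimental or literature-based evidence code. The scan scope is
   configurable (complexes containing the product can be included, off
   by default: uncurated targets rarely have complexes).
2. *Source evidence*: the same scan on S must find at least one
   experimental or literature code.
3. *P-value*: `p ≤ threshold` passes (default `1e-10`; "must not
   exceed" makes the boundary inclusive).
4. *Length*: `|len_S − len_T| / max(len_S, len_T) ≤ threshold` passes
   (default 0.10). The denominator is the *longer* sequence — the
   symmetric, conservative choice (it flags slightly more pairs than a
   min-denominator would).
5. *Complex*: for every heteromultimeric complex containing S —
   membership flattened through sub-complexes — each other protein
   component must have at least one ortholog pair; any RNA or otherwise
   unproduced component fails the test outright, since RNA is excluded
   from orthology. This is why ribosomal proteins never propagate; no
   RNA workaround is attempted.

The evidence-code inventory ships as data: the GO experimental set
(EXP, IDA, IPI, IMP, IGI, IEP, HTP, HDA, HMP, HGI, HEP), the literature
set (TAS, IC, NAS), and BioCyc-style prefixes (`EV-EXP*` experimental,
`EV-AS*` literature, `EV-COMP*` computational). Unknown codes are
treated as computational and logged once per code. The classification
named by the method is a class pair ("experimental or literature-based"
vs everything else); the exact inventory is this package's documented,
overridable choice.

## Propagation semantics

* **Names.** T's gene name becomes S's; T's prior name, when present
  and different, is demoted to a synonym (never discarded); S's
  synonyms are unioned in; the primary name is never duplicated in the
  synonym list. The product name/synonyms follow the same scheme.
* **GO.** Source terms with *experimental* evidence codes propagate;
  if the two sequences are identical (exact string equality after
  uppercasing and stop stripping) all source terms propagate. Every
  propagated term is added with evidence code `ISO` and a reference to
  the source protein; terms the target already holds are deduplicated
  by GO id. Note the asymmetry with filter 2: gene-level eligibility
  accepts experimental *or* literature evidence, but term-level GO
  propagation requires experimental evidence — both scopes are as the
  method defines them.
* **Reactions.** Full replacement, not union: the target's reaction set
  becomes exactly the source's. Replacement is required because
  spurious target assignments must be *removable* (a regulator wrongly
  assigned a transport reaction loses it) as well as extendable (an
  enzyme's secondary activities are added). Reaction records missing
  from the target database are created from the source's.
* **Complexes.** Each heteromultimeric complex of S is instantiated in
  the target with components mapped through the ortholog map
  (stoichiometry preserved) and the complex's reactions copied.
  Creation is idempotent: an existing target complex with the same
  mapped component multiset is reused. When a source component has
  several target orthologs, a target that *resolved* to that source is
  preferred, remaining ties break on the smallest id — deterministic by
  construction. Complexes carry the source complex's name (a package
  choice; the alternative of leaving them nameless loses information).
* **Provenance.** Every propagated gene gets a structured history
  record (source gene, fields changed, prior values, optional
  timestamp); a renderer (`format_history_note`) produces the
  human-readable note. Records with no changed fields are still
  produced, flagged no-op. Textual summaries are never copied — they
  are often strain-specific — but the source gene id is stored on the
  target gene so a display layer can show the source summary alongside.
  An attribute is only recorded as propagated when its serialized value
  actually changed.

The run orchestrator validates both databases before touching anything,
mutates a copy of the target, and never modifies the source. Timestamps
default to absent so identical runs produce byte-identical outputs; a
real timestamp can be recorded via configuration. Pathway re-inference
after propagation is out of scope; the propagated reaction complement is
the intended input for an external pathway predictor run afterwards.

## PGDB-lite format

The native exchange format is a single canonical JSON document per
database (schema in `src/orthoprop/data/pgdb_lite_schema.json`):
replicons with explicit `gene_order`, 1-based inclusive gene
coordinates, proteins with sequences over the 20-letter alphabet plus X,
GO annotations with evidence codes, reactions, complexes (components may
be proteins, sub-complexes, or RNA gene ids), and embedded propagation
records. Serialization sorts keys and record lists and omits empty
optional fields, so write∘read is the identity and equal databases give
byte-identical files. Validation is structural and collects every
violation with the offending record id. GenBank/GFF import is a
non-goal; proteome sequences can also be read from FASTA (uppercased,
terminal `*` stripped).

## Synthetic test bed

`synthgen` generates a curated source genome (one circular replicon,
names, specific product names, experimental GO, reactions,
heteromultimeric complexes, optionally with an RNA component) and a
target derived by seeded events: per-residue substitutions, per-gene
indels (geometric lengths), gene loss, target-side duplication (exact
copies — truth maps both copies to one source gene), *decoy*
duplication (an exact copy planted in the source, optionally with the
target copy relocated, which is what produces genuinely ambiguous
multi-candidate targets), and block inversions. Curation stripping then
removes all GO and evidence from the target, drops gene names and
degrades product names to vague/unknown boilerplate with probability
`name_dropout`, and replaces reaction sets with decoy reactions at rate
`spurious_reaction_rate`.

Default parameters model a mildly diverged same-species strain pair at
desk scale: 120 genes, 2% substitution per residue, 10% indel
probability (mean length 4), 5% loss, 2% duplication and decoy
duplication, two inversions, 50% name dropout (many real annotation
pipelines omit gene names entirely), 10% spurious reactions, and four
complexes including one RNA-containing three-member complex
(ribosome-like). `experimental_evidence_fraction` defaults to 1.0: the
generator models the *curated, propagation-eligible* subset of a source
database — in a real curated genome only a subset of genes carries
experimental evidence, and that regime is exercised explicitly by
lowering the fraction.

`generate_pair_with_expected_outcomes` replays the propagation rules
analytically over the event log and genome structures — candidate sets
from exact sequence-group identity, synteny from `gene_order`, name
matching, and the evidence/length/complex filters from the truth map —
without importing any pipeline module. It is the independent end-to-end
oracle: on every generated pair the pipeline's per-gene decisions must
match it exactly. Two predictions are by construction rather than
computation: the generator's divergence levels keep true-ortholog
E-values so far below both the BBH cutoff and the P-value threshold
that the replay asserts those tests pass (random-sequence hits cannot
become BBH pairs because reciprocity always prefers the true
descendant). To keep that construction sound, deletions never cut a
protein below 50 retained residues — the generator models indels within
recognizable orthologs, not pseudogenization — so length-filter
failures come from large insertions and large-but-bounded deletions.
The assertion holds for substitution rates up to roughly 15% at the
default lengths; the generator is not meant to be driven into the
twilight zone.

What passing these tests does *not* show: performance of the built-in
aligner's E-values against a production aligner's (only rank behaviour
is promised), behaviour on real annotation noise (truncated genes,
frameshifts, contaminant proteins), multi-replicon genomes with
plasmid-borne duplications, or curation conflicts on partially curated
targets beyond the evidence-code mechanism.

## Numerical and degenerate-input choices

* E-value tie comparison is exact float equality; the built-in backend
  guarantees identical floats for identical sequences because both
  directions share one score computation.
* `math.exp` underflow to 0.0 in the Karlin–Altschul map is harmless:
  ties remain exact and comparisons remain consistent.
* Length filter with two empty sequences passes vacuously (sequences
  are validated non-empty upstream).
* A replicon with a single gene has no neighbours; a two-gene circular
  replicon's duplicate neighbour is deduplicated.
* Degenerate specs (complex larger than the genome, rates outside
  [0, 1]) are rejected before generation.
* All randomness in the generator flows through one integer seed
  (`numpy` PCG64); identical specs give byte-identical databases.

## Problem sizes

The shipped tests and the acceptance script run at desk scale — 100
random ≤50-protein hit-table pairs for the BBH oracle, 20 evolved
strain pairs of 30–60 genes for the end-to-end oracle, 120-gene pairs
for the headline run — sizes chosen so the whole suite completes in
well under a minute of alignment time while still exercising every
event type the generator models.
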