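"""Domain model for annotated genome databases ("PGDB-lite") and its I/O.

A PGDB (Pathway/Genome Database) bundles a genome — replicons carrying
genes — with the proteins those genes encode, the reactions the proteins
catalyze, heteromultimeric protein complexes, GO annotations, and the
evidence codes that say *how* each piece of annotation was established.
This module defines the in-memory types, a canonical JSON exchange format
(PGDB-lite), a FASTA proteome reader, and the evidence-code classifier
used by the propagation quality filters.

Coordinates are 1-based inclusive (GenBank convention).  Gene adjacency is
always taken from a replicon's explicit ``gene_order``, never recomputed
from raw coordinates, so overlapping genes still have a defined order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO

logger = logging.getLogger("orthoprop")

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWYX")

# ---------------------------------------------------------------------------
# Evidence codes
# ---------------------------------------------------------------------------

#: GO evidence codes established by direct experiment.
GO_EXPERIMENTAL_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "HTP", "HDA", "HMP", "HGI", "HEP"}
)
#: GO codes asserted from the literature by a curator.
GO_LITERATURE_CODES = frozenset({"TAS", "IC", "NAS"})

CLASS_EXPERIMENTAL = "experimental"
CLASS_LITERATURE = "literature"
CLASS_COMPUTATIONAL = "computational"

_unknown_codes_seen: set[str] = set()


def evidence_code_class(code: str) -> str:
    """Classify a single evidence code as experimental / literature / computational.

    GO three-letter codes are matched against a fixed table; BioCyc-style
    codes map by prefix (``EV-EXP*`` experimental, ``EV-AS*`` literature,
    ``EV-COMP*`` computational).  Unknown codes are treated as
    computational and logged once per distinct code.
    """
    c = code.upper()
    if c in GO_EXPERIMENTAL_CODES:
        return CLASS_EXPERIMENTAL
    if c in GO_LITERATURE_CODES:
        return CLASS_LITERATURE
    if c.startswith("EV-EXP"):
        return CLASS_EXPERIMENTAL
    if c.startswith("EV-AS"):
        return CLASS_LITERATURE
    if c.startswith("EV-COMP") or c in {"IEA", "ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "RCA", "ND"}:
        return CLASS_COMPUTATIONAL
    if c not in _unknown_codes_seen:
        _unknown_codes_seen.add(c)
        logger.warning("unknown evidence code %r treated as computational", code)
    return CLASS_COMPUTATIONAL


# Aggregate classes returned by evidence_class_of().
EXPERIMENTAL_OR_LITERATURE = "experimental-or-literature"
COMPUTATIONAL_ONLY = "computational-only"
NO_EVIDENCE = "none"


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class PGDBError(Exception):
    """Base class for PGDB-lite problems."""


class PGDBParseError(PGDBError):
    """The file is not well-formed PGDB-lite JSON."""


class PGDBValidationError(PGDBError):
    """Structurally valid JSON that violates the model's invariants.

    ``problems`` lists one human-readable message per violation, each
    naming the offending record id.
    """

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Replicon:
    id: str
    topology: str  # "linear" | "circular"
    gene_order: list[str] = field(default_factory=list)


@dataclass
class Gene:
    id: str
    replicon: str
    start: int
    end: int
    strand: str  # "+" | "-"
    name: Optional[str] = None
    synonyms: set[str] = field(default_factory=set)
    product: Optional[str] = None  # protein id; RNA genes have none
    evidence: set[str] = field(default_factory=set)
    propagated_from: Optional[str] = None  # source gene id, set by propagation


@dataclass
class GOAnnotation:
    term: str
    evidence_code: str
    with_ref: Optional[str] = None

    def key(self) -> str:
        return self.term


@dataclass
class Protein:
    id: str
    gene: str
    sequence: str
    name: Optional[str] = None
    synonyms: set[str] = field(default_factory=set)
    go_annotations: list[GOAnnotation] = field(default_factory=list)
    reactions: set[str] = field(default_factory=set)
    evidence: set[str] = field(default_factory=set)


@dataclass
class Complex:
    """A protein complex; components may be proteins, sub-complexes, or
    (for e.g. the ribosome) RNA genes referenced by gene id."""

    id: str
    components: dict[str, int] = field(default_factory=dict)  # id -> stoichiometry
    reactions: set[str] = field(default_factory=set)
    name: Optional[str] = None
    # Derived during linking:
    heteromultimeric: bool = False
    contains_rna: bool = False


@dataclass
class Reaction:
    id: str
    ec_number: Optional[str] = None
    name: Optional[str] = None


@dataclass
class PropagationRecord:
    """Provenance ledger for one propagated target gene (the history note's
    data): which fields changed and what their prior values were."""

    target_gene: str
    source_gene: str
    changed_fields: list[str] = field(default_factory=list)
    prior_values: dict[str, object] = field(default_factory=dict)
    timestamp: Optional[str] = None

    @property
    def no_op(self) -> bool:
        return not self.changed_fields


@dataclass
class PGDB:
    id: str
    replicons: dict[str, Replicon] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    proteins: dict[str, Protein] = field(default_factory=dict)
    complexes: dict[str, Complex] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)
    propagation_records: list[PropagationRecord] = field(default_factory=list)

    # -- convenience -------------------------------------------------------

    def protein_of_gene(self, gene_id: str) -> Optional[Protein]:
        g = self.genes[gene_id]
        return self.proteins[g.product] if g.product else None

    def protein_coding_genes(self) -> list[Gene]:
        return [g for g in sorted(self.genes.values(), key=lambda g: g.id) if g.product]

    def complexes_containing(self, protein_id: str) -> list[Complex]:
        """All complexes whose *flattened* component set includes the protein."""
        out = []
        for cx in sorted(self.complexes.values(), key=lambda c: c.id):
            if protein_id in flatten_complex(cx, self):
                out.append(cx)
        return out


def flatten_complex(cx: Complex, db: PGDB) -> dict[str, int]:
    """Expand sub-complexes to a flat multiset of leaf component ids
    (protein ids and RNA gene ids) with total stoichiometry."""
    flat: dict[str, int] = {}

    def walk(cid: str, mult: int) -> None:
        if cid in db.complexes:
            for sub_id, n in db.complexes[cid].components.items():
                walk(sub_id, mult * n)
        else:
            flat[cid] = flat.get(cid, 0) + mult

    for comp_id, n in cx.components.items():
        walk(comp_id, n)
    return flat


# ---------------------------------------------------------------------------
# Linking & validation
# ---------------------------------------------------------------------------


def link_and_validate(db: PGDB) -> PGDB:
    """Resolve cross-references, derive complex flags, and enforce the
    model invariants.  Raises :class:`PGDBValidationError` listing every
    violation found, each naming the offending record."""
    problems: list[str] = []

    gene_replicon_listed: dict[str, str] = {}
    for rep in db.replicons.values():
        if rep.topology not in ("linear", "circular"):
            problems.append(f"replicon {rep.id}: topology {rep.topology!r} not linear/circular")
        seen: set[str] = set()
        for gid in rep.gene_order:
            if gid in seen:
                problems.append(f"replicon {rep.id}: gene {gid} listed twice in gene_order")
            seen.add(gid)
            if gid not in db.genes:
                problems.append(f"replicon {rep.id}: gene_order references missing gene {gid}")
            else:
                gene_replicon_listed[gid] = rep.id

    product_owner: dict[str, str] = {}
    for gene in db.genes.values():
        if gene.replicon not in db.replicons:
            problems.append(f"gene {gene.id}: unknown replicon {gene.replicon}")
        elif gene_replicon_listed.get(gene.id) != gene.replicon:
            problems.append(f"gene {gene.id}: not listed in gene_order of replicon {gene.replicon}")
        if gene.start > gene.end:
            problems.append(f"gene {gene.id}: start {gene.start} > end {gene.end}")
        if gene.strand not in ("+", "-"):
            problems.append(f"gene {gene.id}: strand {gene.strand!r} not +/-")
        if gene.name is not None and gene.name in gene.synonyms:
            problems.append(f"gene {gene.id}: name {gene.name!r} duplicated in synonyms")
        if gene.product is not None:
            if gene.product not in db.proteins:
                problems.append(f"gene {gene.id}: product references missing protein {gene.product}")
            elif gene.product in product_owner:
                problems.append(
                    f"protein {gene.product}: claimed by both gene "
                    f"{product_owner[gene.product]} and gene {gene.id}"
                )
            else:
                product_owner[gene.product] = gene.id

    for prot in db.proteins.values():
        if prot.gene not in db.genes:
            problems.append(f"protein {prot.id}: references missing gene {prot.gene}")
        elif db.genes[prot.gene].product != prot.id:
            problems.append(f"protein {prot.id}: gene {prot.gene} does not list it as product")
        if not prot.sequence:
            problems.append(f"protein {prot.id}: empty sequence")
        else:
            bad = set(prot.sequence) - AMINO_ACIDS
            if bad:
                problems.append(
                    f"protein {prot.id}: illegal sequence characters {sorted(bad)}"
                )
        if prot.name is not None and prot.name in prot.synonyms:
            problems.append(f"protein {prot.id}: name {prot.name!r} duplicated in synonyms")
        for ann in prot.go_annotations:
            if not _is_go_id(ann.term):
                problems.append(f"protein {prot.id}: malformed GO id {ann.term!r}")
        for rxn in prot.reactions:
            if rxn not in db.reactions:
                problems.append(f"protein {prot.id}: unknown reaction {rxn}")

    # Complexes: component resolution, acyclicity, derived flags.
    for cx in db.complexes.values():
        for comp_id in cx.components:
            if comp_id not in db.proteins and comp_id not in db.complexes and comp_id not in db.genes:
                problems.append(f"complex {cx.id}: unresolvable component {comp_id}")
            elif comp_id in db.genes and db.genes[comp_id].product is not None:
                problems.append(
                    f"complex {cx.id}: component {comp_id} is a protein-coding gene; "
                    "reference its protein instead"
                )
        for rxn in cx.reactions:
            if rxn not in db.reactions:
                problems.append(f"complex {cx.id}: unknown reaction {rxn}")
    cycle = _find_complex_cycle(db)
    if cycle:
        problems.append(f"complex {cycle}: component graph is cyclic")

    if problems:
        raise PGDBValidationError(problems)

    for cx in db.complexes.values():
        flat = flatten_complex(cx, db)
        cx.heteromultimeric = len(flat) >= 2
        cx.contains_rna = any(cid in db.genes for cid in flat)
    return db


def _find_complex_cycle(db: PGDB) -> Optional[str]:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {cid: WHITE for cid in db.complexes}

    def visit(cid: str) -> Optional[str]:
        color[cid] = GRAY
        for sub in db.complexes[cid].components:
            if sub in db.complexes:
                if color[sub] == GRAY:
                    return sub
                if color[sub] == WHITE:
                    found = visit(sub)
                    if found:
                        return found
        color[cid] = BLACK
        return None

    for cid in sorted(color):
        if color[cid] == WHITE:
            found = visit(cid)
            if found:
                return found
    return None


def _is_go_id(term: str) -> bool:
    return (
        len(term) == 10
        and term.startswith("GO:")
        and term[3:].isdigit()
    )


# ---------------------------------------------------------------------------
# PGDB-lite JSON serialization
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def _opt(d: dict, key: str, value) -> None:
    """Store only meaningful values: canonical files omit empty optionals."""
    if value is None:
        return
    if isinstance(value, (list, dict, set)) and not value:
        return
    d[key] = value


def pgdb_to_dict(db: PGDB) -> dict:
    out: dict[str, object] = {"format": "pgdb-lite", "version": _FORMAT_VERSION, "id": db.id}
    _opt(out, "provenance", db.provenance)
    out["replicons"] = [
        {"id": r.id, "topology": r.topology, "gene_order": list(r.gene_order)}
        for r in sorted(db.replicons.values(), key=lambda r: r.id)
    ]
    genes = []
    for g in sorted(db.genes.values(), key=lambda g: g.id):
        d = {"id": g.id, "replicon": g.replicon, "start": g.start, "end": g.end, "strand": g.strand}
        _opt(d, "name", g.name)
        _opt(d, "synonyms", sorted(g.synonyms))
        _opt(d, "product", g.product)
        _opt(d, "evidence", sorted(g.evidence))
        _opt(d, "propagated_from", g.propagated_from)
        genes.append(d)
    out["genes"] = genes
    prots = []
    for p in sorted(db.proteins.values(), key=lambda p: p.id):
        d = {"id": p.id, "gene": p.gene, "sequence": p.sequence}
        _opt(d, "name", p.name)
        _opt(d, "synonyms", sorted(p.synonyms))
        anns = []
        for a in sorted(p.go_annotations, key=lambda a: (a.term, a.evidence_code, a.with_ref or "")):
            ad = {"term": a.term, "evidence_code": a.evidence_code}
            _opt(ad, "with_ref", a.with_ref)
            anns.append(ad)
        _opt(d, "go_annotations", anns)
        _opt(d, "reactions", sorted(p.reactions))
        _opt(d, "evidence", sorted(p.evidence))
        prots.append(d)
    out["proteins"] = prots
    cplxs = []
    for c in sorted(db.complexes.values(), key=lambda c: c.id):
        d: dict[str, object] = {"id": c.id}
        _opt(d, "name", c.name)
        d["components"] = {k: c.components[k] for k in sorted(c.components)}
        _opt(d, "reactions", sorted(c.reactions))
        cplxs.append(d)
    _opt(out, "complexes", cplxs)
    rxns = []
    for r in sorted(db.reactions.values(), key=lambda r: r.id):
        d = {"id": r.id}
        _opt(d, "ec_number", r.ec_number)
        _opt(d, "name", r.name)
        rxns.append(d)
    _opt(out, "reactions", rxns)
    recs = []
    for rec in db.propagation_records:
        d = {
            "target_gene": rec.target_gene,
            "source_gene": rec.source_gene,
            "changed_fields": list(rec.changed_fields),
            "prior_values": {k: rec.prior_values[k] for k in sorted(rec.prior_values)},
        }
        _opt(d, "timestamp", rec.timestamp)
        recs.append(d)
    _opt(out, "propagation_records", sorted(recs, key=lambda d: d["target_gene"]))
    return out


def pgdb_from_dict(data: Mapping) -> PGDB:
    if not isinstance(data, Mapping) or data.get("format") != "pgdb-lite":
        raise PGDBParseError("not a pgdb-lite document (missing format tag)")
    try:
        db = PGDB(id=data["id"], provenance=dict(data.get("provenance", {})))
        for r in data.get("replicons", []):
            db.replicons[r["id"]] = Replicon(
                id=r["id"], topology=r["topology"], gene_order=list(r["gene_order"])
            )
        for g in data.get("genes", []):
            db.genes[g["id"]] = Gene(
                id=g["id"],
                replicon=g["replicon"],
                start=int(g["start"]),
                end=int(g["end"]),
                strand=g["strand"],
                name=g.get("name"),
                synonyms=set(g.get("synonyms", [])),
                product=g.get("product"),
                evidence=set(g.get("evidence", [])),
                propagated_from=g.get("propagated_from"),
            )
        for p in data.get("proteins", []):
            db.proteins[p["id"]] = Protein(
                id=p["id"],
                gene=p["gene"],
                sequence=p["sequence"],
                name=p.get("name"),
                synonyms=set(p.get("synonyms", [])),
                go_annotations=[
                    GOAnnotation(term=a["term"], evidence_code=a["evidence_code"], with_ref=a.get("with_ref"))
                    for a in p.get("go_annotations", [])
                ],
                reactions=set(p.get("reactions", [])),
                evidence=set(p.get("evidence", [])),
            )
        for c in data.get("complexes", []):
            db.complexes[c["id"]] = Complex(
                id=c["id"],
                name=c.get("name"),
                components={k: int(v) for k, v in c.get("components", {}).items()},
                reactions=set(c.get("reactions", [])),
            )
        for r in data.get("reactions", []):
            db.reactions[r["id"]] = Reaction(id=r["id"], ec_number=r.get("ec_number"), name=r.get("name"))
        for rec in data.get("propagation_records", []):
            db.propagation_records.append(
                PropagationRecord(
                    target_gene=rec["target_gene"],
                    source_gene=rec["source_gene"],
                    changed_fields=list(rec["changed_fields"]),
                    prior_values=dict(rec["prior_values"]),
                    timestamp=rec.get("timestamp"),
                )
            )
    except (KeyError, TypeError, ValueError) as exc:
        raise PGDBParseError(f"malformed pgdb-lite record: {exc!r}") from exc
    return link_and_validate(db)


def read_pgdb(path: str | Path) -> PGDB:
    """Read and validate a PGDB-lite JSON file."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PGDBParseError(f"{path}: invalid JSON: {exc}") from exc
    return pgdb_from_dict(data)


def write_pgdb(db: PGDB, path: str | Path) -> None:
    """Write canonical PGDB-lite JSON: sorted keys, sorted record lists,
    empty optionals omitted — identical inputs give identical bytes."""
    link_and_validate(db)
    text = json.dumps(pgdb_to_dict(db), indent=1, sort_keys=True, ensure_ascii=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)
        fh.write("\n")


# ---------------------------------------------------------------------------
# FASTA proteome I/O
# ---------------------------------------------------------------------------


def read_proteome_fasta(path: str | Path, known_ids: Optional[Iterable[str]] = None):
    """Read a protein FASTA into ``{protein_id: sequence}``.

    Sequences are uppercased and a trailing ``*`` stop is stripped.
    Duplicate ids raise; ids absent from ``known_ids`` (when given) are
    collected as warnings, not fatal.  Returns ``(mapping, warnings)``.
    """
    known = set(known_ids) if known_ids is not None else None
    seqs: dict[str, str] = {}
    warnings: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if rec.id in seqs:
            raise PGDBParseError(f"duplicate FASTA id {rec.id}")
        if known is not None and rec.id not in known:
            warnings.append(f"FASTA id {rec.id} not present in PGDB")
        seqs[rec.id] = seq
    return seqs, warnings


def write_proteome_fasta(db: PGDB, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for pid in sorted(db.proteins):
            fh.write(f">{pid}\n{db.proteins[pid].sequence}\n")


# ---------------------------------------------------------------------------
# Evidence classification
# ---------------------------------------------------------------------------


def evidence_class_of(obj, db: PGDB, include_complexes: bool = False) -> str:
    """Aggregate evidence class for a gene, protein, or GO annotation.

    For a gene or protein the scan covers the gene's own codes, its
    product's codes, the product's GO annotation codes and, when
    ``include_complexes`` is set, the codes of complexes containing the
    product.  Returns ``experimental-or-literature`` if any scanned code is
    experimental or literature-based, ``computational-only`` if codes exist
    but none qualify, and ``none`` when no codes are attached at all.
    """
    codes: list[str] = []
    if isinstance(obj, GOAnnotation):
        codes.append(obj.evidence_code)
    else:
        if isinstance(obj, Protein):
            gene: Optional[Gene] = db.genes.get(obj.gene)
            prot: Optional[Protein] = obj
        elif isinstance(obj, Gene):
            gene = obj
            prot = db.proteins.get(obj.product) if obj.product else None
        else:
            raise TypeError(f"cannot classify evidence of {type(obj).__name__}")
        if gene is not None:
            codes.extend(gene.evidence)
        if prot is not None:
            codes.extend(prot.evidence)
            codes.extend(a.evidence_code for a in prot.go_annotations)
            if include_complexes:
                for cx in db.complexes_containing(prot.id):
                    # complexes carry no evidence field of their own in this
                    # model; scan their other protein components' codes
                    for cid in flatten_complex(cx, db):
                        if cid in db.proteins and cid != prot.id:
                            codes.extend(db.proteins[cid].evidence)
    if not codes:
        return NO_EVIDENCE
    for code in codes:
        if evidence_code_class(code) in (CLASS_EXPERIMENTAL, CLASS_LITERATURE):
            return EXPERIMENTAL_OR_LITERATURE
    return COMPUTATIONAL_ONLY


def copy_pgdb(db: PGDB) -> PGDB:
    """Deep copy via the canonical dict form (guarantees independence)."""
    return pgdb_from_dict(pgdb_to_dict(db))
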