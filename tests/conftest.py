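"""Shared fixture builders: tiny hand-built genome databases."""

from __future__ import annotations

import pytest

from orthoprop.pgdb_model import (
    PGDB,
    Complex,
    GOAnnotation,
    Gene,
    Protein,
    Reaction,
    Replicon,
    link_and_validate,
)


def build_pgdb(
    pgdb_id: str,
    genes: list[dict],
    complexes: list[dict] | None = None,
    reactions: list[str] | None = None,
    topology: str = "linear",
) -> PGDB:
    """Construct a small validated PGDB from compact gene dicts.

    Each gene dict: id (required), seq (None for RNA genes), and optional
    name, synonyms, go [(term, code) or (term, code, with_ref)],
    reactions, evidence, product_name, product_synonyms.
    Genome order is the list order.
    """
    db = PGDB(id=pgdb_id)
    rep = Replicon(id="R1", topology=topology)
    db.replicons["R1"] = rep
    for rid in reactions or []:
        db.reactions[rid] = Reaction(id=rid)
    cursor = 1
    for spec in genes:
        gid = spec["id"]
        seq = spec.get("seq")
        pid = f"{gid}-P" if seq is not None else None
        span = (3 * len(seq) + 2) if seq else 100
        db.genes[gid] = Gene(
            id=gid,
            replicon="R1",
            start=cursor,
            end=cursor + span,
            strand=spec.get("strand", "+"),
            name=spec.get("name"),
            synonyms=set(spec.get("synonyms", [])),
            product=pid,
            evidence=set(spec.get("gene_evidence", [])),
        )
        cursor += span + 50
        rep.gene_order.append(gid)
        if pid:
            anns = []
            for entry in spec.get("go", []):
                term, code = entry[0], entry[1]
                with_ref = entry[2] if len(entry) > 2 else None
                anns.append(GOAnnotation(term=term, evidence_code=code, with_ref=with_ref))
            rxns = set(spec.get("reactions", []))
            for rid in rxns:
                db.reactions.setdefault(rid, Reaction(id=rid))
            db.proteins[pid] = Protein(
                id=pid,
                gene=gid,
                sequence=seq,
                name=spec.get("product_name"),
                synonyms=set(spec.get("product_synonyms", [])),
                go_annotations=anns,
                reactions=rxns,
                evidence=set(spec.get("evidence", [])),
            )
    for cspec in complexes or []:
        for rid in cspec.get("reactions", []):
            db.reactions.setdefault(rid, Reaction(id=rid))
        db.complexes[cspec["id"]] = Complex(
            id=cspec["id"],
            name=cspec.get("name"),
            components=dict(cspec["components"]),
            reactions=set(cspec.get("reactions", [])),
        )
    return link_and_validate(db)


@pytest.fixture
def three_gene_pair():
    """Two identical 3-gene genomes (source curated, target stripped)."""
    seqs = {
        "A": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
        "B": "MSERIVLAMSGGVDSSVTAALLKEQGYDVIGIF",
        "C": "MTNWKQLLNPTQWAKEHFYQLFGLESFEQGKSF",
    }
    source = build_pgdb(
        "SRC",
        [
            {"id": f"S{g}", "name": g.lower() + "srC", "seq": seqs[g],
             "go": [("GO:0016301", "IDA")], "evidence": ["EV-EXP-IDA"],
             "product_name": f"{g} kinase subunit", "reactions": [f"RXN-{g}"]}
            for g in "ABC"
        ],
    )
    target = build_pgdb(
        "TGT",
        [
            {"id": f"T{g}", "name": g.lower() + "srC", "seq": seqs[g],
             "product_name": "hypothetical protein"}
            for g in "ABC"
        ],
    )
    return source, target
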