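"""Resolution of targets that map to multiple source orthologs.

Exact gene duplications make BBH ties real: a target protein T can tie
with several source proteins.  Propagation needs a single source, so the
resolver applies, in order:

1. synteny — a candidate source gene S passes if the product of either
   gene directly adjacent to S is an ortholog of the product of either
   gene directly adjacent to T (a strictly local, ±1-gene test);
2. gene name — only consulted when *no* candidate passes synteny: a
   candidate wins if its primary gene name equals T's, exactly and
   case-sensitively.

Anything short of a unique winner (two syntenic candidates, two or zero
name matches, unnamed T) rejects T outright: the method prefers not to
propagate at all over guessing and overwriting correct information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .ortholog_map import OrthologPair
from .pgdb_model import PGDB, Gene

RESOLUTION_UNIQUE = "unique"
RESOLUTION_SYNTENY = "synteny"
RESOLUTION_GENE_NAME = "gene-name"
RESOLUTION_REJECTED = "rejected"


@dataclass
class Candidate:
    target_protein: str
    source_candidates: list[OrthologPair] = field(default_factory=list)
    resolution: str = RESOLUTION_REJECTED
    chosen: Optional[str] = None  # source protein id; absent iff rejected


def adjacent_genes(gene_id: str, db: PGDB) -> list[str]:
    """The up-to-two immediate neighbours of a gene in its replicon's
    gene_order.  Circular replicons wrap; ends of a linear replicon yield
    a single neighbour; a 2-gene circular replicon's double neighbour is
    deduplicated.  Strand is ignored."""
    gene = db.genes[gene_id]
    rep = db.replicons.get(gene.replicon)
    if rep is None or gene_id not in rep.gene_order:
        raise ValueError(f"gene {gene_id} has no replicon placement")
    order = rep.gene_order
    i = order.index(gene_id)
    n = len(order)
    neighbours: list[str] = []
    if rep.topology == "circular":
        if n > 1:
            neighbours = [order[(i - 1) % n], order[(i + 1) % n]]
    else:
        if i > 0:
            neighbours.append(order[i - 1])
        if i < n - 1:
            neighbours.append(order[i + 1])
    out: list[str] = []
    for g in neighbours:
        if g not in out and g != gene_id:
            out.append(g)
    return out


def synteny_pass(
    source_gene: str,
    target_gene: str,
    pairs: Iterable[OrthologPair],
    source_db: PGDB,
    target_db: PGDB,
) -> bool:
    """True iff some flank of the source gene and some flank of the target
    gene have products that form an ortholog pair.  Neighbours without a
    protein product (RNA genes) are skipped."""
    pair_set = {(p.source_protein, p.target_protein) for p in pairs}
    s_flank_products = [
        source_db.genes[g].product
        for g in adjacent_genes(source_gene, source_db)
        if source_db.genes[g].product
    ]
    t_flank_products = [
        target_db.genes[g].product
        for g in adjacent_genes(target_gene, target_db)
        if target_db.genes[g].product
    ]
    for sp in s_flank_products:
        for tp in t_flank_products:
            if (sp, tp) in pair_set:
                return True
    return False


def resolve(
    target_gene: Gene,
    candidate_pairs: list[OrthologPair],
    all_pairs: Iterable[OrthologPair],
    source_db: PGDB,
    target_db: PGDB,
) -> Candidate:
    """Pick the single best source ortholog for a target gene, or reject.

    Decision table: one candidate → unique.  Several candidates → exactly
    one passing synteny wins; if none passes synteny, exactly one whose
    source gene name equals the target's wins; every other outcome
    (several syntenic, several or zero name matches, unnamed target)
    rejects.  The outcome is independent of candidate order."""
    if not candidate_pairs:
        raise ValueError(f"no candidate pairs for target gene {target_gene.id}")
    ordered = sorted(candidate_pairs, key=lambda p: p.source_protein)
    cand = Candidate(target_protein=ordered[0].target_protein, source_candidates=ordered)
    if len(ordered) == 1:
        cand.resolution = RESOLUTION_UNIQUE
        cand.chosen = ordered[0].source_protein
        return cand

    all_pairs = list(all_pairs)
    syntenic = [
        p
        for p in ordered
        if synteny_pass(
            source_db.proteins[p.source_protein].gene,
            target_gene.id,
            all_pairs,
            source_db,
            target_db,
        )
    ]
    if len(syntenic) == 1:
        cand.resolution = RESOLUTION_SYNTENY
        cand.chosen = syntenic[0].source_protein
        return cand
    if len(syntenic) == 0 and target_gene.name is not None:
        name_matches = [
            p
            for p in ordered
            if source_db.genes[source_db.proteins[p.source_protein].gene].name == target_gene.name
        ]
        if len(name_matches) == 1:
            cand.resolution = RESOLUTION_GENE_NAME
            cand.chosen = name_matches[0].source_protein
            return cand
    cand.resolution = RESOLUTION_REJECTED
    cand.chosen = None
    return cand
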