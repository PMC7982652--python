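"""Attribute propagation from a curated source genome to ortholog targets.

Given a resolved, filter-passing ortholog pair (S, T), the following
attributes — and only these — are copied from S to T:

* gene name and synonyms, product name and synonyms.  The target's prior
  primary name is demoted to a synonym, never discarded, and a name is
  never duplicated in its own synonym list.
* GO term assignments.  Only source terms with *experimental* evidence
  codes propagate, unless the two protein sequences are identical, in
  which case all source terms propagate.  Every propagated term gets an
  ISO ("inferred from sequence orthology") evidence code whose reference
  points back to the source protein.
* reaction assignments, with *replacement* semantics: the target's
  reaction set becomes exactly the source's, so spurious target reactions
  are removed and secondary source activities are added.  Reactions
  missing from the target database are created from the source's records.
* membership in heteromultimeric complexes: each source complex is
  instantiated in the target with components mapped through the ortholog
  map, preserving stoichiometry, together with the complex's reactions.
  Creation is idempotent — an equivalent complex is reused, not cloned.

An attribute counts as propagated only when its new value actually
differs from the old one.  Each propagated gene gets a history record
(source gene, fields changed, prior values), and the source database is
never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import report as report_mod
from .disambiguate import RESOLUTION_REJECTED, resolve
from .filters import FilterConfig, evaluate_all
from .ortholog_map import (
    DEFAULT_EVALUE_CUTOFF,
    HitTable,
    OrthologPair,
    ScoringConfig,
    align_bidirectional,
    bidirectional_orthologs,
)
from .pgdb_model import (
    CLASS_EXPERIMENTAL,
    Complex,
    GOAnnotation,
    PGDB,
    PropagationRecord,
    Protein,
    copy_pgdb,
    evidence_code_class,
    flatten_complex,
    link_and_validate,
)

ISO_CODE = "ISO"


@dataclass(frozen=True)
class RunOptions:
    """Knobs of a propagation run (all thresholds are configurable)."""

    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
    filters: FilterConfig = field(default_factory=FilterConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    timestamp: Optional[str] = None  # recorded on history notes when set

    def threshold_echo(self) -> dict:
        return {
            "evalue_cutoff": self.evalue_cutoff,
            "p_value_threshold": self.filters.p_value_threshold,
            "length_threshold": self.filters.length_threshold,
        }


# ---------------------------------------------------------------------------
# Field-level propagation operations
# ---------------------------------------------------------------------------


def _propagate_name_and_synonyms(
    src_name: Optional[str],
    src_synonyms: set[str],
    obj,
    name_field: str,
    syn_field: str,
) -> tuple[list[str], dict]:
    """Shared name/synonym scheme for genes and proteins: adopt the source
    name, demote the target's prior name to a synonym, union the source
    synonyms in, and keep the primary name out of the synonym list."""
    changed: list[str] = []
    prior: dict = {}
    old_name = getattr(obj, "name")
    old_syn = set(getattr(obj, "synonyms"))
    new_syn = old_syn | set(src_synonyms)
    new_name = old_name
    if src_name is not None and src_name != old_name:
        new_name = src_name
        if old_name is not None:
            new_syn.add(old_name)
    if new_name is not None:
        new_syn.discard(new_name)
    if new_name != old_name:
        changed.append(name_field)
        prior[name_field] = old_name
        setattr(obj, "name", new_name)
    if new_syn != old_syn:
        changed.append(syn_field)
        prior[syn_field] = sorted(old_syn)
        setattr(obj, "synonyms", new_syn)
    return changed, prior


def propagate_names(
    source_db: PGDB, target_db: PGDB, source_protein: str, target_protein: str
) -> tuple[list[str], dict]:
    """Propagate gene and product names/synonyms from S's gene to T's."""
    s_prot = source_db.proteins[source_protein]
    t_prot = target_db.proteins[target_protein]
    s_gene = source_db.genes[s_prot.gene]
    t_gene = target_db.genes[t_prot.gene]
    changed, prior = _propagate_name_and_synonyms(
        s_gene.name, s_gene.synonyms, t_gene, "gene_name", "gene_synonyms"
    )
    c2, p2 = _propagate_name_and_synonyms(
        s_prot.name, s_prot.synonyms, t_prot, "product_name", "product_synonyms"
    )
    changed.extend(c2)
    prior.update(p2)
    return changed, prior


def propagate_go(
    source_protein: Protein, target_protein: Protein, sequences_identical: bool
) -> tuple[list[str], dict]:
    """Copy GO annotations as ISO-coded terms referencing the source.

    Only source terms with experimental evidence codes are taken, unless
    the two sequences are identical, in which case all terms are.  Terms
    the target already holds are skipped (dedup by GO id)."""
    existing = {a.term for a in target_protein.go_annotations}
    prior_terms = sorted(existing)
    added = False
    for ann in sorted(source_protein.go_annotations, key=lambda a: (a.term, a.evidence_code)):
        if not sequences_identical and evidence_code_class(ann.evidence_code) != CLASS_EXPERIMENTAL:
            continue
        if ann.term in existing:
            continue
        target_protein.go_annotations.append(
            GOAnnotation(term=ann.term, evidence_code=ISO_CODE, with_ref=source_protein.id)
        )
        existing.add(ann.term)
        added = True
    if added:
        return ["go_terms"], {"go_terms": prior_terms}
    return [], {}


def propagate_reactions(
    source_db: PGDB, target_db: PGDB, source_protein: str, target_protein: str
) -> tuple[list[str], dict]:
    """Replace the target's reaction set with the source's (additions and
    removals both count), creating missing reaction records."""
    s_prot = source_db.proteins[source_protein]
    t_prot = target_db.proteins[target_protein]
    if s_prot.reactions == t_prot.reactions:
        return [], {}
    prior = sorted(t_prot.reactions)
    _ensure_reactions(source_db, target_db, s_prot.reactions)
    t_prot.reactions = set(s_prot.reactions)
    return ["reactions"], {"reactions": prior}


def _ensure_reactions(source_db: PGDB, target_db: PGDB, reaction_ids: Iterable[str]) -> None:
    for rid in reaction_ids:
        if rid not in target_db.reactions:
            src = source_db.reactions[rid]
            target_db.reactions[rid] = type(src)(id=src.id, ec_number=src.ec_number, name=src.name)


def build_component_map(
    pairs: Iterable[OrthologPair], resolved: Optional[dict[str, str]] = None
) -> dict[str, str]:
    """Deterministic source-protein → target-protein map for complex
    instantiation.  A target that *resolved* to the source is preferred;
    remaining ambiguity breaks on the smallest target id."""
    resolved = resolved or {}  # target protein -> chosen source protein
    by_source: dict[str, list[str]] = {}
    for p in pairs:
        by_source.setdefault(p.source_protein, []).append(p.target_protein)
    out: dict[str, str] = {}
    for s, targets in by_source.items():
        preferred = sorted(t for t in targets if resolved.get(t) == s)
        out[s] = preferred[0] if preferred else min(targets)
    return out


def propagate_complexes(
    source_protein: str,
    source_db: PGDB,
    target_db: PGDB,
    pairs: Iterable[OrthologPair],
    resolved: Optional[dict[str, str]] = None,
) -> tuple[list[str], dict]:
    """Instantiate S's heteromultimeric complexes in the target, mapping
    each protein component through the ortholog map with stoichiometry
    preserved, and copying the complex's reactions.  Requires the complex
    filter to have passed (every other component has an ortholog).
    Idempotent: an existing complex with the same mapped component
    multiset is reused."""
    pairs = list(pairs)
    comp_map = build_component_map(pairs, resolved)
    created: list[str] = []
    for cx in source_db.complexes_containing(source_protein):
        if not cx.heteromultimeric:
            continue
        flat = flatten_complex(cx, source_db)
        mapped: dict[str, int] = {}
        ok = True
        for comp_id, n in sorted(flat.items()):
            if comp_id not in source_db.proteins or comp_id not in comp_map:
                ok = False  # RNA component or unmapped protein: cannot instantiate
                break
            tgt = comp_map[comp_id]
            mapped[tgt] = mapped.get(tgt, 0) + n
        if not ok:
            continue
        existing = _find_equivalent_complex(target_db, mapped)
        if existing is not None:
            continue
        new_id = cx.id if cx.id not in target_db.complexes else f"{cx.id}-PROP"
        suffix = 1
        while new_id in target_db.complexes:
            suffix += 1
            new_id = f"{cx.id}-PROP{suffix}"
        _ensure_reactions(source_db, target_db, cx.reactions)
        target_db.complexes[new_id] = Complex(
            id=new_id,
            name=cx.name,
            components=dict(mapped),
            reactions=set(cx.reactions),
            heteromultimeric=len(mapped) >= 2,
            contains_rna=False,
        )
        created.append(new_id)
    if created:
        return ["complex_membership"], {"complex_membership": []}
    return [], {}


def _find_equivalent_complex(target_db: PGDB, mapped: dict[str, int]) -> Optional[str]:
    for cid in sorted(target_db.complexes):
        if flatten_complex(target_db.complexes[cid], target_db) == mapped:
            return cid
    return None


def propagate_gene(
    source_db: PGDB,
    target_db: PGDB,
    source_protein: str,
    target_protein: str,
    pairs: Iterable[OrthologPair],
    resolved: Optional[dict[str, str]] = None,
    timestamp: Optional[str] = None,
) -> PropagationRecord:
    """Apply all four propagation operations for one (S, T) pair and
    record the history note; a record with no changed fields is still
    produced (flagged no-op via ``record.no_op``)."""
    pairs = list(pairs)
    s_prot = source_db.proteins[source_protein]
    t_prot = target_db.proteins[target_protein]
    t_gene = target_db.genes[t_prot.gene]
    changed: list[str] = []
    prior: dict = {}
    for fields_changed, priors in (
        propagate_names(source_db, target_db, source_protein, target_protein),
        propagate_go(s_prot, t_prot, s_prot.sequence == t_prot.sequence),
        propagate_reactions(source_db, target_db, source_protein, target_protein),
        propagate_complexes(source_protein, source_db, target_db, pairs, resolved),
    ):
        changed.extend(fields_changed)
        prior.update(priors)
    t_gene.propagated_from = s_prot.gene
    rec = PropagationRecord(
        target_gene=t_gene.id,
        source_gene=s_prot.gene,
        changed_fields=sorted(changed),
        prior_values=prior,
        timestamp=timestamp,
    )
    target_db.propagation_records.append(rec)
    return rec


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_propagation(
    source: PGDB,
    target: PGDB,
    options: RunOptions = RunOptions(),
    fwd: Optional[HitTable] = None,
    rev: Optional[HitTable] = None,
) -> tuple[PGDB, "report_mod.RunReport"]:
    """Full pipeline over every protein-coding gene of the target:
    ortholog mapping → disambiguation → quality filters → propagation.

    Hit tables may be supplied (external aligner output); otherwise the
    built-in all-vs-all aligner runs on the two proteomes.  The source is
    never modified; the returned database is an updated *copy* of the
    target carrying all propagation records.
    """
    link_and_validate(source)
    link_and_validate(target)
    work = copy_pgdb(target)

    if fwd is None or rev is None:
        proteome_s = {pid: p.sequence for pid, p in source.proteins.items()}
        proteome_t = {pid: p.sequence for pid, p in work.proteins.items()}
        fwd, rev = align_bidirectional(proteome_s, proteome_t, options.scoring)
    pairs = bidirectional_orthologs(fwd, rev, options.evalue_cutoff)
    pairs_by_target: dict[str, list[OrthologPair]] = {}
    for p in pairs:
        pairs_by_target.setdefault(p.target_protein, []).append(p)

    outcomes: list[report_mod.GeneOutcome] = []
    eligible: list[tuple[str, str]] = []  # (source_protein, target_protein)
    resolved_map: dict[str, str] = {}
    resolutions: dict[str, str] = {}

    for t_gene in work.protein_coding_genes():
        pid = t_gene.product
        cand_pairs = pairs_by_target.get(pid, [])
        if not cand_pairs:
            outcomes.append(
                report_mod.GeneOutcome(
                    target_gene=t_gene.id,
                    status=report_mod.STATUS_REJECTED,
                    reason=report_mod.REASON_NO_ORTHOLOG,
                )
            )
            continue
        cand = resolve(t_gene, cand_pairs, pairs, source, work)
        if cand.resolution == RESOLUTION_REJECTED:
            outcomes.append(
                report_mod.GeneOutcome(
                    target_gene=t_gene.id,
                    status=report_mod.STATUS_REJECTED,
                    reason=report_mod.REASON_AMBIGUOUS,
                    resolution=cand.resolution,
                )
            )
            continue
        chosen_pair = next(p for p in cand_pairs if p.source_protein == cand.chosen)
        verdict = evaluate_all(chosen_pair, source, work, pairs, options.filters)
        if not verdict.passed_all:
            outcomes.append(
                report_mod.GeneOutcome(
                    target_gene=t_gene.id,
                    status=report_mod.STATUS_REJECTED,
                    reason=report_mod.rejection_reason(verdict.failed),
                    failed_filters=verdict.failed,
                    resolution=cand.resolution,
                    source_gene=source.proteins[cand.chosen].gene,
                )
            )
            continue
        resolved_map[pid] = cand.chosen
        resolutions[pid] = cand.resolution
        eligible.append((cand.chosen, pid))

    outcome_by_target_protein: dict[str, report_mod.GeneOutcome] = {}
    for s_pid, t_pid in sorted(eligible, key=lambda st: st[1]):
        rec = propagate_gene(
            source, work, s_pid, t_pid, pairs, resolved_map, options.timestamp
        )
        outcome = report_mod.GeneOutcome(
            target_gene=rec.target_gene,
            status=report_mod.STATUS_PROPAGATED,
            resolution=resolutions[t_pid],
            source_gene=rec.source_gene,
            record=rec,
        )
        outcomes.append(outcome)
        outcome_by_target_protein[t_pid] = outcome

    link_and_validate(work)
    report = report_mod.build_report(
        outcomes, target_db=work, thresholds=options.threshold_echo()
    )
    return work, report
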