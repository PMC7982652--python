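"""Attribute propagation semantics, provenance, and run-level invariants."""

import pytest

from orthoprop.pgdb_model import pgdb_to_dict, write_pgdb
from orthoprop.ortholog_map import OrthologPair
from orthoprop.propagate import (
    RunOptions,
    propagate_complexes,
    propagate_gene,
    propagate_go,
    propagate_names,
    propagate_reactions,
    run_propagation,
)
from orthoprop.synthgen import StrainPairSpec, generate_pair

from conftest import build_pgdb

SEQ = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
SEQ2 = "MSERIVLAMSGGVDSSVTAALLKEQGYDVIGIF"


def mkpair(s, t):
    return OrthologPair(s, t, 1e-40, 1e-40)


# -- names -------------------------------------------------------------------


def test_renamed_gene_demotes_prior_name_to_synonym():
    # the renamed-gene precedent: the old target name survives as a synonym
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "name": "btsR", "synonyms": ["yehT"]}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ, "name": "yehT"}])
    changed, prior = propagate_names(src, tgt, "S1-P", "T1-P")
    assert tgt.genes["T1"].name == "btsR"
    assert "yehT" in tgt.genes["T1"].synonyms
    assert "btsR" not in tgt.genes["T1"].synonyms
    assert "gene_name" in changed and prior["gene_name"] == "yehT"


def test_equal_names_record_no_change():
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "name": "abcD"}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ, "name": "abcD"}])
    changed, _ = propagate_names(src, tgt, "S1-P", "T1-P")
    assert changed == []


def test_unnamed_target_gains_name_without_synonym():
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "name": "abcD"}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ}])
    changed, _ = propagate_names(src, tgt, "S1-P", "T1-P")
    assert tgt.genes["T1"].name == "abcD" and tgt.genes["T1"].synonyms == set()
    assert changed == ["gene_name"]


def test_product_names_follow_same_scheme():
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "product_name": "sugar phosphatase YbiV"}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ, "product_name": "haloacid dehalogenase"}])
    changed, prior = propagate_names(src, tgt, "S1-P", "T1-P")
    assert tgt.proteins["T1-P"].name == "sugar phosphatase YbiV"
    assert "haloacid dehalogenase" in tgt.proteins["T1-P"].synonyms
    assert prior["product_name"] == "haloacid dehalogenase"


# -- GO ----------------------------------------------------------------------


def go_dbs(src_go, tgt_go=(), identical=True):
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "go": src_go, "evidence": ["EV-EXP-IDA"]}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ if identical else SEQ2, "go": tgt_go}])
    return src.proteins["S1-P"], tgt.proteins["T1-P"], src, tgt


def test_divergent_sequences_take_only_experimental_terms_as_iso():
    s, t, _, _ = go_dbs([("GO:0016301", "IDA"), ("GO:0005737", "IEA")], identical=False)
    changed, _ = propagate_go(s, t, sequences_identical=False)
    assert changed == ["go_terms"]
    assert [(a.term, a.evidence_code, a.with_ref) for a in t.go_annotations] == [
        ("GO:0016301", "ISO", "S1-P")
    ]


def test_identical_sequences_take_all_terms_as_iso():
    s, t, _, _ = go_dbs([("GO:0016301", "IDA"), ("GO:0005737", "IEA")])
    propagate_go(s, t, sequences_identical=True)
    assert {(a.term, a.evidence_code) for a in t.go_annotations} == {
        ("GO:0016301", "ISO"), ("GO:0005737", "ISO")
    }


def test_literature_coded_terms_do_not_propagate_when_divergent():
    s, t, _, _ = go_dbs([("GO:0016301", "TAS")], identical=False)
    changed, _ = propagate_go(s, t, sequences_identical=False)
    assert changed == [] and t.go_annotations == []


def test_terms_already_held_are_deduplicated_by_term():
    s, t, _, _ = go_dbs([("GO:0016301", "IDA")], tgt_go=[("GO:0016301", "IEA")])
    changed, _ = propagate_go(s, t, sequences_identical=False)
    assert changed == [] and len(t.go_annotations) == 1


# -- reactions ---------------------------------------------------------------


def test_reaction_replacement_removes_spurious_assignments():
    # a protein wrongly assigned dehalogenase reactions gets exactly the
    # curated sugar-phosphatase reaction instead
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "reactions": ["SUGAR-PHOSPHATASE-RXN"]}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ, "reactions": ["DEHALOGENASE-RXN-1", "DEHALOGENASE-RXN-2"]}])
    changed, prior = propagate_reactions(src, tgt, "S1-P", "T1-P")
    assert changed == ["reactions"]
    assert tgt.proteins["T1-P"].reactions == {"SUGAR-PHOSPHATASE-RXN"}
    assert prior["reactions"] == ["DEHALOGENASE-RXN-1", "DEHALOGENASE-RXN-2"]
    assert "SUGAR-PHOSPHATASE-RXN" in tgt.reactions  # created from source


def test_secondary_reactions_are_added():
    # an adenylate-kinase-like source with seven secondary activities
    rxns = ["ADK-RXN"] + [f"SIDE-RXN-{i}" for i in range(7)]
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "reactions": rxns}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ, "reactions": ["ADK-RXN"]}])
    changed, _ = propagate_reactions(src, tgt, "S1-P", "T1-P")
    assert changed == ["reactions"] and len(tgt.proteins["T1-P"].reactions) == 8


def test_empty_source_set_clears_spurious_reaction():
    # a regulator wrongly assigned a transport reaction loses it
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ, "reactions": ["PHOSPHATE-TRANSPORT-RXN"]}])
    changed, _ = propagate_reactions(src, tgt, "S1-P", "T1-P")
    assert changed == ["reactions"] and tgt.proteins["T1-P"].reactions == set()


# -- complexes ---------------------------------------------------------------


def heterodimer_fixture():
    src = build_pgdb(
        "S",
        [{"id": "S1", "seq": SEQ, "evidence": ["EV-EXP-IDA"]}, {"id": "S2", "seq": SEQ2}],
        complexes=[{"id": "CX1", "components": {"S1-P": 2, "S2-P": 1},
                    "reactions": ["CX-RXN"], "name": "demo dimer"}],
    )
    tgt = build_pgdb("T", [{"id": "T1", "seq": SEQ}, {"id": "T2", "seq": SEQ2}])
    pairs = [mkpair("S1-P", "T1-P"), mkpair("S2-P", "T2-P")]
    return src, tgt, pairs


def test_heterodimer_created_with_mapped_stoichiometry():
    src, tgt, pairs = heterodimer_fixture()
    changed, _ = propagate_complexes("S1-P", src, tgt, pairs)
    assert changed == ["complex_membership"]
    cx = tgt.complexes["CX1"]
    assert cx.components == {"T1-P": 2, "T2-P": 1}
    assert cx.reactions == {"CX-RXN"} and "CX-RXN" in tgt.reactions


def test_complex_creation_is_idempotent():
    src, tgt, pairs = heterodimer_fixture()
    propagate_complexes("S1-P", src, tgt, pairs)
    changed, _ = propagate_complexes("S1-P", src, tgt, pairs)
    assert changed == [] and len(tgt.complexes) == 1


def test_equivalent_existing_complex_is_reused_not_duplicated():
    src, tgt, pairs = heterodimer_fixture()
    from orthoprop.pgdb_model import Complex

    tgt.complexes["OWN-CX"] = Complex(id="OWN-CX", components={"T1-P": 2, "T2-P": 1})
    changed, _ = propagate_complexes("S1-P", src, tgt, pairs)
    assert changed == [] and set(tgt.complexes) == {"OWN-CX"}


# -- per-gene and whole-run --------------------------------------------------


def test_propagate_gene_assembles_record_and_provenance(three_gene_pair):
    source, target = three_gene_pair
    target.proteins["TA-P"].name = "hypothetical protein"
    pairs = [mkpair(f"S{g}-P", f"T{g}-P") for g in "ABC"]
    rec = propagate_gene(source, target, "SA-P", "TA-P", pairs, timestamp="2021-03-08")
    assert rec.target_gene == "TA" and rec.source_gene == "SA"
    assert set(rec.changed_fields) == {
        "product_name", "product_synonyms", "go_terms", "reactions"
    }
    assert set(rec.prior_values) == set(rec.changed_fields)
    assert rec.timestamp == "2021-03-08"
    assert target.genes["TA"].propagated_from == "SA"
    assert rec in target.propagation_records


def test_noop_record_still_produced(three_gene_pair):
    source, target = three_gene_pair
    pairs = [mkpair(f"S{g}-P", f"T{g}-P") for g in "ABC"]
    propagate_gene(source, target, "SA-P", "TA-P", pairs)
    rec = propagate_gene(source, target, "SA-P", "TA-P", pairs)
    assert rec.no_op and rec.changed_fields == []


def test_clone_run_propagates_everything(three_gene_pair):
    source, target = three_gene_pair
    updated, report = run_propagation(source, target)
    assert report.summary["propagated"] == 3 and report.summary["rejected"] == 0
    for rec in updated.propagation_records:
        assert "go_terms" in rec.changed_fields


def test_disjoint_genomes_propagate_nothing():
    src = build_pgdb("S", [{"id": "S1", "seq": SEQ, "evidence": ["EV-EXP-IDA"]}])
    tgt = build_pgdb("T", [{"id": "T1", "seq": "MNIFEMLRIDEGLRLKIYKDTEGYYTIGIGHLL"}])
    updated, report = run_propagation(src, tgt)
    assert report.summary["propagated"] == 0
    assert report.summary["rejected_by_reason"] == {"no-ortholog": 1}


def test_source_never_modified_and_counts_conserved(tmp_path):
    source, target, _ = generate_pair(StrainPairSpec(n_genes=25, seed=9))
    src_path = tmp_path / "source.json"
    write_pgdb(source, src_path)
    before = src_path.read_bytes()
    snapshot = pgdb_to_dict(source)
    updated, _ = run_propagation(source, target)
    assert pgdb_to_dict(source) == snapshot
    write_pgdb(source, src_path)
    assert src_path.read_bytes() == before
    # propagation changes attributes and complexes, never gene/protein counts
    assert len(updated.genes) == len(target.genes)
    assert len(updated.proteins) == len(target.proteins)


def test_rerun_on_own_output_changes_no_fields():
    source, target, _ = generate_pair(StrainPairSpec(n_genes=25, seed=10))
    once, _ = run_propagation(source, target)
    twice, report = run_propagation(source, once)
    assert all(not fields for _, fields in report.per_protein_propagated)


def test_iso_annotations_reference_resolvable_source_proteins():
    source, target, _ = generate_pair(StrainPairSpec(n_genes=25, seed=11))
    updated, _ = run_propagation(source, target)
    iso = [
        a
        for p in updated.proteins.values()
        for a in p.go_annotations
        if a.evidence_code == "ISO"
    ]
    assert iso, "expected ISO annotations after propagation"
    assert all(a.with_ref in source.proteins for a in iso)


def test_invalid_input_aborts_before_mutation(three_gene_pair):
    source, target = three_gene_pair
    target.genes["TA"].product = "MISSING-P"
    from orthoprop.pgdb_model import PGDBValidationError

    with pytest.raises(PGDBValidationError):
        run_propagation(source, target)
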