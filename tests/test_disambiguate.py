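"""Adjacency, the ±1-gene synteny test, and candidate resolution."""

import itertools

import pytest

from orthoprop.disambiguate import (
    RESOLUTION_GENE_NAME,
    RESOLUTION_REJECTED,
    RESOLUTION_SYNTENY,
    RESOLUTION_UNIQUE,
    adjacent_genes,
    resolve,
    synteny_pass,
)
from orthoprop.ortholog_map import OrthologPair

from conftest import build_pgdb

SEQS = [
    "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
    "MSERIVLAMSGGVDSSVTAALLKEQGYDVIGIF",
    "MTNWKQLLNPTQWAKEHFYQLFGLESFEQGKSF",
    "MADIKLTQGQLAERVGVSRQTIYNWFKEGRLSP",
    "MGHHHHLEVLFQGPAMGSSHDDTNNAAVVKQTS",
    "MALWMRLLPLLALLALWGPDPAAAFVNQHLCGS",
    "MQIFVKTLTGKTITLEVEPSDTIENVKAKIQDK",
    "MSDNEDNFDGDDFDDVEEDEGLDDLENAEEEGQ",
    "MKKLVLSLSLVLAFSSATAAFAAIPQNIRIGTD",
    "MNIFEMLRIDEGLRLKIYKDTEGYYTIGIGHLL",
]


def linear_genome(pgdb_id, ids, seqs=None, names=None):
    seqs = seqs or SEQS
    genes = []
    for i, gid in enumerate(ids):
        g = {"id": gid, "seq": seqs[i % len(seqs)]}
        if names and names[i]:
            g["name"] = names[i]
        genes.append(g)
    return build_pgdb(pgdb_id, genes, topology="linear")


def pair(s, t):
    return OrthologPair(f"{s}-P", f"{t}-P", 1e-40, 1e-40)


# -- adjacency ---------------------------------------------------------------


def test_adjacency_linear_middle_and_ends():
    db = linear_genome("L", ["G1", "G2", "G3"])
    assert adjacent_genes("G2", db) == ["G1", "G3"]
    assert adjacent_genes("G1", db) == ["G2"]
    assert adjacent_genes("G3", db) == ["G2"]


def test_adjacency_circular_wraps_and_dedupes():
    db = build_pgdb(
        "C",
        [{"id": "G1", "seq": SEQS[0]}, {"id": "G2", "seq": SEQS[1]}],
        topology="circular",
    )
    assert adjacent_genes("G1", db) == ["G2"]
    three = build_pgdb(
        "C3", [{"id": g, "seq": SEQS[i]} for i, g in enumerate(["G1", "G2", "G3"])],
        topology="circular",
    )
    assert set(adjacent_genes("G1", three)) == {"G3", "G2"}


def test_adjacency_requires_replicon_placement():
    db = linear_genome("L", ["G1", "G2"])
    db.replicons["R1"].gene_order.remove("G2")
    with pytest.raises(ValueError):
        adjacent_genes("G2", db)


# -- synteny -----------------------------------------------------------------


def test_synteny_identity_genomes_pass():
    src = linear_genome("S", ["S1", "S2", "S3"])
    tgt = linear_genome("T", ["T1", "T2", "T3"])
    pairs = [pair(f"S{i}", f"T{i}") for i in (1, 2, 3)]
    assert synteny_pass("S2", "T2", pairs, src, tgt)


def test_synteny_fails_when_neighbourhood_shuffled():
    src = linear_genome("S", ["S1", "S2", "S3", "S4", "S5"])
    tgt = linear_genome("T", ["T4", "T2", "T5", "T1", "T3"])
    pairs = [pair(f"S{i}", f"T{i}") for i in range(1, 6)]
    # T2's neighbours are T4/T5 whose sources S4/S5 do not flank S2
    assert not synteny_pass("S2", "T2", pairs, src, tgt)


def test_synteny_skips_rna_neighbours():
    src = build_pgdb(
        "S",
        [{"id": "S1", "seq": SEQS[0]}, {"id": "RNA", "seq": None},
         {"id": "S2", "seq": SEQS[1]}, {"id": "S3", "seq": SEQS[2]}],
    )
    tgt = linear_genome("T", ["T1", "T2", "T3"])
    pairs = [pair(f"S{i}", f"T{i}") for i in (1, 2, 3)]
    # S2's productive flank is S3 only (RNA skipped); T2 flanks T1,T3
    assert synteny_pass("S2", "T2", pairs, src, tgt)


def test_synteny_agrees_with_exhaustive_flank_check_under_inversion():
    """10-gene genomes with one inverted block: the module's verdict must
    equal brute force over all 2x2 flank combinations, for every gene."""
    ids_s = [f"S{i}" for i in range(10)]
    order_t = [0, 1, 2, 6, 5, 4, 3, 7, 8, 9]  # invert block 3..6
    ids_t = [f"T{i}" for i in order_t]
    src = linear_genome("S", ids_s)
    tgt = linear_genome("T", ids_t, seqs=[SEQS[i] for i in order_t])
    pairs = [pair(f"S{i}", f"T{i}") for i in range(10)]
    pair_set = {(p.source_protein, p.target_protein) for p in pairs}
    for i in range(10):
        expected = False
        s_adj = adjacent_genes(f"S{i}", src)
        t_adj = adjacent_genes(f"T{i}", tgt)
        for s_n, t_n in itertools.product(s_adj, t_adj):
            sp, tp = src.genes[s_n].product, tgt.genes[t_n].product
            if sp and tp and (sp, tp) in pair_set:
                expected = True
        assert synteny_pass(f"S{i}", f"T{i}", pairs, src, tgt) == expected


# -- resolve -----------------------------------------------------------------


def two_candidate_setup(target_name=None, s1_name=None, s2_name=None, syntenic=True):
    """Target gene T2 maps to both S2 and S2D (a decoy at the far end)."""
    src = build_pgdb(
        "S",
        [
            {"id": "S1", "seq": SEQS[0]},
            {"id": "S2", "seq": SEQS[1], "name": s1_name},
            {"id": "S3", "seq": SEQS[2]},
            {"id": "S4", "seq": SEQS[3]},
            {"id": "S2D", "seq": SEQS[1], "name": s2_name},
        ],
    )
    tgt_genes = [
        {"id": "T1", "seq": SEQS[0]},
        {"id": "T2", "seq": SEQS[1], "name": target_name},
        {"id": "T3", "seq": SEQS[2]},
        {"id": "T4", "seq": SEQS[3]},
    ]
    if not syntenic:
        # isolate T2 between two genes that have no orthologs at all, so
        # neither candidate's flanks can match
        t2 = tgt_genes.pop(1)
        tgt_genes += [{"id": "T5", "seq": SEQS[4]}, t2, {"id": "T6", "seq": SEQS[5]}]
    tgt = build_pgdb("T", tgt_genes)
    flank_pairs = [pair("S1", "T1"), pair("S3", "T3"), pair("S4", "T4")]
    cand_pairs = [pair("S2", "T2"), pair("S2D", "T2")]
    return src, tgt, cand_pairs, flank_pairs + cand_pairs


def test_single_candidate_is_unique():
    src, tgt, cand, all_pairs = two_candidate_setup()
    res = resolve(tgt.genes["T2"], cand[:1], all_pairs, src, tgt)
    assert res.resolution == RESOLUTION_UNIQUE and res.chosen == "S2-P"


def test_synteny_preferred_over_name():
    src, tgt, cand, all_pairs = two_candidate_setup(
        target_name="abcD", s1_name="abcD", s2_name="abcD", syntenic=True
    )
    res = resolve(tgt.genes["T2"], cand, all_pairs, src, tgt)
    assert res.resolution == RESOLUTION_SYNTENY and res.chosen == "S2-P"


def test_gene_name_breaks_tie_when_no_synteny():
    src, tgt, cand, all_pairs = two_candidate_setup(
        target_name="abcD", s1_name="abcD", s2_name=None, syntenic=False
    )
    res = resolve(tgt.genes["T2"], cand, all_pairs, src, tgt)
    assert res.resolution == RESOLUTION_GENE_NAME and res.chosen == "S2-P"


def test_duplicate_names_without_synteny_reject():
    src, tgt, cand, all_pairs = two_candidate_setup(
        target_name="abcD", s1_name="abcD", s2_name="abcD", syntenic=False
    )
    res = resolve(tgt.genes["T2"], cand, all_pairs, src, tgt)
    assert res.resolution == RESOLUTION_REJECTED and res.chosen is None


def test_unnamed_target_cannot_use_name_fallback():
    src, tgt, cand, all_pairs = two_candidate_setup(
        target_name=None, s1_name="abcD", s2_name=None, syntenic=False
    )
    res = resolve(tgt.genes["T2"], cand, all_pairs, src, tgt)
    assert res.resolution == RESOLUTION_REJECTED


def test_name_comparison_is_case_sensitive_and_ignores_synonyms():
    src, tgt, cand, all_pairs = two_candidate_setup(
        target_name="AbcD", s1_name="abcD", s2_name=None, syntenic=False
    )
    src.genes["S2D"].synonyms = {"AbcD"}  # synonym must not count
    res = resolve(tgt.genes["T2"], cand, all_pairs, src, tgt)
    assert res.resolution == RESOLUTION_REJECTED


def test_resolution_is_order_independent_and_chosen_is_a_candidate():
    src, tgt, cand, all_pairs = two_candidate_setup(
        target_name="abcD", s1_name="abcD", s2_name=None, syntenic=False
    )
    r1 = resolve(tgt.genes["T2"], cand, all_pairs, src, tgt)
    r2 = resolve(tgt.genes["T2"], list(reversed(cand)), all_pairs, src, tgt)
    assert (r1.resolution, r1.chosen) == (r2.resolution, r2.chosen)
    assert r1.chosen in {p.source_protein for p in cand}
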