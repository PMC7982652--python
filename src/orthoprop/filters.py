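"""The five propagation quality filters.

A resolved source/target ortholog pair (S, T) qualifies for propagation
only if it passes all of:

1. target evidence — T lacks any experimental or literature-based
   evidence code (do not overwrite curation on the target side);
2. source evidence — S carries at least one experimental or
   literature-based code (do not transitively propagate inferences);
3. P-value — the pair's P-value (mean of the two BBH E-values) must not
   exceed a threshold, default 1e-10; equality passes;
4. length — the two sequences must not differ in length by more than a
   threshold fraction, default 10%, of the longer sequence;
5. complex — if S belongs to a heteromultimeric complex, every other
   protein component of that complex (flattened through sub-complexes)
   must have at least one ortholog; any RNA component fails the test
   outright, which is why ribosomal proteins never propagate.

All five are always evaluated, even after an early failure, so reports
can split single-filter from multi-filter failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .ortholog_map import OrthologPair
from .pgdb_model import (
    EXPERIMENTAL_OR_LITERATURE,
    PGDB,
    evidence_class_of,
    flatten_complex,
)

FILTER_TARGET_EVIDENCE = "target_evidence"
FILTER_SOURCE_EVIDENCE = "source_evidence"
FILTER_P_VALUE = "p_value"
FILTER_LENGTH = "length"
FILTER_COMPLEX = "complex"
FILTER_NAMES = (
    FILTER_TARGET_EVIDENCE,
    FILTER_SOURCE_EVIDENCE,
    FILTER_P_VALUE,
    FILTER_LENGTH,
    FILTER_COMPLEX,
)

DEFAULT_P_VALUE_THRESHOLD = 1e-10
DEFAULT_LENGTH_THRESHOLD = 0.10


@dataclass(frozen=True)
class FilterConfig:
    p_value_threshold: float = DEFAULT_P_VALUE_THRESHOLD
    length_threshold: float = DEFAULT_LENGTH_THRESHOLD
    #: scan complexes containing T's product for target-side evidence?
    target_evidence_includes_complexes: bool = False


@dataclass
class FilterVerdict:
    pair: OrthologPair
    results: dict[str, bool] = field(default_factory=dict)  # name -> passed

    @property
    def passed_all(self) -> bool:
        return all(self.results[name] for name in FILTER_NAMES)

    @property
    def failed(self) -> list[str]:
        return [name for name in FILTER_NAMES if not self.results[name]]


def target_evidence_filter(
    target_protein_id: str, target_db: PGDB, config: FilterConfig = FilterConfig()
) -> bool:
    """Pass iff the target gene, its product, and the product's GO
    annotations carry no experimental or literature-based evidence code —
    any such code signals prior curation and blocks propagation."""
    prot = target_db.proteins[target_protein_id]
    cls = evidence_class_of(
        prot, target_db, include_complexes=config.target_evidence_includes_complexes
    )
    return cls != EXPERIMENTAL_OR_LITERATURE


def source_evidence_filter(source_protein_id: str, source_db: PGDB) -> bool:
    """Pass iff the source side has experimental or literature evidence."""
    prot = source_db.proteins[source_protein_id]
    return evidence_class_of(prot, source_db) == EXPERIMENTAL_OR_LITERATURE


def p_value_filter(
    pair: OrthologPair, threshold: float = DEFAULT_P_VALUE_THRESHOLD
) -> bool:
    """Pass iff the pair's P-value does not exceed the threshold
    (equality passes)."""
    return pair.p_value <= threshold


def length_filter(
    len_source: int, len_target: int, threshold: float = DEFAULT_LENGTH_THRESHOLD
) -> bool:
    """Pass iff the relative length difference, taken over the longer of
    the two sequences, does not exceed the threshold."""
    longer = max(len_source, len_target)
    if longer == 0:
        return True
    return abs(len_source - len_target) / longer <= threshold


def complex_filter(
    source_protein_id: str,
    source_db: PGDB,
    pairs: Iterable[OrthologPair],
) -> bool:
    """Pass iff every heteromultimeric complex containing S (flattened
    through sub-complexes) has an ortholog for each of its other protein
    components; an RNA component fails automatically because RNA is
    excluded from the ortholog computation."""
    sources_with_orthologs = {p.source_protein for p in pairs}
    for cx in source_db.complexes_containing(source_protein_id):
        if not cx.heteromultimeric:
            continue
        flat = flatten_complex(cx, source_db)
        for comp_id in flat:
            if comp_id == source_protein_id:
                continue
            if comp_id not in source_db.proteins:
                return False  # RNA / unproduced component
            if comp_id not in sources_with_orthologs:
                return False
    return True


def evaluate_all(
    pair: OrthologPair,
    source_db: PGDB,
    target_db: PGDB,
    all_pairs: Iterable[OrthologPair],
    config: FilterConfig = FilterConfig(),
) -> FilterVerdict:
    """Evaluate all five filters for a resolved pair; every filter runs
    regardless of the others' outcomes."""
    all_pairs = list(all_pairs)
    s_prot = source_db.proteins[pair.source_protein]
    t_prot = target_db.proteins[pair.target_protein]
    verdict = FilterVerdict(pair=pair)
    verdict.results[FILTER_TARGET_EVIDENCE] = target_evidence_filter(
        t_prot.id, target_db, config
    )
    verdict.results[FILTER_SOURCE_EVIDENCE] = source_evidence_filter(s_prot.id, source_db)
    verdict.results[FILTER_P_VALUE] = p_value_filter(pair, config.p_value_threshold)
    verdict.results[FILTER_LENGTH] = length_filter(
        len(s_prot.sequence), len(t_prot.sequence), config.length_threshold
    )
    verdict.results[FILTER_COMPLEX] = complex_filter(s_prot.id, source_db, all_pairs)
    return verdict
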