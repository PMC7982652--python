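"""Ortholog detection as bidirectional best hits (BBH) with tie retention.

Two proteins are called orthologs when each is the other's best hit in a
reciprocal all-vs-all comparison of the two proteomes, with both E-values
below a cutoff (default 1e-3, strict ``<``).  "Best" means the minimal
E-value among a query's hits; exact ties are all kept, since exact gene
duplications genuinely produce identical scores.  Each accepted pair also
carries a P-value defined as the arithmetic mean of its two E-values,
consumed later by the propagation quality filters.

Hits come either from an external aligner's 12-column tabular output
(the common BLAST ``outfmt 6`` dialect) or from the built-in Smith–
Waterman all-vs-all aligner.  The built-in backend converts raw local
alignment scores to E-values with the Karlin–Altschul formula
``E = K * m * n * exp(-lambda * S)``; it promises the same score *ranking*
as BLAST for desk-scale proteomes, not numerically identical E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from Bio import Align
from Bio.Align import substitution_matrices

DEFAULT_EVALUE_CUTOFF = 1e-3

# Gapped Karlin-Altschul parameters for BLOSUM62 with open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class Hit:
    query: str
    subject: str
    evalue: float
    bitscore: float
    align_length: int = 0


@dataclass
class HitTable:
    """Best row per (query, subject) for one direction of the comparison."""

    direction: str
    rows: dict[tuple[str, str], Hit] = field(default_factory=dict)

    def add_best(self, hit: Hit) -> None:
        """Insert, keeping only the best HSP per (query, subject):
        minimal E-value, ties broken by maximal bitscore."""
        key = (hit.query, hit.subject)
        old = self.rows.get(key)
        if old is None or (hit.evalue, -hit.bitscore) < (old.evalue, -old.bitscore):
            self.rows[key] = hit

    def hits_of(self, query: str) -> list[Hit]:
        return [h for (q, _s), h in self.rows.items() if q == query]


@dataclass(frozen=True)
class OrthologPair:
    source_protein: str
    target_protein: str
    e_forward: float
    e_reverse: float
    tie_group: Optional[str] = None

    @property
    def p_value(self) -> float:
        return (self.e_forward + self.e_reverse) / 2.0


class TabularFormatError(ValueError):
    pass


def load_tabular_hits(path: str | Path, direction: str) -> HitTable:
    """Parse 12-column tab-separated hits (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore), reducing
    multiple HSPs per (query, subject) to the single best row."""
    table = HitTable(direction=direction)
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise TabularFormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                hit = Hit(
                    query=cols[0],
                    subject=cols[1],
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                    align_length=int(cols[3]),
                )
            except ValueError as exc:
                raise TabularFormatError(f"{path}:{lineno}: {exc}") from exc
            if hit.evalue < 0:
                raise TabularFormatError(f"{path}:{lineno}: negative E-value")
            table.add_best(hit)
    return table


def best_hits(
    hits: HitTable, evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF
) -> dict[str, set[str]]:
    """Per query, the subjects achieving that query's minimal E-value,
    provided the minimum is strictly below the cutoff.  All exact ties are
    returned.  E-values are compared exactly as parsed — no epsilon."""
    best_e: dict[str, float] = {}
    for (q, _s), hit in hits.rows.items():
        if q not in best_e or hit.evalue < best_e[q]:
            best_e[q] = hit.evalue
    out: dict[str, set[str]] = {}
    for (q, s), hit in hits.rows.items():
        if best_e[q] < evalue_cutoff and hit.evalue == best_e[q]:
            out.setdefault(q, set()).add(s)
    return out


def bidirectional_orthologs(
    fwd: HitTable,
    rev: HitTable,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> set[OrthologPair]:
    """BBH pairs: (A, B) is a pair iff B is among A's best forward hits and
    A is among B's best reverse hits.  A source protein may appear in
    several pairs (and so may a target protein); pairs sharing a target
    protein are stamped with a common tie group id."""
    fwd_best = best_hits(fwd, evalue_cutoff)
    rev_best = best_hits(rev, evalue_cutoff)
    raw: list[tuple[str, str, float, float]] = []
    per_target: dict[str, int] = {}
    for a, subjects in fwd_best.items():
        for b in subjects:
            if a in rev_best.get(b, ()):
                e_f = fwd.rows[(a, b)].evalue
                e_r = rev.rows[(b, a)].evalue
                raw.append((a, b, e_f, e_r))
                per_target[b] = per_target.get(b, 0) + 1
    pairs: set[OrthologPair] = set()
    for a, b, e_f, e_r in raw:
        tie = f"tie:{b}" if per_target[b] > 1 else None
        pairs.add(
            OrthologPair(
                source_protein=a, target_protein=b, e_forward=e_f, e_reverse=e_r, tie_group=tie
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Built-in all-vs-all Smith-Waterman backend
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoringConfig:
    matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K


def _make_aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(config.matrix)
    aligner.open_gap_score = config.gap_open
    aligner.extend_gap_score = config.gap_extend
    return aligner


def _check_sequences(proteome: Mapping[str, str], alphabet: set[str]) -> None:
    for pid, seq in proteome.items():
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"sequence {pid}: illegal characters {sorted(bad)}")
        if not seq:
            raise ValueError(f"sequence {pid}: empty")


def _evalue(score: float, m: int, n: int, config: ScoringConfig) -> float:
    # Karlin-Altschul; clamp the exponent so short random hits cannot
    # overflow and true hits cannot underflow to exactly 0 vs each other
    # asymmetrically (math.exp underflows to 0.0 identically either way).
    return config.ka_k * m * n * math.exp(-config.ka_lambda * score)


def align_bidirectional(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    config: ScoringConfig = ScoringConfig(),
) -> tuple[HitTable, HitTable]:
    """All-vs-all local alignment computed once, reported in both
    directions (the raw Smith-Waterman score is symmetric; only the
    E-value's query/database sizes differ)."""
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    alphabet = set(str(substitution_matrices.load(config.matrix).alphabet))
    _check_sequences(proteome_a, alphabet)
    _check_sequences(proteome_b, alphabet)
    aligner = _make_aligner(config)
    n_a = sum(len(s) for s in proteome_a.values())
    n_b = sum(len(s) for s in proteome_b.values())
    fwd = HitTable(direction=FORWARD)
    rev = HitTable(direction=REVERSE)
    ln2 = math.log(2.0)
    for aid in sorted(proteome_a):
        sa = proteome_a[aid]
        for bid in sorted(proteome_b):
            sb = proteome_b[bid]
            score = aligner.score(sa, sb)
            bits = (config.ka_lambda * score - math.log(config.ka_k)) / ln2
            fwd.add_best(Hit(aid, bid, _evalue(score, len(sa), n_b, config), bits))
            rev.add_best(Hit(bid, aid, _evalue(score, len(sb), n_a, config), bits))
    return fwd, rev


def align_all_vs_all(
    proteome_query: Mapping[str, str],
    proteome_db: Mapping[str, str],
    config: ScoringConfig = ScoringConfig(),
    direction: str = FORWARD,
) -> HitTable:
    """One direction of the all-vs-all comparison (see align_bidirectional
    for the shared-score two-direction form the pipeline uses)."""
    fwd, _rev = align_bidirectional(proteome_query, proteome_db, config)
    fwd.direction = direction
    return fwd


def brute_force_bbh(
    fwd: HitTable,
    rev: HitTable,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> set[tuple[str, str]]:
    """Independent oracle: exhaustive double loop over every (query,
    subject) row in both tables, no intermediate best-hit maps.  Used only
    by tests to cross-check ``bidirectional_orthologs``."""
    accepted: set[tuple[str, str]] = set()
    for (a, b), hit in fwd.rows.items():
        if hit.evalue >= evalue_cutoff:
            continue
        if any(h2.evalue < hit.evalue for (q2, _s2), h2 in fwd.rows.items() if q2 == a):
            continue
        rhit = rev.rows.get((b, a))
        if rhit is None or rhit.evalue >= evalue_cutoff:
            continue
        if any(h2.evalue < rhit.evalue for (q2, _s2), h2 in rev.rows.items() if q2 == b):
            continue
        accepted.add((a, b))
    return accepted
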