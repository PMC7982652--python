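"""Run reports: summary statistics, per-gene outcomes, and the
function-name classifier.

Every propagation run yields a three-part report: (a) summary counts,
(b) the fields propagated for every gene whose data was propagated, and
(c) the reason each remaining gene was *not* propagated (no ortholog,
ambiguous ortholog, or the full set of failed filters — multi-filter
failures are recorded as a set so single-vs-multiple failure histograms
can be drawn).  The report also counts, per attribute class, how many
genes changed, and how many gene products were upgraded from an unknown
or vague function name to a specific one.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .pgdb_model import PGDB, PropagationRecord

STATUS_PROPAGATED = "propagated"
STATUS_REJECTED = "rejected"

REASON_NO_ORTHOLOG = "no-ortholog"
REASON_AMBIGUOUS = "ambiguous-ortholog"

#: report-facing spellings of the five filter names
FILTER_REASONS = {
    "target_evidence": "target-evidence",
    "source_evidence": "source-evidence",
    "p_value": "p-value",
    "length": "length",
    "complex": "complex",
}

ATTRIBUTE_FIELDS = (
    "gene_name",
    "gene_synonyms",
    "product_name",
    "product_synonyms",
    "go_terms",
    "reactions",
    "complex_membership",
)

CLASS_UNKNOWN = "unknown"
CLASS_VAGUE = "vague"
CLASS_SPECIFIC = "specific"


@dataclass
class GeneOutcome:
    """Per-target-gene decision from one propagation run."""

    target_gene: str
    status: str
    reason: Optional[str] = None  # set when rejected
    failed_filters: list[str] = field(default_factory=list)
    resolution: Optional[str] = None
    source_gene: Optional[str] = None
    record: Optional[PropagationRecord] = None


def rejection_reason(failed_filters: list[str]) -> str:
    """Single failed filter → its name; several → ``multiple:a,b``."""
    names = sorted(FILTER_REASONS[f] for f in failed_filters)
    if len(names) == 1:
        return names[0]
    return "multiple:" + ",".join(names)


# ---------------------------------------------------------------------------
# Function-name classifier
# ---------------------------------------------------------------------------


def _load_default_patterns() -> dict:
    with resources.files("orthoprop.data").joinpath("function_patterns.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


class FunctionNameClassifier:
    """Classifies product names as unknown / vague / specific.

    "hypothetical protein" or "orf"-style names mean the function is
    unknown; bare class words such as "transporter" or "oxidoreductase",
    optionally prefixed by generic qualifiers ("MFS", "putative"), are
    vague; anything else — e.g. a name specifying a substrate — is
    specific.  Pattern lists ship as editable data and can be overridden.
    """

    def __init__(self, patterns: Optional[dict] = None):
        patterns = patterns if patterns is not None else _load_default_patterns()
        self._unknown = [
            re.compile(r"\b" + re.escape(p.lower()) + r"\w*", re.IGNORECASE)
            for p in patterns["unknown"]
        ]
        quals = "|".join(re.escape(q.lower()) for q in patterns["qualifiers"])
        bases = "|".join(re.escape(b.lower()) for b in patterns["vague"])
        self._vague = re.compile(rf"(?:(?:{quals})\s+)*(?:{bases})s?", re.IGNORECASE)

    def classify(self, name: Optional[str]) -> str:
        if name is None or not name.strip():
            return CLASS_UNKNOWN
        text = " ".join(name.strip().split())
        for rx in self._unknown:
            if rx.search(text):
                return CLASS_UNKNOWN
        if self._vague.fullmatch(text):
            return CLASS_VAGUE
        return CLASS_SPECIFIC


_default_classifier: Optional[FunctionNameClassifier] = None


def classify_function_name(name: Optional[str], patterns: Optional[dict] = None) -> str:
    """Classify one product name; total over arbitrary strings."""
    global _default_classifier
    if patterns is not None:
        return FunctionNameClassifier(patterns).classify(name)
    if _default_classifier is None:
        _default_classifier = FunctionNameClassifier()
    return _default_classifier.classify(name)


def count_function_upgrades(
    records: list[PropagationRecord],
    target_db: PGDB,
    patterns: Optional[dict] = None,
) -> int:
    """Number of propagated proteins whose product name went from an
    unknown or vague function to a specific one."""
    clf = FunctionNameClassifier(patterns) if patterns is not None else None
    classify = clf.classify if clf else classify_function_name
    n = 0
    for rec in records:
        if "product_name" not in rec.changed_fields:
            continue
        before = rec.prior_values.get("product_name")
        gene = target_db.genes[rec.target_gene]
        after = target_db.proteins[gene.product].name if gene.product else None
        if classify(before) in (CLASS_UNKNOWN, CLASS_VAGUE) and classify(after) == CLASS_SPECIFIC:
            n += 1
    return n


# ---------------------------------------------------------------------------
# RunReport
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    summary: dict = field(default_factory=dict)
    per_protein_propagated: list[tuple[str, list[str]]] = field(default_factory=list)
    per_protein_rejected: list[tuple[str, str]] = field(default_factory=list)
    attribute_counts: dict[str, int] = field(default_factory=dict)
    function_upgrades: int = 0
    thresholds: dict = field(default_factory=dict)


def build_report(
    outcomes: list[GeneOutcome],
    target_db: Optional[PGDB] = None,
    thresholds: Optional[dict] = None,
    patterns: Optional[dict] = None,
) -> RunReport:
    """Assemble the three-part report from per-gene outcomes.

    Invariant: propagated + rejected (each multi-filter failure counted
    once, with its full failing set) partitions the candidate genes.
    """
    outcomes = sorted(outcomes, key=lambda o: o.target_gene)
    report = RunReport(thresholds=dict(thresholds or {}))
    rejected_by_reason: dict[str, int] = {}
    resolutions: dict[str, int] = {}
    n_fail_single = 0
    n_fail_multiple = 0
    for o in outcomes:
        if o.resolution:
            resolutions[o.resolution] = resolutions.get(o.resolution, 0) + 1
        if o.status == STATUS_PROPAGATED:
            fields = list(o.record.changed_fields) if o.record else []
            report.per_protein_propagated.append((o.target_gene, fields))
        else:
            report.per_protein_rejected.append((o.target_gene, o.reason or "unknown"))
            rejected_by_reason[o.reason or "unknown"] = (
                rejected_by_reason.get(o.reason or "unknown", 0) + 1
            )
            if len(o.failed_filters) == 1:
                n_fail_single += 1
            elif len(o.failed_filters) > 1:
                n_fail_multiple += 1
    report.attribute_counts = {f: 0 for f in ATTRIBUTE_FIELDS}
    records = [o.record for o in outcomes if o.record is not None]
    for rec in records:
        for f in rec.changed_fields:
            report.attribute_counts[f] = report.attribute_counts.get(f, 0) + 1
    if target_db is not None:
        report.function_upgrades = count_function_upgrades(records, target_db, patterns)
    report.summary = {
        "candidates": len(outcomes),
        "propagated": len(report.per_protein_propagated),
        "rejected": len(report.per_protein_rejected),
        "rejected_by_reason": {k: rejected_by_reason[k] for k in sorted(rejected_by_reason)},
        "resolutions": {k: resolutions[k] for k in sorted(resolutions)},
        "failed_single_filter": n_fail_single,
        "failed_multiple_filters": n_fail_multiple,
        "function_upgrades": report.function_upgrades,
    }
    return report


def histogram_bins(values: list[float], bin_width: float, origin: float = 0.0):
    """Histogram-ready (bin_start, count) pairs for figure drawing."""
    counts: dict[float, int] = {}
    for v in values:
        start = origin + bin_width * int((v - origin) // bin_width)
        counts[start] = counts.get(start, 0) + 1
    return sorted(counts.items())


# ---------------------------------------------------------------------------
# Report files
# ---------------------------------------------------------------------------


def write_report(report: RunReport, out_dir: str | Path) -> None:
    """Write summary.json, propagated.tsv, rejected.tsv and report.txt
    with deterministic (gene-id) ordering; re-generation from the same
    records is byte-identical."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summary = {
        "summary": report.summary,
        "attribute_counts": report.attribute_counts,
        "function_upgrades": report.function_upgrades,
        "thresholds": report.thresholds,
    }
    with open(out / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")

    with open(out / "propagated.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_gene", "fields_propagated"])
        for gene, fields in sorted(report.per_protein_propagated):
            w.writerow([gene, ",".join(fields)])

    with open(out / "rejected.tsv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["target_gene", "reason"])
        for gene, reason in sorted(report.per_protein_rejected):
            w.writerow([gene, reason])

    lines = ["Annotation propagation report", "=" * 29, ""]
    s = report.summary
    lines.append(f"Candidate protein-coding genes: {s.get('candidates', 0)}")
    lines.append(f"Propagated: {s.get('propagated', 0)}")
    lines.append(f"Rejected:   {s.get('rejected', 0)}")
    for reason, n in sorted(s.get("rejected_by_reason", {}).items()):
        lines.append(f"  {reason}: {n}")
    lines.append("")
    lines.append("Attribute propagation counts:")
    for f in ATTRIBUTE_FIELDS:
        lines.append(f"  {f}: {report.attribute_counts.get(f, 0)}")
    lines.append("")
    lines.append(f"Function upgrades (unknown/vague -> specific): {report.function_upgrades}")
    if report.thresholds:
        lines.append("")
        lines.append("Thresholds:")
        for k, v in sorted(report.thresholds.items()):
            lines.append(f"  {k}: {v}")
    with open(out / "report.txt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines))
        fh.write("\n")


def format_history_note(rec: PropagationRecord) -> str:
    """Human-readable rendering of one propagation history record."""
    when = f" on {rec.timestamp}" if rec.timestamp else ""
    if rec.no_op:
        return f"Checked against source gene {rec.source_gene}{when}; no fields changed."
    parts = []
    for f in rec.changed_fields:
        prior = rec.prior_values.get(f)
        parts.append(f"{f} (was {prior!r})")
    return f"Propagated from source gene {rec.source_gene}{when}: " + "; ".join(parts) + "."
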