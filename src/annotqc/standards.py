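"""Minimal annotation standards for a complete prokaryotic genome.

A complete genome is expected to carry a full ribosomal RNA set (5S, 16S,
23S), at least one tRNA per standard amino acid, protein-coding genes at an
expected density with core conserved functions annotated and not every
protein named "hypothetical protein", valid locus_tags and pseudogene
formats, and clean feature-table structure.  Genomes that genuinely cannot
meet a standard (endosymbiont tRNA loss through codon recoding, genome
degradation) may document an exception on the record; the corresponding
check is then reported EXEMPT rather than FAIL.

The exception syntax accepted here is an ``annotation-exception:
<CHECK_ID>: <free text>`` line in a structured comment block or a feature
/note -- explicit and greppable, since the standards mandate documented
exceptions without fixing a syntax.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

from .config import QCConfig, STANDARD_AMINO_ACIDS
from .lint import Finding, lint_record
from .metrics import MetricsRow, compute_metrics, is_protein_cds, protein_length_aa
from .records import GenomeRecord

CHECK_IDS = (
    "RRNA_SET", "TRNA_SET", "CORE_FUNCS", "DENSITY",
    "HYPOTHETICAL_RATIO", "LOCUS_TAGS", "PSEUDO_FORMAT", "VALIDATION_CLEAN",
)

STATUSES = ("PASS", "FAIL", "WARN", "EXEMPT")


@dataclass(frozen=True)
class CoreFunction:
    """One expected core gene function, matched by product-name patterns."""

    function_id: str
    display_name: str
    name_patterns: tuple[str, ...]
    additions: int = 0
    expected_avg_len_aa: Optional[float] = None
    len_sd: Optional[float] = None

    def matches(self, product: str) -> bool:
        # word-bounded substring match so "ribosomal protein L2" does not
        # also match L23/L29 products
        return any(
            re.search(rf"(?<!\w){re.escape(pat)}(?!\w)", product, re.IGNORECASE)
            for pat in self.name_patterns
        )


def load_core_catalog(path=None) -> list[CoreFunction]:
    """Load a core-function catalog TSV; default is the shipped catalog."""
    if path is None:
        text = resources.files("annotqc.data").joinpath("core_functions.tsv").read_text()
    else:
        text = Path(path).read_text()
    catalog = []
    header: Optional[list[str]] = None
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cells = line.rstrip("\n").split("\t")
        if header is None:
            header = cells
            continue
        row = dict(zip(header, cells))
        catalog.append(CoreFunction(
            function_id=row["function_id"],
            display_name=row["display_name"],
            name_patterns=tuple(p.strip() for p in row["patterns"].split("|") if p.strip()),
            additions=int(row.get("additions", 0) or 0),
            expected_avg_len_aa=float(row["expected_len_aa"]) if row.get("expected_len_aa") else None,
            len_sd=float(row["len_sd"]) if row.get("len_sd") else None,
        ))
    if not catalog:
        raise ValueError("core-function catalog is empty")
    ids = [c.function_id for c in catalog]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate function_id in core catalog")
    return catalog


def extended_catalog_path() -> Path:
    return Path(str(resources.files("annotqc.data").joinpath("core_functions_extended.tsv")))


@dataclass
class StandardCheck:
    """Outcome of one minimal-standard check."""

    check_id: str
    status: str
    detail: str = ""
    missing_items: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.check_id not in CHECK_IDS:
            raise ValueError(f"unknown check id {self.check_id!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


@dataclass
class ComplianceReport:
    """Per-genome aggregation of checks and findings with an overall verdict."""

    genome: str
    checks: list[StandardCheck]
    findings: list[Finding]
    metrics: Optional[MetricsRow] = None

    @property
    def overall(self) -> str:
        has_fail = any(c.status == "FAIL" for c in self.checks)
        has_error = any(f.severity == "ERROR" for f in self.findings)
        if has_fail or has_error:
            return "NONCOMPLIANT"
        if any(c.status == "EXEMPT" for c in self.checks):
            return "COMPLIANT_WITH_EXEMPTIONS"
        return "COMPLIANT"

    def check(self, check_id: str) -> StandardCheck:
        for c in self.checks:
            if c.check_id == check_id:
                return c
        raise KeyError(check_id)

    def to_text(self) -> str:
        lines = [f"Genome: {self.genome}", f"Overall: {self.overall}", "", "Checks:"]
        for c in self.checks:
            extra = f" missing={','.join(c.missing_items)}" if c.missing_items else ""
            lines.append(f"  {c.check_id:20s} {c.status:7s} {c.detail}{extra}")
        lines.append("")
        lines.append(f"Findings: {len(self.findings)}")
        for f in sorted(self.findings, key=lambda x: (x.severity, x.rule_id)):
            lines.append(f"  [{f.severity}] {f.rule_id} {f.feature_handle}: {f.message}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# individual checks
# ---------------------------------------------------------------------------

_RRNA_PATTERNS = {
    "5S": re.compile(r"\b5S\b", re.IGNORECASE),
    "16S": re.compile(r"\b16S\b|small\s+subunit\s+ribosomal", re.IGNORECASE),
    "23S": re.compile(r"\b23S\b|large\s+subunit\s+ribosomal", re.IGNORECASE),
}


def classify_rrna(product: Optional[str]) -> Optional[str]:
    if not product:
        return None
    for cls, pat in _RRNA_PATTERNS.items():
        if pat.search(product):
            return cls
    return None


def check_rrna_set(record: GenomeRecord) -> StandardCheck:
    """At least one each of 5S, 16S and 23S rRNA, as functional features."""
    functional: set[str] = set()
    pseudo_only: set[str] = set()
    unclassified = 0
    for rep, feat in record.iter_features():
        if feat.key != "rRNA":
            continue
        cls = classify_rrna(feat.product)
        if cls is None:
            unclassified += 1
            continue
        if feat.is_pseudo:
            pseudo_only.add(cls)
        else:
            functional.add(cls)
    pseudo_only -= functional
    missing = [c for c in ("5S", "16S", "23S") if c not in functional and c not in pseudo_only]
    detail_bits = []
    if unclassified:
        detail_bits.append(f"{unclassified} rRNA feature(s) with unclassifiable product")
    if missing:
        return StandardCheck("RRNA_SET", "FAIL",
                             "missing ribosomal RNA class(es); " + "; ".join(detail_bits),
                             missing_items=missing)
    if pseudo_only:
        return StandardCheck("RRNA_SET", "WARN",
                             f"present only as pseudogene: {sorted(pseudo_only)}",
                             missing_items=sorted(pseudo_only))
    return StandardCheck("RRNA_SET", "PASS", "5S, 16S and 23S rRNA all present")


def check_trna_set(record: GenomeRecord) -> StandardCheck:
    """At least one functional tRNA per standard amino acid."""
    from .metrics import amino_acids_with_trna

    _, functional, pseudo, _ = amino_acids_with_trna(record)
    missing = [aa for aa in STANDARD_AMINO_ACIDS if aa not in functional]
    pseudo_covered = [aa for aa in missing if aa in pseudo]
    hard_missing = [aa for aa in missing if aa not in pseudo]
    if hard_missing:
        return StandardCheck("TRNA_SET", "FAIL",
                             "missing tRNA for standard amino acid(s)",
                             missing_items=hard_missing)
    if pseudo_covered:
        return StandardCheck("TRNA_SET", "WARN",
                             f"covered only by pseudo-tRNA: {pseudo_covered}",
                             missing_items=pseudo_covered)
    return StandardCheck("TRNA_SET", "PASS", "all 20 standard amino acids covered")


def check_core_functions(record: GenomeRecord, catalog: Optional[list[CoreFunction]] = None,
                         config: Optional[QCConfig] = None) -> tuple[StandardCheck, list[Finding]]:
    """Every cataloged core function must be annotated on some protein.

    A core function matched only by a pseudogene product/note downgrades to
    WARN for that item; a matched protein whose length is far outside the
    expected range for the function yields an advisory finding.
    """
    config = config or QCConfig()
    catalog = catalog if catalog is not None else load_core_catalog(config.catalog_path)
    if not catalog:
        raise ValueError("empty core-function catalog")
    findings: list[Finding] = []
    missing: list[str] = []
    pseudo_only: list[str] = []
    for func in catalog:
        found = False
        found_pseudo = False
        for rep, feat in record.iter_features():
            if feat.key != "CDS":
                continue
            texts = [feat.product or ""]
            if feat.is_pseudo:
                texts.extend(v or "" for v in feat.get_all("note"))
            if not any(func.matches(t) for t in texts if t):
                continue
            if feat.is_pseudo:
                found_pseudo = True
                continue
            found = True
            if func.expected_avg_len_aa and func.len_sd:
                length = protein_length_aa(feat)
                spread = config.core_length_sd_multiplier * func.len_sd
                if abs(length - func.expected_avg_len_aa) > spread:
                    findings.append(Finding(
                        rule_id="CORE001", severity="INFO", replicon=rep.name,
                        feature_handle=feat.handle(rep.name),
                        message=(f"{func.display_name}: length {length} aa outside "
                                 f"expected {func.expected_avg_len_aa}+/-{spread:.1f}"),
                    ))
        if not found:
            if found_pseudo:
                pseudo_only.append(func.display_name)
            else:
                missing.append(func.display_name)
    if missing:
        return StandardCheck("CORE_FUNCS", "FAIL", "core function(s) not annotated",
                             missing_items=missing), findings
    if pseudo_only:
        return StandardCheck("CORE_FUNCS", "WARN",
                             "core function(s) present only as pseudogene",
                             missing_items=pseudo_only), findings
    return StandardCheck("CORE_FUNCS", "PASS",
                         f"all {len(catalog)} core functions annotated"), findings


def check_density_and_names(metrics: MetricsRow, config: Optional[QCConfig] = None
                            ) -> list[StandardCheck]:
    """Coding density within expected bounds; not everything hypothetical."""
    config = config or QCConfig()
    checks = []
    d = metrics.coding_density
    if d is None:
        checks.append(StandardCheck("DENSITY", "WARN", "coding density not computable"))
    elif d < config.density_lo or d > config.density_hi:
        checks.append(StandardCheck(
            "DENSITY", "WARN",
            f"coding density {d:.2f} proteins/kbp outside expected "
            f"[{config.density_lo}, {config.density_hi}]"))
    else:
        checks.append(StandardCheck("DENSITY", "PASS",
                                    f"coding density {d:.2f} proteins/kbp"))
    ratio = metrics.hypothetical_ratio
    if ratio is None:
        checks.append(StandardCheck("HYPOTHETICAL_RATIO", "WARN",
                                    "no proteins; hypothetical ratio undefined"))
    elif ratio >= config.hypothetical_fail_ratio:
        checks.append(StandardCheck(
            "HYPOTHETICAL_RATIO", "FAIL",
            f"hypothetical ratio {ratio:.2f} at or near 1: essentially every "
            "protein is unannotated"))
    elif ratio >= config.hypothetical_warn_ratio:
        checks.append(StandardCheck("HYPOTHETICAL_RATIO", "WARN",
                                    f"hypothetical ratio {ratio:.2f} is high"))
    else:
        checks.append(StandardCheck("HYPOTHETICAL_RATIO", "PASS",
                                    f"hypothetical ratio {ratio:.2f}"))
    return checks


# ---------------------------------------------------------------------------
# exceptions and evaluation
# ---------------------------------------------------------------------------

_EXCEPTION_RE = re.compile(
    r"annotation-exception:\s*([A-Z_]+)\s*:\s*(.+)", re.IGNORECASE)


def documented_exceptions(record: GenomeRecord) -> dict[str, str]:
    """Collect 'annotation-exception: CHECK_ID: reason' notes on the record."""
    out: dict[str, str] = {}

    def scan(text: str) -> None:
        for m in _EXCEPTION_RE.finditer(text):
            check_id = m.group(1).upper()
            if check_id in CHECK_IDS:
                out[check_id] = m.group(2).strip()

    if record.structured_comment:
        for block in record.structured_comment.values():
            for value in block.values():
                scan(value)
    for _, feat in record.iter_features():
        for note in feat.get_all("note"):
            if note:
                scan(note)
    return out


def _derived_checks(findings: list[Finding]) -> list[StandardCheck]:
    by_rule: dict[str, int] = {}
    for f in findings:
        by_rule[f.rule_id] = by_rule.get(f.rule_id, 0) + 1

    def any_of(*rules):
        return [r for r in rules if by_rule.get(r)]

    checks = []
    lt_fail = any_of("LT001", "LT002")
    lt_warn = any_of("LT003", "LT004")
    if lt_fail:
        checks.append(StandardCheck("LOCUS_TAGS", "FAIL",
                                    f"locus_tag rule violations: {lt_fail}"))
    elif lt_warn:
        checks.append(StandardCheck("LOCUS_TAGS", "WARN",
                                    f"locus_tag guideline issues: {lt_warn}"))
    else:
        checks.append(StandardCheck("LOCUS_TAGS", "PASS", "locus_tags clean"))

    ps_fail = any_of("PSEUDO001", "PSEUDO003")
    ps_warn = any_of("PSEUDO002", "PSEUDO004")
    if ps_fail:
        checks.append(StandardCheck("PSEUDO_FORMAT", "FAIL",
                                    f"pseudogene format violations: {ps_fail}"))
    elif ps_warn:
        checks.append(StandardCheck("PSEUDO_FORMAT", "WARN",
                                    f"pseudogene format issues: {ps_warn}"))
    else:
        checks.append(StandardCheck("PSEUDO_FORMAT", "PASS", "pseudogene formats clean"))

    errors = [f.rule_id for f in findings if f.severity == "ERROR"]
    fails = [f.rule_id for f in findings if f.severity == "FAIL"]
    warns = [f.rule_id for f in findings if f.severity == "WARN"]
    if errors or fails:
        checks.append(StandardCheck("VALIDATION_CLEAN", "FAIL",
                                    f"validation errors: {sorted(set(errors + fails))}"))
    elif warns:
        checks.append(StandardCheck("VALIDATION_CLEAN", "WARN",
                                    f"validation warnings: {sorted(set(warns))}"))
    else:
        checks.append(StandardCheck("VALIDATION_CLEAN", "PASS", "no validation findings"))
    return checks


def evaluate(record: GenomeRecord, config: Optional[QCConfig] = None,
             catalog: Optional[list[CoreFunction]] = None) -> ComplianceReport:
    """Run metrics, all standards checks and the lint engine on one genome.

    Deterministic and pure: the same record and configuration always yield
    the identical report.  Documented exceptions flip a FAIL on the named
    check to EXEMPT.
    """
    config = config or QCConfig()
    metrics = compute_metrics(record, config)
    findings: list[Finding] = list(record.parse_findings)
    findings.extend(metrics.findings)
    core_check, core_findings = check_core_functions(record, catalog, config)
    findings.extend(core_findings)
    lint_findings = lint_record(record, config)
    findings.extend(lint_findings)

    checks = [
        check_rrna_set(record),
        check_trna_set(record),
        core_check,
        *check_density_and_names(metrics, config),
        *_derived_checks(lint_findings),
    ]

    exceptions = documented_exceptions(record)
    for i, c in enumerate(checks):
        if c.status == "FAIL" and c.check_id in exceptions:
            checks[i] = StandardCheck(
                c.check_id, "EXEMPT",
                f"documented exception: {exceptions[c.check_id]} (was: {c.detail})",
                missing_items=c.missing_items,
            )

    genome = record.organism or record.replicons[0].name
    return ComplianceReport(genome=genome, checks=checks, findings=findings,
                            metrics=metrics)
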