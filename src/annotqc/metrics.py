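"""Annotation-report measures for one genome.

These are the quantitative measures a submitter sees in an annotation
report: replicon count, genome length, GC%, protein and RNA counts, tRNA
isoacceptor coverage, hypothetical-protein count, coding density
(proteins per kbp), protein length statistics, the short-protein ratio and
the standard (ATG) start-codon percentage.

Report rounding follows the published presentation: half-away-from-zero,
two decimals for percentages and density, nearest integer for the average
protein length.  Raw (unrounded) values are retained on the row.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

from .config import QCConfig, STANDARD_AMINO_ACIDS, EXTRA_TRNA_TOKENS, normalize_name
from .records import (
    Feature,
    GenomeRecord,
    SequenceUnavailableError,
    extract_feature_seq,
)


def round_report(value: float, decimals: int = 2) -> float:
    """Half-away-from-zero rounding used for report presentation."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MetricsRow:
    """The measure vector for one genome (raw values plus findings)."""

    organism: str = ""
    replicon_count: int = 0
    total_length_bp: int = 0
    gc_percent: Optional[float] = None
    protein_count: int = 0
    rna_count: int = 0
    trna_aa_count: int = 0
    trna_aa_set: frozenset = frozenset()
    pseudo_trna_aa_set: frozenset = frozenset()
    hypothetical_count: int = 0
    coding_density: Optional[float] = None
    avg_protein_len_aa: Optional[float] = None
    min_protein_len_aa: Optional[int] = None
    short_protein_percent: Optional[float] = None
    standard_start_percent: Optional[float] = None
    findings: list = field(default_factory=list, compare=False, repr=False)

    @property
    def total_length_mbp(self) -> float:
        return self.total_length_bp / 1e6

    @property
    def hypothetical_ratio(self) -> Optional[float]:
        if self.protein_count == 0:
            return None
        return self.hypothetical_count / self.protein_count

    TSV_COLUMNS = (
        "organism", "replicon_count", "total_length_mbp", "gc_percent",
        "protein_count", "rna_count", "trna_aa_count", "hypothetical_count",
        "coding_density", "avg_protein_len_aa", "min_protein_len_aa",
        "short_protein_percent", "standard_start_percent",
    )

    def to_tsv_row(self) -> list[str]:
        def fmt(name):
            v = getattr(self, name)
            if v is None:
                return "NA"
            if name == "total_length_mbp":
                return f"{round_report(v, 3):.3f}"
            if name == "avg_protein_len_aa":
                return str(int(round_report(v, 0)))
            if name in ("gc_percent", "coding_density", "short_protein_percent",
                        "standard_start_percent"):
                return f"{round_report(v, 2):.2f}"
            return str(v)

        return [fmt(c) for c in self.TSV_COLUMNS]


def coding_density(protein_count: int, total_length_kbp: float) -> float:
    """Protein-coding genes per kilobase (raw; round with :func:`round_report`)."""
    if total_length_kbp <= 0:
        raise ValueError("total length must be positive")
    if protein_count < 0:
        raise ValueError("protein count must be non-negative")
    return protein_count / total_length_kbp


def gc_percent(seqs) -> float:
    """Pooled GC% over one or more sequences; ambiguity codes are excluded
    from both numerator and denominator."""
    counts: Counter = Counter()
    for seq in seqs:
        counts.update(seq.upper())
    unambiguous = sum(counts[b] for b in "ACGT")
    if unambiguous == 0:
        raise ValueError("no unambiguous bases in input")
    return 100.0 * (counts["G"] + counts["C"]) / unambiguous


def is_protein_cds(feat: Feature) -> bool:
    """CDS features that yield a protein product: non-pseudo CDS, including
    those rescued via /exception or /artificial_location."""
    return feat.key == "CDS" and not feat.is_pseudo


def protein_length_aa(feat: Feature) -> int:
    """Protein length in aa: /translation length when present (the archived
    record is authoritative), else span/3 minus the stop codon."""
    transl = feat.get("translation")
    if transl:
        return len(transl)
    codons = feat.location.span // 3
    if feat.location.partial3:
        return codons
    return max(codons - 1, 0)


@dataclass
class ProteinStats:
    count: int
    avg_len: Optional[float]
    min_len: Optional[int]
    short_percent: Optional[float]
    lengths: list[int] = field(default_factory=list, repr=False)


def protein_stats(record: GenomeRecord, short_threshold_aa: int = 150) -> tuple[ProteinStats, list]:
    """Protein count and length statistics; absent (None) when no proteins."""
    from .lint import Finding

    findings = []
    lengths = []
    for rep, feat in record.iter_features():
        if is_protein_cds(feat):
            lengths.append(protein_length_aa(feat))
    if not lengths:
        findings.append(
            Finding(rule_id="MET001", severity="WARN", replicon="", feature_handle="",
                    message="no protein-coding (CDS) features annotated")
        )
        return ProteinStats(0, None, None, None), findings
    short = sum(1 for x in lengths if x < short_threshold_aa)
    stats = ProteinStats(
        count=len(lengths),
        avg_len=sum(lengths) / len(lengths),
        min_len=min(lengths),
        short_percent=100.0 * short / len(lengths),
        lengths=lengths,
    )
    return stats, findings


_TRNA_PRODUCT_RE = re.compile(r"^tRNA-([A-Za-z0-9]+)", re.IGNORECASE)

_TOKEN_LOOKUP = {t.casefold(): t for t in STANDARD_AMINO_ACIDS + EXTRA_TRNA_TOKENS}


def trna_amino_acid_token(product: Optional[str]) -> Optional[str]:
    """Parse the amino-acid token from a tRNA /product such as 'tRNA-Ala'.

    Returns the canonical token, OTHER for unrecognised isoacceptors, or
    None when the product does not look like a tRNA name at all.
    """
    if not product:
        return None
    m = _TRNA_PRODUCT_RE.match(product.strip())
    if not m:
        return None
    return _TOKEN_LOOKUP.get(m.group(1).casefold(), "OTHER")


def rna_count(record: GenomeRecord, config: Optional[QCConfig] = None) -> int:
    """Count of RNA features (transfer, ribosomal, non-coding, tmRNA)."""
    config = config or QCConfig()
    keys = set(config.effective_rna_keys)
    return sum(1 for _, f in record.iter_features() if f.key in keys)


def amino_acids_with_trna(record: GenomeRecord) -> tuple[int, frozenset, frozenset, list]:
    """Isoacceptor coverage: (count, functional set, pseudo-only set, findings).

    The functional set contains tokens covered by at least one non-pseudo
    tRNA; pseudo-tRNA coverage is returned separately so completeness checks
    can downgrade rather than pass.
    """
    from .lint import Finding

    findings = []
    functional: set[str] = set()
    pseudo: set[str] = set()
    for rep, feat in record.iter_features():
        if feat.key != "tRNA":
            continue
        token = trna_amino_acid_token(feat.product)
        if token is None:
            token = "OTHER"
            findings.append(
                Finding(rule_id="MET002", severity="WARN", replicon=rep.name,
                        feature_handle=feat.handle(rep.name),
                        message=f"unparseable tRNA product {feat.product!r}; counted as OTHER")
            )
        if feat.is_pseudo:
            pseudo.add(token)
        else:
            functional.add(token)
    return len(functional), frozenset(functional), frozenset(pseudo), findings


def hypothetical_count(record: GenomeRecord, config: Optional[QCConfig] = None) -> tuple[int, list]:
    """Count non-pseudo CDS whose normalized /product is a hypothetical-name.

    A CDS lacking /product counts as hypothetical and is reported (NAME006).
    """
    from .lint import Finding

    config = config or QCConfig()
    name_set = {normalize_name(n) for n in config.hypothetical_names}
    findings = []
    count = 0
    for rep, feat in record.iter_features():
        if not is_protein_cds(feat):
            continue
        product = feat.product
        if product is None or not product.strip():
            count += 1
            findings.append(
                Finding(rule_id="NAME006", severity="WARN", replicon=rep.name,
                        feature_handle=feat.handle(rep.name),
                        message="CDS lacks a /product name; counted as hypothetical")
            )
        elif normalize_name(product) in name_set:
            count += 1
    return count, findings


def standard_start_percent(record: GenomeRecord, config: Optional[QCConfig] = None) -> Optional[float]:
    """Percentage of 5'-complete, non-pseudo CDS starting with ATG.

    5'-partial CDS are excluded from numerator and denominator.  Raises
    :class:`SequenceUnavailableError` when the record has no sequence.
    """
    eligible = 0
    standard = 0
    for rep, feat in record.iter_features():
        if not is_protein_cds(feat) or feat.location.partial5:
            continue
        if not rep.has_sequence:
            raise SequenceUnavailableError(
                f"replicon {rep.name} has no sequence; cannot inspect start codons"
            )
        start = extract_feature_seq(rep, feat.location)[:3]
        eligible += 1
        if start == "ATG":
            standard += 1
    if eligible == 0:
        return None
    return 100.0 * standard / eligible


def compute_metrics(record: GenomeRecord, config: Optional[QCConfig] = None) -> MetricsRow:
    """Assemble the full measure vector for one genome.

    Sequence-dependent fields (GC%, start-codon%) are left None with a WARN
    finding when the record carries no sequence; everything else is filled.
    """
    from .lint import Finding

    config = config or QCConfig()
    row = MetricsRow(
        organism=record.organism,
        replicon_count=len(record.replicons),
        total_length_bp=record.total_length,
    )
    stats, findings = protein_stats(record, config.short_protein_aa)
    row.protein_count = stats.count
    row.avg_protein_len_aa = stats.avg_len
    row.min_protein_len_aa = stats.min_len
    row.short_protein_percent = stats.short_percent
    row.findings.extend(findings)

    row.rna_count = rna_count(record, config)
    n_aa, aa_set, pseudo_set, trna_findings = amino_acids_with_trna(record)
    row.trna_aa_count = n_aa
    row.trna_aa_set = aa_set
    row.pseudo_trna_aa_set = pseudo_set
    row.findings.extend(trna_findings)

    hyp, hyp_findings = hypothetical_count(record, config)
    row.hypothetical_count = hyp
    row.findings.extend(hyp_findings)

    if record.total_length > 0:
        row.coding_density = coding_density(stats.count, record.total_length / 1000.0)

    if record.has_sequence and record.total_length > 0:
        row.gc_percent = gc_percent(r.sequence for r in record.replicons)
        row.standard_start_percent = standard_start_percent(record, config)
    else:
        row.findings.append(
            Finding(rule_id="MET003", severity="WARN", replicon="", feature_handle="",
                    message="sequence unavailable: GC% and start-codon% not computed")
        )
    return row


def metrics_tsv(rows: list[MetricsRow]) -> str:
    """Serialize measure rows as a TSV table in report column order."""
    lines = ["\t".join(MetricsRow.TSV_COLUMNS)]
    for row in rows:
        lines.append("\t".join(row.to_tsv_row()))
    return "\n".join(lines) + "\n"
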