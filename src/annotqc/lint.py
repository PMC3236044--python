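"""Per-feature INSDC convention lint: naming, evidence, pseudogenes,
locus_tags and feature structure.

Every outcome is a :class:`Finding` on a fixed severity scale:

* ``ERROR`` - violates an INSDC prohibition; the record is unsubmittable
  (e.g. a translated product on a /pseudo feature).
* ``FAIL``  - violates an accepted standard (banned protein names,
  duplicate locus_tags, missing mandatory evidence).
* ``WARN``  - outside guideline but tolerated.
* ``INFO``  - advisory only.

The rule catalog below is the single registry; every rule the engine can
emit is listed there with its default severity and a one-line description.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .config import QCConfig, ACCEPTED_UNKNOWN_NAMES, normalize_name
from .records import (
    Feature,
    GenomeRecord,
    InternalStopError,
    Replicon,
    TranslationError,
    extract_feature_seq,
    feature_transl_table,
    translate_cds,
)

SEVERITIES = ("ERROR", "FAIL", "WARN", "INFO")


@dataclass(frozen=True)
class Finding:
    """One validation result."""

    rule_id: str
    severity: str
    replicon: str
    feature_handle: str
    message: str
    suggestion: Optional[str] = None

    def __post_init__(self) -> None:
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")

    def to_tsv_row(self) -> list[str]:
        return [self.rule_id, self.severity, self.replicon, self.feature_handle,
                self.message, self.suggestion or ""]


#: rule_id -> (default severity, description)
RULE_CATALOG: dict[str, tuple[str, str]] = {
    "NAME001": ("FAIL", "banned unknown-function synonym; only 'hypothetical protein' or 'uncharacterized protein' are acceptable"),
    "NAME002": ("WARN", "leading/trailing/multiple whitespace in protein name"),
    "NAME003": ("WARN", "protein name is all-uppercase (style rule, off by default)"),
    "NAME004": ("WARN", "protein name carries a vague style qualifier such as 'homolog' or 'fragment' (style rule, off by default)"),
    "NAME005": ("WARN", "protein name is a bare locus_tag / ORF identifier"),
    "NAME006": ("WARN", "CDS lacks a /product name"),
    "EV001": ("FAIL", "unknown /inference category or evidence type"),
    "EV002": ("WARN", "/inference type requires an evidence basis but none given"),
    "EV003": ("FAIL", "/experiment category token with empty description"),
    "PSEUDO001": ("ERROR", "/pseudo feature carries /translation or /protein_id (translated products are not allowed on pseudogenes)"),
    "PSEUDO002": ("WARN", "/pseudo CDS carries /product (product name belongs in /note)"),
    "PSEUDO003": ("FAIL", "CDS with /exception='annotated by transcript or proteomic data' lacks both /experiment and /inference"),
    "PSEUDO004": ("WARN", "/artificial_location CDS product not prefaced with 'LOW-QUALITY PROTEIN:'"),
    "PSEUDO005": ("INFO", "similarity-region misc_feature carries /locus_tag or /gene (should have neither)"),
    "PSEUDO006": ("INFO", "/pseudogene qualifier accepted as /pseudo synonym (INSDC split proposal pending)"),
    "LT001": ("FAIL", "duplicate locus_tag on distinct loci"),
    "LT002": ("FAIL", "more than one locus_tag prefix in one genome"),
    "LT003": ("WARN", "locus_tag does not match registry syntax (letter start, alphanumeric prefix of >=3, single underscore)"),
    "LT004": ("WARN", "gene/CDS/tRNA/rRNA feature lacks /locus_tag"),
    "STRUCT001": ("WARN", "CDS without a same-range gene feature"),
    "STRUCT002": ("ERROR", "computed translation conflicts with /translation"),
    "STRUCT003": ("WARN", "CDS span not divisible by 3 without partial markers or /exception"),
    "STRUCT004": ("INFO", "structured metadata comment block absent"),
    "STRUCT005": ("WARN", "missing BioProject identifier"),
    "FMT001": ("INFO", "unknown feature key retained verbatim"),
    "MET001": ("WARN", "no protein-coding features annotated"),
    "MET002": ("WARN", "unparseable tRNA product"),
    "MET003": ("WARN", "sequence unavailable for sequence-dependent measures"),
    "CORE001": ("INFO", "core-function protein length far outside the expected range for the function"),
    "OUT001": ("WARN", "genome measure is a cross-genome outlier (|z| above threshold)"),
}


def _finding(rule_id: str, replicon: str, handle: str, message: str,
             suggestion: Optional[str] = None) -> Finding:
    severity = RULE_CATALOG[rule_id][0]
    return Finding(rule_id, severity, replicon, handle, message, suggestion)


# ---------------------------------------------------------------------------
# protein naming
# ---------------------------------------------------------------------------

_LOCUS_LIKE_RE = re.compile(r"^(?:[A-Za-z][A-Za-z0-9]{2,}_[A-Za-z0-9]+|ORF\s*\d+)$")


def lint_protein_name(name: str, config: Optional[QCConfig] = None,
                      replicon: str = "", handle: str = "") -> list[Finding]:
    """Check one protein /product value against the naming standards.

    The two accepted unknown-function names pass untouched; the banned
    synonyms get a FAIL with the replacement suggestion.  Style rules beyond
    the accepted standards (case, 'homolog', ...) are off unless enabled in
    the configuration.
    """
    config = config or QCConfig()
    findings: list[Finding] = []
    norm = normalize_name(name)
    if norm in ACCEPTED_UNKNOWN_NAMES:
        pass
    elif norm in {normalize_name(b) for b in config.banned_unknown_names}:
        findings.append(_finding(
            "NAME001", replicon, handle,
            f"name {name!r} is no longer acceptable for unknown-function proteins",
            suggestion="hypothetical protein",
        ))
    if name != " ".join(name.split()):
        findings.append(_finding(
            "NAME002", replicon, handle,
            f"irregular whitespace in name {name!r}",
            suggestion=" ".join(name.split()),
        ))
    if _LOCUS_LIKE_RE.match(name.strip()):
        findings.append(_finding(
            "NAME005", replicon, handle,
            f"name {name!r} looks like a locus_tag or ORF identifier, not a product name",
        ))
    if config.style_name_rules:
        letters = [c for c in name if c.isalpha()]
        if letters and all(c.isupper() for c in letters) and len(letters) > 3:
            findings.append(_finding("NAME003", replicon, handle,
                                     f"name {name!r} is all-uppercase"))
        lowered = norm
        for word in config.style_words:
            if re.search(rf"\b{word}\b", lowered):
                findings.append(_finding(
                    "NAME004", replicon, handle,
                    f"name {name!r} carries vague qualifier {word!r}",
                ))
                break
    return findings


# ---------------------------------------------------------------------------
# structured evidence (/inference, /experiment)
# ---------------------------------------------------------------------------

EVIDENCE_CATEGORIES = ("EXISTENCE", "COORDINATES", "DESCRIPTION")

#: canonical /inference evidence types (INSDC-refined vocabulary)
INFERENCE_TYPES = (
    "non-experimental evidence, no additional details recorded",
    "similar to sequence",
    "similar to AA sequence",
    "similar to DNA sequence",
    "similar to RNA sequence",
    "similar to RNA sequence, mRNA",
    "similar to RNA sequence, EST",
    "similar to RNA sequence, other RNA",
    "profile",
    "nucleotide motif",
    "protein motif",
    "ab initio prediction",
    "alignment",
)

#: types for which an evidence basis (algorithm/database + version/accession)
#: is expected
_TYPES_NEEDING_BASIS = tuple(
    t for t in INFERENCE_TYPES if t.startswith("similar to") or t in
    ("profile", "nucleotide motif", "protein motif", "ab initio prediction", "alignment")
)


def _canon_type(raw: str) -> Optional[str]:
    norm = " ".join(raw.replace("-", " ").split()).casefold()
    for t in INFERENCE_TYPES:
        if " ".join(t.replace("-", " ").split()).casefold() == norm:
            return t
    if norm in ("non experimental", "non experimental evidence"):
        return INFERENCE_TYPES[0]
    return None


@dataclass
class InferenceEvidence:
    """Parsed /inference qualifier: category, type, same-species flag, basis."""

    type: str
    category: Optional[str] = None
    same_species: bool = False
    basis: list[tuple[str, Optional[str]]] = field(default_factory=list)

    def render(self) -> str:
        parts = []
        if self.category:
            parts.append(f"{self.category}: ")
        parts.append(self.type)
        if self.same_species:
            parts.append(" (same species)")
        for source, version in self.basis:
            parts.append(f":{source}")
            if version is not None:
                parts.append(f":{version}")
        return "".join(parts)


def parse_inference(raw: str, replicon: str = "", handle: str = ""
                    ) -> tuple[Optional[InferenceEvidence], list[Finding]]:
    """Parse an /inference value; grammar problems come back as Findings.

    Grammar: ``[CATEGORY: ] type [(same species)] [:source[:version]]...``.
    ``render(parse(x))`` is the canonical form of ``x``.
    """
    findings: list[Finding] = []
    text = raw.strip()
    if not text:
        findings.append(_finding("EV001", replicon, handle, "empty /inference value"))
        return None, findings
    category = None
    head, sep, rest = text.partition(":")
    if sep and head.strip().upper() in EVIDENCE_CATEGORIES:
        category = head.strip().upper()
        text = rest.strip()
    # longest canonical type matching the head of the remaining text
    matched_type = None
    remainder = ""
    for t in sorted(INFERENCE_TYPES, key=len, reverse=True):
        pattern = re.escape(t).replace(r"\ ", r"[\s\-]+")
        m = re.match(pattern, text, flags=re.IGNORECASE)
        if m:
            matched_type = t
            remainder = text[m.end():]
            break
    if matched_type is None:
        # try the loose "non experimental" synonym before giving up
        head2 = text.split(":", 1)[0]
        canon = _canon_type(head2)
        if canon:
            matched_type = canon
            remainder = text[len(head2):]
    if matched_type is None:
        offending = text.split(":", 1)[0].strip()
        findings.append(_finding(
            "EV001", replicon, handle,
            f"unknown inference type {offending!r}",
        ))
        return None, findings
    remainder = remainder.strip()
    same_species = False
    m = re.match(r"\(\s*same\s+species\s*\)", remainder, flags=re.IGNORECASE)
    if m:
        same_species = True
        remainder = remainder[m.end():].strip()
    basis: list[tuple[str, Optional[str]]] = []
    if remainder.startswith(":"):
        tokens = [t.strip() for t in remainder[1:].split(":")]
        tokens = [t for t in tokens if t]
        for i in range(0, len(tokens), 2):
            source = tokens[i]
            version = tokens[i + 1] if i + 1 < len(tokens) else None
            basis.append((source, version))
    elif remainder:
        findings.append(_finding(
            "EV001", replicon, handle,
            f"unparseable trailing inference text {remainder!r}",
        ))
        return None, findings
    evidence = InferenceEvidence(type=matched_type, category=category,
                                 same_species=same_species, basis=basis)
    if not basis and matched_type in _TYPES_NEEDING_BASIS:
        findings.append(_finding(
            "EV002", replicon, handle,
            f"inference type {matched_type!r} given without an evidence basis",
        ))
    return evidence, findings


@dataclass
class ExperimentEvidence:
    """Parsed /experiment qualifier: category, free-text description, citation."""

    description: str
    category: Optional[str] = None
    citation: Optional[str] = None

    def render(self) -> str:
        parts = []
        if self.category:
            parts.append(f"{self.category}: ")
        parts.append(self.description)
        if self.citation:
            parts.append(f" [{self.citation}]")
        return "".join(parts)


_CITATION_RE = re.compile(r"\[\s*(PMID:\s*\d+|doi:\s*\S+?)\s*\]\s*$", re.IGNORECASE)


def parse_experiment(raw: str, replicon: str = "", handle: str = ""
                     ) -> tuple[Optional[ExperimentEvidence], list[Finding]]:
    """Parse an /experiment value: optional category prefix, free-text
    description, optional trailing bracketed PMID/DOI citation."""
    findings: list[Finding] = []
    text = raw.strip()
    category = None
    head, sep, rest = text.partition(":")
    if sep and head.strip().upper() in EVIDENCE_CATEGORIES:
        category = head.strip().upper()
        text = rest.strip()
    citation = None
    m = _CITATION_RE.search(text)
    if m:
        citation = re.sub(r"\s+", "", m.group(1))
        citation = citation if citation.lower().startswith("doi") is False else "doi:" + citation.split(":", 1)[1]
        if citation.upper().startswith("PMID"):
            citation = "PMID:" + citation.split(":", 1)[1]
        text = text[: m.start()].strip()
    if category and not text:
        findings.append(_finding(
            "EV003", replicon, handle,
            f"/experiment category {category} with empty description",
        ))
        return None, findings
    if not text and not citation:
        findings.append(_finding("EV003", replicon, handle, "empty /experiment value"))
        return None, findings
    return ExperimentEvidence(description=text, category=category, citation=citation), findings


# ---------------------------------------------------------------------------
# pseudogene strategies
# ---------------------------------------------------------------------------

TRANSCRIPT_EXCEPTION = "annotated by transcript or proteomic data"
LOW_QUALITY_PREFIX = "LOW-QUALITY PROTEIN:"

_SIMILARITY_NOTE_RE = re.compile(r"similar(ity)?\s+to|region of similarity", re.IGNORECASE)


def validate_pseudogenes(record: GenomeRecord) -> list[Finding]:
    """Enforce the accepted pseudogene annotation strategies.

    The hard prohibition: no translated product on a /pseudo feature.
    Rescue routes (transcript/proteomic exception, artificial_location)
    must carry their mandated evidence or product prefix.
    """
    findings: list[Finding] = []
    for rep, feat in record.iter_features():
        handle = feat.handle(rep.name)
        if feat.has("pseudogene"):
            findings.append(_finding(
                "PSEUDO006", rep.name, handle,
                "/pseudogene accepted as a synonym of /pseudo; the INSDC split into "
                "/pseudogene + /nonfunctional is still a pending proposal",
            ))
        if feat.is_pseudo:
            if feat.has("translation") or feat.has("protein_id"):
                findings.append(_finding(
                    "PSEUDO001", rep.name, handle,
                    "translated product (/translation or /protein_id) on a pseudogene "
                    "is not allowed",
                ))
            if feat.key == "CDS" and feat.has("product"):
                findings.append(_finding(
                    "PSEUDO002", rep.name, handle,
                    "pseudogene CDS should carry its product name in /note, not /product",
                    suggestion=f"/note=\"{feat.product}\"",
                ))
        if feat.key == "CDS" and not feat.is_pseudo:
            exception = feat.get("exception")
            if exception and normalize_name(exception) == TRANSCRIPT_EXCEPTION:
                if not (feat.has("experiment") or feat.has("inference")):
                    findings.append(_finding(
                        "PSEUDO003", rep.name, handle,
                        "transcript/proteomic-data exception requires /experiment or /inference",
                    ))
            if feat.has("artificial_location"):
                product = feat.product or ""
                if not product.startswith(LOW_QUALITY_PREFIX):
                    findings.append(_finding(
                        "PSEUDO004", rep.name, handle,
                        "artificial_location CDS product must be prefaced with "
                        f"{LOW_QUALITY_PREFIX!r}",
                        suggestion=f"{LOW_QUALITY_PREFIX} {product}".strip(),
                    ))
        if feat.key == "misc_feature":
            note = " ".join(v or "" for v in feat.get_all("note"))
            if _SIMILARITY_NOTE_RE.search(note) and (feat.has("locus_tag") or feat.has("gene")):
                findings.append(_finding(
                    "PSEUDO005", rep.name, handle,
                    "similarity-region misc_feature should carry no gene or locus_tag",
                ))
    return findings


# ---------------------------------------------------------------------------
# locus_tags
# ---------------------------------------------------------------------------

LOCUS_TAG_FEATURE_KEYS = ("gene", "CDS", "tRNA", "rRNA")

_PREFIX_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]{2,}$")


def split_locus_tag(tag: str) -> tuple[Optional[str], str]:
    if tag.count("_") == 1:
        prefix, rest = tag.split("_")
        return prefix, rest
    return None, tag


def validate_locus_tags(record: GenomeRecord) -> list[Finding]:
    """Uniqueness, single registered prefix, and syntax of locus_tags."""
    findings: list[Finding] = []
    tag_loci: dict[str, set] = {}
    tag_handle: dict[str, str] = {}
    prefixes: dict[str, str] = {}
    for rep, feat in record.iter_features():
        handle = feat.handle(rep.name)
        tag = feat.locus_tag
        if tag is None:
            if feat.key in LOCUS_TAG_FEATURE_KEYS:
                findings.append(_finding(
                    "LT004", rep.name, handle,
                    f"{feat.key} feature lacks a /locus_tag",
                ))
            continue
        locus = (rep.name,) + feat.location.range_key()
        tag_loci.setdefault(tag, set()).add(locus)
        tag_handle.setdefault(tag, handle)
        prefix, _ = split_locus_tag(tag)
        if prefix is None or not _PREFIX_RE.match(prefix):
            findings.append(_finding(
                "LT003", rep.name, handle,
                f"locus_tag {tag!r} does not match the registry syntax "
                "(letter start, alphanumeric prefix of length >=3, single underscore)",
            ))
        if prefix is not None:
            prefixes.setdefault(prefix, handle)
    for tag, loci in sorted(tag_loci.items()):
        if len(loci) > 1:
            findings.append(_finding(
                "LT001", "", tag_handle[tag],
                f"locus_tag {tag!r} assigned to {len(loci)} distinct loci",
            ))
    if len(prefixes) > 1:
        findings.append(_finding(
            "LT002", "", "",
            f"multiple locus_tag prefixes in one genome: {sorted(prefixes)}",
        ))
    return findings


# ---------------------------------------------------------------------------
# structural validity
# ---------------------------------------------------------------------------

def _gene_ranges(rep: Replicon) -> set:
    return {f.location.range_key() for f in rep.features if f.key == "gene"}


def validate_structure(record: GenomeRecord, config: Optional[QCConfig] = None) -> list[Finding]:
    """Feature-table validity: gene/CDS pairing, translation consistency,
    frame sanity, metadata presence, unknown feature keys."""
    config = config or QCConfig()
    findings: list[Finding] = []
    from .records import KNOWN_FEATURE_KEYS

    for rep in record.replicons:
        gene_ranges = _gene_ranges(rep)
        for feat in rep.features:
            handle = feat.handle(rep.name)
            if feat.key not in KNOWN_FEATURE_KEYS:
                findings.append(_finding(
                    "FMT001", rep.name, handle,
                    f"unknown feature key {feat.key!r} retained verbatim",
                ))
            if feat.key != "CDS":
                continue
            if feat.location.range_key() not in gene_ranges:
                findings.append(_finding(
                    "STRUCT001", rep.name, handle,
                    "CDS has no gene feature covering the same range",
                ))
            exempt = feat.has("exception") or feat.has("artificial_location") or feat.is_pseudo
            frame_ok = feat.location.span % 3 == 0
            if not frame_ok and not feat.location.is_partial and not exempt:
                findings.append(_finding(
                    "STRUCT003", rep.name, handle,
                    f"CDS span {feat.location.span} not divisible by 3 "
                    "without partial markers or /exception",
                ))
            stored = feat.get("translation")
            if stored and rep.has_sequence and frame_ok and not exempt:
                try:
                    computed = translate_cds(
                        extract_feature_seq(rep, feat.location),
                        transl_table=feature_transl_table(feat, config.transl_table),
                        partial5=feat.location.partial5,
                        partial3=feat.location.partial3,
                    )
                except InternalStopError as err:
                    findings.append(_finding(
                        "STRUCT002", rep.name, handle,
                        f"internal stop codon at codon {err.codon_index} conflicts "
                        "with stored /translation",
                    ))
                    continue
                except TranslationError:
                    continue
                if computed != stored:
                    findings.append(_finding(
                        "STRUCT002", rep.name, handle,
                        "computed translation conflicts with stored /translation",
                    ))
    if not record.structured_comment:
        findings.append(_finding(
            "STRUCT004", "", "",
            "no structured metadata comment block (annotation provenance/SOP)",
        ))
    if not record.bioproject:
        findings.append(_finding(
            "STRUCT005", "", "",
            "record carries no BioProject identifier",
        ))
    return findings


# ---------------------------------------------------------------------------
# whole-record rule engine
# ---------------------------------------------------------------------------

def lint_record(record: GenomeRecord, config: Optional[QCConfig] = None) -> list[Finding]:
    """Run every per-feature rule family over the record.

    The result is order-independent as a multiset: permuting features only
    permutes the findings.
    """
    config = config or QCConfig()
    findings: list[Finding] = []
    for rep, feat in record.iter_features():
        handle = feat.handle(rep.name)
        if feat.key == "CDS" and not feat.is_pseudo:
            product = feat.product
            if product is None or not product.strip():
                findings.append(_finding(
                    "NAME006", rep.name, handle, "CDS lacks a /product name",
                ))
            else:
                findings.extend(lint_protein_name(product, config, rep.name, handle))
        for raw in feat.get_all("inference"):
            if raw is not None:
                findings.extend(parse_inference(raw, rep.name, handle)[1])
        for raw in feat.get_all("experiment"):
            if raw is not None:
                findings.extend(parse_experiment(raw, rep.name, handle)[1])
    findings.extend(validate_pseudogenes(record))
    findings.extend(validate_locus_tags(record))
    findings.extend(validate_structure(record, config))
    return findings


def findings_tsv(findings: list[Finding]) -> str:
    header = ["rule_id", "severity", "replicon", "feature", "message", "suggestion"]
    lines = ["\t".join(header)]
    for f in findings:
        lines.append("\t".join(f.to_tsv_row()))
    return "\n".join(lines) + "\n"
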