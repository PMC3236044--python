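"""Data model for annotated prokaryotic genome records and flat-file I/O.

The in-memory model is deliberately small: a :class:`GenomeRecord` holds one
or more :class:`Replicon` objects (sequence + feature list), each feature a
typed, located annotation with an INSDC-style qualifier multimap.  All
internal coordinates are 0-based half-open; the GenBank/GFF3/.tbl boundary
converts to and from the 1-based inclusive convention of those formats.

GenBank reading and writing is delegated to Biopython; GFF3 reading to
gffutils.  The GFF3 and 5-column feature-table writers are local because no
installed library emits them from an arbitrary in-memory model.
"""

from __future__ import annotations

import io
import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    CompoundLocation,
    ExactPosition,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

FORWARD = 1
REVERSE = -1

#: Feature keys the validator recognises; anything else is retained but
#: reported as an advisory finding (rule FMT001).
KNOWN_FEATURE_KEYS = frozenset(
    {
        "source", "gene", "CDS", "tRNA", "rRNA", "ncRNA", "tmRNA",
        "misc_RNA", "precursor_RNA", "misc_feature", "repeat_region",
        "mobile_element", "regulatory", "rep_origin", "operon",
        "misc_binding", "STS",
    }
)

#: Qualifiers that are bare flags (no value) in the INSDC feature table.
FLAG_QUALIFIERS = frozenset({"pseudo", "artificial_location", "ribosomal_slippage", "trans_splicing"})


class ParseError(ValueError):
    """Raised for malformed input that cannot be represented in the model."""


class SequenceUnavailableError(RuntimeError):
    """A sequence-dependent operation was requested on a sequence-less record."""


class TranslationError(ValueError):
    """Base class for CDS translation problems."""


class InternalStopError(TranslationError):
    def __init__(self, codon_index: int):
        self.codon_index = codon_index
        super().__init__(f"internal stop codon at codon index {codon_index}")


@dataclass(frozen=True)
class Location:
    """A located span: ordered 0-based half-open segments on one strand.

    ``segments`` are kept in the order written in the source location string
    (ascending for ordinary joins; an origin-wrapping location on a circular
    replicon has first-segment start greater than last-segment end).
    ``partial5``/``partial3`` are relative to the strand, i.e. partial5 on the
    reverse strand corresponds to a ``>`` marker on the highest coordinate.
    """

    segments: tuple[tuple[int, int], ...]
    strand: int = FORWARD
    partial5: bool = False
    partial3: bool = False
    operator: str = "join"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("location needs at least one segment")
        for s, e in self.segments:
            if not (0 <= s < e):
                raise ValueError(f"bad segment ({s},{e}): need 0 <= start < end")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError("strand must be +1 or -1")
        if self.operator not in ("join", "order", "single"):
            raise ValueError(f"unknown location operator {self.operator!r}")

    @property
    def span(self) -> int:
        return sum(e - s for s, e in self.segments)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.segments)

    @property
    def end(self) -> int:
        return max(e for _, e in self.segments)

    @property
    def wraps_origin(self) -> bool:
        return len(self.segments) > 1 and self.segments[0][0] > self.segments[-1][1]

    @property
    def is_partial(self) -> bool:
        return self.partial5 or self.partial3

    def range_key(self) -> tuple[int, int, int]:
        """(min start, max end, strand): identity of the gene locus."""
        return (self.start, self.end, self.strand)


def location_to_genbank(loc: Location) -> str:
    """Render a location in GenBank notation (1-based inclusive)."""
    # partial markers sit on the genomic-left of the first written segment
    # and genomic-right of the last, mapped from strand-relative flags.
    if loc.strand == FORWARD:
        left_partial, right_partial = loc.partial5, loc.partial3
    else:
        left_partial, right_partial = loc.partial3, loc.partial5
    parts = []
    for i, (s, e) in enumerate(loc.segments):
        lp = "<" if (left_partial and i == 0) else ""
        rp = ">" if (right_partial and i == len(loc.segments) - 1) else ""
        parts.append(f"{lp}{s + 1}..{rp}{e}")
    if len(parts) == 1:
        body = parts[0]
    else:
        op = "order" if loc.operator == "order" else "join"
        body = f"{op}({','.join(parts)})"
    if loc.strand == REVERSE:
        body = f"complement({body})"
    return body


Qualifiers = dict[str, list[Optional[str]]]


@dataclass
class Feature:
    """One typed annotation: a feature key, a location and a qualifier multimap.

    Flag qualifiers (``/pseudo`` and friends) are stored with value ``None``.
    A qualifier name maps to a list because INSDC allows repetition.
    """

    key: str
    location: Location
    qualifiers: Qualifiers = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.key:
            raise ValueError("feature key must be non-empty")

    def get(self, name: str) -> Optional[str]:
        vals = self.qualifiers.get(name)
        return vals[0] if vals else None

    def get_all(self, name: str) -> list[Optional[str]]:
        return list(self.qualifiers.get(name, []))

    def has(self, name: str) -> bool:
        return name in self.qualifiers

    def add(self, name: str, value: Optional[str] = None) -> None:
        self.qualifiers.setdefault(name, []).append(value)

    def remove(self, name: str) -> None:
        self.qualifiers.pop(name, None)

    @property
    def is_pseudo(self) -> bool:
        # /pseudogene (with a value) is accepted as a synonym of /pseudo;
        # the split of /pseudo into /pseudogene + /nonfunctional is still a
        # pending INSDC proposal and is reported as an advisory elsewhere.
        return self.has("pseudo") or self.has("pseudogene")

    @property
    def locus_tag(self) -> Optional[str]:
        return self.get("locus_tag")

    @property
    def product(self) -> Optional[str]:
        return self.get("product")

    def handle(self, replicon: str = "") -> str:
        parts = [self.key, "@" + replicon if replicon else "", ":", location_to_genbank(self.location)]
        if self.locus_tag:
            parts.append(f" [{self.locus_tag}]")
        return "".join(parts)


@dataclass
class Replicon:
    """One replicon: a named sequence with its feature list."""

    name: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)
    definition: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_sequence(self) -> bool:
        return len(self.sequence) > 0

    def features_of(self, *keys: str) -> list[Feature]:
        want = set(keys)
        return [f for f in self.features if f.key in want]

    def validate_bounds(self, feature: Feature) -> None:
        n = len(self.sequence)
        for s, e in feature.location.segments:
            if e > n:
                if self.topology == "circular":
                    continue
                raise ParseError(
                    f"feature {feature.key} at {location_to_genbank(feature.location)} "
                    f"exceeds linear replicon {self.name} length {n}"
                )
        if feature.location.wraps_origin and self.topology != "circular":
            raise ParseError(
                f"origin-wrapping location on linear replicon {self.name}: "
                f"{location_to_genbank(feature.location)}"
            )


@dataclass
class GenomeRecord:
    """One annotated genome: organism metadata plus its replicons."""

    replicons: list[Replicon]
    organism: str = ""
    bioproject: Optional[str] = None
    structured_comment: Optional[dict[str, dict[str, str]]] = None
    parse_findings: list = field(default_factory=list, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError("a genome record needs at least one replicon")
        names = [r.name for r in self.replicons]
        if len(set(names)) != len(names):
            raise ValueError(f"replicon names not unique: {names}")

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.replicons)

    @property
    def has_sequence(self) -> bool:
        return all(r.has_sequence for r in self.replicons)

    def iter_features(self) -> Iterable[tuple[Replicon, Feature]]:
        for rep in self.replicons:
            for feat in rep.features:
                yield rep, feat


# ---------------------------------------------------------------------------
# sequence extraction and translation
# ---------------------------------------------------------------------------

def extract_feature_seq(replicon: Replicon, location: Location) -> str:
    """Strand-aware, join-aware sequence of ``location`` on ``replicon``.

    Segments are concatenated in written order, then the whole string is
    reverse-complemented for reverse-strand locations.  Segments past the
    replicon end are wrapped modulo the length on circular replicons.
    """
    if not replicon.has_sequence:
        raise SequenceUnavailableError(f"replicon {replicon.name} carries no sequence")
    n = len(replicon.sequence)
    pieces = []
    for s, e in location.segments:
        if e > n:
            if replicon.topology != "circular":
                raise ParseError(f"segment ({s},{e}) out of bounds for linear replicon of length {n}")
            pieces.append(replicon.sequence[s % n :] + replicon.sequence[: e % n])
        else:
            pieces.append(replicon.sequence[s:e])
    seq = "".join(pieces)
    if location.strand == REVERSE:
        seq = str(Seq(seq).reverse_complement())
    return seq


_AMBIGUOUS = set("RYSWKMBDHVN")


def _codon_maps(transl_table: int) -> tuple[dict[str, str], frozenset[str], frozenset[str]]:
    table = CodonTable.unambiguous_dna_by_id[transl_table]
    return dict(table.forward_table), frozenset(table.stop_codons), frozenset(table.start_codons)


def translate_cds(
    nt: str,
    transl_table: int = 11,
    partial5: bool = False,
    partial3: bool = False,
) -> str:
    """Translate a CDS nucleotide string under a genetic-code table.

    The bacterial/archaeal code (table 11) is the default.  A complete 5' end
    renders the initiator codon as ``M`` when it is a valid start codon of the
    table (GTG/TTG initiators included); the trailing stop codon is dropped.
    Codons containing ambiguity codes translate to ``X``.  An in-frame stop
    before the final codon raises :class:`InternalStopError` carrying the
    codon index.
    """
    nt = nt.upper()
    forward, stops, starts = _codon_maps(transl_table)
    rem = len(nt) % 3
    if rem:
        if partial3 and not partial5:
            nt = nt[: len(nt) - rem]
        elif partial5:
            nt = nt[rem:]
        else:
            raise TranslationError(f"length {len(nt)} not a multiple of 3 on a complete CDS")
    if len(nt) < 3:
        raise TranslationError("fewer than one codon after trimming")
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    if codons[-1] in stops and not partial3:
        codons = codons[:-1]
        if not codons:
            raise TranslationError("CDS consists of a stop codon only")
    aa = []
    for i, codon in enumerate(codons):
        if set(codon) & _AMBIGUOUS or any(b not in "ACGT" for b in codon):
            aa.append("X")
            continue
        if codon in stops:
            raise InternalStopError(i)
        aa.append(forward[codon])
    if not partial5 and codons[0] in starts:
        aa[0] = "M"
    return "".join(aa)


def feature_transl_table(feature: Feature, default: int = 11) -> int:
    raw = feature.get("transl_table")
    try:
        return int(raw) if raw else default
    except ValueError:
        return default


# ---------------------------------------------------------------------------
# GenBank I/O (Biopython behind the module surface)
# ---------------------------------------------------------------------------

def _position(value: int, partial: Optional[str]) -> ExactPosition:
    if partial == "<":
        return BeforePosition(value)
    if partial == ">":
        return AfterPosition(value)
    return ExactPosition(value)


def _loc_to_biopython(loc: Location):
    if loc.strand == FORWARD:
        left_partial, right_partial = loc.partial5, loc.partial3
    else:
        left_partial, right_partial = loc.partial3, loc.partial5
    parts = []
    for i, (s, e) in enumerate(loc.segments):
        start = _position(s, "<" if (left_partial and i == 0) else None)
        end = _position(e, ">" if (right_partial and i == len(loc.segments) - 1) else None)
        parts.append(SimpleLocation(start, end, loc.strand))
    if len(parts) == 1:
        return parts[0]
    if loc.strand == REVERSE:
        # Biopython renders complement(join(...)) from parts in reverse order.
        parts = parts[::-1]
    return CompoundLocation(parts, operator="order" if loc.operator == "order" else "join")


def _loc_from_biopython(biol) -> Location:
    strand = REVERSE if biol.strand == -1 else FORWARD
    parts = list(biol.parts)
    if strand == REVERSE and len(parts) > 1:
        starts = [int(p.start) for p in parts]
        if starts == sorted(starts, reverse=True):
            parts = parts[::-1]
    segments = []
    left_partial = right_partial = False
    for i, p in enumerate(parts):
        s, e = int(p.start), int(p.end)
        if i == 0 and isinstance(p.start, BeforePosition):
            left_partial = True
        if i == len(parts) - 1 and isinstance(p.end, AfterPosition):
            right_partial = True
        segments.append((s, e))
    if strand == FORWARD:
        partial5, partial3 = left_partial, right_partial
    else:
        partial5, partial3 = right_partial, left_partial
    operator = getattr(biol, "operator", "join") if len(segments) > 1 else "join"
    return Location(tuple(segments), strand, partial5, partial3, operator)


def _qualifiers_from_biopython(q: dict) -> Qualifiers:
    out: Qualifiers = {}
    for name, values in q.items():
        cleaned: list[Optional[str]] = []
        for v in values:
            if v is None or v == "":
                cleaned.append(None)
            else:
                cleaned.append(str(v))
        out[name] = cleaned
    return out


_BIOPROJECT_RE = re.compile(r"BioProject:\s*(\S+)")


def parse_genbank(stream) -> GenomeRecord:
    """Read a (possibly multi-record) GenBank flat file into one GenomeRecord.

    Each LOCUS block becomes one replicon.  ``source`` features are folded
    into record metadata rather than kept in the feature list (the writer
    regenerates them), so parse/write round-trips are exact on the model.
    Unknown feature keys are retained and reported via ``parse_findings``.
    """
    from .lint import Finding  # local import: lint depends on records

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    replicons: list[Replicon] = []
    organism = ""
    bioproject: Optional[str] = None
    structured_comment: Optional[dict] = None
    findings: list = []
    seen = False
    for rec in SeqIO.parse(stream, "genbank"):
        seen = True
        topology = rec.annotations.get("topology", "linear")
        try:
            seq = str(rec.seq).upper()
        except Exception:  # undefined sequence (CONTIG-only records)
            seq = ""
        replicon = Replicon(
            name=rec.name or rec.id,
            sequence=seq,
            topology=topology if topology in ("linear", "circular") else "linear",
            definition=rec.description,
        )
        organism = rec.annotations.get("organism", organism) or organism
        for ref in rec.dbxrefs:
            m = _BIOPROJECT_RE.match(ref.replace("BioProject:", "BioProject: ", 1))
            if m:
                bioproject = m.group(1)
        sc = rec.annotations.get("structured_comment")
        if sc:
            structured_comment = {k: dict(v) for k, v in sc.items()}
        for bf in rec.features:
            if bf.type == "source":
                org = bf.qualifiers.get("organism", [None])[0]
                if org:
                    organism = org
                continue
            feat = Feature(
                key=bf.type,
                location=_loc_from_biopython(bf.location),
                qualifiers=_qualifiers_from_biopython(bf.qualifiers),
            )
            if replicon.has_sequence:
                replicon.validate_bounds(feat)
            if feat.key not in KNOWN_FEATURE_KEYS:
                findings.append(
                    Finding(
                        rule_id="FMT001",
                        severity="INFO",
                        replicon=replicon.name,
                        feature_handle=feat.handle(replicon.name),
                        message=f"unknown feature key {feat.key!r} retained verbatim",
                    )
                )
            replicon.features.append(feat)
        replicons.append(replicon)
    if not seen:
        raise ParseError("no LOCUS block found in GenBank input")
    record = GenomeRecord(
        replicons=replicons,
        organism=organism,
        bioproject=bioproject,
        structured_comment=structured_comment,
    )
    record.parse_findings = findings
    return record


def write_genbank(record: GenomeRecord) -> str:
    """Render a GenomeRecord as a GenBank flat file (one LOCUS per replicon)."""
    out = io.StringIO()
    for rep in record.replicons:
        annotations = {
            "molecule_type": "DNA",
            "topology": rep.topology,
            "data_file_division": "BCT",
            "date": "01-JAN-2011",
            "organism": record.organism or ".",
            "source": record.organism or ".",
        }
        if record.structured_comment:
            annotations["structured_comment"] = {
                k: dict(v) for k, v in record.structured_comment.items()
            }
        seqrec = SeqRecord(
            Seq(rep.sequence),
            id=rep.name,
            name=rep.name[:16],
            description=rep.definition or f"{record.organism} {rep.name}".strip(),
            annotations=annotations,
        )
        if record.bioproject:
            seqrec.dbxrefs = [f"BioProject:{record.bioproject}"]
        source = SeqFeature(
            SimpleLocation(0, len(rep.sequence), 1),
            type="source",
            qualifiers={"organism": [record.organism or "unknown"], "mol_type": ["genomic DNA"]},
        )
        features = [source]
        for feat in rep.features:
            q = {}
            for name, values in feat.qualifiers.items():
                q[name] = [("" if v is None else v) for v in values]
            features.append(SeqFeature(_loc_to_biopython(feat.location), type=feat.key, qualifiers=q))
        seqrec.features = features
        SeqIO.write(seqrec, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# INSDC 5-column feature table (.tbl) writer
# ---------------------------------------------------------------------------

def write_feature_table(record: GenomeRecord) -> str:
    """Render the record as an INSDC 5-column feature table (.tbl).

    Intervals are 1-based inclusive; on the minus strand each interval is
    written high-to-low and segments are listed in reverse, matching the
    convention expected by submission tooling.  Partial markers ``<``/``>``
    prefix the 5'/3' coordinate of the first/last written interval.
    """
    lines = []
    for rep in record.replicons:
        lines.append(f">Feature {rep.name}")
        for feat in rep.features:
            loc = feat.location
            if loc.strand == FORWARD:
                ivals = [(s + 1, e) for s, e in loc.segments]
            else:
                ivals = [(e, s + 1) for s, e in reversed(loc.segments)]
            for i, (a, b) in enumerate(ivals):
                first = i == 0
                last = i == len(ivals) - 1
                a_txt = f"<{a}" if (first and loc.partial5) else str(a)
                b_txt = f">{b}" if (last and loc.partial3) else str(b)
                if first:
                    lines.append(f"{a_txt}\t{b_txt}\t{feat.key}")
                else:
                    lines.append(f"{a_txt}\t{b_txt}")
            for name, values in feat.qualifiers.items():
                for v in values:
                    if v is None:
                        lines.append(f"\t\t\t{name}")
                    else:
                        lines.append(f"\t\t\t{name}\t{v}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

_GFF3_ESCAPE = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C"}


def _gff3_escape(value: str) -> str:
    value = value.replace("%", "%25")
    for ch, rep in _GFF3_ESCAPE.items():
        value = value.replace(ch, rep)
    return value.replace("\t", "%09").replace("\n", "%0A")


def write_gff3(record: GenomeRecord, with_fasta: bool = True) -> str:
    """Render a GenomeRecord as GFF3 (optionally with an embedded ##FASTA).

    Multi-segment features emit one line per segment sharing an ``ID``.
    Flag qualifiers map to ``name=true``; strand-relative partial flags map
    to ``five_prime_partial``/``three_prime_partial`` attributes.
    """
    lines = ["##gff-version 3"]
    for rep in record.replicons:
        lines.append(f"##sequence-region {rep.name} 1 {len(rep.sequence)}")
    for rep in record.replicons:
        if rep.definition:
            lines.append(f"#!definition {_gff3_escape(rep.name)}|{_gff3_escape(rep.definition)}")
    if record.organism:
        lines.append(f"#!organism {_gff3_escape(record.organism)}")
    if record.bioproject:
        lines.append(f"#!bioproject {_gff3_escape(record.bioproject)}")
    if record.structured_comment:
        for block, kv in record.structured_comment.items():
            for k, v in kv.items():
                lines.append(
                    "#!structured-comment "
                    f"{_gff3_escape(block)}|{_gff3_escape(k)}|{_gff3_escape(v)}"
                )
    idx = 0
    for rep in record.replicons:
        if rep.topology == "circular":
            lines.append(f"{rep.name}\tannotqc\tregion\t1\t{len(rep.sequence)}\t.\t+\t.\tID=region-{rep.name};Is_circular=true")
        for feat in rep.features:
            idx += 1
            fid = f"f{idx:05d}"
            attrs = [f"ID={fid}"]
            if feat.location.partial5:
                attrs.append("five_prime_partial=true")
            if feat.location.partial3:
                attrs.append("three_prime_partial=true")
            if feat.location.operator == "order":
                attrs.append("location_operator=order")
            for name, values in feat.qualifiers.items():
                for v in values:
                    if name == "pseudogene" and v is not None:
                        attrs.append(f"pseudogene={_gff3_escape(v)}")
                    elif v is None:
                        attrs.append(f"{name}=true")
                    else:
                        attrs.append(f"{name}={_gff3_escape(v)}")
            strand = "+" if feat.location.strand == FORWARD else "-"
            attr_txt = ";".join(attrs)
            phase_acc = 0
            for s, e in feat.location.segments:
                phase = str((3 - phase_acc % 3) % 3) if feat.key == "CDS" else "."
                phase_acc += e - s
                lines.append(f"{rep.name}\tannotqc\t{feat.key}\t{s + 1}\t{e}\t.\t{strand}\t{phase}\t{attr_txt}")
    text = "\n".join(lines) + "\n"
    if with_fasta and record.has_sequence:
        fasta = []
        for rep in record.replicons:
            fasta.append(f">{rep.name}")
            for i in range(0, len(rep.sequence), 70):
                fasta.append(rep.sequence[i : i + 70])
        text += "##FASTA\n" + "\n".join(fasta) + "\n"
    return text


def _read_fasta(stream) -> dict[str, str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(stream, "fasta")}


def parse_gff3(gff_stream, fasta_stream=None) -> GenomeRecord:
    """Read GFF3 (+FASTA) into a GenomeRecord.

    CDS lines sharing an ``ID`` merge into one multi-segment feature;
    ``pseudo=true``/``pseudogene`` attributes map to the ``/pseudo`` flag
    convention of the model.  Sequences may come from an embedded ##FASTA
    section or a separate FASTA stream; without either, the record is built
    sequence-less and sequence-dependent operations fail explicitly later.
    """
    import gffutils

    text = gff_stream.read() if hasattr(gff_stream, "read") else str(gff_stream)
    if "##gff-version" not in text.split("\n", 1)[0]:
        raise ParseError("missing ##gff-version directive")
    fasta_part = ""
    if "##FASTA" in text:
        text, fasta_part = text.split("##FASTA", 1)
    sequences: dict[str, str] = {}
    if fasta_part.strip():
        sequences.update(_read_fasta(fasta_part.lstrip("\n")))
    if fasta_stream is not None:
        sequences.update(_read_fasta(fasta_stream))

    region_lengths: dict[str, int] = {}
    organism = ""
    bioproject = None
    structured_comment: dict[str, dict[str, str]] = {}
    definitions: dict[str, str] = {}
    ordered_regions: list[str] = []
    for line in text.splitlines():
        if line.startswith("#!definition "):
            payload = line.split(" ", 1)[1]
            name, definition = (urllib.parse.unquote(p) for p in payload.split("|", 1))
            definitions[name] = definition
        elif line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                region_lengths[parts[1]] = int(parts[3])
                ordered_regions.append(parts[1])
        elif line.startswith("#!organism "):
            organism = urllib.parse.unquote(line.split(" ", 1)[1].strip())
        elif line.startswith("#!bioproject "):
            bioproject = urllib.parse.unquote(line.split(" ", 1)[1].strip())
        elif line.startswith("#!structured-comment "):
            payload = line.split(" ", 1)[1]
            block, k, v = (urllib.parse.unquote(p) for p in payload.split("|", 2))
            structured_comment.setdefault(block, {})[k] = v

    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, keep_order=True,
        merge_strategy="create_unique",
    )

    circular: set[str] = set()
    replicon_map: dict[str, Replicon] = {}

    def _get_replicon(name: str) -> Replicon:
        if name not in replicon_map:
            replicon_map[name] = Replicon(
                name=name,
                sequence=sequences.get(name, ""),
                topology="circular" if name in circular else "linear",
            )
        return replicon_map[name]

    grouped: dict[tuple[str, str, str], list] = {}
    order: list[tuple[str, str, str]] = []
    for gf in db.all_features():
        if gf.featuretype == "region":
            if gf.attributes.get("Is_circular", ["false"])[0].lower() == "true":
                circular.add(gf.seqid)
            continue
        fid = gf.attributes.get("ID", [gf.id])[0]
        key = (gf.seqid, gf.featuretype, fid)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(gf)

    for seqid, ftype, fid in order:
        parts = sorted(grouped[(seqid, ftype, fid)], key=lambda g: g.start)
        first = parts[0]
        limit = region_lengths.get(seqid) or (len(sequences.get(seqid, "")) or None)
        segments = []
        for p in parts:
            if p.start < 1 or (limit and p.end > limit):
                raise ParseError(
                    f"feature {fid} coordinates ({p.start},{p.end}) outside region {seqid} bounds"
                )
            segments.append((p.start - 1, p.end))
        strand = REVERSE if first.strand == "-" else FORWARD
        attrs = {k: list(v) for k, v in first.attributes.items()}
        partial5 = attrs.pop("five_prime_partial", ["false"])[0].lower() == "true"
        partial3 = attrs.pop("three_prime_partial", ["false"])[0].lower() == "true"
        operator = attrs.pop("location_operator", ["join"])[0]
        qualifiers: Qualifiers = {}
        for name, values in attrs.items():
            if name in ("ID", "Parent", "Name"):
                continue
            if name == "pseudo" or (name == "pseudogene" and values == ["true"]):
                qualifiers["pseudo"] = [None]
            elif name == "pseudogene":
                qualifiers["pseudogene"] = list(values)
            elif name in FLAG_QUALIFIERS and values == ["true"]:
                qualifiers[name] = [None]
            else:
                qualifiers[name] = list(values)
        rep = _get_replicon(seqid)
        rep.features.append(
            Feature(
                key=ftype,
                location=Location(tuple(segments), strand, partial5, partial3,
                                  operator if operator in ("join", "order") else "join"),
                qualifiers=qualifiers,
            )
        )

    for name in ordered_regions:
        _get_replicon(name)
    if not replicon_map:
        raise ParseError("GFF3 input contains no features or sequence regions")
    # sequence-less replicons need a placeholder length for bounds math
    replicons = []
    for name, rep in replicon_map.items():
        if not rep.sequence:
            # keep an empty sequence; sequence-dependent ops raise later
            rep.sequence = ""
        if name in circular:
            rep.topology = "circular"
        if name in definitions:
            rep.definition = definitions[name]
        replicons.append(rep)
    record = GenomeRecord(
        replicons=replicons,
        organism=organism,
        bioproject=bioproject,
        structured_comment=structured_comment or None,
    )
    return record
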