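"""Deterministic generator of annotated genome records with known truth.

Every measure the toolkit computes and every rule it enforces is testable
against records built here: counts (hypothetical names, standard start
codons, short proteins) are constructed exactly rather than sampled, so the
declared truth is sharp; GC content is realised by exact base-count
construction of the non-coding pool; and planted rule violations are
introduced exactly once each from a registry covering the whole rule
catalog.

The generator makes no attempt at biological realism beyond the measured
quantities: no operons, no codon-usage bias, no realistic intergenic
grammar.  Its defaults are scaled-down but ratio-realistic: coding density,
protein-length moments, hypothetical fraction and start-codon usage all sit
inside the ranges seen in real complete genomes, while the absolute genome
length (200 kb) keeps fixtures fast.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .config import QCConfig, STANDARD_AMINO_ACIDS
from .records import (
    FORWARD,
    REVERSE,
    Feature,
    GenomeRecord,
    Location,
    Replicon,
    translate_cds,
)
from .standards import CHECK_IDS, load_core_catalog

_SENSE_CODONS = tuple(
    a + b + c
    for a in "TCAG" for b in "TCAG" for c in "TCAG"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

_RRNA_LENGTHS = {"5S": 120, "16S": 1542, "23S": 2904}
_RRNA_PRODUCTS = {"5S": "5S ribosomal RNA", "16S": "16S ribosomal RNA",
                  "23S": "23S ribosomal RNA"}
_TRNA_LENGTH = 76

_GENERIC_NAME_POOL = (
    "DNA gyrase subunit A",
    "DNA-directed RNA polymerase subunit beta",
    "chaperone protein DnaK",
    "ATP synthase subunit beta",
    "phosphoglycerate kinase",
    "aspartate aminotransferase",
    "outer membrane channel protein",
    "two-component sensor kinase",
    "ABC transporter permease",
    "sodium/proline symporter",
    "acyl carrier protein",
    "cell division protein FtsZ",
    "peptide deformylase",
    "recombination protein RecA",
    "thioredoxin reductase",
)


class InfeasibleSpecError(ValueError):
    """The requested genome cannot be laid out (too much payload, bad GC)."""


@dataclass(frozen=True)
class GenomeSpec:
    """All knobs of one synthetic genome; defaults are the study conditions."""

    seed: int = 0
    length_bp: int = 200_000
    gc_target: float = 50.0
    n_proteins: int = 150
    protein_len_dist: tuple[float, float, int] = (300.0, 80.0, 50)
    hypothetical_fraction: float = 0.10
    standard_start_fraction: float = 0.90
    trna_aa_subset: tuple[str, ...] = STANDARD_AMINO_ACIDS
    rrna_subset: tuple[str, ...] = ("5S", "16S", "23S")
    pseudo_cases: tuple[str, ...] = ()
    evidence_fraction: float = 0.2
    planted_violations: tuple[str, ...] = ()
    include_core_functions: bool = True
    organism: str = "Synthetica exemplaris"
    replicon_name: str = "SYNREP01"
    bioproject: Optional[str] = "PRJNA000001"
    with_structured_comment: bool = True
    locus_prefix: str = "SYN"
    exemptions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for frac in (self.hypothetical_fraction, self.standard_start_fraction,
                     self.evidence_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for case in self.pseudo_cases:
            if case not in ("1", "3a", "3c", "3d", "4"):
                raise ValueError(f"unknown pseudogene case token {case!r}")


@dataclass
class Truth:
    """Ground truth declared by construction.

    ``metrics`` is None when planted violations invalidate the measure
    bookkeeping; count-exact fields are identical across seeds for the same
    spec, length-derived fields depend on the seeded length draws.
    """

    metrics: Optional[dict]
    expected_findings: Counter = field(default_factory=Counter)
    expected_checks: dict = field(default_factory=dict)


@dataclass
class _BuildContext:
    record: GenomeRecord
    generic: list[tuple[Feature, Feature]]  # (gene, CDS) forward-strand generic proteins
    trna_features: list[tuple[Feature, Feature]]
    next_tag: int
    rng: np.random.Generator

    @property
    def replicon(self) -> Replicon:
        return self.record.replicons[0]

    def fresh_tag(self, spec: GenomeSpec) -> str:
        tag = f"{spec.locus_prefix}_{self.next_tag:04d}"
        self.next_tag += 1
        return tag


def _sample_lengths(spec: GenomeSpec, rng: np.random.Generator,
                    catalog) -> list[int]:
    mean, sd, lmin = spec.protein_len_dist
    lengths = np.rint(rng.normal(mean, sd, spec.n_proteins)).astype(int)
    lengths = np.maximum(lengths, lmin)
    lengths = lengths.tolist()
    if spec.include_core_functions:
        for i, func in enumerate(catalog):
            if i >= len(lengths):
                break
            if func.expected_avg_len_aa:
                lengths[i] = int(round(func.expected_avg_len_aa))
    return lengths


def _build_cds_nt(rng: np.random.Generator, aa_len: int, standard_start: bool) -> str:
    start = "ATG" if standard_start else "GTG"
    body_idx = rng.integers(0, len(_SENSE_CODONS), size=aa_len - 1)
    body = "".join(_SENSE_CODONS[i] for i in body_idx)
    return start + body + "TAA"


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def generate(spec: GenomeSpec, config: Optional[QCConfig] = None
             ) -> tuple[GenomeRecord, Truth]:
    """Build one annotated replicon and its declared truth.

    Deterministic under ``spec.seed``: the same spec yields byte-identical
    flat-file output.  Raises :class:`InfeasibleSpecError` before emitting
    anything when the payload cannot fit or the GC target is unreachable.
    """
    config = config or QCConfig()
    rng = np.random.default_rng(spec.seed)
    catalog = load_core_catalog()
    n = spec.n_proteins
    if spec.include_core_functions and n < len(catalog):
        raise InfeasibleSpecError(
            f"need at least {len(catalog)} proteins to include the core functions")
    mean_len = spec.protein_len_dist[0]
    if n * mean_len * 3 > spec.length_bp:
        raise InfeasibleSpecError("protein payload exceeds genome length")

    lengths = _sample_lengths(spec, rng, catalog)

    # exact-count assignments -------------------------------------------------
    n_core = len(catalog) if spec.include_core_functions else 0
    n_hyp = int(round(spec.hypothetical_fraction * n))
    if n_hyp > n - n_core:
        raise InfeasibleSpecError(
            "hypothetical fraction leaves no room for the core functions")
    non_core = np.arange(n_core, n)
    hyp_idx = set(int(i) for i in rng.choice(non_core, size=n_hyp, replace=False)) if n_hyp else set()
    n_std = int(round(spec.standard_start_fraction * n))
    std_idx = set(int(i) for i in rng.choice(n, size=n_std, replace=False)) if n else set()
    strands = [FORWARD if s else REVERSE for s in rng.integers(0, 2, size=n)]
    n_ev = int(round(spec.evidence_fraction * n))
    ev_idx = set(int(i) for i in rng.choice(n, size=n_ev, replace=False)) if n_ev else set()

    names: list[Optional[str]] = []
    pool_i = 0
    for i in range(n):
        if i < n_core:
            names.append(catalog[i].display_name)
        elif i in hyp_idx:
            names.append("hypothetical protein")
        else:
            base = _GENERIC_NAME_POOL[pool_i % len(_GENERIC_NAME_POOL)]
            rep_no = pool_i // len(_GENERIC_NAME_POOL)
            names.append(base if rep_no == 0 else f"{base} {rep_no + 1}")
            pool_i += 1

    # payload layout ----------------------------------------------------------
    case_aa_len = 200
    items: list[tuple[str, int]] = [("cds", 3 * L + 3) for L in lengths]
    for case in spec.pseudo_cases:
        size = {"1": 303, "3a": 400, "3c": 3 * case_aa_len + 3,
                "3d": 3 * case_aa_len + 3, "4": 200}[case]
        items.append((f"case{case}", size))
    for aa in spec.trna_aa_subset:
        items.append((f"trna:{aa}", _TRNA_LENGTH))
    for cls in ("5S", "16S", "23S"):
        if cls in spec.rrna_subset:
            items.append((f"rrna:{cls}", _RRNA_LENGTHS[cls]))

    payload = sum(size for _, size in items)
    spare = spec.length_bp - payload
    n_items = len(items)
    gap = spare // (n_items + 1) if n_items else spare
    if spare < 0 or (n_items and gap < 1):
        raise InfeasibleSpecError(
            f"payload {payload} bp does not fit in {spec.length_bp} bp with gaps")

    # coding sequence bodies --------------------------------------------------
    cds_seqs = [
        _build_cds_nt(rng, lengths[i], i in std_idx) for i in range(n)
    ]
    case_bodies: dict[int, str] = {}
    for j, (kind, size) in enumerate(items):
        if kind in ("case3c", "case3d"):
            case_bodies[j] = _build_cds_nt(rng, case_aa_len, True)
    coding_total = sum(len(s) for s in cds_seqs) + sum(len(s) for s in case_bodies.values())
    coding_gc = sum(s.count("G") + s.count("C") for s in cds_seqs)
    coding_gc += sum(s.count("G") + s.count("C") for s in case_bodies.values())

    # exact-GC non-coding pool ------------------------------------------------
    pool_len = spec.length_bp - coding_total
    target_gc_total = int(round(spec.gc_target / 100.0 * spec.length_bp))
    need = target_gc_total - coding_gc
    if not 0 <= need <= pool_len:
        raise InfeasibleSpecError(
            f"GC target {spec.gc_target}% unreachable: need {need} G/C in a "
            f"{pool_len} bp non-coding pool")
    n_g = need // 2
    n_c = need - n_g
    n_at = pool_len - need
    n_a = n_at // 2
    pool = np.array(
        list(b"G" * n_g + b"C" * n_c + b"A" * n_a + b"T" * (n_at - n_a)),
        dtype=np.uint8,
    )
    rng.shuffle(pool)
    pool_str = pool.tobytes().decode("ascii")
    pool_pos = 0

    def take_pool(k: int) -> str:
        nonlocal pool_pos
        out = pool_str[pool_pos:pool_pos + k]
        pool_pos += k
        return out

    # assembly ----------------------------------------------------------------
    pieces: list[str] = []
    pos = 0

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        start = pos
        pieces.append(seq)
        pos += len(seq)
        return start, pos

    replicon = Replicon(name=spec.replicon_name, sequence="", topology="linear",
                        definition=f"{spec.organism} {spec.replicon_name}")
    features: list[Feature] = []
    ctx_generic: list[tuple[Feature, Feature]] = []
    ctx_trna: list[tuple[Feature, Feature]] = []
    tag_no = 1

    def fresh_tag() -> str:
        nonlocal tag_no
        tag = f"{spec.locus_prefix}_{tag_no:04d}"
        tag_no += 1
        return tag

    def add_gene_pair(key: str, loc: Location, quals: dict, gene_quals=None
                      ) -> tuple[Feature, Feature]:
        tag = fresh_tag()
        gene_loc = Location(((loc.start, loc.end),), loc.strand)
        gq = {"locus_tag": [tag]}
        if gene_quals:
            gq.update(gene_quals)
        gene = Feature("gene", gene_loc, gq)
        child = Feature(key, loc, {"locus_tag": [tag], **quals})
        features.append(gene)
        features.append(child)
        return gene, child

    cds_i = 0
    for j, (kind, size) in enumerate(items):
        emit(take_pool(gap))
        if kind == "cds":
            i = cds_i
            cds_i += 1
            nt = cds_seqs[i]
            strand = strands[i]
            start, end = emit(nt if strand == FORWARD else _revcomp(nt))
            loc = Location(((start, end),), strand)
            quals: dict = {}
            if names[i] is not None:
                quals["product"] = [names[i]]
            quals["translation"] = [translate_cds(nt)]
            if i in ev_idx:
                quals["inference"] = [
                    f"COORDINATES: similar to AA sequence:INSD:{spec.locus_prefix}{i:05d}.1"
                ]
                if i % 5 == 0:
                    quals["experiment"] = [
                        "EXISTENCE: N-terminal sequencing [PMID:1234567]"
                    ]
            gene, cds = add_gene_pair("CDS", loc, quals)
            if i >= n_core and i not in hyp_idx and strand == FORWARD:
                ctx_generic.append((gene, cds))
        elif kind == "case1":
            start, end = emit(take_pool(size))
            loc = Location(((start, end),), FORWARD)
            add_gene_pair("CDS", loc,
                          {"pseudo": [None],
                           "note": ["DNA topoisomerase IV subunit B pseudogene"]},
                          gene_quals={"pseudo": [None]})
        elif kind == "case3a":
            start, end = emit(take_pool(size))
            loc = Location(((start, start + 150), (start + 160, end)), FORWARD)
            add_gene_pair("CDS", loc,
                          {"pseudo": [None],
                           "note": ["frameshifted glycosyltransferase pseudogene; "
                                    "sequence verified correct"]},
                          gene_quals={"pseudo": [None]})
        elif kind in ("case3c", "case3d"):
            nt = case_bodies[j]
            start, end = emit(nt)
            loc = Location(((start, end),), FORWARD)
            transl = translate_cds(nt)
            if kind == "case3c":
                add_gene_pair("CDS", loc, {
                    "product": ["penicillin-binding protein"],
                    "exception": ["annotated by transcript or proteomic data"],
                    "inference": ["similar to AA sequence:INSD:AAD51968.1"],
                    "translation": [transl],
                })
            else:
                add_gene_pair("CDS", loc, {
                    "product": ["LOW-QUALITY PROTEIN: DNA ligase"],
                    "artificial_location": [None],
                    "translation": [transl],
                })
        elif kind == "case4":
            start, end = emit(take_pool(size))
            features.append(Feature(
                "misc_feature", Location(((start, end),), FORWARD),
                {"note": ["region of similarity to RecA; no complete reading frame"]},
            ))
        elif kind.startswith("trna:"):
            aa = kind.split(":", 1)[1]
            start, end = emit(take_pool(size))
            loc = Location(((start, end),), FORWARD)
            gene, trna = add_gene_pair("tRNA", loc, {"product": [f"tRNA-{aa}"]})
            ctx_trna.append((gene, trna))
        elif kind.startswith("rrna:"):
            cls = kind.split(":", 1)[1]
            start, end = emit(take_pool(size))
            loc = Location(((start, end),), FORWARD)
            add_gene_pair("rRNA", loc, {"product": [_RRNA_PRODUCTS[cls]]})
    emit(take_pool(pool_len - pool_pos))

    replicon.sequence = "".join(pieces)
    assert len(replicon.sequence) == spec.length_bp
    replicon.features = features

    structured_comment = None
    if spec.with_structured_comment:
        block = {
            "Annotation Provider": "annotqc synthetic generator",
            "Annotation Pipeline": "annotqc-synth",
        }
        for k, (check_id, reason) in enumerate(spec.exemptions):
            block[f"Annotation Exception {k + 1}"] = (
                f"annotation-exception: {check_id}: {reason}")
        structured_comment = {"Genome-Annotation-Data": block}

    record = GenomeRecord(
        replicons=[replicon],
        organism=spec.organism,
        bioproject=spec.bioproject,
        structured_comment=structured_comment,
    )

    truth = _derive_truth(spec, lengths, n_core, n_hyp, n_std,
                          coding_gc + need, config)

    if spec.planted_violations:
        ctx = _BuildContext(record=record, generic=ctx_generic,
                            trna_features=ctx_trna, next_tag=9000, rng=rng)
        planted = Counter()
        for k, rule_id in enumerate(spec.planted_violations):
            if rule_id not in VIOLATION_REGISTRY:
                raise ValueError(f"no planted-violation recipe for rule {rule_id!r}")
            VIOLATION_REGISTRY[rule_id].apply(ctx, spec, k)
            planted[rule_id] += 1
        truth.metrics = None
        truth.expected_findings = planted
    return record, truth


def _derive_truth(spec: GenomeSpec, lengths: list[int], n_core: int,
                  n_hyp: int, n_std: int, total_gc: int,
                  config: QCConfig) -> Truth:
    n_cases = sum(1 for c in spec.pseudo_cases if c in ("3c", "3d"))
    all_lengths = list(lengths) + [200] * n_cases
    n_prot = len(all_lengths)
    metrics: Optional[dict]
    if n_prot:
        short = sum(1 for x in all_lengths if x < config.short_protein_aa)
        metrics = {
            "replicon_count": 1,
            "total_length_bp": spec.length_bp,
            "protein_count": n_prot,
            "rna_count": len(spec.trna_aa_subset) + len(spec.rrna_subset),
            "trna_aa_count": len(spec.trna_aa_subset),
            "trna_aa_set": frozenset(spec.trna_aa_subset),
            "hypothetical_count": n_hyp,
            "hypothetical_ratio": n_hyp / n_prot,
            "coding_density": n_prot / (spec.length_bp / 1000.0),
            "avg_protein_len_aa": sum(all_lengths) / n_prot,
            "min_protein_len_aa": min(all_lengths),
            "short_protein_percent": 100.0 * short / n_prot,
            "standard_start_percent": 100.0 * (n_std + n_cases) / n_prot,
            "gc_percent": 100.0 * total_gc / spec.length_bp,
        }
    else:
        metrics = {
            "replicon_count": 1,
            "total_length_bp": spec.length_bp,
            "protein_count": 0,
            "rna_count": len(spec.trna_aa_subset) + len(spec.rrna_subset),
            "trna_aa_count": len(spec.trna_aa_subset),
            "trna_aa_set": frozenset(spec.trna_aa_subset),
            "hypothetical_count": 0,
            "hypothetical_ratio": None,
            "coding_density": 0.0,
            "avg_protein_len_aa": None,
            "min_protein_len_aa": None,
            "short_protein_percent": None,
            "standard_start_percent": None,
            "gc_percent": 100.0 * total_gc / spec.length_bp,
        }

    checks: dict[str, str] = {}
    missing_rrna = [c for c in ("5S", "16S", "23S") if c not in spec.rrna_subset]
    checks["RRNA_SET"] = "FAIL" if missing_rrna else "PASS"
    missing_trna = [aa for aa in STANDARD_AMINO_ACIDS if aa not in spec.trna_aa_subset]
    checks["TRNA_SET"] = "FAIL" if missing_trna else "PASS"
    checks["CORE_FUNCS"] = "PASS" if spec.include_core_functions else "FAIL"
    density = metrics["coding_density"]
    checks["DENSITY"] = ("PASS" if config.density_lo <= density <= config.density_hi
                         else "WARN")
    ratio = metrics["hypothetical_ratio"]
    if ratio is None:
        checks["HYPOTHETICAL_RATIO"] = "WARN"
    elif ratio >= config.hypothetical_fail_ratio:
        checks["HYPOTHETICAL_RATIO"] = "FAIL"
    elif ratio >= config.hypothetical_warn_ratio:
        checks["HYPOTHETICAL_RATIO"] = "WARN"
    else:
        checks["HYPOTHETICAL_RATIO"] = "PASS"
    checks["LOCUS_TAGS"] = "PASS"
    checks["PSEUDO_FORMAT"] = "PASS"
    for check_id, _ in spec.exemptions:
        if checks.get(check_id) == "FAIL":
            checks[check_id] = "EXEMPT"
    return Truth(metrics=metrics, expected_checks=checks)


# ---------------------------------------------------------------------------
# planted violations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """A recipe that introduces exactly one instance of one rule violation."""

    rule_id: str
    apply: Callable
    description: str


def _target(ctx: _BuildContext, k: int) -> tuple[Feature, Feature]:
    if k >= len(ctx.generic):
        raise InfeasibleSpecError("not enough generic proteins to plant violations")
    return ctx.generic[k]


def _mut_name001(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["product"] = ["conserved hypothetical protein"]


def _mut_name002(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["product"] = ["DNA  binding   protein "]


def _mut_name003(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["product"] = ["ALKALINE PHOSPHATASE"]


def _mut_name004(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["product"] = ["ABC transporter homolog"]


def _mut_name005(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["product"] = [cds.locus_tag]


def _mut_name006(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.remove("product")


def _mut_ev001(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["inference"] = ["EXISTENCE: banana"]


def _mut_ev002(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["inference"] = ["profile"]


def _mut_ev003(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.qualifiers["experiment"] = ["DESCRIPTION:"]


def _mut_pseudo001(ctx, spec, k):
    gene, cds = _target(ctx, k)
    cds.remove("product")
    cds.add("pseudo")
    gene.add("pseudo")


def _mut_pseudo002(ctx, spec, k):
    gene, cds = _target(ctx, k)
    cds.remove("translation")
    cds.add("pseudo")
    gene.add("pseudo")


def _mut_pseudo003(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.remove("inference")
    cds.remove("experiment")
    cds.remove("translation")
    cds.qualifiers["exception"] = ["annotated by transcript or proteomic data"]


def _mut_pseudo004(ctx, spec, k):
    _, cds = _target(ctx, k)
    cds.remove("translation")
    cds.add("artificial_location")


def _mut_pseudo005(ctx, spec, k):
    ctx.replicon.features.append(Feature(
        "misc_feature", Location(((0, 120),), FORWARD),
        {"note": ["region of similarity to DNA polymerase I"],
         "locus_tag": [f"{spec.locus_prefix}_{9900 + k:04d}"]},
    ))


def _mut_pseudo006(ctx, spec, k):
    gene, cds = _target(ctx, k)
    cds.remove("translation")
    note = cds.product
    cds.remove("product")
    cds.qualifiers["pseudogene"] = ["unprocessed"]
    if note:
        cds.add("note", f"{note} pseudogene")
    gene.add("pseudo")


def _mut_lt001(ctx, spec, k):
    gene_a, cds_a = _target(ctx, k)
    gene_b, cds_b = _target(ctx, k + 1)
    tag = gene_a.get("locus_tag")
    gene_b.qualifiers["locus_tag"] = [tag]
    cds_b.qualifiers["locus_tag"] = [tag]


def _mut_lt002(ctx, spec, k):
    gene, cds = _target(ctx, k)
    gene.qualifiers["locus_tag"] = ["ABC_9001"]
    cds.qualifiers["locus_tag"] = ["ABC_9001"]


def _mut_lt004(ctx, spec, k):
    gene, cds = _target(ctx, k)
    gene.remove("locus_tag")
    cds.remove("locus_tag")


def _mut_struct001(ctx, spec, k):
    gene, _ = _target(ctx, k)
    ctx.replicon.features.remove(gene)


def _mut_struct002(ctx, spec, k):
    _, cds = _target(ctx, k)
    transl = cds.get("translation")
    mid = len(transl) // 2
    swapped = "W" if transl[mid] != "W" else "K"
    cds.qualifiers["translation"] = [transl[:mid] + swapped + transl[mid + 1:]]


def _mut_struct003(ctx, spec, k):
    gene, cds = _target(ctx, k)
    (s, e), = cds.location.segments
    short = Location(((s, e - 1),), cds.location.strand)
    cds.location = short
    gene.location = short


def _mut_met002(ctx, spec, k):
    start = 200 + 100 * k
    tag = f"{spec.locus_prefix}_{9800 + k:04d}"
    loc = Location(((start, start + _TRNA_LENGTH),), FORWARD)
    ctx.replicon.features.append(Feature("gene", loc, {"locus_tag": [tag]}))
    ctx.replicon.features.append(Feature(
        "tRNA", loc, {"locus_tag": [tag], "product": ["transfer RNA of unclear identity"]}))


def _mut_met003(ctx, spec, k):
    for rep in ctx.record.replicons:
        rep.sequence = ""


def _mut_fmt001(ctx, spec, k):
    ctx.replicon.features.append(Feature(
        "wibble_region", Location(((0, 50),), FORWARD),
        {"note": ["nonstandard feature key"]}))


def _mut_core001(ctx, spec, k):
    start = 600
    tag = f"{spec.locus_prefix}_{9700 + k:04d}"
    loc = Location(((start, start + 903),), FORWARD)
    ctx.replicon.features.append(Feature("gene", loc, {"locus_tag": [tag]}))
    ctx.replicon.features.append(Feature(
        "CDS", loc,
        {"locus_tag": [tag], "product": ["30S ribosomal protein S14"]}))


VIOLATION_REGISTRY: dict[str, Violation] = {
    v.rule_id: v for v in (
        Violation("NAME001", _mut_name001, "banned unknown-function synonym"),
        Violation("NAME002", _mut_name002, "irregular whitespace in product"),
        Violation("NAME003", _mut_name003, "all-uppercase product (style)"),
        Violation("NAME004", _mut_name004, "vague qualifier word in product (style)"),
        Violation("NAME005", _mut_name005, "locus_tag used as product name"),
        Violation("NAME006", _mut_name006, "CDS without /product"),
        Violation("EV001", _mut_ev001, "unknown inference type"),
        Violation("EV002", _mut_ev002, "inference without evidence basis"),
        Violation("EV003", _mut_ev003, "experiment category with empty description"),
        Violation("PSEUDO001", _mut_pseudo001, "pseudo CDS retaining /translation"),
        Violation("PSEUDO002", _mut_pseudo002, "pseudo CDS retaining /product"),
        Violation("PSEUDO003", _mut_pseudo003, "transcript exception without evidence"),
        Violation("PSEUDO004", _mut_pseudo004, "artificial_location without LOW-QUALITY prefix"),
        Violation("PSEUDO005", _mut_pseudo005, "similarity misc_feature with locus_tag"),
        Violation("PSEUDO006", _mut_pseudo006, "/pseudogene synonym qualifier"),
        Violation("LT001", _mut_lt001, "duplicate locus_tag"),
        Violation("LT002", _mut_lt002, "second locus_tag prefix"),
        Violation("LT004", _mut_lt004, "tagged feature without locus_tag"),
        Violation("STRUCT001", _mut_struct001, "CDS without same-range gene"),
        Violation("STRUCT002", _mut_struct002, "corrupted /translation"),
        Violation("STRUCT003", _mut_struct003, "CDS span not divisible by 3"),
        Violation("MET002", _mut_met002, "unparseable tRNA product"),
        Violation("MET003", _mut_met003, "sequence stripped from record"),
        Violation("FMT001", _mut_fmt001, "unknown feature key"),
        Violation("CORE001", _mut_core001, "core protein at implausible length"),
    )
}

#: rules planted through a different GenomeSpec instead of a mutation
SPEC_CASE_OVERRIDES: dict[str, dict] = {
    "LT003": {"locus_prefix": "ab"},
    "STRUCT004": {"with_structured_comment": False},
    "STRUCT005": {"bioproject": None},
    "MET001": {"n_proteins": 0, "include_core_functions": False},
    "RRNA_SET": {"rrna_subset": ("16S", "23S")},
    "TRNA_SET": {"trna_aa_subset": tuple(a for a in STANDARD_AMINO_ACIDS if a != "Trp")},
    "CORE_FUNCS": {"include_core_functions": False},
    "DENSITY": {"n_proteins": 40, "hypothetical_fraction": 0.3},
    "HYPOTHETICAL_RATIO": {"length_bp": 500_000, "n_proteins": 400,
                           "hypothetical_fraction": 0.96},
}

#: standard-check fixtures that alias a lint-rule mutation
CHECK_ALIASES: dict[str, str] = {
    "LOCUS_TAGS": "LT001",
    "PSEUDO_FORMAT": "PSEUDO001",
    "VALIDATION_CLEAN": "STRUCT002",
}

GOLD_SEED = 42


def gold_spec(seed: int = GOLD_SEED) -> GenomeSpec:
    """The fully compliant reference spec (default study conditions)."""
    return GenomeSpec(seed=seed)


def gold_standard(seed: int = GOLD_SEED) -> GenomeRecord:
    """A genome that meets every minimal standard (evaluates COMPLIANT)."""
    record, _ = generate(gold_spec(seed))
    return record


def registered_case_ids() -> list[str]:
    """Every rule/check id for which a dedicated violation fixture exists."""
    ids = set(VIOLATION_REGISTRY) | set(SPEC_CASE_OVERRIDES) | set(CHECK_ALIASES)
    return sorted(ids)


def case_fixture(rule_id: str, seed: int = GOLD_SEED) -> GenomeRecord:
    """A gold-standard variant violating exactly ``rule_id``.

    Accepts lint rule ids (NAME001, ...), metric rules (MET001, ...) and
    standard check ids (RRNA_SET, ...).  Unregistered ids are an error.
    """
    rule_id = rule_id.upper()
    if rule_id in CHECK_ALIASES:
        rule_id = CHECK_ALIASES[rule_id]
    if rule_id in SPEC_CASE_OVERRIDES:
        spec = replace(gold_spec(seed), **SPEC_CASE_OVERRIDES[rule_id])
        record, _ = generate(spec)
        return record
    if rule_id in VIOLATION_REGISTRY:
        spec = replace(gold_spec(seed), planted_violations=(rule_id,))
        record, _ = generate(spec)
        return record
    raise ValueError(f"no fixture registered for rule {rule_id!r}")


def endosymbiont_fixture(seed: int = GOLD_SEED) -> GenomeRecord:
    """A reduced genome missing tRNAs for real biological reasons, with the
    documented exception note that makes the loss exempt rather than failing
    (modelled on endosymbionts that lost isoacceptors through codon
    recoding)."""
    missing = ("Trp", "Cys")
    spec = replace(
        gold_spec(seed),
        trna_aa_subset=tuple(a for a in STANDARD_AMINO_ACIDS if a not in missing),
        exemptions=(("TRNA_SET",
                     "tRNA-Trp and tRNA-Cys lost through codon recoding; "
                     "verified against the genome sequence"),),
    )
    record, _ = generate(spec)
    return record
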