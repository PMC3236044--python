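"""Run configuration: every tunable threshold and name set in one place.

Defaults mirror the accepted annotation standards: the two acceptable
unknown-function names plus legacy synonyms kept measurable, a short-protein
threshold of 150 aa, density bounds bracketing the extremes observed in real
complete genomes (0.49-1.19 proteins/kbp), and a hypothetical-ratio failure
point just below "every protein is hypothetical".
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

#: Accepted names for proteins of unknown function.
ACCEPTED_UNKNOWN_NAMES = ("hypothetical protein", "uncharacterized protein")

#: Names counted as "hypothetical" for metrics purposes.  A superset of the
#: accepted pair so that pre-standard records remain measurable; the members
#: beyond the accepted pair also trip the naming lint.
DEFAULT_HYPOTHETICAL_NAMES = (
    "hypothetical protein",
    "uncharacterized protein",
    "conserved hypothetical protein",
    "protein of unknown function",
    "unknown",
    "unnamed protein product",
)

#: Unknown-function synonyms no longer acceptable in submissions.
BANNED_UNKNOWN_NAMES = (
    "conserved hypothetical protein",
    "novel protein",
    "protein of unknown function",
    "unknown",
    "unnamed protein product",
    "hypothetical conserved protein",
)

DEFAULT_RNA_KEYS = ("tRNA", "rRNA", "ncRNA", "tmRNA")

STANDARD_AMINO_ACIDS = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

#: tRNA isoacceptor tokens recognised beyond the standard twenty.
EXTRA_TRNA_TOKENS = ("Sec", "Pyl", "fMet", "Ile2", "OTHER")


@dataclass
class QCConfig:
    """Thresholds and vocabularies for metrics, lint and standards checks."""

    short_protein_aa: int = 150
    hypothetical_warn_ratio: float = 0.8
    hypothetical_fail_ratio: float = 0.95
    density_lo: float = 0.5
    density_hi: float = 1.25
    z_threshold: float = 3.0
    core_length_sd_multiplier: float = 4.0
    transl_table: int = 11
    hypothetical_names: tuple[str, ...] = DEFAULT_HYPOTHETICAL_NAMES
    banned_unknown_names: tuple[str, ...] = BANNED_UNKNOWN_NAMES
    rna_keys: tuple[str, ...] = DEFAULT_RNA_KEYS
    count_misc_rna: bool = False
    style_name_rules: bool = False
    style_words: tuple[str, ...] = ("homolog", "homologue", "fragment", "putative?")
    catalog_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.hypothetical_warn_ratio <= self.hypothetical_fail_ratio <= 1:
            raise ValueError("hypothetical thresholds must satisfy 0 <= warn <= fail <= 1")
        if not 0 < self.density_lo < self.density_hi:
            raise ValueError("density bounds must satisfy 0 < lo < hi")
        if self.short_protein_aa < 0 or self.z_threshold <= 0:
            raise ValueError("thresholds out of range")

    @property
    def effective_rna_keys(self) -> tuple[str, ...]:
        keys = tuple(self.rna_keys)
        if self.count_misc_rna:
            keys = keys + ("misc_RNA", "precursor_RNA")
        return keys

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "QCConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hypothetical_names", "banned_unknown_names", "rna_keys", "style_words"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.to_dict().items()},
            sort_keys=True,
        )


def normalize_name(name: str) -> str:
    """Case-fold, trim and collapse inner whitespace for name comparison."""
    return " ".join(name.split()).casefold()
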