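"""Core I/O and configuration for the 6S RNA annotation toolkit.

Defines the two carrier types everything downstream operates on — a
:class:`Genome` (a named DNA sequence) and a :class:`Feature` (a stranded,
0-based half-open interval on a genome) — plus the resolved pipeline
configuration, FASTA/GFF3 readers and writers, and logging setup.

Coordinate convention: every coordinate held in memory is 0-based,
half-open.  GFF3 on disk is 1-based, inclusive; the writer and reader
convert, and the round trip is the identity.
"""
from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from Bio import SeqIO

__all__ = [
    "Genome",
    "Feature",
    "PipelineConfig",
    "SixscanError",
    "FormatError",
    "ConfigError",
    "revcomp",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "load_config",
    "setup_logging",
]

GAP = "-"
ALPHABET = "ACGT"

#: IUPAC ambiguity codes and the concrete bases each may stand for.
IUPAC_AMBIGUITY = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SixscanError(Exception):
    """Base class for all validation and format errors raised here."""


class FormatError(SixscanError):
    """A file did not conform to its declared format."""


class ConfigError(SixscanError):
    """An invalid or unknown configuration value."""


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, *, strict: bool = True,
                       rng: np.random.Generator | None = None,
                       context: str = "") -> str:
    """Normalize a raw nucleotide string to uppercase DNA over {A,C,G,T}.

    U becomes T and lowercase becomes uppercase, so RNA and DNA inputs are
    interchangeable.  In strict mode any other character is a
    :class:`FormatError`; in lenient mode IUPAC ambiguity codes are replaced
    by a uniformly chosen concrete base (``rng`` required for determinism).
    """
    s = seq.upper().replace("U", "T")
    if all(c in ALPHABET for c in s):
        return s
    if strict:
        bad = next(c for c in s if c not in ALPHABET)
        raise FormatError(
            f"invalid character {bad!r} in sequence {context or '<anonymous>'}")
    if rng is None:
        raise ConfigError("lenient normalization needs a seeded generator")
    out = []
    for c in s:
        if c in ALPHABET:
            out.append(c)
        elif c in IUPAC_AMBIGUITY:
            choices = IUPAC_AMBIGUITY[c]
            out.append(choices[rng.integers(len(choices))])
        else:
            raise FormatError(
                f"invalid character {c!r} in sequence {context or '<anonymous>'}")
    return "".join(out)


@dataclass(frozen=True)
class Genome:
    """A named nucleotide sequence; the unit all scanning operates on."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"genome {self.id!r} has an empty sequence")
        if not all(c in ALPHABET for c in self.seq):
            raise FormatError(
                f"genome {self.id!r} contains non-ACGT characters; "
                "normalize before constructing")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A stranded interval annotation (0-based, half-open) on a genome."""

    genome_id: str
    start: int
    end: int
    strand: str
    kind: str
    score: float | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature on {self.genome_id}: bad interval "
                f"[{self.start}, {self.end})")
        if self.strand not in "+-":
            raise FormatError(f"feature strand must be + or -, got {self.strand!r}")

    def overlaps(self, other: "Feature") -> bool:
        return (self.genome_id == other.genome_id
                and self.start < other.end and other.start < self.end)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All thresholds of the annotation pipeline, with study defaults.

    The e-value tiers mirror the tiered search strategy (strict first pass,
    relaxed profile-like tier, permissive synteny rescue, very strict anchor
    annotation); the remaining knobs control redundancy reduction, the
    shuffled-genome terminator threshold, cre scanning, and pRNA calling.
    """

    evalue_primary: float = 1e-30
    evalue_cm_like: float = 1e-8
    evalue_rescue: float = 0.1
    evalue_anchor: float = 1e-40
    anchor_window_nt: int = 2000
    merge_edit_distance: int = 10
    n_shuffles: int = 10
    fdr_fraction: float = 0.05
    cre_upstream_nt: int = 100
    cre_pvalue: float = 1e-5
    prna_length: int = 16
    prna_max_shift: int = 3
    seed: int = 0
    # search-engine calibration (see homology_search)
    match: int = 1
    mismatch: int = -1
    k_const: float = 0.1
    seed_len: int = 11
    rescue_seed_len: int = 4
    x_drop: float = 20.0

    def validate(self) -> "PipelineConfig":
        for name in ("evalue_primary", "evalue_cm_like", "evalue_rescue",
                     "evalue_anchor", "cre_pvalue", "k_const", "x_drop"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not (0 < self.fdr_fraction <= 1):
            raise ConfigError("fdr_fraction must lie in (0, 1]")
        if self.anchor_window_nt < 1:
            raise ConfigError("anchor_window_nt must be >= 1")
        if self.merge_edit_distance < 0:
            raise ConfigError("merge_edit_distance must be >= 0")
        if self.n_shuffles < 1:
            raise ConfigError("n_shuffles must be >= 1")
        if self.cre_upstream_nt < 0:
            raise ConfigError("cre_upstream_nt must be >= 0")
        if self.prna_length < 1:
            raise ConfigError("prna_length must be >= 1")
        if self.prna_max_shift < 0:
            raise ConfigError("prna_max_shift must be >= 0")
        if self.seed_len < 4 or self.rescue_seed_len < 4:
            raise ConfigError("seed lengths must be >= 4")
        if self.match <= 0 or self.mismatch >= 0:
            raise ConfigError("match must be positive and mismatch negative")
        return self

    def log_resolved(self, logger: logging.Logger) -> None:
        """Log every resolved value so a run is fully reproducible."""
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat key→value YAML config; unspecified keys take defaults.

    Unknown keys and non-positive thresholds are errors, so typos cannot
    silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config {path} must be a flat key: value mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc
    return cfg.validate()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, strict: bool = True,
               rng: np.random.Generator | None = None) -> list[Genome]:
    """Read a (multi-record) FASTA file into normalized Genomes.

    Record order is preserved.  An empty file yields an empty list; a record
    with an empty sequence or a disallowed character raises a
    :class:`FormatError` naming the record.
    """
    genomes: list[Genome] = []
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        seq = normalize_sequence(seq, strict=strict, rng=rng, context=rec.id)
        genomes.append(Genome(id=rec.id, seq=seq, description=rec.description))
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            header = g.description if g.description.startswith(g.id) else g.id
            fh.write(f">{header}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_ESCAPES = {";": "%3B", "=": "%3D", "&": "%26", ",": "%2C", "%": "%25"}


def _gff_escape(value: str) -> str:
    out = value.replace("%", "%25")
    for char, code in _GFF_ESCAPES.items():
        if char != "%":
            out = out.replace(char, code)
    return out


def _gff_unescape(value: str) -> str:
    for char, code in _GFF_ESCAPES.items():
        value = value.replace(code, char)
    return value


def write_gff3(features: Sequence[Feature], path: str | Path,
               genome_lengths: Mapping[str, int] | None = None,
               source: str = "sixscan") -> None:
    """Write features as GFF3 (1-based inclusive on disk).

    When ``genome_lengths`` is supplied, a feature extending past the end of
    its genome is a validation error.
    """
    if genome_lengths is not None:
        for f in features:
            n = genome_lengths.get(f.genome_id)
            if n is not None and f.end > n:
                raise FormatError(
                    f"feature [{f.start},{f.end}) exceeds length {n} "
                    f"of genome {f.genome_id}")
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs.setdefault("kind", f.kind)
            attr_str = ";".join(
                f"{_gff_escape(str(k))}={_gff_escape(str(v))}"
                for k, v in attrs.items())
            score = "." if f.score is None else f"{f.score:g}"
            fh.write("\t".join([
                f.genome_id, source, f.kind,
                str(f.start + 1), str(f.end), score, f.strand, ".",
                attr_str or ".",
            ]) + "\n")


def read_gff3(path: str | Path) -> list[Feature]:
    """Read GFF3 back into 0-based half-open Features (round trip of the writer)."""
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, "
                                  f"got {len(cols)}")
            seqid, _source, kind, start, end, score, strand, _phase, attrs = cols
            attributes: dict = {}
            if attrs != ".":
                for item in attrs.split(";"):
                    if not item:
                        continue
                    key, _, value = item.partition("=")
                    attributes[_gff_unescape(key)] = _gff_unescape(value)
            attributes.pop("kind", None)
            feats.append(Feature(
                genome_id=seqid,
                start=int(start) - 1,
                end=int(end),
                strand=strand,
                kind=kind,
                score=None if score == "." else float(score),
                attributes=attributes,
            ))
    return feats


# ---------------------------------------------------------------------------
# Logging
# ---------------------------------------------------------------------------

def setup_logging(level: int = logging.INFO) -> logging.Logger:
    """Configure the package logger to write level-prefixed lines to stderr."""
    logger = logging.getLogger("sixscan")
    logger.setLevel(level)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s: %(message)s"))
        logger.addHandler(handler)
    return logger
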