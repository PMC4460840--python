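"""Domain types for annotated mitochondrial genomes.

Coordinates are 0-based half-open throughout.  On a circular chromosome a
feature may wrap the sequence origin; such an interval is stored with
``end < start`` and resolved through the record's topology flag.  Strands use
the organellar J/N convention: J is the majority-coding strand (maps to
GenBank ``+``), N the minority-coding strand (``-``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import vocab

IUPAC_DNA = set("ACGTNRYSWKMBDHV")
UNAMBIGUOUS = set("ACGT")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised for unparseable or empty input files."""


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence with explicit topology."""

    id: str
    residues: str
    topology: str = "linear"  # circular | linear

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValidationError(f"{self.id}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"{self.id}: bad topology {self.topology!r}")
        bad = set(self.residues.upper()) - IUPAC_DNA
        if bad:
            raise ValidationError(
                f"{self.id}: non-IUPAC residues {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature on a chromosome.

    ``start``/``end`` are 0-based half-open.  ``end < start`` denotes an
    origin-wrapping feature, legal only on circular records.  ``end == len``
    is an ordinary feature touching the last residue.
    """

    name: str
    kind: str       # PCG | tRNA | rRNA | control | noncoding
    strand: str     # J | N
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("J", "N"):
            raise ValidationError(
                f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.kind not in ("PCG", "tRNA", "rRNA", "control", "noncoding"):
            raise ValidationError(f"{self.name}: bad kind {self.kind!r}")
        if self.start < 0 or self.end < 0:
            raise ValidationError(f"{self.name}: negative coordinate")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def length(self, seq_len: int) -> int:
        if self.wraps:
            return seq_len - self.start + self.end
        return self.end - self.start


@dataclass(frozen=True)
class Chromosome:
    """A sequence record plus its ordered gene features."""

    record: SequenceRecord
    features: tuple[GeneFeature, ...] = ()

    def __post_init__(self):
        n = len(self.record)
        feats = tuple(self.features)
        for f in feats:
            if f.start > n or f.end > n:
                raise ValidationError(
                    f"{f.name}: interval ({f.start},{f.end}) outside "
                    f"[0,{n}] on {self.record.id}")
            if f.wraps and self.record.topology != "circular":
                raise ValidationError(
                    f"{f.name}: origin-wrapping feature on linear record "
                    f"{self.record.id}")
        object.__setattr__(self, "features",
                           tuple(sorted(feats, key=lambda f: (f.start, f.end))))

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Residues of a feature in its coding orientation (J left as-is,
        N reverse-complemented)."""
        s = self.record.residues
        raw = s[feat.start:] + s[:feat.end] if feat.wraps else s[feat.start:feat.end]
        return reverse_complement(raw) if feat.strand == "N" else raw

    def genes(self, canonical_only: bool = True):
        for f in self.features:
            if not canonical_only or f.name in vocab.CANONICAL_GENES \
                    or f.name == vocab.CONTROL:
                yield f


@dataclass(frozen=True)
class MitoGenome:
    """A named set of chromosomes forming one mitochondrial genome."""

    label: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        object.__setattr__(self, "chromosomes", tuple(self.chromosomes))

    def gene_names(self) -> list[str]:
        return [f.name for c in self.chromosomes for f in c.features]

    def missing_genes(self) -> set[str]:
        present = set(self.gene_names())
        return set(vocab.CANONICAL_GENES) - present

    def is_complete(self) -> bool:
        """True when each of the 37 canonical genes occurs on >=1 chromosome.

        Paralogs and duplicates are allowed; a fragmented genome whose
        mini-circle carries genes missing from the main chromosome still
        passes.
        """
        return not self.missing_genes()

    def find_features(self, name: str) -> list[tuple[Chromosome, GeneFeature]]:
        return [(c, f) for c in self.chromosomes for f in c.features
                if f.name == name]


def rotate_chromosome(chrom: Chromosome, offset: int) -> Chromosome:
    """Rotate a circular chromosome so old position ``offset`` becomes 0."""
    if chrom.record.topology != "circular":
        raise ValidationError("rotation requires a circular record")
    n = len(chrom.record)
    offset %= n
    seq = chrom.record.residues
    new_seq = seq[offset:] + seq[:offset]
    new_feats = []
    for f in chrom.features:
        new_start = (f.start - offset) % n
        new_end = (f.end - offset) % n
        if new_end == 0 and f.length(n) > 0:
            new_end = n
        new_feats.append(replace(f, start=new_start, end=new_end))
    rec = replace(chrom.record, residues=new_seq)
    return Chromosome(record=rec, features=tuple(new_feats))


def at_content(record: SequenceRecord, interval: tuple[int, int] | None = None) -> float:
    """A+T percentage of a record (or sub-interval), ambiguity codes excluded.

    The denominator counts unambiguous A/C/G/T only, so N-padded drafts do
    not dilute the composition estimate.
    """
    s = record.residues
    if interval is not None:
        lo, hi = interval
        if lo < 0 or hi > len(s) or (lo > hi and record.topology != "circular"):
            raise ValidationError(f"interval ({lo},{hi}) outside record")
        s = s[lo:] + s[:hi] if lo > hi else s[lo:hi]
    at = sum(s.count(b) for b in "AT")
    total = sum(s.count(b) for b in "ACGT")
    if total == 0:
        raise ValidationError("A+T content undefined on empty/all-ambiguous sequence")
    return 100.0 * at / total
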