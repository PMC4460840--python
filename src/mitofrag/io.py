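"""Readers and writers for annotated mitogenomes.

GenBank flat files are the primary interchange format (Bio.SeqIO does the
parsing); FASTA plus a tab-separated feature table serves as a plain-text
side channel.  Internal coordinates are 0-based half-open; GenBank I/O
converts to and from the format's 1-based inclusive convention.  A feature
wrapping the origin of a circular record is serialized as a ``join``
location and read back into the single-interval ``end < start``
representation.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import vocab
from .genome import (Chromosome, FormatError, GeneFeature, MitoGenome,
                     SequenceRecord, ValidationError)

logger = logging.getLogger("mitofrag")

_GB_TYPE_BY_KIND = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                    "control": "D-loop", "noncoding": "misc_feature"}
_NAMED_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature")


def _feature_name(sf) -> tuple[str | None, str | None]:
    """Extract (label, anticodon) from a Biopython SeqFeature's qualifiers."""
    label = None
    for key in ("gene", "product", "standard_name", "note"):
        vals = sf.qualifiers.get(key)
        if vals:
            label = str(vals[0])
            break
    anticodon = None
    ac = sf.qualifiers.get("anticodon")
    if ac:
        anticodon = str(ac[0]).strip("()").split(":")[-1]
    return label, anticodon


def _location_to_interval(loc, seq_len: int) -> tuple[int, int]:
    """Collapse a (possibly origin-spanning join) location to (start, end)."""
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join: last part ends at seq end, first begins at 0
        if len(parts) == 2 and int(parts[1].end) == seq_len and int(parts[0].start) == 0:
            return int(parts[1].start), int(parts[0].end)
        return int(parts[0].start), int(parts[-1].end)
    return int(loc.start), int(loc.end)


def _seqrecord_to_chromosome(rec, name_map: dict[str, str] | None) -> Chromosome:
    seq = str(rec.seq)
    if not seq:
        raise FormatError(f"record {rec.id!r} has an empty sequence")
    topology = rec.annotations.get("topology", "linear")
    srec = SequenceRecord(id=rec.id, residues=seq, topology=topology)

    feats: dict[tuple[int, int, str], GeneFeature] = {}
    # typed features first; bare `gene` features only fill gaps, so that
    # gene/CDS pairs at the same locus yield a single domain feature
    ordered = [sf for sf in rec.features if sf.type in _NAMED_TYPES]
    ordered += [sf for sf in rec.features if sf.type == "gene"]
    for sf in ordered:
        if sf.type == "source":
            continue
        label, anticodon = _feature_name(sf)
        start, end = _location_to_interval(sf.location, len(seq))
        strand = "N" if sf.location.strand == -1 else "J"
        if sf.type == "D-loop":
            name = vocab.CONTROL
        else:
            name = vocab.normalize_gene_name(label, anticodon, name_map) \
                if label else None
        if name is None:
            name = vocab.NONCODING
            if sf.type != "misc_feature" or (label and label != "noncoding"):
                logger.warning("unmappable feature %r at %d..%d on %s kept as noncoding",
                               label, start, end, rec.id)
        key = (start, end, name)
        if key not in feats:
            feats[key] = GeneFeature(name=name, kind=vocab.gene_kind(name),
                                     strand=strand, start=start, end=end)
    return Chromosome(record=srec, features=tuple(feats.values()))


def read_genbank(path, label: str | None = None,
                 name_map: dict[str, str] | None = None) -> MitoGenome:
    """Read a GenBank flat file (>=1 record) into a MitoGenome.

    Feature names are normalized onto the controlled vocabulary; unmappable
    names are preserved as ``noncoding`` with a logged warning.  Topology is
    taken from the record header and defaults to linear.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise FormatError(f"cannot parse {path} as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    chroms = [_seqrecord_to_chromosome(r, name_map) for r in records]
    return MitoGenome(label=label or path.stem, chromosomes=tuple(chroms))


def _chromosome_to_seqrecord(chrom: Chromosome) -> SeqRecord:
    n = len(chrom.record)
    rec = SeqRecord(Seq(chrom.record.residues), id=chrom.record.id,
                    name=chrom.record.id[:16], description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = chrom.record.topology
    for f in chrom.features:
        if f.start > n or f.end > n:
            raise ValidationError(f"{f.name}: feature outside sequence")
        strand = -1 if f.strand == "N" else 1
        if f.wraps:
            loc = CompoundLocation([SimpleLocation(f.start, n, strand),
                                    SimpleLocation(0, f.end, strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        sf = SeqFeature(loc, type=_GB_TYPE_BY_KIND[f.kind])
        if f.kind == "noncoding":
            sf.qualifiers["note"] = [f.name]
        elif f.kind == "control":
            sf.qualifiers["note"] = [vocab.CONTROL]
        else:
            sf.qualifiers["gene"] = [f.name]
        rec.features.append(sf)
    return rec


def write_genbank(genome: MitoGenome, path) -> None:
    """Write a genome as a multi-record GenBank flat file (round-trip safe)."""
    records = [_chromosome_to_seqrecord(c) for c in genome.chromosomes]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def read_fasta(path, topology: str = "linear", label: str | None = None,
               feature_table=None) -> MitoGenome:
    """Read sequences from FASTA, optionally attaching a feature table.

    ``feature_table`` maps record id -> list of GeneFeature (see
    :func:`read_feature_table`); a single unkeyed list is applied to a
    single-record file.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    chroms = []
    for r in records:
        feats: tuple = ()
        if isinstance(feature_table, dict):
            feats = tuple(feature_table.get(r.id, ()))
        elif feature_table is not None and len(records) == 1:
            feats = tuple(feature_table)
        srec = SequenceRecord(id=r.id, residues=str(r.seq), topology=topology)
        chroms.append(Chromosome(record=srec, features=feats))
    return MitoGenome(label=label or path.stem, chromosomes=tuple(chroms))


def write_fasta(genome: MitoGenome, path) -> None:
    records = [SeqRecord(Seq(c.record.residues), id=c.record.id, description="")
               for c in genome.chromosomes]
    SeqIO.write(records, str(path), "fasta")


_TABLE_HEADER = "name\tkind\tstrand\tstart\tend"


def read_feature_table(path) -> list[GeneFeature]:
    """Read the TSV annotation side channel (name, kind, strand, start, end)."""
    feats = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or (i == 0 and line == _TABLE_HEADER):
                continue
            try:
                name, kind, strand, start, end = line.split("\t")
                feats.append(GeneFeature(name=name, kind=kind, strand=strand,
                                         start=int(start), end=int(end)))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}:{i + 1}: bad feature row: {exc}") from exc
    return feats


def write_feature_table(chrom: Chromosome, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TABLE_HEADER + "\n")
        for f in chrom.features:
            fh.write(f"{f.name}\t{f.kind}\t{f.strand}\t{f.start}\t{f.end}\n")
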