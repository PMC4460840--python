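"""NGS-contig vs. reference error audit.

Flow-based sequencers (e.g. Ion Torrent) miscount run lengths in
homopolymers, and contig ends assemble from fewer, worse-placed reads.  The
audit aligns a contig to a validated reference, records every discrepancy,
and classifies each one by two rules: *terminal* — the change lies within a
fixed window (default 80 nt) of either contig end; *homopolymer* — the
change lies within, or immediately adjacent to, a reference run of >=8
identical A or T residues.  The raw error rate uses all changes; the
filtered rate keeps only changes matching neither rule, i.e. the residual
error not attributable to the two known failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import edlib

from .genome import Chromosome, ValidationError


class AlignmentFailure(ValueError):
    """Contig could not be aligned over enough of the reference."""


@dataclass(frozen=True)
class AuditRules:
    terminal_window: int = 80
    homopolymer_min: int = 8
    homopolymer_bases: frozenset = frozenset("AT")
    #: bases on each side of a run still counted as inside it (indel placement
    #: at run edges is alignment-ambiguous); set 0 for strict membership
    homopolymer_margin: int = 1

    def __post_init__(self):
        if self.terminal_window < 0:
            raise ValidationError("terminal_window must be >= 0")
        if self.homopolymer_min < 2:
            raise ValidationError("homopolymer_min must be >= 2")


@dataclass(frozen=True)
class ChangeRecord:
    """One contig-vs-reference discrepancy."""

    contig_pos: int
    ref_pos: int
    type: str               # substitution | insertion | deletion
    ref_residues: str
    contig_residues: str
    terminal: bool = False
    homopolymer: bool = False


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _best_rotation(contig: str, ref: str) -> int:
    """Offset at which to rotate a circular reference before global alignment."""
    doubled = ref + ref
    hit = edlib.align(contig, doubled, mode="HW", task="locations")
    locs = hit.get("locations") or [(0, None)]
    start = locs[0][0] or 0
    return start % len(ref)


def diff_contig(contig: str, reference: Chromosome) -> list[ChangeRecord]:
    """Globally align a contig to its reference and list every change.

    A circular reference is first rotated to the contig's best start so the
    global alignment is not penalized by the arbitrary origin.  Each maximal
    gap run yields a single insertion/deletion record; each mismatch column
    yields one substitution record.
    """
    if not contig or not len(reference.record):
        raise ValidationError("empty contig or reference")
    contig = contig.upper()
    ref = reference.record.residues
    offset = 0
    if reference.record.topology == "circular":
        offset = _best_rotation(contig, ref)
        ref = ref[offset:] + ref[:offset]
    result = edlib.align(contig, ref, mode="NW", task="path")
    n_ref = len(ref)
    changes: list[ChangeRecord] = []
    qpos = tpos = matched = 0
    for length, op in _cigar_ops(result["cigar"]):
        if op == "=":
            matched += length
            qpos += length
            tpos += length
        elif op == "X":
            for j in range(length):
                changes.append(ChangeRecord(
                    contig_pos=qpos + j, ref_pos=(tpos + j + offset) % n_ref,
                    type="substitution", ref_residues=ref[tpos + j],
                    contig_residues=contig[qpos + j]))
            qpos += length
            tpos += length
        elif op == "I":   # bases present in the contig, absent from reference
            changes.append(ChangeRecord(
                contig_pos=qpos, ref_pos=(tpos + offset) % n_ref,
                type="insertion", ref_residues="",
                contig_residues=contig[qpos:qpos + length]))
            qpos += length
        elif op == "D":   # bases present in the reference, absent from contig
            changes.append(ChangeRecord(
                contig_pos=qpos, ref_pos=(tpos + offset) % n_ref,
                type="deletion", ref_residues=ref[tpos:tpos + length],
                contig_residues=""))
            tpos += length
    if matched < 0.5 * n_ref:
        raise AlignmentFailure(
            f"only {matched}/{n_ref} reference positions matched (<50%)")
    return left_align_changes(changes, reference)


def left_align_changes(changes: list[ChangeRecord],
                       reference: Chromosome) -> list[ChangeRecord]:
    """Normalize indel placement by shifting each indel as far left as the
    reference allows (the usual variant-normalization convention).  Indel
    position within a homopolymer run is alignment-ambiguous; after
    left-alignment, records from different alignments of the same contig
    are comparable."""
    ref = reference.record.residues
    out = []
    for c in changes:
        if c.type == "substitution":
            out.append(c)
            continue
        pos, cpos = c.ref_pos, c.contig_pos
        allele = c.contig_residues if c.type == "insertion" else c.ref_residues
        while pos > 0 and ref[pos - 1] == allele[-1]:
            allele = allele[-1] + allele[:-1]
            pos -= 1
            cpos = max(0, cpos - 1)
        if c.type == "insertion":
            out.append(replace(c, ref_pos=pos, contig_pos=cpos,
                               contig_residues=allele))
        else:
            out.append(replace(c, ref_pos=pos, contig_pos=cpos,
                               ref_residues=allele))
    return sorted(out, key=lambda c: (c.ref_pos, c.type))


def homopolymer_mask(reference: Chromosome, rules: AuditRules) -> list[bool]:
    """Per-reference-position flag: inside (or within the margin of) an A/T
    run of at least ``homopolymer_min``; circular runs wrap the origin."""
    seq = reference.record.residues
    n = len(seq)
    mask = [False] * n
    circular = reference.record.topology == "circular"
    i = 0
    while i < n:
        b = seq[i]
        j = i + 1
        while j < n and seq[j] == b:
            j += 1
        run_len = j - i
        if circular and i == 0 and j < n and seq[-1] == b:
            pass  # handled by the wrapping run ending here
        if circular and j == n and seq[0] == b and i > 0:
            k = 0
            while k < n and seq[k] == b:
                k += 1
            run_len += k
        if b in rules.homopolymer_bases and run_len >= rules.homopolymer_min:
            lo = i - rules.homopolymer_margin
            hi = i + run_len + rules.homopolymer_margin
            for p in range(lo, hi):
                mask[p % n if circular else min(max(p, 0), n - 1)] = True
        i = j
    return mask


def classify_changes(changes: list[ChangeRecord], contig_length: int,
                     reference: Chromosome,
                     rules: AuditRules = AuditRules()) -> tuple[list[ChangeRecord], dict]:
    """Annotate changes with terminal/homopolymer flags and tally categories.

    The terminal window is measured on the contig (contig ends are the
    assembly artifact); homopolymer runs are measured on the reference.
    Returns (annotated records, counts) with counts keyed total / terminal /
    homopolymer / both / neither.
    """
    mask = homopolymer_mask(reference, rules)
    n_ref = len(mask)
    annotated = []
    for c in changes:
        if not 0 <= c.contig_pos <= contig_length or not 0 <= c.ref_pos < n_ref:
            raise ValidationError(f"change position out of bounds: {c}")
        terminal = (c.contig_pos < rules.terminal_window
                    or c.contig_pos >= contig_length - rules.terminal_window)
        span = max(1, len(c.ref_residues))
        homopoly = any(mask[(c.ref_pos + j) % n_ref] for j in range(span))
        annotated.append(replace(c, terminal=terminal, homopolymer=homopoly))
    counts = {
        "total": len(annotated),
        "terminal": sum(c.terminal for c in annotated),
        "homopolymer": sum(c.homopolymer for c in annotated),
        "both": sum(c.terminal and c.homopolymer for c in annotated),
        "neither": sum(not c.terminal and not c.homopolymer for c in annotated),
    }
    return annotated, counts


def error_rates(counts: dict, reference_length: int,
                rules: AuditRules = AuditRules()) -> dict:
    """Raw and filtered NGS error rates as percentages of reference length."""
    if reference_length <= 0:
        raise ValidationError("reference length must be positive")
    return {
        "raw": 100.0 * counts["total"] / reference_length,
        "filtered": 100.0 * counts["neither"] / reference_length,
    }
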