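"""Pairwise homolog divergence with indel collapsing.

The statistic is a raw percent difference computed from a global pairwise
alignment under two counting rules used for rearranged mitogenome
comparisons: every maximal gap run counts as a single difference regardless
of its length, and non-overlapping overhangs at the termini of tRNA
alignments are ignored (tRNA boundaries are annotation-dependent, so
overhangs reflect annotation, not evolution).  The denominator is the number
of effective columns: aligned columns minus gap columns plus one per indel
event, which makes the percentage invariant to indel length.  No
model-based distance correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio import Align

from .genome import MitoGenome, ValidationError

logger = logging.getLogger("mitofrag")

#: alignment scoring defaults (match, mismatch, gap open, gap extend)
DEFAULT_SCORING = (1.0, -1.0, -2.0, -0.5)


@dataclass(frozen=True)
class HomologAlignment:
    """A pairwise global alignment of one homolog (gapped rows of equal length)."""

    gene: str
    a_aligned: str
    b_aligned: str
    kind: str = "PCG"   # PCG | tRNA | rRNA | control

    def __post_init__(self):
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValidationError(f"{self.gene}: row lengths differ")
        if any(x == "-" and y == "-" for x, y in zip(self.a_aligned, self.b_aligned)):
            raise ValidationError(f"{self.gene}: gap-gap column")

    @property
    def columns(self) -> int:
        return len(self.a_aligned)


@dataclass(frozen=True)
class DivergenceResult:
    gene: str
    substitutions: int
    indel_events: int
    effective_columns: int

    @property
    def differences(self) -> int:
        return self.substitutions + self.indel_events

    @property
    def percent(self) -> float:
        return 100.0 * self.differences / self.effective_columns


def make_aligner(scoring=DEFAULT_SCORING) -> Align.PairwiseAligner:
    match, mismatch, gap_open, gap_extend = scoring
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_homologs(a: str, b: str, kind: str = "PCG", gene: str = "",
                   scoring=DEFAULT_SCORING) -> HomologAlignment:
    """Optimal global alignment of two homologous sequences.

    Affine gap costs: a run of k gaps scores open + (k-1)*extend.  Among
    co-optimal alignments the aligner's first traceback is returned, which
    is deterministic for fixed inputs.
    """
    if not a or not b:
        raise ValidationError(f"{gene or 'homolog'}: empty input sequence")
    aligner = make_aligner(scoring)
    aln = aligner.align(a.upper(), b.upper())[0]
    return HomologAlignment(gene=gene, a_aligned=str(aln[0]),
                            b_aligned=str(aln[1]), kind=kind)


def trim_trna_termini(aln: HomologAlignment) -> HomologAlignment:
    """Drop terminal overhang columns from a tRNA alignment.

    Leading and trailing columns belonging to terminal gap runs (where one
    sequence overhangs the other) are removed; interior columns are
    untouched.  Non-tRNA alignments are passed through with a warning.
    """
    if aln.kind != "tRNA":
        logger.warning("trim_trna_termini called on %s alignment %r; no-op",
                       aln.kind, aln.gene)
        return aln
    lo, hi = 0, aln.columns
    while lo < hi and (aln.a_aligned[lo] == "-" or aln.b_aligned[lo] == "-"):
        lo += 1
    while hi > lo and (aln.a_aligned[hi - 1] == "-" or aln.b_aligned[hi - 1] == "-"):
        hi -= 1
    return HomologAlignment(gene=aln.gene, a_aligned=aln.a_aligned[lo:hi],
                            b_aligned=aln.b_aligned[lo:hi], kind=aln.kind)


def homolog_divergence(aln: HomologAlignment) -> DivergenceResult:
    """Count differences under the indel-collapse rule.

    substitutions = mismatch columns; indel_events = maximal gap runs (one
    difference each, regardless of length); effective_columns = columns −
    gap columns + indel_events.
    """
    subs = 0
    gap_cols = 0
    indels = 0
    prev_gap_side = None   # which row carried the gap in the previous column
    for x, y in zip(aln.a_aligned, aln.b_aligned):
        if x == "-" or y == "-":
            side = "a" if x == "-" else "b"
            gap_cols += 1
            if side != prev_gap_side:
                indels += 1
            prev_gap_side = side
        else:
            prev_gap_side = None
            if x != y:
                subs += 1
    effective = aln.columns - gap_cols + indels
    if effective == 0:
        raise ValidationError(f"{aln.gene}: zero effective columns")
    return DivergenceResult(gene=aln.gene, substitutions=subs,
                            indel_events=indels, effective_columns=effective)


def divergence_between(a: str, b: str, kind: str = "PCG", gene: str = "",
                       scoring=DEFAULT_SCORING) -> DivergenceResult:
    """Align two homolog sequences and score them (tRNAs get trimmed).

    The pair is aligned in a canonical order so the statistic is exactly
    symmetric: co-optimal alignments can distribute differences between
    substitutions and indels differently depending on which sequence is
    given first.
    """
    if (len(a), a) > (len(b), b):
        a, b = b, a
    aln = align_homologs(a, b, kind=kind, gene=gene, scoring=scoring)
    if kind == "tRNA":
        aln = trim_trna_termini(aln)
    return homolog_divergence(aln)


def aggregate_divergence(results: list[DivergenceResult],
                         mode: str = "pooled") -> float:
    """Aggregate per-homolog divergences.

    ``pooled`` weights each homolog by its effective length
    (100·Σdifferences/Σeffective_columns); ``mean`` is the unweighted
    average of the percentages.
    """
    if not results:
        raise ValidationError("aggregate_divergence over an empty list")
    if mode == "pooled":
        return 100.0 * sum(r.differences for r in results) / \
            sum(r.effective_columns for r in results)
    if mode == "mean":
        return sum(r.percent for r in results) / len(results)
    raise ValidationError(f"unknown aggregation mode {mode!r}")


def paralog_divergence(genome: MitoGenome, feature: str,
                       scoring=DEFAULT_SCORING) -> DivergenceResult:
    """Divergence between two copies of a duplicated feature in one genome.

    Copies are compared in the order found (largest chromosome first); with
    more than two copies the first two are scored.
    """
    hits = genome.find_features(feature)
    if len(hits) < 2:
        raise ValidationError(
            f"{feature!r} occurs {len(hits)} time(s) in {genome.label}; "
            "paralog divergence needs >=2 copies")
    hits = sorted(hits, key=lambda cf: -len(cf[0].record))
    (c1, f1), (c2, f2) = hits[:2]
    return divergence_between(c1.feature_sequence(f1), c2.feature_sequence(f2),
                              kind=f1.kind, gene=feature, scoring=scoring)
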