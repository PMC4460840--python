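"""Whole-genome comparison reports.

Assembles the per-homolog divergence table, rearrangement event list, A+T
composition table and chromosome inventory for a pair of annotated
mitogenomes.  Homology between genomes is assigned by gene name
(annotations are trusted); unnamed noncoding regions are matched by
alignment identity and marked non-homologous below a configurable floor
instead of being scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import vocab
from .divergence import (DEFAULT_SCORING, DivergenceResult, aggregate_divergence,
                         align_homologs, divergence_between, paralog_divergence)
from .genome import MitoGenome, ValidationError, at_content
from .rearrange import (RearrangementEvent, base, classify_events,
                        dedup_paralogs, extract_order)


@dataclass(frozen=True)
class CompareConfig:
    anchor: str = "cox1"
    scoring: tuple = DEFAULT_SCORING
    identity_floor: float = 50.0   # % identity below which noncoding regions
                                   # are declared non-homologous
    aggregate_mode: str = "pooled"


@dataclass
class HomologRow:
    gene: str
    kind: str
    strand_a: str
    strand_b: str
    result: DivergenceResult | None   # None -> non-homologous / unscored
    note: str = ""

    @property
    def percent(self) -> float | None:
        return None if self.result is None else self.result.percent


@dataclass
class ComparisonReport:
    label_a: str
    label_b: str
    rows: list[HomologRow]
    noncoding_rows: list[HomologRow]
    paralog_rows: list[HomologRow]
    events: list[RearrangementEvent]
    aggregates: dict
    at_table: dict
    inventory: list[dict]
    config: CompareConfig = field(default_factory=CompareConfig)

    def to_tsv(self) -> str:
        lines = ["gene\tkind\tstrand_a\tstrand_b\tpercent"]
        for row in self.rows + self.noncoding_rows:
            pct = "Non-homologous" if row.result is None else f"{row.percent:.2f}"
            lines.append(f"{row.gene}\t{row.kind}\t{row.strand_a}\t"
                         f"{row.strand_b}\t{pct}")
        return "\n".join(lines) + "\n"


def _home_copy(genome: MitoGenome, gene: str):
    hits = genome.find_features(gene)
    if not hits:
        return None
    # home copy = the one on the chromosome with most annotated genes
    return max(hits, key=lambda cf: len(cf[0].features))


def _alignment_identity(a: str, b: str, scoring) -> float:
    aln = align_homologs(a, b, gene="noncoding", scoring=scoring)
    matches = sum(x == y for x, y in zip(aln.a_aligned, aln.b_aligned)
                  if x != "-" and y != "-")
    return 100.0 * matches / max(len(a), len(b))


def compare_genomes(a: MitoGenome, b: MitoGenome,
                    config: CompareConfig = CompareConfig()) -> ComparisonReport:
    """Full comparison of two mitogenomes (divergence, events, composition).

    Row order follows genome A's anchor-linearized gene order with paralogs
    reduced to their home copy; each canonical gene plus the control region
    appears exactly once, duplicated features additionally land in a
    paralog section.
    """
    for g in (a, b):
        if not g.is_complete():
            raise ValidationError(
                f"{g.label}: genome incomplete; missing {sorted(g.missing_genes())}")
    order_a = extract_order(a, anchor=config.anchor)
    order_b = extract_order(b, anchor=config.anchor)
    events = classify_events(order_a, order_b)

    rows: list[HomologRow] = []
    for _, genes in dedup_paralogs(order_a).chromosomes:
        for token in genes:
            gene = base(token)
            ca, fa = _home_copy(a, gene)
            cb, fb = _home_copy(b, gene)
            res = divergence_between(ca.feature_sequence(fa), cb.feature_sequence(fb),
                                     kind=fa.kind, gene=gene, scoring=config.scoring)
            rows.append(HomologRow(gene=gene, kind=fa.kind, strand_a=fa.strand,
                                   strand_b=fb.strand, result=res))

    noncoding_rows: list[HomologRow] = []
    nc_a = [(c, f) for c in a.chromosomes for f in c.features
            if f.name == vocab.NONCODING]
    nc_b = [(c, f) for c in b.chromosomes for f in c.features
            if f.name == vocab.NONCODING]
    for (ca, fa) in nc_a:
        best = None
        for (cb, fb) in nc_b:
            ident = _alignment_identity(ca.feature_sequence(fa),
                                        cb.feature_sequence(fb), config.scoring)
            if best is None or ident > best[0]:
                best = (ident, cb, fb)
        if best is not None and best[0] >= config.identity_floor:
            res = divergence_between(ca.feature_sequence(fa),
                                     best[1].feature_sequence(best[2]),
                                     kind="noncoding", gene=vocab.NONCODING,
                                     scoring=config.scoring)
            noncoding_rows.append(HomologRow(
                gene=vocab.NONCODING, kind="noncoding", strand_a=fa.strand,
                strand_b=best[2].strand, result=res))
        else:
            noncoding_rows.append(HomologRow(
                gene=vocab.NONCODING, kind="noncoding", strand_a=fa.strand,
                strand_b="-" if best is None else best[2].strand,
                result=None, note="no reciprocal match above identity floor"))
    for (cb, fb) in nc_b:
        if not nc_a:
            noncoding_rows.append(HomologRow(
                gene=vocab.NONCODING, kind="noncoding", strand_a="-",
                strand_b=fb.strand, result=None, note="absent from A"))

    paralog_rows: list[HomologRow] = []
    for genome in (a, b):
        counts: dict[str, int] = {}
        for name in genome.gene_names():
            counts[name] = counts.get(name, 0) + 1
        for name, c in sorted(counts.items()):
            if c > 1 and name != vocab.NONCODING:
                res = paralog_divergence(genome, name, scoring=config.scoring)
                paralog_rows.append(HomologRow(
                    gene=name, kind=vocab.gene_kind(name), strand_a="", strand_b="",
                    result=res, note=f"paralogs within {genome.label}"))

    scored = [r.result for r in rows if r.result is not None]
    pcg = [r.result for r in rows if r.result is not None and r.kind == "PCG"]
    aggregates = {
        "all_pooled": aggregate_divergence(scored, "pooled"),
        "all_mean": aggregate_divergence(scored, "mean"),
        "pcg_pooled": aggregate_divergence(pcg, "pooled"),
        "pcg_mean": aggregate_divergence(pcg, "mean"),
        "n_homologs": len(scored),
    }

    at_table = {}
    for label, genome in ((a.label, a), (b.label, b)):
        per_chrom = {c.record.id: at_content(c.record) for c in genome.chromosomes}
        merged = "".join(c.record.residues for c in genome.chromosomes)
        from .genome import SequenceRecord
        whole = at_content(SequenceRecord(id="_", residues=merged))
        at_table[label] = {"chromosomes": per_chrom, "genome": whole}

    inventory = [{"genome": g.label, "chromosome": c.record.id,
                  "length": len(c.record), "topology": c.record.topology,
                  "features": len(c.features)}
                 for g in (a, b) for c in g.chromosomes]

    return ComparisonReport(label_a=a.label, label_b=b.label, rows=rows,
                            noncoding_rows=noncoding_rows,
                            paralog_rows=paralog_rows, events=events,
                            aggregates=aggregates, at_table=at_table,
                            inventory=inventory, config=config)
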