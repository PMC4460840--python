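"""Synthetic thrips-like mitogenomes with planted, recorded truth.

The generator emits a 37-gene + control-region circular mitogenome with an
A+T-rich base composition typical of thrips (~75-82%), evolves a pair of
genomes apart by planted substitutions and rearrangement events (tRNA
inversions, translocations, fission of a mini-circle with duplicated
control region and trnS1), and simulates NGS-style contigs whose errors
are enriched at contig termini and in A/T homopolymers.  Every random
choice derives from an explicit seed and the full truth (events, per-gene
divergence, per-position changes) is returned alongside the data, so each
downstream analysis can be tested by exact recovery.

The substitution process is i.i.d. per site with an A/T-biased equilibrium
holding the composition target; divergence is planted as an exact number of
substituted sites and verified against the package's own divergence
statistic (rejection-resampled within tolerance when needed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import vocab
from .audit import AuditRules, ChangeRecord, classify_changes
from .divergence import divergence_between
from .genome import (Chromosome, GeneFeature, MitoGenome, SequenceRecord,
                     ValidationError)
from .rearrange import GeneOrder, RearrangementEvent, base, extract_order
from .thrips import ANCESTRAL_ORDER

#: thrips-typical gene lengths (bp); tRNAs ~65, control region ~350, so the
#: canonical fission products form a mini-circle of just under 1 kb
DEFAULT_GENE_LENGTHS: dict[str, int] = (
    {
        "cox1": 1530, "cox2": 680, "cox3": 780, "cob": 1130,
        "nad1": 930, "nad2": 980, "nad3": 350, "nad4": 1330, "nad4L": 290,
        "nad5": 1700, "nad6": 500, "atp6": 670, "atp8": 160,
        "rrnS": 780, "rrnL": 1250, vocab.CONTROL: 350,
    }
    | {t: 65 for t in vocab.TRNAS}
)

#: probability that a base repeats its predecessor; AT-rich mitogenome
#: sequence is strongly homopolymer-rich, which an i.i.d. draw understates.
#: The chain's stationary distribution equals the i.i.d. composition, so the
#: A+T target is unaffected.
RUN_EXTENSION = 0.45


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    gene_lengths: dict = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    at_target: float = 78.0
    order_template: GeneOrder = ANCESTRAL_ORDER
    run_extension: float = RUN_EXTENSION

    def __post_init__(self):
        if not 50.0 <= self.at_target <= 95.0:
            raise ValidationError("at_target must be within [50, 95]")
        if any(length < 1 for length in self.gene_lengths.values()):
            raise ValidationError("all gene lengths must be >= 1")
        if not 0.0 <= self.run_extension < 1.0:
            raise ValidationError("run_extension must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated dataset."""

    planted_events: list = field(default_factory=list)
    planted_divergence: dict = field(default_factory=dict)
    planted_changes: list = field(default_factory=list)
    seed: int | None = None

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (RearrangementEvent, ChangeRecord)):
                d = dataclasses.asdict(o)
                for k, v in d.items():
                    if isinstance(v, frozenset):
                        d[k] = sorted(v)
                return d
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(type(o))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


def _random_seq(rng: np.random.Generator, length: int, at: float,
                rho: float = RUN_EXTENSION) -> str:
    p_at = at / 100.0
    probs = np.array([p_at / 2, (1 - p_at) / 2, (1 - p_at) / 2, p_at / 2])
    draws = rng.choice(4, size=length, p=probs)
    repeat = rng.random(length) < rho
    bases = "ACGT"
    out = [bases[draws[0]]]
    for i in range(1, length):
        out.append(out[-1] if repeat[i] else bases[draws[i]])
    return "".join(out)


def _control_region_seq(rng: np.random.Generator, length: int, at: float,
                        rho: float = RUN_EXTENSION) -> str:
    """Control region with its diagnostic motifs: a T-stretch and an
    A+T-rich segment."""
    t_stretch = "T" * 12
    rich_len = max(1, length // 4)
    rich = _random_seq(rng, rich_len, 100.0, rho)
    rest = _random_seq(rng, max(0, length - len(t_stretch) - rich_len), at, rho)
    return (t_stretch + rich + rest)[:length]


def generate_ancestor(config: GeneratorConfig,
                      label: str = "synthetic_ancestor") -> MitoGenome:
    """Build a single circular chromosome following the order template.

    Genes are drawn i.i.d. at the A+T target (whole-genome composition lands
    within a fraction of a point of the target); strands follow the signs of
    the template.  Multi-chromosome templates are concatenated into one
    circle: the ancestor is unipartite by construction.
    """
    rng = np.random.default_rng(config.seed)
    blocks: list[tuple[str, str, str]] = []   # (name, strand, genome-strand seq)
    seen: set[str] = set()
    for _, genes in config.order_template.chromosomes:
        for token in genes:
            name = base(token)
            if name in seen:      # template paralogs collapse in the ancestor
                continue
            seen.add(name)
            length = config.gene_lengths.get(name, 100)
            if name == vocab.CONTROL:
                seq = _control_region_seq(rng, length, config.at_target,
                                          config.run_extension)
            else:
                seq = _random_seq(rng, length, config.at_target,
                                  config.run_extension)
            strand = "N" if token.startswith("-") else "J"
            blocks.append((name, strand, seq))
    return MitoGenome(label=label, chromosomes=(
        _blocks_to_chromosome(blocks, f"{label}_chr1"),))


def _blocks_to_chromosome(blocks, record_id: str) -> Chromosome:
    seq_parts, feats, pos = [], [], 0
    for name, strand, seq in blocks:
        seq_parts.append(seq)
        feats.append(GeneFeature(name=name, kind=vocab.gene_kind(name),
                                 strand=strand, start=pos, end=pos + len(seq)))
        pos += len(seq)
    rec = SequenceRecord(id=record_id, residues="".join(seq_parts),
                         topology="circular")
    return Chromosome(record=rec, features=tuple(feats))


def _chromosome_to_blocks(chrom: Chromosome) -> list[tuple[str, str, str]]:
    n = len(chrom.record)
    out = []
    for f in chrom.features:
        s = chrom.record.residues
        raw = s[f.start:] + s[:f.end] if f.wraps else s[f.start:f.end]
        out.append((f.name, f.strand, raw))
    if sum(len(b[2]) for b in out) != n:
        raise ValidationError("chromosome has unannotated sequence; "
                              "block-level editing requires full tiling")
    return out


_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _mutate_to_target(rng: np.random.Generator, seq: str, target: float,
                      kind: str, tol: float, max_tries: int = 100) -> str:
    """Substitute round(target*L/100) distinct sites; verify the realized
    divergence statistic and resample sites if rounding or alignment quirks
    push it outside ``tol``.

    Replacement bases are drawn from the sequence's own composition so the
    substitution process is stationary: a diverged AT-rich genome stays
    AT-rich.
    """
    if target <= 0:
        return seq
    L = len(seq)
    k = min(L, round(target * L / 100.0))
    freq = {b: max(seq.count(b), 1) for b in "ACGT"}
    repl_probs = {}
    for b in "ACGT":
        others = _OTHER[b]
        w = np.array([freq[o] for o in others], dtype=float)
        repl_probs[b] = (others, w / w.sum())
    best = None
    for _ in range(max_tries):
        sites = rng.choice(L, size=k, replace=False)
        out = list(seq)
        for i in sites:
            others, p = repl_probs[out[i]]
            out[i] = others[rng.choice(3, p=p)]
        cand = "".join(out)
        realized = divergence_between(seq, cand, kind=kind).percent
        if abs(realized - target) <= tol:
            return cand
        if best is None or abs(realized - target) < best[0]:
            best = (abs(realized - target), cand)
    return best[1]


def fission_minicircle(genome: MitoGenome, move: set[str], duplicate: set[str],
                       paralog_divergence: float | dict = 0.0,
                       seed: int = 0) -> MitoGenome:
    """Split a unipartite genome: ``move`` genes leave for a new mini-circle,
    ``duplicate`` features are copied onto it and diverged from their
    parent copies by ``paralog_divergence`` percent (scalar or per-feature
    map; realized within +-0.5)."""
    if len(genome.chromosomes) != 1:
        raise ValidationError("fission requires a unipartite genome")
    move, duplicate = set(move), set(duplicate)
    if not move and not duplicate:
        return genome
    present = set(genome.gene_names())
    missing = (move | duplicate) - present
    if missing:
        raise ValidationError(f"cannot fission absent genes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    blocks = _chromosome_to_blocks(genome.chromosomes[0])
    main = [b for b in blocks if b[0] not in move]
    mini = [b for b in blocks if b[0] in move]
    for name, strand, seq in blocks:
        if name in duplicate:
            target = (paralog_divergence.get(name, 0.0)
                      if isinstance(paralog_divergence, dict)
                      else paralog_divergence)
            copy = _mutate_to_target(rng, seq, target,
                                     kind=vocab.gene_kind(name), tol=0.5)
            mini.append((name, strand, copy))
    chr1 = _blocks_to_chromosome(main, f"{genome.label}_chr1")
    chr2 = _blocks_to_chromosome(mini, f"{genome.label}_chr2")
    return MitoGenome(label=genome.label, chromosomes=(chr1, chr2))


def _apply_inversion(blocks, gene):
    from .genome import reverse_complement
    out = []
    for name, strand, seq in blocks:
        if name == gene:
            out.append((name, "N" if strand == "J" else "J",
                        reverse_complement(seq)))
        else:
            out.append((name, strand, seq))
    return out


def _apply_translocation(blocks, run: list[str], rng: np.random.Generator,
                         frozen: set[str]):
    names = [b[0] for b in blocks]
    start = names.index(run[0])
    if names[start:start + len(run)] != list(run):
        raise ValidationError(f"translocation run {run} not contiguous")
    moved = blocks[start:start + len(run)]
    rest = blocks[:start] + blocks[start + len(run):]
    # insertion boundaries must not restore the original context, sit next
    # to a gene touched by another event, or land beside the run's old
    # neighbors (an adjacent swap is explainable by moving either gene, so
    # the planted event would not be uniquely recoverable)
    old_nb = {names[(start - 1) % len(names)],
              names[(start + len(run)) % len(names)]}
    n = len(rest)
    legal = [i for i in range(n + 1)
             if i != start
             and rest[(i - 1) % n][0] not in frozen | old_nb
             and rest[i % n][0] not in frozen | old_nb]
    if not legal:
        raise ValidationError("no legal insertion point for translocation")
    at = legal[rng.integers(len(legal))]
    return rest[:at] + moved + rest[at:]


def evolve_pair(ancestor: MitoGenome, events: list[RearrangementEvent],
                divergence: dict[str, float], seed: int,
                paralog_divergence: dict | float | None = None,
                ) -> tuple[MitoGenome, MitoGenome, SyntheticTruth]:
    """Derive genome B from the ancestor by planted events and divergence.

    Genome A is the ancestor itself; genome B carries exactly ``events``
    (applied to its gene order) and per-homolog substitution divergence from
    ``divergence`` (absent genes stay at 0).  Realized divergence, measured
    by this package's own statistic, lands within +-1 point of each target.
    Duplicated-feature divergence for a fragmentation event defaults to the
    values observed between the sequenced mini-circle paralogs and their
    large-chromosome copies (control region 1.65%, trnS1 0%).
    """
    if len(ancestor.chromosomes) != 1:
        raise ValidationError("evolve_pair expects a unipartite ancestor")
    present = set(ancestor.gene_names())
    touched: set[str] = set()
    for ev in events:
        genes = set(ev.genes) | set(ev.duplicated)
        if genes - present:
            raise ValidationError(f"event {ev} names absent genes")
        if genes & touched:
            raise ValidationError("events touch overlapping gene sets")
        touched |= genes
    unknown = set(divergence) - present
    if unknown:
        raise ValidationError(f"divergence targets for absent genes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    blocks = _chromosome_to_blocks(ancestor.chromosomes[0])
    mutated = []
    for name, strand, seq in blocks:
        target = divergence.get(name, 0.0)
        # mutate in coding orientation so the statistic sees the same string
        from .genome import reverse_complement
        coding = reverse_complement(seq) if strand == "N" else seq
        out = _mutate_to_target(rng, coding, target, kind=vocab.gene_kind(name),
                                tol=1.0)
        mutated.append((name, strand,
                        reverse_complement(out) if strand == "N" else out))

    for ev in sorted(events, key=lambda e: (e.kind != "inversion", str(e))):
        if ev.kind == "inversion":
            (gene,) = ev.genes
            mutated = _apply_inversion(mutated, gene)
        elif ev.kind == "translocation":
            names = [b[0] for b in mutated]
            run = sorted(ev.genes, key=names.index)
            mutated = _apply_translocation(mutated, run, rng, touched - set(run))
        elif ev.kind != "fragmentation":
            raise ValidationError(f"unsupported planted event kind {ev.kind!r}")

    genome_b = MitoGenome(label=f"{ancestor.label}_derived", chromosomes=(
        _blocks_to_chromosome(mutated, f"{ancestor.label}_derived_chr1"),))
    for ev in events:
        if ev.kind == "fragmentation":
            pdiv = paralog_divergence
            if pdiv is None:
                pdiv = {vocab.CONTROL: 1.65, "trnS1": 0.0}
            genome_b = fission_minicircle(genome_b, set(ev.genes),
                                          set(ev.duplicated), pdiv,
                                          seed=int(rng.integers(2**31)))
    truth = SyntheticTruth(planted_events=list(events),
                           planted_divergence=dict(divergence), seed=seed)
    return ancestor, genome_b, truth


def simulate_contig(chromosome: Chromosome, base_error: float = 0.0045,
                    terminal_multiplier: float = 4.0,
                    homopolymer_multiplier: float = 6.0,
                    seed: int = 0,
                    rules: AuditRules = AuditRules(),
                    ) -> tuple[str, SyntheticTruth]:
    """Emit an NGS-style contig of a chromosome with planted errors.

    Per-position error probability is ``base_error`` scaled by the terminal
    multiplier inside the first/last ``rules.terminal_window`` positions and
    by the homopolymer multiplier inside A/T runs of >=
    ``rules.homopolymer_min`` (factors stack, capped at 0.95).  Errors in
    homopolymer context are mostly run-length indels; elsewhere mostly
    substitutions.  The contig differs from the chromosome exactly at the
    returned ChangeRecords.
    """
    if not 0.0 <= base_error <= 1.0:
        raise ValidationError("base_error must be in [0,1]")
    if terminal_multiplier < 1 or homopolymer_multiplier < 1:
        raise ValidationError("multipliers must be >= 1")
    from .audit import homopolymer_mask
    rng = np.random.default_rng(seed)
    ref = chromosome.record.residues
    n = len(ref)
    hmask = homopolymer_mask(chromosome, rules)
    out: list[str] = []
    changes: list[ChangeRecord] = []
    for i, b in enumerate(ref):
        p = base_error
        if i < rules.terminal_window or i >= n - rules.terminal_window:
            p *= terminal_multiplier
        if hmask[i]:
            p *= homopolymer_multiplier
        if rng.random() >= min(p, 0.95):
            out.append(b)
            continue
        if hmask[i]:
            kinds, probs = ("insertion", "deletion", "substitution"), (.35, .35, .30)
        else:
            kinds, probs = ("substitution", "insertion", "deletion"), (.60, .20, .20)
        kind = kinds[rng.choice(3, p=probs)]
        if kind == "substitution":
            new = _OTHER[b][rng.integers(3)] if b in _OTHER else "A"
            changes.append(ChangeRecord(contig_pos=len(out), ref_pos=i,
                                        type="substitution", ref_residues=b,
                                        contig_residues=new))
            out.append(new)
        elif kind == "insertion":
            ins = b if hmask[i] else "ACGT"[rng.integers(4)]
            changes.append(ChangeRecord(contig_pos=len(out), ref_pos=i,
                                        type="insertion", ref_residues="",
                                        contig_residues=ins))
            out.append(ins)
            out.append(b)
        else:
            changes.append(ChangeRecord(contig_pos=len(out), ref_pos=i,
                                        type="deletion", ref_residues=b,
                                        contig_residues=""))
    contig = "".join(out)
    from .audit import left_align_changes
    changes = left_align_changes(changes, chromosome)
    annotated, _ = classify_changes(changes, len(contig), chromosome, rules)
    truth = SyntheticTruth(planted_changes=annotated, seed=seed)
    return contig, truth


def unify_bipartite(genome: MitoGenome, insert_after: str = "nad4L") -> MitoGenome:
    """Inverse of fission: fold a mini-circle back into the main chromosome.

    Genes unique to the smaller chromosome are inserted (in their mini-circle
    order) after ``insert_after`` on the main chromosome; duplicated
    features' extra copies are dropped.  This builds the unipartite
    null-hypothesis model for the in-silico PCR architecture test from the
    very same sequences as the bipartite genome.
    """
    if len(genome.chromosomes) != 2:
        raise ValidationError("unify_bipartite expects a bipartite genome")
    main, mini = sorted(genome.chromosomes, key=lambda c: -len(c.record))
    main_names = {f.name for f in main.features}
    moved = [b for b in _chromosome_to_blocks(mini) if b[0] not in main_names]
    blocks = _chromosome_to_blocks(main)
    i = [j for j, b in enumerate(blocks) if b[0] == insert_after]
    if not i:
        raise ValidationError(f"{insert_after!r} absent from main chromosome")
    at = i[0] + 1
    merged = blocks[:at] + moved + blocks[at:]
    return MitoGenome(label=f"{genome.label}_unified", chromosomes=(
        _blocks_to_chromosome(merged, f"{genome.label}_unified_chr1"),))


def diagnostic_panel(unipartite: MitoGenome, gene: str = "nad6",
                     flank: int = 200, primer_len: int = 22):
    """Extract the four-primer-pair panel that discriminates architectures.

    From a unipartite model: two boundary-spanning pairs (across the
    upstream and downstream junctions of ``gene``), one inward internal pair
    within the gene, and the outward-facing pair (reverse complements of the
    internal primers).  If ``gene`` sits on its own mini-circle, the
    boundary pairs find no convergent sites, while the outward pair
    amplifies the complementary arc of the mini-circle.
    """
    from .genome import reverse_complement
    from .pcr import PrimerPair
    (chrom, feat), = unipartite.find_features(gene)
    seq = chrom.record.residues
    n = len(seq)
    if feat.wraps:
        raise ValidationError("panel design across a wrapping gene unsupported")
    s, e = feat.start, feat.end
    up_f = seq[(s - flank) % n:(s - flank) % n + primer_len]
    down_r = seq[(e + flank - primer_len) % n:(e + flank - primer_len) % n + primer_len]
    inner_f = seq[s + 20:s + 20 + primer_len]
    inner_r = seq[e - 20 - primer_len:e - 20]
    return [
        PrimerPair(name=f"{gene}_upstream_boundary", forward=up_f,
                   reverse=reverse_complement(inner_f)),
        PrimerPair(name=f"{gene}_downstream_boundary", forward=inner_r,
                   reverse=reverse_complement(down_r)),
        PrimerPair(name=f"{gene}_internal", forward=inner_f,
                   reverse=reverse_complement(inner_r)),
        PrimerPair(name=f"{gene}_outward", forward=reverse_complement(inner_f),
                   reverse=inner_r),
    ]


def random_synthetic_pair(seed: int, n_events: int = 3,
                          divergence_range: tuple[float, float] = (2.0, 25.0),
                          ) -> tuple[MitoGenome, MitoGenome, SyntheticTruth]:
    """Convenience: ancestor + derived genome with random non-overlapping
    planted events (inversions/translocations/one optional fission) and
    random per-gene divergence targets."""
    rng = np.random.default_rng(seed)
    cfg = GeneratorConfig(seed=int(rng.integers(2**31)))
    anc = generate_ancestor(cfg)
    order = extract_order(anc)
    genes = [base(t) for t in order.chromosomes[0][1]]
    trnas = [g for g in genes if g.startswith("trn")]
    rng.shuffle(trnas)
    pool = list(trnas)
    events: list[RearrangementEvent] = []
    kinds = list(rng.choice(["inversion", "translocation"], size=n_events))
    if n_events and rng.random() < 0.5:
        kinds[0] = "fragmentation"
    for kind in kinds:
        if kind == "fragmentation":
            events.append(RearrangementEvent(
                kind="fragmentation", genes=frozenset(("nad6", "trnC")),
                duplicated=frozenset((vocab.CONTROL, "trnS1"))))
            for g in ("nad6", "trnC", "trnS1"):
                if g in pool:
                    pool.remove(g)
        else:
            # keep event gene sets non-adjacent so recovery is unambiguous
            g = None
            while pool:
                cand = pool.pop()
                i = genes.index(cand)
                nbrs = {genes[(i - 1) % len(genes)], genes[(i + 1) % len(genes)]}
                if not nbrs & {x for e in events for x in e.genes}:
                    g = cand
                    break
            if g is None:
                continue
            events.append(RearrangementEvent(kind=kind, genes=frozenset((g,))))
    lo, hi = divergence_range
    div = {g: float(rng.uniform(lo, hi)) for g in genes}
    return evolve_pair(anc, events, div, seed=int(rng.integers(2**31)))
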