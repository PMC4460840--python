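"""Signed gene-order algebra: adjacencies, shared blocks, event calls.

A genome's gene order is a signed, anchored linearization of each circular
chromosome: ``+gene`` lies on the majority-coding (J) strand, ``-gene`` on
the minority (N) strand.  Gene boundaries (adjacencies) are compared
strand-blind — a tRNA flipped in place keeps both its boundaries — and
orientation is consulted only to call inversions.  The event taxonomy is
deliberately small (single-gene inversions, contiguous-run translocations,
chromosome fission with an attendant duplication), matching how
rearrangements are described in highly rearranged insect mitogenomes; no
genome-rearrangement distance machinery (DCJ etc.) is involved.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from . import vocab
from .genome import MitoGenome, ValidationError


def signed(name: str, strand: str) -> str:
    return ("-" + name) if strand == "N" else name


def base(token: str) -> str:
    return token[1:] if token.startswith("-") else token


def flip(token: str) -> str:
    return token[1:] if token.startswith("-") else "-" + token


@dataclass(frozen=True)
class GeneOrder:
    """Signed gene order of a genome, one tuple of tokens per chromosome."""

    chromosomes: tuple[tuple[str, tuple[str, ...]], ...]
    anchor: str = "cox1"
    circular: bool = True

    def all_tokens(self) -> list[str]:
        return [t for _, genes in self.chromosomes for t in genes]

    def gene_counts(self) -> Counter:
        return Counter(base(t) for t in self.all_tokens())


@dataclass(frozen=True)
class RearrangementEvent:
    kind: str                      # inversion | translocation | fragmentation | duplication
    genes: frozenset
    duplicated: frozenset = frozenset()
    evidence: tuple = field(default=(), compare=False)

    def __str__(self) -> str:
        parts = f"{self.kind}({{{', '.join(sorted(self.genes))}}}"
        if self.duplicated:
            parts += f", duplication {{{', '.join(sorted(self.duplicated))}}}"
        return parts + ")"


def extract_order(genome: MitoGenome, anchor: str = "cox1") -> GeneOrder:
    """Linearize each circular chromosome into a signed gene order.

    The chromosome carrying the anchor is rotated so the anchor comes first
    and, if the anchor sits on the N strand, the whole chromosome is flipped
    so the anchor reads ``+``.  Chromosomes without the anchor are rotated to
    start at their lexicographically smallest gene.  Annotated noncoding
    regions are not part of the gene order.
    """
    if not any(f.name == anchor for c in genome.chromosomes for f in c.features):
        raise ValidationError(f"anchor {anchor!r} absent from genome {genome.label}")
    chrom_orders = []
    for chrom in genome.chromosomes:
        tokens = [signed(f.name, f.strand) for f in chrom.features
                  if f.name != vocab.NONCODING]
        if not tokens:
            continue
        names = [base(t) for t in tokens]
        if anchor in names:
            i = names.index(anchor)
            if tokens[i].startswith("-"):
                tokens = [flip(t) for t in reversed(tokens)]
                names = [base(t) for t in tokens]
                i = names.index(anchor)
            tokens = tokens[i:] + tokens[:i]
        else:
            i = names.index(min(names))
            tokens = tokens[i:] + tokens[:i]
        chrom_orders.append((chrom.record.id, tuple(tokens)))
    return GeneOrder(chromosomes=tuple(chrom_orders), anchor=anchor)


def _pairs(genes: tuple[str, ...], circular: bool):
    n = len(genes)
    if n < 2:
        return
    for i in range(n - 1):
        yield genes[i], genes[i + 1]
    if circular:
        yield genes[-1], genes[0]


def adjacency_set(order: GeneOrder, oriented: bool = False) -> frozenset:
    """Gene-boundary set of an order, with circular closure per chromosome.

    Strand-blind adjacencies are unordered name pairs; oriented adjacencies
    keep signs, canonicalized so that reading the circle in either direction
    gives the same element.
    """
    out = set()
    for _, genes in order.chromosomes:
        for a, b in _pairs(genes, order.circular):
            if oriented:
                fwd = (a, b)
                rev = (flip(b), flip(a))
                out.add(min(fwd, rev))
            else:
                out.add(frozenset((base(a), base(b))))
    return frozenset(out)


def dedup_paralogs(order: GeneOrder) -> GeneOrder:
    """Drop extra paralog copies, keeping the copy on its home chromosome.

    Home = the chromosome with the most genes (the copy embedded in the
    larger conserved context), so a mini-circle's duplicated control region
    does not manufacture spurious breakpoints.
    """
    counts = order.gene_counts()
    dups = {g for g, c in counts.items() if c > 1}
    if not dups:
        return order
    sizes = {cid: len(genes) for cid, genes in order.chromosomes}
    home = {g: max((cid for cid, genes in order.chromosomes
                    if g in {base(t) for t in genes}), key=lambda c: sizes[c])
            for g in dups}
    new_chroms = []
    for cid, genes in order.chromosomes:
        kept = []
        seen_here = set()
        for t in genes:
            b = base(t)
            if b in dups:
                if home[b] != cid or b in seen_here:
                    continue
                seen_here.add(b)
            kept.append(t)
        if kept:
            new_chroms.append((cid, tuple(kept)))
    return GeneOrder(chromosomes=tuple(new_chroms), anchor=order.anchor,
                     circular=order.circular)


def _neighbors(order: GeneOrder) -> dict[str, frozenset]:
    """Strand-blind neighbor pair of each (deduplicated) gene."""
    nb: dict[str, list] = {}
    for _, genes in order.chromosomes:
        n = len(genes)
        for i, t in enumerate(genes):
            left = genes[(i - 1) % n] if (order.circular or i > 0) else None
            right = genes[(i + 1) % n] if (order.circular or i < n - 1) else None
            nb[base(t)] = frozenset(base(x) for x in (left, right) if x is not None)
    return nb


def _signs(order: GeneOrder) -> dict[str, str]:
    return {base(t): ("-" if t.startswith("-") else "+")
            for _, genes in order.chromosomes for t in genes}


def _remove_genes(order: GeneOrder, drop: set[str]) -> GeneOrder:
    chroms = []
    for cid, genes in order.chromosomes:
        kept = tuple(t for t in genes if base(t) not in drop)
        if kept:
            chroms.append((cid, kept))
    return GeneOrder(chromosomes=tuple(chroms), anchor=order.anchor,
                     circular=order.circular)


def _candidate_runs(order: GeneOrder, candidates: set[str]) -> list[tuple[str, ...]]:
    """All contiguous runs of candidate genes along the order's chromosomes."""
    runs = []
    for _, genes in order.chromosomes:
        names = [base(t) for t in genes]
        n = len(names)
        # maximal candidate stretches, then every contiguous sub-run of each
        idx = [i for i, g in enumerate(names) if g in candidates]
        if not idx:
            continue
        stretches, cur = [], [idx[0]]
        for i in idx[1:]:
            if i == cur[-1] + 1:
                cur.append(i)
            else:
                stretches.append(cur)
                cur = [i]
        stretches.append(cur)
        if order.circular and len(stretches) > 1 and \
                stretches[0][0] == 0 and stretches[-1][-1] == n - 1:
            stretches[0] = stretches.pop() + stretches[0]
        for s in stretches:
            for a in range(len(s)):
                for b in range(a, len(s)):
                    runs.append(tuple(names[i % n] for i in s[a:b + 1]))
    return runs


def _is_contiguous_run(order: GeneOrder, run: tuple[str, ...]) -> bool:
    """True when ``run`` appears as consecutive genes (forward or reversed)
    on some chromosome of the order, with circular wrap."""
    k = len(run)
    targets = (tuple(run), tuple(reversed(run)))
    for _, genes in order.chromosomes:
        names = [base(t) for t in genes]
        n = len(names)
        if k > n:
            continue
        doubled = names + names if order.circular else names
        for i in range(n if order.circular else n - k + 1):
            if tuple(doubled[i:i + k]) in targets:
                return True
    return False


def classify_events(order_a: GeneOrder, order_b: GeneOrder,
                    max_events: int = 4) -> list[RearrangementEvent]:
    """Explain order B relative to order A as a minimal set of events.

    Calls, in order of preference: (i) in-place inversions (both strand-blind
    boundaries conserved, sign flipped); (ii) fission of genes onto an extra
    chromosome, with duplicated features reported as a duplication sub-event;
    (iii) translocations of single genes or contiguous runs, found as the
    smallest set of runs whose removal from both orders equalizes the
    remaining boundary sets (ties broken by fewest moved genes, then
    alphabetically).
    """
    set_a = set(order_a.gene_counts())
    set_b = set(order_b.gene_counts())
    if set_a != set_b:
        orphans = sorted(set_a ^ set_b)
        raise ValidationError(f"gene vocabularies disagree; orphans: {orphans}")

    counts_a, counts_b = order_a.gene_counts(), order_b.gene_counts()
    dup_in_b = frozenset(g for g in counts_b if counts_b[g] > counts_a[g])
    dup_in_a = frozenset(g for g in counts_a if counts_a[g] > counts_b[g])

    a = dedup_paralogs(order_a)
    b = dedup_paralogs(order_b)
    events: list[RearrangementEvent] = []

    # (iii-fission) extra chromosomes on one side
    fission_genes: set[str] = set()
    if len(b.chromosomes) != len(a.chromosomes):
        many, few = (b, a) if len(b.chromosomes) > len(a.chromosomes) else (a, b)
        dup = dup_in_b if many is b else dup_in_a
        main = max(many.chromosomes, key=lambda c: len(c[1]))
        for cid, genes in many.chromosomes:
            if cid == main[0]:
                continue
            moved = frozenset(base(t) for t in genes)
            fission_genes |= moved
            events.append(RearrangementEvent(
                kind="fragmentation", genes=moved, duplicated=dup,
                evidence=(("chromosome", cid),)))
        a = _remove_genes(a, fission_genes)
        b = _remove_genes(b, fission_genes)
    elif dup_in_a or dup_in_b:
        events.append(RearrangementEvent(kind="duplication",
                                         genes=dup_in_a | dup_in_b))

    # (i) inversions: conserved strand-blind context, flipped sign
    nb_a, nb_b = _neighbors(a), _neighbors(b)
    sg_a, sg_b = _signs(a), _signs(b)
    for g in sorted(nb_a):
        if g in nb_b and nb_a[g] == nb_b[g] and sg_a[g] != sg_b[g]:
            events.append(RearrangementEvent(kind="inversion",
                                             genes=frozenset((g,))))

    # (ii) translocations: smallest run set whose removal equalizes boundaries
    adj_a, adj_b = adjacency_set(a), adjacency_set(b)
    if adj_a != adj_b:
        diff = adj_a ^ adj_b
        candidates = {g for pair in diff for g in pair}
        runs = sorted({r for r in _candidate_runs(b, candidates)
                       if _is_contiguous_run(a, r)},
                      key=lambda r: (len(r), r))
        solution = None
        for k in range(1, max_events + 1):
            best = None
            for combo in itertools.combinations(runs, k):
                genes = [g for r in combo for g in r]
                if len(set(genes)) != len(genes):
                    continue
                drop = set(genes)
                if adjacency_set(_remove_genes(a, drop)) == \
                        adjacency_set(_remove_genes(b, drop)):
                    key = (len(genes), tuple(sorted(sorted(r) for r in combo)))
                    if best is None or key < best[0]:
                        best = (key, combo)
            if best is not None:
                solution = best[1]
                break
        if solution is None:
            events.append(RearrangementEvent(
                kind="translocation", genes=frozenset(candidates),
                evidence=(("unresolved", tuple(sorted(map(tuple, diff)))),)))
        else:
            for run in sorted(solution, key=lambda r: sorted(r)):
                events.append(RearrangementEvent(kind="translocation",
                                                 genes=frozenset(run)))
    return events


def shared_blocks(orders: list[GeneOrder]) -> list[dict]:
    """Maximal gene runs whose strand-blind boundaries hold in every order.

    Blocks are reported along the first order's linearization; adding a
    further order can only split or shrink blocks, never grow them.
    """
    if len(orders) < 2:
        raise ValidationError("shared_blocks needs >=2 gene orders")
    deduped = [dedup_paralogs(o) for o in orders]
    shared = frozenset.intersection(*(adjacency_set(o) for o in deduped))
    blocks = []
    for cid, genes in deduped[0].chromosomes:
        names = [base(t) for t in genes]
        n = len(names)
        if n == 1:
            blocks.append({"chromosome": cid, "genes": list(names), "size": 1})
            continue
        joined = [frozenset((names[i], names[(i + 1) % n])) in shared
                  for i in range(n)]  # joined[i]: boundary after gene i holds
        if not deduped[0].circular:
            joined[-1] = False
        if all(joined):
            blocks.append({"chromosome": cid, "genes": list(names), "size": n})
            continue
        # walk runs between broken boundaries, merging across the origin
        start = next(i for i in range(n) if not joined[i]) + 1
        run = []
        for k in range(n):
            i = (start + k) % n
            run.append(names[i])
            if not joined[i]:
                blocks.append({"chromosome": cid, "genes": run, "size": len(run)})
                run = []
        if run:
            blocks.append({"chromosome": cid, "genes": run, "size": len(run)})
    return blocks
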