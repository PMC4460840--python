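"""Controlled vocabulary for animal mitochondrial gene names.

The 37 canonical metazoan mitochondrial genes (13 protein-coding genes, 2
ribosomal RNAs, 22 tRNAs) plus the control region.  Annotation nomenclature
varies wildly across GenBank depositors ("ND6", "nad6", "NADH dehydrogenase
subunit 6" ...), so a mapping table normalizes incoming feature names onto
canonical tokens.  The two serine and two leucine tRNAs are disambiguated by
anticodon: S1 (tct/gct), S2 (tga), L1 (tag), L2 (taa).
"""

from __future__ import annotations

PCGS = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNAS = ("rrnS", "rrnL")
TRNA_LETTERS = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)
TRNAS = tuple(f"trn{x}" for x in TRNA_LETTERS)

#: the 37 genes every complete animal mitogenome is expected to carry
CANONICAL_GENES = PCGS + RRNAS + TRNAS

CONTROL = "control_region"
NONCODING = "noncoding"

KIND_BY_GENE = (
    {g: "PCG" for g in PCGS}
    | {g: "rRNA" for g in RRNAS}
    | {g: "tRNA" for g in TRNAS}
    | {CONTROL: "control", NONCODING: "noncoding"}
)

# anticodon -> canonical serine/leucine token
_SL_ANTICODONS = {"tct": "trnS1", "gct": "trnS1", "tga": "trnS2",
                  "tag": "trnL1", "taa": "trnL2"}

_PCG_ALIASES = {
    "atp6": ["atp6", "atpase6", "atpase 6", "atp synthase f0 subunit 6"],
    "atp8": ["atp8", "atpase8", "atpase 8", "atp synthase f0 subunit 8"],
    "cob": ["cob", "cytb", "cyt b", "cytochrome b"],
    "cox1": ["cox1", "coi", "co1", "coxi", "cytochrome c oxidase subunit 1",
             "cytochrome c oxidase subunit i"],
    "cox2": ["cox2", "coii", "co2", "coxii", "cytochrome c oxidase subunit 2",
             "cytochrome c oxidase subunit ii"],
    "cox3": ["cox3", "coiii", "co3", "coxiii", "cytochrome c oxidase subunit 3",
             "cytochrome c oxidase subunit iii"],
    "nad1": ["nad1", "nd1", "nadh1", "nadh dehydrogenase subunit 1"],
    "nad2": ["nad2", "nd2", "nadh2", "nadh dehydrogenase subunit 2"],
    "nad3": ["nad3", "nd3", "nadh3", "nadh dehydrogenase subunit 3"],
    "nad4": ["nad4", "nd4", "nadh4", "nadh dehydrogenase subunit 4"],
    "nad4L": ["nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l"],
    "nad5": ["nad5", "nd5", "nadh5", "nadh dehydrogenase subunit 5"],
    "nad6": ["nad6", "nd6", "nadh6", "nadh dehydrogenase subunit 6"],
}
_RRNA_ALIASES = {
    "rrnS": ["rrns", "12s", "12s rrna", "s-rrna", "srrna", "small subunit ribosomal rna",
             "12s ribosomal rna", "rns"],
    "rrnL": ["rrnl", "16s", "16s rrna", "l-rrna", "lrrna", "large subunit ribosomal rna",
             "16s ribosomal rna", "rnl"],
}
_AA3 = {
    "ala": "A", "cys": "C", "asp": "D", "glu": "E", "phe": "F", "gly": "G",
    "his": "H", "ile": "I", "lys": "K", "met": "M", "asn": "N", "pro": "P",
    "gln": "Q", "arg": "R", "thr": "T", "val": "V", "trp": "W", "tyr": "Y",
}
_CONTROL_ALIASES = ["control_region", "control region", "a+t rich region",
                    "at rich region", "a+t-rich region", "d-loop", "dloop", "cr"]


def _build_alias_table() -> dict[str, str]:
    table: dict[str, str] = {}
    for canon, aliases in (_PCG_ALIASES | _RRNA_ALIASES).items():
        for a in aliases:
            table[a] = canon
    for canon in TRNAS:
        table[canon.lower()] = canon
    for aa3, letter in _AA3.items():
        for tok in (f"trn{letter.lower()}", f"trn-{letter.lower()}",
                    f"trn({letter.lower()})", f"trna-{aa3}", f"trna {aa3}", aa3):
            table[tok] = f"trn{letter}"
    for n in ("1", "2"):
        for tok in (f"trns{n}", f"trn-s{n}", f"trna-ser{n}", f"trna-ser {n}", f"ser{n}"):
            table[tok] = f"trnS{n}"
        for tok in (f"trnl{n}", f"trn-l{n}", f"trna-leu{n}", f"trna-leu {n}", f"leu{n}"):
            table[tok] = f"trnL{n}"
    for a in _CONTROL_ALIASES:
        table[a] = CONTROL
    return table


_ALIASES = _build_alias_table()


def normalize_gene_name(raw: str, anticodon: str | None = None,
                        extra: dict[str, str] | None = None) -> str | None:
    """Map an annotation label onto a canonical token.

    ``anticodon`` (if supplied) disambiguates serine/leucine tRNAs.  ``extra``
    lets callers extend the shipped alias table.  Returns ``None`` when the
    label is not recognized; callers should then fall back to ``noncoding``.
    """
    key = raw.strip().lower().replace("_", " ")
    key = " ".join(key.split())
    if extra:
        lowered = {k.strip().lower(): v for k, v in extra.items()}
        if key in lowered:
            return lowered[key]
    hit = _ALIASES.get(key) or _ALIASES.get(key.replace(" ", ""))
    # ambiguous trnS/trnL labels are resolved by anticodon when available
    if hit is None and anticodon:
        hit = _SL_ANTICODONS.get(anticodon.strip().lower())
    return hit


def gene_kind(name: str) -> str:
    """Return PCG|tRNA|rRNA|control|noncoding for a canonical token."""
    return KIND_BY_GENE.get(name, "noncoding")
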