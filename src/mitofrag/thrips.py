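"""Published signed gene orders for *Scirtothrips dorsalis* mitogenomes.

Gene orders and coding strands of the two cryptic species, transcribed from
the published genome comparison: East Asia 1 (EA1, GenBank KM349826) has the
single circular chromosome typical of animals; South Asia 1 (SA1) is
bipartite, with a large chromosome (KM349827) and a 921 bp mini-circle
(KM349828) carrying *nad6* and *trnC* plus duplicated copies of *trnS1* and
the control region.  Orders are cox1-anchored linearizations; a leading
``-`` marks the minority (N) coding strand.  The long non-coding regions
unique to each genome (no cross-species homolog) are not part of the gene
order.
"""

from __future__ import annotations

from .rearrange import GeneOrder

# shared backbone of the two cryptic species, cox1-first
_BACKBONE_5P = (
    "cox1", "nad3", "trnL2", "cox2", "trnD", "trnR", "trnG", "trnK",
    "cox3", "trnI", "trnL1", "trnT", "trnP", "trnN", "trnE", "trnQ", "cob",
)
_BACKBONE_MID = (
    "nad2", "trnW", "nad1", "trnM", "trnA",
)
_BACKBONE_3P = (
    "rrnS", "atp8", "atp6", "trnS1", "control_region",
    "-nad5", "-trnH", "-nad4", "-nad4L",
)

#: EA1: unipartite; trnY inverted to N, trnF on J; nad6/trnC in situ.
EA1_ORDER = GeneOrder(chromosomes=(
    ("KM349826", _BACKBONE_5P + ("-trnY",) + _BACKBONE_MID + ("trnF",)
     + _BACKBONE_3P + ("trnC", "nad6", "trnV", "rrnL", "trnS2")),
), anchor="cox1")

#: SA1: bipartite; trnF inverted to N, trnY on J; nad6+trnC on the
#: mini-circle together with paralogous trnS1 and control region.
SA1_ORDER = GeneOrder(chromosomes=(
    ("KM349827", _BACKBONE_5P + ("trnY",) + _BACKBONE_MID + ("-trnF",)
     + _BACKBONE_3P + ("trnV", "rrnL", "trnS2")),
    ("KM349828", ("trnC", "nad6", "trnS1", "control_region")),
), anchor="cox1")

#: unipartite view of the SA1 order with the mini-circle genes restored to
#: their ancestral location (between nad4L and trnV, where nad6 sits in all
#: other thrips); used as the default template for synthetic ancestors
ANCESTRAL_ORDER = GeneOrder(chromosomes=(
    ("ancestor", _BACKBONE_5P + ("trnY",) + _BACKBONE_MID + ("-trnF",)
     + _BACKBONE_3P + ("trnC", "nad6", "trnV", "rrnL", "trnS2")),
), anchor="cox1")

#: the ten-gene run (trnY..atp6) whose boundaries are conserved in all five
#: sequenced thrips mitogenomes
TEN_GENE_BLOCK = ("trnY", "nad2", "trnW", "nad1", "trnM", "trnA", "trnF",
                  "rrnS", "atp8", "atp6")

#: published per-homolog percent differences between the two cryptic species
#: (38 homologs: 37 genes + the control region); the default divergence
#: targets for synthetic genome pairs
TABLE_DIVERGENCE: dict[str, float] = {
    "cox1": 11.76, "nad3": 19.21, "trnL2": 5.97, "cox2": 12.83, "trnD": 13.43,
    "trnR": 1.47, "trnG": 9.23, "trnK": 4.76, "cox3": 11.28, "trnI": 14.29,
    "trnL1": 9.23, "trnT": 7.81, "trnP": 9.23, "trnN": 10.17, "trnE": 12.12,
    "trnQ": 2.94, "cob": 13.51, "trnY": 10.61, "nad2": 19.64, "trnW": 7.35,
    "nad1": 17.80, "trnM": 6.25, "trnA": 3.03, "trnF": 4.41, "rrnS": 12.42,
    "atp8": 21.14, "atp6": 18.82, "trnS1": 11.67, "control_region": 29.15,
    "nad5": 16.34, "trnH": 15.15, "nad4": 19.12, "nad4L": 20.63, "trnC": 8.06,
    "nad6": 21.37, "trnV": 13.33, "rrnL": 12.09, "trnS2": 4.41,
}
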