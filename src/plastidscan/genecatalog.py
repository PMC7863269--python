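"""Deterministic toy plastid gene catalogs for the simulator.

The "full" catalog carries the standard 113-gene plastome complement
(79 protein-coding, 30 tRNA, 4 rRNA genes; 17 of them duplicated in the
inverted repeats, counted once), with gene order and intron placement
modelled on a typical Asteraceae plastome.  Gene lengths are plausible
rather than exact; the intergenic spacers that serve as classic barcode
markers (trnH-psbA, psbM-trnD, trnR-trnT, trnT-trnL, rpl22-rps19-rpl2) are
given fixed widths so marker extraction has stable anchors.  The "toy"
catalog is a 13-gene miniature for fast simulations.

All positions are computed from the requested region lengths: genes keep
their order, explicitly sized spacers keep their width, and the remaining
space is shared equally among the free spacers.
"""
from __future__ import annotations

from dataclasses import dataclass

from .records import GeneFeature

__all__ = ["build_catalog", "DEFAULT_MARKERS", "CatalogError"]


class CatalogError(ValueError):
    """Region too small for the requested gene complement."""


@dataclass(frozen=True)
class _G:
    name: str
    kind: str  # p / t / r shorthand expanded below
    length: int
    exons: int = 1


_KIND = {"p": "protein_coding", "t": "tRNA", "r": "rRNA"}

# name, kind, length, exon count
_LSC = [
    _G("trnH-GUG", "t", 75), _G("psbA", "p", 1060), _G("trnK-UUU", "t", 2500, 2),
    _G("matK", "p", 1520), _G("rps16", "p", 1100, 2), _G("trnQ-UUG", "t", 75),
    _G("psbK", "p", 186), _G("psbI", "p", 111), _G("trnS-GCU", "t", 75),
    _G("trnG-UCC", "t", 75), _G("trnR-UCU", "t", 75), _G("trnT-GGU", "t", 75),
    _G("atpA", "p", 1500), _G("atpF", "p", 1200, 2), _G("atpH", "p", 246),
    _G("atpI", "p", 744), _G("rps2", "p", 711), _G("rpoC2", "p", 4100),
    _G("rpoC1", "p", 2800, 2), _G("rpoB", "p", 3200), _G("trnC-GCA", "t", 75),
    _G("petN", "p", 90), _G("psbM", "p", 105), _G("trnD-GUC", "t", 75),
    _G("trnY-GUA", "t", 75), _G("trnE-UUC", "t", 75), _G("psbD", "p", 1062),
    _G("psbC", "p", 1386), _G("trnS-UGA", "t", 75), _G("psbZ", "p", 189),
    _G("trnG-GCC", "t", 700, 2), _G("trnfM-CAU", "t", 75), _G("rps14", "p", 303),
    _G("psaB", "p", 2205), _G("psaA", "p", 2253), _G("ycf3", "p", 1500, 3),
    _G("trnS-GGA", "t", 75), _G("rps4", "p", 606), _G("trnT-UGU", "t", 75),
    _G("trnL-UAA", "t", 600, 2), _G("trnF-GAA", "t", 75), _G("ndhJ", "p", 477),
    _G("ndhK", "p", 678), _G("trnV-UAC", "t", 700, 2), _G("ndhC", "p", 363),
    _G("trnM-CAU", "t", 75), _G("atpE", "p", 402), _G("atpB", "p", 1497),
    _G("rbcL", "p", 1434), _G("accD", "p", 1500), _G("psaI", "p", 111),
    _G("ycf4", "p", 555), _G("cemA", "p", 690), _G("petA", "p", 963),
    _G("psbJ", "p", 123), _G("psbL", "p", 117), _G("psbF", "p", 120),
    _G("psbE", "p", 252), _G("petL", "p", 96), _G("petG", "p", 114),
    _G("trnW-CCA", "t", 75), _G("trnP-UGG", "t", 75), _G("psaJ", "p", 135),
    _G("rpl33", "p", 201), _G("rps18", "p", 306), _G("rpl20", "p", 355),
    _G("clpP", "p", 1800, 3), _G("psbB", "p", 1527), _G("psbT", "p", 108),
    _G("psbN", "p", 132), _G("psbH", "p", 222), _G("petB", "p", 1300, 2),
    _G("petD", "p", 750), _G("rpoA", "p", 1014), _G("rps11", "p", 417),
    _G("rpl36", "p", 114), _G("infA", "p", 234), _G("rps8", "p", 399),
    _G("rpl14", "p", 369), _G("rpl16", "p", 450), _G("rps3", "p", 657),
    _G("rpl22", "p", 460), _G("rps19", "p", 279),
]

_IRB = [
    _G("rpl2", "p", 1490, 2), _G("rpl23", "p", 282), _G("trnI-CAU", "t", 75),
    _G("ycf2", "p", 6800), _G("trnL-CAA", "t", 75), _G("ndhB", "p", 1500, 2),
    _G("rps7", "p", 470), _G("rps12", "p", 900, 2), _G("trnV-GAC", "t", 75),
    _G("rrn16", "r", 1490), _G("trnI-GAU", "t", 950, 2), _G("trnA-UGC", "t", 880, 2),
    _G("rrn23", "r", 2810), _G("rrn4.5", "r", 100), _G("rrn5", "r", 120),
    _G("trnR-ACG", "t", 75), _G("trnN-GUU", "t", 75),
]

_SSC = [
    _G("ndhF", "p", 2200), _G("rpl32", "p", 171), _G("trnL-UAG", "t", 75),
    _G("ccsA", "p", 960), _G("ndhD", "p", 1500), _G("psaC", "p", 246),
    _G("ndhE", "p", 306), _G("ndhG", "p", 531), _G("ndhI", "p", 540),
    _G("ndhA", "p", 2000, 2), _G("ndhH", "p", 1180), _G("rps15", "p", 270),
    _G("ycf1", "p", 4500),
]

# fixed spacer widths (None keys address the region's leading/trailing gap)
_LSC_GAPS = {
    ("trnH-GUG", "psbA"): 393,
    ("psbM", "trnD-GUC"): 827,
    ("trnR-UCU", "trnT-GGU"): 715,
    ("trnT-UGU", "trnL-UAA"): 921,
    ("ndhC", "trnM-CAU"): 1400,
    ("rpl22", "rps19"): 400,
    ("rps19", None): 376,
}
_IRB_GAPS = {(None, "rpl2"): 50}
_SSC_GAPS = {}

_TOY_LSC = [
    _G("trnH-GUG", "t", 60), _G("psbA", "p", 300), _G("psbM", "p", 100),
    _G("trnD-GUC", "t", 60), _G("trnR-UCU", "t", 60), _G("trnT-GGU", "t", 60),
    _G("trnT-UGU", "t", 60), _G("trnL-UAA", "t", 120, 2), _G("ndhC", "p", 150),
    _G("trnM-CAU", "t", 60), _G("rbcL", "p", 400), _G("atpF", "p", 400, 2),
    _G("rpl22", "p", 200), _G("rps19", "p", 120),
]
_TOY_LSC_GAPS = {
    ("trnH-GUG", "psbA"): 150,
    ("psbM", "trnD-GUC"): 200,
    ("trnR-UCU", "trnT-GGU"): 180,
    ("trnT-UGU", "trnL-UAA"): 200,
    ("ndhC", "trnM-CAU"): 300,
    ("rpl22", "rps19"): 120,
    ("rps19", None): 100,
}
_TOY_IRB = [_G("rpl2", "p", 300, 2), _G("rrn16", "r", 400)]
_TOY_IRB_GAPS = {(None, "rpl2"): 30}
_TOY_SSC = [_G("ndhF", "p", 300), _G("ycf1", "p", 500)]

DEFAULT_MARKERS: dict[str, list[str]] = {
    "trnH-psbA": ["trnH-GUG", "psbA"],
    "psbM-trnD": ["psbM", "trnD-GUC"],
    "trnR-trnT": ["trnR-UCU", "trnT-GGU"],
    "trnT-trnL": ["trnT-UGU", "trnL-UAA"],
    "rpl22-rps19-rpl2": ["rpl22", "rpl2"],
    "rbcL": ["rbcL"],
    "matK": ["matK"],
}


def _split_exons(start: int, length: int, n_exons: int, strand: int):
    if n_exons == 1:
        return ((start, start + length, strand),)
    intron_total = int(0.4 * length)
    per_intron = intron_total // (n_exons - 1)
    exon_total = length - per_intron * (n_exons - 1)
    sizes = [exon_total // n_exons] * n_exons
    sizes[0] += exon_total - sum(sizes)
    parts = []
    pos = start
    for k, sz in enumerate(sizes):
        parts.append((pos, pos + sz, strand))
        pos += sz
        if k < n_exons - 1:
            pos += per_intron
    return tuple(parts)


def _layout_region(specs, gaps, region_start, region_len, region_name):
    names = [s.name for s in specs]
    n_gaps = len(specs) + 1
    explicit: dict[int, int] = {}
    for (prev, nxt), bp in gaps.items():
        if prev is None:
            idx = 0
        elif nxt is None:
            idx = n_gaps - 1
        else:
            idx = names.index(prev) + 1
            if names[idx] != nxt:
                raise CatalogError(f"{region_name}: gap key ({prev},{nxt}) not adjacent")
        explicit[idx] = bp
    gene_bp = sum(s.length for s in specs)
    free_idx = [i for i in range(n_gaps) if i not in explicit]
    free_bp = region_len - gene_bp - sum(explicit.values())
    if free_bp < 2 * len(free_idx):
        raise CatalogError(
            f"{region_name}: region length {region_len} too small for catalog "
            f"({gene_bp} bp of genes + {sum(explicit.values())} bp fixed spacers)"
        )
    base, rem = divmod(free_bp, len(free_idx))
    gap_bp = dict(explicit)
    for k, i in enumerate(free_idx):
        gap_bp[i] = base + (1 if k < rem else 0)

    feats = []
    pos = region_start
    for i, s in enumerate(specs):
        pos += gap_bp[i]
        strand = -1 if i % 3 == 2 else 1
        feats.append(
            GeneFeature(
                gene_name=s.name,
                kind=_KIND[s.kind],
                parts=_split_exons(pos, s.length, s.exons, strand),
            )
        )
        pos += s.length
    pos += gap_bp[n_gaps - 1]
    assert pos == region_start + region_len
    return feats


def _mirror_irb(feats_irb, irb, ira):
    s1, e1 = irb
    s2, _ = ira
    mirrored = []
    for f in feats_irb:
        parts = tuple(
            sorted((s2 + (e1 - b), s2 + (e1 - a), -strand) for a, b, strand in f.parts)
        )
        mirrored.append(
            GeneFeature(gene_name=f.gene_name, kind=f.kind, parts=parts, copy_tag="IRa")
        )
    return mirrored


def build_catalog(
    lsc_len: int, ir_len: int, ssc_len: int, which: str = "full"
) -> list[GeneFeature]:
    """Gene features for an LSC+IRb+SSC+IRa genome of the given region sizes.

    IRb genes are mirrored into IRa (``copy_tag="IRa"``) so the annotation
    respects the inverted-repeat symmetry.
    """
    if which == "full":
        lsc, lsc_gaps = _LSC, _LSC_GAPS
        irb, irb_gaps = _IRB, _IRB_GAPS
        ssc, ssc_gaps = _SSC, _SSC_GAPS
    elif which == "toy":
        lsc, lsc_gaps = _TOY_LSC, _TOY_LSC_GAPS
        irb, irb_gaps = _TOY_IRB, _TOY_IRB_GAPS
        ssc, ssc_gaps = _TOY_SSC, {}
    else:
        raise ValueError(f"unknown catalog {which!r}")

    feats = []
    feats += _layout_region(lsc, lsc_gaps, 0, lsc_len, "LSC")
    irb_feats = _layout_region(irb, irb_gaps, lsc_len, ir_len, "IRb")
    feats += irb_feats
    feats += _layout_region(ssc, ssc_gaps, lsc_len + ir_len, ssc_len, "SSC")
    irb_iv = (lsc_len, lsc_len + ir_len)
    ira_iv = (lsc_len + ir_len + ssc_len, lsc_len + 2 * ir_len + ssc_len)
    feats += _mirror_irb(irb_feats, irb_iv, ira_iv)
    return feats
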