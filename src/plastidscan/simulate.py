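"""Synthetic annotated plastomes evolved along a known tree.

The generator emulates the statistical regime of a small congeneric
plastome comparison: six ~150 kb quadripartite genomes (LSC ~84 kb,
IR ~25 kb x2, SSC ~18.7 kb), overall nucleotide diversity near 1e-3 with
the IR markedly colder and the SSC hotter than the LSC, a handful of
localized mutation hotspots at classic spacer markers, A/T-dominated
mononucleotide SSR tracts (~44 reportable loci per genome), slippage
indels of one repeat unit at SSR tracts, and non-SSR indels with a 1 bp
mode and a rare ~1 kb deletion tail.

Evolution operates directly on an explicit alignment representation:
substitutions are applied along branches in ancestor coordinates, indel
events are recorded with their carrier leaf sets, and the true multiple
alignment is assembled column-by-column from the event list, so no
external aligner is involved and every downstream stage has exact ground
truth.  Mutations in the inverted repeat are applied to IRb and mirrored
into IRa (concerted evolution); indels are restricted to the single-copy
regions, which keeps the two IR copies byte-identical mirrors in every
leaf.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alignment import GAP, Alignment
from .genecatalog import DEFAULT_MARKERS, build_catalog
from .diversity import _marker_ref_interval
from .indels import IndelEvent, NON_SSR, SSR_RELATED, left_normalize
from .records import GeneFeature, PlastomeRecord, revcomp
from .ssr import SSRLocus, SSRThresholds

__all__ = ["SimParams", "SimEvent", "SimTruth", "simulate", "write_fixture", "toy_params"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(x) for x in "ACGT")
_TRANSITION = np.zeros(256, dtype=np.uint8)
_TRANSITION[_A], _TRANSITION[_G] = _G, _A
_TRANSITION[_C], _TRANSITION[_T] = _T, _C

# six-taxon guide tree; branch lengths (expected substitutions/site) are set
# so the mean pairwise path length, i.e. the expected diversity at rate
# multiplier 1, is ~1e-3
DEFAULT_TREE = (
    "(A_carlinoides:0.0008,(A_macrocephala:0.00054,"
    "((A_japonica:0.00013,A_lancea:0.00013):0.00013,"
    "(A_chinensis:0.00013,A_coreana:0.00013):0.00013):0.00027):0.00027);"
)


@dataclass
class SimParams:
    """All knobs of the generator; defaults are the study-scale regime."""

    lsc_len: int = 84_000
    ir_len: int = 25_000
    ssc_len: int = 18_700
    tree: str = DEFAULT_TREE
    catalog: str = "full"  # "full" (113 genes) or "toy" (13 genes)
    seed: int = 0

    # substitutions
    region_rate_scale: dict = field(
        default_factory=lambda: {"LSC": 1.3, "IR": 0.3, "SSC": 1.8}
    )
    hotspot_markers: dict = field(
        default_factory=lambda: {
            "rpl22-rps19-rpl2": 6.5,
            "psbM-trnD": 5.0,
            "trnR-trnT": 5.0,
            "trnT-trnL": 5.0,
        }
    )
    extra_hotspots: tuple = ()  # (start, end, multiplier) in ancestor coords
    ts_tv: float = 2.0  # transition:transversion weight

    # base composition per region
    gc_by_region: dict = field(
        default_factory=lambda: {"LSC": 0.358, "IR": 0.432, "SSC": 0.315}
    )

    # SSR tracts planted in the ancestor: (region, motif_len, count)
    ssr_tracts: tuple = (
        ("LSC", 1, 21),
        ("LSC", 2, 3),
        ("LSC", 3, 1),
        ("LSC", 4, 5),
        ("SSC", 1, 4),
        ("IR", 1, 1),
    )
    mono_at_fraction: float = 0.99  # fraction of mononucleotide tracts that are A/T

    # indels
    ssr_slippage_rate: float = 350.0  # events per tract per unit branch length
    slippage_expansion_bias: float = 0.55
    non_ssr_indel_rate: float = 0.32  # events per SC site per unit branch length
    indel_size_geom_p: float = 0.55
    indel_mid_mean: float = 12.0
    indel_large_range: tuple = (500, 1000)
    indel_size_mix: tuple = (0.90, 0.08, 0.02)  # short / mid / large weights
    noncoding_bias: float = 0.9  # fraction of non-SSR indels placed outside exons

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.non_ssr_indel_rate < 0 or self.ssr_slippage_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.indel_large_range[1] + 200 > min(self.lsc_len, self.ssc_len):
            raise ValueError(
                "largest indel does not fit in the smallest single-copy region"
            )

    @property
    def genome_len(self) -> int:
        return self.lsc_len + 2 * self.ir_len + self.ssc_len

    @property
    def evolving_len(self) -> int:
        # LSC + IRb + SSC; IRa is derived by mirroring
        return self.lsc_len + self.ir_len + self.ssc_len


def toy_params(**overrides) -> SimParams:
    """Small-genome parameters for fast tests (same rates, 13-gene catalog)."""
    defaults = dict(
        lsc_len=6000,
        ir_len=1500,
        ssc_len=1800,
        catalog="toy",
        ssr_tracts=(("LSC", 1, 6), ("LSC", 4, 2), ("SSC", 1, 2), ("IR", 1, 1)),
        indel_large_range=(300, 600),
    )
    defaults.update(overrides)
    return SimParams(**defaults)


@dataclass(frozen=True)
class SimEvent:
    """One true indel event in ancestor coordinates.

    For deletions ``anc_start`` is the first deleted ancestor base; for
    insertions it is the anchor (the inserted block precedes ancestor base
    ``anc_start``).  ``carriers`` are the leaves that underwent the event.
    """

    anc_start: int
    length: int
    kind: str  # insertion | deletion (relative to the ancestor)
    seq: str
    carriers: frozenset[str]
    branch: str
    klass: str  # SSR_related | non_SSR


@dataclass
class SimTruth:
    """Everything the simulator knows: records, alignment, events, catalogs."""

    params: SimParams
    tree: str
    ancestor: PlastomeRecord
    leaf_records: dict[str, PlastomeRecord]
    alignment: Alignment
    events: list[SimEvent]
    ssr_catalogs: dict[str, list[SSRLocus]]  # per leaf plus "ancestor"
    region_lengths: dict[str, tuple[int, int, int]]  # (lsc, ir, ssc) per leaf
    anc_col: np.ndarray  # alignment column of each ancestor base

    def events_vs_reference(self, ref_taxon: str | None = None) -> list[IndelEvent]:
        """True events re-expressed against one leaf, the way a caller that
        uses that leaf as its reference would report them (left-normalized
        reference coordinates, polarity and carriers relative to it)."""
        ref = ref_taxon or self.alignment.ref_taxon
        taxa = self.alignment.taxa
        ref_seq = self.alignment.ungapped(ref)
        ref_dels = sorted(
            (ev.anc_start, ev.length)
            for ev in self.events
            if ref in ev.carriers and ev.kind == "deletion"
        )
        ref_inss = sorted(
            (ev.anc_start, ev.length)
            for ev in self.events
            if ref in ev.carriers and ev.kind == "insertion"
        )

        def map_base(x: int) -> int:
            d = sum(min(l, max(0, x - s)) for s, l in ref_dels)
            i = sum(l for a, l in ref_inss if a <= x)
            return x - d + i

        out: list[IndelEvent] = []
        for ev in self.events:
            ref_has_fragment = (ref in ev.carriers) == (ev.kind == "insertion")
            if ref_has_fragment:
                carriers = frozenset(t for t in taxa if (t in ev.carriers) != (ref in ev.carriers))
                if ev.kind == "deletion":
                    s = map_base(ev.anc_start)
                else:
                    s = map_base(ev.anc_start) - ev.length
                start, seq = left_normalize(ref_seq, s, ref_seq[s : s + ev.length], "deletion")
                out.append(
                    IndelEvent(
                        ref_pos=start - 1,
                        length=ev.length,
                        seq=seq,
                        polarity="deletion",
                        carriers=carriers,
                        klass=ev.klass,
                    )
                )
            else:
                carriers = frozenset(t for t in taxa if (t in ev.carriers) != (ref in ev.carriers))
                if ev.kind == "insertion":
                    seq = ev.seq
                    pos = map_base(ev.anc_start)
                else:
                    # the ancestor fragment deleted in the reference: residues
                    # as carried by the first fragment-bearing taxon
                    w = next(t for t in taxa if t not in ev.carriers)
                    wi = taxa.index(w)
                    cols = self.anc_col[ev.anc_start : ev.anc_start + ev.length]
                    seq = self.alignment.matrix[wi, cols].tobytes().decode("ascii")
                    pos = map_base(ev.anc_start)
                start, seq = left_normalize(ref_seq, pos, seq, "insertion")
                out.append(
                    IndelEvent(
                        ref_pos=start - 1,
                        length=ev.length,
                        seq=seq,
                        polarity="insertion",
                        carriers=carriers,
                        klass=ev.klass,
                    )
                )
        out.sort(key=lambda e: (e.ref_pos, e.length, e.seq))
        return out


# ---------------------------------------------------------------------------
# ancestor construction


def _random_region(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p)


_MOTIF_POOL = {
    2: ["TA", "AT"],
    3: ["AAT", "TTA"],
    4: ["TTTC", "AAAG", "TATT"],
    5: ["TTTTA", "AAAAT"],
    6: ["TATATT", "ATAAAT"],
}


def _plant_tracts(rng, anc, params, region_iv):
    """Write perfect SSR tracts into the ancestor; returns tract list."""
    thresholds = SSRThresholds()
    tracts = []
    occupied: list[tuple[int, int]] = []

    def free(s, e):
        return all(e + 10 <= a or b + 10 <= s for a, b in occupied)

    for region, mlen, count in params.ssr_tracts:
        lo, hi = region_iv[region]
        for _ in range(count):
            if mlen == 1:
                if rng.random() < params.mono_at_fraction:
                    motif = "A" if rng.random() < 0.5 else "T"
                else:
                    motif = "G" if rng.random() < 0.5 else "C"
                units = thresholds[1] + int(rng.geometric(0.5)) - 1
            else:
                motif = _MOTIF_POOL[mlen][int(rng.integers(len(_MOTIF_POOL[mlen])))]
                units = thresholds[mlen] + int(rng.geometric(0.7)) - 1
            span = mlen * units
            for _try in range(200):
                s = int(rng.integers(lo + 50, hi - 50 - span))
                if free(s, s + span):
                    break
            else:
                raise ValueError(f"cannot place SSR tract in {region}")
            arr = np.frombuffer((motif * units).encode(), dtype=np.uint8)
            anc[s : s + span] = arr
            occupied.append((s, s + span))
            tracts.append({"start": s, "end": s + span, "motif": motif, "region": region})
    return tracts


# ---------------------------------------------------------------------------
# evolution


def _mutate(rng, seq, p_site, ts_tv):
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.shape[0]) < p_site)[0]
    if hits.size == 0:
        return out
    p_ts = ts_tv / (ts_tv + 2.0)
    is_ts = rng.random(hits.size) < p_ts
    ts_new = _TRANSITION[out[hits]]
    # transversion: pick one of the two non-self, non-transition bases
    pick = rng.integers(0, 2, size=hits.size)
    tv_new = np.empty(hits.size, dtype=np.uint8)
    for k, h in enumerate(hits):
        b = out[h]
        choices = [x for x in (_A, _C, _G, _T) if x != b and x != _TRANSITION[b]]
        tv_new[k] = choices[pick[k]]
    out[hits] = np.where(is_ts, ts_new, tv_new)
    return out


def _sample_indel_size(rng, params) -> int:
    r = rng.random()
    w_short, w_mid, _ = params.indel_size_mix
    if r < w_short:
        return int(rng.geometric(params.indel_size_geom_p))
    if r < w_short + w_mid:
        return 1 + int(rng.geometric(1.0 / params.indel_mid_mean))
    lo, hi = params.indel_large_range
    return int(rng.integers(lo, hi + 1))


def simulate(params: SimParams | None = None) -> SimTruth:
    """Run the generator; deterministic under ``params.seed``."""
    if params is None:
        params = SimParams()
    rng = np.random.default_rng(params.seed)
    lsc, ir, ssc = params.lsc_len, params.ir_len, params.ssc_len
    Le = params.evolving_len
    L0 = params.genome_len

    features = build_catalog(lsc, ir, ssc, which=params.catalog)

    # ancestor: LSC + IRb + SSC drawn per-region, IRa mirrored from IRb
    region_iv = {"LSC": (0, lsc), "IR": (lsc, lsc + ir), "SSC": (lsc + ir, Le)}
    anc_e = np.concatenate(
        [
            _random_region(rng, lsc, params.gc_by_region["LSC"]),
            _random_region(rng, ir, params.gc_by_region["IR"]),
            _random_region(rng, ssc, params.gc_by_region["SSC"]),
        ]
    )
    tracts = _plant_tracts(rng, anc_e, params, region_iv)
    # Pin the four region-junction bases so the maximal *exact* inverted
    # repeat is precisely the simulated IR (a chance complementary base just
    # outside a junction would otherwise extend it); these sites are also
    # excluded from mutation below.
    comp_tab = dict(zip(b"ACGT", b"TGCA"))
    if anc_e[0] == comp_tab[anc_e[lsc - 1]]:
        anc_e[0] = _A if comp_tab[anc_e[lsc - 1]] != _A else _C
    if anc_e[Le - 1] == comp_tab[anc_e[lsc + ir]]:
        anc_e[Le - 1] = _A if comp_tab[anc_e[lsc + ir]] != _A else _C

    # per-site substitution-rate multipliers on the evolving coordinates
    mult = np.empty(Le)
    mult[0:lsc] = params.region_rate_scale["LSC"]
    mult[lsc : lsc + ir] = params.region_rate_scale["IR"]
    mult[lsc + ir : Le] = params.region_rate_scale["SSC"]
    hotspot_spans = []
    for marker, m in sorted(params.hotspot_markers.items()):
        s, e = _marker_ref_interval(DEFAULT_MARKERS[marker], features)
        if e <= Le:
            mult[s:e] *= m
            hotspot_spans.append((marker, s, e, m))
    for s, e, m in params.extra_hotspots:
        mult[s:e] *= m
        hotspot_spans.append(("extra", s, e, m))
    mult[[0, lsc - 1, lsc + ir, Le - 1]] = 0.0  # junction bases stay pinned

    # guide tree
    tree = dendropy.Tree.get(
        data=params.tree, schema="newick", preserve_underscores=True
    )
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if len(leaves) < 3:
        raise ValueError("guide tree needs at least 3 leaves")

    # traversal state
    leaf_seqs: dict[str, np.ndarray] = {}
    events: list[SimEvent] = []
    used: list[tuple[int, int]] = [(t["start"] - 1, t["end"] + 1) for t in tracts]
    sc_pool_size = lsc + ssc
    exon_mask = np.zeros(Le, dtype=bool)
    for f in features:
        if f.copy_tag:
            continue
        for a, b, _ in f.parts:
            if b <= Le:
                exon_mask[a:b] = True

    def leafset(node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def span_free(s, e) -> bool:
        return all(e + 1 <= a or b + 1 <= s for a, b in used)

    def sc_region_of(x: int) -> tuple[int, int]:
        return (0, lsc) if x < lsc else (lsc + ir, Le)

    # deletions may clip exons but never remove a whole gene: congeneric
    # plastomes conserve the gene complement
    gene_spans = [f.span for f in features if not f.copy_tag and f.span[1] <= Le]

    def swallows_gene(s: int, e: int) -> bool:
        return any(s <= gs and ge <= e for gs, ge in gene_spans)

    tract_used = [False] * len(tracts)

    def do_branch(branch_label: str, t: float, carriers: frozenset[str]):
        # SSR slippage: +/- one repeat unit at a planted single-copy tract
        for ti, tr in enumerate(tracts):
            if tract_used[ti] or tr["region"] == "IR":
                continue
            if rng.random() >= min(1.0, params.ssr_slippage_rate * t):
                continue
            u = len(tr["motif"])
            expand = rng.random() < params.slippage_expansion_bias
            if expand:
                ev = SimEvent(
                    anc_start=tr["end"],
                    length=u,
                    kind="insertion",
                    seq=tr["motif"],
                    carriers=carriers,
                    branch=branch_label,
                    klass=SSR_RELATED,
                )
            else:
                ev = SimEvent(
                    anc_start=tr["end"] - u,
                    length=u,
                    kind="deletion",
                    seq=tr["motif"],
                    carriers=carriers,
                    branch=branch_label,
                    klass=SSR_RELATED,
                )
            events.append(ev)
            tract_used[ti] = True

        # non-SSR indels over the single-copy site pool
        n_ev = rng.poisson(params.non_ssr_indel_rate * t * sc_pool_size)
        for _ in range(int(n_ev)):
            size = _sample_indel_size(rng, params)
            is_del = size >= params.indel_large_range[0] or rng.random() < 0.5
            for _try in range(300):
                x = int(rng.integers(0, sc_pool_size))
                pos = x if x < lsc else x - lsc + lsc + ir
                if params.noncoding_bias > rng.random() and exon_mask[pos]:
                    continue
                lo, hi = sc_region_of(pos)
                if not (lo + 50 <= pos and pos + size <= hi - 50):
                    continue
                if is_del:
                    if not span_free(pos, pos + size) or swallows_gene(pos, pos + size):
                        continue
                    ev = SimEvent(
                        anc_start=pos,
                        length=size,
                        kind="deletion",
                        seq=anc_e[pos : pos + size].tobytes().decode(),
                        carriers=carriers,
                        branch=branch_label,
                        klass=NON_SSR,
                    )
                    used.append((pos - 1, pos + size + 1))
                else:
                    if not span_free(pos, pos + 1):
                        continue
                    ins = rng.choice(
                        _BASES, size=size, p=[0.35, 0.15, 0.15, 0.35]
                    ).tobytes().decode()
                    ev = SimEvent(
                        anc_start=pos,
                        length=size,
                        kind="insertion",
                        seq=ins,
                        carriers=carriers,
                        branch=branch_label,
                        klass=NON_SSR,
                    )
                    used.append((pos - 1, pos + 1))
                events.append(ev)
                break
            # a proposal that cannot be placed is dropped silently

    def walk(node, seq: np.ndarray):
        children = sorted(node.child_nodes(), key=lambda c: min(leafset(c)))
        for child in children:
            t = child.edge.length or 0.0
            child_seq = _mutate(rng, seq, np.minimum(t * mult, 1.0), params.ts_tv)
            carriers = leafset(child)
            label = "+".join(sorted(carriers))
            do_branch(label, t, carriers)
            if child.is_leaf():
                leaf_seqs[child.taxon.label] = child_seq
            else:
                walk(child, child_seq)

    walk(tree.seed_node, anc_e)

    # -- assemble the true alignment -------------------------------------
    taxa = leaves
    inss = sorted(
        [(ev.anc_start, ev.length, ev) for ev in events if ev.kind == "insertion"]
    )
    # base x sits after all insertion blocks anchored at a <= x
    add = np.zeros(L0, dtype=np.int64)
    for a, l, _ in inss:
        add[a] += l
    anc_col = np.arange(L0, dtype=np.int64) + np.cumsum(add)

    total_cols = L0 + sum(l for _, l, _ in inss)
    mat = np.full((len(taxa), total_cols), GAP, dtype=np.uint8)

    # full-genome leaf sequences in ancestor coordinates (IRa mirrored)
    full = {}
    for tname in taxa:
        e = leaf_seqs[tname]
        ira = np.frombuffer(
            revcomp(e[lsc : lsc + ir].tobytes().decode()).encode(), dtype=np.uint8
        )
        full[tname] = np.concatenate([e, ira])

    for i, tname in enumerate(taxa):
        mat[i, anc_col] = full[tname]
    for ev in events:
        if ev.kind != "deletion":
            continue
        cols = anc_col[ev.anc_start : ev.anc_start + ev.length]
        for tname in ev.carriers:
            mat[taxa.index(tname), cols] = GAP
    for a, l, ev in inss:
        block = slice(anc_col[a] - l, anc_col[a])
        seq_arr = np.frombuffer(ev.seq.encode(), dtype=np.uint8)
        for tname in ev.carriers:
            mat[taxa.index(tname), block] = seq_arr

    ref = "A_chinensis" if "A_chinensis" in taxa else taxa[0]
    aln = Alignment(taxa=list(taxa), matrix=mat, ref_taxon=ref)

    # -- leaf records via alignment-derived liftover ----------------------
    leaf_records = {}
    region_lengths = {}
    for i, tname in enumerate(taxa):
        row = mat[i]
        nongap_before = np.concatenate([[0], np.cumsum(row != GAP)])

        def lift(x: int) -> int:  # ancestor coord -> leaf coord
            return int(nongap_before[anc_col[x]])

        def lift_end(x: int) -> int:
            return int(nongap_before[anc_col[x - 1] + 1])

        feats = []
        for f in features:
            parts = []
            for a, b, strand in f.parts:
                na, nb = lift(a), lift_end(b)
                if nb > na:
                    parts.append((na, nb, strand))
            if parts:
                feats.append(
                    GeneFeature(
                        gene_name=f.gene_name,
                        kind=f.kind,
                        parts=tuple(parts),
                        copy_tag=f.copy_tag,
                    )
                )
        seq = row[row != GAP].tobytes().decode("ascii")
        leaf_records[tname] = PlastomeRecord(
            taxon_id=tname, sequence=seq, features=feats
        )
        region_lengths[tname] = (
            lift(lsc) - lift(0),
            lift(lsc + ir) - lift(lsc),
            lift(Le) - lift(lsc + ir),
        )

    anc_rec = PlastomeRecord(
        taxon_id="ancestor",
        sequence=np.concatenate(
            [anc_e, np.frombuffer(revcomp(anc_e[lsc : lsc + ir].tobytes().decode()).encode(), np.uint8)]
        ).tobytes().decode("ascii"),
        features=list(features),
    )

    catalogs = {"ancestor": enumerate_ssrs(anc_rec.sequence)}
    for tname, rec in leaf_records.items():
        catalogs[tname] = enumerate_ssrs(rec.sequence)

    return SimTruth(
        params=params,
        tree=params.tree,
        ancestor=anc_rec,
        leaf_records=leaf_records,
        alignment=aln,
        events=sorted(events, key=lambda e: (e.anc_start, e.length, e.kind)),
        ssr_catalogs=catalogs,
        region_lengths=region_lengths,
        anc_col=anc_col,
    )


# ---------------------------------------------------------------------------
# independent SSR enumeration for the truth catalog (vectorized run finder,
# a separate code path from the scanner module)


def enumerate_ssrs(sequence: str, thresholds: SSRThresholds | None = None) -> list[SSRLocus]:
    if thresholds is None:
        thresholds = SSRThresholds()
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    n = seq.shape[0]
    loci = []
    for m in range(1, 7):
        if n < 2 * m:
            continue
        match = (seq[:-m] == seq[m:]) & (seq[:-m] != ord("N"))
        padded = np.concatenate([[False], match, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0]
        for s, e in zip(starts, ends):
            count = (e - s + m) // m
            if count < thresholds[m]:
                continue
            motif = sequence[s : s + m]
            # primitivity
            if any(m % dd == 0 and motif == motif[:dd] * (m // dd) for dd in range(1, m)):
                continue
            loci.append(
                SSRLocus(motif=motif, repeat_count=count, start=int(s), end=int(s + count * m))
            )
    kept = [
        a
        for a in loci
        if not any(
            b.start <= a.start and a.end <= b.end and (b.end - b.start) > (a.end - a.start)
            for b in loci
        )
    ]
    kept.sort(key=lambda l: (l.start, l.end, l.motif))
    return kept


# ---------------------------------------------------------------------------
# fixture output


def write_fixture(truth: SimTruth, outdir) -> dict[str, Path]:
    """Write the simulated study as plain-text files a pipeline can consume."""
    from . import io as pio

    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for tname, rec in truth.leaf_records.items():
        p = out / "genomes" / f"{tname}.gb"
        pio.write_genbank(rec, p)
        paths[f"genome:{tname}"] = p
    pio.write_fasta(list(truth.leaf_records.values()), out / "genomes.fasta")
    truth.alignment.to_fasta(out / "alignment.fasta")
    paths["alignment"] = out / "alignment.fasta"

    import pandas as pd

    ev_rows = [
        {
            "anc_start": e.anc_start,
            "length": e.length,
            "kind": e.kind,
            "klass": e.klass,
            "branch": e.branch,
            "carriers": ",".join(sorted(e.carriers)),
            "seq": e.seq if e.length <= 50 else e.seq[:47] + "...",
        }
        for e in truth.events
    ]
    pd.DataFrame(ev_rows).to_csv(out / "truth_events.tsv", sep="\t", index=False)
    ssr_rows = [
        {
            "taxon": tname,
            "motif": l.motif,
            "repeat_count": l.repeat_count,
            "start": l.start,
            "end": l.end,
        }
        for tname, loci in truth.ssr_catalogs.items()
        for l in loci
    ]
    pd.DataFrame(ssr_rows).to_csv(out / "truth_ssrs.tsv", sep="\t", index=False)
    reg_rows = [
        {"taxon": t, "lsc": a, "ir": b, "ssc": c}
        for t, (a, b, c) in truth.region_lengths.items()
    ]
    pd.DataFrame(reg_rows).to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    (out / "tree.nwk").write_text(truth.tree.strip() + "\n")
    (out / "params.json").write_text(
        json.dumps(dataclasses.asdict(truth.params), indent=2, default=list) + "\n"
    )
    return paths
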