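"""Reading and writing annotated plastomes.

GenBank and FASTA go through Biopython; GFF3 features are read/written as
the plain 9-column tab format with ``gene``/``exon`` rows linked by
``ID``/``Parent`` attributes.  Unknown feature kinds are dropped with a
warning rather than failing the parse.
"""
from __future__ import annotations

import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .records import GeneFeature, PlastomeRecord

__all__ = [
    "PlastomeParseError",
    "read_plastome",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "write_genbank",
    "read_gff3",
    "write_gff3",
]

_GB_KIND = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
_GFF_KIND = {"gene": None, "CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}
_KIND_TO_GB = {v: k for k, v in _GB_KIND.items()}


class PlastomeParseError(ValueError):
    """A plastome file failed to parse under the named standard."""


def read_plastome(path, format: str = "genbank", gff3=None, taxon_id: str | None = None) -> PlastomeRecord:
    """Read one annotated plastome.

    ``format`` is ``"genbank"`` or ``"fasta"``; for FASTA an optional GFF3
    companion supplies the features.
    """
    if format == "genbank":
        return read_genbank(path, taxon_id=taxon_id)
    if format == "fasta":
        rec = read_fasta(path, taxon_id=taxon_id)
        if gff3 is not None:
            rec.features.extend(read_gff3(gff3, genome_length=rec.length_bp))
        return rec
    raise ValueError(f"unknown format {format!r}")


def _features_from_seqrecord(sr: SeqRecord) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    seen: set[tuple] = set()
    for f in sr.features:
        if f.type in ("gene", "source"):
            continue
        kind = _GB_KIND.get(f.type)
        if kind is None:
            warnings.warn(f"dropping feature of unknown kind {f.type!r}", stacklevel=2)
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or ["?"])[0]
        copy_tag = (f.qualifiers.get("note") or [""])[0]
        if not copy_tag.startswith("IR"):
            copy_tag = ""
        parts = tuple(
            sorted(
                (int(p.start), int(p.end), 1 if p.strand in (1, None) else -1)
                for p in f.location.parts
            )
        )
        key = (name, kind, parts)
        if key in seen:
            continue
        seen.add(key)
        feats.append(GeneFeature(gene_name=name, kind=kind, parts=parts, copy_tag=copy_tag))
    return feats


def read_genbank(path, taxon_id: str | None = None) -> PlastomeRecord:
    """Read a GenBank flat file into a :class:`PlastomeRecord`."""
    path = Path(path)
    try:
        sr = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise PlastomeParseError(f"{path}: no record found")
    except ValueError as exc:
        raise PlastomeParseError(f"{path}: {exc}") from exc
    seq = str(sr.seq).upper()
    if not seq:
        raise PlastomeParseError(f"{path}: record {sr.id} has an empty sequence")
    return PlastomeRecord(
        taxon_id=taxon_id or (sr.annotations.get("organism") or sr.name or sr.id).replace(" ", "_"),
        sequence=seq,
        accession=sr.id,
        features=_features_from_seqrecord(sr),
    )


def read_fasta(path, taxon_id: str | None = None) -> PlastomeRecord:
    """Read the first sequence of a FASTA file (no annotation)."""
    path = Path(path)
    try:
        sr = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise PlastomeParseError(f"{path}: no FASTA record found")
    seq = str(sr.seq).upper()
    if not seq:
        raise PlastomeParseError(f"{path}: record {sr.id} has an empty sequence")
    return PlastomeRecord(taxon_id=taxon_id or sr.id, sequence=seq, accession=sr.id)


def _to_seqrecord(record: PlastomeRecord) -> SeqRecord:
    sr = SeqRecord(
        Seq(record.sequence),
        id=record.accession or record.taxon_id,
        name=record.taxon_id[:16],
        description=record.taxon_id,
    )
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular"
    sr.annotations["date"] = "01-JAN-2000"  # fixed so output is reproducible
    sr.annotations["organism"] = record.taxon_id
    for f in record.features:
        locs = [SimpleLocation(s, e, strand) for s, e, strand in f.parts]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.gene_name]}
        if f.copy_tag:
            quals["note"] = [f.copy_tag]
        sr.features.append(SeqFeature(loc, type="gene", qualifiers=dict(quals)))
        sr.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=quals))
    return sr


def write_genbank(record: PlastomeRecord, path) -> None:
    SeqIO.write([_to_seqrecord(record)], str(path), "genbank")


def write_fasta(record_or_records, path) -> None:
    recs = record_or_records
    if isinstance(recs, PlastomeRecord):
        recs = [recs]
    srs = [
        SeqRecord(Seq(r.sequence), id=r.taxon_id, description=r.accession or "")
        for r in recs
    ]
    SeqIO.write(srs, str(path), "fasta")


def write_gff3(record: PlastomeRecord, path, source: str = "plastidscan") -> None:
    """Write features as GFF3 (1-based inclusive coordinates on output)."""
    seqid = record.taxon_id
    lines = ["##gff-version 3", f"##sequence-region {seqid} 1 {record.length_bp}"]
    for i, f in enumerate(record.features):
        s, e = f.span
        strand = "+" if f.strand == 1 else "-"
        gid = f"gene{i:04d}"
        attrs = f"ID={gid};Name={f.gene_name};gene_kind={f.kind}"
        if f.copy_tag:
            attrs += f";copy_tag={f.copy_tag}"
        lines.append(
            "\t".join([seqid, source, "gene", str(s + 1), str(e), ".", strand, ".", attrs])
        )
        for j, (ps, pe, pstrand) in enumerate(f.parts):
            lines.append(
                "\t".join(
                    [
                        seqid,
                        source,
                        "exon",
                        str(ps + 1),
                        str(pe),
                        ".",
                        "+" if pstrand == 1 else "-",
                        ".",
                        f"ID={gid}.e{j};Parent={gid}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path, genome_length: int | None = None) -> list[GeneFeature]:
    """Read gene features from a GFF3 file written in the layout above.

    ``gene`` rows carry name/kind; ``exon`` rows with ``Parent`` supply the
    parts.  Rows of other types are ignored with a warning.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise PlastomeParseError(f"{path}:{lineno}: expected 9 columns")
        _, _, ftype, start, end, _, strand, _, attrs = cols
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "gene":
            gid = attr.get("ID", f"line{lineno}")
            kind = attr.get("gene_kind", "protein_coding")
            if kind not in ("protein_coding", "tRNA", "rRNA"):
                warnings.warn(f"{path}:{lineno}: dropping unknown kind {kind!r}", stacklevel=2)
                continue
            genes[gid] = {
                "name": attr.get("Name", gid),
                "kind": kind,
                "copy_tag": attr.get("copy_tag", ""),
                "parts": [],
            }
            order.append(gid)
        elif ftype == "exon":
            parent = attr.get("Parent")
            if parent in genes:
                genes[parent]["parts"].append(
                    (int(start) - 1, int(end), 1 if strand != "-" else -1)
                )
        else:
            warnings.warn(f"{path}:{lineno}: ignoring feature type {ftype!r}", stacklevel=2)
    feats = []
    for gid in order:
        g = genes[gid]
        if not g["parts"]:
            continue
        feats.append(
            GeneFeature(
                gene_name=g["name"],
                kind=g["kind"],
                parts=tuple(sorted(g["parts"])),
                copy_tag=g["copy_tag"],
            )
        )
    return feats
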