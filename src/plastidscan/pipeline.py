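"""End-to-end study workflow: structure -> SSR -> indels -> diversity ->
markers -> trees -> report.

The pipeline consumes annotated genomes plus an externally produced
whole-genome alignment (any aligner that writes aligned FASTA; alignment
itself is deliberately out of scope) and emits a reproducible set of
plain-text tables.  All randomness (bootstrap resampling) is funnelled
through one seed, and a manifest of content hashes is written so reruns
can be verified byte-for-byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alignment import Alignment
from .diversity import (
    classify_sites,
    extract_marker,
    marker_report,
    nucleotide_diversity,
    rank_hotspots,
    sliding_window_pi,
    UndefinedPiError,
)
from .genecatalog import DEFAULT_MARKERS
from .indels import (
    annotate_indels,
    build_indel_matrix,
    call_indels,
    classify_indel,
    indel_spectrum,
    indel_table,
)
from .io import read_plastome
from .phylo import bootstrap_support, indel_distance, neighbor_joining, p_distance
from .ssr import SSRThresholds, annotate_ssrs, find_ssrs, ssr_locus_table, tabulate_ssrs
from .structure import canonicalize, detect_quadripartite, summarize_genome, write_summary_tsv

__all__ = ["RunConfig", "StudyReport", "ConfigError", "DataError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class RunConfig:
    """Plain-text configuration of one pipeline run."""

    genomes_dir: str
    alignment_path: str
    outdir: str
    genome_format: str = "genbank"
    ref_taxon: str = "A_chinensis"
    group_b_exclude: list[str] = field(default_factory=lambda: ["A_carlinoides"])
    min_ir: int = 10_000
    ssr_min_repeats: dict = field(
        default_factory=lambda: {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
    )
    window: int = 600
    step: int = 100
    markers: dict = field(default_factory=lambda: dict(DEFAULT_MARKERS))
    bootstrap_replicates: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "ssr_min_repeats" in raw:
            raw["ssr_min_repeats"] = {int(k): int(v) for k, v in raw["ssr_min_repeats"].items()}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations, human-readable; an empty list means OK."""
    v: list[str] = []
    gdir = Path(config.genomes_dir)
    if not gdir.is_dir():
        v.append(f"genomes_dir does not exist: {gdir}")
    elif not sorted(gdir.glob("*.gb")) and config.genome_format == "genbank":
        v.append(f"genomes_dir contains no .gb files: {gdir}")
    apath = Path(config.alignment_path)
    if not apath.is_file():
        v.append(f"alignment_path does not exist: {apath}")
    else:
        headers = [
            line[1:].split()[0]
            for line in apath.read_text().splitlines()
            if line.startswith(">")
        ]
        if config.ref_taxon not in headers:
            v.append(f"reference taxon {config.ref_taxon!r} not in alignment taxa {headers}")
    if not (config.window > config.step > 0):
        v.append(f"require window > step > 0 (got window={config.window}, step={config.step})")
    if set(config.ssr_min_repeats) != {1, 2, 3, 4, 5, 6}:
        v.append("ssr_min_repeats must cover motif lengths 1..6")
    if config.bootstrap_replicates < 1:
        v.append("bootstrap_replicates must be >= 1")
    return v


@dataclass
class StudyReport:
    """All tables and trees of one run, plus where they were written."""

    summaries: pd.DataFrame
    ssr_loci: pd.DataFrame
    ssr_counts: pd.DataFrame
    indel_events: pd.DataFrame
    indel_spectra: dict
    site_counts: pd.DataFrame
    windows: dict[str, pd.DataFrame]
    markers: pd.DataFrame
    trees: dict[str, str]  # name -> newick
    supports: dict
    paths: dict[str, Path]
    group_taxa: dict[str, list[str]] = field(default_factory=dict)

    def crossfoot_ok(self) -> bool:
        """Marginal totals of the SSR table are consistent by construction;
        verify anyway (region margins sum to per-taxon totals)."""
        if self.ssr_counts.empty:
            return True
        per_taxon = self.ssr_counts.groupby("taxon")["n"].sum()
        per_taxon_region = self.ssr_counts.groupby(["taxon", "region"])["n"].sum().groupby("taxon").sum()
        return bool((per_taxon == per_taxon_region).all())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _windows_df(windows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_start": [w.window_start for w in windows],
            "window_end": [w.window_end for w in windows],
            "midpoint": [w.midpoint for w in windows],
            "pi": [w.pi if w.pi is not None else float("nan") for w in windows],
            "valid_sites": [w.valid_sites for w in windows],
        }
    )


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute all stages in dependency order; outputs land in ``outdir``."""
    violations = validate_config(config)
    if violations:
        raise ConfigError("; ".join(violations))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    thresholds = SSRThresholds(min_repeats=dict(config.ssr_min_repeats))

    # -- stage: structure --------------------------------------------------
    records = {}
    structures = {}
    for p in sorted(Path(config.genomes_dir).glob("*.gb")):
        rec = read_plastome(p, format="genbank")
        rec.taxon_id = p.stem  # file stem is the taxon label used throughout
        try:
            struct = detect_quadripartite(rec, min_ir=config.min_ir)
        except ValueError as exc:
            raise DataError(f"structure stage failed on {p.name}: {exc}") from exc
        rec, struct = canonicalize(rec, struct)
        records[rec.taxon_id] = rec
        structures[rec.taxon_id] = struct
    if not records:
        raise DataError("no genomes loaded")
    summaries = [summarize_genome(records[t], structures[t]) for t in sorted(records)]
    paths["genome_summary"] = out / "genome_summary.tsv"
    write_summary_tsv(summaries, paths["genome_summary"])
    summaries_df = pd.read_csv(paths["genome_summary"], sep="\t")

    # -- stage: SSR --------------------------------------------------------
    loci_by_taxon = {}
    for t in sorted(records):
        loci = find_ssrs(records[t].sequence, thresholds)
        loci_by_taxon[t] = annotate_ssrs(loci, records[t], structures[t])
    ssr_loci = ssr_locus_table(loci_by_taxon)
    ssr_counts = tabulate_ssrs(loci_by_taxon, structures)
    ssr_counts_dedup = tabulate_ssrs(loci_by_taxon, structures, dedup_ir=True)
    paths["ssr_loci"] = out / "ssr_loci.tsv"
    ssr_loci.to_csv(paths["ssr_loci"], sep="\t", index=False)
    paths["ssr_counts"] = out / "ssr_counts.tsv"
    ssr_counts.to_csv(paths["ssr_counts"], sep="\t", index=False)
    paths["ssr_counts_dedup"] = out / "ssr_counts_dedup.tsv"
    ssr_counts_dedup.to_csv(paths["ssr_counts_dedup"], sep="\t", index=False)

    # -- stage: alignment --------------------------------------------------
    aln = Alignment.from_fasta(config.alignment_path, ref_taxon=config.ref_taxon)
    missing = set(records) - set(aln.taxa)
    if missing:
        raise DataError(f"alignment lacks genome taxa: {sorted(missing)}")
    ref_rec = records[config.ref_taxon]
    ref_struct = structures[config.ref_taxon]
    if aln.ungapped(config.ref_taxon) != ref_rec.sequence:
        raise DataError(
            "reference row of the alignment does not match the canonicalized "
            "reference genome sequence (check orientation/rotation)"
        )
    group_b_taxa = [t for t in aln.taxa if t not in set(config.group_b_exclude)]
    groups = {"A": aln, "B": aln.subset(group_b_taxa, ref_taxon=config.ref_taxon)}

    # -- stage: indels -----------------------------------------------------
    events = call_indels(aln)
    events = [classify_indel(e, ref_rec.sequence, thresholds) for e in events]
    events = annotate_indels(events, ref_struct, ref_rec.features)
    spectra = indel_spectrum(events)
    ev_df = indel_table(events)
    paths["indel_events"] = out / "indel_events.tsv"
    ev_df.to_csv(paths["indel_events"], sep="\t", index=False)
    for key in ("by_size", "by_context"):
        paths[f"indel_{key}"] = out / f"indel_{key}.tsv"
        spectra[key].to_csv(paths[f"indel_{key}"], sep="\t", index=False)

    # -- stage: diversity --------------------------------------------------
    site_rows = []
    windows: dict[str, pd.DataFrame] = {}
    cols_of_ref = aln.col_of_ref_coord()
    hotspot_lines = []
    for gname, gal in groups.items():
        sc = classify_sites(gal)
        try:
            pi = nucleotide_diversity(gal)
        except UndefinedPiError:
            pi = float("nan")
        site_rows.append(
            {
                "group": gname,
                "region": "complete",
                "length": sc.aligned_length,
                "variable_sites": sc.variable_sites,
                "pct_variable": round(sc.pct_variable, 4),
                "informative_sites": sc.informative_sites,
                "pct_informative": round(sc.pct_informative, 4),
                "pi": round(pi, 5),
            }
        )
        if gname == "A":
            # region rows in the alignment frame, sliced through the reference
            for rname, (s, e) in ref_struct.region_intervals().items():
                c0, c1 = int(cols_of_ref[s]), int(cols_of_ref[e - 1]) + 1
                sub = gal.slice_cols(c0, c1)
                rsc = classify_sites(sub)
                try:
                    rpi = nucleotide_diversity(sub)
                except UndefinedPiError:
                    rpi = float("nan")
                site_rows.append(
                    {
                        "group": gname,
                        "region": rname,
                        "length": rsc.aligned_length,
                        "variable_sites": rsc.variable_sites,
                        "pct_variable": round(rsc.pct_variable, 4),
                        "informative_sites": rsc.informative_sites,
                        "pct_informative": round(rsc.pct_informative, 4),
                        "pi": round(rpi, 5),
                    }
                )
        wd = sliding_window_pi(gal, window=config.window, step=config.step)
        windows[gname] = _windows_df(wd)
        paths[f"windows_{gname}"] = out / f"windows_group{gname}.tsv"
        windows[gname].to_csv(paths[f"windows_{gname}"], sep="\t", index=False)
        ref_coord = gal.ref_coord_of_col()
        for w in rank_hotspots(wd, top=10):
            mid_col = int(w.midpoint)
            refpos = int(ref_coord[min(mid_col, len(ref_coord) - 1)])
            while refpos < 0 and mid_col > 0:
                mid_col -= 1
                refpos = int(ref_coord[mid_col])
            from .structure import classify_position

            _, region, name = classify_position(ref_struct, ref_rec.features, max(refpos, 0))
            hotspot_lines.append(
                (config.ref_taxon, max(refpos - config.window // 2, 0),
                 refpos + config.window // 2, f"{gname}:{name}", f"{w.pi:.5f}")
            )
    site_counts = pd.DataFrame(site_rows)
    paths["site_counts"] = out / "site_counts.tsv"
    site_counts.to_csv(paths["site_counts"], sep="\t", index=False)
    paths["hotspots"] = out / "hotspots.bed"
    with open(paths["hotspots"], "w") as fh:
        for chrom, s, e, name, score in hotspot_lines:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\n")

    # -- stage: markers ----------------------------------------------------
    marker_alns = {}
    for name, anchors in config.markers.items():
        try:
            marker_alns[name] = extract_marker(aln, ref_rec.features, list(anchors))
        except KeyError:
            continue  # anchor gene absent from this annotation
    markers_df = marker_report(marker_alns) if marker_alns else pd.DataFrame()
    paths["markers"] = out / "marker_report.tsv"
    markers_df.to_csv(paths["markers"], sep="\t", index=False)

    # -- stage: trees ------------------------------------------------------
    trees: dict[str, str] = {}
    supports: dict = {}
    seq_tree = bootstrap_support(
        aln, replicates=config.bootstrap_replicates, seed=config.seed
    )
    trees["nj_sequence"] = seq_tree.newick
    supports["nj_sequence"] = {
        "|".join(sorted(k)): v for k, v in sorted(seq_tree.supports.items(), key=lambda kv: sorted(kv[0]))
    }
    try:
        imat = build_indel_matrix(events, aln.taxa, config.ref_taxon)
        trees["nj_indels"] = neighbor_joining(indel_distance(imat)).newick
    except ValueError:
        trees["nj_indels"] = ""
    for name, nwk in trees.items():
        paths[name] = out / f"{name}.nwk"
        paths[name].write_text((nwk.strip() + "\n") if nwk else "")
    paths["supports"] = out / "supports.json"
    paths["supports"].write_text(json.dumps(supports, indent=2, sort_keys=True) + "\n")

    # -- manifest ----------------------------------------------------------
    manifest = {str(k): _sha256(p) for k, p in sorted(paths.items())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return StudyReport(
        summaries=summaries_df,
        ssr_loci=ssr_loci,
        ssr_counts=ssr_counts,
        indel_events=ev_df,
        indel_spectra=spectra,
        site_counts=site_counts,
        windows=windows,
        markers=markers_df,
        trees=trees,
        supports=supports,
        paths=paths,
        group_taxa={g: list(a.taxa) for g, a in groups.items()},
    )
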