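"""Orchestration: the full comparative report over a set of genomes.

Given one or more annotated mitogenomes (GenBank files or in-memory
objects), emits the battery of comparative tables — per-gene architecture,
partition composition, codon usage and bias summaries, per-gene Ka/Ks,
non-coding inventory, tandem repeats, control-region annotation,
sliding-window profiles, and a concatenated supermatrix with a
neighbor-joining tree.  Stages whose inputs are missing (too few genomes,
unalignable genes, absent control region) are skipped with a logged reason
rather than failing.  Identical configuration and inputs produce
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import architecture, codon_usage, composition, evol_rates, noncoding_structure
from . import phylo_lite
from .codon_usage import InternalStopError
from .io import MitoGenome, feature_sequence, read_genbank


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)  # GenBank paths
    outdir: str = "mitocomp_report"
    transl_table: int = 5
    nc_min: int = 100
    window: int = 200
    step: int = 100
    repeat_min_unit: int = 10
    repeat_max_unit: int = 200
    repeat_min_copies: float = 2.0
    repeat_min_identity: float = 0.8
    block_window: int = noncoding_structure.BLOCK_WINDOW
    min_stem: int = 6
    loop_min: int = 3
    loop_max: int = 20
    partitions: list[str] = field(default_factory=lambda: list(composition.PARTITIONS))
    exclude_genes: list[str] = field(default_factory=lambda: ["trnI", "trnQ", "trnM"])
    distance_model: str = "p_distance"
    outgroup: list[str] = field(default_factory=list)
    alignments_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("nc_min", "window", "step", "repeat_min_unit", "block_window",
                     "min_stem"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _fmt(value, digits: int = 4) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.{digits}f}"
    return str(value)


def run_comparative_report(config: RunConfig,
                           genomes: list[MitoGenome] | None = None) -> Path:
    """Run every comparative stage and write the report bundle.

    ``genomes`` may be passed directly (e.g. synthetic ones); otherwise the
    configured GenBank inputs are read.  Returns the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = ["mitocomp comparative report", "parameters:"]
    for key, value in sorted(asdict(config).items()):
        log.append(f"  {key}: {value}")

    if genomes is None:
        genomes = [read_genbank(p) for p in config.inputs]
    if not genomes:
        raise ValueError("no genomes to analyse")
    genomes = sorted(genomes, key=lambda g: g.id)
    log.append(f"genomes: {', '.join(g.id for g in genomes)}")

    _architecture_table(genomes, outdir, log)
    _composition_table(genomes, config, outdir, log)
    tables = _codon_tables(genomes, config, outdir, log)
    per_gene = _collect_gene_alignments(genomes, config, log)
    _kaks_table(per_gene, genomes, config, outdir, log)
    _noncoding_tables(genomes, config, outdir, log)
    _profiles(genomes, config, outdir, log)
    _phylogeny(per_gene, genomes, config, outdir, log)

    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return outdir


def _architecture_table(genomes, outdir: Path, log: list[str]) -> None:
    rows = []
    for g in genomes:
        terminals = {r.gene: r for r in architecture.classify_terminal_codons(g)}
        genes = sorted(g.genes(), key=lambda f: f.start)
        L = len(g)
        for i, f in enumerate(genes):
            nxt = genes[(i + 1) % len(genes)]
            offset = (nxt.start - f.end) % L
            if offset > L // 2:
                offset -= L  # overlap with the next gene
            term = terminals.get(f.name)
            rows.append({
                "genome": g.id, "gene": f.name, "kind": f.kind,
                "strand": f.strand, "start": f.start + 1, "end": f.end,
                "length": f.length(L),
                "start_codon": term.start_codon if term else "",
                "stop_codon": term.stop_codon if term else "",
                "truncated": term.truncated if term else "",
                "intergenic_offset": offset,
            })
        overlaps = architecture.find_gene_overlaps(g)
        log.append(f"{g.id}: {len(overlaps)} gene overlaps")
    pd.DataFrame(rows).to_csv(outdir / "architecture.tsv", sep="\t", index=False)


def _composition_table(genomes, config: RunConfig, outdir: Path,
                       log: list[str]) -> None:
    rows = []
    for g in genomes:
        for part in config.partitions:
            try:
                s = composition.partition_composition(g, part)
            except ValueError as exc:
                log.append(f"{g.id}: composition {part} skipped ({exc})")
                continue
            rows.append({
                "genome": g.id, "partition": part, "length": s.length,
                "A": s.counts["A"], "C": s.counts["C"], "G": s.counts["G"],
                "T": s.counts["T"], "at_content": _fmt(s.at_content),
                "at_skew": _fmt(s.at_skew), "gc_skew": _fmt(s.gc_skew),
            })
    pd.DataFrame(rows).to_csv(outdir / "composition.tsv", sep="\t", index=False)


def _codon_tables(genomes, config: RunConfig, outdir: Path,
                  log: list[str]) -> dict[str, codon_usage.CodonUsageTable]:
    codon_rows = []
    summary_rows = []
    tables: dict[str, codon_usage.CodonUsageTable] = {}
    for g in genomes:
        pcgs = g.genes("PCG")
        if not pcgs:
            log.append(f"{g.id}: codon usage skipped (no PCGs)")
            continue
        try:
            table = codon_usage.count_codons(
                [feature_sequence(g, f) for f in pcgs],
                transl_table=g.transl_table, names=[f.name for f in pcgs])
        except (InternalStopError, ValueError) as exc:
            log.append(f"{g.id}: codon usage skipped ({exc})")
            continue
        tables[g.id] = table
        rel = codon_usage.rscu(table)
        trans = {}
        for aa, codons in table.families.items():
            for c in codons:
                trans[c] = aa
        for codon in sorted(trans):
            codon_rows.append({
                "genome": g.id, "codon": codon, "aa": trans[codon],
                "count": table.counts.get(codon, 0),
                "rscu": _fmt(rel[codon]),
            })
        s = codon_usage.summarize(table)
        summary_rows.append({
            "genome": g.id, "n_codons": table.total, "enc": _fmt(s.enc, 2),
            "cbi": _fmt(s.cbi, 3), "gc": _fmt(s.gc_all), "gc3": _fmt(s.gc3),
            "at_ending": _fmt(s.at_ending),
            "unused": ",".join(sorted(s.unused)),
        })
    pd.DataFrame(codon_rows).to_csv(outdir / "codon_usage.tsv", sep="\t",
                                    index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "codon_summary.tsv", sep="\t",
                                      index=False)
    if len(summary_rows) >= 3:
        xs = [float(r["gc"]) for r in summary_rows]
        ys = [float(r["enc"]) for r in summary_rows]
        try:
            slope, intercept, r2 = codon_usage.linear_fit(xs, ys)
            log.append(f"ENC ~ GC fit: slope={_fmt(slope)} r2={_fmt(r2)}")
        except ValueError as exc:
            log.append(f"ENC ~ GC fit skipped ({exc})")
    return tables


def _collect_gene_alignments(genomes, config: RunConfig,
                             log: list[str]) -> dict[str, dict[str, str]]:
    """Per-gene {taxon: sequence} maps, from an alignment dir or equal-length
    extracted gene sequences."""
    from .io import read_fasta

    if config.alignments_dir:
        per_gene = {}
        for path in sorted(Path(config.alignments_dir).glob("*.fasta")):
            per_gene[path.stem] = read_fasta(path)
        log.append(f"alignments loaded for {len(per_gene)} genes")
        return per_gene
    if len(genomes) < 2:
        log.append("comparative stages skipped (single genome)")
        return {}
    per_gene: dict[str, dict[str, str]] = {}
    names = sorted({f.name for g in genomes for f in g.genes()})
    for name in names:
        seqs = {}
        for g in genomes:
            f = g.get(name)
            if f is not None and f.kind in ("PCG", "tRNA", "rRNA"):
                seqs[g.id] = feature_sequence(g, f)
        if len(seqs) < 2:
            log.append(f"{name}: skipped (present in < 2 genomes)")
            continue
        if len({len(s) for s in seqs.values()}) != 1:
            log.append(f"{name}: skipped (unequal gene lengths; provide alignments)")
            continue
        per_gene[name] = seqs
    return per_gene


def _kaks_table(per_gene, genomes, config: RunConfig, outdir: Path,
                log: list[str]) -> None:
    pcg_names = {f.name for g in genomes for f in g.genes("PCG")}
    pcg_alns = {k: v for k, v in per_gene.items() if k in pcg_names}
    if not pcg_alns:
        log.append("Ka/Ks skipped (no per-gene PCG alignments)")
        pd.DataFrame(columns=["gene", "ka", "ks", "ka_ks", "gc", "n_pairs"]
                     ).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
        return
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        estimates, fit = evol_rates.gene_average_kaks(
            pcg_alns, transl_table=config.transl_table)
    rows = [{"gene": e.gene, "ka": _fmt(e.ka), "ks": _fmt(e.ks),
             "ka_ks": _fmt(e.ratio), "gc": _fmt(e.gc), "n_pairs": e.n_pairs}
            for e in sorted(estimates, key=lambda e: e.gene)]
    pd.DataFrame(rows).to_csv(outdir / "kaks.tsv", sep="\t", index=False)
    if fit:
        log.append(f"Ka/Ks ~ GC fit: slope={_fmt(fit[0])} r2={_fmt(fit[2])}")


def _noncoding_tables(genomes, config: RunConfig, outdir: Path,
                      log: list[str]) -> None:
    nc_rows, repeat_rows, cr_rows = [], [], []
    for g in genomes:
        regions = architecture.find_noncoding_regions(g, config.nc_min)
        total = sum(r.length for r in regions)
        log.append(f"{g.id}: total NC length {total} bp")
        res = g.seq.residues
        for r in regions:
            nc_rows.append({
                "genome": g.id, "flank_a": r.flank_a, "flank_b": r.flank_b,
                "start": r.start + 1, "end": r.end, "length": r.length,
                "is_large": r.is_large, "label": r.label or "",
            })
            if r.length < 2 * config.repeat_min_unit:
                continue
            seq = (res[r.start:r.end] if r.end >= r.start
                   else res[r.start:] + res[:r.end])
            for rep in noncoding_structure.find_tandem_repeats(
                    seq, min_unit=config.repeat_min_unit,
                    max_unit=config.repeat_max_unit,
                    min_copies=config.repeat_min_copies,
                    min_identity=config.repeat_min_identity):
                repeat_rows.append({
                    "genome": g.id, "flank_a": r.flank_a, "flank_b": r.flank_b,
                    "start": r.start + rep.start + 1,
                    "unit_length": rep.unit_length,
                    "copies": rep.copies, "span": rep.span,
                    "identity": _fmt(rep.identity, 3),
                })
            if r.label == "CR":
                ann = noncoding_structure.annotate_control_region(
                    seq, window=config.block_window, min_stem=config.min_stem,
                    loop_range=(config.loop_min, config.loop_max))
                for kind, block in (("GA", ann.ga_block), ("C", ann.c_block),
                                    ("AT", ann.at_block)):
                    if block:
                        cr_rows.append({
                            "genome": g.id, "element": f"{kind}_block",
                            "start": r.start + block.start + 1,
                            "end": r.start + block.end,
                            "detail": _fmt(block.fraction, 3)})
                for sl in ann.stem_loops[:3]:
                    cr_rows.append({
                        "genome": g.id, "element": "stem_loop",
                        "start": r.start + sl.start + 1,
                        "end": r.start + sl.end,
                        "detail": f"stem={sl.stem_len},loop={sl.loop_len}"})
        if not any(r.label == "CR" for r in regions):
            log.append(f"{g.id}: CR not found; CR annotation skipped")
    pd.DataFrame(nc_rows).to_csv(outdir / "noncoding.tsv", sep="\t", index=False)
    pd.DataFrame(repeat_rows).to_csv(outdir / "repeats.tsv", sep="\t", index=False)
    pd.DataFrame(cr_rows).to_csv(outdir / "cr_annotation.tsv", sep="\t",
                                 index=False)


def _profiles(genomes, config: RunConfig, outdir: Path, log: list[str]) -> None:
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    for g in genomes:
        window = min(config.window, len(g))
        rows = []
        for metric in ("gc_content", "gc_skew"):
            for mid, dev in composition.sliding_window_profile(
                    g, window, config.step, metric):
                rows.append({"metric": metric, "midpoint": _fmt(mid, 1),
                             "deviation": _fmt(dev, 5)})
        pd.DataFrame(rows).to_csv(prof_dir / f"{g.id}_profile.tsv", sep="\t",
                                  index=False)


def _phylogeny(per_gene, genomes, config: RunConfig, outdir: Path,
               log: list[str]) -> None:
    usable = {k: v for k, v in per_gene.items()
              if k not in set(config.exclude_genes)}
    if len(genomes) < 3 or not usable:
        log.append("phylogeny skipped (need >= 3 genomes with shared genes)")
        return
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        sm = phylo_lite.concatenate_supermatrix(per_gene,
                                                exclude=set(config.exclude_genes))
        dm = phylo_lite.distance_matrix(sm, model=config.distance_model)
        from .io import write_fasta
        write_fasta(sm.matrix, outdir / "supermatrix.fasta")
        with open(outdir / "partitions.tsv", "w") as fh:
            fh.write("gene\tstart\tend\n")
            for gene, (s, e) in sorted(sm.partitions.items(),
                                       key=lambda kv: kv[1][0]):
                fh.write(f"{gene}\t{s + 1}\t{e}\n")
        with open(outdir / "distances.tsv", "w") as fh:
            fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
            for i, t in enumerate(dm.taxa):
                fh.write(t + "\t" + "\t".join(_fmt(x, 6) for x in dm.d[i]) + "\n")
        import numpy as np
        if np.isnan(dm.d).any():
            log.append("tree skipped (missing distances)")
            return
        tree = phylo_lite.nj_tree(dm, outgroup=set(config.outgroup))
        (outdir / "tree.nwk").write_text(phylo_lite.to_newick(tree) + "\n")
        log.append(f"supermatrix: {len(sm.taxa)} taxa x {sm.width} columns, "
                   f"{len(sm.partitions)} partitions")
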