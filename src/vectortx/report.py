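"""Pipeline orchestration: simulate/classify, render all tables, manifest.

A run directory contains: the inputs used (in simulate mode), the group
table, the per-ORF gene table, the splice audit, the RCA summary, a
Table-1-style accounting row, BED12 transcript models, novel-end
clusters, and a manifest recording the config hash so that identical
configs provably produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .genome_model import VectorGenome, FeatureCatalog, load_genome, load_feature_catalog
from .simulate import (
    NoiseModel,
    ToyParams,
    build_toy_genome,
    nonpermissive_profile,
    permissive_profile,
    sample_reads,
)
from .ingest import (
    filter_alignments,
    parse_spliced_alignments,
    read_accounting,
    write_accounting_tsv,
)
from .grouping import (
    GroupingParams,
    TranscriptGroup,
    cluster_novel_ends,
    group_transcripts,
    assign_tss,
    write_group_tsv,
)
from .orfcall import CATEGORY_CATALOG, OrfCall, assign_orf, gene_table
from .splicestats import screen_e1, transgene_splice_stats, write_splice_audit_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one reproducible run needs; one seed drives all randomness."""

    mode: str = "simulate"                 # "simulate" | "classify"
    outdir: str = "vectortx_run"
    # classify-mode inputs
    genome: Optional[str] = None
    catalog: Optional[str] = None
    alignments: Optional[str] = None
    # simulate-mode inputs
    n_reads: int = 5000
    profile: str = "nonpermissive"         # "nonpermissive" | "permissive"
    noise: NoiseModel = field(default_factory=NoiseModel)
    toy_params: ToyParams = field(default_factory=ToyParams)
    # shared
    seed: int = 0
    grouping: GroupingParams = field(default_factory=GroupingParams)
    table_decimals: int = 2
    min_read_length: int = 0
    mapped_host: int = 0
    sample_name: str = "sample"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config from YAML; keyword arguments override file values.

        Nested sections ``noise``, ``toy_params`` and ``grouping`` map onto
        their dataclasses; unknown keys are rejected.
        """
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise PipelineError("config", f"{path} does not contain a mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        nested = {"noise": NoiseModel, "toy_params": ToyParams,
                  "grouping": GroupingParams}
        kwargs = {}
        valid = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in valid:
                raise PipelineError("config", f"unknown config field {key!r}")
            if key in nested and isinstance(value, dict):
                value = nested[key](**value)
            kwargs[key] = value
        return cls(**kwargs)

    def validate(self) -> None:
        if self.mode not in ("simulate", "classify"):
            raise PipelineError("config", f"unknown mode {self.mode!r}")
        if self.mode == "classify":
            for fieldname in ("genome", "catalog", "alignments"):
                if getattr(self, fieldname) is None:
                    raise PipelineError(
                        "config", f"classify mode requires the {fieldname!r} field")
        if self.n_reads < 0:
            raise PipelineError("config", "n_reads must be >= 0")


def _config_hash(config: RunConfig) -> str:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        return obj

    d = enc(config)
    d.pop("outdir", None)  # where outputs land does not change what they are
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def export_bed12(groups: Sequence[TranscriptGroup], contig: str,
                 calls: Optional[Sequence[OrfCall]] = None,
                 catalog: Optional[FeatureCatalog] = None) -> list[str]:
    """One BED12 line per transcript group (score = read count, capped 1000).

    thickStart/thickEnd span the called catalog ORF where one exists;
    groups without a catalog call get a zero-width thick region at
    chromStart, the BED convention for non-coding entries.
    """
    if not groups:
        raise ValueError("no transcript groups to export")
    call_by_group = {c.group_id: c for c in (calls or [])}
    lines = []
    for g in groups:
        chain = g.representative_chain
        start, end = chain.span
        thick_start = thick_end = start
        call = call_by_group.get(g.group_id)
        if call is not None and call.category == CATEGORY_CATALOG and catalog is not None:
            orf = next(o for o in catalog.orfs if o.label == call.orf_label)
            lo, hi = orf.genomic_interval
            thick_start, thick_end = max(lo, start), min(hi, end)
        sizes = ",".join(str(e - s) for s, e in chain.blocks)
        starts = ",".join(str(s - start) for s, e in chain.blocks)
        lines.append("\t".join(str(v) for v in (
            contig, start, end, g.group_id, min(g.count, 1000), g.strand,
            thick_start, thick_end, "0", len(chain.blocks), sizes, starts,
        )))
    return lines


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write tables + manifest to the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "tool": "vectortx",
        "version": __version__,
        "config_hash": _config_hash(config),
        "mode": config.mode,
        "seed": config.seed,
    }

    # --- stage: inputs ---
    if config.mode == "simulate":
        noise = dataclasses.replace(config.noise, seed=config.seed)
        toy = build_toy_genome(config.toy_params, seed=config.seed)
        genome, catalog = toy.genome, toy.catalog
        if config.profile == "nonpermissive":
            profile = nonpermissive_profile(toy.models)
        elif config.profile == "permissive":
            profile = permissive_profile(toy.models)
        else:
            raise PipelineError("simulate", f"unknown profile {config.profile!r}")
        readset = sample_reads(genome, toy.models, profile, config.n_reads,
                               noise, host_contig=toy.host_contig)
        fastq_path = outdir / "reads.fastq"
        sam_path = outdir / "truth.sam"
        readset.write_fastq(fastq_path)
        readset.write_sam(sam_path)
        readset.write_ground_truth(outdir / "ground_truth.tsv")
        _write_fasta(outdir / "genome.fasta", [genome] +
                     ([toy.host_contig] if toy.host_contig else []))
        alignments_path = sam_path
        manifest["profile"] = config.profile
        manifest["n_reads_simulated"] = config.n_reads
    else:
        try:
            genome = load_genome(config.genome)
            catalog = load_feature_catalog(config.catalog, genome)
        except Exception as exc:
            raise PipelineError("inputs", str(exc)) from exc
        alignments_path = Path(config.alignments)

    # --- stage: ingest ---
    try:
        reads = parse_spliced_alignments(alignments_path)
    except Exception as exc:
        raise PipelineError("ingest", str(exc)) from exc
    reads = filter_alignments(reads, config.min_read_length, primary_only=True)
    vector_reads = [r for r in reads if r.contig == genome.name]
    e1_contig_reads = [r for r in reads if r.contig != genome.name]
    manifest["n_alignments"] = len(reads)
    manifest["n_vector_reads"] = len(vector_reads)
    manifest["n_e1_contig_reads"] = len(e1_contig_reads)

    accounting = read_accounting(
        [r.read_length for r in vector_reads] + [r.read_length for r in e1_contig_reads],
        mapped_host=config.mapped_host,
        vaccine_reads=vector_reads,
        e1_reads=len(e1_contig_reads) or None,
        sample=config.sample_name,
    )
    write_accounting_tsv([accounting], outdir / "accounting.tsv")

    # --- stage: grouping ---
    groups, unclassified = group_transcripts(vector_reads, catalog, config.grouping)
    manifest["n_groups"] = len(groups)
    manifest["n_unclassified"] = unclassified
    write_group_tsv(groups, outdir / "groups.tsv")

    unassigned_5p = [r for r in vector_reads
                     if assign_tss(r.chain, catalog, config.grouping.tss_window) is None]
    clusters = cluster_novel_ends(unassigned_5p, config.grouping.cluster_gap,
                                  config.grouping.min_cluster_count)
    with open(outdir / "novel_ends.tsv", "w", encoding="utf-8") as fh:
        fh.write("cluster_id\tposition\tstrand\tcount\tkind\n")
        for c in clusters:
            fh.write(f"{c.cluster_id}\t{c.position + 1}\t{c.strand}\t{c.count}\t{c.kind}\n")

    # --- stage: ORF calls + gene table ---
    calls = [assign_orf(g, genome, catalog) for g in groups]
    classified = sum(g.count for g in groups)
    if classified:
        table = gene_table(calls, groups, classified, config.table_decimals)
        table.to_tsv(outdir / "gene_table.tsv")
        manifest["gene_table_denominator"] = classified

    # --- stage: splice audit + RCA ---
    stat = transgene_splice_stats(groups, catalog)
    write_splice_audit_tsv(stat, groups, outdir / "splice_audit.tsv")
    rca = screen_e1(calls, groups, catalog, e1_contig_count=len(e1_contig_reads))
    with open(outdir / "rca_summary.txt", "w", encoding="utf-8") as fh:
        fh.write(f"e1_orf_read_count={rca.e1_orf_read_count}\n")
        fh.write(f"e1_contig_read_count={rca.e1_contig_read_count}\n")
        fh.write(f"verdict={rca.verdict}\n")

    # --- stage: export ---
    if groups:
        bed = export_bed12(groups, genome.name, calls, catalog)
        (outdir / "transcripts.bed").write_text("\n".join(bed) + "\n")

    with open(outdir / "manifest.txt", "w", encoding="utf-8") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    logger.info("run complete: %s", outdir)
    return outdir


def _write_fasta(path: Path, genomes: Sequence[VectorGenome]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genomes:
            fh.write(f">{g.name}\n")
            for i in range(0, g.length, 80):
                fh.write(g.sequence[i:i + 80] + "\n")


def write_catalog_tsv(catalog: FeatureCatalog, path) -> None:
    """Serialize a catalog back to the 6-column TSV schema."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# class\tlabel\tstart\tend\tstrand\ttags\n")
        for o in catalog.orfs:
            tags = ",".join(sorted(o.category_tags)) or "."
            fh.write(f"orf\t{o.label}\t{o.start_codon_pos}\t{o.stop_pos}\t{o.strand}\t{tags}\n")
        for t in catalog.tss_sites:
            tags = "transgene" if t.label == catalog.transgene_tss_label else "."
            fh.write(f"tss\t{t.label}\t{t.position}\t.\t{t.strand}\t{tags}\n")
        for p in catalog.polya_sites:
            fh.write(f"polya\t{p.label}\t{p.position}\t.\t{p.strand}\t.\n")
        for pos, strand in catalog.donors:
            fh.write(f"donor\tdonor_{pos}\t{pos}\t.\t{strand}\t.\n")
        for pos, strand in catalog.acceptors:
            fh.write(f"acceptor\tacceptor_{pos}\t{pos}\t.\t{strand}\t.\n")
        fh.write(f"cassette\tcassette\t{catalog.cassette[0]}\t{catalog.cassette[1]}\t.\t.\n")
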