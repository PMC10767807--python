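"""Thin command-line layer over the library: predict / associate / network /
stats / simulate.

Stages communicate through documented TSVs on disk so each one is
independently runnable and resumable.  Every run writes a manifest
recording the package version, the thresholds in force (defaults equal
the published values; overrides are echoed) and SHA-256 checksums of the
inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import click
import yaml

from taloci import __version__, caller, genome_io, mge_association, minhash, netstats
from taloci.config import (
    DEFAULT_EVALUE_CEILING,
    DEFAULT_FLANK_BP,
    DEFAULT_H_THRESHOLD,
    DEFAULT_HASH_SEED,
    DEFAULT_K,
    DEFAULT_LEN_MAX,
    DEFAULT_LEN_MIN,
    DEFAULT_MASH_THRESHOLD,
    DEFAULT_SKETCH_SIZE,
)
from taloci.genome_io import FormatError
from taloci.homology import read_reference_fasta
from taloci.pipeline import predict_loci
from taloci.synthetic_data import PlanError, generate, plan_from_dict, write_bundle

log = logging.getLogger("taloci")


@dataclass
class RunConfig:
    """Tunable thresholds of one run; defaults are the published values."""

    h_value: float = DEFAULT_H_THRESHOLD
    len_min: int = DEFAULT_LEN_MIN
    len_max: int = DEFAULT_LEN_MAX
    flank_bp: int = DEFAULT_FLANK_BP
    mash_threshold: float = DEFAULT_MASH_THRESHOLD
    k: int = DEFAULT_K
    s: int = DEFAULT_SKETCH_SIZE
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING
    rules: str | None = None
    seed: int = DEFAULT_HASH_SEED
    overrides: list[str] = field(default_factory=list)

    @classmethod
    def load(cls, config_path: str | None, **cli_overrides) -> "RunConfig":
        cfg = cls()
        if config_path:
            data = yaml.safe_load(Path(config_path).read_text()) or {}
            for key, value in data.items():
                if not hasattr(cfg, key):
                    raise click.UsageError(f"unknown config key {key!r}")
                setattr(cfg, key, value)
                cfg.overrides.append(f"{key}={value}")
        for key, value in cli_overrides.items():
            if value is not None:
                setattr(cfg, key, value)
                cfg.overrides.append(f"{key}={value}")
        for item in cfg.overrides:
            log.info("config override: %s", item)
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, command: str, cfg: RunConfig, inputs: dict[str, str]) -> None:
    manifest = {
        "tool": "taloci",
        "version": __version__,
        "command": command,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "thresholds": asdict(cfg),
        "input_checksums": {name: _sha256(p) for name, p in inputs.items() if Path(p).exists()},
    }
    (outdir / f"manifest_{command}.json").write_text(json.dumps(manifest, indent=1) + "\n")


def _read_genome(genome: str, gff: str | None):
    if gff:
        return genome_io.read_fasta_gff(genome, gff)
    return genome_io.read_genbank(genome)


@click.group()
@click.option("--log-level", default="INFO", show_default=True)
def cli(log_level: str) -> None:
    """Toxin-antitoxin locus prediction and MGE association analysis."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))


@cli.command()
@click.argument("genome", type=click.Path(exists=True))
@click.option("--gff", type=click.Path(exists=True), help="GFF3 if GENOME is a FASTA.")
@click.option("--refs-protein", type=click.Path(exists=True), required=True)
@click.option("--refs-rna", type=click.Path(exists=True))
@click.option("--profiles", type=click.Path(exists=True), help="HMMER3 profile file.")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out-dir", default=".", show_default=True)
@click.option("--h-value", "h_value", type=float, default=None, help="H-value threshold override.")
@click.option("--rules", type=click.Path(exists=True), default=None, help="Rule table TSV override.")
def predict(genome, gff, refs_protein, refs_rna, profiles, config_path, out_dir, h_value, rules):
    """Predict TA loci on an annotated genome; writes loci TSV + GFF3."""
    cfg = RunConfig.load(config_path, h_value=h_value, rules=rules)
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        g = _read_genome(genome, gff)
        refs = read_reference_fasta(refs_protein, "protein")
        if refs_rna:
            refs += read_reference_fasta(refs_rna, "rna")
        rule_table = caller.load_rules(cfg.rules)
        loci = predict_loci(
            g,
            refs,
            profiles=profiles,
            rules=rule_table,
            h_threshold=cfg.h_value,
            len_min=cfg.len_min,
            len_max=cfg.len_max,
            evalue_ceiling=cfg.evalue_ceiling,
        )
    except FormatError as exc:
        click.echo(f"format error: {exc}", err=True)
        sys.exit(1)
    caller.loci_to_tsv(loci, outdir / "loci.tsv")
    genome_io.write_predictions_gff(loci, outdir / "loci.gff3")
    inputs = {"genome": genome, "refs_protein": refs_protein}
    if refs_rna:
        inputs["refs_rna"] = refs_rna
    _write_manifest(outdir, "predict", cfg, inputs)
    click.echo(f"{len(loci)} TA loci -> {outdir / 'loci.tsv'}")


@cli.command()
@click.option("--loci", "loci_path", type=click.Path(exists=True), required=True)
@click.option("--mges", "mges_path", type=click.Path(exists=True), required=True)
@click.option("--genome", type=click.Path(exists=True), help="GenBank; enables plasmid-as-MGE links.")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out-dir", default=".", show_default=True)
@click.option("--flank-bp", type=int, default=None)
def associate(loci_path, mges_path, genome, config_path, out_dir, flank_bp):
    """Link TA loci to MGEs (harboured / IS-flanked); writes links TSV."""
    cfg = RunConfig.load(config_path, flank_bp=flank_bp)
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        loci = caller.read_loci_tsv(loci_path)
        g = genome_io.read_genbank(genome) if genome else None
        mges = mge_association.read_mge_table(mges_path, genome=g)
        if g is not None:
            mges += mge_association.plasmid_mges(g)
    except (FormatError, ValueError) as exc:
        click.echo(f"format error: {exc}", err=True)
        sys.exit(1)
    links = mge_association.associate(loci, mges, flank_bp=cfg.flank_bp)
    mge_association.links_to_tsv(links, mges, outdir / "links.tsv")
    mge_association.write_mge_table(mges, outdir / "mges_effective.tsv")
    _write_manifest(outdir, "associate", cfg, {"loci": loci_path, "mges": mges_path})
    click.echo(f"{len(links)} TA-MGE links -> {outdir / 'links.tsv'}")


@cli.command()
@click.option("--links", "links_path", type=click.Path(exists=True), required=True)
@click.option("--mges", "mges_path", type=click.Path(exists=True), required=True)
@click.option("--genome", type=click.Path(exists=True), help="GenBank; enables MGE sketching.")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out-dir", default=".", show_default=True)
def network(links_path, mges_path, genome, config_path, out_dir):
    """Build the TA-MGE network with MGE-MGE Mash similarity edges."""
    cfg = RunConfig.load(config_path)
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        rows = mge_association.read_links_tsv(links_path)
        g = genome_io.read_genbank(genome) if genome else None
        mges = mge_association.read_mge_table(mges_path, genome=g)
        if g is not None:
            mges += mge_association.plasmid_mges(g)
    except (FormatError, ValueError) as exc:
        click.echo(f"format error: {exc}", err=True)
        sys.exit(1)
    links = [link for link, _ in rows]
    sketches = [
        minhash.sketch(m.sequence, k=cfg.k, s=cfg.s, seed=cfg.seed, mge_id=m.mge_id)
        for m in mges
        if len(m.sequence) >= cfg.k
    ]
    edges = minhash.similar_edges(sketches, threshold=cfg.mash_threshold) if len(sketches) > 1 else []
    minhash.edges_to_tsv(edges, outdir / "similar_edges.tsv")
    minhash.sketches_to_json(sketches, outdir / "sketches.json")
    graph = netstats.build_network(links, edges, mges=mges)
    netstats.network_to_files(graph, outdir / "network")
    _write_manifest(outdir, "network", cfg, {"links": links_path, "mges": mges_path})
    click.echo(
        f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges "
        f"({len(edges)} similarity) -> {outdir / 'network.json'}"
    )


@cli.command()
@click.option("--loci", "loci_path", type=click.Path(exists=True), required=True)
@click.option("--links", "links_path", type=click.Path(exists=True), required=True)
@click.option("--genome", type=click.Path(exists=True), help="GenBank for per-species tallies.")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--out-dir", default=".", show_default=True)
def stats(loci_path, links_path, genome, config_path, out_dir):
    """Summary tables: loci per type, type/family x MGE class, proportions."""
    cfg = RunConfig.load(config_path)
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        loci = caller.read_loci_tsv(loci_path)
        rows = mge_association.read_links_tsv(links_path)
        genomes = [genome_io.read_genbank(genome)] if genome else []
    except (FormatError, ValueError) as exc:
        click.echo(f"format error: {exc}", err=True)
        sys.exit(1)
    links = [link for link, _ in rows]
    classes = [klass for _, klass in rows]
    tables = netstats.summarize(loci, links, genomes, link_classes=classes)
    netstats.summary_to_files(tables, outdir / "summary")
    _write_manifest(outdir, "stats", cfg, {"loci": loci_path, "links": links_path})
    click.echo(
        f"{int(tables.proportions['relationships'])} relationships, "
        f"{tables.proportions['proportion_associated_pct']}% of loci associated "
        f"-> {outdir / 'summary'}"
    )


@cli.command()
@click.option("--plan", "plan_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None, help="Override the plan seed.")
@click.option("--out-dir", default=".", show_default=True)
def simulate(plan_path, seed, out_dir):
    """Generate a synthetic fixture bundle (genome, refs, MGEs, truth) from a plan."""
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = yaml.safe_load(Path(plan_path).read_text())
    if seed is not None:
        payload["seed"] = seed
    try:
        plan = plan_from_dict(payload)
        genome, refs, mges, truth = generate(plan)
    except (PlanError, KeyError, TypeError) as exc:
        click.echo(f"plan error: {exc}", err=True)
        sys.exit(1)
    paths = write_bundle(genome, refs, mges, truth, outdir)
    click.echo(
        f"simulated {len(truth.expected_loci)} loci, {len(mges)} MGEs -> {paths['genome'].parent}"
    )


if __name__ == "__main__":
    cli()
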