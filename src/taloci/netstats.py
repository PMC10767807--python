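"""TA-MGE network construction and summary statistics.

Counting convention: each (locus, MGE) association link is a relationship
of its own, so one locus harboured by an ICE and flanked by an IS counts
as two relationships but one associated locus.  Proportions are reported
to one decimal place as percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from taloci.genome_io import AnnotatedGenome
from taloci.mge_association import MGE_CLASSES, MGEAnnotation, TAMGELink


class ReferenceError_(KeyError):
    """An edge references a node id absent from the inputs."""


def build_network(
    links: Sequence[TAMGELink],
    sim_edges: Sequence[tuple[str, str, float]],
    loci: Sequence = (),
    mges: Sequence[MGEAnnotation] = (),
) -> nx.Graph:
    """Union graph of TA-MGE association links and MGE-MGE similarity edges.

    Nodes are typed (``ta_locus`` / ``mge``); duplicate links between the
    same pair collapse to a single edge.  When ``loci``/``mges`` are given,
    every edge endpoint must resolve against them.
    """
    g = nx.Graph()
    known_loci = {l.locus_id for l in loci} if loci else None
    known_mges = {m.mge_id for m in mges} if mges else None
    for m in mges:
        g.add_node(m.mge_id, node_type="mge", mge_class=m.mge_class)
    for l in loci:
        g.add_node(l.locus_id, node_type="ta_locus", ta_type=getattr(l, "ta_type", ""))
    for link in links:
        if known_loci is not None and link.locus_id not in known_loci:
            raise ReferenceError_(f"link references unknown locus {link.locus_id!r}")
        if known_mges is not None and link.mge_id not in known_mges:
            raise ReferenceError_(f"link references unknown MGE {link.mge_id!r}")
        g.add_node(link.locus_id, node_type="ta_locus")
        g.add_node(link.mge_id, node_type="mge")
        g.add_edge(link.locus_id, link.mge_id, edge_type="association", kind=link.link_kind, gap=link.gap)
    for a, b, d in sim_edges:
        if known_mges is not None and (a not in known_mges or b not in known_mges):
            raise ReferenceError_(f"similarity edge references unknown MGE {a!r}/{b!r}")
        g.add_node(a, node_type="mge")
        g.add_node(b, node_type="mge")
        g.add_edge(a, b, edge_type="similarity", mash_distance=d)
    return g


def locus_subnetwork(g: nx.Graph, locus_id: str) -> nx.Graph:
    """The connected component containing one TA locus."""
    if locus_id not in g:
        raise ReferenceError_(locus_id)
    return g.subgraph(nx.node_connected_component(g, locus_id)).copy()


@dataclass
class SummaryTables:
    """Fixture-scale analogues of the corpus-wide summary tables."""

    per_type_counts: pd.Series  # TA loci per type
    association_matrix: pd.DataFrame  # TA type x MGE class relationship counts
    family_matrix: pd.DataFrame  # TA family x MGE class relationship counts
    per_species: pd.DataFrame  # strains, loci, mean loci per strain
    proportions: dict[str, float]  # percentages, 1-decimal convention


def species_label(organism: str) -> str:
    """First two whitespace tokens of the organism string ('Genus species')."""
    tokens = organism.split()
    return " ".join(tokens[:2]) if tokens else "unknown"


def summarize(
    loci: Sequence,
    links: Sequence[TAMGELink],
    genomes: Sequence[AnnotatedGenome] = (),
    link_classes: Sequence[str] | None = None,
    mges: Sequence[MGEAnnotation] = (),
) -> SummaryTables:
    """Tabulate loci, relationships and proportions.

    ``link_classes`` gives each link's MGE class (parallel to ``links``);
    if omitted it is looked up from ``mges``.  Relationship counts treat
    every (locus, MGE) link separately; the associated-locus proportion
    counts distinct loci with at least one link.
    """
    if link_classes is None:
        class_of = {m.mge_id: m.mge_class for m in mges}
        link_classes = [class_of.get(link.mge_id, "?") for link in links]

    type_of = {l.locus_id: l.ta_type for l in loci}
    family_of = {l.locus_id: getattr(l, "family", "?") for l in loci}
    types = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    per_type = pd.Series(0, index=types, name="loci", dtype=int)
    for l in loci:
        if l.ta_type in per_type.index:
            per_type[l.ta_type] += 1

    assoc = pd.DataFrame(0, index=types, columns=list(MGE_CLASSES), dtype=int)
    families = sorted({family_of[l.locus_id] for l in loci}) or ["?"]
    fam = pd.DataFrame(0, index=families, columns=list(MGE_CLASSES), dtype=int)
    for link, klass in zip(links, link_classes):
        t = type_of.get(link.locus_id)
        f = family_of.get(link.locus_id)
        if t in assoc.index and klass in assoc.columns:
            assoc.loc[t, klass] += 1
        if f in fam.index and klass in fam.columns:
            fam.loc[f, klass] += 1

    # per-species tallies: one genome = one strain
    rows = []
    loci_by_replicon: dict[str, int] = {}
    for l in loci:
        loci_by_replicon[l.replicon_id] = loci_by_replicon.get(l.replicon_id, 0) + 1
    species_strains: dict[str, int] = {}
    species_loci: dict[str, int] = {}
    for genome in genomes:
        label = species_label(genome.replicons[0].organism) if genome.replicons else "unknown"
        species_strains[label] = species_strains.get(label, 0) + 1
        n_loci = sum(loci_by_replicon.get(r.id, 0) for r in genome.replicons)
        species_loci[label] = species_loci.get(label, 0) + n_loci
    for label in sorted(species_strains):
        n_strains = species_strains[label]
        n_loci = species_loci[label]
        rows.append(
            {
                "species": label,
                "strains": n_strains,
                "loci": n_loci,
                "loci_per_strain": round(n_loci / n_strains, 1),
            }
        )
    per_species = pd.DataFrame(rows, columns=["species", "strains", "loci", "loci_per_strain"])

    associated = {link.locus_id for link in links}
    n_loci_total = len(loci)
    prop_associated = 100.0 * len(associated & set(type_of)) / n_loci_total if n_loci_total else 0.0
    plasmids = [r for g in genomes for r in g.replicons if r.kind == "plasmid"]
    plasmids_with_locus = [r for r in plasmids if loci_by_replicon.get(r.id, 0) > 0]
    prop_plasmid = 100.0 * len(plasmids_with_locus) / len(plasmids) if plasmids else 0.0
    proportions = {
        "relationships": float(len(links)),
        "associated_loci": float(len(associated & set(type_of))),
        "proportion_associated_pct": round(prop_associated, 1),
        "proportion_plasmids_with_locus_pct": round(prop_plasmid, 1),
    }
    return SummaryTables(per_type, assoc, fam, per_species, proportions)


def network_to_files(g: nx.Graph, prefix: str | Path) -> None:
    """Export a network as node/edge TSVs and one JSON graph file."""
    prefix = Path(prefix)
    with open(f"{prefix}.nodes.tsv", "w") as fh:
        fh.write("node_id\tnode_type\tattrs\n")
        for n, data in sorted(g.nodes(data=True)):
            extra = {k: v for k, v in data.items() if k != "node_type"}
            fh.write(f"{n}\t{data.get('node_type', '?')}\t{json.dumps(extra, sort_keys=True)}\n")
    with open(f"{prefix}.edges.tsv", "w") as fh:
        fh.write("source\ttarget\tedge_type\tattrs\n")
        for a, b, data in sorted(g.edges(data=True)):
            extra = {k: v for k, v in data.items() if k != "edge_type"}
            fh.write(f"{a}\t{b}\t{data.get('edge_type', '?')}\t{json.dumps(extra, sort_keys=True)}\n")
    payload = nx.node_link_data(g, edges="edges")
    Path(f"{prefix}.json").write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def summary_to_files(tables: SummaryTables, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables.per_type_counts.to_csv(outdir / "per_type_counts.tsv", sep="\t")
    tables.association_matrix.to_csv(outdir / "association_matrix.tsv", sep="\t")
    tables.family_matrix.to_csv(outdir / "family_matrix.tsv", sep="\t")
    tables.per_species.to_csv(outdir / "per_species.tsv", sep="\t", index=False)
    (outdir / "proportions.json").write_text(json.dumps(tables.proportions, indent=1) + "\n")
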