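"""End-to-end prediction: homology search -> candidate filter -> pair calling."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from taloci import homology
from taloci.caller import TALocus, TARule, call_loci, load_rules, resolve_overlaps
from taloci.config import (
    DEFAULT_EVALUE_CEILING,
    DEFAULT_H_THRESHOLD,
    DEFAULT_LEN_MAX,
    DEFAULT_LEN_MIN,
)
from taloci.genome_io import AnnotatedGenome
from taloci.homology import Candidate, ReferenceEntry


def find_candidates(
    genome: AnnotatedGenome,
    refs: Sequence[ReferenceEntry],
    profiles: str | Path | None = None,
    h_threshold: float = DEFAULT_H_THRESHOLD,
    len_min: int = DEFAULT_LEN_MIN,
    len_max: int = DEFAULT_LEN_MAX,
    evalue_ceiling: float = DEFAULT_EVALUE_CEILING,
    require_blast: bool = False,
) -> list[Candidate]:
    """Run the protein/RNA homology searches and the candidate filters.

    Note: RNA hits without an annotated partner feature add synthesised
    ``rna`` features to ``genome`` (see :func:`taloci.homology.search_rna`).
    """
    hits: list[homology.HomologyHit] = []
    if any(r.molecule == "protein" for r in refs):
        hits.extend(homology.search_protein(genome, refs, evalue_ceiling=evalue_ceiling))
    if any(r.molecule == "rna" for r in refs):
        hits.extend(homology.search_rna(genome, refs, evalue_ceiling=evalue_ceiling))
    domain_hits: list[homology.DomainHit] = []
    if profiles is not None:
        domain_hits = homology.scan_domains(genome, profiles)
    return homology.build_candidates(
        hits,
        domain_hits,
        genome,
        refs,
        h_threshold=h_threshold,
        len_min=len_min,
        len_max=len_max,
        require_blast=require_blast,
    )


def predict_loci(
    genome: AnnotatedGenome,
    refs: Sequence[ReferenceEntry],
    profiles: str | Path | None = None,
    rules: Sequence[TARule] | None = None,
    **filter_kwargs,
) -> list[TALocus]:
    """Predict TA loci on a genome: candidates, exhaustive pairing, overlap
    resolution.  Returns loci sorted by (replicon, span start)."""
    candidates = find_candidates(genome, refs, profiles=profiles, **filter_kwargs)
    if rules is None:
        rules = load_rules()
    return resolve_overlaps(call_loci(candidates, rules))
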