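"""Pseudogene and truncation calling for receptor coding sequences.

A sequence is called a *pseudogene* when it carries at least one premature
stop codon or frameshift indel; a sequence with intact reading frame but
missing an entire annotated domain (e.g. lacking the transmembrane and
cytoplasmic domains) is *truncated*, deliberately not a pseudogene — a
short receptor is very likely non-functional but does not meet the
stop/frameshift criterion.  *Absent* is an input-level fact: no record was
supplied for the (species, gene) pair.

Thresholds (both configurable):

* a stop is premature when it falls before 90% of the reference length,
  which keeps near-C-terminal polymorphic stops from flagging;
* a domain is missing when >= 80% of its reference span is gapped in the
  query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import Alignment, CoordinateMap, dna_scoring, map_to_reference, nw_align, protein_scoring
from .seqio import GeneSequence, ReferenceAnnotation

__all__ = [
    "Lesion",
    "PseudogeneCall",
    "detect_premature_stops",
    "detect_frameshifts",
    "detect_missing_domains",
    "classify",
]


@dataclass(frozen=True)
class Lesion:
    """One inactivating feature, located in the reference amino-acid frame.

    ``kind`` is ``premature_stop``, ``frameshift`` or ``missing_domain``;
    point lesions have ``start == end``.
    """

    kind: str
    start: int
    end: int
    detail: str = ""


@dataclass
class PseudogeneCall:
    species_id: str
    gene_label: str
    verdict: str
    lesions: list[Lesion] = field(default_factory=list)

    def __post_init__(self) -> None:
        kinds = {l.kind for l in self.lesions}
        has_inactivating = bool(kinds & {"premature_stop", "frameshift"})
        if self.verdict == "pseudogene" and not has_inactivating:
            raise ValueError("pseudogene verdict requires a stop/frameshift lesion")
        if self.verdict == "truncated" and (has_inactivating or "missing_domain" not in kinds):
            raise ValueError("truncated verdict requires only missing_domain lesions")


def detect_premature_stops(
    protein: str, ref_len: int, premature_frac: float = 0.9
) -> list[Lesion]:
    """Premature stop codons in a translated query.

    One lesion per ``*`` before ``ceil(premature_frac * ref_len)``; a stop
    at the final position of the protein (the natural terminator) is never
    reported.
    """
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    cutoff = math.ceil(premature_frac * ref_len)
    lesions = []
    for pos in range(1, len(protein) + 1):
        if protein[pos - 1] != "*" or pos == len(protein):
            continue
        if pos < cutoff:
            lesions.append(Lesion("premature_stop", pos, pos))
    return lesions


def detect_frameshifts(codon_aln: Alignment) -> list[Lesion]:
    """Frame-breaking indels from a pairwise nucleotide alignment.

    The alignment's first row is the functional reference, the second the
    query.  Each maximal single-row gap run whose length mod 3 != 0 yields
    one frameshift lesion at the reference codon where the run starts;
    in-frame indels (multiples of 3) are ignored, so e.g. a clean
    three-nucleotide deletion never flags.
    """
    if codon_aln.kind != "codon":
        raise ValueError("frameshift detection requires a codon-kind alignment")
    if len(codon_aln.rows) != 2:
        raise ValueError("expected a pairwise reference/query alignment")
    ref_row, query_row = codon_aln.rows
    lesions = []
    ref_pos = 0  # nt position in the reference
    col = 0
    ncol = len(ref_row)
    while col < ncol:
        rch, qch = ref_row[col], query_row[col]
        if rch != "-" and qch != "-":
            ref_pos += 1
            col += 1
            continue
        if rch == "-" and qch == "-":
            col += 1
            continue
        # maximal run of gap in exactly one row
        in_query = qch == "-"
        run_start_ref = ref_pos + 1
        run_len = 0
        while col < ncol and (
            (query_row[col] == "-" and ref_row[col] != "-")
            if in_query
            else (ref_row[col] == "-" and query_row[col] != "-")
        ):
            if in_query:
                ref_pos += 1
            run_len += 1
            col += 1
        if run_len % 3 != 0:
            # report at the reference codon where the run begins; insertions
            # (gap in reference) attach to the last reference nt before them
            anchor_nt = run_start_ref if in_query else max(ref_pos, 1)
            codon = (anchor_nt + 2) // 3
            kind = "deletion" if in_query else "insertion"
            lesions.append(Lesion("frameshift", codon, codon, f"{kind}:{run_len}nt"))
    return lesions


def detect_missing_domains(
    query_map: CoordinateMap,
    ref_annot: ReferenceAnnotation,
    gap_frac: float = 0.8,
) -> list[Lesion]:
    """A ``missing_domain`` lesion per domain >= ``gap_frac`` gapped in the query."""
    lesions = []
    for dom, (start, end) in ref_annot.domains.items():
        span = range(start, end + 1)
        n_gap = sum(1 for pos in span if query_map[pos] is None)
        if n_gap >= gap_frac * len(span):
            lesions.append(Lesion("missing_domain", start, end, dom))
    return lesions


def classify(
    seq: GeneSequence | None,
    ref: ReferenceAnnotation,
    ref_cds: str | None = None,
    species_id: str | None = None,
    gene_label: str | None = None,
    premature_frac: float = 0.9,
    domain_gap_frac: float = 0.8,
) -> PseudogeneCall:
    """Full classification of one coding sequence against the reference.

    ``seq=None`` (or an ``absent`` record) yields the ``absent`` verdict.
    Frameshift detection needs the reference CDS (``ref_cds``); without it
    only stop-codon and domain evidence is used.
    """
    if seq is None or seq.status == "absent" or not seq.ungapped:
        return PseudogeneCall(species_id or "?", gene_label or "?", "absent")

    lesions: list[Lesion] = list(
        detect_premature_stops(seq.protein, len(ref.protein), premature_frac)
    )
    if ref_cds is not None:
        codon_aln = nw_align(
            ref_cds.replace("-", ""),
            seq.ungapped,
            dna_scoring(),
            labels=("ref", "query"),
            kind="codon",
        )
        lesions.extend(detect_frameshifts(codon_aln))

    has_inactivating = any(
        l.kind in ("premature_stop", "frameshift") for l in lesions
    )
    # domain coverage from the protein alignment; stop codons are masked so
    # a readthrough translation still aligns over its full length
    query_protein = seq.protein.replace("*", "X")
    domain_lesions: list[Lesion] = []
    if query_protein:
        aln = nw_align(
            ref.protein, query_protein, protein_scoring(), labels=("ref", "query")
        )
        qmap = map_to_reference(aln, "ref")["query"]
        domain_lesions = detect_missing_domains(qmap, ref, domain_gap_frac)

    if has_inactivating:
        verdict = "pseudogene"
        lesions.extend(domain_lesions)
    elif domain_lesions:
        verdict = "truncated"
        lesions = domain_lesions
    else:
        verdict = "functional"
    return PseudogeneCall(seq.species_id, seq.gene_label, verdict, lesions)
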