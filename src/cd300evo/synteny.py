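"""Synteny-state classification of the receptor gene cluster.

The canonical locus is the interval between two anchor genes (GPRC5C and
RAB37 for the CD300 cluster on human chromosome 17).  Each family gene is
``present_in_locus`` when it lies between the anchors on their chromosome,
``relocated`` when annotated elsewhere, and ``absent`` when not annotated at
all.  ``locus_intact`` requires both anchors on one chromosome; when the
anchors sit on different chromosomes the locus is reported broken and genes
are classified against the interval around whichever anchor shares their
chromosome.

"Between the anchors" is containment of the gene's start coordinate in the
anchor interval, strand-agnostic — the reasoning is at gene-order level, no
assembly liftover is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["LocusState", "classify_locus", "DEFAULT_ANCHORS"]

DEFAULT_ANCHORS = ("GPRC5C", "RAB37")


@dataclass
class LocusState:
    species_id: str
    gene_states: dict[str, str] = field(default_factory=dict)
    locus_intact: bool = False

    def counts(self) -> dict[str, int]:
        out = {"present_in_locus": 0, "relocated": 0, "absent": 0}
        for state in self.gene_states.values():
            out[state] += 1
        return out


def _locate(annot: dict[str, pd.DataFrame], gene: str) -> tuple[str, int] | None:
    for chrom, table in annot.items():
        hit = table[table["gene"] == gene]
        if len(hit):
            return chrom, int(hit["start"].iloc[0])
    return None


def classify_locus(
    annot: dict[str, pd.DataFrame],
    family_genes: set[str] | list[str],
    anchors: tuple[str, str] = DEFAULT_ANCHORS,
    species_id: str = "",
) -> LocusState:
    """Classify every family gene against the anchor interval.

    ``annot`` is the per-chromosome table map from
    :func:`cd300evo.seqio.read_annotation_table`.
    """
    a1, a2 = anchors
    if a1 == a2:
        raise ValueError("anchor names must differ")
    loc1, loc2 = _locate(annot, a1), _locate(annot, a2)

    intervals: dict[str, tuple[int, int]] = {}
    intact = False
    if loc1 and loc2 and loc1[0] == loc2[0]:
        lo, hi = sorted((loc1[1], loc2[1]))
        intervals[loc1[0]] = (lo, hi)
        intact = True
    else:
        if loc1 and loc2:
            warnings.warn(
                f"{species_id or 'species'}: anchors {a1}/{a2} on different "
                f"chromosomes ({loc1[0]} vs {loc2[0]}); locus reported broken"
            )
        # genes judged against the nearest-anchor interval on each chromosome:
        # from the lone anchor to the chromosome end containing it
        for loc in (loc1, loc2):
            if loc is None:
                continue
            chrom = loc[0]
            table = annot[chrom]
            intervals.setdefault(chrom, (int(table["start"].min()), int(table["end"].max())))

    states: dict[str, str] = {}
    for gene in sorted(family_genes):
        loc = _locate(annot, gene)
        if loc is None:
            states[gene] = "absent"
        else:
            chrom, start = loc
            iv = intervals.get(chrom)
            states[gene] = (
                "present_in_locus" if iv is not None and iv[0] <= start <= iv[1] else "relocated"
            )
    return LocusState(species_id=species_id, gene_states=states, locus_intact=intact)
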