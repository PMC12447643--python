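"""Sequence and annotation I/O for the CD300A/CD300C analysis pipeline.

Conventions used throughout the package:

* All residue/site coordinates are **1-based inclusive**, matching the way
  functional sites on these receptors are cited in the literature (N83, E191,
  Y267, ...).
* FASTA headers carry ``species|gene|accession`` (configurable delimiter);
  ``gene`` is one of ``A`` (inhibitory paralog, CD300A role), ``C``
  (activating paralog, CD300C role) or ``outgroup``.
* Nucleotide sequences are over ``{A, C, G, T, N, -}``; the gap character
  marks pre-aligned input and is stripped before translation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSequence",
    "ReferenceAnnotation",
    "FastaParseError",
    "GENE_LABELS",
    "STATUSES",
    "translate",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
]

NUCLEOTIDE_ALPHABET = set("ACGTN-")
GENE_LABELS = ("A", "C", "outgroup")
STATUSES = ("functional", "pseudogene", "truncated", "absent")
DOMAIN_ORDER = ("signal", "ecd", "tm", "cyto")

# Codon -> amino acid map from the standard genetic code; stops become '*'.
_CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TABLE.update({codon: "*" for codon in standard_dna_table.stop_codons})


class FastaParseError(ValueError):
    """Raised when a FASTA record violates the header schema or alphabet."""


def translate(cds: str) -> str:
    """Translate a CDS under the standard genetic code.

    Gaps are stripped first; any codon containing ``N`` translates to ``'X'``
    (and thus can never be read as a stop); stop codons become ``'*'``; a
    trailing partial codon (1-2 nt) is ignored.
    """
    ungapped = cds.replace("-", "").upper()
    bad = set(ungapped) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    out = []
    for i in range(0, len(ungapped) - len(ungapped) % 3, 3):
        codon = ungapped[i : i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


@dataclass
class GeneSequence:
    """One species/gene coding sequence with its translation and status.

    ``protein`` is always the codon-wise translation of the ungapped CDS; it
    is recomputed on construction and must not be set independently.
    """

    species_id: str
    gene_label: str
    accession: str = ""
    cds: str = ""
    status: str = "functional"
    protein: str = field(init=False, default="")

    def __post_init__(self) -> None:
        if self.gene_label not in GENE_LABELS:
            raise ValueError(
                f"gene_label must be one of {GENE_LABELS}, got {self.gene_label!r}"
            )
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        self.cds = self.cds.upper()
        if self.status != "absent" and not self.ungapped:
            raise ValueError(
                f"{self.species_id}|{self.gene_label}: empty CDS for non-absent record"
            )
        self.protein = translate(self.cds)

    @property
    def ungapped(self) -> str:
        return self.cds.replace("-", "")

    @property
    def is_gapped(self) -> bool:
        return "-" in self.cds


@dataclass
class ReferenceAnnotation:
    """Reference protein with domain spans and annotated functional sites.

    ``domains`` maps ``signal``/``ecd``/``tm``/``cyto`` to 1-based inclusive
    ``(start, end)`` spans that tile ``[1, len(protein)]`` in order; ``sites``
    is a list of ``(label, position)`` for annotated cysteines, sequons,
    charged residues and ITIM tyrosines.
    """

    name: str
    protein: str
    domains: dict[str, tuple[int, int]]
    sites: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.protein)
        prev_end = 0
        for dom in DOMAIN_ORDER:
            if dom not in self.domains:
                continue
            start, end = self.domains[dom]
            if not (1 <= start <= end <= n):
                raise ValueError(f"{self.name}: domain {dom} span {start}-{end} outside 1-{n}")
            if start <= prev_end:
                raise ValueError(f"{self.name}: domain {dom} overlaps or is out of order")
            prev_end = end
        for label, pos in self.sites:
            if not (1 <= pos <= n):
                raise ValueError(f"{self.name}: site {label} at {pos} outside 1-{n}")

    def domain_span(self, name: str) -> tuple[int, int]:
        return self.domains[name]

    def site_positions(self, prefix: str) -> list[int]:
        """Positions of sites whose label starts with ``prefix``, sorted."""
        return sorted(pos for label, pos in self.sites if label.startswith(prefix))


def _parse_header(header: str, delimiter: str) -> tuple[str, str, str]:
    parts = header.split(delimiter)
    if len(parts) == 2:
        parts.append("")
    if len(parts) != 3 or not parts[0] or not parts[1]:
        raise FastaParseError(
            f"malformed header {header!r}: expected species{delimiter}gene"
            f"{delimiter}accession"
        )
    return parts[0], parts[1], parts[2]


def read_fasta(path: str | Path, delimiter: str = "|") -> list[GeneSequence]:
    """Read CDS FASTA into :class:`GeneSequence` records, order preserved.

    Gap characters are retained (pre-aligned input is allowed) but a file
    mixing gapped and ungapped records is rejected, since that is almost
    always a sign of concatenating an alignment with raw sequences.
    """
    records: list[GeneSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        species, gene, accession = _parse_header(rec.id, delimiter)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in NUCLEOTIDE_ALPHABET:
                raise FastaParseError(
                    f"record {rec.id!r}: non-IUPAC character {ch!r} at position {pos}"
                )
        try:
            records.append(
                GeneSequence(species_id=species, gene_label=gene, accession=accession, cds=seq)
            )
        except ValueError as exc:
            raise FastaParseError(f"record {rec.id!r}: {exc}") from exc
    gappedness = {rec.is_gapped for rec in records}
    if len(gappedness) > 1:
        raise FastaParseError("file mixes gapped (aligned) and ungapped records")
    return records


def write_fasta(records: Iterable[GeneSequence], path: str | Path, delimiter: str = "|") -> None:
    seqrecs = [
        SeqRecord(
            Seq(rec.cds),
            id=delimiter.join([rec.species_id, rec.gene_label, rec.accession]),
            description="",
        )
        for rec in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta-2line")


REQUIRED_ANNOTATION_COLUMNS = ["gene", "chromosome", "start", "end", "strand"]


def read_annotation_table(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a gene-annotation TSV into per-chromosome lists sorted by start.

    Columns: gene, chromosome, start, end, strand (1-based inclusive,
    start < end). Duplicate gene names on one chromosome are kept with a
    warning, mirroring how tandem copies appear in annotation dumps.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if len(df) and (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]["gene"].tolist()
        raise ValueError(f"start >= end for genes: {bad}")
    out: dict[str, pd.DataFrame] = {}
    for chrom, sub in df.groupby("chromosome", sort=True):
        dup = sub["gene"][sub["gene"].duplicated()].unique().tolist()
        if dup:
            warnings.warn(f"chromosome {chrom}: duplicate gene names kept: {dup}")
        out[str(chrom)] = sub.sort_values("start", kind="mergesort").reset_index(drop=True)
    return out


def by_species_gene(records: Iterable[GeneSequence]) -> Mapping[tuple[str, str], GeneSequence]:
    """Index records by (species, gene); duplicates are an error."""
    out: dict[tuple[str, str], GeneSequence] = {}
    for rec in records:
        key = (rec.species_id, rec.gene_label)
        if key in out:
            raise ValueError(f"duplicate record for {key}")
        out[key] = rec
    return out
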