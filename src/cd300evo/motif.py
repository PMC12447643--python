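"""Functional-element scanning and cross-species conservation reporting.

Scanned element classes and their consensus rules:

* classical ITIM: ``[ILVS] x Y x x [LV]`` (window anchored at the tyrosine,
  positions Y-2 .. Y+3);
* non-classical ITIM: ``[ILVST] x Y x x [LVI]`` — a superset of the
  classical rule, so every classical hit is also a non-classical hit;
* transmembrane charge: any of D/E/K/R inside the TM span (the activating
  paralog signals through a charged TM glutamate, so charge identity matters
  and charge flips such as E->K are reported downstream);
* N-glycosylation sequon: ``N x [ST]`` with x != P (the proline exclusion is
  the standard biochemical rule; switchable);
* cysteine: every C inside a span (disulfide-bond conservation).

The wildcard positions admit the 20 standard residues only: a window
containing ``X`` (ambiguous translation) never matches any class.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import Alignment, map_to_reference
from .seqio import ReferenceAnnotation

__all__ = [
    "MotifHit",
    "scan_itims",
    "scan_tm_charge",
    "scan_sequons",
    "scan_cysteines",
    "itim_class_at",
    "conservation_report",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
ITIM_START_CLASSICAL = set("ILVS")
ITIM_START_NONCLASSICAL = set("ILVST")
ITIM_END_CLASSICAL = set("LV")
ITIM_END_NONCLASSICAL = set("LVI")
CHARGED = set("DEKR")
NEGATIVE = set("DE")
POSITIVE = set("KR")


@dataclass
class MotifHit:
    """One scanner match, anchored at the diagnostic residue.

    ``query_pos`` is the 1-based position of the anchor (ITIM tyrosine,
    charged residue, sequon N, or C); ``ref_pos`` is its projection onto the
    reference frame (``None`` when unmapped); ``matched`` is the residue
    window that satisfied the rule.
    """

    motif_class: str
    query_pos: int
    matched: str
    ref_pos: int | None = None
    note: str = ""


def _check_span(protein: str, span: tuple[int, int]) -> None:
    start, end = span
    if not (1 <= start <= end <= len(protein)):
        raise ValueError(f"span {start}-{end} outside protein 1-{len(protein)}")


def _itim_window_class(window: str) -> str | None:
    """Classify a 6-residue window centred on Y at offset 2; None = no hit."""
    if len(window) != 6 or window[2] != "Y":
        return None
    if any(ch not in STANDARD_AA for ch in window):
        return None
    if window[0] in ITIM_START_NONCLASSICAL and window[5] in ITIM_END_NONCLASSICAL:
        if window[0] in ITIM_START_CLASSICAL and window[5] in ITIM_END_CLASSICAL:
            return "itim_classical"
        return "itim_nonclassical"
    return None


def scan_itims(protein: str, span: tuple[int, int]) -> list[MotifHit]:
    """All ITIM windows whose tyrosine anchor lies inside ``span``.

    Hits are ordered by position and overlapping windows are all reported.
    Classical hits are labelled ``itim_classical``; windows passing only the
    relaxed rule are ``itim_nonclassical``.
    """
    _check_span(protein, span)
    start, end = span
    hits = []
    for pos in range(start, end + 1):  # 1-based anchor position
        if protein[pos - 1] != "Y" or pos - 3 < 0 or pos + 3 > len(protein):
            continue
        window = protein[pos - 3 : pos + 3]
        cls = _itim_window_class(window)
        if cls is not None:
            hits.append(MotifHit(cls, pos, window))
    return hits


def itim_class_at(protein: str, pos: int) -> str | None:
    """ITIM status of the tyrosine at ``pos``: class, ``anchor_only`` (the
    tyrosine is present but its context fails the consensus), or ``None``."""
    if not (1 <= pos <= len(protein)) or protein[pos - 1] != "Y":
        return None
    window = protein[max(pos - 3, 0) : pos + 3]
    cls = _itim_window_class(window) if pos - 3 >= 0 and pos + 3 <= len(protein) else None
    return cls if cls is not None else "anchor_only"


def scan_tm_charge(protein: str, tm_span: tuple[int, int]) -> list[MotifHit]:
    """One hit per charged residue (D/E/K/R) inside the transmembrane span."""
    _check_span(protein, tm_span)
    start, end = tm_span
    return [
        MotifHit("tm_charge", pos, protein[pos - 1])
        for pos in range(start, end + 1)
        if protein[pos - 1] in CHARGED
    ]


def scan_sequons(
    protein: str, span: tuple[int, int], exclude_proline: bool = True
) -> list[MotifHit]:
    """N-glycosylation sequons ``N-x-[S/T]`` with the N anchor inside ``span``.

    Overlapping sequons are all reported. ``exclude_proline`` applies the
    standard x != P rule.
    """
    _check_span(protein, span)
    start, end = span
    hits = []
    for pos in range(start, end + 1):
        if protein[pos - 1] != "N" or pos + 2 > len(protein):
            continue
        window = protein[pos - 1 : pos + 2]
        if any(ch not in STANDARD_AA for ch in window):
            continue
        if window[2] not in "ST":
            continue
        if exclude_proline and window[1] == "P":
            continue
        hits.append(MotifHit("sequon", pos, window))
    return hits


def scan_cysteines(protein: str, span: tuple[int, int]) -> list[MotifHit]:
    """One hit per cysteine inside ``span`` (disulfide-bond positions)."""
    _check_span(protein, span)
    start, end = span
    return [
        MotifHit("cysteine", pos, "C")
        for pos in range(start, end + 1)
        if protein[pos - 1] == "C"
    ]


def project_hits(hits: list[MotifHit], coord_map) -> list[MotifHit]:
    """Fill ``ref_pos`` on hits using an inverse query->reference map."""
    inverse = {q: r for r, q in coord_map.mapping.items() if q is not None}
    return [
        MotifHit(h.motif_class, h.query_pos, h.matched, inverse.get(h.query_pos), h.note)
        for h in hits
    ]


def _charge_sign(res: str) -> int:
    return -1 if res in NEGATIVE else (1 if res in POSITIVE else 0)


def conservation_report(
    aln: Alignment, ref_label: str, annot: ReferenceAnnotation
) -> pd.DataFrame:
    """Per-site conservation of annotated reference positions across rows.

    For every annotated site the report counts rows conserving the reference
    residue, lists substitutions as ``label:REF>OBS``, and lists rows gapped
    at the site, so ``n_conserved + n_substituted + n_gap`` equals the number
    of non-reference rows.  Two site-specific notes are added: a charged TM
    residue replaced by one of opposite sign is a ``charge_flip`` (the E->K
    pattern that may break adaptor coupling), and an ITIM tyrosine whose
    surrounding window fails the consensus is ``anchor_only``.
    """
    if aln.row(ref_label).replace("-", "") != annot.protein:
        raise ValueError("reference row does not match the annotation protein")
    maps = map_to_reference(aln, ref_label)
    queries = {
        label: aln.ungapped(label) for label in aln.labels if label != ref_label
    }
    rows = []
    for label, ref_pos in sorted(annot.sites, key=lambda s: s[1]):
        ref_res = annot.protein[ref_pos - 1]
        conserved, substituted, gapped, notes = [], [], [], []
        for qlabel, protein in queries.items():
            qpos = maps[qlabel][ref_pos]
            if qpos is None or qpos > len(protein):
                gapped.append(qlabel)
                continue
            obs = protein[qpos - 1]
            if obs == ref_res:
                conserved.append(qlabel)
            else:
                substituted.append(f"{qlabel}:{ref_res}>{obs}")
                if (
                    label.startswith("tm_charge")
                    and _charge_sign(obs) != 0
                    and _charge_sign(obs) == -_charge_sign(ref_res)
                ):
                    notes.append(f"{qlabel}:charge_flip")
            if label.startswith("itim") and obs == "Y" and qpos is not None:
                cls = itim_class_at(protein, qpos)
                if cls == "anchor_only":
                    notes.append(f"{qlabel}:anchor_only")
        rows.append(
            {
                "site": label,
                "ref_pos": ref_pos,
                "ref_residue": ref_res,
                "n_conserved": len(conserved),
                "n_substituted": len(substituted),
                "n_gap": len(gapped),
                "substitutions": ";".join(substituted),
                "gaps": ";".join(gapped),
                "notes": ";".join(notes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "ref_pos",
            "ref_residue",
            "n_conserved",
            "n_substituted",
            "n_gap",
            "substitutions",
            "gaps",
            "notes",
        ],
    )
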