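"""Gene-conversion / concerted-evolution signals between the two paralogs.

For each species carrying both paralogs, a sliding window over the protein
alignment contrasts

* ``ident_within`` — identity between the species' own A and C copies, with
* ``ident_between`` — mean identity of same-gene (ortholog) comparisons to
  the other species,

giving ``delta = ident_within - ident_between`` per window.  A converted
tract homogenizes the paralogs locally, so its windows show an excess of
within-species identity over the gene-wide background.

Significance is assessed by permutation.  The default null
(``method="columns"``) permutes alignment columns jointly across rows and
re-reads each window, asking whether a *contiguous* window carries more
within-pair excess than a random draw of the same number of columns from
the analysis region; this is calibrated whenever columns are approximately
exchangeable, and is powered against localized conversion tracts.  The
alternative null (``method="labels"``) reshuffles the A/C labels within
each species; it is retained for comparison but is conservative whenever
orthologs are systematically more similar than cross-paralog pairs (i.e. in
any simulation with appreciable post-duplication divergence), and is not
the default for that reason.

The shared-motif finder reports maximal runs of columns where every member
of a lineage carries the identical state in *both* paralogs while few
outside species carry it — the style of evidence used to argue lineage-level
conversion (family-exclusive shared strings, down to single shared
residues; shared in-frame deletions count as shared states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import Alignment

__all__ = [
    "ConversionWindow",
    "SharedMotif",
    "window_statistic",
    "permutation_test",
    "shared_motifs",
    "paired_species",
]


@dataclass
class ConversionWindow:
    """One sliding-window record for one species.

    ``ref_span`` is the 1-based inclusive column span in the alignment
    frame.  ``delta`` is the mean per-column contrast (within minus
    between), which equals ``ident_within - ident_between`` whenever every
    usable column has at least one ortholog comparison.
    """

    species_id: str
    ref_span: tuple[int, int]
    ident_within: float
    ident_between: float
    delta: float
    n_usable: int
    p_perm: float | None = None


@dataclass
class SharedMotif:
    lineage: str
    ref_span: tuple[int, int]
    residues: str
    background_freq: float


def paired_species(msa: Alignment, delimiter: str = "|") -> list[str]:
    """Species having both an A and a C row in the alignment, sorted."""
    seen: dict[str, set[str]] = {}
    for label in msa.labels:
        parts = label.split(delimiter)
        if len(parts) >= 2:
            seen.setdefault(parts[0], set()).add(parts[1])
    return sorted(s for s, genes in seen.items() if {"A", "C"} <= genes)


def _rows_by_key(msa: Alignment, delimiter: str) -> dict[tuple[str, str], np.ndarray]:
    out = {}
    for label, row in zip(msa.labels, msa.rows):
        parts = label.split(delimiter)
        if len(parts) >= 2 and parts[1] in ("A", "C"):
            out[(parts[0], parts[1])] = np.frombuffer(row.encode("ascii"), dtype=np.uint8)
    return out


_GAP = ord("-")


def _column_profiles(
    msa: Alignment, species: str, delimiter: str = "|"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column within-pair and mean ortholog identity for one species.

    Both arrays are NaN at columns gapped in either of the species' own
    paralogs (unusable columns); ortholog comparisons gapped in the partner
    are dropped per comparison.
    """
    rows = _rows_by_key(msa, delimiter)
    if (species, "A") not in rows or (species, "C") not in rows:
        raise ValueError(f"species {species!r} lacks one of the two paralogs")
    others = sorted({s for s, _ in rows if s != species})
    if len(others) < 2:
        raise ValueError("need at least 2 other species for ortholog comparisons")
    a_s, c_s = rows[(species, "A")], rows[(species, "C")]
    usable = (a_s != _GAP) & (c_s != _GAP)
    ncol = a_s.size

    within = np.where(usable, (a_s == c_s).astype(float), np.nan)

    num = np.zeros(ncol)
    den = np.zeros(ncol)
    for t in others:
        for gene, row_s in (("A", a_s), ("C", c_s)):
            row_t = rows.get((t, gene))
            if row_t is None:
                continue
            ok = usable & (row_t != _GAP)
            num[ok] += (row_s[ok] == row_t[ok]).astype(float)
            den[ok] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        between = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    between[~usable] = np.nan
    return within, between


def window_statistic(
    msa: Alignment,
    species: str,
    win: int = 30,
    step: int = 5,
    region: tuple[int, int] | None = None,
    delimiter: str = "|",
) -> list[ConversionWindow]:
    """Sliding-window within/between identity contrast for one species.

    ``region`` restricts the analysis to a 1-based inclusive column span
    (e.g. the conserved extracellular stretch); windows with fewer than 50%
    usable columns are skipped.
    """
    if win < 5:
        raise ValueError("window length must be >= 5")
    within, between = _column_profiles(msa, species, delimiter)
    lo, hi = region if region is not None else (1, within.size)
    if not (1 <= lo <= hi <= within.size):
        raise ValueError(f"region {region} outside alignment columns")
    out = []
    for start in range(lo - 1, hi - win + 1, step):
        w = slice(start, start + win)
        n_usable = int(np.isfinite(within[w]).sum())
        if n_usable < 0.5 * win:
            continue
        iw = float(np.nanmean(within[w]))
        ib = float(np.nanmean(between[w]))
        contrast = within[w] - between[w]
        delta = float(np.nanmean(contrast)) if np.isfinite(contrast).any() else iw - ib
        out.append(
            ConversionWindow(
                species_id=species,
                ref_span=(start + 1, start + win),
                ident_within=iw,
                ident_between=ib,
                delta=delta,
                n_usable=n_usable,
            )
        )
    return out


def permutation_test(
    windows: list[ConversionWindow],
    msa: Alignment,
    n_perm: int = 999,
    seed: int = 1234,
    region: tuple[int, int] | None = None,
    method: str = "columns",
    delimiter: str = "|",
) -> list[ConversionWindow]:
    """Fill ``p_perm`` on each window: ``p = (1 + #{null >= obs}) / (n_perm + 1)``.

    Identical seeds give identical p-values.  See the module docstring for
    the two null constructions; ``"columns"`` is the default.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if method not in ("columns", "labels"):
        raise ValueError(f"unknown permutation method {method!r}")
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[ConversionWindow]] = {}
    for w in windows:
        by_species.setdefault(w.species_id, []).append(w)

    out: list[ConversionWindow] = []
    for species in sorted(by_species):
        ws = by_species[species]
        if method == "columns":
            within, between = _column_profiles(msa, species, delimiter)
            contrast = within - between
            lo, hi = region if region is not None else (1, within.size)
            cols = np.arange(lo - 1, hi)
            obs = np.array(
                [float(np.nanmean(contrast[w.ref_span[0] - 1 : w.ref_span[1]])) for w in ws]
            )
            widths = np.array([w.ref_span[1] - w.ref_span[0] + 1 for w in ws])
            offsets = np.array([w.ref_span[0] - lo for w in ws])
            region_contrast = contrast[cols]
            vals = np.nan_to_num(region_contrast, nan=0.0)
            fin = np.isfinite(region_contrast).astype(float)
            exceed = np.zeros(len(ws), dtype=int)
            for _ in range(n_perm):
                perm = rng.permutation(cols.size)
                csum = np.concatenate(([0.0], np.cumsum(vals[perm])))
                ccnt = np.concatenate(([0.0], np.cumsum(fin[perm])))
                n_use = ccnt[offsets + widths] - ccnt[offsets]
                with np.errstate(invalid="ignore", divide="ignore"):
                    null = (csum[offsets + widths] - csum[offsets]) / n_use
                exceed += (null >= obs - 1e-12) & (n_use > 0)
            pvals = (1.0 + exceed) / (n_perm + 1.0)
        else:
            pvals = _label_permutation_pvalues(ws, msa, species, n_perm, rng, delimiter)
        for w, p in zip(ws, pvals):
            out.append(
                ConversionWindow(
                    w.species_id, w.ref_span, w.ident_within, w.ident_between,
                    w.delta, w.n_usable, float(p),
                )
            )
    order = {(w.species_id, w.ref_span): i for i, w in enumerate(out)}
    return sorted(out, key=lambda w: order[(w.species_id, w.ref_span)])


def _label_permutation_pvalues(
    ws: list[ConversionWindow],
    msa: Alignment,
    species: str,
    n_perm: int,
    rng: np.random.Generator,
    delimiter: str,
) -> np.ndarray:
    """Null from reshuffling A/C labels within every species independently."""
    rows = _rows_by_key(msa, delimiter)
    others = sorted({s for s, _ in rows if s != species and (s, "A") in rows and (s, "C") in rows})
    a_s, c_s = rows[(species, "A")], rows[(species, "C")]
    usable = (a_s != _GAP) & (c_s != _GAP)
    # per-column identity of the four comparison types per other species
    same = []  # A_s-A_t plus C_s-C_t
    cross = []  # A_s-C_t plus C_s-A_t
    valid = []
    for t in others:
        a_t, c_t = rows[(t, "A")], rows[(t, "C")]
        ok = usable & (a_t != _GAP) & (c_t != _GAP)
        same.append(((a_s == a_t).astype(float) + (c_s == c_t)) / 2.0)
        cross.append(((a_s == c_t).astype(float) + (c_s == a_t)) / 2.0)
        valid.append(ok)
    same, cross, valid = np.array(same), np.array(cross), np.array(valid)
    within = np.where(usable, (a_s == c_s).astype(float), np.nan)

    pvals = np.zeros(len(ws))
    for k, w in enumerate(ws):
        sl = slice(w.ref_span[0] - 1, w.ref_span[1])
        obs = w.delta
        exceed = 0
        for _ in range(n_perm):
            flips = rng.random(len(others)) < 0.5
            mix = np.where(flips[:, None], cross[:, sl], same[:, sl])
            num = (mix * valid[:, sl]).sum(axis=0)
            den = valid[:, sl].sum(axis=0)
            with np.errstate(invalid="ignore"):
                between = np.where(den > 0, num / np.maximum(den, 1), np.nan)
            contrast = within[sl] - between
            if np.isfinite(contrast).any() and np.nanmean(contrast) >= obs - 1e-12:
                exceed += 1
        pvals[k] = (1.0 + exceed) / (n_perm + 1.0)
    return pvals


def shared_motifs(
    msa: Alignment,
    grouping: dict[str, str],
    min_len: int = 1,
    exclusivity: float = 0.10,
    delimiter: str = "|",
) -> list[SharedMotif]:
    """Lineage-exclusive strings shared by both paralogs.

    Candidate lineages are every family in ``grouping`` with >= 2
    two-paralog member species, plus every two-paralog species itself.  A
    motif is a maximal run of >= ``min_len`` columns where all members'
    A and C rows carry one identical state (shared in-frame gaps count),
    kept when at most an ``exclusivity`` fraction of non-member species
    carries the same string in either gene.  Output is independent of the
    alignment's row order.
    """
    rows = _rows_by_key(msa, delimiter)
    species = paired_species(msa, delimiter)
    ncol = msa.n_columns

    families: dict[str, list[str]] = {}
    for sp in species:
        fam = grouping.get(sp)
        if fam is not None:
            families.setdefault(fam, []).append(sp)
    lineages: list[tuple[str, list[str]]] = [
        (fam, sorted(members)) for fam, members in sorted(families.items()) if len(members) >= 2
    ] + [(sp, [sp]) for sp in species]

    out: list[SharedMotif] = []
    for lineage, members in lineages:
        member_rows = [rows[(m, g)] for m in members for g in ("A", "C")]
        stack = np.array(member_rows)
        shared = (stack == stack[0]).all(axis=0)
        outside = [sp for sp in species if sp not in members]
        col = 0
        while col < ncol:
            if not shared[col]:
                col += 1
                continue
            start = col
            while col < ncol and shared[col]:
                col += 1
            if col - start < min_len:
                continue
            motif = stack[0, start:col]
            if (motif == _GAP).all():
                continue
            carriers = 0
            for sp in outside:
                if any(
                    np.array_equal(rows[(sp, g)][start:col], motif) for g in ("A", "C")
                ):
                    carriers += 1
            freq = carriers / len(outside) if outside else 0.0
            if freq <= exclusivity:
                out.append(
                    SharedMotif(
                        lineage=lineage,
                        ref_span=(start + 1, col),
                        residues=motif.tobytes().decode("ascii"),
                        background_freq=freq,
                    )
                )
    return out
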