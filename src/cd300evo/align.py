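"""Global alignment and reference-frame coordinate projection.

The motif and pseudogene analyses report every position in the human-style
reference numbering, so alignment here serves two purposes: building the
multiple alignments the window statistics run on, and projecting per-species
coordinates onto the reference frame.

The aligner is a standard global Needleman-Wunsch/Gotoh with affine gaps
(gap of length k scores ``open + (k-1) * extend``) and a fixed traceback
preference (substitution, then gap in the second sequence, then gap in the
first) so results are bit-identical across platforms.  The multiple aligner
is progressive: pairwise distances from k-mer profiles, UPGMA guide tree,
profile-profile merges under sum-of-pairs scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .seqio import translate

__all__ = [
    "Alignment",
    "CoordinateMap",
    "ScoringScheme",
    "protein_scoring",
    "dna_scoring",
    "nw_align",
    "progressive_msa",
    "map_to_reference",
    "back_translate",
]

PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
DNA_ALPHABET = "ACGTN"

_M, _X, _Y = 0, 1, 2  # DP states: substitution, gap-in-b (consumes a), gap-in-a


@dataclass
class ScoringScheme:
    """Residue alphabet, substitution score matrix and affine gap penalties."""

    alphabet: str
    matrix: np.ndarray  # square, indexed by alphabet position
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def encode(self, seq: str) -> np.ndarray:
        idx = np.full(128, -1, dtype=np.int64)
        for i, ch in enumerate(self.alphabet):
            idx[ord(ch)] = i
        codes = idx[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            bad = sorted({ch for ch in seq if ch not in self.alphabet})
            raise ValueError(f"characters outside scoring alphabet: {bad}")
        return codes


def protein_scoring(gap_open: float = -10.0, gap_extend: float = -1.0) -> ScoringScheme:
    """BLOSUM62 with affine gaps; the package default for proteins."""
    blosum = substitution_matrices.load("BLOSUM62")
    order = blosum.alphabet
    mat = np.zeros((len(PROTEIN_ALPHABET), len(PROTEIN_ALPHABET)))
    pos = {ch: i for i, ch in enumerate(order)}
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            mat[i, j] = blosum[pos[a], pos[b]]
    return ScoringScheme(PROTEIN_ALPHABET, mat, gap_open, gap_extend)


def dna_scoring(
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -16.0,
    gap_extend: float = -4.0,
) -> ScoringScheme:
    """Match/mismatch nucleotide scoring; ``N`` is neutral (0).

    Gap costs are deliberately stiff: these alignments compare homologous
    coding sequences where a real frameshift pays for its single gap many
    times over in downstream frame restoration, while cheap gaps would let
    compensating gap pairs masquerade as matches in diverged regions and
    produce spurious frameshift calls.
    """
    n = len(DNA_ALPHABET)
    mat = np.full((n, n), mismatch)
    np.fill_diagonal(mat, match)
    mat[DNA_ALPHABET.index("N"), :] = 0.0
    mat[:, DNA_ALPHABET.index("N")] = 0.0
    return ScoringScheme(DNA_ALPHABET, mat, gap_open, gap_extend)


@dataclass
class Alignment:
    """Gapped rows of equal length with per-row labels.

    ``kind`` is ``"protein"`` for amino-acid alignments and ``"codon"`` for
    nucleotide alignments (whether codon-aware back-translations, whose gap
    runs are multiples of 3, or raw nucleotide alignments used for
    frameshift detection).
    """

    labels: list[str]
    rows: list[str]
    kind: str = "protein"
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in count")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        if self.kind not in ("protein", "codon"):
            raise ValueError(f"kind must be 'protein' or 'codon', got {self.kind!r}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        try:
            return self.rows[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"label {label!r} not in alignment") from None

    def ungapped(self, label: str) -> str:
        return self.row(label).replace("-", "")

    def drop_gap_only_columns(self) -> "Alignment":
        keep = [i for i in range(self.n_columns) if any(r[i] != "-" for r in self.rows)]
        rows = ["".join(r[i] for i in keep) for r in self.rows]
        return Alignment(list(self.labels), rows, self.kind, self.score)


@dataclass
class CoordinateMap:
    """Projection from reference positions to query positions (1-based).

    ``mapping[ref_pos]`` is the aligned query position, or ``None`` where the
    query has a gap.  Total over ``[1, ref_length]`` and strictly increasing
    where defined.
    """

    ref_label: str
    query_label: str
    mapping: dict[int, int | None]

    def __getitem__(self, ref_pos: int) -> int | None:
        return self.mapping[ref_pos]

    @property
    def ref_length(self) -> int:
        return len(self.mapping)

    def invert(self) -> dict[int, int]:
        return {q: r for r, q in self.mapping.items() if q is not None}


@njit(cache=True)
def _affine_dp(cell: np.ndarray, gap_open: float, gap_extend: float):  # pragma: no cover
    """Gotoh DP over a precomputed cell-score matrix.

    Returns the optimal score, the final state, and per-state backpointer
    matrices.  Tie-breaks always prefer substitution, then gap-in-b, then
    gap-in-a, which fixes the traceback uniquely.
    """
    n, m = cell.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    bM = np.zeros((n + 1, m + 1), dtype=np.int8)
    bX = np.zeros((n + 1, m + 1), dtype=np.int8)
    bY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        bX[i, 0] = _X if i > 1 else _M
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        bY[0, j] = _Y if j > 1 else _M
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # substitution state
            best, arg = M[i - 1, j - 1], _M
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], _X
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], _Y
            M[i, j] = best + cell[i - 1, j - 1]
            bM[i, j] = arg
            # gap in b (consume a_i)
            best, arg = M[i - 1, j] + gap_open, _M
            if X[i - 1, j] + gap_extend > best:
                best, arg = X[i - 1, j] + gap_extend, _X
            if Y[i - 1, j] + gap_open > best:
                best, arg = Y[i - 1, j] + gap_open, _Y
            X[i, j] = best
            bX[i, j] = arg
            # gap in a (consume b_j)
            best, arg = M[i, j - 1] + gap_open, _M
            if X[i, j - 1] + gap_open > best:
                best, arg = X[i, j - 1] + gap_open, _X
            if Y[i, j - 1] + gap_extend > best:
                best, arg = Y[i, j - 1] + gap_extend, _Y
            Y[i, j] = best
            bY[i, j] = arg
    best, arg = M[n, m], _M
    if X[n, m] > best:
        best, arg = X[n, m], _X
    if Y[n, m] > best:
        best, arg = Y[n, m], _Y
    return best, arg, bM, bX, bY


def _traceback(n: int, m: int, state: int, bM, bX, bY) -> list[tuple[int, int]]:
    """Walk backpointers to the list of (i, j) steps; 0 means gap."""
    path = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == _M:
            prev = bM[i, j]
            path.append((i, j))
            i, j = i - 1, j - 1
        elif state == _X:
            prev = bX[i, j]
            path.append((i, 0))
            i -= 1
        else:
            prev = bY[i, j]
            path.append((0, j))
            j -= 1
        state = prev
    path.reverse()
    return path


def _align_core(cell: np.ndarray, scoring: ScoringScheme) -> tuple[float, list[tuple[int, int]]]:
    score, state, bM, bX, bY = _affine_dp(
        np.ascontiguousarray(cell, dtype=np.float64),
        float(scoring.gap_open),
        float(scoring.gap_extend),
    )
    return float(score), _traceback(cell.shape[0], cell.shape[1], state, bM, bX, bY)


def nw_align(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    labels: tuple[str, str] = ("a", "b"),
    kind: str = "protein",
) -> Alignment:
    """Optimal global affine-gap alignment of two ungapped sequences."""
    if not a or not b:
        raise ValueError("nw_align requires non-empty sequences")
    if "-" in a or "-" in b:
        raise ValueError("nw_align inputs must be ungapped")
    if scoring is None:
        scoring = protein_scoring() if kind == "protein" else dna_scoring()
    ca, cb = scoring.encode(a), scoring.encode(b)
    cell = scoring.matrix[np.ix_(ca, cb)]
    score, path = _align_core(cell, scoring)
    row_a = "".join(a[i - 1] if i else "-" for i, _ in path)
    row_b = "".join(b[j - 1] if j else "-" for _, j in path)
    return Alignment(list(labels), [row_a, row_b], kind, score)


def _profile_counts(rows: list[str], scheme: ScoringScheme) -> np.ndarray:
    """Column x alphabet residue-count matrix; gaps contribute nothing."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, len(scheme.alphabet)), dtype=np.float64)
    pos = {ch: i for i, ch in enumerate(scheme.alphabet)}
    for row in rows:
        for c, ch in enumerate(row):
            if ch != "-":
                counts[c, pos[ch]] += 1
    return counts


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    pa = _profile_counts(rows_a, scheme)
    pb = _profile_counts(rows_b, scheme)
    denom = max(len(rows_a) * len(rows_b), 1)
    cell = (pa @ scheme.matrix @ pb.T) / denom
    _, path = _align_core(cell, scheme)
    out_a = ["".join(r[i - 1] if i else "-" for i, _ in path) for r in rows_a]
    out_b = ["".join(r[j - 1] if j else "-" for _, j in path) for r in rows_b]
    return out_a, out_b


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    vocab: dict[str, int] = {}
    vecs = []
    for s in seqs:
        counts: dict[int, float] = {}
        for i in range(max(len(s) - k + 1, 1)):
            kmer = s[i : i + k]
            idx = vocab.setdefault(kmer, len(vocab))
            counts[idx] = counts.get(idx, 0.0) + 1.0
        vecs.append(counts)
    mat = np.zeros((len(seqs), max(len(vocab), 1)))
    for r, counts in enumerate(vecs):
        for idx, v in counts.items():
            mat[r, idx] = v
    with np.errstate(invalid="ignore"):
        dist = pdist(mat, metric="cosine")
    return np.nan_to_num(dist, nan=1.0)


def progressive_msa(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    scoring: ScoringScheme | None = None,
    kind: str = "protein",
) -> Alignment:
    """Progressive multiple alignment (UPGMA guide on k-mer distances).

    Two sequences reduce to :func:`nw_align`; gap-only columns are removed
    from the result.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa requires at least 2 sequences")
    if labels is None:
        labels = [f"seq{i}" for i in range(len(seqs))]
    if len(labels) != len(seqs):
        raise ValueError("labels and seqs differ in count")
    if scoring is None:
        scoring = protein_scoring() if kind == "protein" else dna_scoring()
    if len(seqs) == 2:
        aln = nw_align(seqs[0], seqs[1], scoring, (labels[0], labels[1]), kind)
        return aln.drop_gap_only_columns()

    dist = _kmer_distance_matrix(seqs)
    Z = hierarchy.linkage(dist, method="average")
    # cluster id -> (member indices, gapped rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i]]) for i in range(len(seqs))
    }
    next_id = len(seqs)
    for a_id, b_id, _, _ in Z:
        ia, ra = clusters.pop(int(a_id))
        ib, rb = clusters.pop(int(b_id))
        ra2, rb2 = _merge_profiles(ra, rb, scheme=scoring)
        clusters[next_id] = (ia + ib, ra2 + rb2)
        next_id += 1
    members, rows = clusters.popitem()[1]
    order = np.argsort(members)
    aln = Alignment(
        [labels[members[i]] for i in order], [rows[i] for i in order], kind
    )
    return aln.drop_gap_only_columns()


def map_to_reference(aln: Alignment, ref_label: str) -> dict[str, CoordinateMap]:
    """Per-row projection of reference positions onto each query row."""
    ref_row = aln.row(ref_label)
    out: dict[str, CoordinateMap] = {}
    for label, row in zip(aln.labels, aln.rows):
        if label == ref_label:
            continue
        mapping: dict[int, int | None] = {}
        rpos = qpos = 0
        for rch, qch in zip(ref_row, row):
            if qch != "-":
                qpos += 1
            if rch != "-":
                rpos += 1
                mapping[rpos] = qpos if qch != "-" else None
        out[label] = CoordinateMap(ref_label, label, mapping)
    return out


def back_translate(protein_aln: Alignment, cds_by_label: dict[str, str]) -> Alignment:
    """Thread ungapped CDSs through a protein alignment (codon-aware).

    Every residue becomes its source codon and every gap becomes ``---``, so
    translating each codon row reproduces the protein row.
    """
    rows = []
    for label, prow in zip(protein_aln.labels, protein_aln.rows):
        cds = cds_by_label[label].replace("-", "")
        n_res = sum(1 for ch in prow if ch != "-")
        if len(cds) < 3 * n_res:
            raise ValueError(f"{label}: CDS shorter than 3x aligned residues")
        if translate(cds)[:n_res] != prow.replace("-", ""):
            raise ValueError(f"{label}: CDS does not translate to the aligned protein")
        out = []
        k = 0
        for ch in prow:
            if ch == "-":
                out.append("---")
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        rows.append("".join(out))
    return Alignment(list(protein_aln.labels), rows, "codon")
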