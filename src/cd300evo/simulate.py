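"""Birth-and-death simulator for a two-paralog receptor family.

The generator instantiates the birth-and-death view of multigene-family
evolution: an ancestral CDS is duplicated at the root into paralogs ``A``
(inhibitory role) and ``C`` (activating role), which then evolve along a
primate-like species tree under

* Jukes-Cantor nucleotide substitution (branch lengths in subs/site), with
  substitutions that would create an in-frame stop codon rejected on
  functional genes (a minimal stand-in for purifying selection on the ORF);
* gene conversion: Poisson-many events per branch, each copying a
  geometric-length, codon-aligned tract between the paralogs (skipped once a
  paralog is inactivated, matching the observation that concerted evolution
  stops after pseudogenization);
* pseudogenization of gene ``C`` (a random premature stop codon or a 1-nt
  frameshift deletion) and whole-gene loss of ``C`` — the asymmetry of the
  empirical pattern, where the inhibitory paralog is never lost; a
  symmetric mode exists for calibration work.

No other indel evolution is simulated, so the true alignment is simply the
root coordinate frame ('-' only at frameshift deletions) and every event in
the returned truth table has exact coordinates.  Per-branch random streams
are derived from (seed, CRC32 of the branch's leaf set), so adding species
to the tree does not perturb the evolution of existing branches.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np
import pandas as pd

from .align import Alignment
from .seqio import GeneSequence, ReferenceAnnotation, translate

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_family",
    "make_reference_fixture",
    "default_species_tree",
]

_NT = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}


def default_species_tree() -> str:
    """The bundled 12-leaf primate-family caricature tree (newick)."""
    return (
        resources.files("cd300evo.data").joinpath("primate12.nwk").read_text().strip()
    )


@dataclass
class SimConfig:
    """Simulation conditions.

    Rates are per branch; branch lengths are nucleotide substitutions/site.
    ``paralog_stem`` is the extra divergence applied to each paralog at the
    root duplication before the species tree is descended.
    """

    species_tree: str | None = None  # newick; None = bundled primate tree
    root_cds_length: int = 897  # nt; 299 codons, the inhibitory receptor's length
    subst_rate_scale: float = 1.0
    paralog_stem: float = 0.2
    conversion_rate: float = 0.5  # events per branch
    conversion_tract_mean: float = 45.0  # nt
    pseudogen_prob: float = 0.02  # per branch, gene C
    loss_prob: float = 0.02  # per branch, gene C
    symmetric_inactivation: bool = False
    force_terminal_conversion_nt: int | None = None  # exactly one tract per leaf branch
    motif_guard: bool = False
    guard_codons: tuple[int, ...] = ()  # 1-based codons protected on gene A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_tree is None:
            self.species_tree = default_species_tree()
        if self.root_cds_length < 300 or self.root_cds_length % 3:
            raise ValueError("root_cds_length must be >= 300 and divisible by 3")
        for name in ("pseudogen_prob", "loss_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.conversion_tract_mean < 3:
            raise ValueError("conversion_tract_mean must be >= 3 nt")
        if self.conversion_rate < 0 or self.subst_rate_scale < 0 or self.paralog_stem < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SimResult:
    records: list[GeneSequence]
    truth: pd.DataFrame  # branch, kind, gene, start_nt, end_nt, detail
    alignment: Alignment  # true nucleotide alignment in root coordinates
    statuses: dict[tuple[str, str], str]
    tree: dendropy.Tree = field(repr=False, default=None)

    def protein_alignment(self, labels: list[str] | None = None) -> Alignment:
        """Root-frame codon-column translation of the true alignment.

        A codon column containing a gap translates to ``X``; for frameshifted
        sequences this is a coordinate convenience (root frame), not the
        biological peptide.
        """
        rows, labs = [], []
        for label, row in zip(self.alignment.labels, self.alignment.rows):
            if labels is not None and label not in labels:
                continue
            prot = []
            for i in range(0, len(row) - len(row) % 3, 3):
                codon = row[i : i + 3]
                if codon == "---":
                    prot.append("-")
                elif "-" in codon or "N" in codon:
                    prot.append("X")
                else:
                    prot.append(translate(codon))
            rows.append("".join(prot))
            labs.append(label)
        return Alignment(labs, rows, "protein")


def _branch_key(node: dendropy.Node) -> str:
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return leaves[0] if len(leaves) == 1 else "+".join(leaves)


def _rng(seed: int, key: str, gene: str, purpose: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            [seed & 0x7FFFFFFF, zlib.crc32(key.encode()), zlib.crc32(gene.encode()), purpose]
        )
    )


def _codon_str(seq: np.ndarray, codon_idx: int) -> str:
    return "".join(_NT[seq[3 * codon_idx : 3 * codon_idx + 3]])


def _reject_stops(seq: np.ndarray, parent: np.ndarray, changed: np.ndarray) -> None:
    """Revert any substitution batch that introduced an in-frame stop codon."""
    for codon_idx in np.unique(changed // 3):
        if _codon_str(seq, codon_idx) in _STOP_CODONS:
            sl = slice(3 * codon_idx, 3 * codon_idx + 3)
            seq[sl] = parent[sl]


def _substitute(
    seq: np.ndarray,
    distance: float,
    rng: np.random.Generator,
    protect_orf: bool,
    guard_codons: frozenset[int],
) -> np.ndarray:
    """Jukes-Cantor substitution over `distance` subs/site; returns a copy."""
    out = seq.copy()
    if distance <= 0:
        return out
    p_change = 0.75 * (1.0 - np.exp(-4.0 * distance / 3.0))
    hit = np.flatnonzero(rng.random(seq.size) < p_change)
    if guard_codons:
        hit = np.array([i for i in hit if i // 3 + 1 not in guard_codons], dtype=int)
    if hit.size == 0:
        return out
    # replace with one of the three other nucleotides, uniformly
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    if protect_orf:
        _reject_stops(out, seq, hit)
    return out


@dataclass
class _Lineage:
    """Evolving state of both paralogs along one root-to-node path."""

    seqs: dict[str, np.ndarray]
    deleted: dict[str, np.ndarray]  # boolean masks in root coordinates
    status: dict[str, str]  # functional | pseudogene | lost
    # codons carrying a recorded stop lesion, frozen against later
    # substitution so the ground-truth label stays readable from sequence
    locked: dict[str, frozenset[int]] = field(default_factory=dict)


def _apply_conversion(
    lin: _Lineage,
    rng: np.random.Generator,
    n_events: int,
    tract_mean_nt: float,
    fixed_tract_nt: int | None,
    key: str,
    events: list[dict],
    n_codons: int,
) -> None:
    if lin.status["A"] != "functional" or lin.status["C"] != "functional":
        return
    for _ in range(n_events):
        donor, recipient = ("A", "C") if rng.random() < 0.5 else ("C", "A")
        if fixed_tract_nt is not None:
            tract_codons = max(1, int(round(fixed_tract_nt / 3)))
        else:
            tract_codons = int(rng.geometric(min(3.0 / tract_mean_nt, 1.0)))
        start = int(rng.integers(0, n_codons))
        end = min(start + tract_codons, n_codons)
        sl = slice(3 * start, 3 * end)
        lin.seqs[recipient][sl] = lin.seqs[donor][sl]
        events.append(
            {
                "branch": key,
                "kind": "conversion",
                "gene": recipient,
                "start_nt": 3 * start + 1,
                "end_nt": 3 * end,
                "detail": f"donor:{donor}",
            }
        )


def _apply_inactivation(
    lin: _Lineage,
    gene: str,
    rng: np.random.Generator,
    cfg: SimConfig,
    key: str,
    events: list[dict],
    n_codons: int,
) -> None:
    if lin.status[gene] != "functional":
        return
    if rng.random() < cfg.loss_prob:
        lin.status[gene] = "lost"
        events.append(
            {"branch": key, "kind": "loss", "gene": gene, "start_nt": 0, "end_nt": 0, "detail": ""}
        )
        return
    if rng.random() < cfg.pseudogen_prob:
        # mid-gene lesion, clear of both termini and of the premature-stop cutoff
        lo, hi = int(0.05 * n_codons), int(0.85 * n_codons)
        if rng.random() < 0.5:
            codon = int(rng.integers(lo, hi))
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
            lin.seqs[gene][3 * codon : 3 * codon + 3] = [
                int(np.flatnonzero(_NT == ch)[0]) for ch in stop
            ]
            lin.locked[gene] = lin.locked.get(gene, frozenset()) | {codon + 1}
            events.append(
                {
                    "branch": key,
                    "kind": "stop_lesion",
                    "gene": gene,
                    "start_nt": 3 * codon + 1,
                    "end_nt": 3 * codon + 3,
                    "detail": f"codon:{codon + 1}",
                }
            )
        else:
            nt_pos = int(rng.integers(3 * lo, 3 * hi))
            lin.deleted[gene] = lin.deleted[gene].copy()
            lin.deleted[gene][nt_pos] = True
            events.append(
                {
                    "branch": key,
                    "kind": "frameshift_lesion",
                    "gene": gene,
                    "start_nt": nt_pos + 1,
                    "end_nt": nt_pos + 1,
                    "detail": "deletion:1nt",
                }
            )
        lin.status[gene] = "pseudogene"


def simulate_family(cfg: SimConfig) -> SimResult:
    """Simulate the two-paralog family along the species tree.

    Per-branch order of events: substitutions, gene conversion,
    pseudogenization/loss.  Identical configs (including seed) give
    bit-identical output.
    """
    try:
        tree = dendropy.Tree.get(
            data=cfg.species_tree, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise ValueError(f"malformed newick species tree: {exc}") from exc

    n_codons = cfg.root_cds_length // 3
    guard = frozenset(cfg.guard_codons) if cfg.motif_guard else frozenset()

    root_rng = _rng(cfg.seed, "root", "-", 0)
    # uniform sense codons: redraw any stop
    root = root_rng.integers(0, 4, size=cfg.root_cds_length)
    for idx in range(n_codons):
        while _codon_str(root, idx) in _STOP_CODONS:
            root[3 * idx : 3 * idx + 3] = root_rng.integers(0, 4, size=3)

    base = _Lineage(
        seqs={
            "A": _substitute(root, cfg.paralog_stem, _rng(cfg.seed, "stem", "A", 0), True, guard),
            "C": _substitute(root, cfg.paralog_stem, _rng(cfg.seed, "stem", "C", 0), True, frozenset()),
        },
        deleted={
            "A": np.zeros(cfg.root_cds_length, dtype=bool),
            "C": np.zeros(cfg.root_cds_length, dtype=bool),
        },
        status={"A": "functional", "C": "functional"},
    )

    events: list[dict] = []
    leaf_states: dict[str, _Lineage] = {}

    def descend(node: dendropy.Node, lin: _Lineage) -> None:
        for child in node.child_nodes():
            key = _branch_key(child)
            bl = (child.edge.length or 0.0) * cfg.subst_rate_scale
            child_lin = _Lineage(
                seqs=dict(lin.seqs),
                deleted=dict(lin.deleted),
                status=dict(lin.status),
                locked=dict(lin.locked),
            )
            for gene in ("A", "C"):
                if child_lin.status[gene] == "lost":
                    continue
                gene_guard = guard if gene == "A" else frozenset()
                child_lin.seqs[gene] = _substitute(
                    child_lin.seqs[gene],
                    bl,
                    _rng(cfg.seed, key, gene, 0),
                    protect_orf=child_lin.status[gene] == "functional",
                    guard_codons=gene_guard | child_lin.locked.get(gene, frozenset()),
                )
            conv_rng = _rng(cfg.seed, key, "-", 1)
            if cfg.force_terminal_conversion_nt is not None and child.is_leaf():
                _apply_conversion(
                    child_lin, conv_rng, 1, cfg.conversion_tract_mean,
                    cfg.force_terminal_conversion_nt, key, events, n_codons,
                )
            else:
                n_events = int(conv_rng.poisson(cfg.conversion_rate))
                _apply_conversion(
                    child_lin, conv_rng, n_events, cfg.conversion_tract_mean,
                    None, key, events, n_codons,
                )
            genes = ("A", "C") if cfg.symmetric_inactivation else ("C",)
            for gene in genes:
                _apply_inactivation(
                    child_lin, gene, _rng(cfg.seed, key, gene, 2), cfg, key, events, n_codons
                )
            if child.is_leaf():
                leaf_states[child.taxon.label] = child_lin
            else:
                descend(child, child_lin)

    descend(tree.seed_node, base)

    records: list[GeneSequence] = []
    aln_labels: list[str] = []
    aln_rows: list[str] = []
    statuses: dict[tuple[str, str], str] = {}
    for species in sorted(leaf_states):
        lin = leaf_states[species]
        for gene in ("A", "C"):
            if lin.status[gene] == "lost":
                statuses[(species, gene)] = "absent"
                continue
            full = np.array([*_NT[lin.seqs[gene]]])
            deleted = lin.deleted[gene]
            cds = "".join(full[~deleted])
            statuses[(species, gene)] = lin.status[gene]
            records.append(
                GeneSequence(
                    species_id=species,
                    gene_label=gene,
                    accession="sim",
                    cds=cds,
                    status=lin.status[gene],
                )
            )
            aligned = full.copy()
            aligned[deleted] = "-"
            aln_labels.append(f"{species}|{gene}")
            aln_rows.append("".join(aligned))

    truth = pd.DataFrame(
        events, columns=["branch", "kind", "gene", "start_nt", "end_nt", "detail"]
    )
    return SimResult(
        records=records,
        truth=truth,
        alignment=Alignment(aln_labels, aln_rows, "codon"),
        statuses=statuses,
        tree=tree,
    )


# ---------------------------------------------------------------------------
# Synthetic reference fixtures
# ---------------------------------------------------------------------------

_FILLER = "GQSTAHWFMP"  # no Y/N/C and no charged residues: inert to every scanner


def _filler(n: int, phase: int = 0) -> list[str]:
    return [(_FILLER[(phase + i) % len(_FILLER)]) for i in range(n)]


def make_reference_fixture() -> tuple[ReferenceAnnotation, ReferenceAnnotation]:
    """Synthetic A-like (299 aa) and C-like (224 aa) reference annotations.

    These are constructed stand-ins, not database sequences: inert filler
    residues carry annotated sites at the canonical human positions — for
    the A-like protein the C36/C103 disulfide pair, N83/N92 sequons and four
    ITIMs (three classical, anchors Y231/Y255/Y267, plus the non-classical
    Y282); for the C-like protein the C43/C110 and C57/C65 disulfide pairs,
    N90/N99 sequons and the single transmembrane glutamate E191.
    """
    # --- A-like: signal 1-17, ecd 18-180, tm 181-201, cyto 202-299
    a = _filler(299)
    a[0] = "M"
    a[35] = "C"
    a[102] = "C"
    a[82], a[84] = "N", "T"  # N83 sequon (N-x-T)
    a[91], a[93] = "N", "S"  # N92 sequon (N-x-S)
    a[180:201] = list("LVALLGGLLVVALLVGGLLVA")  # uncharged TM
    a[228:234] = list("LQYATL")  # ITIM 1, classical, Y231
    a[252:258] = list("SVYSEL")  # ITIM 2, classical, Y255
    a[264:270] = list("ITYSQL")  # ITIM 3, classical, Y267
    a[279:285] = list("TQYSEI")  # ITIM 4, non-classical only, Y282
    ref_a = ReferenceAnnotation(
        name="CD300A-like-synthetic",
        protein="".join(a),
        domains={"signal": (1, 17), "ecd": (18, 180), "tm": (181, 201), "cyto": (202, 299)},
        sites=[
            ("cys", 36),
            ("cys", 103),
            ("sequon", 83),
            ("sequon", 92),
            ("itim1", 231),
            ("itim2", 255),
            ("itim3", 267),
            ("itim4", 282),
        ],
    )

    # --- C-like: signal 1-20, ecd 21-183, tm 184-204, cyto 205-224
    c = _filler(224, phase=3)
    c[0] = "M"
    c[42] = "C"
    c[109] = "C"
    c[56] = "C"
    c[64] = "C"
    c[89], c[91] = "N", "T"  # N90 sequon
    c[98], c[100] = "N", "S"  # N99 sequon
    c[183:204] = list("LVALLGGELLVALLVGGLLVA")  # E at 191 (offset 7 in the TM)
    ref_c = ReferenceAnnotation(
        name="CD300C-like-synthetic",
        protein="".join(c),
        domains={"signal": (1, 20), "ecd": (21, 183), "tm": (184, 204), "cyto": (205, 224)},
        sites=[
            ("cys", 43),
            ("cys", 57),
            ("cys", 65),
            ("cys", 110),
            ("sequon", 90),
            ("sequon", 99),
            ("tm_charge", 191),
        ],
    )
    return ref_a, ref_c
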