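"""End-to-end orchestration: sequences in, report bundle out.

A run produces the machine-readable analogue of a copy-number/status survey
(one row per species and gene, asterisk semantics for pseudogenes, dash for
absence), motif and site-conservation tables, gene-conversion window and
shared-motif tables, an NJ tree with bootstrap supports, synteny states,
and a manifest recording the resolved configuration and seed.  Re-running
with an identical config and seed produces byte-identical outputs.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .align import Alignment, progressive_msa
from .geneconv import paired_species, permutation_test, shared_motifs, window_statistic
from .motif import conservation_report, scan_cysteines, scan_itims, scan_sequons, scan_tm_charge
from .phylo import bootstrap, paralog_sister_fraction
from .pseudogene import PseudogeneCall, classify
from .seqio import (
    GeneSequence,
    ReferenceAnnotation,
    by_species_gene,
    read_annotation_table,
    read_fasta,
)
from .simulate import SimConfig, make_reference_fixture, simulate_family
from .synteny import DEFAULT_ANCHORS, classify_locus

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "summarize_table",
    "load_copy_number_table",
    "copy_number_totals",
    "scaled_reference",
]


def load_copy_number_table() -> pd.DataFrame:
    """The packaged primate copy-number/status survey (in-paper data).

    Columns: family, species, CD300A, CD300C; cell values are ``1`` (one
    functional copy), ``1*`` (one copy with pseudogenization marks) or ``-``
    (no identifiable copy).
    """
    path = resources.files("cd300evo.data").joinpath("table1.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


def copy_number_totals(table: pd.DataFrame) -> dict[str, int]:
    """Species and gene-copy totals of a copy-number table."""
    gene_cols = [c for c in table.columns if c not in ("family", "species")]
    copies = 0
    pseudo = 0
    absent = 0
    for col in gene_cols:
        cells = table[col].astype(str)
        copies += int((cells != "-").sum())
        pseudo += int(cells.str.contains(r"\*", regex=True).sum())
        absent += int((cells == "-").sum())
    return {
        "n_species": int(table["species"].nunique()),
        "n_copies": copies,
        "n_pseudogene": pseudo,
        "n_absent": absent,
    }


def summarize_table(
    calls: list[PseudogeneCall], roster: dict[str, str] | None = None
) -> pd.DataFrame:
    """Species x gene summary with copy counts and statuses.

    ``roster`` maps species to family; species present in the roster but
    with no call for a gene get an explicit ``absent`` row.  One row per
    (species, gene); duplicate calls are an error.  The ``cell`` column uses
    the survey rendering: ``1`` functional/truncated, ``1*`` pseudogene,
    ``-`` absent.
    """
    seen = set()
    for call in calls:
        key = (call.species_id, call.gene_label)
        if key in seen:
            raise ValueError(f"duplicate call for {key}")
        seen.add(key)
    by_key = {(c.species_id, c.gene_label): c for c in calls}
    species = sorted({c.species_id for c in calls} | set(roster or {}))
    genes = sorted({c.gene_label for c in calls}) or ["A", "C"]
    rows = []
    for sp in species:
        for gene in genes:
            call = by_key.get((sp, gene))
            verdict = call.verdict if call else "absent"
            copy_count = 0 if verdict == "absent" else 1
            cell = "-" if verdict == "absent" else ("1*" if verdict == "pseudogene" else "1")
            rows.append(
                {
                    "family": (roster or {}).get(sp, ""),
                    "species": sp,
                    "gene": gene,
                    "copy_count": copy_count,
                    "status": verdict,
                    "cell": cell,
                }
            )
    return pd.DataFrame(rows, columns=["family", "species", "gene", "copy_count", "status", "cell"])


def scaled_reference(protein: str, name: str = "reference") -> ReferenceAnnotation:
    """Map the canonical inhibitory-receptor domain layout onto a protein.

    Domain boundaries of the 299-aa A-like layout (signal 1-17, ECD 18-180,
    TM 181-201, cytoplasmic 202-299) are scaled proportionally to the
    protein's length.  Used when no curated annotation is supplied, e.g. for
    simulated references.
    """
    fixture, _ = make_reference_fixture()
    n_fix = len(fixture.protein)
    n = len(protein)
    domains = {}
    prev_end = 0
    for dom, (start, end) in fixture.domains.items():
        s = prev_end + 1
        e = max(s, round(end * n / n_fix))
        if dom == "cyto":
            e = n
        domains[dom] = (s, min(e, n))
        prev_end = domains[dom][1]
    return ReferenceAnnotation(name=name, protein=protein, domains=domains)


@dataclass
class PipelineConfig:
    """Resolved run configuration; every stage is individually toggleable."""

    # input: either a FASTA path or a simulation
    fasta: str | None = None
    simulate: bool = False
    sim: SimConfig | None = None
    roster: dict[str, str] = field(default_factory=dict)  # species -> family
    reference_species: str = "Homo_sapiens"
    outdir: str = "cd300evo_out"
    seed: int = 1234
    delimiter: str = "|"
    # stage toggles
    do_classify: bool = True
    do_motif: bool = True
    do_geneconv: bool = True
    do_tree: bool = True
    # stage parameters
    window: int = 30
    step: int = 5
    n_perm: int = 999
    region: tuple[int, int] | None = None
    boot_reps: int = 100
    tree_model: str = "poisson"
    # synteny: species -> annotation TSV path
    annotation_tables: dict[str, str] = field(default_factory=dict)
    anchors: tuple[str, str] = DEFAULT_ANCHORS
    family_genes: tuple[str, ...] = ("CD300A", "CD300C")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> dict[str, object]:
    """Run all enabled stages; artifacts land in ``cfg.outdir``.

    On stage failure the output directory is removed (no partial bundles)
    and a :class:`PipelineError` naming the stage is raised.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, object] = {}
    stage = "input"
    try:
        records, true_aln, statuses = _load_input(cfg)
        artifacts["n_records"] = len(records)
        idx = by_species_gene(records)
        genes = sorted({r.gene_label for r in records})
        all_species = sorted({r.species_id for r in records} | set(cfg.roster))

        refs: dict[str, GeneSequence] = {}
        annots: dict[str, ReferenceAnnotation] = {}
        for gene in genes:
            ref = idx.get((cfg.reference_species, gene))
            if ref is None or ref.status != "functional":
                candidates = [r for r in records if r.gene_label == gene and r.status == "functional"]
                if not candidates:
                    continue
                ref = candidates[0]
            refs[gene] = ref
            annots[gene] = scaled_reference(ref.protein, name=f"{ref.species_id}|{gene}")

        if cfg.do_classify:
            stage = "classify"
            calls = []
            for sp in all_species:
                for gene in genes:
                    rec = idx.get((sp, gene))
                    if rec is None or rec.status == "absent":
                        calls.append(PseudogeneCall(sp, gene, "absent"))
                        continue
                    ref = refs.get(gene)
                    if ref is None:
                        raise PipelineError(stage, f"no functional reference for gene {gene}")
                    calls.append(classify(rec, annots[gene], ref_cds=ref.cds))
            table = summarize_table(calls, cfg.roster)
            _write_tsv(table, outdir / "species_gene_table.tsv")
            artifacts["species_gene_table"] = table
            artifacts["calls"] = calls

        stage = "alignment"
        msa = true_aln if true_aln is not None else _build_msa(records, cfg.delimiter)

        if cfg.do_motif:
            stage = "motif"
            motif_rows, conservation = _motif_stage(records, refs, annots, msa, cfg.delimiter)
            _write_tsv(motif_rows, outdir / "motif_hits.tsv")
            for gene, report in conservation.items():
                _write_tsv(report, outdir / f"conservation_{gene}.tsv")
            artifacts["motif_hits"] = motif_rows
            artifacts["conservation"] = conservation

        if cfg.do_geneconv:
            stage = "geneconv"
            windows = []
            for sp in paired_species(msa, cfg.delimiter):
                ws = window_statistic(
                    msa, sp, win=cfg.window, step=cfg.step, region=cfg.region,
                    delimiter=cfg.delimiter,
                )
                windows.extend(
                    permutation_test(
                        ws, msa, n_perm=cfg.n_perm, seed=cfg.seed, region=cfg.region,
                        delimiter=cfg.delimiter,
                    )
                )
            wdf = pd.DataFrame(
                [
                    {
                        "species": w.species_id,
                        "start": w.ref_span[0],
                        "end": w.ref_span[1],
                        "ident_within": w.ident_within,
                        "ident_between": w.ident_between,
                        "delta": w.delta,
                        "p_perm": w.p_perm,
                    }
                    for w in windows
                ]
            )
            _write_tsv(wdf, outdir / "conversion_windows.tsv")
            motifs = shared_motifs(msa, cfg.roster, delimiter=cfg.delimiter)
            mdf = pd.DataFrame(
                [
                    {
                        "lineage": m.lineage,
                        "start": m.ref_span[0],
                        "end": m.ref_span[1],
                        "residues": m.residues,
                        "background_freq": m.background_freq,
                    }
                    for m in motifs
                ]
            )
            _write_tsv(mdf, outdir / "shared_motifs.tsv")
            artifacts["conversion_windows"] = wdf
            artifacts["shared_motifs"] = mdf

        if cfg.do_tree:
            stage = "tree"
            # protein rows with stops masked keep pseudogenes placeable
            labels = [l for l in msa.labels]
            rows = [r.replace("*", "X") for r in msa.rows]
            tree_msa = Alignment(labels, rows, "protein")
            tree = bootstrap(tree_msa, n_reps=cfg.boot_reps, seed=cfg.seed, model=cfg.tree_model)
            newick = tree.as_string(schema="newick", suppress_rooting=True)
            (outdir / "tree.nwk").write_text(newick)
            artifacts["tree"] = tree
            try:
                artifacts["paralog_sister_fraction"] = paralog_sister_fraction(
                    tree, cfg.delimiter
                )
            except ValueError:
                artifacts["paralog_sister_fraction"] = float("nan")

        if cfg.annotation_tables:
            stage = "synteny"
            rows = []
            for sp, path in sorted(cfg.annotation_tables.items()):
                state = classify_locus(
                    read_annotation_table(path),
                    set(cfg.family_genes),
                    cfg.anchors,
                    species_id=sp,
                )
                for gene, st in sorted(state.gene_states.items()):
                    rows.append(
                        {
                            "species": sp,
                            "gene": gene,
                            "state": st,
                            "locus_intact": state.locus_intact,
                        }
                    )
            sdf = pd.DataFrame(rows, columns=["species", "gene", "state", "locus_intact"])
            _write_tsv(sdf, outdir / "synteny_states.tsv")
            artifacts["synteny_states"] = sdf

        stage = "manifest"
        manifest = {
            "package": "cd300evo",
            "version": __version__,
            "seed": cfg.seed,
            "config": _config_dict(cfg),
        }
        (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
        artifacts["manifest"] = manifest
    except PipelineError:
        shutil.rmtree(outdir, ignore_errors=True)
        raise
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise PipelineError(stage, str(exc)) from exc
    return artifacts


def _config_dict(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    if d.get("sim") is not None:
        d["sim"] = asdict(cfg.sim)
    d["anchors"] = list(d["anchors"])
    d["family_genes"] = list(d["family_genes"])
    if d.get("region") is not None:
        d["region"] = list(d["region"])
    return d


def _load_input(cfg: PipelineConfig):
    if cfg.simulate:
        sim_cfg = cfg.sim if cfg.sim is not None else SimConfig(seed=cfg.seed)
        res = simulate_family(sim_cfg)
        return res.records, res.protein_alignment(), res.statuses
    if cfg.fasta is None:
        raise ValueError("either fasta or simulate must be given")
    records = read_fasta(cfg.fasta, cfg.delimiter)
    return records, None, None


def _build_msa(records: list[GeneSequence], delimiter: str) -> Alignment:
    labels = [f"{r.species_id}{delimiter}{r.gene_label}" for r in records]
    proteins = [r.protein.replace("*", "X") for r in records]
    if len(records) < 2:
        raise ValueError("need at least 2 sequences to align")
    return progressive_msa(proteins, labels)


def _motif_stage(records, refs, annots, msa, delimiter):
    motif_rows = []
    for rec in records:
        if not rec.protein:
            continue
        annot = scaled_reference(rec.protein)
        scans = (
            scan_itims(rec.protein, annot.domains["cyto"])
            + scan_tm_charge(rec.protein, annot.domains["tm"])
            + scan_sequons(rec.protein, annot.domains["ecd"])
            + scan_cysteines(rec.protein, annot.domains["ecd"])
        )
        for h in scans:
            motif_rows.append(
                {
                    "species": rec.species_id,
                    "gene": rec.gene_label,
                    "motif_class": h.motif_class,
                    "pos": h.query_pos,
                    "matched": h.matched,
                }
            )
    motif_df = pd.DataFrame(
        motif_rows, columns=["species", "gene", "motif_class", "pos", "matched"]
    )

    conservation = {}
    for gene, ref in refs.items():
        ref_label = f"{ref.species_id}{delimiter}{ref.gene_label}"
        if ref_label not in msa.labels:
            continue
        gene_labels = [
            l for l in msa.labels if l.split(delimiter)[1] == gene or l == ref_label
        ]
        sub = Alignment(
            gene_labels, [msa.row(l) for l in gene_labels], "protein"
        ).drop_gap_only_columns()
        annot = annots[gene]
        # annotate scanner-discovered sites on the reference itself
        sites = (
            [("sequon", h.query_pos) for h in scan_sequons(ref.protein, annot.domains["ecd"])]
            + [("cys", h.query_pos) for h in scan_cysteines(ref.protein, annot.domains["ecd"])]
            + [
                (f"itim{i + 1}", h.query_pos)
                for i, h in enumerate(scan_itims(ref.protein, annot.domains["cyto"]))
            ]
            + [("tm_charge", h.query_pos) for h in scan_tm_charge(ref.protein, annot.domains["tm"])]
        )
        full = ReferenceAnnotation(annot.name, annot.protein, dict(annot.domains), sites)
        ref_row_clean = sub.row(ref_label).replace("*", "X")
        if ref_row_clean.replace("-", "") != full.protein:
            continue
        conservation[gene] = conservation_report(sub, ref_label, full)
    return motif_df, conservation
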