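import pytest

from cd300evo.align import Alignment, dna_scoring, nw_align
from cd300evo.pipeline import scaled_reference
from cd300evo.pseudogene import (
    PseudogeneCall,
    classify,
    detect_frameshifts,
    detect_missing_domains,
    detect_premature_stops,
)
from cd300evo.seqio import GeneSequence, by_species_gene


class TestPrematureStops:
    def test_early_stop_flagged(self):
        protein = "MA*" + "K" * 297
        (les,) = detect_premature_stops(protein, ref_len=300)
        assert (les.kind, les.start) == ("premature_stop", 3)

    def test_terminal_stop_never_flagged(self):
        assert detect_premature_stops("MKLV*", ref_len=5) == []

    def test_stop_after_cutoff_not_premature(self):
        # cutoff is ceil(0.9 * 300) = 270; a stop at 280 is near-terminal
        protein = "M" + "K" * 278 + "*" + "L" * 20
        assert detect_premature_stops(protein, ref_len=300) == []
        protein_early = "M" + "K" * 260 + "*" + "L" * 38
        assert len(detect_premature_stops(protein_early, ref_len=300)) == 1

    def test_simulated_lesion_position_matches_truth(self, lesioned_sim):
        truth = lesioned_sim.truth
        stops = truth[truth.kind == "stop_lesion"]
        idx = by_species_gene(lesioned_sim.records)
        checked = 0
        for _, ev in stops.iterrows():
            for sp in ev.branch.split("+"):
                rec = idx.get((sp, ev.gene))
                if rec is None:
                    continue  # lost downstream
                codon = int(ev.detail.split(":")[1])
                lesions = detect_premature_stops(rec.protein, ref_len=299)
                if not rec.cds[3 * codon - 3 : 3 * codon] in ("TAA", "TAG", "TGA"):
                    continue  # overwritten by a later event on a deeper branch
                assert codon in [l.start for l in lesions]
                checked += 1
        assert checked > 0


def _codon_aln(ref_row: str, query_row: str) -> Alignment:
    return Alignment(["ref", "query"], [ref_row, query_row], "codon")


class TestFrameshifts:
    def test_single_nt_deletion(self):
        aln = _codon_aln("ATGAAACCC", "ATGA-ACCC")
        (les,) = detect_frameshifts(aln)
        assert les.kind == "frameshift"
        assert les.start == 2  # deletion starts in reference codon 2

    def test_in_frame_deletion_ignored(self):
        aln = _codon_aln("ATGAAACCC", "ATG---CCC")
        assert detect_frameshifts(aln) == []

    def test_two_separated_indels_give_two_lesions(self):
        # 1-nt deletion, an intact codon, then a 2-nt deletion
        aln = _codon_aln("ATGAAACCCGGG", "AT-AAAC--GGG")
        lesions = detect_frameshifts(aln)
        assert len(lesions) == 2
        assert [l.kind for l in lesions] == ["frameshift", "frameshift"]

    def test_insertion_run_detected(self):
        aln = _codon_aln("ATG--AAA", "ATGCCAAA")
        (les,) = detect_frameshifts(aln)
        assert "insertion" in les.detail

    def test_non_codon_alignment_rejected(self):
        with pytest.raises(ValueError, match="codon"):
            detect_frameshifts(Alignment(["r", "q"], ["MK", "MK"], "protein"))

    def test_recovered_from_real_pairwise_alignment(self):
        from cd300evo.simulate import SimConfig, simulate_family

        sim = simulate_family(
            SimConfig(seed=29, conversion_rate=0.0, pseudogen_prob=0.15, loss_prob=0.0)
        )
        idx = by_species_gene(sim.records)
        truth = sim.truth
        fs = truth[truth.kind == "frameshift_lesion"]
        assert len(fs) > 0
        ref = next(
            r for r in sim.records if r.gene_label == "C" and r.status == "functional"
        )
        found_any = False
        for _, ev in fs.iterrows():
            for sp in ev.branch.split("+"):
                rec = idx.get((sp, "C"))
                if rec is None or rec.species_id == ref.species_id:
                    continue
                aln = nw_align(ref.cds, rec.ungapped, dna_scoring(), kind="codon")
                if any(l.kind == "frameshift" for l in detect_frameshifts(aln)):
                    found_any = True
        assert found_any


class TestMissingDomains:
    def test_truncated_receptor_lacks_tm_and_cyto(self, ref_pair):
        _, ref_c = ref_pair
        # query = signal + ECD only, like the short activating-receptor case
        query = ref_c.protein[:183]
        seq = GeneSequence("Papio_like", "C", cds=_reverse_translate(query))
        call = classify(seq, ref_c)
        assert call.verdict == "truncated"
        assert {l.detail for l in call.lesions} == {"tm", "cyto"}

    def test_full_length_query_has_no_lesions(self, ref_pair):
        ref_a, _ = ref_pair
        from cd300evo.align import map_to_reference

        aln = nw_align(ref_a.protein, ref_a.protein, labels=("ref", "query"))
        qmap = map_to_reference(aln, "ref")["query"]
        assert detect_missing_domains(qmap, ref_a) == []

    def test_half_gapped_domain_below_threshold(self, ref_pair):
        ref_a, _ = ref_pair
        tm_start, tm_end = ref_a.domains["tm"]
        n_tm = tm_end - tm_start + 1
        mapping = {p: p for p in range(1, len(ref_a.protein) + 1)}
        # gap exactly half of the TM: under the 80% rule this is not missing
        for p in range(tm_start, tm_start + n_tm // 2):
            mapping[p] = None
        from cd300evo.align import CoordinateMap

        qmap = CoordinateMap("ref", "q", mapping)
        assert detect_missing_domains(qmap, ref_a) == []


def _reverse_translate(protein: str) -> str:
    table = {
        "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
        "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
        "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
        "W": "TGG", "Y": "TAT",
    }
    return "".join(table[ch] for ch in protein)


class TestClassify:
    def test_intact_simulated_gene_is_functional(self, quiet_sim):
        idx = by_species_gene(quiet_sim.records)
        ref = idx[("Homo_sapiens", "A")]
        annot = scaled_reference(ref.protein)
        call = classify(idx[("Macaca_mulatta", "A")], annot, ref_cds=ref.cds)
        assert call.verdict == "functional"
        assert call.lesions == []

    def test_mid_gene_stop_called_pseudogene(self, quiet_sim):
        idx = by_species_gene(quiet_sim.records)
        ref = idx[("Homo_sapiens", "A")]
        rec = idx[("Macaca_mulatta", "A")]
        broken = rec.cds[:300] + "TAA" + rec.cds[303:]
        seq = GeneSequence(rec.species_id, "A", cds=broken, status="pseudogene")
        call = classify(seq, scaled_reference(ref.protein), ref_cds=ref.cds)
        assert call.verdict == "pseudogene"
        assert any(l.kind == "premature_stop" and l.start == 101 for l in call.lesions)

    def test_in_frame_codon_deletion_stays_functional(self, quiet_sim):
        idx = by_species_gene(quiet_sim.records)
        ref = idx[("Homo_sapiens", "A")]
        rec = idx[("Macaca_mulatta", "A")]
        deleted = rec.cds[:300] + rec.cds[303:]  # clean three-nucleotide deletion
        seq = GeneSequence(rec.species_id, "A", cds=deleted)
        call = classify(seq, scaled_reference(ref.protein), ref_cds=ref.cds)
        assert call.verdict == "functional"

    def test_missing_record_is_absent(self, ref_pair):
        ref_a, _ = ref_pair
        call = classify(None, ref_a, species_id="Hylobates_moloch", gene_label="C")
        assert call.verdict == "absent"

    def test_verdict_invariants_enforced(self):
        with pytest.raises(ValueError):
            PseudogeneCall("s", "A", "pseudogene", [])

    def test_deterministic_across_repeats(self, quiet_sim):
        idx = by_species_gene(quiet_sim.records)
        ref = idx[("Homo_sapiens", "C")]
        annot = scaled_reference(ref.protein)
        rec = idx[("Lemur_catta", "C")]
        first = classify(rec, annot, ref_cds=ref.cds)
        second = classify(rec, annot, ref_cds=ref.cds)
        assert first == second
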