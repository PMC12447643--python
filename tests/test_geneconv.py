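import numpy as np
import pytest

from cd300evo.align import Alignment
from cd300evo.geneconv import (
    paired_species,
    permutation_test,
    shared_motifs,
    window_statistic,
)


def _toy_alignment():
    """3 species; s1's paralogs identical, orthologs 50% diverged in-window."""
    rows = {
        "s1|A": "AAAAAAAAAA",
        "s1|C": "AAAAAAAAAA",
        "s2|A": "ACACACACAC",
        "s2|C": "GAGAGAGAGA",
        "s3|A": "ACACACACAC",
        "s3|C": "GAGAGAGAGA",
    }
    return Alignment(list(rows), list(rows.values()), "protein")


class TestWindowStatistic:
    def test_identical_paralogs_against_diverged_orthologs(self):
        msa = _toy_alignment()
        (w,) = window_statistic(msa, "s1", win=10, step=10)
        assert w.ident_within == 1.0
        # orthologs match s1's all-A rows at half their columns
        assert w.ident_between == pytest.approx(0.5)
        assert w.delta == pytest.approx(0.5)

    def test_all_identical_gives_zero_delta(self):
        rows = {f"s{i}|{g}": "AAAAAAAAAA" for i in range(1, 4) for g in "AC"}
        msa = Alignment(list(rows), list(rows.values()), "protein")
        for w in window_statistic(msa, "s1", win=5, step=5):
            assert w.delta == 0.0

    def test_missing_paralog_errors_with_species_name(self):
        rows = {"s1|A": "AAAA", "s2|A": "AAAA", "s2|C": "AAAA", "s3|A": "AAAA", "s3|C": "AAAA"}
        msa = Alignment(list(rows), list(rows.values()), "protein")
        with pytest.raises(ValueError, match="s1"):
            window_statistic(msa, "s1", win=5, step=5)

    def test_gapped_columns_excluded_from_denominator(self):
        rows = {
            "s1|A": "AA--AAAAAA",
            "s1|C": "AAAAAAAAAA",
            "s2|A": "AAAAAAAAAA",
            "s2|C": "AAAAAAAAAA",
            "s3|A": "AAAAAAAAAA",
            "s3|C": "AAAAAAAAAA",
        }
        msa = Alignment(list(rows), list(rows.values()), "protein")
        (w,) = window_statistic(msa, "s1", win=10, step=10)
        assert w.n_usable == 8
        assert w.ident_within == 1.0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            window_statistic(_toy_alignment(), "s1", win=4)


class TestPermutationTest:
    def test_determinism_bitwise(self, quiet_sim):
        msa = quiet_sim.protein_alignment()
        sp = paired_species(msa)[0]
        ws = window_statistic(msa, sp)
        a = permutation_test(ws, msa, n_perm=99, seed=7)
        b = permutation_test(ws, msa, n_perm=99, seed=7)
        assert [w.p_perm for w in a] == [w.p_perm for w in b]

    def test_pvalues_in_valid_range(self, quiet_sim):
        msa = quiet_sim.protein_alignment()
        sp = paired_species(msa)[0]
        ws = permutation_test(window_statistic(msa, sp), msa, n_perm=99, seed=3)
        for w in ws:
            assert 0.0 < w.p_perm <= 1.0

    def test_too_few_permutations_rejected(self, quiet_sim):
        msa = quiet_sim.protein_alignment()
        sp = paired_species(msa)[0]
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(window_statistic(msa, sp), msa, n_perm=50)

    def test_programmed_tract_found_by_max_delta_window(self):
        from cd300evo.simulate import SimConfig, simulate_family

        res = simulate_family(
            SimConfig(
                seed=77,
                conversion_rate=0.0,
                pseudogen_prob=0.0,
                loss_prob=0.0,
                force_terminal_conversion_nt=90,
            )
        )
        msa = res.protein_alignment()
        conv = res.truth[res.truth.kind == "conversion"]
        overlaps = 0
        species = [sp for sp in paired_species(msa) if (conv.branch == sp).any()]
        for sp in species:
            row = conv[conv.branch == sp].iloc[0]
            s_aa, e_aa = (row.start_nt + 2) // 3, row.end_nt // 3
            ws = window_statistic(msa, sp)
            best = max(ws, key=lambda w: w.delta)
            if best.ref_span[0] <= e_aa and best.ref_span[1] >= s_aa:
                overlaps += 1
        assert overlaps >= 0.8 * len(species)


class TestSharedMotifs:
    def _alignment(self):
        # Cebidae species share 'D' at column 3 in both paralogs; the other
        # family carries 'E' there; column 1 is universally shared.
        rows = {
            "Callithrix|A": "GADAG",
            "Callithrix|C": "GTDSG",
            "Aotus|A": "GADAG",
            "Aotus|C": "GTDSG",
            "Homo|A": "GAEAG",
            "Homo|C": "GTESG",
            "Pan|A": "GAEAG",
            "Pan|C": "GTESG",
        }
        return Alignment(list(rows), list(rows.values()), "protein")

    def _grouping(self):
        return {"Callithrix": "Cebidae", "Aotus": "Cebidae", "Homo": "Hominidae", "Pan": "Hominidae"}

    def test_family_exclusive_single_residue(self):
        motifs = shared_motifs(self._alignment(), self._grouping(), min_len=1, exclusivity=0.10)
        ceb = [m for m in motifs if m.lineage == "Cebidae"]
        assert any(m.residues == "D" and m.ref_span == (3, 3) for m in ceb)

    def test_universal_column_fails_exclusivity(self):
        motifs = shared_motifs(self._alignment(), self._grouping())
        for m in motifs:
            assert not (m.ref_span == (1, 1) and m.residues == "G")

    def test_row_order_invariance(self):
        aln = self._alignment()
        perm = Alignment(list(reversed(aln.labels)), list(reversed(aln.rows)), "protein")
        a = shared_motifs(aln, self._grouping())
        b = shared_motifs(perm, self._grouping())
        key = lambda m: (m.lineage, m.ref_span, m.residues)
        assert sorted(map(key, a)) == sorted(map(key, b))

    def test_shared_in_frame_deletion_counts_as_state(self):
        rows = {
            "Macaca|A": "GA-AG",
            "Macaca|C": "GA-AG",
            "Homo|A": "GATAG",
            "Homo|C": "GACAG",
            "Pan|A": "GATAG",
            "Pan|C": "GACAG",
        }
        aln = Alignment(list(rows), list(rows.values()), "protein")
        motifs = shared_motifs(aln, {}, min_len=1, exclusivity=0.10)
        mac = [m for m in motifs if m.lineage == "Macaca"]
        assert any("-" in m.residues for m in mac)
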