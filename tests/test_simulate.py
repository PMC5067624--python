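import itertools
import math

import numpy as np
import pytest

from rhbulkseq import (
    mendelian_shrivelled_probability,
    simulate_bulk_reads,
    simulate_ct,
    simulate_genome,
    simulate_pyro,
    simulate_rh_panel,
    simulate_testcross,
)
from rhbulkseq._kmers import revcomp
from rhbulkseq.landing import translate_cds
from rhbulkseq.simulate import RHLine, _retained_segments


class TestGenome:
    def test_deterministic_for_fixed_seed(self):
        a = simulate_genome(scaffold_len=30_000, n_genes=2, seed=3)
        b = simulate_genome(scaffold_len=30_000, n_genes=2, seed=3)
        assert [s.sequence for s in a.scaffolds] == [s.sequence for s in b.scaffolds]
        assert a.genes == b.genes

    def test_site_density_near_requested_spacing(self, small_ref):
        spacing = 2000
        seq = small_ref.scaffolds[0].sequence
        count = seq.count("CTGCAG")
        expected = len(seq) / spacing
        assert abs(count - expected) <= 0.1 * expected

    def test_causal_gene_two_start_proteins(self, small_ref):
        gene = small_ref.causal_gene
        assert len(gene.exons) == 5  # five exons, four introns
        cds = gene.spliced_cds(small_ref.scaffold(gene.scaffold).sequence)
        s0, s1 = gene.start_offsets
        p_long = translate_cds(cds[s0:])
        p_short = translate_cds(cds[s1:])
        assert (len(p_long), len(p_short)) == (326, 274)
        assert len(p_long) - len(p_short) == (s1 - s0) // 3

    def test_diagnostic_variant_is_single_residue_r_to_k(self, small_ref):
        gene = small_ref.causal_gene
        cds = gene.spliced_cds(small_ref.scaffold(gene.scaffold).sequence)
        off = gene.variant_cds_offset
        assert cds[off] == gene.functional_base == "G"
        mutated = cds[:off] + gene.nonfunctional_base + cds[off + 1 :]
        p_fun, p_non = translate_cds(cds), translate_cds(mutated)
        diffs = [
            (i, a, b) for i, (a, b) in enumerate(zip(p_fun, p_non), 1) if a != b
        ]
        assert diffs == [(173, "R", "K")]

    def test_gene_density_impossible_errors(self):
        with pytest.raises(ValueError, match="density"):
            simulate_genome(scaffold_len=10_000, n_genes=5, seed=0)


class TestRHPanel:
    def test_no_radiation_no_deletions(self, small_ref):
        lines = simulate_rh_panel(small_ref, n_lines=10, breaks_per_Mb=0, seed=1)
        assert all(not l.deletions for l in lines)
        assert all(l.retains_causal for l in lines)

    def test_full_retention_no_deletions(self, small_ref):
        lines = simulate_rh_panel(
            small_ref, n_lines=10, breaks_per_Mb=50, retention_prob=1.0, seed=1
        )
        assert all(not l.deletions for l in lines)

    def test_deletion_rate_matches_poisson_retention_model(self):
        # analytic P(a fixed window is hit by a deletion): segments
        # overlapping a w-window number B+1 (B ~ Binomial(N, w/L) given N
        # scaffold breaks), each lost with prob 1-r, and a break-free
        # scaffold (prob e^-lambda*L) is never deleted. Marginalizing N:
        #   P(hit) = 1 - r*exp(-lambda*w*(1-r)) - exp(-lambda*L)*(1-r)
        ref = simulate_genome(scaffold_len=100_000, n_genes=2, seed=5)
        rate, r, n = 20.0, 0.75, 2000
        L, w = 100_000, 10_000
        lam = rate / 1e6
        p_expected = 1 - r * math.exp(-lam * w * (1 - r)) - math.exp(-lam * L) * (1 - r)
        lines = simulate_rh_panel(ref, n_lines=n, breaks_per_Mb=rate, retention_prob=r, seed=2)
        window = ("scaffold0", 40_000, 50_000)
        hit = sum(not l.retains_interval(*window) for l in lines)
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(hit / n - p_expected) <= 3 * se


class TestTestcross:
    @staticmethod
    def _enumerate_shrivelled(deleted):
        # independent oracle: enumerate gametes explicitly
        tester = [("scs",), ()]
        donor = [(), ()] if deleted else [("scs",), ()]
        seeds = [t + d for t, d in itertools.product(tester, donor)]
        return sum(1 for s in seeds if len(s) == 0) / len(seeds)

    @pytest.mark.parametrize("deleted,expected", [(True, 0.5), (False, 0.25)])
    def test_mendelian_enumeration(self, deleted, expected):
        assert self._enumerate_shrivelled(deleted) == expected
        assert mendelian_shrivelled_probability(deleted) == expected

    @pytest.mark.parametrize("deleted", [True, False])
    def test_binomial_simulation_matches_enumeration(self, deleted):
        p = self._enumerate_shrivelled(deleted)
        line = RHLine("L", {"scaffold0": [(0, 10)]} if deleted else {}, not deleted)
        n = 100_000
        t = simulate_testcross(line, n_seeds=n, seed=4)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(t.shrivelled / n - p) <= 3 * se
        assert t.plump + t.shrivelled == n

    def test_zero_seeds(self, small_panel):
        t = simulate_testcross(small_panel[0], n_seeds=0, seed=0)
        assert (t.plump, t.shrivelled) == (0, 0)


class TestBulkReads:

    def test_reads_are_substrings_of_retained_genome(self, small_ref, small_panel, clean_bulk):
        lines = {l.line_id: l for l in small_panel}
        scaffold = {s.id: s for s in small_ref.scaffolds}
        retained = {
            lid: [
                scaffold[s.id].sequence[a:b]
                for s in small_ref.scaffolds
                for a, b in _retained_segments(lines[lid], s)
            ]
            for lid in clean_bulk.pos_line_ids + clean_bulk.neg_line_ids
        }
        for pair in clean_bulk.pairs_pos + clean_bulk.pairs_neg:
            lid = pair.id.split(":")[0]
            segs = retained[lid]
            assert any(pair.mate1 in seg for seg in segs)
            assert any(revcomp(pair.mate2) in seg for seg in segs)

    def test_no_neg_reads_from_deleted_fragments(self, small_panel, clean_bulk):
        lines = {l.line_id: l for l in small_panel}
        for pair in clean_bulk.pairs_neg:
            lid, scf, span = pair.id.split(":")[:3]
            start, end = map(int, span.split("-"))
            assert lines[lid].retains_interval(scf, start, end)

    def test_realized_depth_within_ten_percent(self, small_ref, small_panel):
        depth = 5.0
        bulk = simulate_bulk_reads(
            small_ref, small_panel, depth=depth, error_rate=0.0, contam_frac=0.0, seed=6
        )
        # group emitted pairs per (line, fragment); compare realized coverage
        per_frag: dict[tuple, int] = {}
        frag_len: dict[tuple, int] = {}
        for pair in bulk.pairs_pos + bulk.pairs_neg:
            lid, scf, span = pair.id.split(":")[:3]
            start, end = map(int, span.split("-"))
            key = (lid, scf, start, end)
            per_frag[key] = per_frag.get(key, 0) + 1
            frag_len[key] = end - start
        read_len = len(bulk.pairs_pos[0].mate1)
        realized = [
            n * min(2 * read_len, frag_len[k]) / frag_len[k]
            for k, n in per_frag.items()
        ]
        assert abs(np.mean(realized) - depth) <= 0.1 * depth

    def test_contaminant_fraction(self, small_ref, small_panel):
        bulk = simulate_bulk_reads(
            small_ref, small_panel, error_rate=0.0, contam_frac=0.05, seed=6
        )
        total = len(bulk.pairs_pos) + len(bulk.pairs_neg)
        assert abs(bulk.n_contaminant / total - 0.05) < 0.01
        assert bulk.contaminant is not None

    def test_deterministic(self, small_ref, small_panel):
        a = simulate_bulk_reads(small_ref, small_panel, seed=6)
        b = simulate_bulk_reads(small_ref, small_panel, seed=6)
        assert [p.mate1 for p in a.pairs_pos] == [p.mate1 for p in b.pairs_pos]


class TestPyro:
    def test_pure_g_no_noise(self):
        s = simulate_pyro(1.0, total_signal=80.0, noise_sd=0.0)
        assert s.peak_a == 0.0 and s.peak_g == 80.0

    def test_half_and_half(self):
        s = simulate_pyro(0.5, noise_sd=0.0)
        assert s.peak_g == s.peak_a

    def test_noisy_mean_recovers_signal(self):
        g_frac, total, sd, n = 0.3, 100.0, 5.0, 1000
        peaks = [
            simulate_pyro(g_frac, total, noise_sd=sd, seed=i).peak_g for i in range(n)
        ]
        se = sd / math.sqrt(n)
        assert abs(np.mean(peaks) - g_frac * total) <= 3 * se


class TestCt:
    def test_twofold_lowers_ct_by_one_cycle(self):
        table = simulate_ct({"cal": 1.0, "x": 2.0}, "cal", seed=0)
        df = table.data
        cal_ct = df.loc[df["sample"] == "cal", "ct_target"].iloc[0]
        x_ct = df.loc[df["sample"] == "x", "ct_target"].iloc[0]
        assert cal_ct - x_ct == pytest.approx(1.0)

    def test_zero_noise_replicates_identical(self):
        table = simulate_ct({"cal": 1.0, "x": 0.5}, "cal", n_replicates=3, noise_sd=0.0)
        assert (table.data.groupby("sample")["ct_target"].std() == 0).all()

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            simulate_ct({"cal": 1.0, "x": 0.0}, "cal")
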