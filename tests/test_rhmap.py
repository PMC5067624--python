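import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom

from rhbulkseq import (
    PhysicalAnchorSet,
    RetentionMatrix,
    anchor_and_resolution,
    classify_deletion_typing,
    cosegregation_scan,
    order_markers,
    simulate_genome,
    simulate_rh_panel,
    theta_to_cR,
    two_point_distance,
)
from rhbulkseq.rhmap import RHMapResult, build_retention_matrix
from rhbulkseq.simulate import Marker


class TestDeletionTyping:
    @staticmethod
    def _oracle_call(plump, shrivelled, odds=10.0):
        # independent oracle: explicit binomial pmf ratio
        n = plump + shrivelled
        l_del = math.comb(n, shrivelled) * 0.5**shrivelled * 0.5**plump
        l_ret = math.comb(n, shrivelled) * 0.25**shrivelled * 0.75**plump
        if l_del >= odds * l_ret:
            return "deleted"
        if l_ret >= odds * l_del:
            return "retained"
        return "ambiguous"

    @pytest.mark.parametrize(
        "plump,shrivelled,expected",
        [(30, 30, "deleted"), (30, 10, "retained"), (0, 0, "ambiguous")],
    )
    def test_worked_examples(self, plump, shrivelled, expected):
        assert self._oracle_call(plump, shrivelled) == expected
        assert classify_deletion_typing(plump, shrivelled) == expected

    @pytest.mark.parametrize(
        "plump,shrivelled", [(10, 5), (40, 15), (100, 30), (5, 5), (0, 3)]
    )
    def test_matches_likelihood_oracle(self, plump, shrivelled):
        assert classify_deletion_typing(plump, shrivelled) == self._oracle_call(
            plump, shrivelled
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_deletion_typing(-1, 3)

    def test_miscall_rate_matches_exact_binomial_tail(self):
        # under retained truth (p=0.25) at n=40, the "deleted" miscall rate
        # equals the exact binomial mass of the deleted-call region
        n, p = 40, 0.25
        deleted_region = [
            s for s in range(n + 1)
            if classify_deletion_typing(n - s, s) == "deleted"
        ]
        exact = sum(binom.pmf(s, n, p) for s in deleted_region)
        rng = np.random.default_rng(11)
        draws = rng.binomial(n, p, size=10_000)
        observed = np.mean(
            [classify_deletion_typing(n - s, s) == "deleted" for s in draws]
        )
        se = math.sqrt(max(exact, 1e-6) * (1 - exact) / 10_000)
        assert abs(observed - exact) <= 3 * se + 1e-9


class TestTwoPoint:
    def test_identical_vectors_zero_distance(self):
        a = np.array([1, 0, 1, 1, 0], dtype=np.int8)
        assert two_point_distance(a, a) == (0.0, 0.0)

    def test_half_discordant(self):
        a = np.array([1, 1, 1, 1], dtype=np.int8)
        b = np.array([1, 1, 0, 0], dtype=np.int8)
        theta, cr = two_point_distance(a, b)
        assert theta == 0.5
        assert cr == pytest.approx(69.31, abs=0.01)

    def test_missing_calls_ignored(self):
        a = np.array([1, 0, -1, 1], dtype=np.int8)
        b = np.array([1, 1, 1, -1], dtype=np.int8)
        theta, _ = two_point_distance(a, b)
        assert theta == 0.5  # only two informative lines

    def test_all_missing_rejected(self):
        a = np.array([-1, -1], dtype=np.int8)
        with pytest.raises(ValueError):
            two_point_distance(a, a)

    def test_fully_discordant_unlinked(self):
        a = np.array([1, 1], dtype=np.int8)
        b = np.array([0, 0], dtype=np.int8)
        assert two_point_distance(a, b) == (1.0, math.inf)

    def test_monte_carlo_recovers_breakage(self):
        per_interval = 0.04
        n = 2000
        rng = np.random.default_rng(21)
        a = (rng.random(n) < 0.75).astype(np.int8)
        flip = rng.random(n) < per_interval
        b = np.where(flip, 1 - a, a).astype(np.int8)
        theta, cr = two_point_distance(a, b)
        se_theta = math.sqrt(per_interval * (1 - per_interval) / n)
        se_cr = 100 * se_theta / (1 - per_interval)  # delta method
        assert abs(cr - theta_to_cR(per_interval)) <= 3 * se_cr

    def test_cR_strictly_increasing_in_theta(self):
        grid = np.linspace(0, 0.99, 50)
        values = [theta_to_cR(t) for t in grid]
        assert all(x < y for x, y in zip(values, values[1:]))


def _matrix(vectors: dict[str, list[int]]) -> RetentionMatrix:
    loci = list(vectors)
    n = len(next(iter(vectors.values())))
    calls = np.array([[vectors[l][i] for l in loci] for i in range(n)], dtype=np.int8)
    return RetentionMatrix([f"L{i}" for i in range(n)], loci, calls)


class TestOrdering:
    def test_three_locus_planted_order(self):
        # 20 lines; adjacent pairs differ in 2 lines, outer pair in 4
        a = [1] * 20
        b = a.copy(); b[0] = b[1] = 0
        c = b.copy(); c[2] = c[3] = 0
        matrix = _matrix({"A": a, "B": b, "C": c})
        # exhaustive oracle
        cols = {k: np.array(v, dtype=np.int8) for k, v in {"A": a, "B": b, "C": c}.items()}
        def cost(order):
            return sum(
                int(np.sum(cols[x] != cols[y])) for x, y in zip(order, order[1:])
            )
        best = min(
            (p for p in itertools.permutations("ABC")), key=lambda p: (cost(p), p)
        )
        result = order_markers(matrix)
        assert result.locus_ids in (list(best), list(reversed(best)))
        assert result.locus_ids in (["A", "B", "C"], ["C", "B", "A"])

    def test_duplicated_columns_grouped(self):
        v = [1, 0, 1, 1, 0, 1]
        w = [1, 1, 1, 0, 0, 1]
        matrix = _matrix({"A": v, "A2": v, "B": w})
        result = order_markers(matrix)
        assert result.groups["A"] == ["A", "A2"]
        assert result.position("A2") == result.position("A")

    def test_all_identical_single_unique_locus(self):
        matrix = _matrix({"A": [1, 0, 1], "B": [1, 0, 1]})
        result = order_markers(matrix)
        assert result.locus_ids == ["A"] and result.positions_cR == [0.0]

    def test_span_invariant_under_locus_relabelling(self):
        rng = np.random.default_rng(3)
        vectors = {f"m{i}": list((rng.random(40) < 0.7).astype(int)) for i in range(5)}
        span1 = order_markers(_matrix(vectors)).span_cR
        renamed = {f"z{9 - int(k[1])}": v for k, v in vectors.items()}
        span2 = order_markers(_matrix(renamed)).span_cR
        assert span1 == pytest.approx(span2)

    def test_first_locus_at_zero_and_positions_nondecreasing(self):
        rng = np.random.default_rng(4)
        vectors = {f"m{i}": list((rng.random(30) < 0.7).astype(int)) for i in range(6)}
        result = order_markers(_matrix(vectors))
        assert result.positions_cR[0] == 0.0
        assert all(
            x <= y for x, y in zip(result.positions_cR, result.positions_cR[1:])
        )

    def test_planted_order_recovered_in_simulation_study(self):
        # 64-line, 10-marker panels in the sparse-break regime: the planted
        # order (or its reverse) should be recovered in >= 95% of replicates
        ref = simulate_genome(n_scaffolds=1, scaffold_len=100_000, n_genes=2, seed=0)
        markers = [
            Marker(f"m{i:02d}", "scaffold0", 5000 + i * 10_000, 5001 + i * 10_000)
            for i in range(10)
        ]
        planted = [m.marker_id for m in markers]
        recovered = 0
        for rep in range(100):
            lines = simulate_rh_panel(
                ref, 64, breaks_per_Mb=6, retention_prob=0.75, seed=1000 + rep
            )
            result = order_markers(build_retention_matrix(lines, markers))
            order = [m for r in result.locus_ids for m in result.groups[r]]
            recovered += order in (planted, planted[::-1])
        assert recovered >= 95


class TestCosegregation:
    def test_identical_marker_flagged(self):
        matrix = _matrix({"A": [1, 0, 1, 0], "B": [1, 0, 1, 1]})
        calls = {"L0": "retained", "L1": "deleted", "L2": "retained", "L3": "deleted"}
        scan = cosegregation_scan(matrix, calls)
        assert scan.iloc[0]["locus"] == "A" and scan.iloc[0]["cosegregating"]
        assert scan.loc[scan["locus"] == "B", "discordance"].iloc[0] == 1

    def test_ambiguous_phenotype_ignored(self):
        matrix = _matrix({"A": [1, 0, 1]})
        calls = {"L0": "retained", "L1": "ambiguous", "L2": "retained"}
        scan = cosegregation_scan(matrix, calls)
        assert scan.iloc[0]["n_informative"] == 2


class TestAnchoring:
    def _map(self):
        return RHMapResult(
            locus_ids=["F1", "M", "F2"],
            positions_cR=[0.0, 0.3, 1.0],
            groups={"F1": ["F1"], "M": ["M"], "F2": ["F2"]},
        )

    def test_resolution_from_flanking_anchors(self):
        anchors = PhysicalAnchorSet("ctg30", {"F1": 292.0, "F2": 580.0})
        resolution, interval = anchor_and_resolution(self._map(), anchors, "M")
        assert resolution == pytest.approx(288.0)
        assert interval == (292.0, 580.0)

    def test_flank_distances_sum_to_separation(self):
        m = self._map()
        left = m.position("M") - m.position("F1")
        right = m.position("F2") - m.position("M")
        assert left + right == pytest.approx(1.0)

    def test_simple_arithmetic(self):
        m = RHMapResult(["a", "x", "b"], [0.0, 1.0, 2.0], {k: [k] for k in "axb"})
        anchors = PhysicalAnchorSet("s", {"a": 0.0, "b": 100.0})
        resolution, _ = anchor_and_resolution(m, anchors, "x")
        assert resolution == pytest.approx(50.0)

    def test_equal_cR_anchors_rejected(self):
        m = RHMapResult(["a", "x", "b"], [0.0, 0.0, 0.0], {k: [k] for k in "axb"})
        anchors = PhysicalAnchorSet("s", {"a": 0.0, "b": 100.0})
        with pytest.raises(ValueError):
            anchor_and_resolution(m, anchors, "x")

    def test_unflanked_locus_rejected(self):
        m = self._map()
        anchors = PhysicalAnchorSet("s", {"F1": 292.0})
        with pytest.raises(ValueError):
            anchor_and_resolution(m, anchors, "M")
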