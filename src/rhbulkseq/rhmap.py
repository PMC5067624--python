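"""Radiation-hybrid genetics.

Radiation breaks chromosomes; a hemizygous RH line either retains or has
deleted each locus, and the fraction of lines in which two loci disagree
(obligate breaks) measures their physical separation. Distances are
expressed in centiRays via the haploid breakage transform
cR = -100 * ln(1 - theta). Marker ordering minimizes total obligate breaks
over adjacent pairs, the deletion-typing classifier turns test-cross seed
ratios (1:1 deleted vs 1:3 retained shrivelled:plump) into calls by a
binomial likelihood ratio, and physical anchoring converts cR spans into a
Kb-per-cR resolution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

RETAINED, DELETED, MISSING = 1, 0, -1


@dataclass
class RetentionMatrix:
    """Lines x loci retention calls: 1 retained, 0 deleted, -1 missing."""

    line_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray  # shape (n_lines, n_loci), int8

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.line_ids), len(self.locus_ids)):
            raise ValueError("calls shape inconsistent with line/locus ids")

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.calls == MISSING))

    def column(self, locus_id: str) -> np.ndarray:
        return self.calls[:, self.locus_ids.index(locus_id)]


def build_retention_matrix(lines, markers) -> RetentionMatrix:
    """Score each marker amplicon against each line's deletion haplotype."""
    calls = np.empty((len(lines), len(markers)), dtype=np.int8)
    for i, line in enumerate(lines):
        for j, m in enumerate(markers):
            calls[i, j] = (
                RETAINED if line.retains_interval(m.scaffold, m.start, m.end) else DELETED
            )
    return RetentionMatrix(
        [l.line_id for l in lines], [m.marker_id for m in markers], calls
    )


def deletion_typing_log10_lr(plump: int, shrivelled: int) -> float:
    """log10 L(deleted: p=1/2) - log10 L(retained: p=1/4) for the
    shrivelled count under Binomial(n, p)."""
    n = plump + shrivelled
    return float(
        (binom.logpmf(shrivelled, n, 0.5) - binom.logpmf(shrivelled, n, 0.25))
        / math.log(10)
    )


def classify_deletion_typing(
    plump: int, shrivelled: int, min_log10_lr: float = 1.0
) -> str:
    """Call a line deleted/retained from its test-cross seed counts.

    The call goes to the higher-likelihood Mendelian model when the log10
    likelihood ratio reaches `min_log10_lr` (default 10:1 odds); otherwise
    ambiguous. Zero seeds is always ambiguous.
    """
    if plump < 0 or shrivelled < 0:
        raise ValueError("seed counts must be non-negative")
    if plump + shrivelled == 0:
        return "ambiguous"
    lr = deletion_typing_log10_lr(plump, shrivelled)
    if lr >= min_log10_lr:
        return "deleted"
    if lr <= -min_log10_lr:
        return "retained"
    return "ambiguous"


def theta_to_cR(theta: float) -> float:
    """Breakage fraction -> centiRays; theta=1 maps to infinity (unlinked)."""
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    if theta == 1:
        return math.inf
    return -100.0 * math.log1p(-theta)


def two_point_distance(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[float, float]:
    """(theta, cR) between two loci from their retention call vectors.

    theta is the fraction of pairwise-complete lines whose states differ;
    missing calls are ignored. theta=1 returns infinite distance (unlinked).
    """
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    informative = (a != MISSING) & (b != MISSING)
    n = int(informative.sum())
    if n == 0:
        raise ValueError("no informative lines shared by the two loci")
    theta = float(np.mean(a[informative] != b[informative]))
    return theta, theta_to_cR(theta)


def _obligate_breaks(a: np.ndarray, b: np.ndarray) -> int:
    informative = (a != MISSING) & (b != MISSING)
    return int(np.count_nonzero(a[informative] != b[informative]))


def _order_cost(columns: dict[str, np.ndarray], order: tuple[str, ...]) -> int:
    return sum(
        _obligate_breaks(columns[x], columns[y]) for x, y in zip(order, order[1:])
    )


@dataclass
class RHMapResult:
    """Ordered unique loci with cumulative centiRay positions."""

    locus_ids: list[str]  # one representative per unique locus, in map order
    positions_cR: list[float]
    groups: dict[str, list[str]] = field(default_factory=dict)  # rep -> members

    def position(self, locus_id: str) -> float:
        for rep, members in self.groups.items():
            if locus_id in members:
                return self.positions_cR[self.locus_ids.index(rep)]
        raise KeyError(locus_id)

    @property
    def span_cR(self) -> float:
        return self.positions_cR[-1] - self.positions_cR[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, pos in zip(self.locus_ids, self.positions_cR):
            for member in self.groups[rep]:
                rows.append({"locus": member, "cR": pos, "group": rep})
        return pd.DataFrame(rows)


def _group_identical(matrix: RetentionMatrix) -> dict[str, list[str]]:
    """Group loci with identical call vectors (missing breaks identity)."""
    groups: dict[bytes, list[str]] = {}
    for locus in matrix.locus_ids:
        groups.setdefault(matrix.column(locus).tobytes(), []).append(locus)
    return {min(members): sorted(members) for members in groups.values()}


def order_markers(matrix: RetentionMatrix) -> RHMapResult:
    """Order unique loci by minimum total obligate breaks.

    Up to 8 unique loci the search is exhaustive; beyond that, a greedy
    insertion seeded from the best triple is refined by steepest-descent
    single-locus relocation. Ties break toward the lexicographically
    smallest order; orientation is normalized the same way. Positions are
    cumulative two-point cR over adjacent unique loci.
    """
    if len(matrix.locus_ids) < 2:
        raise ValueError("need at least two loci to order")
    groups = _group_identical(matrix)
    reps = sorted(groups)
    columns = {r: matrix.column(r) for r in reps}

    if len(reps) == 1:
        return RHMapResult(locus_ids=reps, positions_cR=[0.0], groups=groups)

    pair_cache: dict[tuple[str, str], int] = {}

    def pair_breaks(x: str, y: str) -> int:
        key = (x, y) if x <= y else (y, x)
        if key not in pair_cache:
            pair_cache[key] = _obligate_breaks(columns[key[0]], columns[key[1]])
        return pair_cache[key]

    if len(reps) <= 8:
        best_order, best_cost = None, None
        for perm in itertools.permutations(reps):
            if perm[0] > perm[-1]:
                continue  # orientation handled by reversal
            cost = sum(pair_breaks(x, y) for x, y in zip(perm, perm[1:]))
            if best_cost is None or cost < best_cost:
                best_order, best_cost = perm, cost
        order = list(best_order)
    else:
        order = _greedy_order(pair_breaks, reps)

    if tuple(reversed(order)) < tuple(order):
        order.reverse()

    positions = [0.0]
    for x, y in zip(order, order[1:]):
        _, cr = two_point_distance(columns[x], columns[y])
        positions.append(positions[-1] + cr)
    return RHMapResult(locus_ids=order, positions_cR=positions, groups=groups)


def _greedy_order(pair_breaks, reps: list[str]) -> list[str]:
    def cost(order) -> int:
        return sum(pair_breaks(x, y) for x, y in zip(order, order[1:]))
    # best triple, exhaustively
    best_triple, best_key = None, None
    for trio in itertools.combinations(reps, 3):
        for perm in itertools.permutations(trio):
            if perm[0] > perm[-1]:
                continue
            key = (cost(perm), perm)
            if best_key is None or key < best_key:
                best_triple, best_key = perm, key
    order = list(best_triple)
    # greedy insertion of the rest
    for locus in reps:
        if locus in order:
            continue
        candidates = [
            order[:i] + [locus] + order[i:] for i in range(len(order) + 1)
        ]
        order = min(candidates, key=lambda o: (cost(o), tuple(o)))
    # descent over single-locus relocations and segment reversals (2-opt) on
    # (break count, lexicographic order): equal-cost moves settle ties toward
    # the lexicographically smallest permutation
    improved = True
    while improved:
        improved = False
        current_key = (cost(order), tuple(order))
        moves = [
            order[:i] + [order[i]] * 0 + order[i + 1 :][:j] + [order[i]] + order[i + 1 :][j:]
            for i in range(len(order))
            for j in range(len(order))
        ]
        moves += [
            order[:i] + order[i:j][::-1] + order[j:]
            for i in range(len(order))
            for j in range(i + 2, len(order) + 1)
        ]
        for cand in moves:
            key = (cost(cand), tuple(cand))
            if key < current_key:
                order = cand
                improved = True
                break
    return order


def cosegregation_scan(matrix: RetentionMatrix, phenotype_calls: dict[str, str]) -> pd.DataFrame:
    """Rank loci by discordance with the phenotype retention vector.

    `phenotype_calls` maps line id to deleted/retained (anything else is
    treated as missing). Discordance counts informative lines where marker
    retention differs from phenotype retention; zero-discordance loci are
    flagged cosegregating.
    """
    pheno = np.array(
        [
            {"retained": RETAINED, "deleted": DELETED}.get(
                phenotype_calls.get(l, "ambiguous"), MISSING
            )
            for l in matrix.line_ids
        ],
        dtype=np.int8,
    )
    rows = []
    for locus in matrix.locus_ids:
        col = matrix.column(locus)
        informative = (col != MISSING) & (pheno != MISSING)
        disc = int(np.count_nonzero(col[informative] != pheno[informative]))
        rows.append(
            {
                "locus": locus,
                "discordance": disc,
                "n_informative": int(informative.sum()),
                "cosegregating": disc == 0,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["discordance", "locus"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass
class PhysicalAnchorSet:
    """Physical positions (Kb) of anchored loci on a named scaffold."""

    scaffold: str
    positions_kb: dict[str, float]


def anchor_and_resolution(
    map_result: RHMapResult,
    anchors: PhysicalAnchorSet,
    locus_id: str,
) -> tuple[float, tuple[float, float]]:
    """Map resolution (Kb/cR) and the physical interval around a locus.

    The flanking pair is the nearest anchored locus on each side of
    `locus_id` in map order (at a distinct cR from its partner); resolution
    is their physical distance over their cR distance, and the interval is
    the physical span between them (Kb, sorted).
    """
    order = map_result.locus_ids
    rep = next(r for r in order if locus_id in map_result.groups[r])
    idx = order.index(rep)
    anchored = {r for r in order if any(m in anchors.positions_kb for m in map_result.groups[r])}

    def _anchor_kb(rep_id: str) -> float:
        for m in map_result.groups[rep_id]:
            if m in anchors.positions_kb:
                return anchors.positions_kb[m]
        raise KeyError(rep_id)

    left = next((order[i] for i in range(idx - 1, -1, -1) if order[i] in anchored), None)
    right = next((order[i] for i in range(idx + 1, len(order)) if order[i] in anchored), None)
    if left is None or right is None:
        raise ValueError(f"locus {locus_id!r} is not flanked by two anchored loci")
    cr_left = map_result.positions_cR[order.index(left)]
    cr_right = map_result.positions_cR[order.index(right)]
    if cr_left == cr_right:
        raise ValueError("flanking anchors at equal cR positions")
    kb_left, kb_right = _anchor_kb(left), _anchor_kb(right)
    resolution = abs(kb_right - kb_left) / abs(cr_right - cr_left)
    interval = (min(kb_left, kb_right), max(kb_left, kb_right))
    return resolution, interval
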