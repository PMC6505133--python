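"""Linkage-map computation and reference-guided refinement ("salmonization").

The refinement algorithm takes one linkage group of phase-known markers and
the coordinates of those markers on an assigned reference chromosome of a
related species, then:

1. reorders the markers by reference coordinate;
2. detects breaks in the cM progression of that order (|delta| > 10 cM, or
   >= 8x the SD of all adjacent deltas in the group), cutting the group into
   1-8 blocks of orderly progressing markers;
3. exhaustively permutes the blocks, keeping the permutation with the
   minimal female map length (ties to the lexicographically smallest);
4. tries inverting each block, accepting a flip only when it strictly
   shortens the map, iterating passes to convergence;
5. validates that the refined order is no longer than any earlier stage.

Map length is the plain additive sum of adjacent recombination fractions
x 100 (no mapping function): only length comparisons matter to the search.

Phase vectors code grandparental origin 0/1 with -1 for missing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BREAK_CM = 10.0
BREAK_SD_MULT = 8.0
MAX_EXHAUSTIVE_BLOCKS = 8


class PhaseMatrix:
    """Phase vectors for the informative meioses of one parent.

    Parameters
    ----------
    phases : (n_markers, n_meioses) int array
        0/1 grandparental origin, -1 missing.
    marker_ids : sequence
        One id per row.
    parent : str
        "female" or "male"; the female map is the refinement objective.
    """

    def __init__(self, phases, marker_ids, parent: str = "female"):
        self.phases = np.ascontiguousarray(phases, dtype=np.int8)
        if self.phases.ndim != 2:
            raise ValueError("phases must be 2-D (markers x meioses)")
        if len(marker_ids) != self.phases.shape[0]:
            raise ValueError("marker_ids length must match phase rows")
        self.marker_ids = list(marker_ids)
        self.parent = parent
        self._r: np.ndarray | None = None
        self._n: np.ndarray | None = None

    @property
    def n_markers(self) -> int:
        return self.phases.shape[0]

    def pairwise(self) -> tuple[np.ndarray, np.ndarray]:
        """(r, n) matrices: phase-agnostic recombination fraction and the
        number of doubly-informative meioses for every marker pair."""
        if self._r is None:
            P = self.phases
            valid = (P >= 0)
            ones = ((P == 1) & valid).astype(np.int32)
            zeros = ((P == 0) & valid).astype(np.int32)
            n = (ones + zeros) @ (ones + zeros).T
            mismatch = ones @ zeros.T + zeros @ ones.T
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.minimum(mismatch, n - mismatch) / n
            self._r, self._n = r, n
        return self._r, self._n


def recombination_fraction(i: int, j: int, matrix: PhaseMatrix) -> float:
    """r = min(m, n-m)/n over doubly-informative meioses (phase-agnostic).

    Raises ValueError when no meiosis is informative for both markers.
    """
    r, n = matrix.pairwise()
    if n[i, j] == 0:
        raise ValueError(f"no doubly-informative meioses for markers {i}, {j}")
    return float(r[i, j])


def map_length(order, matrix: PhaseMatrix) -> float:
    """Additive map length (cM) of a marker order: sum of adjacent 100*r."""
    order = np.asarray(order)
    if order.size <= 1:
        return 0.0
    r, n = matrix.pairwise()
    a, b = order[:-1], order[1:]
    if np.any(n[a, b] == 0):
        bad = [(int(x), int(y)) for x, y in zip(a, b) if n[x, y] == 0]
        raise ValueError(f"undefined recombination fraction for adjacent pairs {bad}")
    return float(100.0 * r[a, b].sum())


def cumulative_positions(order, matrix: PhaseMatrix) -> np.ndarray:
    """Cumulative cM positions along ``order`` (position of first marker 0)."""
    order = np.asarray(order)
    if order.size == 0:
        return np.zeros(0)
    r, _ = matrix.pairwise()
    steps = 100.0 * r[order[:-1], order[1:]]
    return np.concatenate([[0.0], np.cumsum(steps)])


@dataclass
class LinkageGroup:
    group_id: str
    marker_ids: list
    positions_cm: np.ndarray
    ref_chrom: str | None = None
    ref_positions: np.ndarray | None = None


@dataclass
class BlockPartition:
    """Contiguous marker-index blocks of a group in salmonized order."""

    blocks: list[np.ndarray]  # marker indices (into the PhaseMatrix)
    permutation: tuple[int, ...] = ()
    flipped: tuple[bool, ...] = ()

    def __post_init__(self):
        if not self.permutation:
            self.permutation = tuple(range(len(self.blocks)))
        if not self.flipped:
            self.flipped = tuple(False for _ in self.blocks)

    def order(self) -> np.ndarray:
        """Current marker order implied by the permutation + orientations."""
        parts = []
        for bi in self.permutation:
            block = self.blocks[bi]
            parts.append(block[::-1] if self.flipped[bi] else block)
        return np.concatenate(parts) if parts else np.zeros(0, dtype=int)


def salmonize_order(
    ref_positions: np.ndarray, marker_indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stable-sort markers by reference coordinate.

    Returns ``(ordered_indices, excluded_indices)`` where the excluded set
    holds markers with missing (NaN) reference positions.
    """
    ref = np.asarray(ref_positions, dtype=float)
    idx = np.arange(ref.size) if marker_indices is None else np.asarray(marker_indices)
    missing = np.isnan(ref)
    keep = idx[~missing]
    order = keep[np.argsort(ref[~missing], kind="stable")]
    return order, idx[missing]


def detect_breaks(
    positions_cm: np.ndarray,
    break_cm: float = BREAK_CM,
    sd_mult: float = BREAK_SD_MULT,
) -> list[int]:
    """Break indices between adjacent markers of a salmonized group.

    A break sits after marker ``i`` when the adjacent |delta cM| exceeds
    ``break_cm`` OR is at least ``sd_mult`` population SDs of all adjacent
    deltas in the group (candidate gap included in the SD).
    """
    pos = np.asarray(positions_cm, dtype=float)
    if pos.size < 2:
        return []
    deltas = np.abs(np.diff(pos))
    sd = float(np.std(deltas))
    breaks = np.flatnonzero((deltas > break_cm) | ((sd > 0) & (deltas >= sd_mult * sd)))
    return [int(b) for b in breaks]


def partition_blocks(order: np.ndarray, breaks: list[int]) -> BlockPartition:
    """Cut a salmonized order into k+1 blocks at k break indices."""
    if len(set(breaks)) != len(breaks):
        raise ValueError("duplicate break indices")
    order = np.asarray(order)
    bounds = [0] + [b + 1 for b in sorted(breaks)] + [order.size]
    if any(b < 0 or b > order.size for b in bounds):
        raise ValueError("break index out of range")
    blocks = [order[bounds[i]:bounds[i + 1]] for i in range(len(bounds) - 1)]
    return BlockPartition(blocks=[b.copy() for b in blocks])


def _length_of(partition: BlockPartition, perm, flips, matrix: PhaseMatrix) -> float:
    trial = BlockPartition(partition.blocks, tuple(perm), tuple(flips))
    return map_length(trial.order(), matrix)


def optimize_block_order(
    partition: BlockPartition,
    matrix: PhaseMatrix,
    max_exhaustive: int = MAX_EXHAUSTIVE_BLOCKS,
) -> BlockPartition:
    """Exhaustive block-permutation search minimising map length.

    Evaluates all k! permutations (orientations untouched); ties go to the
    lexicographically smallest permutation. Above ``max_exhaustive`` blocks
    a greedy best-insertion heuristic is used instead, with a warning.
    """
    k = len(partition.blocks)
    flips = partition.flipped
    if k <= 1:
        return BlockPartition(partition.blocks, tuple(range(k)), flips)
    if k > max_exhaustive:
        import warnings
        warnings.warn(f"{k} blocks exceed the exhaustive limit; using greedy insertion")
        return _greedy_block_order(partition, matrix)
    best_perm, best_len = None, np.inf
    for perm in itertools.permutations(range(k)):  # lexicographic enumeration
        length = _length_of(partition, perm, flips, matrix)
        if length < best_len:
            best_perm, best_len = perm, length
    return BlockPartition(partition.blocks, best_perm, flips)


def _greedy_block_order(partition: BlockPartition, matrix: PhaseMatrix) -> BlockPartition:
    k = len(partition.blocks)
    flips = partition.flipped
    perm: list[int] = [0]
    for b in range(1, k):
        best_pos, best_len = 0, np.inf
        for pos in range(len(perm) + 1):
            trial = perm[:pos] + [b] + perm[pos:]
            length = _length_of(partition, trial, flips, matrix)
            if length < best_len:
                best_pos, best_len = pos, length
        perm.insert(best_pos, b)
    return BlockPartition(partition.blocks, tuple(perm), flips)


def refine_block_inversions(
    partition: BlockPartition, matrix: PhaseMatrix
) -> BlockPartition:
    """Greedy per-block orientation flips, kept only on strict improvement,
    repeated in passes until a full pass changes nothing."""
    flips = list(partition.flipped)
    perm = partition.permutation
    current = _length_of(partition, perm, flips, matrix)
    changed = True
    while changed:
        changed = False
        for bi in perm:
            trial = list(flips)
            trial[bi] = not trial[bi]
            length = _length_of(partition, perm, trial, matrix)
            if length < current:
                flips, current = trial, length
                changed = True
    return BlockPartition(partition.blocks, perm, tuple(flips))


def optimize_blocks_joint(
    partition: BlockPartition,
    matrix: PhaseMatrix,
    max_joint: int = 6,
) -> BlockPartition:
    """Joint (order x orientation) completion of the block search.

    Permuting with orientations fixed and flipping with the order fixed can
    each get stuck when the two interact (an inverted block prefers a
    different slot once flipped), so the refinement is completed jointly:
    exhaustively over all k! x 2^k configurations for k <= ``max_joint``
    (junction costs precomputed, so each configuration is k additions), and
    by alternating permutation/flip passes to convergence for larger k.
    Ties go to the lexicographically smallest (permutation, flips).
    """
    blocks = partition.blocks
    k = len(blocks)
    if k <= 1:
        return partition
    if k > max_joint:
        current = partition
        while True:
            step = refine_block_inversions(
                optimize_block_order(current, matrix), matrix)
            if (step.permutation == current.permutation
                    and step.flipped == current.flipped):
                return step
            current = step
    r, n = matrix.pairwise()
    # only junction costs vary across configurations (internal block lengths
    # are orientation-invariant); endpoint marker per (block, flipped)
    head = [[b[0], b[-1]] for b in blocks]
    tail = [[b[-1], b[0]] for b in blocks]
    best = None
    best_key = None
    for perm in itertools.permutations(range(k)):
        for flips in itertools.product((0, 1), repeat=k):
            cost = 0.0
            valid = True
            for a, b in zip(range(k - 1), range(1, k)):
                i, j = perm[a], perm[b]
                t, h = tail[i][flips[a]], head[j][flips[b]]
                if n[t, h] == 0:
                    valid = False
                    break
                cost += r[t, h]
            if not valid:
                continue
            key = (cost, perm, flips)
            if best_key is None or cost < best_key[0] - 1e-12 or (
                    abs(cost - best_key[0]) <= 1e-12
                    and (perm, flips) < (best_key[1], best_key[2])):
                best_key = key
    perm, flips = best_key[1], best_key[2]
    flipped_by_block = [False] * k
    for pos, bi in enumerate(perm):
        flipped_by_block[bi] = bool(flips[pos])
    return BlockPartition(blocks, perm, tuple(flipped_by_block))


@dataclass
class SalmonizationResult:
    group_id: str
    original_order: np.ndarray
    salmonized_order: np.ndarray
    partition: BlockPartition
    final_order: np.ndarray
    stage_lengths: dict[str, float]
    breaks: list[int]
    excluded_markers: list[int]
    validated: bool
    fused: bool = False
    diagnostics: list[str] = field(default_factory=list)

    @property
    def final_length(self) -> float:
        return self.stage_lengths["final"]

    def audit(self) -> dict:
        return {
            "group": self.group_id,
            "stage_lengths": self.stage_lengths,
            "n_blocks": len(self.partition.blocks),
            "block_permutation": list(self.partition.permutation),
            "flipped_blocks": list(self.partition.flipped),
            "breaks": self.breaks,
            "excluded_markers": [int(i) for i in self.excluded_markers],
            "validated": self.validated,
            "fused": self.fused,
            "diagnostics": self.diagnostics,
        }


def validate_final_map(
    candidates: dict[str, np.ndarray], matrix: PhaseMatrix
) -> tuple[str, dict[str, float], bool, list[str]]:
    """Check that the fully refined order is minimal among all candidates.

    Returns ``(best_name, lengths, validated, diagnostics)``; validated is
    False (with a diagnostic, never a silent acceptance) when some earlier
    stage beats the refined order, in which case the caller should fall back
    to the best candidate.
    """
    lengths = {name: map_length(order, matrix) for name, order in candidates.items()}
    diagnostics: list[str] = []
    refined = lengths.get("refined", np.inf)
    best_name = min(lengths, key=lambda k: lengths[k])
    validated = refined <= lengths[best_name] + 1e-12
    if not validated:
        diagnostics.append(
            f"refined order ({refined:.3f} cM) is longer than stage "
            f"'{best_name}' ({lengths[best_name]:.3f} cM); best candidate returned"
        )
    return (("refined" if validated else best_name), lengths, validated, diagnostics)


def _ref_chrom_runs(ref_chroms) -> int:
    runs = 1
    for a, b in zip(ref_chroms[:-1], ref_chroms[1:]):
        if a != b:
            runs += 1
    return runs


def salmonize_group(
    group_id: str,
    matrix: PhaseMatrix,
    ref_positions: np.ndarray,
    ref_chroms: np.ndarray | None = None,
    break_cm: float = BREAK_CM,
    sd_mult: float = BREAK_SD_MULT,
    max_exhaustive: int = MAX_EXHAUSTIVE_BLOCKS,
) -> SalmonizationResult:
    """Run the full refinement on one linkage group.

    ``ref_positions`` aligns with the rows of ``matrix`` (NaN = no reference
    position; such markers are excluded from the refinement and reported).
    ``ref_chroms`` (optional, same alignment) lets the routine flag fused
    groups: markers from two reference chromosomes/arms interleaving with no
    detected break between them.
    """
    original = np.arange(matrix.n_markers)
    salmonized, excluded = salmonize_order(ref_positions)
    positions = cumulative_positions(salmonized, matrix)
    breaks = detect_breaks(positions, break_cm=break_cm, sd_mult=sd_mult)
    partition = partition_blocks(salmonized, breaks)
    permuted = optimize_block_order(partition, matrix, max_exhaustive=max_exhaustive)
    sequential = refine_block_inversions(permuted, matrix)
    refined = optimize_blocks_joint(sequential, matrix)
    if _length_of(refined, refined.permutation, refined.flipped, matrix) > \
            _length_of(sequential, sequential.permutation, sequential.flipped, matrix):
        refined = sequential  # alternating fallback can only improve; keep best

    orig_eval = original[~np.isnan(np.asarray(ref_positions, float))] \
        if len(excluded) else original
    candidates = {
        "original": orig_eval,
        "salmonized": salmonized,
        "permuted": permuted.order(),
        "refined": refined.order(),
    }
    best_name, lengths, validated, diagnostics = validate_final_map(candidates, matrix)
    final_order = candidates[best_name]
    lengths["final"] = lengths[best_name]

    fused = False
    if ref_chroms is not None and len(set(np.asarray(ref_chroms)[salmonized])) > 1:
        chroms_in_order = list(np.asarray(ref_chroms)[final_order])
        if _ref_chrom_runs(chroms_in_order) > len(set(chroms_in_order)):
            fused = True
            diagnostics.append(
                "markers from multiple reference chromosomes interleave without "
                "a separating break; group flagged fused, no split forced"
            )

    return SalmonizationResult(
        group_id=group_id,
        original_order=original,
        salmonized_order=salmonized,
        partition=refined,
        final_order=np.asarray(final_order),
        stage_lengths=lengths,
        breaks=breaks,
        excluded_markers=list(excluded),
        validated=validated,
        fused=fused,
        diagnostics=diagnostics,
    )


def choose_homeolog(
    matrix: PhaseMatrix,
    candidate_ref_positions: dict[str, np.ndarray],
    **kwargs,
) -> tuple[str, dict[str, SalmonizationResult], bool]:
    """Disambiguate a group mapping equally well to two reference homeologs.

    The group is salmonized against each candidate's coordinates; the
    homeolog yielding the shorter refined map wins. Returns
    ``(winner, results, tied)``.
    """
    results = {
        name: salmonize_group(name, matrix, pos, **kwargs)
        for name, pos in candidate_ref_positions.items()
    }
    lengths = {name: res.final_length for name, res in results.items()}
    winner = min(sorted(lengths), key=lambda k: lengths[k])
    values = sorted(lengths.values())
    tied = len(values) > 1 and abs(values[0] - values[1]) < 1e-9
    return winner, results, tied
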