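"""Fluence stratification and step-and-shoot MLC leaf sequencing.

A continuous fluence map cannot be delivered directly: it is first
*stratified* onto equidistant intensity levels (default 7, per beam)
and then decomposed into multi-leaf-collimator (MLC) apertures, one
unit level step per segment, using the classic unidirectional sweep.

For a row profile f over bixel columns j, let

    A[j] = sum_{k<=j} max(f[k] - f[k-1], 0)   (positive gradients)
    B[j] = sum_{k<=j} max(f[k-1] - f[k], 0)   (negative gradients)

with f[-1] = 0; then f[j] = A[j] - B[j], and the aperture of unit
segment t opens column j iff A[j] >= t > B[j]. Left and right leaf
positions are therefore the first columns where A and B reach t — both
non-decreasing in t, so every leaf moves monotonically left to right
across segments, and summing the apertures reconstructs the stratified
map exactly. This exact-reconstruction property doubles as the
deliverability check for a shaped plan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .dose import FluenceMap, compute_dose

__all__ = [
    "StratifiedMap",
    "Segment",
    "stratify",
    "sequence_sweep",
    "reconstruct",
    "segment_counts",
    "deliverability_delta",
]


@dataclass(frozen=True)
class StratifiedMap:
    """Per-beam integer level maps with their level steps.

    ``levels[b]`` has the shape of beam b's fluence map with integer
    entries in [0, L]; the delivered fluence is ``step[b] * levels[b]``.
    A beam whose map is all-zero has step 0 (nothing to deliver).
    """

    levels: List[np.ndarray]
    steps: List[float]
    n_levels: int

    def fluence(self) -> FluenceMap:
        return FluenceMap([lv * st for lv, st in zip(self.levels, self.steps)])


@dataclass(frozen=True)
class Segment:
    """One MLC aperture of a beam, at unit level weight.

    Rows are leaf pairs (the v axis, one per 5 mm leaf width at the
    default bixel size); ``left``/``right`` are half-open column bounds
    [left, right) in bixel units along the leaf travel direction u. A
    closed row has left == right.
    """

    beam: int
    left: np.ndarray  # (n_rows,)
    right: np.ndarray  # (n_rows,)
    weight: float  # fluence units of one level step

    def aperture(self, n_cols: int) -> np.ndarray:
        """Boolean (n_cols, n_rows) open-bixel map of this segment."""
        cols = np.arange(n_cols)[:, None]
        return (cols >= self.left[None, :]) & (cols < self.right[None, :])


def stratify(fluence: FluenceMap, n_levels: int = 7) -> StratifiedMap:
    """Round each beam's map onto equidistant levels (half-up rounding).

    The step is the beam's maximum weight divided by the level count, so
    the quantization error is at most half a step per bixel.
    """
    if n_levels < 1:
        raise ValueError("need at least one fluence level")
    levels, steps = [], []
    for m in fluence.maps:
        top = float(m.max())
        if top <= 0.0:
            levels.append(np.zeros(m.shape, dtype=np.int64))
            steps.append(0.0)
            continue
        step = top / n_levels
        lv = np.floor(m / step + 0.5).astype(np.int64)  # round half-up
        levels.append(np.clip(lv, 0, n_levels))
        steps.append(step)
    return StratifiedMap(levels=levels, steps=steps, n_levels=int(n_levels))


def _row_gradients(profile: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    padded = np.concatenate([[0], profile])
    diff = np.diff(padded)
    a = np.cumsum(np.maximum(diff, 0))
    b = np.cumsum(np.maximum(-diff, 0))
    return a, b


def sequence_sweep(strat: StratifiedMap) -> List[Segment]:
    """Decompose stratified maps into unit-weight sweep segments.

    Per beam, each row's leaf trajectories come from the cumulative
    positive/negative gradients of its integer profile; rows are
    synchronized into global segments (the beam's segment count is the
    maximum row demand). Rows already finished stay closed with both
    leaves parked at their final position.
    """
    segments: List[Segment] = []
    for beam, (lv, step) in enumerate(zip(strat.levels, strat.steps)):
        n_cols, n_rows = lv.shape  # u (leaf travel) x v (leaf pairs)
        a_list, b_list, t_max = [], [], 0
        for rrow in range(n_rows):
            a, b = _row_gradients(lv[:, rrow])
            a_list.append(a)
            b_list.append(b)
            t_max = max(t_max, int(a[-1]) if a.size else 0)
        for t in range(1, t_max + 1):
            left = np.zeros(n_rows, dtype=np.int64)
            right = np.zeros(n_rows, dtype=np.int64)
            for rrow in range(n_rows):
                a, b = a_list[rrow], b_list[rrow]
                if a.size == 0 or a[-1] < t:
                    # finished row: park closed at its final right-leaf
                    # position so neither leaf ever moves backwards
                    pos = int(np.searchsorted(b, a[-1])) if a.size else 0
                    left[rrow] = right[rrow] = pos
                    continue
                left[rrow] = int(np.searchsorted(a, t))
                right[rrow] = int(np.searchsorted(b, t))
            segments.append(Segment(beam=beam, left=left, right=right, weight=step))
    return segments


def reconstruct(
    segments: Sequence[Segment],
    shapes: Sequence[Tuple[int, int]],
) -> List[np.ndarray]:
    """Sum unit-weight apertures back into per-beam integer maps."""
    maps = [np.zeros(s, dtype=np.int64) for s in shapes]
    for seg in segments:
        shape = shapes[seg.beam]
        if seg.left.shape[0] != shape[1]:
            raise ValueError(
                f"segment of beam {seg.beam} has {seg.left.shape[0]} rows, map expects {shape[1]}"
            )
        maps[seg.beam] += seg.aperture(shape[0]).astype(np.int64)
    return maps


def segment_counts(segments: Sequence[Segment], n_beams: int) -> Dict[str, int]:
    per_beam = [0] * n_beams
    for seg in segments:
        per_beam[seg.beam] += 1
    return {"per_beam": per_beam, "total": int(sum(per_beam))}


def deliverability_delta(state, n_levels: int = 7, threshold_fraction: float = 0.95) -> dict:
    """Metric impact of sequencing the current plan.

    Stratifies the plan's fluence, sequences it, verifies the exact
    reconstruction, recomputes dose from the reconstructed fluence, and
    reports the plan-quality metrics of both plans together with the
    worst per-voxel dose change and its linearity bound (the dose of a
    uniform half-step fluence perturbation on the modulated bixels).
    """
    from .metrics import compute_report

    strat = stratify(state.fluence, n_levels)
    segs = sequence_sweep(strat)
    shapes = [lv.shape for lv in strat.levels]
    recon = reconstruct(segs, shapes)
    for lv, rc in zip(strat.levels, recon):
        if not np.array_equal(lv, rc):
            raise AssertionError("sweep reconstruction mismatch: plan not deliverable")

    seq_fluence = FluenceMap([rc * st for rc, st in zip(recon, strat.steps)])
    dose_seq = compute_dose(state.influence, seq_fluence)

    # linearity bound: |D (w_s - w)| <= D |w_s - w| <= D (step/2 on each bixel)
    bound_fluence = FluenceMap(
        [np.full(s, st / 2.0) for s, st in zip(shapes, strat.steps)]
    )
    bound_dose = compute_dose(state.influence, bound_fluence)

    report_plan = compute_report(state.dose, state.grid, state.vois, state.rx, threshold_fraction)
    report_seq = compute_report(dose_seq, state.grid, state.vois, state.rx, threshold_fraction)
    delta = dose_seq - state.dose
    return {
        "unsequenced": report_plan,
        "sequenced": report_seq,
        "dose_delta_max_gy": float(np.max(np.abs(delta))),
        "dose_delta_bound_gy": float(np.max(bound_dose)),
        "segment_counts": segment_counts(segs, len(strat.levels)),
        "stratified": strat,
        "segments": segs,
    }
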