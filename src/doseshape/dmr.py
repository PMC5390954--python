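"""Dose modification and recovery (DMR): the core shaping operator.

A DMR instance is a two-step operation on the current plan:

1. **Modification** — a requested dose change ``dd`` at a voxel ``v``
   is enforced by a *fluence patch*: the minimum-norm weight delta
   along the voxel's influence row, ``P = dd * a / ||a||^2`` with ``a``
   the row of the dose-influence matrix at ``v``, clamped so no bixel
   weight becomes negative.
2. **Recovery** — the patch inevitably perturbs dose elsewhere; the
   voxels outside the intended modification region whose dose deviates
   from the pre-modification dose by more than a tolerance ``tau`` are
   ranked by deviation magnitude, the worst ``N_R`` are selected, and
   each receives its own counteracting fluence patch (single pass, in
   rank order).

The three interactive shaping tools (single voxel, isodose-line drag,
isodose-sphere push/pull) are scripted here as gesture objects that
expand into ordered lists of DMR requests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

log = logging.getLogger("doseshape.dmr")

from .dose import DoseInfluence

__all__ = [
    "InfeasibleModification",
    "DMRRequest",
    "FluencePatch",
    "RecoveryPlan",
    "DMRResult",
    "fluence_patch",
    "identify_recovery",
    "apply_dmr",
    "VoxelGesture",
    "SphereGesture",
    "IsodoseDragGesture",
    "tool_requests",
    "execute_tool",
]


class InfeasibleModification(RuntimeError):
    """No fluence patch can change the dose at the requested voxel."""


@dataclass(frozen=True)
class DMRRequest:
    """A requested local dose change.

    ``voxel`` is a flat (C-order) voxel index; ``dd_gy`` the signed dose
    change; ``vm_flat`` the flat indices of the modification region
    (voxels whose change is intended — minimally the voxel itself).
    """

    voxel: int
    dd_gy: float
    vm_flat: np.ndarray

    @classmethod
    def single(cls, voxel: int, dd_gy: float) -> "DMRRequest":
        return cls(voxel=int(voxel), dd_gy=float(dd_gy), vm_flat=np.asarray([voxel], dtype=np.int64))


@dataclass(frozen=True)
class FluencePatch:
    """Sparse per-bixel weight delta enforcing one dose change."""

    bixels: np.ndarray  # flat column indices
    deltas: np.ndarray  # weight changes
    achieved_dd_gy: float  # a . P, the dose change actually enforced at the voxel


@dataclass(frozen=True)
class RecoveryPlan:
    """Ranked voxels to recover after a modification."""

    voxels: np.ndarray  # flat indices, sorted by decreasing |deviation|
    deviations_gy: np.ndarray  # dose_new - dose_ref at those voxels
    budget: int
    tolerance_gy: float


@dataclass
class DMRResult:
    """Outcome of one DMR instance."""

    request: DMRRequest
    achieved_dd_gy: float  # dose change enforced by the modification patch
    net_dd_gy: float  # final-minus-reference dose at the voxel after recovery
    n_recovered: int
    residual_max_gy: float  # worst off-target deviation after recovery
    residual_rms_gy: float
    patches: List[FluencePatch] = field(default_factory=list)


def fluence_patch(
    influence: DoseInfluence,
    weights: np.ndarray,
    voxel: int,
    dd_gy: float,
    exclude: Optional[set] = None,
    max_passes: int = 10,
) -> FluencePatch:
    """Minimum-norm fluence patch enforcing a dose change at one voxel.

    Starting from the unconstrained minimizer ``P = dd * a / ||a||^2``
    on the voxel's influence row ``a``, entries that would drive a
    weight negative are clamped to the non-negativity bound and the
    remaining free entries re-solved, for at most ``max_passes``
    rounds. ``exclude`` removes protected bixels (those that enforced
    an earlier modification) from the patch support. The achieved
    change is ``a . P``; it has the sign of the request or is zero.
    """
    cols, a = influence.row(voxel)
    if exclude:
        keep = ~np.isin(cols, list(exclude))
        cols, a = cols[keep], a[keep]
    if cols.size == 0 or not np.any(a > 0):
        raise InfeasibleModification(
            f"voxel {voxel} has no usable bixel influence; no patch exists"
        )
    if dd_gy == 0.0:
        return FluencePatch(bixels=np.empty(0, dtype=np.int64), deltas=np.empty(0), achieved_dd_gy=0.0)

    w = np.asarray(weights, dtype=float)[cols]
    # per-bixel lower bound on the delta: never below -w (non-negativity)
    lb = -w.copy()

    p = np.zeros_like(a)
    free = np.ones_like(a, dtype=bool)
    for _ in range(max_passes):
        fixed_contrib = float(a[~free] @ p[~free])
        resid = dd_gy - fixed_contrib
        denom = float(a[free] @ a[free])
        if denom <= 0.0 or not free.any():
            break
        p_free = resid * a[free] / denom
        p[free] = p_free
        viol = free & (p < lb - 1e-15)
        if not viol.any():
            break
        p[viol] = lb[viol]
        free &= ~viol
    # final safety clamp (numerical noise only)
    p = np.maximum(p, lb)
    achieved = float(a @ p)
    nz = p != 0.0
    return FluencePatch(bixels=cols[nz], deltas=p[nz], achieved_dd_gy=achieved)


def identify_recovery(
    dose_ref: np.ndarray,
    dose_new: np.ndarray,
    vm_flat: np.ndarray,
    tau_gy: float,
    n_r: int,
) -> RecoveryPlan:
    """Rank the collateral dose deviations and truncate to the budget.

    Candidates are voxels outside the modification region whose dose
    deviates from the reference by more than ``tau_gy``; they are sorted
    by decreasing |deviation| (ties broken by ascending flat index) and
    the first ``n_r`` kept.
    """
    if dose_ref.shape != dose_new.shape:
        raise ValueError("dose grids must share a shape")
    dev = (dose_new - dose_ref).ravel()
    cand = np.flatnonzero(np.abs(dev) > tau_gy)
    if vm_flat is not None and len(vm_flat):
        cand = cand[~np.isin(cand, vm_flat)]
    if cand.size and n_r > 0:
        mag = np.abs(dev[cand])
        order = np.lexsort((cand, -mag))  # primary: -|dev|, tie: ascending index
        cand = cand[order][:n_r]
    else:
        cand = cand[:0]
    return RecoveryPlan(
        voxels=cand,
        deviations_gy=dev[cand],
        budget=int(n_r),
        tolerance_gy=float(tau_gy),
    )


def _protected_bixels(
    influence: DoseInfluence, patch: FluencePatch, voxel: int, share: float = 0.9
) -> set:
    """Bixels shielded from recovery because they carry the modification.

    A bixel carrying at least ``share`` of the enforced dose change is
    protected: the instance's recovery patches must not touch it, so an
    established local dose feature cannot be undone outright. In
    realistic plans the change spreads over hundreds of bixels and no
    single one reaches the share, so the guard only bites on sparse
    (near-separable) geometries.
    """
    if patch.bixels.size == 0 or patch.achieved_dd_gy == 0.0:
        return set()
    cols, a = influence.row(voxel)
    lookup = {int(c): float(val) for c, val in zip(cols, a)}
    protected = set()
    for c, dp in zip(patch.bixels, patch.deltas):
        contrib = lookup.get(int(c), 0.0) * dp
        if contrib / patch.achieved_dd_gy >= share:
            protected.add(int(c))
    return protected


def apply_dmr(
    state,
    req: DMRRequest,
    tau_gy: float,
    n_r: int,
) -> DMRResult:
    """Run one two-step DMR instance on a plan state, in place.

    Step 1 applies the modification patch and updates the dose
    incrementally; step 2 identifies the recovery set against the
    pre-modification dose and applies one counteracting patch per
    recovery voxel, in rank order, single pass (recovery patches do not
    trigger further recovery). On an infeasible modification the state
    is left unchanged.
    """
    influence: DoseInfluence = state.influence
    dose_ref = state.dose.copy()
    w_ref = state.fluence_flat.copy()

    if req.dd_gy == 0.0:
        return DMRResult(
            request=req, achieved_dd_gy=0.0, net_dd_gy=0.0, n_recovered=0,
            residual_max_gy=0.0, residual_rms_gy=0.0, patches=[],
        )

    try:
        mod_patch = fluence_patch(influence, state.fluence_flat, req.voxel, req.dd_gy)
    except InfeasibleModification:
        raise  # state untouched

    patches = [mod_patch]
    state.apply_patch(mod_patch.bixels, mod_patch.deltas)

    protect = _protected_bixels(influence, mod_patch, req.voxel)

    plan = identify_recovery(dose_ref, state.dose, req.vm_flat, tau_gy, n_r)
    dose_ref_flat = dose_ref.ravel()
    n_rec = 0
    for r in plan.voxels:
        # the recovery target is the voxel's original dose; the deviation
        # is re-read against the live dose because earlier recovery
        # patches perturb later recovery voxels too
        dev = float(state.dose.ravel()[r] - dose_ref_flat[r])
        if dev == 0.0:
            continue
        try:
            p = fluence_patch(influence, state.fluence_flat, int(r), -dev, exclude=protect)
        except InfeasibleModification:
            continue
        state.apply_patch(p.bixels, p.deltas)
        patches.append(p)
        n_rec += 1

    dev_final = (state.dose - dose_ref).ravel()
    outside = np.ones(dev_final.size, dtype=bool)
    outside[req.vm_flat] = False
    out_dev = dev_final[outside]
    res = DMRResult(
        request=req,
        achieved_dd_gy=mod_patch.achieved_dd_gy,
        net_dd_gy=float(dev_final[req.voxel]),
        n_recovered=n_rec,
        residual_max_gy=float(np.max(np.abs(out_dev))) if out_dev.size else 0.0,
        residual_rms_gy=float(np.sqrt(np.mean(out_dev**2))) if out_dev.size else 0.0,
        patches=patches,
    )
    state.record(res)
    log.info(
        "dmr voxel=%d requested=%.3f achieved=%.3f recovered=%d residual_max=%.3f",
        req.voxel, req.dd_gy, res.achieved_dd_gy, n_rec, res.residual_max_gy,
    )
    return res


# ---------------------------------------------------------------------------
# Shaping tools


@dataclass(frozen=True)
class VoxelGesture:
    """Single-voxel manipulation: raise or lower the dose at one voxel."""

    voxel: Tuple[int, int, int]
    dd_gy: float


@dataclass(frozen=True)
class SphereGesture:
    """Isodose-surface push/pull: a spherical local modification.

    Every body voxel within ``radius_mm`` of the center receives a
    request; the requested change falls off radially with a raised
    cosine, full ``dd_gy`` at the center and zero at the sphere surface.
    The sphere is the shared modification region of all its requests.
    """

    center: Tuple[int, int, int]  # voxel index
    radius_mm: float
    dd_gy: float


@dataclass(frozen=True)
class IsodoseDragGesture:
    """Drag an isodose line from one point to another.

    Dragging outward (from inside the level toward lower dose) raises
    the voxels along the segment that are below the level up to it;
    dragging inward lowers voxels above the level down to it.
    """

    level_gy: float
    p_from: Tuple[int, int, int]
    p_to: Tuple[int, int, int]


Gesture = Union[VoxelGesture, SphereGesture, IsodoseDragGesture]


def _sphere_requests(state, g: SphereGesture) -> List[DMRRequest]:
    grid = state.grid
    body = state.vois["body"].mask
    center_idx = tuple(int(c) for c in g.center)
    if not body[center_idx]:
        raise ValueError(f"sphere center {center_idx} lies outside the body")
    c_mm = np.asarray(grid.origin) + (np.asarray(center_idx) + 0.5) * np.asarray(grid.spacing)
    pts = grid.voxel_centers()
    dist = np.linalg.norm(pts - c_mm, axis=1)
    inside = (dist <= g.radius_mm) & body.ravel()
    idx = np.flatnonzero(inside)
    if idx.size == 0:  # radius below half a voxel: the center voxel alone
        idx = np.asarray([grid.flat_index(center_idx)], dtype=np.int64)
        dist_sel = np.asarray([0.0])
    else:
        dist_sel = dist[idx]
    vm = idx.copy()
    falloff = 0.5 * (1.0 + np.cos(np.pi * np.minimum(dist_sel / max(g.radius_mm, 1e-12), 1.0)))
    reqs = []
    for v, f in zip(idx, falloff):
        dd = g.dd_gy * float(f)
        if dd != 0.0:
            reqs.append(DMRRequest(voxel=int(v), dd_gy=dd, vm_flat=vm))
    return reqs


def _segment_voxels(grid, p_from, p_to) -> List[Tuple[int, int, int]]:
    """Voxels crossed by the straight segment between two voxel centers."""
    a = np.asarray(p_from, dtype=float)
    b = np.asarray(p_to, dtype=float)
    n = int(np.ceil(np.abs(b - a).max() * 4)) + 1
    seen, out = set(), []
    for t in np.linspace(0.0, 1.0, n):
        ijk = tuple(np.round(a + t * (b - a)).astype(int))
        if ijk not in seen:
            seen.add(ijk)
            out.append(ijk)
    return out


def _isodose_requests(state, g: IsodoseDragGesture) -> List[DMRRequest]:
    dose = state.dose
    if not (dose.min() <= g.level_gy <= dose.max()):
        raise ValueError(
            f"isodose level {g.level_gy} Gy outside the current dose range "
            f"[{dose.min():.2f}, {dose.max():.2f}] Gy"
        )
    if tuple(g.p_from) == tuple(g.p_to):
        return []
    d_from = float(dose[tuple(g.p_from)])
    voxels = _segment_voxels(state.grid, g.p_from, g.p_to)
    body = state.vois["body"].mask
    vm = np.asarray([state.grid.flat_index(v) for v in voxels if body[v]], dtype=np.int64)
    reqs = []
    outward = d_from >= g.level_gy  # dragging the line from the hot side outward
    for v in voxels:
        if not body[v]:
            continue
        dv = float(dose[v])
        if outward and dv < g.level_gy:
            reqs.append(DMRRequest(state.grid.flat_index(v), g.level_gy - dv, vm))
        elif not outward and dv > g.level_gy:
            reqs.append(DMRRequest(state.grid.flat_index(v), g.level_gy - dv, vm))
    return reqs


def tool_requests(state, gesture: Gesture) -> List[DMRRequest]:
    """Expand a shaping gesture into an ordered list of DMR requests."""
    if isinstance(gesture, VoxelGesture):
        return [DMRRequest.single(state.grid.flat_index(tuple(gesture.voxel)), gesture.dd_gy)]
    if isinstance(gesture, SphereGesture):
        return _sphere_requests(state, gesture)
    if isinstance(gesture, IsodoseDragGesture):
        return _isodose_requests(state, gesture)
    raise TypeError(f"unknown gesture type {type(gesture).__name__}")


def gesture_from_dict(d: dict) -> Gesture:
    """Build a gesture from a plain mapping (one entry of a shaping script).

    ``tool`` selects the gesture type; the remaining keys are its
    parameters, e.g. ``{"tool": "sphere", "center": [10, 12, 8],
    "radius_mm": 12.0, "dd_gy": -5.0}``.
    """
    d = dict(d)
    tool = d.pop("tool")
    d.pop("tau_gy", None)
    d.pop("n_r", None)
    if tool == "voxel":
        return VoxelGesture(voxel=tuple(d["voxel"]), dd_gy=float(d["dd_gy"]))
    if tool == "sphere":
        return SphereGesture(
            center=tuple(d["center"]), radius_mm=float(d["radius_mm"]), dd_gy=float(d["dd_gy"])
        )
    if tool == "isodose_drag":
        return IsodoseDragGesture(
            level_gy=float(d["level_gy"]), p_from=tuple(d["p_from"]), p_to=tuple(d["p_to"])
        )
    raise ValueError(f"unknown tool {tool!r} in gesture script")


def run_gesture_script(
    state,
    script: Sequence[dict],
    tau_gy: float,
    n_r: int,
) -> List[DMRResult]:
    """Run a shaping script: a list of gesture mappings, in order.

    Each entry may override ``tau_gy`` and ``n_r`` for its own
    instances.
    """
    results: List[DMRResult] = []
    for entry in script:
        g = gesture_from_dict(entry)
        results.extend(
            execute_tool(
                state, g,
                tau_gy=float(entry.get("tau_gy", tau_gy)),
                n_r=int(entry.get("n_r", n_r)),
            )
        )
    return results


def execute_tool(
    state,
    gesture: Gesture,
    tau_gy: float,
    n_r: int,
) -> List[DMRResult]:
    """Run a gesture as consecutive DMR instances.

    The first infeasible instance aborts the remainder; earlier
    instances persist (the tools are interactive, not transactional).
    """
    results: List[DMRResult] = []
    for req in tool_requests(state, gesture):
        try:
            results.append(apply_dmr(state, req, tau_gy, n_r))
        except InfeasibleModification:
            break
    return results
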