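"""Plan state, initialization, goal-driven shaping, and a baseline optimizer.

The plan state couples the fluence maps to the current dose and keeps
an operation history, mirroring the workflow of an interactive planning
session: initialize with open fields scaled so the PTV median dose
meets the average of the PTV and boost prescriptions, then shape the
dose with DMR gestures in a hierarchical order — organ-at-risk Quantec
constraints first, then trade-off goals — and save satisfying states.

The interactive shaping of the original workflow (a planner clicking on
isodose surfaces, guided by a physician) is replaced by a scripted
greedy loop: for the currently most-violating constraint, push down the
hottest contributing organ voxel with a sphere-decrease gesture, keep
the instance only if a scalar objective improves and no already
satisfied higher-priority goal breaks, otherwise roll back and
blacklist the voxel.

``baseline_optimize`` is a conventional fluence-map optimizer (projected
gradient on a piece-wise quadratic objective) standing in for the
reference plans produced by a clinical inverse-planning system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np

from .dmr import DMRResult, SphereGesture, execute_tool
from .dose import DoseInfluence, FluenceMap, compute_dose, incremental_dose, open_field
from .metrics import QUANTEC_CONSTRAINTS, dose_at_volume, volume_at_dose
from .phantom import VOI, Prescription, VoxelGrid

__all__ = [
    "PlanState",
    "Goal",
    "GoalList",
    "default_goals",
    "load_goals",
    "save_goals",
    "init_plan",
    "goal_script_run",
    "baseline_optimize",
    "save_state",
    "load_state",
]


@dataclass
class PlanState:
    """Mutable plan: fluence, consistent dose, history, snapshots."""

    grid: VoxelGrid
    vois: Dict[str, VOI]
    rx: Prescription
    influence: DoseInfluence
    fluence_flat: np.ndarray
    dose: np.ndarray  # 3D, always consistent with fluence_flat
    history: List[dict] = field(default_factory=list)
    snapshots: Dict[str, np.ndarray] = field(default_factory=dict)
    init_scale: float = 1.0
    goal_report: List[dict] = field(default_factory=list)

    @property
    def fluence(self) -> FluenceMap:
        return FluenceMap.from_flat(self.influence, self.fluence_flat)

    def apply_patch(self, bixels: np.ndarray, deltas: np.ndarray) -> None:
        """Apply a sparse fluence delta and update the dose incrementally."""
        if bixels.size == 0:
            return
        self.fluence_flat[bixels] += deltas
        # clamp numerical dust; patches guarantee w >= 0 up to rounding
        np.clip(self.fluence_flat, 0.0, None, out=self.fluence_flat)
        incremental_dose(self.influence, self.dose, bixels, deltas, out=self.dose)

    def record(self, result: DMRResult) -> None:
        self.history.append(
            {
                "voxel": int(result.request.voxel),
                "requested_dd_gy": float(result.request.dd_gy),
                "achieved_dd_gy": float(result.achieved_dd_gy),
                "net_dd_gy": float(result.net_dd_gy),
                "n_recovered": int(result.n_recovered),
                "residual_max_gy": float(result.residual_max_gy),
            }
        )

    def save_snapshot(self, name: str) -> None:
        """Save the current fluence as a named dose state."""
        self.snapshots[name] = self.fluence_flat.copy()

    def recompute_dose(self) -> np.ndarray:
        return compute_dose(self.influence, self.fluence)

    def checkpoint(self) -> Tuple[np.ndarray, np.ndarray, int]:
        return self.fluence_flat.copy(), self.dose.copy(), len(self.history)

    def rollback(self, cp: Tuple[np.ndarray, np.ndarray, int]) -> None:
        self.fluence_flat, self.dose = cp[0], cp[1]
        del self.history[cp[2]:]


@dataclass(frozen=True)
class Goal:
    """One planning goal.

    kind "quantec": keep ``V_{x_gy}`` of ``structure`` strictly below
    ``limit_percent``. kind "cover": raise the structure's D98% to
    ``limit_percent`` percent of its prescription. kind "spare": push
    the structure's mean dose down as a trade-off exploration, bounded
    by the instance budget.
    """

    name: str
    kind: str  # "quantec" | "cover" | "spare"
    structure: str
    x_gy: float = 0.0
    limit_percent: float = 0.0
    budget: int = 40


GoalList = List[Goal]


def default_goals(budget: int = 40, spare_budget: int = 8) -> GoalList:
    """Hierarchical default: all Quantec constraints per OAR, then sparing."""
    goals = [
        Goal(
            name=f"{organ}_V{x:g}",
            kind="quantec",
            structure=organ,
            x_gy=x,
            limit_percent=limit,
            budget=budget,
        )
        for organ, x, limit in QUANTEC_CONSTRAINTS
    ]
    goals += [
        Goal(name=f"{tgt}_cover", kind="cover", structure=tgt, limit_percent=95.0, budget=spare_budget)
        for tgt in ("ptv", "boost")
    ]
    goals += [
        Goal(name=f"{organ}_spare", kind="spare", structure=organ, budget=spare_budget)
        for organ in ("rectum", "bladder")
    ]
    return goals


def load_goals(path) -> GoalList:
    """Read a goal list from YAML: a list of Goal field mappings.

    Order in the file is strict priority order.
    """
    import yaml

    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    return [Goal(**e) for e in entries]


def save_goals(path, goals: GoalList) -> None:
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([dataclasses.asdict(g) for g in goals], fh, sort_keys=False)


def init_plan(
    grid: VoxelGrid,
    vois: Dict[str, VOI],
    rx: Prescription,
    influence: DoseInfluence,
    margin_mm: float = 5.0,
) -> PlanState:
    """Open-field initialization scaled to the target median-dose condition.

    The open fields conform to the PTV plus a margin; a single scale
    factor, exact because D50% is linear in the fluence, brings the PTV
    median dose to the average of the PTV and boost prescriptions.
    """
    ptv = vois["ptv"]
    if not ptv.mask.any():
        raise ValueError("PTV is empty")
    w0 = open_field(influence, ptv, margin_mm=margin_mm)
    dose0 = compute_dose(influence, w0)
    d50 = dose_at_volume(dose0, ptv.mask, 50.0)
    if d50 <= 0:
        raise ValueError("open fields deliver no dose to the PTV")
    s = rx.mean_target_gy / d50
    flat = s * w0.flat
    return PlanState(
        grid=grid,
        vois=vois,
        rx=rx,
        influence=influence,
        fluence_flat=flat,
        dose=dose0 * s,
        init_scale=s,
    )


def _objective(
    state: PlanState,
    quantec_weight: float = 1.0,
    coverage_weight: float = 10.0,
    coverage_fraction: float = 0.95,
    spare_structure: Optional[str] = None,
    spare_weight: float = 0.05,
) -> float:
    """Scalar accept/reject objective for the shaping loop.

    Sum of Quantec constraint violations (percentage points) plus a
    target-coverage penalty: D98% floors at ``coverage_fraction`` of the
    prescription for both the PTV and the boost volume. During a
    sparing goal a small term on the organ's mean dose is added so
    sparing progress is measurable once all constraints are met.
    """
    dose = state.dose
    obj = 0.0
    for organ, x, limit in QUANTEC_CONSTRAINTS:
        vx = volume_at_dose(dose, state.vois[organ].mask, x)
        obj += quantec_weight * max(0.0, vx - limit)
    for tgt, rx_gy in (("ptv", state.rx.ptv_gy), ("boost", state.rx.boost_gy)):
        d98 = dose_at_volume(dose, state.vois[tgt].mask, 98.0)
        obj += coverage_weight * max(0.0, coverage_fraction * rx_gy - d98)
    if spare_structure is not None:
        obj += spare_weight * float(np.mean(dose[state.vois[spare_structure].mask]))
    return obj


def _rx_of(state: PlanState, structure: str) -> float:
    return state.rx.boost_gy if structure == "boost" else state.rx.ptv_gy


def _satisfied(state: PlanState, goal: Goal) -> Optional[bool]:
    if goal.kind == "quantec":
        vx = volume_at_dose(state.dose, state.vois[goal.structure].mask, goal.x_gy)
        return vx < goal.limit_percent
    if goal.kind == "cover":
        floor = goal.limit_percent / 100.0 * _rx_of(state, goal.structure)
        return dose_at_volume(state.dose, state.vois[goal.structure].mask, 98.0) >= floor
    return None


def _quantec_status(state: PlanState) -> Dict[str, bool]:
    out = {}
    for organ, x, limit in QUANTEC_CONSTRAINTS:
        vx = volume_at_dose(state.dose, state.vois[organ].mask, x)
        out[f"{organ}_V{x:g}"] = vx < limit
    return out


def goal_script_run(
    state: PlanState,
    goals: Optional[GoalList] = None,
    tau_gy: Optional[float] = None,
    n_r: int = 15,
    sphere_radius_voxels: float = 3.0,
    undershoot_gy: float = 1.0,
) -> PlanState:
    """Greedy hierarchical shaping toward the goal list, in place.

    Goals are visited in strict priority order. For a Quantec goal the
    loop repeatedly picks the hottest non-blacklisted organ voxel at or
    above the constraint threshold and runs a sphere-decrease gesture
    aiming ``undershoot_gy`` below the threshold; the instance is kept
    only if the scalar objective strictly improves *and* no previously
    satisfied higher-priority constraint breaks, else it is rolled back
    and the voxel blacklisted. Each goal stops at satisfaction or when
    its gesture budget is exhausted (reported, not fatal).
    """
    goals = goals if goals is not None else default_goals()
    tau = tau_gy if tau_gy is not None else 0.005 * state.rx.boost_gy
    radius_mm = sphere_radius_voxels * min(state.grid.spacing)

    for gi, goal in enumerate(goals):
        blacklist: set = set()
        n_used = 0
        accepted = 0
        obj = _objective(state, spare_structure=goal.structure if goal.kind == "spare" else None)
        obj_trace = [obj]
        satisfied_before = _quantec_status(state)
        organ_mask = state.vois[goal.structure].mask

        while n_used < goal.budget:
            if goal.kind in ("quantec", "cover") and _satisfied(state, goal):
                break
            dose_flat = state.dose.ravel()
            organ_flat = np.flatnonzero(organ_mask.ravel())
            if goal.kind == "quantec":
                cand = organ_flat[dose_flat[organ_flat] >= goal.x_gy]
            elif goal.kind == "cover":
                floor = goal.limit_percent / 100.0 * _rx_of(state, goal.structure)
                cand = organ_flat[dose_flat[organ_flat] < floor]
            else:
                cand = organ_flat
            cand = cand[~np.isin(cand, list(blacklist))] if blacklist else cand
            if cand.size == 0:
                break
            if goal.kind == "cover":
                v = int(cand[np.argmin(dose_flat[cand])])  # coldest target voxel
                dd = floor + undershoot_gy - float(dose_flat[v])
            else:
                v = int(cand[np.argmax(dose_flat[cand])])  # hottest organ voxel
                dv = float(dose_flat[v])
                dd = (goal.x_gy - undershoot_gy - dv) if goal.kind == "quantec" else -0.1 * dv
            ijk = np.unravel_index(v, state.grid.dims)
            if (goal.kind != "cover" and dd >= 0) or (goal.kind == "cover" and dd <= 0):
                blacklist.add(v)
                continue

            cp = state.checkpoint()
            gesture = SphereGesture(center=tuple(int(i) for i in ijk), radius_mm=radius_mm, dd_gy=dd)
            try:
                execute_tool(state, gesture, tau, n_r)
            except ValueError:
                blacklist.add(v)
                n_used += 1
                continue
            n_used += 1
            new_obj = _objective(state, spare_structure=goal.structure if goal.kind == "spare" else None)
            status = _quantec_status(state)
            broke_earlier = any(
                satisfied_before[k] and not status[k] for k in status
            )
            if new_obj < obj - 1e-9 and not broke_earlier:
                obj = new_obj
                obj_trace.append(obj)
                accepted += 1
                satisfied_before = status
            else:
                state.rollback(cp)
                blacklist.add(v)

        state.goal_report.append(
            {
                "goal": goal.name,
                "kind": goal.kind,
                "satisfied": _satisfied(state, goal),
                "instances_used": n_used,
                "accepted": accepted,
                "objective_trace": obj_trace,
            }
        )
    return state


def baseline_optimize(
    grid: VoxelGrid,
    vois: Dict[str, VOI],
    rx: Prescription,
    influence: DoseInfluence,
    weights: Optional[Dict[str, Tuple[float, float, float]]] = None,
    iters: int = 60,
    margin_mm: float = 5.0,
) -> PlanState:
    """Conventional fluence-map optimization: projected gradient descent.

    The objective is a weighted sum of piece-wise quadratic penalties
    per VOI, ``weight * mean(max(0, lower - d)^2 + max(0, d - upper)^2)``,
    minimized over non-negative bixel weights with a backtracking line
    search (objective never increases). Initialization is the scaled
    open field, so the run is fully deterministic.

    ``weights`` maps VOI name to (weight, lower Gy, upper Gy); the
    default prescribes the boost and PTV doses and bounds the OARs and
    normal tissue.
    """
    if weights is None:
        weights = {
            "boost": (1.0, rx.boost_gy, rx.boost_gy),
            "ptv": (1.0, rx.ptv_gy, rx.boost_gy),
            "rectum": (0.4, 0.0, 45.0),
            "bladder": (0.4, 0.0, 45.0),
            "body": (0.05, 0.0, 0.9 * rx.ptv_gy),
        }
    for name, (wgt, lo, hi) in weights.items():
        if wgt < 0:
            raise ValueError(f"negative weight for {name}")

    state = init_plan(grid, vois, rx, influence, margin_mm=margin_mm)
    w = state.fluence_flat.copy()
    D = influence.matrix_csc
    DT = D.T.tocsr()

    masks = {}
    for name in weights:
        m = vois[name].mask.copy()
        if name == "ptv":
            m = m & ~vois["boost"].mask  # boost handled by its own term
        if name == "body":
            m = m & ~vois["ptv"].mask
        masks[name] = np.flatnonzero(m.ravel())

    def obj_and_grad(wvec: np.ndarray):
        d = D @ wvec
        f = 0.0
        r = np.zeros_like(d)
        for name, (wgt, lo, hi) in weights.items():
            idx = masks[name]
            if idx.size == 0:
                continue
            dv = d[idx]
            under = np.maximum(0.0, lo - dv)
            over = np.maximum(0.0, dv - hi)
            f += wgt * float(under @ under + over @ over) / idx.size
            r[idx] += wgt * 2.0 * (over - under) / idx.size
        return f, r

    f, r = obj_and_grad(w)
    step = 1.0
    for _ in range(int(iters)):
        g = DT @ r
        # normalize step to the gradient scale on first use
        gnorm = float(np.linalg.norm(g))
        if gnorm == 0.0:
            break
        trial_step = step
        for _bt in range(30):
            w_new = np.maximum(0.0, w - trial_step * g)
            f_new, r_new = obj_and_grad(w_new)
            if f_new <= f:
                break
            trial_step *= 0.5
        if f_new > f:
            break
        if not np.isfinite(f_new):
            raise FloatingPointError("non-finite objective in baseline optimization")
        w, f, r = w_new, f_new, r_new
        step = trial_step * 2.0

    dose = (D @ w).reshape(grid.dims)
    return PlanState(
        grid=grid, vois=vois, rx=rx, influence=influence,
        fluence_flat=w, dose=dose, init_scale=state.init_scale,
    )


def save_state(state: PlanState, path) -> None:
    """Persist a plan state to an HDF5 container (bit-reproducible).

    Fluence and dose are stored exactly; the prescription, history and
    snapshot fluences travel along. Timestamps are disabled so saving
    the same state twice yields byte-identical files.
    """
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset("fluence", data=state.fluence_flat, track_times=False)
        f.create_dataset("dose", data=state.dose, track_times=False)
        f.attrs["ptv_gy"] = state.rx.ptv_gy
        f.attrs["boost_gy"] = state.rx.boost_gy
        f.attrs["init_scale"] = state.init_scale
        f.attrs["history_json"] = json.dumps(state.history, sort_keys=True)
        f.attrs["goal_report_json"] = json.dumps(state.goal_report, sort_keys=True)
        snaps = f.create_group("snapshots", track_order=True)
        for name in sorted(state.snapshots):
            snaps.create_dataset(name, data=state.snapshots[name], track_times=False)


def load_state(
    path,
    grid: VoxelGrid,
    vois: Dict[str, VOI],
    influence: DoseInfluence,
) -> PlanState:
    """Load a plan state saved by :func:`save_state`."""
    try:
        with h5py.File(path, "r") as f:
            fluence = f["fluence"][...]
            dose = f["dose"][...]
            rx = Prescription(ptv_gy=float(f.attrs["ptv_gy"]), boost_gy=float(f.attrs["boost_gy"]))
            history = json.loads(f.attrs["history_json"])
            goal_report = json.loads(f.attrs.get("goal_report_json", "[]"))
            init_scale = float(f.attrs["init_scale"])
            snapshots = {name: f["snapshots"][name][...] for name in f["snapshots"]}
    except (OSError, KeyError) as exc:
        raise IOError(f"corrupt or incompatible plan container {path}: {exc}") from exc
    return PlanState(
        grid=grid, vois=vois, rx=rx, influence=influence,
        fluence_flat=fluence, dose=dose, history=history,
        snapshots=snapshots, init_scale=init_scale, goal_report=goal_report,
    )
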