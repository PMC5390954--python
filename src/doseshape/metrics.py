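"""Plan-quality mathematics: DVH, DVH indicators, CI, HI, NTID, Quantec.

All metrics are voxel-exact (no interpolation) and deterministic. The
conformity index follows the van't Riet decomposition

    CI = CI1 * CI2 = (V_t,ref / V_t) * (V_t,ref / V_ref)

where ``V_t,ref`` is the target volume receiving at least the reference
dose (a threshold fraction of the prescription, default 95%), ``V_t``
the target volume, and ``V_ref`` the whole-body volume at or above the
reference dose. The homogeneity index is the population standard
deviation of dose inside a structure, in Gy. The non-tumor integral
dose is ``rho * volume * mean dose`` over the body-minus-PTV tissue, in
litre-Gy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DVHCurve",
    "dvh",
    "dose_at_volume",
    "volume_at_dose",
    "conformity",
    "homogeneity",
    "ntid",
    "quantec_check",
    "QUANTEC_CONSTRAINTS",
    "MetricsReport",
    "compute_report",
]

# Quantec dose-volume constraints for prostate IMRT: (structure, x Gy, limit %).
# Strict inequalities: V_x must stay *below* the limit.
QUANTEC_CONSTRAINTS: Tuple[Tuple[str, float, float], ...] = (
    ("rectum", 50.0, 50.0),
    ("rectum", 60.0, 35.0),
    ("rectum", 65.0, 25.0),
    ("rectum", 70.0, 20.0),
    ("rectum", 75.0, 15.0),
    ("bladder", 65.0, 50.0),
    ("bladder", 70.0, 35.0),
    ("bladder", 75.0, 25.0),
    ("bladder", 80.0, 15.0),
)


def _masked(dose: np.ndarray, mask: np.ndarray) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dose.shape != mask.shape:
        raise ValueError(f"dose shape {dose.shape} != mask shape {mask.shape}")
    vals = dose[mask]
    if vals.size == 0:
        raise ValueError("mask selects no voxels")
    return vals


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of volume >= each dose."""

    dose_gy: np.ndarray
    fraction: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"dose_gy": self.dose_gy, "fraction": self.fraction})


def dvh(dose: np.ndarray, mask: np.ndarray, bin_width_gy: float = 0.1) -> DVHCurve:
    """Exact cumulative >=-dose curve from the voxel doses of a structure."""
    vals = _masked(dose, mask)
    top = float(vals.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    frac = np.array([(vals >= e).mean() for e in edges])
    return DVHCurve(dose_gy=edges, fraction=frac)


def dose_at_volume(dose: np.ndarray, mask: np.ndarray, q_percent: float) -> float:
    """D_q%: the largest dose d such that at least q% of the VOI receives >= d.

    Voxel-exact: d is always one of the sampled voxel doses. D50% is the
    median dose indicator used in plan tables.
    """
    if not (0.0 < q_percent <= 100.0):
        raise ValueError(f"q must be in (0, 100], got {q_percent}")
    vals = np.sort(_masked(dose, mask))[::-1]
    k = int(np.ceil(q_percent / 100.0 * vals.size))
    return float(vals[k - 1])


def volume_at_dose(dose: np.ndarray, mask: np.ndarray, x_gy: float) -> float:
    """V_x: percent of the VOI receiving at least x Gy (inclusive)."""
    if x_gy < 0:
        raise ValueError("dose threshold must be non-negative")
    vals = _masked(dose, mask)
    return float(100.0 * (vals >= x_gy).mean())


def conformity(
    dose: np.ndarray,
    target: np.ndarray,
    body: np.ndarray,
    rx_gy: float,
    threshold_fraction: float = 0.95,
) -> Tuple[float, float, float]:
    """van't Riet conformity index (CI1, CI2, CI = CI1*CI2).

    The reference dose is ``threshold_fraction * rx_gy`` (default 95% of
    the prescription). If no body voxel reaches the reference dose all
    three indices are 0 by convention.
    """
    if rx_gy <= 0:
        raise ValueError("prescription must be positive")
    target = np.asarray(target, dtype=bool)
    body = np.asarray(body, dtype=bool)
    if not target.any():
        raise ValueError("target mask is empty")
    dose = np.asarray(dose, dtype=float)
    level = threshold_fraction * rx_gy
    v_t = int(target.sum())
    v_t_ref = int((target & (dose >= level)).sum())
    v_ref = int((body & (dose >= level)).sum())
    if v_ref == 0:
        return 0.0, 0.0, 0.0
    ci1 = v_t_ref / v_t
    ci2 = v_t_ref / v_ref
    return float(ci1), float(ci2), float(ci1 * ci2)


def homogeneity(dose: np.ndarray, mask: np.ndarray) -> float:
    """HI: population standard deviation of the dose inside a VOI, in Gy."""
    return float(np.std(_masked(dose, mask)))


def ntid(
    dose: np.ndarray,
    nontumor: np.ndarray,
    voxel_volume_mm3: float,
    rho: float = 1.0,
) -> float:
    """Non-tumor integral dose, litre-Gy: rho * (V/N) * sum of voxel doses.

    ``V/N`` is the volume of one voxel; with unit density the NTID is
    simply the tissue volume in litres times the mean dose.
    """
    vals = _masked(dose, nontumor)
    voxel_litre = voxel_volume_mm3 * 1e-6
    return float(rho * voxel_litre * vals.sum())


def quantec_check(
    dose: np.ndarray,
    rectum: np.ndarray,
    bladder: np.ndarray,
) -> pd.DataFrame:
    """Evaluate the nine Quantec dose-volume constraints (strict bounds).

    Returns a frame with one row per constraint: structure, threshold
    x (Gy), observed V_x (%), limit (%), and pass (V_x strictly below
    the limit).
    """
    masks = {"rectum": rectum, "bladder": bladder}
    rows = []
    for organ, x, limit in QUANTEC_CONSTRAINTS:
        vx = volume_at_dose(dose, masks[organ], x)
        rows.append(
            {"structure": organ, "x_gy": x, "vx_percent": vx, "limit_percent": limit, "passed": bool(vx < limit)}
        )
    return pd.DataFrame(rows)


@dataclass
class MetricsReport:
    """Full plan-quality report for one dose distribution."""

    per_voi: pd.DataFrame  # mean, median (D50%), D98%, D2%, HI per VOI
    conformity: Dict[str, Dict[str, float]]  # per target: CI1, CI2, CI
    vx_table: pd.DataFrame  # OAR V_x values (%)
    ntid_litre_gy: float
    quantec: pd.DataFrame
    dvh_curves: Dict[str, DVHCurve] = field(default_factory=dict)

    @property
    def all_quantec_pass(self) -> bool:
        return bool(self.quantec["passed"].all())

    def to_dict(self) -> Dict:
        return {
            "per_voi": self.per_voi.to_dict(orient="records"),
            "conformity": self.conformity,
            "vx_table": self.vx_table.to_dict(orient="records"),
            "ntid_litre_gy": self.ntid_litre_gy,
            "quantec": self.quantec.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        """Flat CSV: one row per (VOI, indicator)."""
        rows: List[Dict] = []
        for rec in self.per_voi.to_dict(orient="records"):
            voi = rec.pop("voi")
            for k, v in rec.items():
                rows.append({"voi": voi, "indicator": k, "value": v})
        for tgt, cis in self.conformity.items():
            for k, v in cis.items():
                rows.append({"voi": tgt, "indicator": k, "value": v})
        for rec in self.vx_table.to_dict(orient="records"):
            rows.append(
                {"voi": rec["structure"], "indicator": f"V{rec['x_gy']:g}", "value": rec["vx_percent"]}
            )
        rows.append({"voi": "body-ptv", "indicator": "NTID_litre_gy", "value": self.ntid_litre_gy})
        pd.DataFrame(rows).to_csv(path, index=False)


def compute_report(
    dose: np.ndarray,
    grid,
    vois: Dict[str, "object"],
    rx,
    threshold_fraction: float = 0.95,
    bin_width_gy: float = 0.5,
    with_dvh: bool = False,
) -> MetricsReport:
    """Compute the standard study report for one plan.

    ``vois`` maps names to VOI objects (body, ptv, boost, rectum,
    bladder); ``rx`` is the Prescription; ``grid`` provides the voxel
    volume for the NTID. PTV indicators are computed on the whole PTV
    including the boost region.
    """
    from .phantom import nontumor_mask

    masks = {name: v.mask for name, v in vois.items()}
    per_voi_rows = []
    for name in ("boost", "ptv", "rectum", "bladder", "body"):
        if name not in masks:
            continue
        m = masks[name]
        per_voi_rows.append(
            {
                "voi": name,
                "mean_gy": float(np.mean(dose[m])),
                "median_gy": dose_at_volume(dose, m, 50.0),
                "d98_gy": dose_at_volume(dose, m, 98.0),
                "d2_gy": dose_at_volume(dose, m, 2.0),
                "hi_gy": homogeneity(dose, m),
            }
        )

    conf = {}
    for tgt, rx_gy in (("boost", rx.boost_gy), ("ptv", rx.ptv_gy)):
        ci1, ci2, ci = conformity(dose, masks[tgt], masks["body"], rx_gy, threshold_fraction)
        conf[tgt] = {"ci1": ci1, "ci2": ci2, "ci": ci}

    vx_rows = []
    for organ, levels in (("rectum", (50, 60, 65, 70, 75)), ("bladder", (65, 70, 75, 80))):
        for x in levels:
            vx_rows.append(
                {"structure": organ, "x_gy": float(x), "vx_percent": volume_at_dose(dose, masks[organ], x)}
            )

    nt = nontumor_mask(vois["body"], vois["ptv"])
    report = MetricsReport(
        per_voi=pd.DataFrame(per_voi_rows),
        conformity=conf,
        vx_table=pd.DataFrame(vx_rows),
        ntid_litre_gy=ntid(dose, nt, grid.voxel_volume_mm3),
        quantec=quantec_check(dose, masks["rectum"], masks["bladder"]),
    )
    if with_dvh:
        for name, v in vois.items():
            report.dvh_curves[name] = dvh(dose, v.mask, bin_width_gy)
    return report


def plot_dvh(curves: Dict[str, DVHCurve], path=None):
    """Plot cumulative DVHs for a set of structures (one line each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, c in curves.items():
        ax.plot(c.dose_gy, 100.0 * c.fraction, label=name)
    ax.set_xlabel("Dose (Gy)")
    ax.set_ylabel("Volume (%)")
    ax.set_ylim(0, 105)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
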