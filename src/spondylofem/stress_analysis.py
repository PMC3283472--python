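"""Stress interpretation in the growth-plate local frame.

All stresses are expressed in a local frame anchored at the middle of
the L5 growth plate: the x'y' plane lies on the plate, y' is the
in-plane sagittal (anterior) direction and z' is the plate normal
opposed to gravity.  A negative normal stress sigma_n means compression
of the plate; a positive slip shear tau_slip (the z'y' component) means
the traction on the cranial face points anteriorly, i.e. promotes
anterior slippage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PlateFrame

REGIONS = ("anterior", "posterior", "lateral-left", "lateral-right", "dome")


def build_plate_frame(plate_nodes: np.ndarray,
                      gravity_direction=(0.0, 0.0, -1.0),
                      anterior_hint=(1.0, 0.0, 0.0)) -> PlateFrame:
    """Fit the local plate frame to a cloud of growth-plate nodes.

    Origin = node centroid; z' = best-fit plane normal with positive
    component opposite gravity; y' = projection of the sagittal anterior
    direction onto the plate; x' = y' x z' (to the patient's right).
    """
    pts = np.asarray(plate_nodes, dtype=float).reshape(-1, 3)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 plate nodes")
    origin = pts.mean(axis=0)
    centered = pts - origin
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("plate nodes are collinear; cannot fit a plane")
    z = vt[2]
    g = np.asarray(gravity_direction, dtype=float)
    if z @ (-g) < 0:
        z = -z
    a = np.asarray(anterior_hint, dtype=float)
    y = a - (a @ z) * z
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise ValueError("anterior direction is normal to the plate")
    y = y / ny
    x = np.cross(y, z)
    return PlateFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def transform_to_plate_frame(stress_field: np.ndarray, frame: PlateFrame
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotate stress tensors into the plate frame.

    Returns (rotated tensors, sigma_n, tau_slip) where sigma_n is the
    plate-normal component sigma'_z'z' and tau_slip the sagittal shear
    sigma'_z'y' (positive = slip-promoting anterior traction on the
    cranial face).
    """
    sig = np.asarray(stress_field, dtype=float)
    single = sig.ndim == 2
    if single:
        sig = sig[None]
    R = frame.rotation
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ValueError("plate frame axes are not orthonormal")
    rotated = np.einsum("ab,nbc,dc->nad", R, sig, R)
    sigma_n = rotated[:, 2, 2].copy()
    tau_slip = rotated[:, 2, 1].copy()
    if single:
        return rotated[0], sigma_n[0], tau_slip[0]
    return rotated, sigma_n, tau_slip


def partition_plate_regions(centroids: np.ndarray, frame: PlateFrame,
                            dome_height_quantile: float = 0.8,
                            lateral_quantile: float = 0.7) -> np.ndarray:
    """Label element centroids as anterior / posterior / lateral bands /
    dome.

    Dome = elements whose plate-normal elevation z' exceeds the stated
    quantile of the structure's surface; lateral bands by |x'| quantile;
    the rest split anterior/posterior by the sign of y'.  Coordinates
    are centered on the structure's own centroid first, so the labels
    stay anatomical for structures displaced by slip or pelvic rotation.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 3)
    if pts.shape[0] == 0:
        raise ValueError("empty structure: no element centroids to label")
    local = frame.to_local(pts)
    local = local - local.mean(axis=0)
    labels = np.empty(pts.shape[0], dtype=object)
    z_cut = np.quantile(local[:, 2], dome_height_quantile)
    x_cut = np.quantile(np.abs(local[:, 0]), lateral_quantile)
    for k, (x, y, z) in enumerate(local):
        if z > z_cut:
            labels[k] = "dome"
        elif abs(x) >= x_cut and x < 0:
            labels[k] = "lateral-left"   # patient's left is -x'
        elif abs(x) >= x_cut:
            labels[k] = "lateral-right"
        elif y > 0:
            labels[k] = "anterior"
        else:
            labels[k] = "posterior"
    return labels


@dataclass
class StressSummary:
    """Per-region normal/shear stress statistics for one structure."""

    structure: str
    table: pd.DataFrame    # rows: region; cols: stats (MPa)
    missing_regions: list[str] = field(default_factory=list)

    def stat(self, region: str, name: str) -> float:
        return float(self.table.loc[region, name])

    def overall(self, name: str) -> float:
        if name.startswith("max_sigma"):
            v = self.table["max_sigma_n"]
            return float(v.iloc[np.argmax(np.abs(v.to_numpy()))])
        if name.startswith("max_tau"):
            return float(self.table["max_tau_slip"].max())
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        df = self.table.reset_index().rename(columns={"index": "region"})
        df.insert(0, "structure", self.structure)
        return df


def summarize_stresses(sigma_n: np.ndarray, tau_slip: np.ndarray,
                       region_labels: np.ndarray,
                       structure: str = "structure") -> StressSummary:
    """Per-region max/mean of sigma_n and tau_slip.

    The normal-stress maximum is taken by magnitude (keeping its sign,
    so a dominating compression reports negative); the slip shear
    maximum is the signed maximum (most slip-promoting).  Regions with
    no elements are flagged in ``missing_regions`` rather than dropped
    silently.
    """
    sigma_n = np.asarray(sigma_n, dtype=float)
    tau_slip = np.asarray(tau_slip, dtype=float)
    labels = np.asarray(region_labels)
    if not (sigma_n.shape == tau_slip.shape == labels.shape):
        raise ValueError("components and region labels differ in length")
    rows = {}
    missing = []
    for region in REGIONS:
        mask = labels == region
        if not mask.any():
            missing.append(region)
            continue
        s = sigma_n[mask]
        t = tau_slip[mask]
        rows[region] = {
            "max_sigma_n": s[np.argmax(np.abs(s))],
            "mean_sigma_n": s.mean(),
            "max_tau_slip": t.max(),
            "mean_tau_slip": t.mean(),
            "n_elements": int(mask.sum()),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return StressSummary(structure=structure, table=table,
                         missing_regions=missing)


def percent_difference(value_a: float, value_b: float) -> float:
    """Signed relative difference (a - b) / |b| in percent."""
    if value_b == 0:
        raise ValueError("reference value must be nonzero")
    return float((value_a - value_b) / abs(value_b) * 100.0)


def summaries_to_csv(summaries: list[StressSummary], path: str | Path) -> None:
    """Long-format CSV: structure, region, stat, value_MPa."""
    rows = []
    for s in summaries:
        for region, row in s.table.iterrows():
            for stat, value in row.items():
                if stat == "n_elements":
                    continue
                rows.append((s.structure, region, stat, value))
    pd.DataFrame(rows, columns=["structure", "region", "stat", "value_MPa"]
                 ).to_csv(path, index=False)
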