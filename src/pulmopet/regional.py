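"""Regional (ROI-level) quantities of the perfusion/blood-volume analysis.

The lung field is partitioned into 15 isogravitational layers x 2 axial
sections = 30 ROIs. Per ROI the derived quantities are::

    F_tis   = 1 - F_gas - F_b                  tissue fraction
    F_tis,n = F_tis / mean(F_tis)              normalized tissue fraction
    Q_n     = Q_r / mean(Q_r) / F_tis,n        normalized perfusion
    F_bn    = F_b / mean(F_b) / F_tis,n        normalized blood volume

with all means taken over the 30 ROIs of one animal under one condition, so
normalized quantities account for regional lung tissue density. Longitudinal
(injury vs baseline) comparisons rescale the injury values by whole-animal
ratios: ``Q_a = Q_n * CO_INJ/CO_BL`` and ``F_ba = F_bn * V_B,INJ/V_B,BL``,
where the total pulmonary blood volume ``V_B = sum(F_b * roi_volume)``.
Baseline rows carry ``Q_a = Q_n`` and ``F_ba = F_bn``. Animals without a
usable injury cardiac output are excluded from the adjusted analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "partition_rois",
    "save_label_map",
    "load_mask",
    "tissue_fractions",
    "normalize_metrics",
    "total_blood_volume",
    "build_regional_table",
    "adjust_longitudinal",
]

log = logging.getLogger("pulmopet.regional")


def partition_rois(lung_mask: np.ndarray, n_layers: int = 15, n_axial: int = 2,
                   vertical_axis: int = 0, axial_axis: int = 2,
                   method: str = "height") -> np.ndarray:
    """Label each mask voxel with one of ``n_layers * n_axial`` ROIs.

    Vertical cuts are isogravitational: by default equally spaced in
    geometric height across the mask's vertical bounding box
    (``method='height'``); ``method='counts'`` instead uses equal-count
    height quantiles. The axial cut splits the mask's axial extent into
    contiguous groups. Returns an integer label map (0 outside the mask,
    1..n_layers*n_axial inside), with label = (layer-1)*n_axial + section.
    Layer 1 is at the low-coordinate (dependent) end of the vertical axis.
    """
    mask = np.asarray(lung_mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("lung_mask must be 3-D")
    if not mask.any():
        raise ValueError("empty lung mask")
    if vertical_axis == axial_axis:
        raise ValueError("vertical and axial axes must differ")

    idx = np.nonzero(mask)
    v = idx[vertical_axis].astype(float)
    a = idx[axial_axis].astype(float)
    vmin, vmax = v.min(), v.max()
    if vmax - vmin + 1 < n_layers:
        raise ValueError(f"mask spans {int(vmax - vmin + 1)} voxels vertically; "
                         f"cannot cut {n_layers} layers")
    if method == "height":
        # voxel centers spread over [vmin, vmax+1); equal geometric slabs
        frac = (v - vmin + 0.5) / (vmax - vmin + 1.0)
    elif method == "counts":
        order = np.argsort(v, kind="stable")
        rank = np.empty(v.size)
        rank[order] = np.arange(v.size)
        frac = (rank + 0.5) / v.size
    else:
        raise ValueError(f"unknown partition method {method!r}")
    layer = np.clip((frac * n_layers).astype(int), 0, n_layers - 1)

    amin, amax = a.min(), a.max()
    afrac = (a - amin + 0.5) / (amax - amin + 1.0)
    section = np.clip((afrac * n_axial).astype(int), 0, n_axial - 1)

    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[idx] = layer * n_axial + section + 1
    return labels


def save_label_map(labels: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write an ROI label map as NIfTI (identity affine by default)."""
    import nibabel as nib
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int32), affine), str(path))


def load_mask(path) -> np.ndarray:
    """Read a volumetric lung mask (any nonzero voxel is inside)."""
    import nibabel as nib
    return np.asarray(nib.load(str(path)).get_fdata()) != 0


def tissue_fractions(F_gas: np.ndarray, F_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """F_tis = 1 - F_gas - F_b and its mean-normalized counterpart."""
    F_gas = np.asarray(F_gas, dtype=float)
    F_b = np.asarray(F_b, dtype=float)
    if np.any((F_gas < 0) | (F_gas > 1)) or np.any((F_b < 0) | (F_b > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    over = F_gas + F_b > 1 + 1e-12
    if np.any(over):
        raise ValueError(f"F_gas + F_b > 1 for ROI indices {np.where(over)[0].tolist()}")
    F_tis = 1.0 - F_gas - F_b
    m = F_tis.mean()
    if m <= 0:
        raise ValueError("mean tissue fraction is not positive")
    return F_tis, F_tis / m


def normalize_metrics(Q_r: np.ndarray, F_b: np.ndarray, F_tis_n: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Q_n and F_bn, normalized within one animal-condition."""
    Q_r = np.asarray(Q_r, dtype=float)
    F_b = np.asarray(F_b, dtype=float)
    F_tis_n = np.asarray(F_tis_n, dtype=float)
    if Q_r.mean() <= 0:
        raise ValueError("mean perfusion is zero (dead study)")
    if F_b.mean() <= 0:
        raise ValueError("mean blood fraction is zero")
    Q_n = Q_r / Q_r.mean() / F_tis_n
    F_bn = F_b / F_b.mean() / F_tis_n
    return Q_n, F_bn


def total_blood_volume(F_b: np.ndarray, roi_volume: np.ndarray) -> float:
    """V_B = sum over ROIs of blood fraction times ROI volume (ml)."""
    F_b = np.asarray(F_b, dtype=float)
    vol = np.asarray(roi_volume, dtype=float)
    if np.any(vol <= 0):
        raise ValueError("ROI volumes must be positive")
    return float(np.sum(F_b * vol))


def build_regional_table(meta: pd.DataFrame, F_gas: np.ndarray, F_b: np.ndarray,
                         Q_r: np.ndarray) -> pd.DataFrame:
    """Assemble one animal-condition regional table with all derived columns.

    ``meta`` must carry animal, condition, layer_index, axial_section,
    height_fraction, roi_volume (one row per ROI, measured quantities given
    per ROI in the same order).
    """
    F_tis, F_tis_n = tissue_fractions(F_gas, F_b)
    Q_n, F_bn = normalize_metrics(Q_r, F_b, F_tis_n)
    out = meta.copy()
    out["F_gas"] = np.asarray(F_gas, dtype=float)
    out["F_b"] = np.asarray(F_b, dtype=float)
    out["Q_r"] = np.asarray(Q_r, dtype=float)
    out["F_tis"] = F_tis
    out["F_tis_n"] = F_tis_n
    out["Q_n"] = Q_n
    out["F_bn"] = F_bn
    return out


def adjust_longitudinal(table_bl: pd.DataFrame, table_inj: pd.DataFrame,
                        hemodynamics: pd.DataFrame) -> pd.DataFrame:
    """Fill Q_a / F_ba referenced to baseline.

    ``hemodynamics`` needs columns animal, CO_BL, CO_INJ (l/min). V_B ratios
    are computed from each table's F_b and roi_volume. Baseline rows get
    ``Q_a = Q_n`` and ``F_ba = F_bn``; injury rows are scaled by the CO and
    V_B ratios. Animals with a missing or nonpositive injury CO are excluded
    from the output (and logged); they remain in the normalized tables.
    """
    hemo = hemodynamics.set_index("animal")
    out = []
    for animal, bl in table_bl.groupby("animal"):
        inj = table_inj[table_inj["animal"] == animal]
        if inj.empty:
            raise ValueError(f"animal {animal}: injury table missing")
        if animal not in hemo.index:
            raise ValueError(f"animal {animal}: no hemodynamic record")
        co_bl = hemo.loc[animal, "CO_BL"]
        co_inj = hemo.loc[animal, "CO_INJ"]
        if pd.isna(co_inj):
            log.info("animal %s excluded from adjusted analysis (missing injury CO)",
                     animal)
            continue
        if co_bl <= 0 or co_inj <= 0:
            raise ValueError(f"animal {animal}: nonpositive cardiac output")
        vb_bl = total_blood_volume(bl["F_b"].to_numpy(), bl["roi_volume"].to_numpy())
        vb_inj = total_blood_volume(inj["F_b"].to_numpy(), inj["roi_volume"].to_numpy())
        if vb_bl <= 0 or vb_inj <= 0:
            raise ValueError(f"animal {animal}: nonpositive blood volume")
        bl = bl.copy()
        bl["Q_a"] = bl["Q_n"]
        bl["F_ba"] = bl["F_bn"]
        inj = inj.copy()
        inj["Q_a"] = inj["Q_n"] * (co_inj / co_bl)
        inj["F_ba"] = inj["F_bn"] * (vb_inj / vb_bl)
        out.append(bl)
        out.append(inj)
    if not out:
        return pd.DataFrame(columns=list(table_bl.columns) + ["Q_a", "F_ba"])
    return pd.concat(out, ignore_index=True)
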