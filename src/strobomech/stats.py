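"""Population statistics, validation metrics and the error budget.

The statistical unit is the DIC box (2.57 x 2.57 um^2 at the default pixel
pitch): every valid box fully inside a (warped) cell mask contributes one
record with its modulus components, channel label, edge distance and optional
cell id.  Box-based statistics avoid error-prone per-cell segmentation and,
on comparable scenes, agree with cell-based statistics.

Moduli populations are typically non-normal (Shapiro-Wilk), so group
differences are assessed with the two-sided Mann-Whitney U test.  The error
budget combines the flow-field residual error, the blank-area strain noise
and their quadrature propagation into the modulus, plus the depth-of-field
systematic bound on the stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mechanics import ModulusMaps, StrainMaps

__all__ = [
    "ErrorBudget",
    "build_box_table",
    "cell_based_table",
    "population_stats",
    "edge_profile",
    "loss_vs_storage",
    "blank_strain_noise",
    "propagate_errors",
    "depth_of_field_bias",
]

_VALUE_COLS = ("g_abs", "g_storage", "g_loss")


@dataclass
class ErrorBudget:
    """Relative errors of the analysis chain (fractions, not percent)."""

    rel_flow_error: float
    rel_strain_error: float
    rel_modulus_error: float
    systematic_stress_error_bound: float

    def as_dict(self) -> dict[str, float]:
        return {
            "rel_flow_error": self.rel_flow_error,
            "rel_strain_error": self.rel_strain_error,
            "rel_modulus_error": self.rel_modulus_error,
            "systematic_stress_error_bound": self.systematic_stress_error_bound,
        }


def build_box_table(
    moduli: ModulusMaps,
    box_centers_x: np.ndarray,
    box_centers_y: np.ndarray,
    box_size: int,
    affine: np.ndarray,
    channel_masks: dict[str, np.ndarray],
    edge_maps: dict[str, np.ndarray] | None = None,
    *,
    fluo_pixel_pitch_um: float = 1.0,
    instance_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """One record per valid DIC box, labelled against the fluorescence masks.

    A box receives a channel label only when its entire ``box_size`` x
    ``box_size`` footprint maps inside that channel's mask ("unassigned"
    otherwise — boundary boxes never dilute a population).  Edge distance is
    sampled from the channel's distance map at the warped box centre;
    ``cell_id`` comes from an optional fast-camera instance-label image.
    """
    affine = np.asarray(affine, dtype=float)
    nby, nbx = moduli.g.shape
    cx, cy = np.meshgrid(box_centers_x, box_centers_y)
    half = (box_size - 1) / 2.0
    offsets = np.arange(-half, half + 1.0)
    foot_dx, foot_dy = np.meshgrid(offsets, offsets)

    labels = np.full((nby, nbx), "unassigned", dtype=object)
    edge = np.full((nby, nbx), np.nan)
    for name, mask in channel_masks.items():
        mask = np.asarray(mask, dtype=bool)
        inside_all = np.ones((nby, nbx), dtype=bool)
        for dx, dy in zip(foot_dx.ravel(), foot_dy.ravel()):
            fx = affine[0, 0] * (cx + dx) + affine[0, 1] * (cy + dy) + affine[0, 2]
            fy = affine[1, 0] * (cx + dx) + affine[1, 1] * (cy + dy) + affine[1, 2]
            xi = np.round(fx).astype(int)
            yi = np.round(fy).astype(int)
            ok = (xi >= 0) & (xi < mask.shape[1]) & (yi >= 0) & (yi < mask.shape[0])
            inside = np.zeros((nby, nbx), dtype=bool)
            inside[ok] = mask[yi[ok], xi[ok]]
            inside_all &= inside
        labels[inside_all] = name
        if edge_maps is not None and name in edge_maps:
            fx = affine[0, 0] * cx + affine[0, 1] * cy + affine[0, 2]
            fy = affine[1, 0] * cx + affine[1, 1] * cy + affine[1, 2]
            xi = np.clip(np.round(fx).astype(int), 0, mask.shape[1] - 1)
            yi = np.clip(np.round(fy).astype(int), 0, mask.shape[0] - 1)
            edge[inside_all] = edge_maps[name][yi, xi][inside_all]

    cell_id = np.zeros((nby, nbx), dtype=int)
    if instance_labels is not None:
        xi = np.clip(np.round(cx).astype(int), 0, instance_labels.shape[1] - 1)
        yi = np.clip(np.round(cy).astype(int), 0, instance_labels.shape[0] - 1)
        cell_id = instance_labels[yi, xi]

    fx = affine[0, 0] * cx + affine[0, 1] * cy + affine[0, 2]
    fy = affine[1, 0] * cx + affine[1, 1] * cy + affine[1, 2]
    table = pd.DataFrame(
        {
            "box_row": np.repeat(np.arange(nby), nbx),
            "box_col": np.tile(np.arange(nbx), nby),
            "x_um": (fx * fluo_pixel_pitch_um).ravel(),
            "y_um": (fy * fluo_pixel_pitch_um).ravel(),
            "label": labels.ravel(),
            "g_abs": moduli.amplitude.ravel(),
            "g_storage": moduli.storage.ravel(),
            "g_loss": moduli.loss.ravel(),
            "edge_dist_um": edge.ravel(),
            "cell_id": cell_id.ravel(),
            "valid": moduli.valid.ravel(),
        }
    )
    return table[table["valid"]].drop(columns="valid").reset_index(drop=True)


def cell_based_table(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse the DIC-box table to one record per cell (cell-based statistics).

    Requires ``cell_id`` > 0 (an instance segmentation); each cell keeps its
    majority channel label and the mean of every modulus component over its
    boxes.  Cell-based and box-based statistics agree on comparable scenes,
    but only the cell-based standard error of the mean is biologically
    meaningful.
    """
    df = table[(table["cell_id"] > 0) & (table["label"] != "unassigned")]
    if df.empty:
        return pd.DataFrame(columns=["cell_id", "label", "n_boxes", *_VALUE_COLS])
    rows = []
    for cid, grp in df.groupby("cell_id"):
        rows.append(
            {
                "cell_id": int(cid),
                "label": grp["label"].mode().iloc[0],
                "n_boxes": int(len(grp)),
                **{c: float(grp[c].mean()) for c in _VALUE_COLS},
                "edge_dist_um": float(grp["edge_dist_um"].mean()),
            }
        )
    return pd.DataFrame(rows)


def _shapiro_p(values: np.ndarray, max_n: int = 5000) -> float:
    """Shapiro-Wilk normality p-value; large samples use the leading max_n
    values (deterministic) to stay within the test's validated range."""
    v = values[np.isfinite(values)]
    if v.size < 3:
        return np.nan
    return float(sps.shapiro(v[:max_n]).pvalue)


def population_stats(
    table: pd.DataFrame,
    group_by: str = "label",
    value_cols: tuple[str, ...] = _VALUE_COLS,
    *,
    min_group_size: int = 20,
    exclude_unassigned: bool = True,
) -> dict:
    """Per-group summaries plus normality and pairwise Mann-Whitney tests.

    Outliers (beyond 1.5 x IQR) are reported as plot whisker bounds only and
    are never removed from the test samples.  With a single group the tests
    are skipped.
    """
    df = table
    if exclude_unassigned and group_by == "label":
        df = df[df["label"] != "unassigned"]
    groups = sorted(df[group_by].unique())
    summary: dict = {"groups": {}, "tests": {}}
    for g in groups:
        rows = df[df[group_by] == g]
        entry: dict = {"n": int(len(rows))}
        for col in value_cols:
            v = rows[col].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            iqr = q3 - q1
            entry[col] = {
                "median": float(med),
                "mean": float(v.mean()),
                "q1": float(q1),
                "q3": float(q3),
                "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
                "shapiro_p": _shapiro_p(v),
                "whisker_lo": float(q1 - 1.5 * iqr),
                "whisker_hi": float(q3 + 1.5 * iqr),
            }
        summary["groups"][str(g)] = entry
    testable = [
        g for g in groups if len(df[df[group_by] == g]) >= min_group_size
    ]
    if len(testable) >= 2:
        for i, a in enumerate(testable):
            for b in testable[i + 1 :]:
                pair: dict = {}
                for col in value_cols:
                    va = df.loc[df[group_by] == a, col].dropna()
                    vb = df.loc[df[group_by] == b, col].dropna()
                    res = sps.mannwhitneyu(va, vb, alternative="two-sided")
                    pair[col] = {"U": float(res.statistic), "p": float(res.pvalue)}
                summary["tests"][f"{a} vs {b}"] = pair
    return summary


def edge_profile(
    table: pd.DataFrame,
    bin_width_um: float = 2.0,
    value_col: str = "g_abs",
) -> pd.DataFrame:
    """Binned mean of a modulus component versus distance to the cell edge.

    Returns one row per (label, bin) with the bin centre, mean, SEM and count;
    groups without edge distances simply contribute no rows.
    """
    df = table[np.isfinite(table["edge_dist_um"]) & np.isfinite(table[value_col])]
    if df.empty:
        return pd.DataFrame(columns=["label", "bin_center_um", "mean", "sem", "n"])
    edges = np.arange(0.0, df["edge_dist_um"].max() + bin_width_um, bin_width_um)
    if edges.size < 2:
        edges = np.array([0.0, bin_width_um])
    out = []
    for label, rows in df.groupby("label"):
        idx = np.digitize(rows["edge_dist_um"], edges) - 1
        for k in range(edges.size - 1):
            v = rows[value_col].to_numpy()[idx == k]
            if v.size == 0:
                continue
            out.append(
                {
                    "label": label,
                    "bin_center_um": 0.5 * (edges[k] + edges[k + 1]),
                    "mean": float(v.mean()),
                    "sem": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan,
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(out)


def loss_vs_storage(table: pd.DataFrame) -> pd.DataFrame:
    """Paired (G', G'') values with a Gaussian-kernel local density estimate.

    The density column colours scatter plots of the loss-versus-storage
    distribution (the reference line of interest is G'' = G').  Degenerate
    tiny samples fall back to a uniform density instead of failing.
    """
    df = table[np.isfinite(table["g_storage"]) & np.isfinite(table["g_loss"])].copy()
    if df.empty:
        df["density"] = pd.Series(dtype=float)
        return df
    pts = df[["g_storage", "g_loss"]].to_numpy().T
    try:
        density = sps.gaussian_kde(pts)(pts)
    except (np.linalg.LinAlgError, ValueError):
        density = np.ones(pts.shape[1]) / pts.shape[1]
    df["density"] = density
    return df


def blank_strain_noise(
    strains: StrainMaps,
    blank_boxes: np.ndarray,
    cell_boxes: np.ndarray,
    *,
    min_blank_boxes: int = 100,
) -> float:
    """Strain noise floor: median strain amplitude in a blank region (no
    cells, no tracers — the static dish bottom) relative to the median over
    cell-labelled boxes.  The blank and cell selections must be disjoint."""
    blank_boxes = np.asarray(blank_boxes, dtype=bool)
    cell_boxes = np.asarray(cell_boxes, dtype=bool)
    if (blank_boxes & cell_boxes).any():
        raise ValueError("blank region overlaps cell-labelled boxes")
    if (blank_boxes & strains.valid).sum() < min_blank_boxes:
        raise ValueError(f"blank region smaller than {min_blank_boxes} valid boxes")
    amp = np.hypot(np.abs(strains.gamma_p), np.abs(strains.gamma_s))
    blank = np.nanmedian(amp[blank_boxes & strains.valid])
    cells = np.nanmedian(amp[cell_boxes & strains.valid])
    if not np.isfinite(cells) or cells <= 0:
        raise ValueError("no valid cell-labelled strains to compare against")
    return float(blank / cells)


def propagate_errors(rel_flow_error: float, rel_strain_error: float) -> float:
    """Quadrature propagation of stress and strain errors into the modulus:
    ``sqrt(a^2 + b^2)`` for G = sigma / gamma with independent relative errors."""
    if rel_flow_error < 0 or rel_strain_error < 0:
        raise ValueError("relative errors must be non-negative")
    return float(np.hypot(rel_flow_error, rel_strain_error))


def depth_of_field_bias(depth_of_field_um: float, bead_radius_um: float) -> float:
    """Systematic relative stress-error bound from tracer defocus.

    Tracers assumed at z = R_b may sit anywhere within the depth of field,
    biasing the inferred velocity gradient by up to ``depth_of_field / R_b``
    (mitigated in practice by sedimentation of slightly dense tracers).
    """
    if bead_radius_um <= 0:
        raise ValueError("bead radius must be positive")
    if depth_of_field_um < 0:
        raise ValueError("depth of field must be non-negative")
    return float(depth_of_field_um / bead_radius_um)
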