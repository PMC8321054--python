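"""Segmentation evaluation: overlap and surface-distance metrics, volume
agreement, and per-structure report aggregation.

Definitions
-----------
DSC(G, P) = 2|G ∩ P| / (|G| + |P|)                       (overlap, in [0,1])
HD(G, P)  = max over one boundary of the min Euclidean distance (mm) to
            the other; `directed` uses G→P only, `symmetric` (default)
            the max of both directions.
ASD(G, P) = symmetric average of nearest-boundary distances, normalised
            by the total number of boundary voxels, in mm.

Boundary voxels are foreground voxels with at least one background
6-neighbour; the volume border counts as background. Distances are
computed with an exact Euclidean distance transform using the
anisotropic voxel spacing.

Bland–Altman agreement: for paired volume measurements the bias is the
mean signed difference and the limits of agreement are bias ± 1.96·SD
(SD with n−1 denominator). With differences taken as (reference −
automated), a negative bias means the automated method overestimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import LabelVolume

__all__ = [
    "boundary_voxels",
    "dsc",
    "hausdorff",
    "asd",
    "bland_altman",
    "BlandAltmanResult",
    "MetricsReport",
    "evaluate_cases",
    "evaluate_run",
    "bland_altman_plot",
]

_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def _as_binary(mask) -> np.ndarray:
    m = np.asarray(mask)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be binary")
        m = m.astype(bool)
    return m


def boundary_voxels(mask) -> np.ndarray:
    """Boolean grid of foreground voxels with a background 6-neighbour.

    The volume border counts as background, so a full-grid mask has all
    its border-face voxels on the boundary.
    """
    m = _as_binary(mask)
    if not m.any():
        return np.zeros_like(m)
    interior = ndimage.binary_erosion(m, structure=_SIX_CONN, border_value=0)
    return m & ~interior


def _check_shapes(g, p) -> tuple[np.ndarray, np.ndarray]:
    g, p = _as_binary(g), _as_binary(p)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    return g, p


def dsc(g, p) -> float:
    """Dice similarity coefficient; both-empty is defined as 1.0."""
    g, p = _check_shapes(g, p)
    sg, sp = int(g.sum()), int(p.sum())
    if sg == 0 and sp == 0:
        return 1.0
    return 2.0 * int((g & p).sum()) / (sg + sp)


def _surface_distances(
    a_boundary: np.ndarray, b_boundary: np.ndarray, spacing
) -> np.ndarray:
    """Distances (mm) from each voxel of a's boundary to b's boundary."""
    dt = ndimage.distance_transform_edt(~b_boundary, sampling=spacing)
    return dt[a_boundary]


def hausdorff(g, p, spacing=(1.0, 1.0, 1.0), mode: str = "symmetric") -> float:
    """Hausdorff distance between object boundaries, in mm."""
    g, p = _check_shapes(g, p)
    if not g.any() or not p.any():
        raise ValueError("Hausdorff distance requires two non-empty masks")
    bg, bp = boundary_voxels(g), boundary_voxels(p)
    d_gp = _surface_distances(bg, bp, spacing).max()
    if mode == "directed":
        return float(d_gp)
    if mode == "symmetric":
        d_pg = _surface_distances(bp, bg, spacing).max()
        return float(max(d_gp, d_pg))
    raise ValueError(f"unknown mode {mode!r}")


def asd(g, p, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric average surface distance in mm.

    Sum of nearest-boundary distances in both directions, divided by the
    total number of boundary voxels (N_G + N_P).
    """
    g, p = _check_shapes(g, p)
    if not g.any() or not p.any():
        raise ValueError("average surface distance requires two non-empty masks")
    bg, bp = boundary_voxels(g), boundary_voxels(p)
    d_gp = _surface_distances(bg, bp, spacing)
    d_pg = _surface_distances(bp, bg, spacing)
    return float((d_gp.sum() + d_pg.sum()) / (d_gp.size + d_pg.size))


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    per_case_diffs: list[float] = field(default_factory=list)
    per_case_means: list[float] = field(default_factory=list)


def bland_altman(vol_a, vol_b) -> BlandAltmanResult:
    """Agreement between two paired volume measurements.

    diffs = a − b; bias = mean(diffs); limits = bias ± 1.96·SD(diffs),
    SD with n−1 denominator (zero for constant differences with n ≥ 2).
    """
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1D sequences")
    if a.size < 2:
        raise ValueError("need at least 2 paired measurements")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        per_case_diffs=diffs.tolist(),
        per_case_means=((a + b) / 2.0).tolist(),
    )


@dataclass
class MetricsReport:
    """Per-case, per-structure metrics plus mean ± std aggregates."""

    per_case: pd.DataFrame
    aggregates: pd.DataFrame
    missing: list[str] = field(default_factory=list)
    hd_mode: str = "symmetric"

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.per_case.to_csv(path, index=False)
        return path


def evaluate_cases(
    preds: dict[str, LabelVolume],
    gts: dict[str, LabelVolume],
    structures: list[str] | None = None,
    hd_mode: str = "symmetric",
) -> tuple[MetricsReport, dict[str, BlandAltmanResult]]:
    """Evaluate predicted label volumes against ground truth.

    Volumes (mm^3) are foreground voxel count times the voxel volume.
    Cases without a prediction are listed in ``report.missing`` and
    excluded from aggregates. Bland–Altman differences are taken as
    (ground truth − predicted), so dilated (over-segmented) predictions
    produce a negative bias.
    """
    rows = []
    missing = sorted(set(gts) - set(preds))
    for case_id in sorted(gts):
        if case_id in missing:
            continue
        gt, pred = gts[case_id], preds[case_id]
        if gt.shape != pred.shape:
            raise ValueError(f"{case_id}: prediction/ground-truth shape mismatch")
        names = structures or gt.class_names
        voxel_mm3 = float(np.prod(gt.spacing))
        for k, name in enumerate(names, start=1):
            g = np.asarray(gt.data) == k
            p = np.asarray(pred.data) == k
            both = g.any() and p.any()
            rows.append(
                {
                    "case_id": case_id,
                    "structure": name,
                    "dsc": dsc(g, p),
                    "hd_mm": hausdorff(g, p, gt.spacing, mode=hd_mode)
                    if both
                    else np.nan,
                    "asd_mm": asd(g, p, gt.spacing) if both else np.nan,
                    "vol_pred_mm3": float(p.sum()) * voxel_mm3,
                    "vol_gt_mm3": float(g.sum()) * voxel_mm3,
                    "hd_mode": hd_mode,
                }
            )
    per_case = pd.DataFrame(rows)
    if len(per_case):
        agg = (
            per_case.groupby("structure")[
                ["dsc", "hd_mm", "asd_mm", "vol_pred_mm3", "vol_gt_mm3"]
            ]
            .agg(["mean", "std"])
            .reset_index()
        )
    else:
        agg = pd.DataFrame()
    report = MetricsReport(per_case, agg, missing=missing, hd_mode=hd_mode)
    ba: dict[str, BlandAltmanResult] = {}
    if len(per_case):
        for name, grp in per_case.groupby("structure"):
            if len(grp) >= 2:
                ba[name] = bland_altman(
                    grp["vol_gt_mm3"].to_numpy(), grp["vol_pred_mm3"].to_numpy()
                )
    return report, ba


def evaluate_run(
    pred_dir: str | Path,
    gt_dir: str | Path,
    structures: list[str],
    out_dir: str | Path | None = None,
    hd_mode: str = "symmetric",
) -> tuple[MetricsReport, dict[str, BlandAltmanResult]]:
    """Evaluate a directory of predictions against a ground-truth directory.

    Case ids are file stems; any format readable by
    :func:`locseg3d.io.read_labelvolume` is accepted. Writes a CSV report
    and one Bland–Altman plot per structure when `out_dir` is given.
    """
    from .io import read_labelvolume

    def load_dir(d: Path) -> dict[str, LabelVolume]:
        vols = {}
        for path in sorted(d.iterdir()):
            if path.suffix in (".nii", ".gz", ".nrrd"):
                stem = path.name.split(".")[0]
                vols[stem] = read_labelvolume(path, class_names=list(structures))
        return vols

    preds = load_dir(Path(pred_dir))
    gts = load_dir(Path(gt_dir))
    report, ba = evaluate_cases(preds, gts, structures, hd_mode=hd_mode)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "metrics.csv")
        for name, res in ba.items():
            bland_altman_plot(res, name, out_dir / f"bland_altman_{name}.png")
    return report, ba


def bland_altman_plot(res: BlandAltmanResult, structure: str, path: str | Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(res.per_case_means, res.per_case_diffs, s=18)
    ax.axhline(res.bias, color="red", label=f"bias {res.bias:.2f}")
    ax.axhline(res.loa_low, color="blue", ls="--", label="±1.96 SD")
    ax.axhline(res.loa_high, color="blue", ls="--")
    ax.set_xlabel("mean volume (mm$^3$)")
    ax.set_ylabel("difference (mm$^3$)")
    ax.set_title(structure)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
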