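"""Batch metric tables and pairwise Pearson correlation reports.

Correlations between shape ratios (U/D, W/H, W/D) and complexity metrics
(OI, S/V, rugosity, fractal dimension) use pairwise-complete observations:
open meshes legitimately lack S/V, so each variable pair is correlated over
the specimens where both are present, and the per-pair n is reported so the
choice is visible.  No multiple-testing correction is applied by default
(star thresholds .05/.01/.001); Holm adjustment is available via a flag.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mesh_core import TriangleMesh, validate_mesh
from .surface_metrics import (
    MetricsRecord,
    enclosed_volume,
    estimate_symmetry_plane,
    oi_from_meshes,
    projected_area,
    rugosity,
    surface_area,
)

__all__ = [
    "CorrelationMatrix",
    "MetricsConfig",
    "compute_all_metrics",
    "pearson_matrix",
    "significance_stars",
    "write_report",
    "records_to_frame",
]

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "specimen_id",
    "S_mm2",
    "Sref_mm2",
    "V_mm3",
    "Sp_mm2",
    "OI_fraction",
    "OI_percent",
    "SV_per_mm",
    "rugosity",
    "MFD_D",
    "U_D",
    "W_H",
    "W_D",
]


def significance_stars(p: float) -> str:
    """Star annotation: *** p<.001, ** p<.01, * p<.05, '' otherwise."""
    if p is None or not math.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r / p over metric columns, with per-pair n.

    Undefined entries (constant variable, n < 3) are NaN and listed in
    ``undefined``; they are reported as null, never coerced to zero.
    """

    variables: list
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray
    undefined: list = field(default_factory=list)
    p_adjusted: Optional[np.ndarray] = None

    def stars(self) -> np.ndarray:
        out = np.empty(self.r.shape, dtype=object)
        for i in range(len(self.variables)):
            for j in range(len(self.variables)):
                out[i, j] = significance_stars(self.p[i, j])
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables):
                if j <= i:
                    continue
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "r": self.r[i, j],
                        "p": self.p[i, j],
                        "stars": significance_stars(self.p[i, j]),
                        "n": int(self.n[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["var1", "var2", "r", "p", "stars", "n"])

    def to_dict(self) -> dict:
        def cell(x):
            return None if (x is None or not math.isfinite(x)) else float(x)

        return {
            "variables": list(self.variables),
            "r": [[cell(x) for x in row] for row in self.r],
            "p": [[cell(x) for x in row] for row in self.p],
            "n": self.n.astype(int).tolist(),
            "stars": self.stars().tolist(),
            "undefined": list(self.undefined),
        }


@dataclass
class MetricsConfig:
    """Knobs for batch metric computation.

    ``normal`` is the silhouette projection direction: an explicit 3-vector
    or ``'auto'`` (estimate the symmetry plane per mesh).  ``pixel`` is the
    silhouette raster pixel size in mm; ``spacing``/``radii`` configure the
    fractal dimension when ``compute_fd`` is on.
    """

    normal: object = "auto"
    pixel: float = 0.05
    compute_fd: bool = False
    spacing: float = 0.2
    radii: Sequence[float] = tuple(range(3, 21))


def compute_all_metrics(
    mesh: TriangleMesh,
    reference: Optional[TriangleMesh] = None,
    config: Optional[MetricsConfig] = None,
    shape_ratios: Optional[dict] = None,
) -> MetricsRecord:
    """One fully populated MetricsRecord for a specimen.

    Metrics whose preconditions fail are left absent with a logged reason:
    volume and S/V require a watertight mesh, OI requires a reference,
    rugosity requires a resolvable projection normal.
    """
    config = config or MetricsConfig()
    rec = MetricsRecord(specimen_id=mesh.name or "specimen")
    diag = validate_mesh(mesh)
    if diag.n_components > 1:
        log.warning(
            "%s: %d disconnected components; metrics use the union",
            rec.specimen_id,
            diag.n_components,
        )
    rec.S = surface_area(mesh)
    if reference is not None:
        oi_rec = oi_from_meshes(mesh, reference)
        rec.S_ref, rec.OI = oi_rec.S_ref, oi_rec.OI
    else:
        rec.notes["OI"] = "no reference mesh supplied"
    if diag.is_watertight:
        rec.V = enclosed_volume(mesh)
        rec.sv_ratio = rec.S / rec.V
    else:
        rec.notes["volume"] = "mesh not watertight; V and S/V absent"
        log.info("%s: open mesh, skipping V and S/V", rec.specimen_id)
    normal = config.normal
    try:
        if isinstance(normal, str) and normal == "auto":
            normal = estimate_symmetry_plane(mesh)
        rec.Sp = projected_area(mesh, normal, resolution=config.pixel)
        rec.rugosity = rec.S / rec.Sp
    except ValueError as exc:
        rec.notes["rugosity"] = str(exc)
        log.info("%s: rugosity skipped (%s)", rec.specimen_id, exc)
    if config.compute_fd:
        from .minkowski_fd import mfd_for_mesh

        rec.fd = mfd_for_mesh(mesh, spacing=config.spacing, radii=config.radii).D
    if shape_ratios:
        rec.U_D = shape_ratios.get("U_D")
        rec.W_H = shape_ratios.get("W_H")
        rec.W_D = shape_ratios.get("W_D")
    return rec


def records_to_frame(records: Sequence[MetricsRecord]) -> pd.DataFrame:
    """Records as a DataFrame with the documented fixed column order."""
    return pd.DataFrame(
        [r.to_dict() for r in records], columns=CSV_COLUMNS
    )


def pearson_matrix(
    records,
    variables: Sequence[str],
    holm: bool = False,
) -> CorrelationMatrix:
    """Pairwise Pearson correlations over metric columns.

    ``records`` may be a list of MetricsRecord or a DataFrame whose columns
    include ``variables``.  r uses the product-moment formula; p the
    two-sided t transform with n-2 degrees of freedom.  Constant variables
    and pairs with n < 3 are undefined (NaN, flagged), not zero.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(records)
    missing = [v for v in variables if v not in frame.columns]
    if missing:
        raise ValueError(f"variables not in records: {missing}")
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    undefined = []
    for i in range(k):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = int(frame[variables[i]].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            sub = frame[[variables[i], variables[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3:
                undefined.append((variables[i], variables[j], "n < 3"))
                continue
            x = sub[variables[i]].to_numpy(float)
            y = sub[variables[j]].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                undefined.append((variables[i], variables[j], "constant variable"))
                continue
            res = sps.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    out = CorrelationMatrix(
        variables=list(variables), r=r, p=p, n=n, undefined=undefined
    )
    if holm:
        from statsmodels.stats.multitest import multipletests

        iu = np.triu_indices(k, 1)
        raw = p[iu]
        ok = np.isfinite(raw)
        adj = np.full_like(raw, np.nan)
        if ok.any():
            adj[ok] = multipletests(raw[ok], method="holm")[1]
        padj = np.full((k, k), np.nan)
        padj[iu] = adj
        padj.T[iu] = adj
        np.fill_diagonal(padj, 0.0)
        out.p_adjusted = padj
    return out


def write_report(
    records: Sequence[MetricsRecord],
    matrix: Optional[CorrelationMatrix],
    out_dir,
    fmt: str = "csv",
) -> list:
    """Serialise records (and optionally the correlation matrix) losslessly.

    ``fmt='csv'`` writes ``metrics.csv`` (fixed column order, 9 significant
    digits) and ``correlations.csv`` (long format); ``fmt='json'`` writes
    the same content as JSON with nulls for missing values.  Returns the
    paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    frame = records_to_frame(records)
    if fmt == "csv":
        path = out_dir / "metrics.csv"
        frame.to_csv(path, index=False, float_format="%.9g")
        written.append(path)
        if matrix is not None:
            path = out_dir / "correlations.csv"
            matrix.to_long_frame().to_csv(path, index=False, float_format="%.9g")
            written.append(path)
    elif fmt == "json":
        path = out_dir / "metrics.json"
        payload = frame.where(frame.notna(), None).to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, default=float))
        written.append(path)
        if matrix is not None:
            path = out_dir / "correlations.json"
            path.write_text(json.dumps(matrix.to_dict(), indent=2))
            written.append(path)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return written
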