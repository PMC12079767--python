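"""Evaluation battery: topology, structural similarity, and volume trends.

Covers: Jacobian-determinant summaries of deformation fields (topology
preservation means det > 0 everywhere), windowed SSIM and RMSD between
templates, Dice overlap of label maps, and normalized-volume trend analysis
in which every ROI's volumes are divided by their mean across the
conditioning set so template curves can be compared with binned per-scan
reference curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from skimage.metrics import structural_similarity

from .diffeo import jacobian_determinant
from .grids import ImageGrid, VectorField

__all__ = [
    "JacobianSummary",
    "jacobian_report",
    "ssim",
    "rmsd",
    "dice",
    "normalized_volumes",
    "binned_reference_volumes",
    "trend_recovery",
]


@dataclass
class JacobianSummary:
    min: float
    max: float
    mean: float
    std: float
    nonpos_count: int
    n_voxels: int
    histogram: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("inconsistent Jacobian summary")


def _summarize(values: np.ndarray, bins: int = 50) -> JacobianSummary:
    hist = np.histogram(values, bins=bins)
    return JacobianSummary(
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        std=float(values.std()),
        nonpos_count=int(np.sum(values <= 0)),
        n_voxels=int(values.size),
        histogram=hist,
    )


def jacobian_report(
    phis: list[VectorField], mask: ImageGrid | None = None
) -> tuple[list[JacobianSummary], JacobianSummary]:
    """Per-field and pooled Jacobian-determinant summaries.

    Voxels are restricted to ``mask`` (e.g. a brain mask) when provided.
    """
    if not phis:
        raise ValueError("empty deformation list")
    per_field = []
    pooled = []
    for phi in phis:
        det = jacobian_determinant(phi).data
        vals = det[mask.data > 0] if mask is not None else det.ravel()
        per_field.append(_summarize(vals))
        pooled.append(vals)
    return per_field, _summarize(np.concatenate(pooled))


def ssim(x: ImageGrid, y: ImageGrid, data_range: float = 1.0) -> float:
    """Windowed SSIM with the standard parameters.

    Gaussian window sigma 1.5 (11-wide), K1=0.01, K2=0.03, population
    covariance; symmetric in its arguments.
    """
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    return float(
        structural_similarity(
            x.data.astype(float),
            y.data.astype(float),
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def rmsd(x: ImageGrid, y: ImageGrid) -> float:
    """Root mean squared intensity difference."""
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((x.data.astype(float) - y.data.astype(float)) ** 2)))


def dice(a: ImageGrid, b: ImageGrid, labels) -> dict[int, float | None]:
    """Per-label Dice overlap ``2|A∩B| / (|A| + |B|)``.

    Labels absent from both maps are reported as ``None`` (undefined).
    """
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    la = np.rint(a.data).astype(int)
    lb = np.rint(b.data).astype(int)
    out: dict[int, float | None] = {}
    for lab in labels:
        ma, mb = la == lab, lb == lab
        denom = ma.sum() + mb.sum()
        out[int(lab)] = None if denom == 0 else float(2.0 * np.sum(ma & mb) / denom)
    return out


def normalized_volumes(volumes: dict[float, float]) -> pd.DataFrame:
    """Normalize one ROI's volumes by their mean across the conditioning set.

    ``volumes`` maps conditioning value (age) -> raw volume. The outputs
    average to 1 by construction.
    """
    if not volumes:
        raise ValueError("empty volume set")
    vals = np.array(list(volumes.values()), dtype=float)
    if np.any(vals <= 0):
        raise ValueError("volumes must be strictly positive")
    norm = vals / vals.mean()
    return pd.DataFrame({"alpha": list(volumes.keys()), "volume": vals, "vnorm": norm})


def binned_reference_volumes(
    volumes: np.ndarray, ages: np.ndarray, bin_width: float = 2.0
) -> pd.DataFrame:
    """Per-scan reference curve: bin by age, average, then normalize.

    Per-bin mean volumes are normalized by the mean over bins; each row also
    carries the bin's std and a 95% interval half-width on the same
    normalized scale. Empty bins are reported with NaN, never imputed.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    volumes = np.asarray(volumes, dtype=float)
    ages = np.asarray(ages, dtype=float)
    lo = np.floor(ages.min() / bin_width) * bin_width
    hi = np.ceil(ages.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n_b = int(sel.sum())
        if n_b == 0:
            rows.append((0.5 * (edges[b] + edges[b + 1]), np.nan, np.nan, 0))
            continue
        rows.append((0.5 * (edges[b] + edges[b + 1]), volumes[sel].mean(), volumes[sel].std(ddof=0), n_b))
    df = pd.DataFrame(rows, columns=["bin_centre", "mean_volume", "std_volume", "n"])
    grand = df["mean_volume"].mean(skipna=True)
    df["vnorm"] = df["mean_volume"] / grand
    df["vnorm_std"] = df["std_volume"] / grand
    df["ci95_half"] = 1.96 * df["vnorm_std"] / np.sqrt(df["n"].clip(lower=1))
    return df


def trend_recovery(curve: pd.DataFrame, reference: pd.DataFrame) -> dict:
    """Compare a template volume curve against the binned reference curve.

    ``curve`` needs columns (alpha, vnorm); ``reference`` needs
    (bin_centre, vnorm). The template curve is averaged within the reference
    bins before comparison. Reports the sign of each fitted slope, whether
    the signs agree, the Spearman correlation between the curves, and the
    largest absolute normalized-volume gap.
    """
    ref = reference.dropna(subset=["vnorm"])
    if len(ref) < 3 or len(curve) < 3:
        raise ValueError("need at least 3 support points per curve")
    centres = ref["bin_centre"].to_numpy()
    width = np.min(np.diff(np.sort(centres))) if len(centres) > 1 else 1.0
    tmpl = []
    for c in centres:
        sel = np.abs(curve["alpha"].to_numpy() - c) <= width / 2
        tmpl.append(curve["vnorm"].to_numpy()[sel].mean() if sel.any() else np.nan)
    tmpl = np.asarray(tmpl)
    ok = np.isfinite(tmpl)
    if ok.sum() < 3:
        raise ValueError("curves share fewer than 3 age-support points")
    t, r = tmpl[ok], ref["vnorm"].to_numpy()[ok]
    c = centres[ok]
    rho = spearmanr(t, r).statistic
    slope_t = np.polyfit(c, t, 1)[0]
    slope_r = np.polyfit(c, r, 1)[0]
    return {
        "spearman": float(rho),
        "template_slope": float(slope_t),
        "reference_slope": float(slope_r),
        "sign_agree": bool(np.sign(slope_t) == np.sign(slope_r)),
        "max_abs_gap": float(np.max(np.abs(t - r))),
    }
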