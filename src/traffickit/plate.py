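"""Plate-level screen statistics: well summaries, robust z-scores, QC, hit calls.

The screen quantifies three metrics per imaged cell -- cell-surface channel
intensity, total-channel intensity, and their per-cell trafficking ratio
(surface/total) -- and aggregates them to well means.  Compound wells are then
scored on a plate-by-plate basis with a median-based modified z-score

    z_i = (x_i - median(x)) / (1.4826 * MAD(x))

where the reference population is the plate's *compound* wells only (most
compounds are inactive, and controls would bias the scale), MAD is the median
absolute deviation from the median, and 1.4826 makes the score consistent with
a classical z-score under normality.  A compound is a hit when |z| > tau on at
least one metric and its cell-count z does not indicate toxicity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from traffickit.errors import ConfigurationError

log = logging.getLogger(__name__)

#: Consistency constant making MAD estimate the SD of a normal distribution.
MAD_CONSISTENCY = 1.4826

METRICS = ("surface", "total", "ratio")

ROLE_COMPOUND = "compound"
ROLE_NEG = "dmso_neg"
ROLE_POS = "e115g_pos"


def robust_center_scale(values) -> tuple[float, float]:
    """Median and consistency-scaled MAD (``1.4826 * MAD``) of ``values``."""
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, MAD_CONSISTENCY * mad


def robust_z(values) -> np.ndarray:
    """Robust z-scores of ``values`` against their own median/MAD reference."""
    x = np.asarray(values, dtype=float)
    med, scale = robust_center_scale(x)
    if scale == 0.0:
        raise ConfigurationError("degenerate scale: MAD is zero")
    return (x - med) / scale


# ---------------------------------------------------------------------------
# Well summaries
# ---------------------------------------------------------------------------

def summarize_wells(
    records: pd.DataFrame,
    plate_map: pd.DataFrame | None = None,
    min_cells: int = 1,
) -> pd.DataFrame:
    """Aggregate a per-cell feature table to per-well summaries.

    Parameters
    ----------
    records
        Per-cell table with columns ``plate_id, well, compound_id, cell_id,
        surface_fiu, total_fiu``.
    plate_map
        Optional layout with columns ``plate_id, well, role`` (and optionally
        ``compound_id``); wells present in the map but absent from ``records``
        appear in the output with ``n_cells = 0``.
    min_cells
        Wells with fewer quantified cells are flagged ``excluded`` and must be
        dropped from downstream plate statistics.

    Returns
    -------
    DataFrame with one row per well: ``plate_id, well, role, compound_id,
    n_cells, n_ratio_dropped, mean_surface, mean_total, mean_ratio, excluded``.
    The trafficking ratio is computed per cell and then averaged (mean of
    ratios, not ratio of means); cells with ``total_fiu == 0`` are excluded
    from the ratio mean and counted in ``n_ratio_dropped``.
    """
    if min_cells < 1:
        raise ConfigurationError("min_cells must be >= 1")
    if records.empty:
        warnings.warn("summarize_wells: empty per-cell table", stacklevel=2)

    rec = records.copy()
    valid_total = rec["total_fiu"] > 0
    rec["ratio"] = np.where(valid_total, rec["surface_fiu"] / rec["total_fiu"].where(valid_total, 1.0), np.nan)

    grouped = rec.groupby(["plate_id", "well"], sort=True)
    out = grouped.agg(
        compound_id=("compound_id", "first"),
        n_cells=("cell_id", "size"),
        mean_surface=("surface_fiu", "mean"),
        mean_total=("total_fiu", "mean"),
        mean_ratio=("ratio", "mean"),
    ).reset_index()
    out["n_ratio_dropped"] = grouped["ratio"].apply(lambda s: int(s.isna().sum())).to_numpy()

    if plate_map is not None:
        cols = ["plate_id", "well", "role"]
        if "compound_id" in plate_map.columns:
            cols.append("compound_id")
        merged = plate_map[cols].merge(
            out, on=["plate_id", "well"], how="outer",
            suffixes=("_map", ""), indicator=True,
        )
        # wells in the map but with no cells
        empty = merged["_merge"] == "left_only"
        merged.loc[empty, "n_cells"] = 0
        merged.loc[empty, "n_ratio_dropped"] = 0
        if "compound_id_map" in merged.columns:
            merged["compound_id"] = merged["compound_id"].where(
                merged["compound_id"].notna(), merged["compound_id_map"]
            )
            merged = merged.drop(columns="compound_id_map")
        unknown = merged["_merge"] == "right_only"
        if unknown.any():
            merged.loc[unknown, "role"] = ROLE_COMPOUND
            warnings.warn(
                f"{int(unknown.sum())} wells in the per-cell table are absent from the plate map",
                stacklevel=2,
            )
        out = merged.drop(columns="_merge")
    else:
        out["role"] = ROLE_COMPOUND

    out["n_cells"] = out["n_cells"].astype(int)
    out["excluded"] = out["n_cells"] < min_cells
    order = [
        "plate_id", "well", "role", "compound_id", "n_cells", "n_ratio_dropped",
        "mean_surface", "mean_total", "mean_ratio", "excluded",
    ]
    return out[order]


# ---------------------------------------------------------------------------
# Robust z-scores
# ---------------------------------------------------------------------------

def robust_z_scores(
    wells: pd.DataFrame,
    metrics: tuple[str, ...] = METRICS,
    min_compound_wells: int = 8,
    cellcount: bool = True,
) -> pd.DataFrame:
    """Per-plate robust z-scores for each screen metric.

    For every plate and metric the reference median and MAD are computed over
    the plate's non-excluded *compound* wells; control wells are scored against
    the same reference (they are never hits).  ``z_cellcount`` supports the
    toxicity rule.  Plates with a zero MAD on some metric get ``NaN`` z-scores
    for that metric and a ``degenerate_<metric>`` flag; plate_qc treats any
    degenerate metric as a QC failure.

    Returns a DataFrame with per-well ``z_<metric>`` columns; the per-plate
    reference table (median, scaled MAD, degeneracy) is attached as
    ``result.attrs["reference"]``.
    """
    cols = {m: f"mean_{m}" for m in metrics}
    if cellcount:
        cols["cellcount"] = "n_cells"

    frames = []
    reference_rows = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        usable = grp[~grp["excluded"]]
        compounds = usable[usable["role"] == ROLE_COMPOUND]
        if len(compounds) < min_compound_wells:
            raise ConfigurationError(
                f"plate {plate_id}: {len(compounds)} compound wells < floor {min_compound_wells}"
            )
        res = grp[["plate_id", "well", "role", "compound_id", "excluded"]].copy()
        for metric, col in cols.items():
            med, scale = robust_center_scale(compounds[col].to_numpy())
            degenerate = scale == 0.0
            reference_rows.append(
                {"plate_id": plate_id, "metric": metric, "median": med,
                 "scaled_mad": scale, "degenerate": degenerate}
            )
            if degenerate:
                log.warning("plate %s metric %s: degenerate scale (MAD = 0)", plate_id, metric)
                res[f"z_{metric}"] = np.nan
            else:
                res[f"z_{metric}"] = (grp[col] - med) / scale
            res.loc[grp["excluded"], f"z_{metric}"] = np.nan
        frames.append(res)

    out = pd.concat(frames, ignore_index=True)
    out.attrs["reference"] = pd.DataFrame(reference_rows)
    return out


# ---------------------------------------------------------------------------
# Plate QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Plate acceptance thresholds.

    ``z_prime``: minimum assay window on the QC metric; ``pct_cv``: maximum
    percent CV of the negative controls; ``min_median_cell_count``: floor on
    the plate's median per-well cell count; ``min_focus_score``: floor on the
    imager's focus score when a ``focus_score`` column is present.
    """

    z_prime: float = 0.5
    pct_cv: float = 20.0
    min_median_cell_count: float = 50.0
    min_focus_score: float | None = None
    qc_metric: str = "mean_total"


def z_prime_factor(neg, pos) -> float:
    """Z' = 1 - 3(sigma_pos + sigma_neg)/|mu_pos - mu_neg| (1 is ideal)."""
    neg = np.asarray(neg, dtype=float)
    pos = np.asarray(pos, dtype=float)
    window = abs(pos.mean() - neg.mean())
    if window == 0:
        return -np.inf
    return 1.0 - 3.0 * (pos.std(ddof=1) + neg.std(ddof=1)) / window


def plate_qc(
    wells: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
    zscores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-plate QC: Z' factor, negative-control %CV, cell count, focus score.

    Pass requires every configured threshold to hold and, when ``zscores``
    (with its reference table) is supplied, no degenerate-scale metric on the
    plate.  Failures carry reason codes.
    """
    degenerate_by_plate: dict[object, list[str]] = {}
    if zscores is not None and "reference" in zscores.attrs:
        ref = zscores.attrs["reference"]
        for _, row in ref[ref["degenerate"]].iterrows():
            degenerate_by_plate.setdefault(row["plate_id"], []).append(row["metric"])

    rows = []
    for plate_id, grp in wells.groupby("plate_id", sort=True):
        usable = grp[~grp["excluded"]]
        neg = usable.loc[usable["role"] == ROLE_NEG, thresholds.qc_metric]
        pos = usable.loc[usable["role"] == ROLE_POS, thresholds.qc_metric]
        reasons = []
        if len(neg) < 2 or len(pos) < 2:
            zp = np.nan
            pct_cv = np.nan
            reasons.append("controls-absent")
        else:
            zp = z_prime_factor(neg, pos)
            pct_cv = 100.0 * neg.std(ddof=1) / neg.mean() if neg.mean() > 0 else np.inf
            if zp < thresholds.z_prime:
                reasons.append("z-prime-low")
            if pct_cv > thresholds.pct_cv:
                reasons.append("neg-cv-high")
        median_cells = float(usable["n_cells"].median())
        if median_cells < thresholds.min_median_cell_count:
            reasons.append("cell-count-low")
        focus = float(usable["focus_score"].median()) if "focus_score" in usable else np.nan
        if thresholds.min_focus_score is not None:
            if not focus >= thresholds.min_focus_score:
                reasons.append("focus-low")
        for metric in degenerate_by_plate.get(plate_id, []):
            reasons.append(f"degenerate-scale-{metric}")
        rows.append(
            {"plate_id": plate_id, "z_prime": zp, "pct_cv_neg": pct_cv,
             "median_cell_count": median_cells, "focus_score": focus,
             "pass": not reasons, "reasons": ";".join(reasons)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hit calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitThresholds:
    """Hit-calling rule: |z| strictly greater than ``tau`` on >= 1 metric,
    toxicity as cell-count robust z below ``toxicity_z`` (reduced cell count
    is the toxicity observable)."""

    tau: float = 3.0
    toxicity_z: float = -3.0
    metrics: tuple[str, ...] = METRICS


def call_hits(
    zscores: pd.DataFrame,
    thresholds: HitThresholds = HitThresholds(),
    qc: pd.DataFrame | None = None,
    allow_failed_qc: bool = False,
) -> pd.DataFrame:
    """Call hits from per-well robust z-scores.

    A compound well is a hit iff |z| > tau on at least one metric and the well
    is not toxic (``z_cellcount < toxicity_z``).  Metrics whose z is undefined
    (degenerate plate scale) are skipped with a warning, never treated as 0.
    Control and excluded wells are never hits.  When a QC table is given,
    wells on failing plates are dropped unless ``allow_failed_qc`` (the
    override is recorded in the ``qc_overridden`` column).
    """
    z = zscores
    if qc is not None:
        failing = set(qc.loc[~qc["pass"], "plate_id"])
        if failing and not allow_failed_qc:
            z = z[~z["plate_id"].isin(failing)]
        overridden = allow_failed_qc and bool(failing)
    else:
        overridden = False

    rows = []
    for _, r in z.iterrows():
        if r["role"] != ROLE_COMPOUND or r.get("excluded", False):
            continue
        hit_metrics, directions = [], []
        for m in thresholds.metrics:
            zm = r.get(f"z_{m}", np.nan)
            if np.isnan(zm):
                warnings.warn(
                    f"plate {r['plate_id']} well {r['well']}: z undefined on '{m}', metric skipped",
                    stacklevel=2,
                )
                continue
            if abs(zm) > thresholds.tau:
                hit_metrics.append(m)
                directions.append("up" if zm > 0 else "down")
        zc = r.get("z_cellcount", np.nan)
        is_toxic = bool(not np.isnan(zc) and zc < thresholds.toxicity_z)
        rows.append(
            {"plate_id": r["plate_id"], "well": r["well"], "compound_id": r["compound_id"],
             "z_surface": r.get("z_surface", np.nan), "z_total": r.get("z_total", np.nan),
             "z_ratio": r.get("z_ratio", np.nan), "z_cellcount": zc,
             "is_toxic": is_toxic,
             "is_hit": bool(hit_metrics) and not is_toxic,
             "hit_metrics": ",".join(hit_metrics),
             "directions": ",".join(directions),
             "qc_overridden": overridden}
        )
    return pd.DataFrame(rows)
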