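"""Regression metrics, survival-term stratification and sensitivity sweeps.

MSE and MAE are reported with the sample standard deviation of the
per-patient squared and absolute errors (spread across patients, not across
runs). Survival terms: short (t <= 12 months), medium (12 < t <= 60), long
(t > 60).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

TERMS = ("short", "medium", "long")

logger = logging.getLogger(__name__)


def _check_pair(t: np.ndarray, t_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(t, dtype=float)
    t_pred = np.asarray(t_pred, dtype=float)
    if t.shape != t_pred.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("need equal-length non-empty 1-D arrays")
    return t, t_pred


def mse(t: np.ndarray, t_pred: np.ndarray) -> float:
    t, t_pred = _check_pair(t, t_pred)
    return float(np.mean((t - t_pred) ** 2))


def mae(t: np.ndarray, t_pred: np.ndarray) -> float:
    t, t_pred = _check_pair(t, t_pred)
    return float(np.mean(np.abs(t - t_pred)))


def error_sd(t: np.ndarray, t_pred: np.ndarray) -> tuple[float, float]:
    """Sample sd of per-patient squared errors and absolute errors."""
    t, t_pred = _check_pair(t, t_pred)
    se = (t - t_pred) ** 2
    ae = np.abs(t - t_pred)
    ddof = 1 if t.size > 1 else 0
    return float(np.std(se, ddof=ddof)), float(np.std(ae, ddof=ddof))


def stratify_terms(t: np.ndarray) -> np.ndarray:
    """Label each survival time short / medium / long (months)."""
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("negative survival time")
    return np.select([t <= 12, t <= 60], ["short", "medium"], default="long")


def error_series(
    patient_ids: list[str], t: np.ndarray, t_pred: np.ndarray
) -> pd.DataFrame:
    """Per-patient errors ordered by ascending true survival, ties by id."""
    t, t_pred = _check_pair(np.asarray(t), np.asarray(t_pred))
    df = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "survival_months": t,
            "predicted_months": t_pred,
            "absolute_error": np.abs(t - t_pred),
            "term": stratify_terms(t),
        }
    )
    return df.sort_values(["survival_months", "patient_id"], kind="stable").reset_index(drop=True)


def _metric_block(t: np.ndarray, t_pred: np.ndarray) -> dict:
    sd_se, sd_ae = error_sd(t, t_pred)
    return {
        "mse": mse(t, t_pred),
        "mae": mae(t, t_pred),
        "sd_se": sd_se,
        "sd_ae": sd_ae,
        "n": int(len(t)),
    }


def evaluate_predictions(
    patient_ids: list[str],
    t: np.ndarray,
    t_pred: np.ndarray,
    model_tag: str,
    metadata: dict | None = None,
) -> dict:
    """Full evaluation report: overall and per-term metrics + patient table."""
    t, t_pred = _check_pair(np.asarray(t), np.asarray(t_pred))
    terms = stratify_terms(t)
    report = {
        "model_tag": model_tag,
        "overall": _metric_block(t, t_pred),
        "per_term": {},
        "per_patient": error_series(list(patient_ids), t, t_pred).to_dict(orient="records"),
        "metadata": metadata or {},
    }
    for term in TERMS:
        sel = terms == term
        if sel.any():
            report["per_term"][term] = _metric_block(t[sel], t_pred[sel])
        else:
            report["per_term"][term] = {"mse": None, "mae": None, "sd_se": None, "sd_ae": None, "n": 0}
    return report


def sensitivity_sweep(
    axis: str,
    grid: list,
    base_config,
    cohort,
    enforce_eta_floor: bool = True,
) -> pd.DataFrame:
    """Re-run the pipeline across a grid of one hyperparameter.

    ``axis`` is one of n_clusters / ssl_epochs / eta; ``cohort`` is the
    (expression, interactions, survival) triple. The seed is shared across
    grid values so only the swept axis differs. Failures at individual grid
    points are recorded, not raised.
    """
    from .training import run_mvmwgl  # local import to avoid a cycle

    if axis not in ("n_clusters", "ssl_epochs", "eta"):
        raise ValueError(f"unknown sweep axis {axis!r}")
    if axis == "eta" and enforce_eta_floor and any(v < 0.8 for v in grid):
        raise ValueError("eta grid values below the 0.8 floor (pass enforce_eta_floor=False to override)")

    expr, interactions, surv = cohort
    rows = []
    for value in grid:
        config = dataclasses.replace(base_config, **{axis: value})
        try:
            result = run_mvmwgl(expr, interactions, surv, config)
            overall = result.report["overall"]
            rows.append(
                {axis: value, "mse": overall["mse"], "mae": overall["mae"], "error": None}
            )
        except Exception as exc:  # noqa: BLE001 - sweep continues past failures
            logger.warning("sweep point %s=%r failed: %s", axis, value, exc)
            rows.append({axis: value, "mse": None, "mae": None, "error": str(exc)})
    return pd.DataFrame(rows)
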