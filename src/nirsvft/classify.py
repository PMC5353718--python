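"""Threshold-based individual classification.

Two fixed cutoffs, taken as given constants from an earlier multi-site ROC
analysis, are applied to each QC-passing subject's frontal features: an
integral below 73 labels the subject ``patient`` (versus ``non-patient``),
and a centroid later than 54 s labels them ``psychosis-spectrum`` (versus
``mdd-like``).  Exact ties classify as the clinical case (patient /
psychosis-spectrum) and are logged; an undefined centroid yields
``indeterminate``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CENTROID_THRESHOLD_S, INTEGRAL_THRESHOLD

logger = logging.getLogger(__name__)

__all__ = ["classify_subject", "classify_features", "summarize_classification"]


def classify_subject(
    row,
    integral_threshold: float = INTEGRAL_THRESHOLD,
    centroid_threshold_s: float = CENTROID_THRESHOLD_S,
) -> tuple[str, str]:
    """Classify one QC-passing feature row.

    ``row`` needs ``integral_value`` and ``centroid_value_s`` attributes or
    keys.  Returns (patient_vs_control, psychosis_vs_mdd).
    """
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    integral = float(get("integral_value"))
    centroid = float(get("centroid_value_s"))

    if integral == integral_threshold:
        logger.info("integral exactly at threshold %s: classifying as patient",
                    integral_threshold)
    patient = "patient" if integral <= integral_threshold else "non-patient"

    if np.isnan(centroid):
        psychosis = "indeterminate"
    else:
        if centroid == centroid_threshold_s:
            logger.info("centroid exactly at threshold %s s: classifying as "
                        "psychosis-spectrum", centroid_threshold_s)
        psychosis = ("psychosis-spectrum" if centroid >= centroid_threshold_s
                     else "mdd-like")
    return patient, psychosis


def classify_features(
    features: pd.DataFrame,
    integral_threshold: float = INTEGRAL_THRESHOLD,
    centroid_threshold_s: float = CENTROID_THRESHOLD_S,
) -> pd.DataFrame:
    """Per-subject classification of all QC-passing rows (vectorized)."""
    qc = features[features["qc_pass"].astype(bool)].copy()
    qc["patient_class"] = np.where(
        qc["integral_value"] <= integral_threshold, "patient", "non-patient")
    centroid = qc["centroid_value_s"].to_numpy(dtype=float)
    qc["psychosis_class"] = np.where(
        np.isnan(centroid), "indeterminate",
        np.where(centroid >= centroid_threshold_s,
                 "psychosis-spectrum", "mdd-like"))
    return qc[["subject_id", "integral_value", "centroid_value_s",
               "patient_class", "psychosis_class"]]


def summarize_classification(
    features: pd.DataFrame,
    subjects: pd.DataFrame | None = None,
    grouping: str | pd.Series = "diagnosis",
    integral_threshold: float = INTEGRAL_THRESHOLD,
    centroid_threshold_s: float = CENTROID_THRESHOLD_S,
) -> pd.DataFrame:
    """Per-group counts and percentages of threshold classifications.

    Percentages are over QC-passing subjects in the group; indeterminate
    centroids are counted separately and excluded from the
    psychosis-spectrum percentage's numerator only.  Empty input yields an
    empty summary; a group with no QC-passing subjects yields n=0 and null
    percentages.
    """
    classified = classify_features(features, integral_threshold,
                                   centroid_threshold_s)
    if subjects is not None:
        merged = classified.merge(subjects, left_on="subject_id",
                                  right_on="id", how="left")
        if isinstance(grouping, str):
            merged["_group"] = merged[grouping]
        else:
            merged["_group"] = merged["subject_id"].map(grouping)
    else:
        merged = classified.copy()
        merged["_group"] = "all"
    merged = merged.dropna(subset=["_group"])

    rows = []
    for group, sub in merged.groupby("_group", sort=True):
        n = len(sub)
        n_patient = int((sub["patient_class"] == "patient").sum())
        n_psy = int((sub["psychosis_class"] == "psychosis-spectrum").sum())
        n_ind = int((sub["psychosis_class"] == "indeterminate").sum())
        rows.append(dict(
            group=group,
            n=n,
            n_classified_patient=n_patient,
            pct_classified_patient=100.0 * n_patient / n if n else np.nan,
            n_classified_psychosis_spectrum=n_psy,
            pct_classified_psychosis_spectrum=100.0 * n_psy / n if n else np.nan,
            n_indeterminate=n_ind,
        ))
    columns = ["group", "n", "n_classified_patient", "pct_classified_patient",
               "n_classified_psychosis_spectrum",
               "pct_classified_psychosis_spectrum", "n_indeterminate"]
    return pd.DataFrame(rows, columns=columns)
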