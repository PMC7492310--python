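"""Ligand-based design screening: score candidates and compare to a template.

Candidate compounds (descriptor rows for proposed analogues of a known
active template) are pushed through a fitted regression model; each gets
a predicted pIC50 and the equivalent IC50 in micromolar, is ranked by
descending predicted potency, and is flagged when strictly more potent
than the template.  An optional activity-threshold filter retains only
candidates below an IC50 ceiling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    ActivitySeries,
    DescriptorTable,
    DomainError,
    LinearModel,
    ic50_uM_from_pic50,
)

__all__ = ["screen", "rank_candidates", "activity_threshold_filter"]

CANDIDATE_COLUMNS = ["pIC50", "IC50_uM", "better_than_template"]


def rank_candidates(pic50: ActivitySeries | pd.Series, template_pic50: float) -> pd.DataFrame:
    """Build a candidate set from predicted pIC50 values.

    Rows are sorted by descending pIC50 (ties by id, for stability);
    ``better_than_template`` uses strict inequality, so a candidate
    exactly matching the template is not flagged.
    """
    series = pic50.series if isinstance(pic50, ActivitySeries) else pic50.astype(float)
    if not np.isfinite(template_pic50):
        raise DomainError("template pIC50 must be finite")
    frame = pd.DataFrame(
        {
            "pIC50": series,
            "IC50_uM": ic50_uM_from_pic50(series.to_numpy()) if len(series) else [],
            "better_than_template": series > template_pic50,
        }
    )
    frame.index = frame.index.rename("id")
    return frame.sort_values(["pIC50", "id"], ascending=[False, True], kind="mergesort")


def screen(
    model: LinearModel, candidates: DescriptorTable, template_pic50: float
) -> pd.DataFrame:
    """Predict candidate activities with ``model`` and rank against the template."""
    if candidates.shape[0] == 0:
        return rank_candidates(pd.Series(dtype=float), template_pic50)
    return rank_candidates(model.predict(candidates), template_pic50)


def activity_threshold_filter(candidates: pd.DataFrame, ic50_max: float) -> pd.DataFrame:
    """Retain candidates whose IC50 is strictly below ``ic50_max`` (uM)."""
    if ic50_max < 0:
        raise DomainError("IC50 threshold must be >= 0")
    if "IC50_uM" not in candidates.columns:
        raise DomainError("candidate set lacks an IC50_uM column")
    return candidates[candidates["IC50_uM"] < ic50_max].copy()
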