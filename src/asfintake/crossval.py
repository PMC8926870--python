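"""Five-fold cross-validation at the survey level.

Whole surveys are held out (all strata of a survey share a fold): row-level
splits would leak within-survey structure into training.  Held-out strata
are predicted at the survey's *own* characteristics — bias terms applied —
so predictions are on the same measurement scale as the raw observations
they are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intake_model import IntakeModel, ModelConfig


@dataclass
class CVMetrics:
    """Per-fold and pooled observed-versus-predicted scores."""

    per_fold: pd.DataFrame       # k rows: slope, intercept, r2, rmse, bias
    pooled: pd.Series            # one pooled row across all held-out rows
    fold_assignment: dict[str, int]
    flagged_folds: tuple[int, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        pooled = self.pooled.to_frame().T
        pooled.insert(0, "fold", "pooled")
        per = self.per_fold.copy()
        per.insert(0, "fold", per.index)
        return pd.concat([per, pooled], ignore_index=True)


def kfold_partition(survey_ids, k: int = 5, seed: int = 0,
                    regions: dict | None = None) -> dict[str, int]:
    """Deterministic partition of surveys into k folds of near-equal size.

    With ``regions`` (survey_id -> region), assignment is stratified so
    each fold receives a near-proportional share of every region's surveys.
    """
    ids = list(dict.fromkeys(survey_ids))  # preserve order, drop duplicates
    if len(ids) < k:
        raise ValueError(f"need at least k={k} surveys, got {len(ids)}")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    if regions is None:
        order = [ids[i] for i in rng.permutation(len(ids))]
        for i, sid in enumerate(order):
            assignment[sid] = i % k
    else:
        offset = 0
        for region in sorted({regions[s] for s in ids}):
            members = [s for s in ids if regions[s] == region]
            members = [members[i] for i in rng.permutation(len(members))]
            for i, sid in enumerate(members):
                assignment[sid] = (offset + i) % k
            offset += len(members)
    return assignment


def _score(observed: np.ndarray, predicted: np.ndarray) -> dict:
    resid = observed - predicted
    out = {"n": len(observed),
           "rmse": float(np.sqrt(np.mean(resid ** 2))),
           "bias": float(np.mean(resid))}
    if np.ptp(predicted) > 0 and len(observed) > 2:
        fit = stats.linregress(predicted, observed)
        out.update(slope=float(fit.slope), intercept=float(fit.intercept),
                   r2=float(fit.rvalue ** 2))
    else:
        out.update(slope=np.nan, intercept=np.nan, r2=0.0)
    return out


def cross_validate(surveys: pd.DataFrame,
                   covariates: pd.DataFrame | None = None,
                   config: ModelConfig | None = None,
                   k: int = 5, seed: int = 0,
                   food: str | None = None,
                   stratify: str | None = None) -> CVMetrics:
    """Survey-level k-fold cross-validation of the intake model.

    For each fold: fit on the other k-1 folds, predict every held-out
    survey-stratum at its own survey characteristics, and score observed
    versus predicted (regression slope/intercept, R^2, RMSE, mean bias).
    Folds whose fit fails the convergence gate are flagged, not dropped
    silently.  ``stratify`` names a survey column (``"region"`` or
    ``"country"``) whose groups are spread evenly across folds — the usual
    choice for hierarchical data, so no unit loses most of its surveys to
    a single fold.
    """
    config = config or ModelConfig()
    if food is not None:
        surveys = surveys[surveys["food"] == food]
    groups = None
    if stratify is not None:
        groups = (surveys.drop_duplicates("survey_id")
                  .set_index("survey_id")[stratify].to_dict())
    assignment = kfold_partition(surveys["survey_id"], k=k, seed=seed,
                                 regions=groups)
    folds = surveys["survey_id"].map(assignment)

    rows_per_fold = []
    flagged = []
    all_obs, all_pred = [], []
    for fold in range(k):
        train = surveys[folds != fold]
        test = surveys[folds == fold]
        model = IntakeModel(config=config, food=food).fit(train, covariates)
        if not model.converged_:
            flagged.append(fold)
        pred_draws = model.predict_observations(test)
        predicted = np.median(pred_draws, axis=1)
        observed = test["mean_g_day"].to_numpy(float)
        rows_per_fold.append(_score(observed, predicted))
        all_obs.append(observed)
        all_pred.append(predicted)

    per_fold = pd.DataFrame(rows_per_fold)
    pooled = pd.Series(_score(np.concatenate(all_obs),
                              np.concatenate(all_pred)))
    return CVMetrics(per_fold=per_fold, pooled=pooled,
                     fold_assignment=assignment,
                     flagged_folds=tuple(flagged))
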