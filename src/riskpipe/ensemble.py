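"""Ensemble transfer learning: stack base-model scores with ten
design-sensitive covariates via unpenalized logistic fine-tuning.

Base models trained on different study designs (the matched case-control
design, the two time-to-event designs, an earlier calendar cohort) score
the target prospective cohort without any refitting — cross-prediction
works because every design shares the same 8-bin longitudinal layout. The
stacking layer then fits an unpenalized logistic regression of the target
outcome on the base scores plus ten covariates expected to shift with
study design and outcome definition (sex, race, ethnicity, the two age
flags, any-window chronic pain / suicide ideation / suicide attempt /
overdose, and the utilization index). No cross-validation and no model
selection: fine-tuning deliberately touches only these few degrees of
freedom.

Fitting follows the even/odd protocol: one fit per date-of-birth half,
final coefficients are the average, and out-of-half scores are retained so
evaluation never uses a model trained on the row it scores. Base scores
enter unstandardized (their range is roughly five times that of the binary
covariates; coefficient magnitudes are read accordingly). Complete
separation in a small cohort falls back to a tiny ridge (1e-6) with a
warning; rank-deficient score blocks drop duplicate columns with a log
message.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riskpipe.features import FINETUNE_NAMES

log = logging.getLogger(__name__)

DEFAULT_REGISTRY_SIZE = 7


class ContractError(ValueError):
    """Registry/feature/schedule mismatch between base models and cohort."""


@dataclass
class EnsembleModel:
    """Fitted stacking model: base-score weights + 10 fine-tune weights."""

    base_names: list
    base_coefficients: np.ndarray
    finetune_names: list
    finetune_coefficients: np.ndarray
    intercept: float
    target: str = "combined"
    dropped_columns: list = field(default_factory=list)
    fit_note: str = ""

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(
            np.concatenate([self.base_coefficients, self.finetune_coefficients]),
            index=list(self.base_names) + list(self.finetune_names))

    def to_frame(self) -> pd.DataFrame:
        s = self.coefficients
        return pd.DataFrame({"component": s.index, "weight": s.to_numpy(),
                             "block": ["base"] * len(self.base_names)
                             + ["finetune"] * len(self.finetune_names)})


def score_base_models(registry, features) -> pd.DataFrame:
    """Score the target cohort with every registry entry; no refitting.

    ``registry`` is an ordered list of (name, ScoreModel); ``features`` the
    target cohort's FeatureMatrix (or ndarray). Each base model's training
    bin layout must match the cohort's — cross-prediction relies on the
    shared eight-bin schedule.
    """
    from riskpipe.features import FeatureMatrix
    cols = {}
    for name, model in registry:
        if isinstance(features, FeatureMatrix) and model.columns \
                and model.columns != features.columns:
            raise ContractError(
                f"base model {name!r} was trained on a different column layout "
                "than the target cohort")
        cols[name] = model.score(features)
    return pd.DataFrame(cols)


def _logit_fit(X, y):
    """Unpenalized logistic fit; tiny-ridge fallback on separation."""
    import statsmodels.api as sm
    Xc = sm.add_constant(X, has_constant="add")
    note = ""
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = np.asarray(res.params)
            if not res.mle_retvals.get("converged", True) \
                    or not np.isfinite(params).all() or np.abs(params).max() > 50:
                params = None  # (quasi-)separation: coefficients diverging
        except Exception:
            params = None
    if params is None:
        note = "unpenalized fit separated or failed to converge; ridge 1e-6 fallback"
        log.warning(note)
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
        lr.fit(X, y)
        return float(lr.intercept_[0]), lr.coef_.ravel(), note
    return params[0], params[1:], note


def fit_ensemble(score_matrix: pd.DataFrame, finetune: pd.DataFrame,
                 outcome, even_mask, target: str = "combined") -> tuple:
    """Fine-tune the ensemble on even and odd halves; average coefficients.

    Returns ``(EnsembleModel, out_of_half_scores)`` where scores are on the
    log-odds scale and each row is scored by the half-model not trained on
    it.
    """
    y = np.asarray(outcome, dtype=float)
    even_mask = np.asarray(even_mask, dtype=bool)
    base_names = list(score_matrix.columns)
    ft_names = list(finetune.columns)
    X = np.hstack([score_matrix.to_numpy(dtype=float),
                   finetune.to_numpy(dtype=float)])
    names = base_names + ft_names
    if len(X) != len(y) or len(X) != len(even_mask):
        raise ContractError("score matrix, fine-tune block and outcome must align")
    if len(np.unique(y[even_mask])) < 2 or len(np.unique(y[~even_mask])) < 2:
        raise ContractError("an even/odd half has a single outcome class; "
                            "too few cases to fine-tune")

    # rank-deficiency guard: drop exact duplicate columns, keep the first
    dropped = []
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(1, X.shape[1]):
        if not keep[j]:
            continue
        for i in range(j):
            if keep[i] and np.array_equal(X[:, i], X[:, j]):
                keep[j] = False
                dropped.append(names[j])
                log.warning("dropping duplicate column %r from fine-tuning", names[j])
                break
    Xk = X[:, keep]
    kept_names = [n for n, k in zip(names, keep) if k]

    notes = []
    ic_e, beta_e, note_e = _logit_fit(Xk[even_mask], y[even_mask])
    ic_o, beta_o, note_o = _logit_fit(Xk[~even_mask], y[~even_mask])
    notes = "; ".join(x for x in (note_e, note_o) if x)
    beta = np.zeros(X.shape[1])
    beta[keep] = (beta_e + beta_o) / 2.0
    intercept = (ic_e + ic_o) / 2.0

    nb = len(base_names)
    model = EnsembleModel(base_names=base_names, base_coefficients=beta[:nb],
                          finetune_names=ft_names, finetune_coefficients=beta[nb:],
                          intercept=float(intercept), target=target,
                          dropped_columns=dropped, fit_note=notes)
    scores = np.empty(len(y))
    scores[~even_mask] = Xk[~even_mask] @ beta_e + ic_e   # even-trained on odd rows
    scores[even_mask] = Xk[even_mask] @ beta_o + ic_o
    return model, scores


def apply_ensemble(model: EnsembleModel, score_matrix: pd.DataFrame,
                   finetune: pd.DataFrame) -> np.ndarray:
    """Log-odds ensemble score; sigmoid of it is the predicted probability."""
    if list(score_matrix.columns) != list(model.base_names):
        raise ContractError("score matrix columns do not match the base registry")
    if list(finetune.columns) != list(model.finetune_names):
        raise ContractError("fine-tune columns do not match the fitted model")
    return (score_matrix.to_numpy(dtype=float) @ model.base_coefficients
            + finetune.to_numpy(dtype=float) @ model.finetune_coefficients
            + model.intercept)


def default_finetune_frame(fm, population) -> pd.DataFrame:
    """The ten fine-tuning covariates for a cohort's FeatureMatrix."""
    from riskpipe.features import aggregate_finetune
    out = aggregate_finetune(fm, population)
    assert list(out.columns) == list(FINETUNE_NAMES)
    return out
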