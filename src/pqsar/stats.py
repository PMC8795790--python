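"""Model validation: goodness of fit, seeded k-fold CV, external prediction.

The three-way protocol reports R^2 and RMSE for (i) the internal fit on the
training set, (ii) pooled out-of-fold predictions from a seeded 10-fold
cross-validation of the training set, and (iii) a single blind prediction
of the held-out test set.  R^2 is the coefficient of determination
1 - RSS/TSS with TSS about the evaluated set's own mean (so it can be
negative); the squared-Pearson alternative is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import apply_scaler, encode_panel, fit_scaler
from .panels import PeptidePanel, SplitSpec


def r_squared(y, y_hat, definition: str = "rss") -> float:
    """Coefficient of determination of predictions ``y_hat`` against ``y``.

    ``definition="rss"`` (default) is 1 - RSS/TSS; ``"pearson"`` is the
    squared Pearson correlation.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("R^2 is undefined for a constant response")
    if definition == "pearson":
        return float(np.corrcoef(y, y_hat)[0, 1] ** 2)
    rss = float(np.sum((y - y_hat) ** 2))
    return 1.0 - rss / tss


def rmse(y, y_hat) -> float:
    """Root-mean-square prediction error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 1:
        raise ValueError("need two equal-length nonempty vectors")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def make_folds(n: int, k: int, seed) -> list[np.ndarray]:
    """Seeded k-fold assignment: permute indices, split into near-equal folds.

    ``seed`` may be an int or a numpy Generator.  The remainder is spread
    one sample per fold.
    """
    if k < 2:
        raise ValueError(f"need at least 2 folds, got {k}")
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), k)


@dataclass(frozen=True)
class ModelStats:
    """The six-statistic validation record for one fitted panel model."""

    r2_fit: float
    rmse_fit: float
    r2_cv: float
    rmse_cv: float
    r2_prd: float
    rmse_prd: float
    n_train: int
    n_test: int
    method: str = ""
    table_name: str = ""
    seed: int | None = None
    params: dict = field(default_factory=dict)
    q2_trace: tuple = ()
    #: per-set prediction arrays kept for scatter export
    predictions: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.r2_fit > 1 + 1e-12:
            raise ValueError("r2_fit cannot exceed 1")
        for name in ("rmse_fit", "rmse_cv", "rmse_prd"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative")


def cross_validate(X, y, config, mode: str = "nested", fitted=None,
                   return_predictions: bool = False):
    """Seeded k-fold CV of the full modeling pipeline on training data.

    Within every fold the scaler is re-fitted on the fold's training part
    and the model is re-trained.  ``mode="nested"`` re-runs the method's
    hyperparameter selection inside each fold (the headline protocol);
    ``mode="flat"`` reuses the parameters already selected in ``fitted``
    on the full training set (cheaper, slightly optimistic).

    Returns ``(r2_cv, rmse_cv)``, plus the pooled out-of-fold prediction
    vector if ``return_predictions``.
    """
    from . import models  # deferred: models imports this module's helpers

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if mode not in ("nested", "flat"):
        raise ValueError(f"unknown CV mode {mode!r}")
    if mode == "flat" and fitted is None:
        raise ValueError("flat CV mode requires the fitted model")
    fold_config = config if mode == "nested" \
        else models.pin_config(config, fitted)
    folds = make_folds(len(y), config.cv_folds, config.seed)
    oof = np.empty_like(y)
    for test_idx in folds:
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        spec = fit_scaler(X[mask], models.scaling_for(fold_config))
        model = models.fit(apply_scaler(spec, X[mask]), y[mask], fold_config)
        oof[test_idx] = models.predict(model, apply_scaler(spec, X[test_idx]))
    result = (r_squared(y, oof), rmse(y, oof))
    return (*result, oof) if return_predictions else result


def evaluate(panel: PeptidePanel, table, config, split: SplitSpec,
             cv_mode: str = "nested", policy: str = "parent_residue") -> ModelStats:
    """Full protocol on one panel: fit on train, CV the train set, blind-test.

    The panel must be validated and log-transformed.  Test rows are used
    exactly once, for the external prediction; they never influence
    scaling, fitting or parameter selection.  ``cv_mode`` may be
    ``"nested"``, ``"flat"`` or ``"none"`` (skip CV, report NaN).
    """
    from . import models

    em = encode_panel(panel, table, policy=policy)
    tr = np.asarray(split.train_indices, dtype=int)
    te = np.asarray(split.test_indices, dtype=int)
    X_tr, y_tr = em.X[tr], em.y[tr]
    X_te, y_te = em.X[te], em.y[te]

    spec = fit_scaler(X_tr, models.scaling_for(config))
    model = models.fit(apply_scaler(spec, X_tr), y_tr, config)
    fit_pred = models.predict(model, apply_scaler(spec, X_tr))
    test_pred = models.predict(model, apply_scaler(spec, X_te))

    if cv_mode == "none":
        r2_cv = rmse_cv = float("nan")
        oof = None
    else:
        r2_cv, rmse_cv, oof = cross_validate(
            X_tr, y_tr, config, mode=cv_mode, fitted=model,
            return_predictions=True,
        )

    return ModelStats(
        r2_fit=r_squared(y_tr, fit_pred),
        rmse_fit=rmse(y_tr, fit_pred),
        r2_cv=r2_cv,
        rmse_cv=rmse_cv,
        r2_prd=r_squared(y_te, test_pred),
        rmse_prd=rmse(y_te, test_pred),
        n_train=len(tr),
        n_test=len(te),
        method=config.method,
        table_name=em.table_name,
        seed=config.seed,
        params=dict(model.params),
        q2_trace=tuple(model.q2_trace) if model.q2_trace else (),
        predictions={
            "train_sequences": tuple(em.sequences[i] for i in tr),
            "test_sequences": tuple(em.sequences[i] for i in te),
            "y_train": y_tr, "y_test": y_te,
            "train_fit": fit_pred, "cv_oof": oof, "test": test_pred,
        },
    )
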