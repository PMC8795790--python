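"""Positionwise descriptor encoding of peptide panels and feature scaling.

An L-mer encoded with an m-dimensional descriptor table becomes an L*m
feature vector: the concatenation of the residue vectors in sequence order.
A validated panel therefore becomes an (n_samples x L*m) matrix X with the
LogBLU vector y as response.

Two scaling schemes are provided, both fitted on training rows only:
autoscaling (zero mean, unit sample SD per column) and [-1,+1] range
scaling.  Columns that are constant on the training rows (routine when a
motif fixes a position) map to zero under both schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aad import AADError, AADTable
from .panels import PeptidePanel

SCALING_METHODS = ("autoscale", "range_pm1")


@dataclass(frozen=True)
class EncodedMatrix:
    """Feature matrix X (n x L*m), response y (LogBLU), and column labels."""

    X: np.ndarray
    y: np.ndarray
    columns: tuple
    table_name: str
    sequences: tuple = ()

    def __post_init__(self):
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X column count must match the column labels")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("y length must match the row count of X")


def encode_peptide(sequence: str, table: AADTable, policy: str = "parent_residue") -> np.ndarray:
    """Encode one peptide as the position-major concatenation of AAD vectors."""
    parts = []
    for pos, code in enumerate(sequence, start=1):
        try:
            parts.append(table.vector(code, policy=policy))
        except AADError:
            raise AADError(
                f"unresolvable residue {code!r} at position {pos} "
                f"under table {table.name!r}"
            ) from None
    return np.concatenate(parts) if parts else np.empty(0)


def encode_panel(panel: PeptidePanel, table: AADTable, policy: str = "parent_residue") -> EncodedMatrix:
    """Encode a validated, log-transformed panel into an EncodedMatrix."""
    L = panel.length  # raises on mixed lengths
    y = panel.log_affinities()
    X = np.empty((len(panel), L * table.m))
    for i, rec in enumerate(panel.records):
        X[i] = encode_peptide(rec.sequence, table, policy=policy)
    columns = tuple(
        f"pos{p}_c{c}" for p in range(1, L + 1) for c in range(1, table.m + 1)
    )
    return EncodedMatrix(
        X=X, y=y, columns=columns, table_name=table.name,
        sequences=tuple(panel.sequences),
    )


def export_encoded(em: EncodedMatrix, path) -> None:
    """Write an encoded panel as CSV: sequence, features, logblu."""
    with open(path, "w") as fh:
        fh.write("sequence," + ",".join(em.columns) + ",logblu\n")
        for seq, row, yv in zip(em.sequences, em.X, em.y):
            fh.write(seq + "," + ",".join(repr(float(v)) for v in row)
                     + f",{float(yv)!r}\n")


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScalingSpec:
    """Per-column affine scaling parameters estimated from training rows.

    ``center``/``halfwidth`` are (mean, SD) for autoscaling and
    (midrange, halfrange) for [-1,+1] scaling; ``degenerate`` marks
    constant training columns, which always scale to zero.
    """

    method: str
    center: np.ndarray
    halfwidth: np.ndarray
    degenerate: np.ndarray

    @property
    def n_columns(self) -> int:
        return self.center.size


def fit_scaler(X_train: np.ndarray, method: str = "autoscale") -> ScalingSpec:
    """Estimate scaling parameters from training rows only."""
    if method not in SCALING_METHODS:
        raise ValueError(
            f"unknown scaling method {method!r}; expected one of {SCALING_METHODS}"
        )
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0 or X_train.shape[0] == 0:
        raise ValueError("cannot fit a scaler on an empty matrix")
    if method == "autoscale":
        center = X_train.mean(axis=0)
        halfwidth = X_train.std(axis=0, ddof=1) if X_train.shape[0] > 1 \
            else np.zeros(X_train.shape[1])
    else:
        mn, mx = X_train.min(axis=0), X_train.max(axis=0)
        center = (mn + mx) / 2.0
        halfwidth = (mx - mn) / 2.0
    degenerate = halfwidth == 0
    return ScalingSpec(
        method=method,
        center=center,
        halfwidth=np.where(degenerate, 1.0, halfwidth),
        degenerate=degenerate,
    )


def apply_scaler(spec: ScalingSpec, X: np.ndarray) -> np.ndarray:
    """Scale rows (training or unseen) with the stored training parameters."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.n_columns:
        raise ValueError(
            f"matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
            f"scaler expects {spec.n_columns}"
        )
    out = (X - spec.center) / spec.halfwidth
    out[:, spec.degenerate] = 0.0
    return out


def inverse_scaler(spec: ScalingSpec, Xs: np.ndarray) -> np.ndarray:
    """Undo scaling for non-degenerate columns (degenerate ones return center)."""
    Xs = np.asarray(Xs, dtype=float)
    return Xs * spec.halfwidth + spec.center
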