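"""Per-subject functional connectomes from parcel time series.

A connectome here is the matrix of pairwise Pearson correlations between
regional (parcel) time series. One row of that matrix with the self-entry
removed is the parcel's *connectivity profile* — the feature vector on
which the per-parcel classifiers operate. Before correlation, parcel
series are cleaned by regressing out nuisance signals (white-matter and
CSF mean-signal analogs); motion regressors are deliberately not part of
the cleaning model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError


def _default_parcel_ids(p: int) -> tuple[str, ...]:
    width = max(3, len(str(p - 1)))
    return tuple(f"parcel{i:0{width}d}" for i in range(p))


@dataclass
class ParcelTimeSeries:
    """T x P array of parcel-mean signals (timepoints x parcels)."""

    values: np.ndarray
    parcel_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("time series must be a 2-D (T x P) array")
        if self.values.shape[0] < 3:
            raise ConfigurationError(
                f"need at least 3 timepoints, got T={self.values.shape[0]}"
            )
        if not np.isfinite(self.values).all():
            raise DegenerateDataError("time series contain non-finite values")
        if self.parcel_ids is None:
            self.parcel_ids = _default_parcel_ids(self.values.shape[1])
        self.parcel_ids = tuple(self.parcel_ids)
        if len(self.parcel_ids) != self.values.shape[1]:
            raise ConfigurationError("parcel_ids length does not match P")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]


@dataclass
class NuisanceSignals:
    """T x K nuisance regressors (K=2: WM and CSF mean-signal analogs).

    ``loadings`` optionally records the ground-truth K x P mixing matrix
    used by the synthetic generator, so cleaning can be verified exactly.
    """

    values: np.ndarray
    names: tuple[str, ...] | None = None
    loadings: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.names is None:
            self.names = tuple(f"nuisance{k}" for k in range(self.values.shape[1]))
        self.names = tuple(self.names)
        if len(self.names) != self.values.shape[1]:
            raise ConfigurationError("names length does not match K")


@dataclass
class Connectome:
    """Symmetric P x P Pearson-correlation matrix with unit diagonal."""

    matrix: np.ndarray
    parcel_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConfigurationError("connectome must be a square matrix")
        if np.abs(m - m.T).max() > 1e-12:
            raise ConfigurationError("connectome matrix is not symmetric")
        if not np.allclose(np.diag(m), 1.0, rtol=0, atol=0):
            raise ConfigurationError("connectome diagonal must be exactly 1")
        off = m[~np.eye(m.shape[0], dtype=bool)]
        if off.size and (off.min() < -1.0 or off.max() > 1.0):
            raise ConfigurationError("off-diagonal entries must lie in [-1, 1]")
        if self.parcel_ids is None:
            self.parcel_ids = _default_parcel_ids(m.shape[0])
        self.parcel_ids = tuple(self.parcel_ids)
        if len(self.parcel_ids) != m.shape[0]:
            raise ConfigurationError("parcel_ids length does not match P")

    @property
    def n_parcels(self) -> int:
        return self.matrix.shape[0]


def clean_timeseries(
    ts: ParcelTimeSeries, nuisance: NuisanceSignals
) -> ParcelTimeSeries:
    """Regress nuisance signals out of every parcel series.

    Each parcel series is replaced by its ordinary-least-squares residual
    against the design [intercept, nuisance columns]; residuals are
    therefore orthogonal to every nuisance column.
    """
    y = ts.values
    n = nuisance.values
    if n.shape[0] != y.shape[0]:
        raise ConfigurationError(
            f"timepoint mismatch: series T={y.shape[0]}, nuisance T={n.shape[0]}"
        )
    design = np.column_stack([np.ones(y.shape[0]), n])
    # identify collinear columns before solving so the error is actionable
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = ["intercept", *nuisance.names]
        names = [cols[i] for i in np.flatnonzero(bad)]
        raise DegenerateDataError(
            f"nuisance design is rank deficient; collinear column(s): {names}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return ParcelTimeSeries(resid, ts.parcel_ids)


def compute_connectome(ts: ParcelTimeSeries) -> Connectome:
    """Pairwise Pearson correlations between all parcel series."""
    sd = ts.values.std(axis=0)
    zero = np.flatnonzero(sd <= 1e-300)
    if zero.size:
        ids = [ts.parcel_ids[i] for i in zero]
        raise DegenerateDataError(
            f"zero-variance parcel series, cannot correlate: {ids}"
        )
    c = np.corrcoef(ts.values, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return Connectome(c, ts.parcel_ids)


def parcel_profile(c: Connectome, p: int) -> np.ndarray:
    """Connectivity profile of parcel ``p``: row ``p`` minus the self-entry.

    Length P-1 (435 at the full 436-parcel scale), in fixed parcel order.
    """
    n = c.n_parcels
    if not 0 <= p < n:
        raise ConfigurationError(f"parcel index {p} out of range [0, {n})")
    return np.delete(c.matrix[p], p)


def stack_profiles(connectomes: np.ndarray) -> np.ndarray:
    """Stack per-subject connectomes into per-parcel feature blocks.

    Parameters
    ----------
    connectomes : array, shape (n_subjects, P, P)

    Returns
    -------
    array, shape (n_subjects, P, P-1) — ``out[:, p, :]`` is the feature
    block for parcel ``p`` (row p of each subject's matrix, self-entry
    removed).
    """
    connectomes = np.asarray(connectomes, dtype=float)
    if connectomes.ndim != 3 or connectomes.shape[1] != connectomes.shape[2]:
        raise ConfigurationError("expected an (n, P, P) array of connectomes")
    n, p, _ = connectomes.shape
    out = np.empty((n, p, p - 1))
    for j in range(p):
        mask = np.arange(p) != j
        out[:, j, :] = connectomes[:, j, mask]
    return out


def make_parcel_label_table(
    n_cortical: int = 400, n_subcortical: int = 36
) -> pd.DataFrame:
    """Parcel label table: cortical + subcortical parcels.

    At full scale this mirrors the 400 cortical (Schaefer) + 36
    subcortical (Brainnetome) parcellation (436 parcels); smaller counts
    yield synthetic desk-scale labels. Internal indices are 0-based;
    ``atlas_id`` carries the atlas's native 1-based id.
    """
    rows = []
    for i in range(n_cortical):
        rows.append((i, "schaefer", i + 1, f"cortical_{i + 1:03d}"))
    for j in range(n_subcortical):
        rows.append(
            (n_cortical + j, "brainnetome", j + 1, f"subcortical_{j + 1:03d}")
        )
    return pd.DataFrame(
        rows, columns=["parcel_index", "atlas", "atlas_id", "label"]
    )
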