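"""Background-connectivity estimation from task-run time series.

"Background connectivity" is functional connectivity computed on the
residuals of a node-wise general linear model: the (already HRF-convolved)
task regressors and nuisance regressors are projected out of every node's
time series, and the pairwise Pearson correlations of the residuals are
Fisher z-transformed. Run-level matrices are averaged entrywise in z space
to give one connectome per subject.

An intercept column is always appended to the residualising design, and
correlations are clipped to +/-(1 - 1e-7) before arctanh so that perfectly
correlated residuals map to a large finite z instead of infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Connectome
from .errors import DegenerateSeriesError, IncompatibleInputError, ParameterError

#: Correlations are clipped to +/-(1 - FISHER_EPS) before arctanh.
FISHER_EPS = 1e-7


@dataclass
class RunTimeseries:
    """One run's T x N node time-series matrix (time points x nodes)."""

    data: np.ndarray
    run_id: str = "run0"
    subject_id: str = "s0"
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 3:
            raise ParameterError("time series must be T x N with T >= 3")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("time series contains non-finite values")
        if self.node_ids is None:
            self.node_ids = np.arange(self.data.shape[1])
        self.node_ids = np.asarray(self.node_ids, dtype=int)


@dataclass
class DesignMatrix:
    """Task and nuisance regressors for one run (T rows each)."""

    task: np.ndarray
    nuisance: np.ndarray | None = None

    def stacked(self, n_timepoints: int) -> np.ndarray:
        """Full design [task | nuisance | intercept] for the residual GLM."""
        cols = [np.atleast_2d(np.asarray(self.task, dtype=float).reshape(n_timepoints, -1))]
        if self.nuisance is not None and np.size(self.nuisance) > 0:
            cols.append(np.asarray(self.nuisance, dtype=float).reshape(n_timepoints, -1))
        cols.append(np.ones((n_timepoints, 1)))
        design = np.hstack(cols)
        if not np.all(np.isfinite(design)):
            raise ParameterError("design matrix contains non-finite values")
        return design


def residualize(data: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residuals of every column of ``data`` against ``design``."""
    beta, *_ = np.linalg.lstsq(design, data, rcond=None)
    return data - design @ beta


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """arctanh with clipping at +/-(1 - FISHER_EPS)."""
    return np.arctanh(np.clip(r, -(1.0 - FISHER_EPS), 1.0 - FISHER_EPS))


def background_connectivity(run: RunTimeseries, design: DesignMatrix) -> Connectome:
    """Residualize a run against its design and correlate the residuals.

    Raises
    ------
    DegenerateSeriesError
        If any node's residual has zero variance (e.g. the node series lies
        in the span of the design), naming the offending node.
    """
    T = run.data.shape[0]
    X = design.stacked(T)
    resid = residualize(run.data, X)
    sd = resid.std(axis=0)
    dead = np.flatnonzero(sd <= 1e-12 * max(1.0, np.abs(run.data).max()))
    if dead.size:
        raise DegenerateSeriesError(
            f"zero residual variance for node(s) {[int(run.node_ids[i]) for i in dead]}"
        )
    r = np.corrcoef(resid, rowvar=False)
    z = np.asarray(fisher_z(r), dtype=float)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return Connectome(z=z, nodes=run.node_ids, subject_id=run.subject_id, group="HC")


def average_runs(connectomes: list[Connectome]) -> Connectome:
    """Entrywise mean of run-level connectomes in Fisher-z space."""
    if not connectomes:
        raise ParameterError("need at least one run-level connectome")
    first = connectomes[0]
    for c in connectomes[1:]:
        if c.subject_id != first.subject_id:
            raise IncompatibleInputError(
                f"runs from different subjects: {c.subject_id} vs {first.subject_id}"
            )
        if not np.array_equal(c.nodes, first.nodes):
            raise IncompatibleInputError("runs have different retained node sets")
    mean_z = np.mean(np.stack([c.z for c in connectomes]), axis=0)
    return Connectome(
        z=mean_z, nodes=first.nodes.copy(), subject_id=first.subject_id, group=first.group
    )
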