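"""Picture-level nose temperatures -> one corrected temperature per event.

Chimpanzees rarely face the camera, and off-axis views read systematically
colder.  The correction treats the per-event mean temperature at each of
the seven head-orientation categories as a partially observed events x
angles matrix and completes it with a regularized iterative PCA (EM-PCA)
scheme, then takes the facing-angle column — observed where a facing
picture exists, imputed otherwise — as the event's facing-equivalent
temperature.  Downstream models work on its natural log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import ANGLE_CATEGORIES

logger = logging.getLogger(__name__)

#: usable capture window, seconds after event onset
TIME_WINDOW = (15, 300)
#: physiologically plausible nose-temperature bounds, deg C
PHYSIO_BOUNDS = (20.0, 42.0)


@dataclass
class AngleMatrix:
    """Events x angle-categories matrix of mean temperatures.

    ``values[i, j]`` is the mean temperature of event ``event_ids[i]``
    over its pictures at angle ``angles[j]``; NaN where the event has no
    picture at that angle.  ``angles[0]`` is always "facing".
    """

    event_ids: list[str]
    values: np.ndarray  # (n_events, n_angles), NaN = missing
    angles: tuple[str, ...] = ANGLE_CATEGORIES
    converged: bool = True
    n_iter: int = 0
    #: mask of cells observed in the source data (True = observed)
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]
    #: per-iteration sum of squared changes in imputed cells (set by the
    #: imputer; useful for convergence diagnostics)
    trace: list = field(default_factory=list)

    def __post_init__(self):
        if self.observed is None:
            self.observed = ~np.isnan(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "AngleMatrix":
        return AngleMatrix(list(self.event_ids), self.values.copy(),
                           self.angles, self.converged, self.n_iter,
                           self.observed.copy(), list(self.trace))


def filter_time_window(observations: pd.DataFrame,
                       window: tuple[int, int] = TIME_WINDOW,
                       bounds: tuple[float, float] = PHYSIO_BOUNDS) -> pd.DataFrame:
    """Keep pictures inside the capture window and physiological bounds."""
    lo, hi = window
    keep = observations["sec_after_event"].between(lo, hi)
    keep &= observations["temp_c"].between(*bounds)
    dropped = int((~keep).sum())
    if dropped:
        logger.warning("dropped %d pictures outside the %d-%d s window or "
                       "physiological bounds", dropped, lo, hi)
    return observations.loc[keep].reset_index(drop=True)


def build_angle_matrix(observations: pd.DataFrame,
                       angles: tuple[str, ...] = ANGLE_CATEGORIES) -> AngleMatrix:
    """Aggregate filtered pictures into the events x angles mean matrix.

    Events with zero valid pictures are excluded (they never appear as
    rows); cells with no picture are NaN.
    """
    if observations.empty:
        raise ValueError("no observations after filtering")
    unknown = set(observations["angle"]) - set(angles)
    if unknown:
        raise ValueError(f"unknown angle categories: {sorted(unknown)}")
    cell = (observations.groupby(["event_id", "angle"], sort=True)["temp_c"]
            .mean().unstack("angle"))
    cell = cell.reindex(columns=list(angles))
    return AngleMatrix(event_ids=list(cell.index), values=cell.to_numpy(float))


def impute_regularized_pca(matrix: AngleMatrix, rank: int = 2,
                           tol: float = 1e-6, max_iter: int = 1000,
                           regularized: bool = True) -> AngleMatrix:
    """Complete the angle matrix by regularized iterative PCA (EM-PCA).

    Missing cells start at their column means; each iteration centers the
    columns on the current filled-in values, takes an SVD, reconstructs
    with the top ``rank`` components (singular values shrunk by the noise
    estimate from the discarded components when ``regularized``), and
    overwrites the missing cells with the reconstruction.  Stops when the
    sum of squared changes in imputed cells falls below ``tol``.

    Observed cells are returned bit-identical; only missing cells change.
    """
    X = matrix.values
    n, p = X.shape
    if rank >= min(n, p):
        raise ValueError(f"rank must be < min(n_events={n}, n_angles={p})")
    miss = np.isnan(X)
    if miss.all(axis=0).any():
        bad = [matrix.angles[j] for j in np.where(miss.all(axis=0))[0]]
        raise ValueError(f"angle columns with no observations: {bad}")
    if not miss.any():
        out = matrix.copy()
        out.converged, out.n_iter = True, 0
        return out

    filled = X.copy()
    col_means = np.nanmean(X, axis=0)
    filled[miss] = np.take(col_means, np.where(miss)[1])

    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        mu = filled.mean(axis=0)
        centered = filled - mu
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        s_use = s[:rank].copy()
        if regularized and len(s) > rank:
            # noise level estimated as the mean discarded squared singular
            # value; retained values are shrunk s -> (s^2 - sigma^2)/s,
            # which damps the reconstruction toward the column means and
            # guards against overfitting the observed cells
            sigma2 = float(np.mean(s[rank:] ** 2))
            s_use = np.maximum((s_use**2 - sigma2) / s_use, 0.0)
        recon = (U[:, :rank] * s_use) @ Vt[:rank] + mu
        delta = float(np.sum((recon[miss] - filled[miss]) ** 2))
        trace.append(delta)
        filled[miss] = recon[miss]
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("regularized PCA imputation did not converge in %d "
                       "iterations (last change %.3g)", max_iter, delta)

    out = AngleMatrix(list(matrix.event_ids), filled, matrix.angles,
                      converged, it, observed=~miss, trace=trace)
    return out


def correct_events(matrix: AngleMatrix, bounds: tuple[float, float] = PHYSIO_BOUNDS
                   ) -> pd.DataFrame:
    """Facing-equivalent temperature per event from the completed matrix.

    Events with an observed facing cell use it directly; the rest use the
    imputed facing value (``was_imputed=True``).  Imputed values outside
    physiological bounds are flagged ``excluded`` and should not enter
    downstream models.  Returns columns: event_id, corrected_temp_c,
    log_temp, was_imputed, excluded.
    """
    if matrix.n_missing:
        raise ValueError("matrix must be completed before correcting events")
    facing_col = matrix.angles.index("facing")
    temps = matrix.values[:, facing_col]
    was_imputed = ~matrix.observed[:, facing_col]
    excluded = was_imputed & ~((temps >= bounds[0]) & (temps <= bounds[1]))
    if excluded.any():
        logger.warning("%d imputed facing temperatures outside %s excluded",
                       int(excluded.sum()), bounds)
    out = pd.DataFrame({
        "event_id": matrix.event_ids,
        "corrected_temp_c": temps,
        "log_temp": np.log(np.where(temps > 0, temps, np.nan)),
        "was_imputed": was_imputed,
        "excluded": excluded,
    })
    frac = float(was_imputed.mean()) if len(out) else 0.0
    logger.info("corrected %d of %d events by imputation (%.2f%%)",
                int(was_imputed.sum()), len(out), 100 * frac)
    return out
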