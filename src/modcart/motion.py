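"""Head-motion quality control for resting-state time series.

Framewise displacement (FD) summarises volume-to-volume head movement as the
sum of absolute changes in the six rigid-body realignment parameters
(3 translations, 3 rotations).  Rotations are expected *already expressed in
mm* — i.e. as arc length on a 50-mm sphere, the Power convention — so the six
columns are summed directly without any internal unit conversion.

Rules implemented here:

* subjects with mean FD strictly greater than 0.2 mm are excluded;
* "low-motion frames" are volumes with FD strictly below 0.2 mm;
* nuisance signals (motion parameters, tissue signals, ...) are removed from
  node time series by ordinary least squares residualisation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: default mean-FD exclusion / low-motion threshold, mm
FD_THRESHOLD_MM = 0.2


def _as_trace(trace) -> np.ndarray:
    arr = np.asarray(trace, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(
            f"motion trace must be (n_volumes, 6), got shape {arr.shape}"
        )
    if arr.shape[0] < 2:
        raise ValueError("FD needs at least 2 consecutive volumes")
    if not np.isfinite(arr).all():
        raise ValueError("motion trace contains NaN/inf values")
    return arr


def framewise_displacement(trace) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    FD_i = |Δd_ix| + |Δd_iy| + |Δd_iz| + |Δα_i| + |Δβ_i| + |Δγ_i|,
    with the first volume's FD set to 0 by convention (it has no
    predecessor) and *included* in means over the series.

    Parameters
    ----------
    trace : array-like, shape (n_volumes, 6)
        Rigid-body parameters; rotations already in mm.

    Returns
    -------
    ndarray, shape (n_volumes,)
    """
    arr = _as_trace(trace)
    fd = np.zeros(arr.shape[0])
    fd[1:] = np.abs(np.diff(arr, axis=0)).sum(axis=1)
    return fd


def mean_fd(trace) -> float:
    """Mean FD over all volumes (first volume counted as 0)."""
    return float(framewise_displacement(trace).mean())


def exclude_high_motion(
    phenotypes: pd.DataFrame, fd_threshold: float = FD_THRESHOLD_MM
) -> tuple[list, pd.DataFrame]:
    """Drop subjects whose mean FD exceeds ``fd_threshold`` (strict ``>``).

    Parameters
    ----------
    phenotypes : DataFrame with columns ``subject_id`` and ``mean_fd``.
    fd_threshold : exclusion threshold in mm; a subject with mean FD exactly
        at the threshold is retained.

    Returns
    -------
    (retained_ids, report)
        ``retained_ids`` — subject ids kept, in input order;
        ``report`` — DataFrame (subject_id, mean_fd, excluded).
    """
    if len(phenotypes) == 0:
        raise ValueError("empty cohort: nothing to exclude from")
    if phenotypes["mean_fd"].isna().any():
        raise ValueError("mean_fd missing for some subjects")
    excluded = phenotypes["mean_fd"].to_numpy() > fd_threshold
    report = pd.DataFrame(
        {
            "subject_id": phenotypes["subject_id"].to_numpy(),
            "mean_fd": phenotypes["mean_fd"].to_numpy(),
            "excluded": excluded,
        }
    )
    retained = list(phenotypes.loc[~excluded, "subject_id"])
    return retained, report


def count_low_motion_frames(fd, fd_threshold: float = FD_THRESHOLD_MM) -> int:
    """Number of volumes with FD strictly below ``fd_threshold``."""
    fd = np.asarray(fd, dtype=float)
    if fd.ndim != 1:
        raise ValueError("fd must be a 1-D series")
    if not np.isfinite(fd).all():
        raise ValueError("fd series contains NaN/inf")
    return int(np.sum(fd < fd_threshold))


def residualize_nuisance(ts, nuisance=None) -> np.ndarray:
    """Regress nuisance signals out of every node's time series.

    Each column of ``ts`` is replaced by its OLS residual on
    ``[intercept, nuisance]``; with no nuisance regressors this demeans the
    data.  Residuals are orthogonal to every regressor.

    Parameters
    ----------
    ts : (n_volumes, n_nodes) array
    nuisance : (n_volumes, k) array or None

    Raises
    ------
    ValueError
        on volume-count mismatch or a rank-deficient design (the offending
        columns are named in the message).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be 2-D (volumes x nodes)")
    n_vol = ts.shape[0]
    if nuisance is None or (hasattr(nuisance, "size") and np.size(nuisance) == 0):
        design = np.ones((n_vol, 1))
    else:
        nuis = np.asarray(nuisance, dtype=float)
        if nuis.ndim == 1:
            nuis = nuis[:, None]
        if nuis.shape[0] != n_vol:
            raise ValueError(
                f"nuisance has {nuis.shape[0]} volumes, time series has {n_vol}"
            )
        design = np.column_stack([np.ones(n_vol), nuis])
        # name rank-deficient columns via QR pivots
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            _, r = np.linalg.qr(design)
            bad = np.where(np.abs(np.diag(r)) < 1e-10 * np.abs(r[0, 0]))[0]
            raise ValueError(
                "rank-deficient nuisance design; offending design columns "
                f"(0 = intercept): {bad.tolist()}"
            )
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


# ---------------------------------------------------------------------------
# file I/O

def read_motion_file(path) -> np.ndarray:
    """Read a 6-column whitespace-delimited realignment-parameter file."""
    arr = np.loadtxt(path)
    return _as_trace(arr)


def write_fd_series(fd, path) -> None:
    np.savetxt(path, np.asarray(fd, dtype=float), fmt="%.8g")


def qc_summary(
    traces: dict, fd_threshold: float = FD_THRESHOLD_MM
) -> pd.DataFrame:
    """Per-subject QC table: mean FD, low-motion frame count, exclusion flag.

    ``traces`` maps subject_id -> (n_volumes, 6) motion trace.
    """
    rows = []
    for sid, trace in traces.items():
        fd = framewise_displacement(trace)
        m = float(fd.mean())
        rows.append(
            {
                "subject_id": sid,
                "mean_fd": m,
                "n_low_motion_frames": count_low_motion_frames(fd, fd_threshold),
                "excluded": m > fd_threshold,
            }
        )
    return pd.DataFrame(rows)
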