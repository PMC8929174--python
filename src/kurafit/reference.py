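"""Reference connectivity measures: partial correlation, phase synchrony, AR(1).

These are the three comparison measures computed on the same region time
courses as the Kuramoto couplings:

* **FC** — full-order partial correlation between every region pair,
  controlling for all remaining regions (precision-matrix formula), on
  0.01–0.1 Hz filtered data.
* **PS** — phase synchrony: the median over time of ``cos(phi_j - phi_i)``,
  on phases from the same narrow band (0.05–0.075 Hz) as K.
* **AR** — the transition matrix of a first-order vector autoregression
  ``x(t) = A x(t-1) + eps(t)``, fitted by least squares on 0.01–0.1 Hz
  filtered data (diagonal entries are estimated, not conventioned).
"""

from __future__ import annotations

import numpy as np

from .errors import SingularSystemError, ValidationError
from .kuramoto import CouplingMatrix
from .signals import (
    NARROW_BAND,
    WIDE_BAND,
    AnalyticPhaseSet,
    TimeCourseSet,
    analytic_phase,
    bandpass_filter,
)

__all__ = ["partial_correlation", "phase_synchrony", "ar1_coefficients"]


def partial_correlation(
    tc: TimeCourseSet,
    band: tuple[float, float] | None = WIDE_BAND,
    filter_order: int = 7,
) -> CouplingMatrix:
    """Full-order partial correlations between all region pairs.

    Entry (i, j) is the correlation of regions i and j after regressing out
    all remaining r-2 regions, computed from the precision (inverse
    correlation) matrix: ``-P_ij / sqrt(P_ii * P_jj)``.  ``band=None`` skips
    filtering (useful for already-filtered or synthetic input).
    """
    data = tc.data
    if band is not None:
        data = bandpass_filter(tc, band[0], band[1], order=filter_order).data
    r, T = data.shape
    if T <= r:
        raise ValidationError(f"need T > r to invert the covariance (T={T}, r={r})")
    corr = np.corrcoef(data)
    if not np.all(np.isfinite(corr)):
        bad = [tc.region_labels[i] for i in np.flatnonzero(~np.isfinite(np.diag(corr)))]
        raise SingularSystemError(f"constant region series: {bad}")
    cond = np.linalg.cond(corr)
    if cond > 1e12:
        # name the most collinear pair to aid debugging
        off = corr - np.eye(r)
        i, j = np.unravel_index(np.argmax(np.abs(off)), off.shape)
        raise SingularSystemError(
            f"correlation matrix numerically singular (cond={cond:.3g}); "
            f"most collinear pair: {tc.region_labels[i]}, {tc.region_labels[j]}"
        )
    prec = np.linalg.inv(corr)
    d = np.sqrt(np.diag(prec))
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    pc = 0.5 * (pc + pc.T)  # kill rounding asymmetry
    return CouplingMatrix(
        values=pc,
        measure="FC",
        directed=False,
        region_labels=list(tc.region_labels),
        subject_id=tc.subject_id,
    )


def phase_synchrony(phases: AnalyticPhaseSet) -> CouplingMatrix:
    """Median-over-time cosine of pairwise phase differences.

    ``PS_ij = median_t cos(phi_j(t) - phi_i(t))``; symmetric because cosine
    is even, values in [-1, 1], diagonal exactly 1.  Phases should come from
    the narrow band used for K (the band travels on the input and is recorded
    in the result's metadata by callers that need the audit).
    """
    phi = phases.phases
    r = phi.shape[0]
    # cos(phi_j - phi_i) for all pairs at once: (r, r, T)
    diff = phi[None, :, :] - phi[:, None, :]
    ps = np.median(np.cos(diff), axis=2)
    ps = 0.5 * (ps + ps.T)
    np.fill_diagonal(ps, 1.0)
    return CouplingMatrix(
        values=ps,
        measure="PS",
        directed=False,
        region_labels=list(phases.region_labels),
        subject_id=phases.subject_id,
    )


def phase_synchrony_from_timecourses(
    tc: TimeCourseSet,
    band: tuple[float, float] = NARROW_BAND,
    filter_order: int = 7,
) -> CouplingMatrix:
    """Convenience pipeline: band-pass -> analytic phases -> PS."""
    filtered = bandpass_filter(tc, band[0], band[1], order=filter_order)
    return phase_synchrony(analytic_phase(filtered, band))


def ar1_coefficients(
    tc: TimeCourseSet,
    band: tuple[float, float] | None = WIDE_BAND,
    filter_order: int = 7,
    demean: bool = True,
    intercept: bool = False,
) -> CouplingMatrix:
    """First-order vector-autoregression transition matrix.

    Fits ``x(t) = A x(t-1) + eps(t)`` by multivariate least squares through
    statsmodels' VAR machinery.  The model has no intercept; per-region mean
    removal (``demean=True``, default) is the minimal reconciliation with
    non-zero-mean data.  ``intercept=True`` instead fits a constant term.
    Diagonal entries (auto-regression of a series on itself) are estimated
    like any other entry.
    """
    from statsmodels.tsa.api import VAR

    data = tc.data
    if band is not None:
        data = bandpass_filter(tc, band[0], band[1], order=filter_order).data
    if demean and not intercept:
        data = data - data.mean(axis=1, keepdims=True)
    # statsmodels expects (T, r)
    model = VAR(data.T)
    trend = "c" if intercept else "n"
    try:
        res = model.fit(maxlags=1, trend=trend)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise SingularSystemError(f"rank-deficient lagged design: {exc}") from exc
    A = np.asarray(res.coefs[0])  # x(t) = A x(t-1): A[i, j] = j -> i
    if not np.all(np.isfinite(A)):
        raise SingularSystemError("rank-deficient lagged design (non-finite fit)")
    return CouplingMatrix(
        values=A,
        measure="AR",
        directed=True,
        region_labels=list(tc.region_labels),
        subject_id=tc.subject_id,
        diagonal_convention=None,
    )
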