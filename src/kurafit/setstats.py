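"""Set-level permutation statistics for coupling-regressor dependence.

The question these tests answer is not "which coupling correlates with the
score?" but "are there *more* individually-significant couplings than chance
would produce?".  Per coupling, a simple statistic is computed across
subjects (Spearman correlation to a regressor, Wilcoxon rank-sum between two
groups, or Wilcoxon signed-rank against zero) and thresholded at an
uncorrected ``P_u``; the resulting *set size* is then compared against a
null distribution obtained by randomly permuting each subject's couplings
among coupling positions.  This targets widespread, moderate effects rather
than single localised ones.

Additional machinery: covariate residualisation, Bonferroni bookkeeping for
the small family of regressors x directions, and phase-randomised surrogate
testing (same amplitude spectra, randomised Fourier phases) as an
estimation-bias control.

Implementation note: the per-coupling statistics are computed by a
vectorised column-wise engine (hundreds of couplings x hundreds of
permutations make scalar scipy calls prohibitive); the engine is unit-tested
against scipy's scalar implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations as _iter_permutations
from typing import Callable, Sequence

import numpy as np
from scipy import stats as ss

from .errors import ValidationError
from .kuramoto import MeasureStack
from .signals import TimeCourseSet

__all__ = [
    "Regressor",
    "SetLevelResult",
    "SetLevelTest",
    "correlate_couplings",
    "set_level_test",
    "group_set_test",
    "nonzero_set_test",
    "regress_out_covariate",
    "bonferroni_report",
    "phase_randomized_surrogates",
    "surrogate_set_test",
]

DIRECTIONS = ("bidirectional", "positive", "negative")
#: Spearman p-values switch from exact enumeration to the t approximation
#: above this per-coupling sample size.
EXACT_MAX_N = 9
#: Minimum subjects surviving outlier removal for a per-coupling p-value.
MIN_SUBJECTS = 4


@dataclass
class Regressor:
    """A per-subject scalar regressor (clinical score, age, group label)."""

    values: np.ndarray
    name: str = "score"
    kind: str = "score"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("regressor must be a 1-D vector")
        if self.kind not in ("score", "covariate", "group"):
            raise ValidationError(f"unknown regressor kind {self.kind!r}")
        if self.kind == "score" and np.ptp(self.values) == 0:
            raise ValidationError(f"score regressor {self.name!r} is constant")
        if self.kind == "group" and set(np.unique(self.values)) - {0.0, 1.0}:
            raise ValidationError("group regressor must be binary (0/1)")


# ---------------------------------------------------------------------------
# coupling-position bookkeeping
# ---------------------------------------------------------------------------

def _positions(r: int, symmetric: bool) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the counted coupling positions.

    Upper triangle for symmetric measures (FC, PS); all off-diagonal
    positions for directed measures (K, AR).
    """
    if symmetric:
        return np.triu_indices(r, k=1)
    mask = ~np.eye(r, dtype=bool)
    return np.nonzero(mask)


def _to_matrix(vec: np.ndarray, r: int, symmetric: bool) -> np.ndarray:
    out = np.full((r, r), np.nan)
    ii, jj = _positions(r, symmetric)
    out[ii, jj] = vec
    if symmetric:
        out[jj, ii] = vec
    return out


def _outlier_mask(V: np.ndarray, outlier_sd: float) -> np.ndarray:
    """Per-column inclusion mask: keep values within ``outlier_sd`` SDs of the mean."""
    if outlier_sd is None or not np.isfinite(outlier_sd):
        return np.ones_like(V, dtype=bool)
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        mask = np.abs(V - mean) <= outlier_sd * sd
    mask[:, sd == 0] = True
    return mask


def _rank_columns(V: np.ndarray) -> np.ndarray:
    """Column-wise average ranks; NaN entries stay NaN and are skipped."""
    return ss.rankdata(V, method="average", axis=0, nan_policy="omit")


# ---------------------------------------------------------------------------
# vectorised per-coupling statistics
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _perm_table(n: int) -> np.ndarray:
    return np.array(list(_iter_permutations(range(n))), dtype=np.int8)


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, direction: str) -> float:
    """Exact permutation p for the Spearman statistic of two rank vectors."""
    n = rx.size
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 1.0
    obs = float(rx @ ry / denom)
    P = _perm_table(n)
    null = (ry[P] @ rx) / denom
    eps = 1e-12
    if direction == "bidirectional":
        return float(np.mean(np.abs(null) >= abs(obs) - eps))
    if direction == "positive":
        return float(np.mean(null >= obs - eps))
    return float(np.mean(null <= obs + eps))


def _directional_p(two_sided: np.ndarray, stat: np.ndarray, direction: str) -> np.ndarray:
    """Map two-sided p-values to sign-restricted one-sided ones."""
    if direction == "bidirectional":
        return two_sided
    half = two_sided / 2.0
    if direction == "positive":
        return np.where(stat >= 0, half, 1.0 - half)
    if direction == "negative":
        return np.where(stat <= 0, half, 1.0 - half)
    raise ValidationError(f"unknown direction {direction!r}")


def _spearman_columns(
    V: np.ndarray,
    score: np.ndarray,
    direction: str,
    outlier_sd: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spearman rho and p of each column of V against the score.

    Outliers (> outlier_sd SDs from the column mean) are excluded per
    column before ranking; columns left with fewer than MIN_SUBJECTS
    subjects get p = 1 and rho = NaN.  p-values use the large-sample t
    approximation for n > EXACT_MAX_N and exact permutation enumeration
    otherwise (matching scipy's scalar behaviour at large n).
    """
    s, m = V.shape
    mask = _outlier_mask(V, outlier_sd)
    n = mask.sum(axis=0)
    Vm = np.where(mask, V, np.nan)
    Sm = np.where(mask, score[:, None], np.nan)
    rx = _rank_columns(Vm)
    ry = _rank_columns(Sm)

    mx = np.nanmean(rx, axis=0)
    my = np.nanmean(ry, axis=0)
    dx = np.where(mask, rx - mx, 0.0)
    dy = np.where(mask, ry - my, 0.0)
    cov = (dx * dy).sum(axis=0)
    varx = (dx**2).sum(axis=0)
    vary = (dy**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = cov / np.sqrt(varx * vary)
    rho[(varx == 0) | (vary == 0)] = np.nan

    p = np.ones(m)
    valid = (n >= MIN_SUBJECTS) & np.isfinite(rho)
    # t approximation for the large-n columns
    large = valid & (n > EXACT_MAX_N)
    if np.any(large):
        r_ = np.clip(rho[large], -1.0, 1.0)
        df = n[large] - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r_ * np.sqrt(df / (1.0 - r_**2))
        two = 2.0 * ss.t.sf(np.abs(t), df)
        two = np.where(np.isfinite(t), two, 0.0)  # |rho| == 1
        p[large] = _directional_p(two, r_, direction)
    # exact enumeration for small-n columns
    small = np.flatnonzero(valid & (n <= EXACT_MAX_N))
    for k in small:
        keep = mask[:, k]
        p[k] = _exact_spearman_p(rx[keep, k], ry[keep, k], direction)
    return rho, p, n


def _ranksum_columns(
    Va: np.ndarray,
    Vb: np.ndarray,
    direction: str,
    outlier_sd: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wilcoxon rank-sum z and p per column (group a vs group b).

    Normal approximation identical to ``scipy.stats.ranksums``; the
    ``positive`` direction means larger values in group a.  Outliers are
    removed per column within each group.
    """
    ma = _outlier_mask(Va, outlier_sd)
    mb = _outlier_mask(Vb, outlier_sd)
    n1 = ma.sum(axis=0).astype(float)
    n2 = mb.sum(axis=0).astype(float)
    stacked = np.vstack(
        [np.where(ma, Va, np.nan), np.where(mb, Vb, np.nan)]
    )
    ranks = _rank_columns(stacked)
    W = np.nansum(np.where(np.vstack([ma, np.zeros_like(mb)]), ranks, 0.0), axis=0)
    expected = n1 * (n1 + n2 + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (W - expected) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    two = 2.0 * ss.norm.sf(np.abs(z))
    p = _directional_p(two, z, direction)
    n_used = n1 + n2
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(z)
    p[bad] = 1.0
    z[~np.isfinite(z)] = np.nan
    return z, p, n_used


def _signrank_columns(
    V: np.ndarray,
    direction: str,
    outlier_sd: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wilcoxon signed-rank z and p per column, testing medians against zero.

    Normal approximation with tie correction and without continuity
    correction (``scipy.stats.wilcoxon(..., method="approx",
    correction=False)``); zeros are dropped.  ``positive`` direction means
    median above zero.
    """
    mask = _outlier_mask(V, outlier_sd)
    m = V.shape[1]
    z = np.full(m, np.nan)
    p = np.ones(m)
    n_used = np.zeros(m)
    for k in range(m):
        d = V[mask[:, k], k]
        d = d[d != 0.0]
        n = d.size
        n_used[k] = n
        if n < MIN_SUBJECTS:
            continue
        r = ss.rankdata(np.abs(d))
        w_plus = r[d > 0].sum()
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(r, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        if var <= 0:
            continue
        z[k] = (w_plus - mu) / np.sqrt(var)
    two = 2.0 * ss.norm.sf(np.abs(z))
    with np.errstate(invalid="ignore"):
        p_dir = _directional_p(two, z, direction)
    ok = np.isfinite(z)
    p[ok] = p_dir[ok]
    return z, p, n_used


# ---------------------------------------------------------------------------
# public per-coupling interface
# ---------------------------------------------------------------------------

def correlate_couplings(
    stack: MeasureStack,
    score: Regressor,
    direction: str = "bidirectional",
    outlier_sd: float | None = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coupling Spearman correlation to a regressor.

    Returns (rho, p) as r x r matrices with NaN diagonals (symmetric
    measures are mirrored).  Subjects deviating more than ``outlier_sd``
    standard deviations from a coupling's cross-subject mean are excluded
    for that coupling; couplings left with fewer than four subjects get
    p = 1.
    """
    _check_direction(direction)
    if score.values.size != stack.n_subjects:
        raise ValidationError("regressor length must match the subject count")
    if np.ptp(score.values) == 0:
        raise ValidationError("regressor is constant")
    ii, jj = _positions(stack.n_regions, stack.symmetric)
    V = stack.tensor[:, ii, jj]
    rho, p, _ = _spearman_columns(V, score.values, direction, outlier_sd)
    r = stack.n_regions
    return _to_matrix(rho, r, stack.symmetric), _to_matrix(p, r, stack.symmetric)


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValidationError(
            f"direction must be one of {DIRECTIONS}, got {direction!r}"
        )


# ---------------------------------------------------------------------------
# set-level results
# ---------------------------------------------------------------------------

@dataclass
class SetLevelResult:
    """Outcome of a set-level permutation test.

    ``per_coupling_stat`` holds Spearman rho for correlation tests and the
    Wilcoxon z statistic for group/nonzero tests; ``p_set`` uses the
    add-one-permutation convention ``(1 + #{null >= observed}) / (1 + n_perm)``
    so it can never be exactly zero.
    """

    direction: str
    per_coupling_stat: np.ndarray
    per_coupling_p: np.ndarray
    observed_set_size: int
    null_set_sizes: np.ndarray
    p_set: float
    threshold_pu: float
    n_permutations: int
    significant_couplings: list[tuple[int, int]]
    measure: str = "K"
    kind: str = "correlation"
    seed: int | None = None
    regressor_name: str | None = None
    metadata: dict = field(default_factory=dict)

    # backwards-compatible alias used throughout reports
    @property
    def per_coupling_rho(self) -> np.ndarray:
        return self.per_coupling_stat

    def summary(self) -> str:
        null = self.null_set_sizes
        lines = [
            f"Set-level permutation test ({self.kind}, {self.measure})",
            "=" * 52,
            f"direction:            {self.direction}",
            f"regressor:            {self.regressor_name or '-'}",
            f"uncorrected P_u:      < {self.threshold_pu}",
            f"observed set size:    {self.observed_set_size}",
            f"null set size:        median {np.median(null):.0f}, "
            f"95th pct {np.percentile(null, 95):.0f}, max {null.max()}",
            f"permutations:         {self.n_permutations}",
            f"P_set:                {self.p_set:.4g}",
            f"significant couplings: {len(self.significant_couplings)}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "measure": self.measure,
            "direction": self.direction,
            "regressor": self.regressor_name,
            "threshold_pu": self.threshold_pu,
            "n_permutations": self.n_permutations,
            "observed_set_size": int(self.observed_set_size),
            "p_set": float(self.p_set),
            "seed": self.seed,
            "null_set_sizes": [int(x) for x in self.null_set_sizes],
            "significant_couplings": [
                [int(i), int(j)] for i, j in self.significant_couplings
            ],
            "metadata": self.metadata,
        }

    def edge_list(self) -> list[dict]:
        """Significant couplings as rows suitable for a delimited edge table."""
        rows = []
        for i, j in self.significant_couplings:
            rows.append(
                {
                    "target": int(i),
                    "source": int(j),
                    "stat": float(self.per_coupling_stat[i, j]),
                    "p": float(self.per_coupling_p[i, j]),
                    "direction": self.direction,
                }
            )
        return rows

    def plot_null(self, ax=None):
        """Histogram of the null set sizes with the observed size marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_set_sizes, bins=30, color="0.7")
        ax.axvline(self.observed_set_size, color="C0", lw=2)
        ax.set_xlabel("set size")
        ax.set_ylabel("permutations")
        ax.set_title(f"P_set = {self.p_set:.3g}")
        return ax


# ---------------------------------------------------------------------------
# set-level test engine
# ---------------------------------------------------------------------------

def _run_set_test(
    V_groups: list[np.ndarray],
    stat_fn: Callable[[list[np.ndarray]], tuple[np.ndarray, np.ndarray]],
    n_perm: int,
    threshold_pu: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray, float]:
    """Shared permutation machinery.

    ``stat_fn`` maps the list of (subjects x couplings) matrices to a
    (stat, p) pair; the null shuffles every subject's couplings among
    positions, independently per subject and permutation.
    """
    import warnings as _warnings

    if n_perm < 100:
        _warnings.warn(
            f"n_perm={n_perm} is low; permutation p-values may be unstable",
            stacklevel=3,
        )
    stat, p = stat_fn(V_groups)
    observed = int(np.count_nonzero(p < threshold_pu))
    rng = np.random.default_rng(seed)
    null_sizes = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm_groups = [rng.permuted(V, axis=1) for V in V_groups]
        _, p_b = stat_fn(perm_groups)
        null_sizes[b] = np.count_nonzero(p_b < threshold_pu)
    p_set = (1.0 + np.count_nonzero(null_sizes >= observed)) / (1.0 + n_perm)
    return stat, p, observed, null_sizes, p_set


def _finish_result(
    stack: MeasureStack,
    stat_vec: np.ndarray,
    p_vec: np.ndarray,
    observed: int,
    null_sizes: np.ndarray,
    p_set: float,
    direction: str,
    threshold_pu: float,
    n_perm: int,
    seed: int,
    kind: str,
    regressor_name: str | None,
    metadata: dict,
) -> SetLevelResult:
    r = stack.n_regions
    ii, jj = _positions(r, stack.symmetric)
    sig = [(int(i), int(j)) for i, j, pv in zip(ii, jj, p_vec) if pv < threshold_pu]
    return SetLevelResult(
        direction=direction,
        per_coupling_stat=_to_matrix(stat_vec, r, stack.symmetric),
        per_coupling_p=_to_matrix(p_vec, r, stack.symmetric),
        observed_set_size=observed,
        null_set_sizes=null_sizes,
        p_set=p_set,
        threshold_pu=threshold_pu,
        n_permutations=n_perm,
        significant_couplings=sig,
        measure=stack.measure,
        kind=kind,
        seed=seed,
        regressor_name=regressor_name,
        metadata=metadata,
    )


def set_level_test(
    stack: MeasureStack,
    score: Regressor,
    direction: str = "bidirectional",
    n_perm: int = 500,
    threshold_pu: float = 0.05,
    seed: int | None = None,
    outlier_sd: float | None = 2.0,
) -> SetLevelResult:
    """Set-level test of coupling-regressor dependence (Spearman based)."""
    _check_direction(direction)
    if seed is None:
        raise ValidationError("a seed is required for a reproducible null")
    if stack.n_subjects < 5:
        raise ValidationError("need at least 5 subjects")
    if score.values.size != stack.n_subjects:
        raise ValidationError("regressor length must match the subject count")
    if np.ptp(score.values) == 0:
        raise ValidationError("regressor is constant")
    ii, jj = _positions(stack.n_regions, stack.symmetric)
    V = stack.tensor[:, ii, jj]

    def stat_fn(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        rho, p, _ = _spearman_columns(groups[0], score.values, direction, outlier_sd)
        return rho, p

    stat, p, obs, null, p_set = _run_set_test([V], stat_fn, n_perm, threshold_pu, seed)
    return _finish_result(
        stack, stat, p, obs, null, p_set, direction, threshold_pu, n_perm, seed,
        "correlation", score.name, {"outlier_sd": outlier_sd},
    )


def group_set_test(
    stack_a: MeasureStack,
    stack_b: MeasureStack,
    direction: str = "bidirectional",
    n_perm: int = 500,
    threshold_pu: float = 0.05,
    seed: int | None = None,
    outlier_sd: float | None = 2.0,
) -> SetLevelResult:
    """Set-level test of group differences (Wilcoxon rank-sum based)."""
    _check_direction(direction)
    if seed is None:
        raise ValidationError("a seed is required for a reproducible null")
    if (
        stack_a.n_regions != stack_b.n_regions
        or stack_a.measure != stack_b.measure
        or stack_a.symmetric != stack_b.symmetric
    ):
        raise ValidationError("group stacks must share r, measure and symmetry")
    ii, jj = _positions(stack_a.n_regions, stack_a.symmetric)
    Va = stack_a.tensor[:, ii, jj]
    Vb = stack_b.tensor[:, ii, jj]

    def stat_fn(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        z, p, _ = _ranksum_columns(groups[0], groups[1], direction, outlier_sd)
        return z, p

    stat, p, obs, null, p_set = _run_set_test(
        [Va, Vb], stat_fn, n_perm, threshold_pu, seed
    )
    return _finish_result(
        stack_a, stat, p, obs, null, p_set, direction, threshold_pu, n_perm, seed,
        "group", None, {"outlier_sd": outlier_sd, "n_a": stack_a.n_subjects,
                        "n_b": stack_b.n_subjects},
    )


def nonzero_set_test(
    stack: MeasureStack,
    direction: str = "bidirectional",
    n_perm: int = 500,
    threshold_pu: float = 0.05,
    seed: int | None = None,
    outlier_sd: float | None = 2.0,
) -> SetLevelResult:
    """Set-level test of couplings versus zero (Wilcoxon signed-rank based)."""
    _check_direction(direction)
    if seed is None:
        raise ValidationError("a seed is required for a reproducible null")
    ii, jj = _positions(stack.n_regions, stack.symmetric)
    V = stack.tensor[:, ii, jj]

    def stat_fn(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        z, p, _ = _signrank_columns(groups[0], direction, outlier_sd)
        return z, p

    stat, p, obs, null, p_set = _run_set_test([V], stat_fn, n_perm, threshold_pu, seed)
    return _finish_result(
        stack, stat, p, obs, null, p_set, direction, threshold_pu, n_perm, seed,
        "nonzero", None, {"outlier_sd": outlier_sd},
    )


class SetLevelTest:
    """Model-style front end for the set-level permutation tests.

    ``SetLevelTest(stack, score).fit(n_perm=500, seed=0)`` is equivalent to
    :func:`set_level_test`; ``kind="group"`` (with ``stack_b``) and
    ``kind="nonzero"`` select the Wilcoxon variants.
    """

    def __init__(
        self,
        stack: MeasureStack,
        regressor: Regressor | None = None,
        kind: str = "correlation",
        stack_b: MeasureStack | None = None,
        direction: str = "bidirectional",
        threshold_pu: float = 0.05,
        outlier_sd: float | None = 2.0,
    ) -> None:
        if kind not in ("correlation", "group", "nonzero"):
            raise ValidationError(f"unknown test kind {kind!r}")
        if kind == "correlation" and regressor is None:
            raise ValidationError("correlation test needs a regressor")
        if kind == "group" and stack_b is None:
            raise ValidationError("group test needs a second stack")
        self.stack = stack
        self.regressor = regressor
        self.kind = kind
        self.stack_b = stack_b
        self.direction = direction
        self.threshold_pu = threshold_pu
        self.outlier_sd = outlier_sd

    def fit(self, n_perm: int = 500, seed: int | None = None) -> SetLevelResult:
        common = dict(
            direction=self.direction,
            n_perm=n_perm,
            threshold_pu=self.threshold_pu,
            seed=seed,
            outlier_sd=self.outlier_sd,
        )
        if self.kind == "correlation":
            return set_level_test(self.stack, self.regressor, **common)
        if self.kind == "group":
            return group_set_test(self.stack, self.stack_b, **common)
        return nonzero_set_test(self.stack, **common)


# ---------------------------------------------------------------------------
# covariate regression and Bonferroni bookkeeping
# ---------------------------------------------------------------------------

def regress_out_covariate(stack: MeasureStack, covariate: Regressor) -> MeasureStack:
    """Residualise every coupling on a covariate (intercept included).

    Each coupling's cross-subject values are replaced by the residuals of an
    ordinary linear fit on the covariate, with the coupling's mean restored.
    A constant covariate leaves the stack unchanged (with a warning).
    """
    import warnings as _warnings

    if covariate.values.size != stack.n_subjects:
        raise ValidationError("covariate length must match the subject count")
    if np.ptp(covariate.values) == 0:
        _warnings.warn(
            f"constant covariate {covariate.name!r}: identity transform",
            stacklevel=2,
        )
        return MeasureStack(
            tensor=stack.tensor.copy(),
            measure=stack.measure,
            subject_ids=list(stack.subject_ids),
            symmetric=stack.symmetric,
        )
    s, r, _ = stack.tensor.shape
    V = stack.tensor.reshape(s, r * r)
    X = np.column_stack([np.ones(s), covariate.values])
    beta, *_ = np.linalg.lstsq(X, V, rcond=None)
    resid = V - X @ beta
    out = (resid + V.mean(axis=0)).reshape(s, r, r)
    # the diagonal convention is metadata, not data: keep it untouched
    idx = np.arange(r)
    out[:, idx, idx] = stack.tensor[:, idx, idx]
    return MeasureStack(
        tensor=out,
        measure=stack.measure,
        subject_ids=list(stack.subject_ids),
        symmetric=stack.symmetric,
    )


def bonferroni_report(
    raw_p: Sequence[tuple[str, float]],
    factor: int,
    alpha: float = 0.05,
) -> list[dict]:
    """Bonferroni bookkeeping for a small family of tests.

    Flags ``p < alpha / factor`` and reports the multiplied p capped at 1.
    The typical families are 2 regressors x 3 directions (factor 6) or the
    three directions alone (factor 3).
    """
    if factor < 1:
        raise ValidationError(f"Bonferroni factor must be >= 1, got {factor}")
    out = []
    for label, p in raw_p:
        out.append(
            {
                "label": label,
                "p_raw": float(p),
                "p_adjusted": float(min(1.0, p * factor)),
                "significant": bool(p < alpha / factor),
            }
        )
    return out


# ---------------------------------------------------------------------------
# phase-randomised surrogates
# ---------------------------------------------------------------------------

def phase_randomized_surrogates(
    tc: TimeCourseSet,
    n_surrogates: int,
    seed: int | None = None,
) -> list[TimeCourseSet]:
    """Surrogate series with the original amplitude spectra and random phases.

    Per region and surrogate: Fourier transform, replace the phases of all
    non-DC (and non-Nyquist, for even length) bins with i.i.d. uniform draws
    on (-pi, pi], inverse transform.  DC and Nyquist bins are kept as-is so
    the inverse transform is exactly real-valued; every region is randomised
    independently, which destroys all cross-region dependence while
    preserving each series' power spectrum.
    """
    if n_surrogates < 1:
        raise ValidationError("need at least one surrogate")
    rng = np.random.default_rng(seed)
    r, T = tc.data.shape
    F = np.fft.rfft(tc.data, axis=1)
    mag = np.abs(F)
    n_bins = F.shape[1]
    randomize = np.ones(n_bins, dtype=bool)
    randomize[0] = False
    if T % 2 == 0:
        randomize[-1] = False
    out = []
    for k in range(n_surrogates):
        theta = rng.uniform(-np.pi, np.pi, size=(r, n_bins))
        Fs = np.where(randomize, mag * np.exp(1j * theta), F)
        data = np.fft.irfft(Fs, n=T, axis=1)
        out.append(
            TimeCourseSet(
                data=data,
                dt=tc.dt,
                region_labels=list(tc.region_labels),
                subject_id=f"{tc.subject_id}_surr{k:03d}",
            )
        )
    return out


def surrogate_set_test(
    stack_builder: Callable[[list[TimeCourseSet]], MeasureStack],
    tc_cohort: list[TimeCourseSet],
    score: Regressor,
    direction: str = "bidirectional",
    n_surrogates: int = 500,
    threshold_pu: float = 0.05,
    seed: int | None = None,
    outlier_sd: float | None = 2.0,
) -> dict:
    """Set-level significance against phase-randomised cohorts.

    ``stack_builder`` maps a cohort of time-course sets to a MeasureStack
    (the K or PS pipeline).  The observed set size is compared against the
    set sizes obtained from ``n_surrogates`` cohorts in which every
    subject's series were phase-randomised; ``p = (1 + #{surrogate >=
    observed}) / (1 + n_surrogates)``.
    """
    _check_direction(direction)
    if seed is None:
        raise ValidationError("a seed is required for reproducible surrogates")
    rng = np.random.default_rng(seed)

    def set_size(stack: MeasureStack) -> int:
        ii, jj = _positions(stack.n_regions, stack.symmetric)
        V = stack.tensor[:, ii, jj]
        _, p, _ = _spearman_columns(V, score.values, direction, outlier_sd)
        return int(np.count_nonzero(p < threshold_pu))

    observed = set_size(stack_builder(tc_cohort))
    surrogate_sizes = np.empty(n_surrogates, dtype=int)
    for b in range(n_surrogates):
        cohort_b = [
            phase_randomized_surrogates(tc, 1, seed=int(rng.integers(2**31)))[0]
            for tc in tc_cohort
        ]
        surrogate_sizes[b] = set_size(stack_builder(cohort_b))
    p = (1.0 + np.count_nonzero(surrogate_sizes >= observed)) / (1.0 + n_surrogates)
    return {
        "p": float(p),
        "observed_set_size": observed,
        "surrogate_set_sizes": surrogate_sizes,
        "n_surrogates": n_surrogates,
        "direction": direction,
        "threshold_pu": threshold_pu,
        "seed": seed,
    }
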