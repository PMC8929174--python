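"""Ground-truth simulator: noisy Kuramoto cohorts with score-dependent couplings.

The generator integrates, per subject, the stochastic phase model

    dphi_i/dt = omega_i + (d/r) * sum_j K_ij * M_ij * sin(phi_j - phi_i) + n * eps_i(t)

with the classical Runge-Kutta (RK-4) scheme — deliberately a *different*
integrator than the forward-Euler discretisation the estimator inverts, so
that recovery is not trivially "getting out what was put in".  ``d`` is an
overall coupling weight, ``M`` an individual (mask) weight matrix, ``n`` a
noise weight; ``eps_i(t)`` is i.i.d. standard normal, redrawn once per
output step and held constant within that step's RK-4 substeps (stochastic
forcing, not an Ito scheme).

A cohort consists of ``s`` subjects with random initial phases,
eigenfrequencies, coupling matrices and an independent per-subject score.
:func:`insert_score_dependence` rewrites a chosen subset of coupling
positions as monotone functions of the score (preserving each position's
cross-subject mean and SD), creating the correlation pattern the set-level
statistics are asked to recover.  :func:`run_sweep` maps out for which
(noise, coupling-weight) combinations the injected dependence survives the
generate -> estimate -> permutation-test pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as ss

from .errors import IntegrationError, PatternError, ValidationError
from .kuramoto import MeasureStack, estimate_couplings_from_phases, stack_cohort
from .setstats import Regressor, set_level_test
from .signals import NARROW_BAND, AnalyticPhaseSet

__all__ = [
    "CorrelationPattern",
    "SimulationConfig",
    "coefficient_classes",
    "mask_all_ones",
    "mask_significant",
    "mask_directional",
    "init_cohort",
    "insert_score_dependence",
    "rk4_generate",
    "estimate_cohort",
    "run_sweep",
]

#: band-centre eigenfrequency, rad per sample step, for 0.0625 Hz at dt = 2 s
OMEGA_CENTRE = 2.0 * np.pi * 0.0625 * 2.0

#: default sweep grids: chosen to straddle the detectability transition of the
#: default pattern (see docs/methods.md)
DEFAULT_NOISE_GRID = (0.1, 1.0, 2.0, 3.0)
DEFAULT_COUPLING_GRID = (0.5, 1.5, 2.5, 3.5)


@dataclass
class CorrelationPattern:
    """Which couplings are forced to correlate with the score, and how.

    ``inside_block`` is the correlated cluster of oscillators: positions
    with both ends inside the block are *inside-pattern* (IC) coefficients
    and get the injected dependence; positions bridging the block boundary
    (BC) and fully outside it (RC) stay untouched.  ``trend`` shapes the
    monotone dependence: ``"plateau"`` (default) saturates above the 75th
    score percentile, ``"gradual"`` is linear in the score.
    """

    inside_block: tuple[int, ...] = tuple(range(13))
    target_abs_rho: float = 0.95
    trend: str = "plateau"
    noise_sd: float = 0.02
    sign_map: np.ndarray | None = None
    plateau_quantile: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 < self.target_abs_rho <= 1.0:
            raise ValidationError("target_abs_rho must be in (0, 1]")
        if self.trend not in ("plateau", "gradual"):
            raise ValidationError(f"unknown trend {self.trend!r}")
        if len(self.inside_block) == 0 and self.target_abs_rho > 0:
            raise PatternError("nonempty inside_block required to inject dependence")

    def manipulated_positions(self, r: int) -> tuple[np.ndarray, np.ndarray]:
        classes = coefficient_classes(r, self.inside_block)
        return np.nonzero(classes == "IC")


def coefficient_classes(r: int, inside_block: tuple[int, ...]) -> np.ndarray:
    """Label each off-diagonal position IC (inside), BC (bridging) or RC.

    Diagonal entries carry an empty label (they are conventioned, never
    tested).
    """
    if inside_block and max(inside_block) >= r:
        raise ValidationError(
            f"inside_block indices {tuple(inside_block)} exceed r={r}"
        )
    inside = np.zeros(r, dtype=bool)
    inside[list(inside_block)] = True
    classes = np.empty((r, r), dtype=object)
    for i in range(r):
        for j in range(r):
            if i == j:
                classes[i, j] = ""
            elif inside[i] and inside[j]:
                classes[i, j] = "IC"
            elif inside[i] or inside[j]:
                classes[i, j] = "BC"
            else:
                classes[i, j] = "RC"
    return classes


def mask_all_ones(r: int) -> np.ndarray:
    """Every coupling participates in the generation."""
    return np.ones((r, r))


def mask_significant(pattern: CorrelationPattern, r: int) -> np.ndarray:
    """Binary mask keeping only the score-dependent (inside-pattern) couplings."""
    M = np.zeros((r, r))
    M[pattern.manipulated_positions(r)] = 1.0
    return M


def mask_directional(
    r: int,
    inside_block: tuple[int, ...],
    in_weight: float = 1.0,
    out_weight: float = 0.5,
) -> np.ndarray:
    """Directional-bias mask: couplings INTO the block weighted differently
    than couplings OUT of it; all other positions keep weight 1."""
    inside = np.zeros(r, dtype=bool)
    inside[list(inside_block)] = True
    M = np.ones((r, r))
    M[np.ix_(inside, ~inside)] = in_weight   # targets inside, sources outside
    M[np.ix_(~inside, inside)] = out_weight  # targets outside, sources inside
    return M


@dataclass
class SimulationConfig:
    """All parameters of one synthetic cohort.

    Defaults mirror the study conditions: s=24 subjects, r=20 oscillators,
    T=300 samples at dt=2 s, eigenfrequencies at the 0.05-0.075 Hz band
    centre +/- 10 %, unit-normal coupling coefficients, a Ham-D-like score
    uniform on [0, 30], plateau-trend dependence injected into a 13-region
    block, and the significant-couplings-only binary mask.
    """

    s: int = 24
    r: int = 20
    T: int = 300
    d: float = 1.0
    n: float = 0.1
    dt: float = 2.0
    band: tuple[float, float] = NARROW_BAND
    omega_centre: float = OMEGA_CENTRE
    omega_jitter: float = 0.1
    k_sd: float = 1.0
    score_range: tuple[float, float] = (0.0, 30.0)
    pattern: CorrelationPattern | None = field(default_factory=CorrelationPattern)
    mask: np.ndarray | None = None
    seeds: dict | None = None
    n_runs: int = 6
    n_perm: int = 100
    rk4_step: float = 1.0
    rk4_substeps: int = 1

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValidationError("overall coupling weight d must be positive")
        if self.n < 0:
            raise ValidationError("noise weight n must be nonnegative")
        if self.rk4_substeps < 1:
            raise ValidationError("rk4_substeps must be >= 1")
        if self.seeds is None:
            self.seeds = self.expand_seed(0)
        missing = {"phases", "eigenfrequencies", "noise", "coefficients"} - set(
            self.seeds
        )
        if missing:
            raise ValidationError(f"seeds missing entries: {sorted(missing)}")
        if self.mask is None:
            if self.pattern is not None:
                self.mask = mask_significant(self.pattern, self.r)
            else:
                self.mask = mask_all_ones(self.r)
        self.mask = np.asarray(self.mask, dtype=float)
        if self.mask.shape != (self.r, self.r):
            raise ValidationError("mask must be r x r")

    @staticmethod
    def expand_seed(master_seed: int) -> dict:
        """Deterministically derive the four sub-seeds from one master seed."""
        children = np.random.SeedSequence(master_seed).spawn(4)
        names = ("phases", "eigenfrequencies", "noise", "coefficients")
        return {
            name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, children)
        }

    def with_master_seed(self, master_seed: int) -> "SimulationConfig":
        return replace(self, seeds=self.expand_seed(master_seed))


def init_cohort(
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw eigenfrequencies, initial phases, coupling matrices and scores.

    Returns ``(Omega (s, r), Phi0 (s, r), K_original (s, r, r), score (s,))``.
    All draws are independent of the score, so the original coefficients
    carry no induced correlation with it.
    """
    s, r = config.s, config.r
    rng_phi = np.random.default_rng(config.seeds["phases"])
    rng_om = np.random.default_rng(config.seeds["eigenfrequencies"])
    rng_k = np.random.default_rng(config.seeds["coefficients"])
    Phi0 = rng_phi.uniform(0.0, 2.0 * np.pi, size=(s, r))
    lo = config.omega_centre * (1.0 - config.omega_jitter)
    hi = config.omega_centre * (1.0 + config.omega_jitter)
    Omega = rng_om.uniform(lo, hi, size=(s, r))
    K_original = rng_k.normal(0.0, config.k_sd, size=(s, r, r))
    idx = np.arange(r)
    K_original[:, idx, idx] = 1.0
    score = rng_k.uniform(*config.score_range, size=s)
    return Omega, Phi0, K_original, score


def _trend_values(score: np.ndarray, pattern: CorrelationPattern) -> np.ndarray:
    if pattern.trend == "gradual":
        return score.astype(float)
    cutoff = np.quantile(score, pattern.plateau_quantile)
    return np.minimum(score, cutoff)


def insert_score_dependence(
    K_original: np.ndarray,
    score: np.ndarray,
    pattern: CorrelationPattern,
    seed: int | None = None,
) -> np.ndarray:
    """Force high |Spearman| correlation with the score at pattern positions.

    At each manipulated (inside-pattern) position the subject-wise values
    are replaced by a monotone function of the score — sign per position,
    trend shape per the pattern — plus a small jitter, rescaled to the
    position's original cross-subject mean and SD (so marginal magnitudes
    stay comparable and only the correlation structure changes).  Raises
    :class:`PatternError` if the achieved |rho| falls below the target at
    any position.
    """
    K = np.array(K_original, dtype=float, copy=True)
    s, r, _ = K.shape
    ii, jj = pattern.manipulated_positions(r)
    if ii.size == 0:
        return K
    rng = np.random.default_rng(seed)
    if pattern.sign_map is not None:
        signs = np.asarray(pattern.sign_map)[ii, jj]
    else:
        signs = rng.choice([-1.0, 1.0], size=ii.size)
    base = _trend_values(score, pattern)
    base_sd = base.std()
    if base_sd == 0:
        raise PatternError("score trend is constant; cannot inject dependence")
    for pos, (i, j) in enumerate(zip(ii, jj)):
        orig = K_original[:, i, j]
        raw = signs[pos] * base + pattern.noise_sd * base_sd * rng.standard_normal(s)
        z = (raw - raw.mean()) / raw.std()
        new = orig.mean() + orig.std() * z
        rho = ss.spearmanr(new, score).statistic
        if abs(rho) < pattern.target_abs_rho:
            raise PatternError(
                f"achieved |rho|={abs(rho):.3f} < target "
                f"{pattern.target_abs_rho} at position ({i}, {j}); "
                "reduce the pattern noise or the target"
            )
        K[:, i, j] = new
    return K


def _drift(phi: np.ndarray, omega: np.ndarray, W: np.ndarray, d_over_r: float) -> np.ndarray:
    # phi: (r,); W = K * M elementwise; returns dphi/dt without noise
    sin_diff = np.sin(phi[None, :] - phi[:, None])  # [i, j] = sin(phi_j - phi_i)
    return omega + d_over_r * (W * sin_diff).sum(axis=1)


def rk4_generate(
    config: SimulationConfig,
    K_manipulated: np.ndarray,
    Omega: np.ndarray,
    Phi0: np.ndarray,
) -> np.ndarray:
    """Integrate the noisy phase model with RK-4; returns phases (s, r, T).

    One output step spans ``rk4_step`` time units, integrated with
    ``rk4_substeps`` RK-4 steps; the noise forcing ``n * eps`` is redrawn
    once per output step and held constant across that step's substeps.
    Phases are returned unwrapped (the integration is continuous by
    construction).
    """
    s, r, T = config.s, config.r, config.T
    if K_manipulated.shape != (s, r, r):
        raise ValidationError("K_manipulated must have shape (s, r, r)")
    rng = np.random.default_rng(config.seeds["noise"])
    d_over_r = config.d / r
    h = config.rk4_step / config.rk4_substeps
    phases = np.empty((s, r, T))
    phases[:, :, 0] = Phi0
    W_all = K_manipulated * config.mask[None, :, :]
    for subj in range(s):
        omega = Omega[subj]
        W = W_all[subj]
        phi = Phi0[subj].astype(float).copy()
        for t in range(1, T):
            forcing = config.n * rng.standard_normal(r)
            for _ in range(config.rk4_substeps):
                k1 = _drift(phi, omega, W, d_over_r) + forcing
                k2 = _drift(phi + 0.5 * h * k1, omega, W, d_over_r) + forcing
                k3 = _drift(phi + 0.5 * h * k2, omega, W, d_over_r) + forcing
                k4 = _drift(phi + h * k3, omega, W, d_over_r) + forcing
                phi = phi + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if not np.all(np.isfinite(phi)):
                raise IntegrationError(
                    f"non-finite phase state at subject {subj}, step {t}"
                )
            phases[subj, :, t] = phi
    return phases


def cohort_phase_sets(
    config: SimulationConfig, phases: np.ndarray
) -> list[AnalyticPhaseSet]:
    """Wrap simulated phases as per-subject analytic phase sets (unit amplitude)."""
    return [
        AnalyticPhaseSet(
            phases=phases[subj],
            amplitudes=np.ones_like(phases[subj]),
            band=config.band,
            dt=config.dt,
            subject_id=f"sim{subj:03d}",
        )
        for subj in range(config.s)
    ]


def estimate_cohort(config: SimulationConfig, phases: np.ndarray) -> MeasureStack:
    """Euler-based coupling estimation of every simulated subject.

    The estimator uses the fixed band-centre eigenfrequency (the default of
    the empirical pipeline) — it does not see the per-subject draws.
    """
    omega = np.full(config.r, config.omega_centre)
    mats = [
        estimate_couplings_from_phases(aps, omega)
        for aps in cohort_phase_sets(config, phases)
    ]
    return stack_cohort(mats)


def run_sweep(
    config: SimulationConfig,
    n_values: np.ndarray,
    d_values: np.ndarray,
    master_seed: int = 0,
) -> dict:
    """Median set-level p over repeated runs for every (noise, coupling) cell.

    ``K_original`` and the score are drawn once (per the coefficients seed
    derived from ``master_seed``); each of ``config.n_runs`` runs redraws the
    eigenfrequency and initial-phase matrices.  Per cell and run the pipeline
    is: RK-4 generation -> Euler-based estimation -> bidirectional set-level
    permutation test; the cell records the median ``p_set`` over runs.
    """
    n_values = np.atleast_1d(np.asarray(n_values, dtype=float))
    d_values = np.atleast_1d(np.asarray(d_values, dtype=float))
    if n_values.size == 0 or d_values.size == 0:
        raise ValidationError("sweep grid must be nonempty")
    base = config.with_master_seed(master_seed)
    _, _, K_original, score = init_cohort(base)
    if base.pattern is not None:
        K_used = insert_score_dependence(
            K_original, score, base.pattern, seed=base.seeds["coefficients"]
        )
    else:
        K_used = K_original
    regressor = Regressor(values=score, name="score", kind="score")

    median_p = np.full((n_values.size, d_values.size), np.nan)
    runs: list[dict] = []
    for a, n_val in enumerate(n_values):
        for b, d_val in enumerate(d_values):
            cell_p = []
            for run in range(base.n_runs):
                run_seed = int(
                    np.random.SeedSequence(
                        [master_seed, run, a, b]
                    ).generate_state(1)[0]
                    % (2**31)
                )
                cfg = replace(
                    base,
                    n=float(n_val),
                    d=float(d_val),
                    seeds=SimulationConfig.expand_seed(run_seed),
                )
                Omega, Phi0, _, _ = init_cohort(cfg)
                phases = rk4_generate(cfg, K_used, Omega, Phi0)
                stack = estimate_cohort(cfg, phases)
                res = set_level_test(
                    stack,
                    regressor,
                    direction="bidirectional",
                    n_perm=base.n_perm,
                    seed=run_seed,
                )
                cell_p.append(res.p_set)
                runs.append(
                    {
                        "n": float(n_val),
                        "d": float(d_val),
                        "run": run,
                        "seed": run_seed,
                        "p_set": float(res.p_set),
                        "observed_set_size": int(res.observed_set_size),
                    }
                )
            median_p[a, b] = float(np.median(cell_p))
    return {
        "n_values": n_values,
        "d_values": d_values,
        "median_p": median_p,
        "runs": runs,
        "n_runs": base.n_runs,
        "n_perm": base.n_perm,
        "master_seed": master_seed,
    }
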