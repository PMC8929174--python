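"""On-disk fixture cohorts binding the whole pipeline together.

Three kinds, each written as a directory of per-subject TSV files plus a
``manifest.json`` recording the ground truth and every seed:

* ``null`` — uncoupled noisy oscillators projected to signals
  (``cos(phase)``); no coupling-score dependence exists.
* ``injected`` — a simulator cohort with the default score-dependence
  pattern, also projected to signals.
* ``euler_exact`` — phase courses built by forward-iterating the
  discretised phase model from a stored coupling matrix; estimating from
  these phases must recover the stored couplings exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import write_timecourses
from .kuramoto import euler_forward_phases
from .signals import TimeCourseSet
from .simulate import (
    SimulationConfig,
    cohort_phase_sets,
    init_cohort,
    insert_score_dependence,
    rk4_generate,
)

__all__ = ["make_fixture_cohort"]


def make_fixture_cohort(
    kind: str,
    seed: int,
    out_dir: str | Path,
    s: int = 24,
    r: int = 20,
    T: int = 300,
    dt: float = 2.0,
) -> dict:
    """Write a fixture cohort to ``out_dir``; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "euler_exact":
        manifest = _euler_exact(seed, out_dir, s, r, T, dt)
    elif kind in ("null", "injected"):
        manifest = _simulated(kind, seed, out_dir, s, r, T, dt)
    else:
        raise ValidationError(f"unknown fixture kind {kind!r}")
    manifest["kind"] = kind
    manifest["seed"] = seed
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _euler_exact(seed: int, out_dir: Path, s: int, r: int, T: int, dt: float) -> dict:
    rng = np.random.default_rng(seed)
    omega_centre = 2.0 * np.pi * 0.0625 * dt
    subjects = []
    for subj in range(s):
        K = rng.normal(0.0, 0.5, size=(r, r))
        np.fill_diagonal(K, 1.0)
        omega = rng.uniform(0.9, 1.1, size=r) * omega_centre
        phi0 = rng.uniform(0.0, 2.0 * np.pi, size=r)
        phases = euler_forward_phases(K, omega, phi0, T)
        sid = f"subj{subj:03d}"
        tc = TimeCourseSet(data=phases, dt=dt, subject_id=sid)
        write_timecourses(tc, out_dir / f"{sid}.tsv")
        np.savetxt(out_dir / f"{sid}_K.tsv", K, delimiter="\t")
        subjects.append(
            {"subject": sid, "omega": [float(x) for x in omega], "K_file": f"{sid}_K.tsv"}
        )
    return {
        "content": "phases",
        "dt": dt,
        "n_subjects": s,
        "n_regions": r,
        "n_samples": T,
        "subjects": subjects,
    }


def _simulated(kind: str, seed: int, out_dir: Path, s: int, r: int, T: int, dt: float) -> dict:
    from .simulate import CorrelationPattern

    inject = kind == "injected"
    # the null cohort keeps a vanishing coupling weight: uncoupled noisy drift
    config = SimulationConfig(
        s=s, r=r, T=T, dt=dt,
        d=2.0 if inject else 1e-6,
        n=0.1,
        pattern=CorrelationPattern() if inject else None,
    ).with_master_seed(seed)
    Omega, Phi0, K_original, score = init_cohort(config)
    if inject:
        K_used = insert_score_dependence(
            K_original, score, config.pattern, seed=config.seeds["coefficients"]
        )
        manipulated = [
            [int(i), int(j)]
            for i, j in zip(*config.pattern.manipulated_positions(r))
        ]
    else:
        K_used = K_original
        manipulated = []
    phases = rk4_generate(config, K_used, Omega, Phi0)
    subjects = []
    for aps in cohort_phase_sets(config, phases):
        signals = np.cos(aps.phases)
        tc = TimeCourseSet(data=signals, dt=dt, subject_id=aps.subject_id)
        write_timecourses(tc, out_dir / f"{aps.subject_id}.tsv")
        subjects.append(aps.subject_id)
    return {
        "content": "signals",
        "dt": dt,
        "n_subjects": s,
        "n_regions": r,
        "n_samples": T,
        "subjects": subjects,
        "score": [float(x) for x in score],
        "manipulated_positions": manipulated,
        "seeds": config.seeds,
        "d": config.d,
        "n": config.n,
    }
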