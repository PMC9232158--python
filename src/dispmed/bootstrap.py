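"""Nonparametric bootstrap inference for the effect decomposition.

Each replicate resamples n rows with replacement, refits every model and
re-estimates all six effects.  Standard errors are the standard deviation
over replicates; confidence intervals are normal-approximation Wald
intervals around the original-sample point estimate (the published interval
style is symmetric, consistent with this construction); percentile
intervals are available as an option.  Replicates whose models fail
(non-convergence, degenerate resample) are dropped and counted; a run with
more than 5% failed replicates is flagged.

The seed schedule spawns one independent substream per replicate from the
root seed, so results are exactly reproducible and invariant to the worker
count under parallel execution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import norm

from .data import StudyData
from .design import FormulaSpec
from .exceptions import DispmedError
from .mediation import EFFECT_NAMES, EffectEstimates, estimate_effects

logger = logging.getLogger(__name__)

FAILURE_FLAG_FRACTION = 0.05


@dataclass
class BootstrapResult:
    """Point estimates with bootstrap SEs, CIs and p-values per effect."""

    estimates: EffectEstimates
    se: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p_values: dict[str, float]
    n_replicates: int
    n_failed: int
    seed: int | None
    ci_method: str = "normal"
    replicate_estimates: np.ndarray | None = field(default=None, repr=False)

    @property
    def flagged(self) -> bool:
        total = self.n_replicates + self.n_failed
        return total > 0 and self.n_failed > FAILURE_FLAG_FRACTION * total


def _two_sided_p(est: float, se: float) -> float:
    if se == 0:
        # degenerate bootstrap distribution: an exactly null effect carries
        # no evidence against the null, a nonzero one is infinitely precise
        return 1.0 if est == 0 else 0.0
    return float(2.0 * norm.sf(abs(est) / se))


def _one_replicate(data: StudyData, schema, formula, mode, draws, reference,
                   anchor, ridge, rep_seed) -> np.ndarray | None:
    rng = np.random.default_rng(rep_seed)
    idx = rng.integers(0, data.n, size=data.n)
    try:
        eff = estimate_effects(data.subset(idx), schema, formula=formula,
                               mode=mode, draws=draws,
                               seed=int(rng.integers(2 ** 31)),
                               reference=reference, anchor=anchor, ridge=ridge)
    except DispmedError:
        return None
    return eff.as_array()


def bootstrap_effects(data: StudyData, schema=None,
                      formula: FormulaSpec = FormulaSpec(), mode: str = "mc",
                      draws: int = 500, n_boot: int = 1000,
                      seed: int | None = None, reference: str = "exposed",
                      anchor: str = "a_first", ridge: float = 0.0,
                      ci_method: str = "normal",
                      n_jobs: int = 1) -> BootstrapResult:
    """Point estimates plus bootstrap SE/CI/p for all six effects.

    ``n_boot`` defaults to 1000 replicates; ``draws`` is the Monte-Carlo
    simulation count per regime when ``mode="mc"``.
    """
    if n_boot < 2:
        raise DispmedError("bootstrap needs at least 2 replicates")
    schema = schema or data.schema
    root = np.random.SeedSequence(0 if seed is None else seed)
    point_ss, *rep_ss = root.spawn(n_boot + 1)
    point = estimate_effects(
        data, schema, formula=formula, mode=mode, draws=draws,
        seed=int(np.random.default_rng(point_ss).integers(2 ** 31)),
        reference=reference, anchor=anchor, ridge=ridge)

    runner = Parallel(n_jobs=n_jobs) if n_jobs != 1 else None
    job = delayed(_one_replicate)
    args = (data, schema, formula, mode, draws, reference, anchor, ridge)
    if runner is None:
        raw = [_one_replicate(*args, ss) for ss in rep_ss]
    else:
        raw = runner(job(*args, ss) for ss in rep_ss)
    kept = np.array([r for r in raw if r is not None])
    n_failed = sum(r is None for r in raw)
    if len(kept) < 2:
        raise DispmedError(f"bootstrap failed: only {len(kept)} usable replicates")
    if n_failed:
        logger.warning("bootstrap: %d of %d replicates failed", n_failed, n_boot)

    est = point.as_array()
    se = kept.std(axis=0, ddof=1)
    if ci_method == "normal":
        lo = est - 1.96 * se
        hi = est + 1.96 * se
    elif ci_method == "percentile":
        lo = np.percentile(kept, 2.5, axis=0)
        hi = np.percentile(kept, 97.5, axis=0)
    else:
        raise DispmedError(f"unknown ci_method {ci_method!r}")
    return BootstrapResult(
        estimates=point,
        se=dict(zip(EFFECT_NAMES, se)),
        ci_low=dict(zip(EFFECT_NAMES, lo)),
        ci_high=dict(zip(EFFECT_NAMES, hi)),
        p_values={k: _two_sided_p(e, s)
                  for k, e, s in zip(EFFECT_NAMES, est, se)},
        n_replicates=len(kept), n_failed=n_failed, seed=seed,
        ci_method=ci_method, replicate_estimates=kept)
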