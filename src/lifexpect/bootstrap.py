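"""Patient-level bootstrap standard errors for pipeline endpoints.

Patients are resampled with replacement (their cost histories travel with
them, preserving within-patient cost/survival dependence) and the full
estimator is re-run on each resample with a freshly drawn Monte Carlo
referent seed, so referent noise is included in the reported SE.
Resamples the estimator refuses (non-estimable) are counted as failures,
not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import NonEstimableError, ValidationError

DEFAULT_B = 100


@dataclass
class BootstrapResult:
    point_estimate: float
    se: float
    n_replicates: int
    n_failed: int
    seed: int
    replicates: np.ndarray


def _resample(cohort: Cohort, costs: pd.DataFrame | None, rng) -> tuple[Cohort, pd.DataFrame | None]:
    # canonical order so the reported SE is invariant to input row order
    df = cohort.df.sort_values("id", kind="stable").reset_index(drop=True)
    idx = rng.integers(0, len(df), size=len(df))
    boot = df.iloc[idx].reset_index(drop=True)
    new_ids = [f"b{i:06d}" for i in range(len(boot))]
    boot_costs = None
    if costs is not None and not costs.empty:
        pieces = []
        by_id = dict(tuple(costs.groupby("id", sort=False)))
        for new_id, old_id in zip(new_ids, boot["id"]):
            c = by_id.get(old_id)
            if c is not None:
                c = c.copy()
                c["id"] = new_id
                pieces.append(c)
        boot_costs = (pd.concat(pieces, ignore_index=True) if pieces
                      else costs.iloc[:0].copy())
    boot = boot.copy()
    boot["id"] = new_ids
    return Cohort(boot, cohort.censor_date), boot_costs


def bootstrap_se(cohort: Cohort, costs: pd.DataFrame | None,
                 estimator: Callable, B: int = DEFAULT_B,
                 seed: int = 0, **estimator_kwargs) -> BootstrapResult:
    """Bootstrap SE of any estimator(cohort, costs, seed=..., **kwargs) -> float.

    The point estimate uses the original data and the base seed; each of the
    B resamples gets an independent seed. More than 50% refused resamples
    aborts with an error (the stratum is too unstable for an SE).
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(B + 1)]
    point = estimator(cohort, costs, seed=child_seeds[0], **estimator_kwargs)

    rng = np.random.default_rng(seed)
    values = []
    n_failed = 0
    for b in range(B):
        boot_cohort, boot_costs = _resample(cohort, costs, rng)
        try:
            values.append(estimator(boot_cohort, boot_costs,
                                    seed=child_seeds[b + 1], **estimator_kwargs))
        except NonEstimableError:
            n_failed += 1
    if n_failed > B / 2:
        raise ValidationError(
            f"stratum too unstable for SE: {n_failed}/{B} resamples non-estimable")
    values = np.asarray(values, float)
    se = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return BootstrapResult(point_estimate=float(point), se=se,
                           n_replicates=B, n_failed=n_failed, seed=seed,
                           replicates=values)
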