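"""Rarefaction-based similarity of a formula set to a reference DOM pool.

Instrument resolution and sample preparation make raw formula counts
incomparable across FT-ICR-MS studies, so convergence toward a degradation
end-member is measured by rarefaction, as in microbial diversity work: each
unit's formula set is repeatedly subsampled without replacement to a fixed
depth (default 6000 formulas, 1000 iterations) and the percentage of drawn
formulas shared with a reference set (e.g. deep-sea DOM) is averaged over
iterations.  The expected shared percentage of a uniform draw is the
hypergeometric expectation 100*k/n (k = |unit ∩ reference|, n = |unit|),
which the tests use as an independent oracle.

Units with fewer formulas than the rarefaction depth are excluded (recorded,
not crashed), mirroring rarefaction practice.  Randomness is controlled by a
single master seed; each unit gets a substream derived by stable hashing of
its id, so results do not depend on processing order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimilarityConfig",
    "SimilarityResult",
    "rarefied_shared_fraction",
    "similarity_to_reference",
    "rarefaction_profile",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityConfig:
    """Rarefaction settings: depth, iteration count, master seed."""

    depth_d: int = 6000
    iterations: int = 1000
    seed: int = 0
    reference_rarefied: bool = False

    def __post_init__(self) -> None:
        if self.depth_d < 1:
            raise ValueError("depth_d must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class SimilarityResult:
    """Mean +/- sd shared percentage for one unit at one rarefaction depth."""

    unit_id: str
    mean_shared_pct: float
    sd_shared_pct: float
    n_formulas_available: int
    depth_d: int


class RarefactionDepthError(ValueError):
    """Unit has fewer formulas than the rarefaction depth."""


def _unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    """Order-independent substream: master seed + CRC32 of the unit id."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(unit_id.encode("utf-8"))])
    )


def rarefied_shared_fraction(
    formulas: Iterable[str],
    reference: Iterable[str],
    config: SimilarityConfig | None = None,
    unit_id: str = "unit",
) -> SimilarityResult:
    """Mean and sd of the shared percentage over rarefied draws.

    Each iteration draws ``depth_d`` formulas uniformly without replacement
    from the unit and computes 100 x |draw ∩ reference| / depth_d.  Raises
    :class:`RarefactionDepthError` when the unit holds fewer formulas than
    the depth (callers batching many units should catch it and record an
    exclusion; :func:`similarity_to_reference` does exactly that).
    """
    config = config or SimilarityConfig()
    pool = sorted(set(formulas))
    ref = set(reference)
    if config.reference_rarefied and len(ref) >= config.depth_d:
        ref_rng = _unit_rng(config.seed, unit_id + "/reference")
        ref_list = sorted(ref)
        ref = set(
            ref_list[i] for i in ref_rng.choice(len(ref_list), config.depth_d, replace=False)
        )
    n = len(pool)
    if n < config.depth_d:
        raise RarefactionDepthError(
            f"unit {unit_id!r} has {n} formulas < rarefaction depth {config.depth_d}"
        )
    member = np.fromiter((f in ref for f in pool), dtype=bool, count=n)
    rng = _unit_rng(config.seed, unit_id)
    if n == config.depth_d:
        # every draw is the full set: no sampling variability
        mean = 100.0 * member.sum() / config.depth_d
        return SimilarityResult(unit_id, float(mean), 0.0, n, config.depth_d)
    shared = np.empty(config.iterations, dtype=float)
    for it in range(config.iterations):
        draw = rng.choice(n, size=config.depth_d, replace=False)
        shared[it] = member[draw].sum()
    pct = 100.0 * shared / config.depth_d
    return SimilarityResult(
        unit_id, float(pct.mean()), float(pct.std(ddof=1)), n, config.depth_d
    )


def similarity_to_reference(
    units: Mapping[str, Iterable[str]],
    reference: Iterable[str],
    config: SimilarityConfig | None = None,
) -> pd.DataFrame:
    """Batch :func:`rarefied_shared_fraction` over units; exclusions recorded.

    Returns a tidy DataFrame with one row per unit: unit_id, status
    ("ok" or "excluded: ..."), mean_shared_pct, sd_shared_pct,
    n_formulas_available.
    """
    config = config or SimilarityConfig()
    ref = set(reference)
    rows = []
    for unit_id in units:
        try:
            r = rarefied_shared_fraction(units[unit_id], ref, config, unit_id=unit_id)
            rows.append(
                dict(unit_id=unit_id, status="ok", mean_shared_pct=r.mean_shared_pct,
                     sd_shared_pct=r.sd_shared_pct, n_formulas_available=r.n_formulas_available)
            )
        except RarefactionDepthError as exc:
            logger.info("similarity: %s", exc)
            rows.append(
                dict(unit_id=unit_id, status=f"excluded: {exc}", mean_shared_pct=np.nan,
                     sd_shared_pct=np.nan, n_formulas_available=len(set(units[unit_id])))
            )
    return pd.DataFrame.from_records(rows)


def rarefaction_profile(
    formulas: Iterable[str],
    reference: Iterable[str],
    depths: Sequence[int],
    iterations: int = 1000,
    seed: int = 0,
    unit_id: str = "unit",
) -> pd.DataFrame:
    """Mean/sd shared percentage across a ladder of rarefaction depths.

    The hypergeometric expectation is depth-free, so the mean series is flat
    up to Monte-Carlo error; the shrinking sd series is the diagnostic for
    judging whether a depth adequately samples the observed compound pool
    (the decision tolerance is the user's).
    """
    pool = sorted(set(formulas))
    if list(depths) != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    if depths and depths[-1] > len(pool):
        raise ValueError(f"max depth {depths[-1]} exceeds unit size {len(pool)}")
    rows = []
    for d in depths:
        cfg = SimilarityConfig(depth_d=int(d), iterations=iterations, seed=seed)
        r = rarefied_shared_fraction(pool, reference, cfg, unit_id=unit_id)
        rows.append(
            dict(depth_d=int(d), mean_shared_pct=r.mean_shared_pct,
                 sd_shared_pct=r.sd_shared_pct, n_formulas_available=r.n_formulas_available)
        )
    return pd.DataFrame.from_records(rows)
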