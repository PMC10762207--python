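"""Universal-pool statistics, class composition profiles, intensity-weighted mass.

The degradation-cascade hypothesis predicts that DOM converges toward a
"universal" pool of compounds — molecular formulas detected in every sample.
This module computes that pool (with a configurable occupancy threshold whose
default, 1.0, is the strict in-all-samples definition), each sample's share
of universal compounds by richness and by summed normalised intensity, the
compound-class composition of any pool subset, and the intensity-weighted
mean molecular mass

    m/z_wm = sum_i(m_i * I_i) / sum_i(I_i)

over any compound group, optionally restricted to universal or non-universal
compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import DOMDataset

__all__ = [
    "UniversalPool",
    "universal_set",
    "universal_fractions",
    "class_profile",
    "weighted_mass",
]

logger = logging.getLogger(__name__)

SUBSETS = ("all", "universal", "non-universal")


@dataclass(frozen=True)
class UniversalPool:
    """Formulas present in at least ``occupancy_threshold`` of samples."""

    formulas: frozenset[str]
    occupancy_threshold: float = 1.0

    def __len__(self) -> int:
        return len(self.formulas)

    def __contains__(self, formula: str) -> bool:
        return formula in self.formulas


def universal_set(dataset: DOMDataset, threshold: float = 1.0) -> UniversalPool:
    """Formulas whose occupancy (share of samples with intensity > 0) >= threshold.

    ``threshold=1.0`` (the default) is the strict definition: present in all
    samples.
    """
    if dataset.n_samples == 0 or dataset.n_formulas == 0:
        raise ValueError("dataset is empty")
    if not 0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    occupancy = dataset.presence().mean(axis=1)
    members = occupancy.index[occupancy >= threshold]
    return UniversalPool(frozenset(members), threshold)


def _subset_mask(dataset: DOMDataset, subset_label: str, pool: UniversalPool | None) -> pd.Series:
    if subset_label not in SUBSETS:
        raise ValueError(f"unknown subset {subset_label!r}; expected one of {SUBSETS}")
    idx = dataset.intensities.index
    if subset_label == "all":
        return pd.Series(True, index=idx)
    if pool is None:
        raise ValueError(f"subset {subset_label!r} needs a UniversalPool")
    in_pool = idx.to_series().isin(pool.formulas)
    return in_pool if subset_label == "universal" else ~in_pool


def universal_fractions(dataset: DOMDataset, pool: UniversalPool) -> pd.DataFrame:
    """Per-sample percentage of compounds and of signal intensity in the pool.

    Returns a DataFrame indexed by sample id with

    - ``richness_pct`` = 100 x |pool ∩ present(s)| / |present(s)|
    - ``intensity_pct`` = 100 x sum of normalised intensities of pool members

    A sample detecting zero formulas is reported as missing (NaN).
    """
    if not set(pool.formulas) <= set(dataset.formulas):
        raise ValueError("pool contains formulas absent from the dataset")
    present = dataset.presence()
    in_pool = _subset_mask(dataset, "universal", pool)
    n_present = present.sum(axis=0).astype(float)
    n_pool_present = present.loc[in_pool.values].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        richness = 100.0 * n_pool_present / n_present.replace(0, np.nan)
    intensity = 100.0 * dataset.intensities.loc[in_pool.values].sum(axis=0)
    intensity[n_present == 0] = np.nan
    out = pd.DataFrame({"richness_pct": richness, "intensity_pct": intensity})
    out.index.name = "sample_id"
    return out


def class_profile(
    dataset: DOMDataset,
    weighting: str = "count",
    subset: str = "all",
    pool: UniversalPool | None = None,
) -> pd.DataFrame:
    """Per-sample per-class shares under count or intensity weighting.

    Count weighting gives the percentage of detected formulas in each class
    (rows sum to 100 over the chosen subset).  Intensity weighting gives the
    summed normalised intensity per class, i.e. shares of the sample's total
    signal: they sum to the subset's total intensity, not to 1, because
    intensities are never renormalised after subsetting.

    Returns a sample x class DataFrame.
    """
    if weighting not in ("count", "intensity"):
        raise ValueError(f"weighting must be 'count' or 'intensity', got {weighting!r}")
    mask = _subset_mask(dataset, subset, pool)
    classes = dataset.descriptors["compound_class"].loc[mask.values]
    inten = dataset.intensities.loc[mask.values]
    if weighting == "count":
        present = (inten > 0).astype(float)
        counts = present.groupby(classes).sum().T
        totals = counts.sum(axis=1)
        shares = 100.0 * counts.div(totals.replace(0, np.nan), axis=0)
    else:
        shares = inten.groupby(classes).sum().T
    shares.index.name = "sample_id"
    shares.columns.name = "compound_class"
    return shares


def weighted_mass(
    dataset: DOMDataset,
    group: str = "all",
    subset: str = "all",
    pool: UniversalPool | None = None,
) -> pd.DataFrame:
    """Intensity-weighted mean neutral mass per sample for one compound group.

    ``group`` is a compound-class label or ``"all"``; ``subset`` restricts to
    universal / non-universal compounds (requires ``pool``).  The statistic
    is scale-invariant in the intensities.  Samples where the group carries
    zero intensity get a missing value (logged).

    Returns a DataFrame indexed by sample id with columns ``mz_wm``,
    ``n_formulas``, ``total_intensity``.
    """
    mask = _subset_mask(dataset, subset, pool).values
    if group != "all":
        known = set(dataset.descriptors["compound_class"].unique())
        mask = mask & (dataset.descriptors["compound_class"] == group).values
        if group not in known:
            logger.warning("compound class %r not present in dataset", group)
    inten = dataset.intensities.loc[mask]
    masses = dataset.descriptors.loc[mask, "neutral_mass"]
    total = inten.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        wm = inten.mul(masses, axis=0).sum(axis=0) / total.replace(0, np.nan)
    empty = total[total == 0]
    if len(empty):
        logger.info(
            "weighted_mass: group %r has zero intensity in %d sample(s)", group, len(empty)
        )
    out = pd.DataFrame(
        {
            "mz_wm": wm,
            "n_formulas": (inten > 0).sum(axis=0),
            "total_intensity": total,
        }
    )
    out.index.name = "sample_id"
    return out
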