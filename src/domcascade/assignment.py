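"""Molecular-formula assignment for negative-mode FT-ICR-MS peak lists.

Calibrated peak lists (m/z, intensity, replicate id) are turned into
per-sample normalised formula-intensity tables: duplicate measurements are
merged (only signals seen in both replicates are retained), a method
detection limit is applied, each surviving neutral mass is matched against an
exhaustive CHNOSP candidate enumeration within a ppm tolerance, and the
intensities of assigned peaks are normalised to sum to one per sample.

All ions are treated as singly charged [M-H]- deprotonated molecules, so the
neutral mass is the measured m/z plus the mass of a proton (1.007276467 Da;
the electron mass is included in this constant — at a 0.2 ppm tolerance it is
decisive).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_core import (
    MONOISOTOPIC_MASS,
    FormulaError,
    MolecularFormula,
    double_bond_equivalents,
    format_formula,
)

__all__ = [
    "PROTON_MASS",
    "Peak",
    "AssignmentConfig",
    "Assignment",
    "neutral_mass_from_mz",
    "ion_mz",
    "enumerate_candidates",
    "passes_chemical_filters",
    "merge_replicates",
    "apply_mdl",
    "assign_peaklist",
]

logger = logging.getLogger(__name__)

#: Mass of a proton in Da (includes the electron-mass correction for [M-H]-).
PROTON_MASS = 1.007276467


@dataclass(frozen=True)
class Peak:
    """One calibrated mass-spectral peak."""

    mz: float
    intensity: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive (got {self.mz})")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0 (got {self.intensity})")


def _decile_median_noise(intensities: np.ndarray) -> float:
    """Noise level = median intensity of the lowest-intensity decile."""
    k = max(1, len(intensities) // 10)
    lowest = np.sort(intensities)[:k]
    return float(np.median(lowest))


@dataclass
class AssignmentConfig:
    """Attribution rules: element bounds, tolerance, window, filters.

    Defaults follow the analysis contract: C 0-100, H 2-200, O 0-70, N 0-3,
    S 0-2, P 0-2 at a tolerance of 0.2 ppm over a 150-1000 m/z window, in
    negative mode with singly charged [M-H]- ions, and a method detection
    limit factor of 2.
    """

    c_bounds: tuple[int, int] = (0, 100)
    h_bounds: tuple[int, int] = (2, 200)
    o_bounds: tuple[int, int] = (0, 70)
    n_bounds: tuple[int, int] = (0, 3)
    s_bounds: tuple[int, int] = (0, 2)
    p_bounds: tuple[int, int] = (0, 2)
    ppm_tolerance: float = 0.2
    mz_window: tuple[float, float] = (150.0, 1000.0)
    mdl_factor: float = 2.0
    replicate_match_ppm: float = 0.5
    require_integer_dbe: bool = True
    require_nonnegative_dbe: bool = True
    hc_max: float | None = None
    oc_max: float | None = None
    noise_estimator: Callable[[np.ndarray], float] = _decile_median_noise

    # cached heavy-atom enumeration grid (built lazily)
    _grid: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")
        if self.mz_window[0] >= self.mz_window[1]:
            raise ValueError("mz window low must be < high")
        for name in ("c", "h", "o", "n", "s", "p"):
            lo, hi = getattr(self, f"{name}_bounds")
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name}_bounds ({lo}, {hi})")

    def _heavy_grid(self) -> dict:
        """Flat arrays of every (C, N, O, S, P) combination within bounds.

        H is solved per query mass (at <= 0.2 ppm on <= 1000 Da the residual
        window is far narrower than one hydrogen, so at most one H count can
        match per heavy-atom combination).
        """
        if self._grid is None:
            c = np.arange(self.c_bounds[0], self.c_bounds[1] + 1)
            n = np.arange(self.n_bounds[0], self.n_bounds[1] + 1)
            o = np.arange(self.o_bounds[0], self.o_bounds[1] + 1)
            s = np.arange(self.s_bounds[0], self.s_bounds[1] + 1)
            p = np.arange(self.p_bounds[0], self.p_bounds[1] + 1)
            C, N, O, S, P = np.meshgrid(c, n, o, s, p, indexing="ij")
            C, N, O, S, P = (a.ravel() for a in (C, N, O, S, P))
            mass = (
                C * MONOISOTOPIC_MASS["C"]
                + N * MONOISOTOPIC_MASS["N"]
                + O * MONOISOTOPIC_MASS["O"]
                + S * MONOISOTOPIC_MASS["S"]
                + P * MONOISOTOPIC_MASS["P"]
            )
            order = np.argsort(mass, kind="stable")
            self._grid = {
                "c": C[order],
                "n": N[order],
                "o": O[order],
                "s": S[order],
                "p": P[order],
                "mass": mass[order],
            }
        return self._grid


@dataclass(frozen=True)
class Assignment:
    """Per-peak assignment log entry."""

    mz: float
    status: str  # "assigned" | "unassigned" | rejection reason
    formula: MolecularFormula | None
    mass_error_ppm: float | None
    candidate_count: int


def neutral_mass_from_mz(mz: float, config: AssignmentConfig | None = None) -> float:
    """Neutral mass of a singly charged [M-H]- ion: m/z + proton mass."""
    if mz <= 0:
        raise ValueError(f"mz must be positive (got {mz})")
    return mz + PROTON_MASS


def ion_mz(neutral_mass: float) -> float:
    """[M-H]- m/z of a neutral mass; inverse of :func:`neutral_mass_from_mz`."""
    if neutral_mass <= PROTON_MASS:
        raise ValueError("neutral mass must exceed the proton mass")
    return neutral_mass - PROTON_MASS


def passes_chemical_filters(f: MolecularFormula, config: AssignmentConfig) -> bool:
    """DBE integrality / non-negativity plus optional H/C and O/C caps."""
    dbe = double_bond_equivalents(f)
    if config.require_integer_dbe and dbe != int(dbe):
        return False
    if config.require_nonnegative_dbe and dbe < 0:
        return False
    if config.hc_max is not None and f.c > 0 and f.h / f.c > config.hc_max:
        return False
    if config.oc_max is not None and f.c > 0 and f.o / f.c > config.oc_max:
        return False
    return True


class OutOfWindowError(ValueError):
    """Neutral mass outside the analytical m/z window."""


def enumerate_candidates(
    neutral_mass: float, config: AssignmentConfig
) -> list[tuple[MolecularFormula, float]]:
    """All in-bounds formulas within the ppm tolerance of ``neutral_mass``.

    Candidates are sorted by \\|mass error (ppm)\\| ascending, ties broken by
    fewest heteroatoms (N+S+P) then lexicographic canonical string — a
    documented deterministic stand-in for the homologous-series logic of
    online assignment tools.

    Raises :class:`OutOfWindowError` when the equivalent ion m/z falls
    outside the configured analytical window.
    """
    lo, hi = config.mz_window
    if not (lo <= neutral_mass - PROTON_MASS <= hi):
        raise OutOfWindowError(
            f"neutral mass {neutral_mass:.6f} Da is out of analytical window "
            f"[{lo}, {hi}] m/z"
        )
    grid = config._heavy_grid()
    tol = config.ppm_tolerance * 1e-6 * neutral_mass
    mh = MONOISOTOPIC_MASS["H"]
    h_lo, h_hi = config.h_bounds

    # prune heavy-atom combinations that cannot reach the target with any H
    gm = grid["mass"]
    lo_idx = np.searchsorted(gm, neutral_mass - tol - h_hi * mh, side="left")
    hi_idx = np.searchsorted(gm, neutral_mass + tol - h_lo * mh, side="right")
    sl = slice(lo_idx, hi_idx)
    heavy = gm[sl]
    if heavy.size == 0:
        return []

    h = np.rint((neutral_mass - heavy) / mh).astype(np.int64)
    mass = heavy + h * mh
    err_ppm = (mass - neutral_mass) / neutral_mass * 1e6
    ok = (h >= h_lo) & (h <= h_hi) & (np.abs(err_ppm) <= config.ppm_tolerance)

    c, n, o, s, p = (grid[k][sl] for k in ("c", "n", "o", "s", "p"))
    if config.require_integer_dbe:
        ok &= (h + n + p) % 2 == 0
    if config.require_nonnegative_dbe:
        # dbe = 1 + c - h/2 + n/2 + p/2  >= 0
        ok &= 2 + 2 * c - h + n + p >= 0
    if config.hc_max is not None:
        ok &= (c > 0) & (h <= config.hc_max * c)
    if config.oc_max is not None:
        ok &= (c > 0) & (o <= config.oc_max * c)

    idx = np.nonzero(ok)[0]
    out = []
    for i in idx:
        f = MolecularFormula(
            c=int(c[i]), h=int(h[i]), o=int(o[i]), n=int(n[i]), s=int(s[i]), p=int(p[i])
        )
        out.append((f, float(err_ppm[i])))
    out.sort(key=lambda fe: (abs(fe[1]), fe[0].n + fe[0].s + fe[0].p, format_formula(fe[0])))
    return out


def merge_replicates(peaks: Sequence[Peak], config: AssignmentConfig) -> list[Peak]:
    """Retain only peaks detected in both duplicate measurements.

    Peaks from the two replicates are greedily matched by closest relative
    mass difference within ``replicate_match_ppm``; each peak is used at most
    once.  A matched pair becomes one peak at the intensity-weighted mean m/z
    with the mean intensity; unmatched peaks are dropped.
    """
    if not peaks:
        return []
    reps = sorted({pk.replicate_id for pk in peaks})
    if len(reps) != 2:
        raise ValueError(f"expected exactly 2 replicate ids, got {reps}")
    a = sorted((pk for pk in peaks if pk.replicate_id == reps[0]), key=lambda pk: pk.mz)
    b = sorted((pk for pk in peaks if pk.replicate_id == reps[1]), key=lambda pk: pk.mz)

    # candidate pairs within tolerance via a two-pointer sweep
    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    for i, pa in enumerate(a):
        tol = config.replicate_match_ppm * 1e-6 * pa.mz
        while j0 < len(b) and b[j0].mz < pa.mz - tol:
            j0 += 1
        j = j0
        while j < len(b) and b[j].mz <= pa.mz + tol:
            d_ppm = abs(b[j].mz - pa.mz) / pa.mz * 1e6
            if d_ppm <= config.replicate_match_ppm:
                pairs.append((d_ppm, i, j))
            j += 1
    pairs.sort()

    used_a: set[int] = set()
    used_b: set[int] = set()
    merged: list[Peak] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pa, pb = a[i], b[j]
        w = pa.intensity + pb.intensity
        mz = (pa.mz * pa.intensity + pb.mz * pb.intensity) / w if w > 0 else (pa.mz + pb.mz) / 2
        merged.append(Peak(mz=mz, intensity=(pa.intensity + pb.intensity) / 2, replicate_id="merged"))
    merged.sort(key=lambda pk: pk.mz)
    return merged


def apply_mdl(peaks: Sequence[Peak], config: AssignmentConfig) -> list[Peak]:
    """Apply the method detection limit: keep intensity >= factor x noise.

    The noise level is estimated by ``config.noise_estimator`` (default:
    median intensity of the lowest-intensity decile).  With fewer than 10
    peaks the estimator degenerates to the minimum intensity (logged).
    """
    if not peaks:
        return []
    intensities = np.array([pk.intensity for pk in peaks], dtype=float)
    if len(peaks) < 10:
        noise = float(intensities.min())
        logger.info("apply_mdl: <10 peaks; noise falls back to min intensity %.4g", noise)
    else:
        noise = float(config.noise_estimator(intensities))
    threshold = config.mdl_factor * noise
    kept = [pk for pk in peaks if pk.intensity >= threshold]
    if not kept:
        warnings.warn(
            f"method detection limit {threshold:.4g} removed every peak",
            stacklevel=2,
        )
    return kept


def assign_peaklist(
    peaks: Sequence[Peak], config: AssignmentConfig | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Full per-sample pipeline: MDL per replicate, merge, window, enumerate.

    Returns ``(intensity, log)`` where ``intensity`` maps canonical formula
    strings to normalised relative intensities summing to 1 over assigned
    peaks (two peaks assigned the same formula have their intensities summed
    first), and ``log`` is the per-peak assignment record (mz, status,
    formula, mass_error_ppm, candidate_count).
    """
    config = config or AssignmentConfig()
    records: list[dict] = []

    # The detection limit applies to each exported (per-replicate) mass list
    # before the duplicate-retention rule: noise peaks anchor the noise
    # estimate and must be removed before they can spuriously match between
    # replicates.
    by_rep: dict[str, list[Peak]] = {}
    for pk in peaks:
        by_rep.setdefault(pk.replicate_id, []).append(pk)
    detected: list[Peak] = []
    for rep_peaks in by_rep.values():
        kept = apply_mdl(rep_peaks, config)
        dropped = len(rep_peaks) - len(kept)
        if dropped:
            kept_ids = {id(pk) for pk in kept}
            records.extend(
                dict(mz=pk.mz, status="below detection limit", formula=None,
                     mass_error_ppm=None, candidate_count=0)
                for pk in rep_peaks if id(pk) not in kept_ids
            )
        detected.extend(kept)

    merged = merge_replicates(detected, config)

    lo, hi = config.mz_window
    surviving: list[Peak] = []
    for pk in merged:
        if lo <= pk.mz <= hi:
            surviving.append(pk)
        else:
            records.append(
                dict(mz=pk.mz, status="out of analytical window", formula=None,
                     mass_error_ppm=None, candidate_count=0)
            )

    totals: dict[str, float] = {}
    for pk in surviving:
        cands = enumerate_candidates(neutral_mass_from_mz(pk.mz), config)
        if not cands:
            records.append(
                dict(mz=pk.mz, status="unassigned", formula=None,
                     mass_error_ppm=None, candidate_count=0)
            )
            continue
        best, err = cands[0]
        key = format_formula(best)
        totals[key] = totals.get(key, 0.0) + pk.intensity
        records.append(
            dict(mz=pk.mz, status="assigned", formula=key,
                 mass_error_ppm=err, candidate_count=len(cands))
        )

    log = pd.DataFrame.from_records(
        records, columns=["mz", "status", "formula", "mass_error_ppm", "candidate_count"]
    ).sort_values("mz", kind="stable").reset_index(drop=True)

    if not totals:
        warnings.warn("no peaks could be assigned a molecular formula", stacklevel=2)
        return pd.Series(dtype=float, name="intensity"), log

    intensity = pd.Series(totals, name="intensity").sort_index()
    intensity /= intensity.sum()
    return intensity, log
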