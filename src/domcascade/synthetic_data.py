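"""Synthetic DOM worlds with known ground truth for every pipeline stage.

The generator emulates the structure of a soil-to-stream FT-ICR-MS survey:

* a formula library within the CHNOSP attribution bounds (150-1000 Da,
  chemically filtered) with a prescribed compound-class mixture;
* a universal core present in every sample, biased toward lignin-like
  composition as observed in field DOM;
* a degradation cascade encoded as one ordinal stage axis applied to both
  soil depth and hillslope position: non-universal members of plant-derived
  classes are removed with probability increasing along the gradient, with
  preferential removal of low-mass members inside the classes that show mass
  shifts (carbohydrate-like, unsaturated-hydrocarbon-like);
* a universal-pool intensity share that rises linearly along each gradient
  axis (percentage points per axis extreme) with small per-sample noise;
* lognormal peak intensities, Gaussian ppm mass jitter in duplicate
  measurements, and sub-detection-limit noise peaks.

The returned :class:`GroundTruth` records the quantities the analysis
pipeline is supposed to recover, so parameter-recovery tests never compare
against anything the pipeline itself computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .assignment import PROTON_MASS, Peak
from .chem_core import (
    ClassBoundaryTable,
    DEFAULT_CLASS_TABLE,
    MolecularFormula,
    descriptors,
    format_formula,
)
from .dataset_io import DEPTHS_CM, DOMDataset, SampleMetadata, build_dataset

__all__ = ["SimulationConfig", "GroundTruth", "generate_library", "simulate_dataset", "simulate_peaklist"]

#: Per-class (H/C window, O/C window, N requirement) proposal windows used by
#: the library sampler; classify() verifies every accepted formula.
_CLASS_PROPOSALS: dict[str, tuple[tuple[float, float], tuple[float, float], int]] = {
    "lignin-like": ((0.75, 1.45), (0.15, 0.65), 0),
    "tannin-like": ((0.70, 1.45), (0.70, 0.95), 0),
    "condensed-aromatic-like": ((0.30, 0.70), (0.02, 0.30), 0),
    "carbohydrate-like": ((1.52, 2.00), (0.70, 0.95), 0),
    "amino-sugar-like": ((1.52, 1.90), (0.56, 0.66), 1),
    "protein-like": ((1.52, 2.00), (0.32, 0.54), 1),
    "lipid-like": ((1.52, 2.00), (0.02, 0.28), 0),
    "unsaturated-hydrocarbon-like": ((0.72, 1.45), (0.0, 0.09), 0),
}


def _default_class_mixture() -> dict[str, float]:
    # lignin-dominated pool echoing field soil/stream DOM
    return {
        "lignin-like": 0.55,
        "tannin-like": 0.10,
        "condensed-aromatic-like": 0.07,
        "carbohydrate-like": 0.07,
        "unsaturated-hydrocarbon-like": 0.07,
        "lipid-like": 0.05,
        "protein-like": 0.05,
        "amino-sugar-like": 0.04,
    }


def _default_core_mixture() -> dict[str, float]:
    # the universal pool is strongly lignin-dominated in field data (~79%)
    return {
        "lignin-like": 0.79,
        "tannin-like": 0.09,
        "condensed-aromatic-like": 0.06,
        "carbohydrate-like": 0.02,
        "unsaturated-hydrocarbon-like": 0.02,
        "lipid-like": 0.01,
        "protein-like": 0.01,
    }


def _default_gradient_effects() -> dict[str, float]:
    # plant-derived classes depleted along the cascade (fraction of
    # non-universal members removable at the gradient extreme)
    return {
        "tannin-like": 0.6,
        "condensed-aromatic-like": 0.6,
        "carbohydrate-like": 0.6,
        "unsaturated-hydrocarbon-like": 0.6,
    }


def _default_mass_bias() -> dict[str, float]:
    # within-class preferential removal of LOW-mass members -> weighted mass rises
    return {"carbohydrate-like": 1.0, "unsaturated-hydrocarbon-like": 1.0}


@dataclass
class SimulationConfig:
    """Ground-truth effect sizes, library composition, noise model, seed."""

    n_catchments: int = 4
    positions: tuple[str, ...] = ("shoulder", "back", "foot", "toe")
    depths_cm: tuple[int, ...] = DEPTHS_CM
    include_stream: bool = True
    library_size: int = 3000
    universal_core_size: int = 400
    class_mixture: dict[str, float] = field(default_factory=_default_class_mixture)
    core_class_mixture: dict[str, float] = field(default_factory=_default_core_mixture)
    gradient_effects: dict[str, float] = field(default_factory=_default_gradient_effects)
    mass_bias: dict[str, float] = field(default_factory=_default_mass_bias)
    universal_intensity_base: float = 0.50
    universal_intensity_slope: float = 0.10  # pp increase per gradient-axis extreme
    universal_share_noise_sd: float = 0.02
    intensity_lognormal: tuple[float, float] = (0.0, 1.0)
    detection_prob: float = 0.6
    ppm_jitter_sd: float = 0.05
    noise_peak_rate: float = 0.1
    intensity_scale: float = 1.0e8
    seed: int = 0
    class_table: ClassBoundaryTable = field(default=DEFAULT_CLASS_TABLE, repr=False)

    def __post_init__(self) -> None:
        if self.library_size <= self.universal_core_size:
            raise ValueError("library_size must exceed universal_core_size")
        for name in ("detection_prob", "noise_peak_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for cls, rate in self.gradient_effects.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"gradient effect for {cls!r} must be in [0, 1]")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class_mixture must sum to 1 (got {total})")


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    universal_core: frozenset[str]
    #: per sample id: the noise-free target universal intensity share
    expected_universal_share: pd.Series
    #: per (class, sample id): expected weighted neutral mass of surviving
    #: non-universal members under the removal model (equal expected
    #: intensities)
    expected_class_weighted_mass: pd.DataFrame
    #: per sample id: (depth stage, position stage) in [0, 1]
    stages: pd.DataFrame


class MixtureError(RuntimeError):
    """A requested class mixture cannot be sampled within the element bounds."""


def _sample_formula_in_class(
    target_class: str, rng: np.random.Generator, table: ClassBoundaryTable,
    max_attempts: int = 400,
) -> MolecularFormula:
    if target_class not in _CLASS_PROPOSALS:
        raise MixtureError(f"no proposal window for class {target_class!r}")
    (hc_lo, hc_hi), (oc_lo, oc_hi), n_min = _CLASS_PROPOSALS[target_class]
    for _ in range(max_attempts):
        # heavy-tailed mass proposal centred near 400 Da, as in field DOM
        mass = float(np.exp(rng.normal(np.log(400.0), 0.35)))
        if not 160.0 <= mass <= 950.0:
            continue
        hc = float(rng.uniform(hc_lo, hc_hi))
        oc = float(rng.uniform(oc_lo, oc_hi))
        n = int(rng.integers(1, 4)) if n_min else int(rng.random() < 0.15)
        s = int(rng.random() < 0.05)
        p = int(rng.random() < 0.05)
        unit = 12.0 + hc * 1.007825032 + oc * 15.99491462
        c = int(round((mass - n * 14.003074 - s * 31.972071 - p * 30.973762) / unit))
        if c < 4 or c > 100:
            continue
        h = int(round(hc * c))
        if (h + n + p) % 2 != 0:
            h += 1
        o = int(round(oc * c))
        if not (2 <= h <= 200 and 0 <= o <= 70):
            continue
        f = MolecularFormula(c=c, h=h, o=o, n=n, s=s, p=p)
        dbe = 1 + c - h / 2 + n / 2 + p / 2
        if dbe < 0 or dbe != int(dbe):
            continue
        d = descriptors(f, table)
        if not 150.0 <= d.neutral_mass <= 1000.0:
            continue
        if d.compound_class != target_class:
            continue
        return f
    raise MixtureError(
        f"could not sample a {target_class!r} formula in {max_attempts} attempts; "
        "the requested mixture may be unreachable within the element bounds"
    )


def generate_library(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample ``library_size`` unique formulas matching the class mixture.

    Per-class quotas are filled by rejection sampling inside class-specific
    H/C-O/C proposal windows; every accepted formula is re-verified with the
    classifier, so class shares match the mixture exactly (well within the
    ±2-point contract).  Returns a descriptor table indexed by canonical
    formula string.
    """
    rng = rng or np.random.default_rng(config.seed)
    quotas: dict[str, int] = {}
    classes = [c for c, w in config.class_mixture.items() if w > 0]
    for cls in classes:
        quotas[cls] = int(round(config.class_mixture[cls] * config.library_size))
    # fix rounding drift on the largest class
    drift = config.library_size - sum(quotas.values())
    quotas[max(quotas, key=quotas.get)] += drift

    seen: set[str] = set()
    rows: dict[str, dict] = {}
    for cls in classes:
        placed = 0
        attempts = 0
        while placed < quotas[cls]:
            attempts += 1
            if attempts > 500 * quotas[cls]:
                raise MixtureError(f"unable to fill quota for class {cls!r}")
            f = _sample_formula_in_class(cls, rng, config.class_table)
            key = format_formula(f)
            if key in seen:
                continue
            seen.add(key)
            d = descriptors(f, config.class_table)
            rows[key] = {
                "c": f.c, "h": f.h, "n": f.n, "o": f.o, "s": f.s, "p": f.p,
                "neutral_mass": d.neutral_mass, "hc": d.hc, "oc": d.oc, "nc": d.nc,
                "dbe": d.dbe, "ai_mod": d.ai_mod, "hetero_group": d.hetero_group,
                "compound_class": d.compound_class,
            }
            placed += 1
    lib = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    lib.index.name = "formula"
    return lib


def _pick_core(lib: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    """Choose the universal core with the configured class bias."""
    core: list[str] = []
    remaining = config.universal_core_size
    mix = dict(config.core_class_mixture)
    for cls, w in mix.items():
        want = int(round(w * config.universal_core_size))
        members = lib.index[lib["compound_class"] == cls].to_numpy()
        members = np.setdiff1d(members, np.array(core, dtype=object), assume_unique=False)
        take = min(want, len(members), remaining)
        if take > 0:
            core.extend(rng.choice(members, size=take, replace=False).tolist())
            remaining -= take
    if remaining > 0:
        pool = np.setdiff1d(lib.index.to_numpy(), np.array(core, dtype=object))
        core.extend(rng.choice(pool, size=remaining, replace=False).tolist())
    return sorted(core)


def _sample_plan(config: SimulationConfig) -> list[tuple[SampleMetadata, float, float]]:
    """All samples with their (depth stage, position stage) in [0, 1]."""
    plan = []
    nd, npos = len(config.depths_cm), len(config.positions)
    for k in range(config.n_catchments):
        cat = f"C{k + 1}"
        for pi, pos in enumerate(config.positions):
            for di, depth in enumerate(config.depths_cm):
                sid = f"{cat}-{pos}-{depth}cm"
                meta = SampleMetadata(sid, cat, pos, float(depth), "soil")
                plan.append((meta, di / max(nd - 1, 1), pi / max(npos - 1, 1)))
        if config.include_stream:
            sid = f"{cat}-stream"
            meta = SampleMetadata(sid, cat, "stream", None, "stream")
            plan.append((meta, 1.0, 1.0))  # the cascade end-member
    return plan


def simulate_dataset(
    config: SimulationConfig, library: pd.DataFrame | None = None
) -> tuple[DOMDataset, GroundTruth]:
    """Generate a gradient-structured DOM dataset with known ground truth.

    The universal core is present in every sample.  Each non-universal
    formula is detected with probability ``detection_prob`` and then removed
    with probability ``rate * (sd + sp)/2 * w(mass)`` where sd, sp are the
    depth/position stages in [0, 1], ``rate`` is the class's gradient effect
    and ``w`` tilts removal toward low-mass members by the class's mass
    bias.  Intensities are lognormal; the summed universal intensity is then
    rescaled to the target share ``base + slope*sd + slope*sp`` (plus noise)
    and columns are normalised to 1.
    """
    rng = np.random.default_rng(config.seed)
    lib = library if library is not None else generate_library(config, rng)
    if len(lib) != config.library_size:
        raise ValueError("library size does not match the configuration")
    core = _pick_core(lib, config, rng)
    core_set = frozenset(core)
    is_core = lib.index.isin(core_set)

    mass = lib["neutral_mass"].to_numpy()
    cls = lib["compound_class"].to_numpy()
    # within-class mass percentile (for the mass-biased removal)
    q = np.zeros(len(lib))
    for c in np.unique(cls):
        m = cls == c
        order = mass[m].argsort().argsort()
        q[m] = order / max(m.sum() - 1, 1)

    rate = np.array([config.gradient_effects.get(c, 0.0) for c in cls])
    bias = np.array([config.mass_bias.get(c, 0.0) for c in cls])
    # removal weight: low-mass members (q ~ 0) removed up to (1 + bias) times
    # the class rate, high-mass members down to (1 - bias) times
    w_mass = np.clip(1.0 + bias * (1.0 - 2.0 * q), 0.0, None)

    mu, sigma = config.intensity_lognormal
    plan = _sample_plan(config)
    tables: dict[str, pd.Series] = {}
    metas: list[SampleMetadata] = []
    target_share: dict[str, float] = {}
    stages: dict[str, tuple[float, float]] = {}
    exp_wm_rows: list[dict] = []

    for meta, sd_stage, sp_stage in plan:
        stage = (sd_stage + sp_stage) / 2.0
        detected = rng.random(len(lib)) < config.detection_prob
        p_remove = np.clip(rate * stage * w_mass, 0.0, 1.0)
        removed = rng.random(len(lib)) < p_remove
        present = is_core | (detected & ~removed)

        inten = np.zeros(len(lib))
        inten[present] = rng.lognormal(mu, sigma, size=int(present.sum()))

        mu_share = config.universal_intensity_base + config.universal_intensity_slope * (
            sd_stage + sp_stage
        )
        noisy = float(
            np.clip(mu_share + rng.normal(0.0, config.universal_share_noise_sd), 0.05, 0.95)
        )
        u = inten[is_core].sum()
        nu = inten[~is_core].sum()
        if u > 0 and nu > 0:
            inten[is_core] *= noisy * nu / ((1.0 - noisy) * u)
        inten /= inten.sum()

        sid = meta.sample_id
        tables[sid] = pd.Series(inten[present], index=lib.index[present])
        metas.append(meta)
        target_share[sid] = mu_share
        stages[sid] = (sd_stage, sp_stage)

        # expected weighted mass of surviving non-universal members (survival
        # probability x equal expected intensity)
        surv = config.detection_prob * (1.0 - p_remove)
        for c in config.gradient_effects:
            m = (cls == c) & ~is_core
            denom = surv[m].sum()
            exp_wm_rows.append(
                dict(compound_class=c, sample_id=sid,
                     expected_wm=float((mass[m] * surv[m]).sum() / denom) if denom > 0 else np.nan)
            )

    dataset = build_dataset(tables, metas, table=config.class_table)
    truth = GroundTruth(
        universal_core=core_set,
        expected_universal_share=pd.Series(target_share, name="expected_universal_share"),
        expected_class_weighted_mass=(
            pd.DataFrame.from_records(exp_wm_rows).pivot(
                index="sample_id", columns="compound_class", values="expected_wm"
            )
            if exp_wm_rows
            else pd.DataFrame(index=pd.Index([], name="sample_id"))
        ),
        stages=pd.DataFrame(
            {sid: dict(zip(("depth_stage", "position_stage"), st)) for sid, st in stages.items()}
        ).T.rename_axis("sample_id"),
    )
    return dataset, truth


def simulate_peaklist(
    intensities: pd.Series,
    neutral_masses: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[Peak]:
    """Emit duplicate [M-H]- peak lists for one sample's formula intensities.

    Each formula produces one peak per replicate at its ion m/z with Gaussian
    ppm jitter (``ppm_jitter_sd``); per-replicate intensities get mild
    lognormal measurement noise.  ``noise_peak_rate`` x n spurious peaks per
    replicate are added at random m/z with intensities well below the method
    detection limit.
    """
    rng = rng or np.random.default_rng(config.seed)
    masses = neutral_masses.loc[intensities.index].to_numpy()
    ion = masses - PROTON_MASS
    base = intensities.to_numpy() * config.intensity_scale
    peaks: list[Peak] = []
    n = len(intensities)
    min_real = base.min() if n else config.intensity_scale
    for rep in ("rep1", "rep2"):
        jitter = rng.normal(0.0, config.ppm_jitter_sd * 1e-6, size=n)
        mz = ion * (1.0 + jitter)
        inten = base * rng.lognormal(0.0, 0.05, size=n)
        peaks.extend(Peak(float(m), float(i), rep) for m, i in zip(mz, inten))
        n_noise = int(round(config.noise_peak_rate * n))
        if n_noise:
            noise_mz = rng.uniform(150.0, 1000.0, size=n_noise)
            # (0.06-0.15) x the faintest real peak: the noise peaks anchor the
            # lowest-decile noise estimate, and with max < 3 x min the MDL
            # threshold (2 x estimate) clears every noise peak while staying
            # far below the faintest real peak
            noise_i = rng.uniform(0.06, 0.15, size=n_noise) * min_real
            peaks.extend(Peak(float(m), float(i), rep) for m, i in zip(noise_mz, noise_i))
    return peaks
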