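"""Peak-list processing: ionisation arithmetic, enumeration, MDL, merging."""

import numpy as np
import pytest

from domcascade.assignment import (
    PROTON_MASS,
    AssignmentConfig,
    OutOfWindowError,
    Peak,
    apply_mdl,
    assign_peaklist,
    enumerate_candidates,
    ion_mz,
    merge_replicates,
    neutral_mass_from_mz,
    passes_chemical_filters,
)
from domcascade.chem_core import MONOISOTOPIC_MASS, MolecularFormula, exact_neutral_mass


def brute_force_candidates(neutral_mass, config):
    """Independent exhaustive oracle: plain nested loops over all elements."""
    tol = config.ppm_tolerance * 1e-6 * neutral_mass
    mC, mH, mN, mO, mS, mP = (MONOISOTOPIC_MASS[e] for e in "CHNOSP")
    found = []
    for c in range(config.c_bounds[0], config.c_bounds[1] + 1):
        if c * mC > neutral_mass + tol:
            break
        for n in range(config.n_bounds[0], config.n_bounds[1] + 1):
            for s in range(config.s_bounds[0], config.s_bounds[1] + 1):
                for p in range(config.p_bounds[0], config.p_bounds[1] + 1):
                    base = c * mC + n * mN + s * mS + p * mP
                    if base > neutral_mass + tol:
                        continue
                    o_max = int((neutral_mass + tol - base) / mO)
                    for o in range(config.o_bounds[0], min(o_max, config.o_bounds[1]) + 1):
                        rem = neutral_mass - base - o * mO
                        h_lo = int(np.floor((rem - tol) / mH))
                        h_hi = int(np.ceil((rem + tol) / mH))
                        for h in range(max(h_lo, config.h_bounds[0]),
                                       min(h_hi, config.h_bounds[1]) + 1):
                            mass = base + o * mO + h * mH
                            err = (mass - neutral_mass) / neutral_mass * 1e6
                            if abs(err) > config.ppm_tolerance:
                                continue
                            f = MolecularFormula(c=c, h=h, o=o, n=n, s=s, p=p)
                            if passes_chemical_filters(f, config):
                                found.append((f, err))
    return found


class TestIonisation:
    def test_glucose_deprotonated(self):
        assert neutral_mass_from_mz(179.056111) == pytest.approx(180.063388, abs=1e-6)

    def test_nonpositive_mz_errors(self):
        with pytest.raises(ValueError):
            neutral_mass_from_mz(0.0)

    def test_round_trip(self):
        x = 523.123456
        assert ion_mz(neutral_mass_from_mz(x)) == pytest.approx(x, abs=1e-9)


class TestChemicalFilters:
    @pytest.mark.parametrize(
        "f,expected",
        [
            (MolecularFormula(c=6, h=13, o=6), False),  # dbe 0.5
            (MolecularFormula(c=2, h=8), False),        # dbe -1
            (MolecularFormula(c=6, h=12, o=6), True),
        ],
    )
    def test_dbe_rules(self, f, expected):
        assert passes_chemical_filters(f, AssignmentConfig()) is expected

    def test_ratio_caps(self):
        cfg = AssignmentConfig(hc_max=2.0, oc_max=1.0)
        assert not passes_chemical_filters(MolecularFormula(c=2, h=6, o=1), cfg)  # hc 3
        assert not passes_chemical_filters(MolecularFormula(c=2, h=4, o=3), cfg)  # oc 1.5


class TestEnumeration:
    def test_glucose_found(self):
        cfg = AssignmentConfig()
        cands = enumerate_candidates(180.063388, cfg)
        strs = {str(f) for f, _ in cands}
        assert "C6H12O6" in strs
        best_err = abs(cands[0][1])
        assert best_err < 0.01

    def test_out_of_window(self):
        with pytest.raises(OutOfWindowError):
            enumerate_candidates(16.0313, AssignmentConfig())

    def test_matches_bruteforce_oracle_spot(self):
        cfg = AssignmentConfig()
        for mass in (180.063388, 300.123456, 366.118157):
            got = {(str(f), round(e, 9)) for f, e in enumerate_candidates(mass, cfg)}
            exp = {(str(f), round(e, 9)) for f, e in brute_force_candidates(mass, cfg)}
            assert got == exp

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(11)
        masses = rng.uniform(150, 500, size=5) + PROTON_MASS
        wide = AssignmentConfig(ppm_tolerance=0.5)
        narrow = AssignmentConfig(ppm_tolerance=0.1)
        for m in masses:
            fw = {str(f) for f, _ in enumerate_candidates(m, wide)}
            fn = {str(f) for f, _ in enumerate_candidates(m, narrow)}
            assert fn <= fw

    def test_sort_order_deterministic(self):
        cfg = AssignmentConfig(ppm_tolerance=5.0)  # force several candidates
        cands = enumerate_candidates(400.100000, cfg)
        assert len(cands) > 1
        keys = [(abs(e), f.n + f.s + f.p, str(f)) for f, e in cands]
        assert keys == sorted(keys)


class TestMergeReplicates:
    def test_matched_pair_averaged(self):
        cfg = AssignmentConfig()
        peaks = [Peak(300.000000, 10, "a"), Peak(300.000060, 12, "b")]
        merged = merge_replicates(peaks, cfg)
        assert len(merged) == 1
        assert merged[0].mz == pytest.approx(
            (300.0 * 10 + 300.00006 * 12) / 22, abs=1e-9
        )
        assert merged[0].intensity == pytest.approx(11.0)

    def test_singleton_dropped(self):
        cfg = AssignmentConfig()
        peaks = [Peak(300.0, 10, "a"), Peak(300.000060, 12, "b"), Peak(500.0, 5, "a")]
        merged = merge_replicates(peaks, cfg)
        assert len(merged) == 1  # the 500 Da peak is only in replicate a

    def test_empty_input(self):
        assert merge_replicates([], AssignmentConfig()) == []

    def test_wrong_replicate_count(self):
        with pytest.raises(ValueError):
            merge_replicates([Peak(300.0, 1.0, "only")], AssignmentConfig())

    def test_each_peak_used_once(self):
        cfg = AssignmentConfig(replicate_match_ppm=10.0)
        peaks = [
            Peak(300.0000, 1, "a"), Peak(300.0005, 1, "a"),
            Peak(300.0001, 1, "b"),
        ]
        merged = merge_replicates(peaks, cfg)
        assert len(merged) == 1  # b-peak pairs with its closest a-peak only


class TestMDL:
    def test_threshold_rule(self):
        cfg = AssignmentConfig()  # factor 2; <10 peaks -> noise = min = 1
        peaks = [Peak(200 + i, v, "a") for i, v in enumerate([1, 1, 1, 100, 200])]
        kept = apply_mdl(peaks, cfg)
        assert sorted(pk.intensity for pk in kept) == [100, 200]

    def test_all_equal_intensities_removed(self):
        cfg = AssignmentConfig()
        peaks = [Peak(200 + i, 5.0, "a") for i in range(12)]
        with pytest.warns(UserWarning):
            kept = apply_mdl(peaks, cfg)
        assert kept == []  # 5 < 2 x 5: documented edge case

    def test_empty_input(self):
        assert apply_mdl([], AssignmentConfig()) == []


class TestAssignPeaklist:
    def _duplicate(self, entries):
        return [Peak(mz, i, r) for mz, i in entries for r in ("a", "b")]

    def test_normalisation_and_rate(self):
        cfg = AssignmentConfig(mdl_factor=0.0)  # arithmetic check, no MDL
        glucose = 180.063388 - PROTON_MASS
        sucrose = exact_neutral_mass(
            MolecularFormula(c=12, h=22, o=11)
        ) - PROTON_MASS
        peaks = self._duplicate([(glucose, 2.0), (sucrose, 3.0), (400.5, 4.0)])
        table, log = assign_peaklist(peaks, cfg)
        assert table.sum() == pytest.approx(1.0, abs=1e-12)
        assert table["C6H12O6"] == pytest.approx(0.4)
        assert table["C12H22O11"] == pytest.approx(0.6)
        counts = log["status"].value_counts()
        assert counts["assigned"] == 2 and counts["unassigned"] == 1

    def test_duplicate_formula_collision_summed(self):
        cfg = AssignmentConfig(replicate_match_ppm=0.01, mdl_factor=0.0)
        glucose = 180.063388 - PROTON_MASS
        # two distinct peaks 0.03 ppm apart, both best-assigned to glucose
        peaks = self._duplicate([(glucose, 0.3), (glucose * (1 + 3e-8), 0.2)])
        table, log = assign_peaklist(peaks, cfg)
        assert len(table) == 1
        assert table["C6H12O6"] == pytest.approx(1.0)
        assert (log["status"] == "assigned").sum() == 2

    def test_deterministic(self):
        cfg = AssignmentConfig()
        glucose = 180.063388 - PROTON_MASS
        peaks = self._duplicate([(glucose, 2.0), (350.1234, 1.0)])
        t1, l1 = assign_peaklist(peaks, cfg)
        t2, l2 = assign_peaklist(peaks, cfg)
        assert t1.equals(t2) and l1.equals(l2)

    def test_zero_assigned_warns(self):
        peaks = self._duplicate([(400.5, 4.0)])
        with pytest.warns(UserWarning):
            table, _ = assign_peaklist(peaks, AssignmentConfig(mdl_factor=0.0))
        assert table.empty
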