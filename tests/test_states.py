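"""Cohort-level state and subgroup contrasts on constructed strength tables."""

import numpy as np
import pandas as pd
import pytest

import ictalgraph as ig
from ictalgraph.cohort import STATES, State
from ictalgraph.connectivity import FCMatrix
from ictalgraph.states import (
    age_correlation,
    between_within_connectivity,
    compare_states,
    inside_outside_contrast,
    percent_difference,
    subgroup_contrasts,
)

BANDS = ["beta"]


def make_table(per_patient_strengths, bands=BANDS, states=None, measure="AEC"):
    """Build a strengths table: per_patient_strengths maps patient ->
    {state: [per-channel strengths]} with optional per-channel flag arrays."""
    states = states or [s.value for s in STATES]
    rows = []
    for pid, info in per_patient_strengths.items():
        flags = info.get("flags", {})
        for band in bands:
            for state in states:
                vals = info[state]
                for k, v in enumerate(vals):
                    rows.append(
                        {
                            "patient_id": pid,
                            "channel_id": f"c{k:02d}",
                            "measure": measure,
                            "band": band,
                            "state": state,
                            "strength": float(v),
                            "electrode_type": flags.get("electrode_type", ["subdural"] * len(vals))[k],
                            "resected": flags.get("resected", [False] * len(vals))[k],
                            "in_soz": flags.get("in_soz", [False] * len(vals))[k],
                            "propagating": flags.get("propagating", [False] * len(vals))[k],
                            "temporal_lobe": flags.get("temporal_lobe", [False] * len(vals))[k],
                            "region_label": "r0",
                            "outcome": info.get("outcome", "good"),
                            "onset_type": info.get("onset_type", "SSO"),
                            "age_at_surgery": info.get("age", 10.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestCompareStates:
    def test_identical_states_give_p_one(self):
        table = make_table(
            {f"p{i}": {s.value: [0.5, 0.6, 0.7] for s in STATES} for i in range(6)}
        )
        with pytest.warns(UserWarning, match="zero"):
            res = compare_states(table, "AEC", band="beta")
        assert len(res) == 10
        assert all(r.p_raw == 1.0 for r in res)

    def test_percent_difference_arithmetic(self):
        assert percent_difference(0.55, 0.50) == pytest.approx(10.0)
        assert percent_difference(0.50, 0.55) == pytest.approx(-9.0909, abs=1e-3)

    def test_planted_ictal_excess_detected(self):
        rng = np.random.default_rng(0)
        tbl = {}
        for i in range(10):
            base = {s.value: list(0.5 + 0.02 * rng.standard_normal(4)) for s in STATES}
            base["ictal"] = list(0.8 + 0.02 * rng.standard_normal(4))
            tbl[f"p{i}"] = base
        res = compare_states(make_table(tbl), "AEC", band="beta")
        hit = [r for r in res if r.state_a == "ictal" and r.state_b == "pre_ictal"][0]
        assert hit.p_fdr < 0.05 and hit.percent_difference > 0

    def test_missing_state_is_an_error(self):
        table = make_table(
            {"p0": {s.value: [0.5] * 3 for s in STATES}},
        )
        table = table[table["state"] != "ictal"]
        with pytest.raises(ValueError, match="missing state"):
            compare_states(table, "AEC", band="beta")


class TestInsideOutside:
    def _cohort_table(self, inside, outside, n=8):
        flags = {"resected": [True, True, False, False]}
        return make_table(
            {
                f"p{i}": {
                    **{s.value: [inside, inside, outside, outside] for s in STATES},
                    "flags": flags,
                }
                for i in range(n)
            }
        )

    def test_planted_inside_excess(self):
        res = inside_outside_contrast(
            self._cohort_table(0.9, 0.4), "resection", "AEC", "beta", "ictal"
        )
        assert res["median_inside"] > res["median_outside"]
        assert res["test"].pvalue < 0.05

    def test_identical_sides_give_p_one(self):
        with pytest.warns(UserWarning, match="zero"):
            res = inside_outside_contrast(
                self._cohort_table(0.5, 0.5), "resection", "AEC", "beta", "ictal"
            )
        assert res["test"].pvalue == 1.0

    def test_patient_without_resected_channels_excluded(self):
        table = self._cohort_table(0.9, 0.4, n=6)
        extra = make_table({"pz": {s.value: [0.5, 0.5] for s in STATES}})
        with pytest.warns(UserWarning, match="pz"):
            res = inside_outside_contrast(
                pd.concat([table, extra]), "resection", "AEC", "beta", "ictal"
            )
        assert res["n_patients"] == 6


class TestSubgroups:
    def test_propagating_excess_paired(self):
        flags = {"propagating": [True, True, False, False]}
        table = make_table(
            {
                f"p{i}": {
                    **{s.value: [0.9, 0.85, 0.5, 0.45] for s in STATES},
                    "flags": flags,
                }
                for i in range(8)
            }
        )
        res = subgroup_contrasts(table, "propagating", "AEC", states=("ictal",))
        assert (res["p_fdr"] < 0.05).all()

    def test_empty_group_for_all_patients_errors(self):
        table = make_table(
            {f"p{i}": {s.value: [0.5, 0.6] for s in STATES} for i in range(4)}
        )
        with pytest.raises(ValueError, match="empty"):
            subgroup_contrasts(table, "propagating", "AEC", states=("ictal",))

    def test_implant_type_contrast_needs_both_groups(self):
        flags_seeg = {"electrode_type": ["depth", "depth"]}
        table = make_table(
            {
                f"p{i}": {
                    **{s.value: [0.5, 0.6] for s in STATES},
                    "flags": flags_seeg,
                }
                for i in range(4)
            }
        )
        with pytest.raises(ValueError, match="implant"):
            subgroup_contrasts(table, "implant_type", "AEC", states=("ictal",))


class TestBetweenWithin:
    def _patient(self, n=4):
        chans = [
            ig.ChannelInfo(
                f"d{i}", "depth", f"s{i // 2}", (0.0, 0.0, float(3 * i)),
                resected=(i < 2), region_label=f"region{i // 2}",
            )
            for i in range(n)
        ]
        data = np.random.default_rng(0).standard_normal((n, 30000))
        return ig.PatientRecord(
            "p1", chans, {State.ICTAL: ig.StateEpoch("ictal", data, 500.0)}, "IA"
        )

    def test_two_region_arithmetic(self):
        p = self._patient()
        v = np.full((4, 4), 0.2)
        v[0, 1] = v[1, 0] = v[2, 3] = v[3, 2] = 0.6  # within-region edges
        fc = FCMatrix(values=v, measure="AEC")
        regions = {r.region_label: r for r in between_within_connectivity(p, fc)}
        assert regions["region0"].between_strength == pytest.approx(0.2)
        assert regions["region0"].within_strength == pytest.approx(0.6)
        assert regions["region0"].epileptogenic
        assert not regions["region1"].epileptogenic

    def test_single_region_rejected(self):
        p = self._patient()
        chans = [
            ig.ChannelInfo(c.channel_id, "depth", c.shaft_id, c.coordinates,
                           region_label="same")
            for c in p.channels
        ]
        p2 = p.with_channels(chans)
        fc = FCMatrix(values=np.full((4, 4), 0.3), measure="AEC")
        with pytest.raises(ValueError, match="2 regions"):
            between_within_connectivity(p2, fc)


class TestAgeCorrelation:
    def _table(self, ages, strengths):
        return make_table(
            {
                f"p{i}": {
                    **{s.value: [v] * 2 for s in STATES},
                    "age": a,
                }
                for i, (a, v) in enumerate(zip(ages, strengths))
            }
        )

    def test_monotone_relationships(self):
        ages = [4, 8, 12, 16, 20, 24]
        res = age_correlation(self._table(ages, [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]),
                              "AEC", "ictal", "beta")
        assert res.statistic == pytest.approx(1.0)
        res = age_correlation(self._table(ages, [0.6, 0.5, 0.4, 0.3, 0.2, 0.1]),
                              "AEC", "ictal", "beta")
        assert res.statistic == pytest.approx(-1.0)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="5"):
            age_correlation(self._table([4, 8], [0.1, 0.2]), "AEC", "ictal", "beta")
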