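"""Binarisation and condition-specificity of bottleneck nodes."""

import itertools

import numpy as np
import pandas as pd
import pytest

from acidae.nodes import (
    AMBIGUOUS,
    OFF,
    ON,
    binarize,
    census_counts,
    find_specific_nodes,
    pattern_census,
    profile_conditions,
)

CONDS = ["acid", "heat", "ethanol", "osmotic"]


def table_from_activations(acts):
    """acts: dict (member, node) -> dict condition -> activation."""
    rows = [
        {"member": m, "node": k, "condition": c, "activation": a}
        for (m, k), per_cond in acts.items()
        for c, a in per_cond.items()
    ]
    return pd.DataFrame(rows)


def boolean_table(rng, n_members, n_nodes, conds):
    acts = {}
    for m in range(n_members):
        for k in range(n_nodes):
            acts[(m, k)] = {c: float(rng.choice([0.05, 0.5, 0.95])) for c in conds}
    return acts


class TestBinarize:
    @pytest.mark.parametrize("activation, state", [
        (0.95, ON), (0.9, ON), (0.05, OFF), (0.1, OFF), (0.5, AMBIGUOUS),
        (0.89, AMBIGUOUS), (0.11, AMBIGUOUS),
    ])
    def test_threshold_mapping(self, activation, state):
        tab = table_from_activations({(0, 0): {"acid": activation}})
        out = binarize(tab, 0.9, 0.1)
        assert out.state.iloc[0] == state

    def test_threshold_order_enforced(self):
        tab = table_from_activations({(0, 0): {"acid": 0.5}})
        with pytest.raises(ValueError):
            binarize(tab, 0.1, 0.9)


class TestProfileConditions:
    class MeanEnsemble:
        """Fake ensemble: bottleneck = mean of first two genes per member offset."""

        members_ = [0, 1]

        def transform(self, X):
            base = X[:, :2].mean(axis=1, keepdims=True)
            return np.stack([np.clip(base + off, 0, 1) for off in (0.0, 0.1)])

    def test_table_is_complete_and_uses_condition_means(self, small_compendium):
        from acidae.normalize import fit_minmax_scaler
        scaled, _ = fit_minmax_scaler(small_compendium, small_compendium.sample_ids)
        tab = profile_conditions(self.MeanEnsemble(), scaled)
        assert len(tab) == 2 * 1 * 2  # members x nodes x conditions
        assert set(tab.condition) == {"control", "acid"}

    def test_missing_condition_is_an_error(self, small_compendium):
        from acidae.normalize import fit_minmax_scaler
        scaled, _ = fit_minmax_scaler(small_compendium, small_compendium.sample_ids)
        with pytest.raises(ValueError, match="ghost"):
            profile_conditions(self.MeanEnsemble(), scaled, conditions=["ghost"])


class TestFindSpecific:
    def test_definition(self):
        acts = {
            (0, 0): {"acid": 0.95, "heat": 0.05, "ethanol": 0.05, "osmotic": 0.05},
            (0, 1): {"acid": 0.95, "heat": 0.05, "ethanol": 0.95, "osmotic": 0.05},
            (0, 2): {"acid": 0.5, "heat": 0.05, "ethanol": 0.05, "osmotic": 0.05},
        }
        states = binarize(table_from_activations(acts))
        grp = find_specific_nodes(states, ["acid"], ["heat", "ethanol", "osmotic"])
        assert grp.members == [(0, 0)]  # node 1 co-activates ethanol; node 2 ambiguous

    def test_co_active_node_lands_in_shared_pattern(self):
        acts = {
            (0, 1): {"acid": 0.95, "heat": 0.05, "ethanol": 0.95, "osmotic": 0.05},
        }
        states = binarize(table_from_activations(acts))
        census = pattern_census(states, ["acid"], ["heat", "ethanol", "osmotic"])
        assert census_counts(census) == {"acid+ethanol": 1}

    def test_overlapping_sets_rejected(self):
        states = binarize(table_from_activations(
            {(0, 0): {"acid": 0.95, "heat": 0.05}}))
        with pytest.raises(ValueError, match="overlap"):
            find_specific_nodes(states, ["acid"], ["acid", "heat"])

    def test_brute_force_oracle(self, rng):
        focal, background = ["acid"], ["heat", "ethanol", "osmotic"]
        for _ in range(100):
            acts = boolean_table(rng, 5, 8, CONDS)
            states = binarize(table_from_activations(acts))
            got = set(find_specific_nodes(states, focal, background).members)
            expected = {
                pair for pair, a in acts.items()
                if all(a[c] >= 0.9 for c in focal)
                and all(a[c] <= 0.1 for c in background)
            }
            assert got == expected

    def test_per_replicate_unanimity(self):
        rows = []
        for rep, act in enumerate([0.95, 0.95, 0.5]):
            rows.append({"member": 0, "node": 0, "condition": "acid",
                         "replicate": rep, "activation": act})
            rows.append({"member": 0, "node": 0, "condition": "heat",
                         "replicate": rep, "activation": 0.05})
        states = binarize(pd.DataFrame(rows))
        grp = find_specific_nodes(states, ["acid"], ["heat"])
        assert grp.members == []  # third replicate disagrees


class TestPatternCensus:
    def test_toy_counts(self):
        acts = {
            (0, 0): {"acid": 0.95, "heat": 0.05, "ethanol": 0.05, "osmotic": 0.05},
            (0, 1): {"acid": 0.95, "heat": 0.05, "ethanol": 0.05, "osmotic": 0.05},
            (0, 2): {"acid": 0.95, "heat": 0.05, "ethanol": 0.95, "osmotic": 0.05},
        }
        states = binarize(table_from_activations(acts))
        counts = census_counts(pattern_census(states, ["acid"],
                                              ["heat", "ethanol", "osmotic"]))
        assert counts == {"acid-only": 2, "acid+ethanol": 1}

    def test_all_off_gives_empty_census(self):
        acts = {(0, k): {c: 0.05 for c in CONDS} for k in range(4)}
        states = binarize(table_from_activations(acts))
        assert pattern_census(states, ["acid"], CONDS[1:]) == {}

    def test_brute_force_oracle_and_exclusivity(self, rng):
        focal, background = ["acid"], ["heat", "ethanol", "osmotic"]
        for _ in range(100):
            acts = boolean_table(rng, 4, 6, CONDS)
            states = binarize(table_from_activations(acts))
            census = pattern_census(states, focal, background)
            # brute-force: classify each pair independently
            expected: dict[str, int] = {}
            for pair, a in acts.items():
                if not all(a[c] >= 0.9 for c in focal):
                    continue
                on_bg = [c for c in background if a[c] >= 0.9]
                off_bg = [c for c in background if a[c] <= 0.1]
                if len(off_bg) == len(background):
                    expected["acid-only"] = expected.get("acid-only", 0) + 1
                elif len(on_bg) == 1 and len(off_bg) == len(background) - 1:
                    key = f"acid+{on_bg[0]}"
                    expected[key] = expected.get(key, 0) + 1
            assert census_counts(census) == expected
            # exclusivity: each pair in at most one pattern
            seen = list(itertools.chain.from_iterable(
                g.members for g in census.values()))
            assert len(seen) == len(set(seen))


class TestMonotonicity:
    def test_raising_theta_on_shrinks_on_sets(self, rng):
        acts = {(m, k): {c: float(rng.uniform(0, 1)) for c in CONDS}
                for m in range(4) for k in range(6)}
        tab = table_from_activations(acts)
        focal, background = ["acid"], CONDS[1:]
        prev = None
        for theta_on in (0.7, 0.8, 0.9, 0.95):
            grp = set(find_specific_nodes(binarize(tab, theta_on, 0.1),
                                          focal, background).members)
            if prev is not None:
                assert grp <= prev
            prev = grp
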