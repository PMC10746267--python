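"""Condition-specificity analysis of bottleneck nodes.

Each trained ensemble member is shown one scaled expression profile per
condition (the mean of that condition's replicates by default) and the
sigmoid activations of its bottleneck nodes are recorded. Activations are
binarised into ON / OFF / AMBIGUOUS states with saturation thresholds, and
(member, node) pairs are classified by which conditions they turn on for:
a node that is ON for every focal condition (e.g. both acid conditions)
and OFF for every background stress is condition-specific; nodes that are
additionally ON for exactly one background stress form the shared-response
patterns (acid+ethanol, acid+antibiotic, ...).

Node identity is always the (member, node) pair — nodes are never matched
across ensemble members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ScaledCompendium
from .dae import DAEEnsemble

ON, OFF, AMBIGUOUS = "ON", "OFF", "AMBIGUOUS"

__all__ = [
    "profile_conditions",
    "binarize",
    "find_specific_nodes",
    "pattern_census",
    "SpecificNodeGroup",
]


def profile_conditions(ensemble: DAEEnsemble, scaled: ScaledCompendium,
                       conditions=None, per_replicate: bool = False) -> pd.DataFrame:
    """Encode per-condition profiles with every ensemble member.

    Returns a long table with columns (member, node, condition, activation)
    — plus ``replicate`` when ``per_replicate=True``, in which case every
    replicate profile is encoded instead of the condition mean.
    """
    if conditions is None:
        conditions = list(dict.fromkeys(scaled.condition_of_sample[s] for s in scaled.sample_ids))
    rows = []
    for cond in conditions:
        samples = scaled.samples_of_condition(cond)
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples in the compendium")
        cols = scaled.column_indices(samples)
        if per_replicate:
            profiles = scaled.values[:, cols].T  # replicates x genes
            reps = list(range(len(samples)))
        else:
            profiles = scaled.values[:, cols].mean(axis=1, keepdims=True).T
            reps = [0]
        acts = ensemble.transform(profiles)  # members x profiles x nodes
        n_members, n_profiles, n_nodes = acts.shape
        for m in range(n_members):
            for r in range(n_profiles):
                for k in range(n_nodes):
                    row = {"member": m, "node": k, "condition": cond,
                           "activation": acts[m, r, k]}
                    if per_replicate:
                        row["replicate"] = reps[r]
                    rows.append(row)
    return pd.DataFrame(rows)


def binarize(table: pd.DataFrame, theta_on: float = 0.9,
             theta_off: float = 0.1) -> pd.DataFrame:
    """Map activations to ON (>= theta_on) / OFF (<= theta_off) / AMBIGUOUS.

    The thresholds target the sigmoid saturation regime; AMBIGUOUS
    activations disqualify a node from both ON and OFF requirements
    downstream (conservative specificity).
    """
    if not 0.0 <= theta_off < theta_on <= 1.0:
        raise ValueError(f"need 0 <= theta_off < theta_on <= 1, got ({theta_on}, {theta_off})")
    out = table.copy()
    a = out["activation"].to_numpy()
    state = np.where(a >= theta_on, ON, np.where(a <= theta_off, OFF, AMBIGUOUS))
    out["state"] = state
    out.attrs["theta_on"] = theta_on
    out.attrs["theta_off"] = theta_off
    return out


def _state_grid(states: pd.DataFrame) -> pd.DataFrame:
    """Pivot to one row per (member, node) with a state column per condition.

    With per-replicate states a condition counts as ON/OFF only if every
    replicate agrees (unanimity); any disagreement becomes AMBIGUOUS.
    """
    df = states
    if "replicate" in df.columns:
        def unanimous(s):
            u = s.unique()
            return u[0] if len(u) == 1 else AMBIGUOUS
        df = (df.groupby(["member", "node", "condition"])["state"]
                .agg(unanimous).reset_index())
    return df.pivot_table(index=["member", "node"], columns="condition",
                          values="state", aggfunc="first")


@dataclass
class SpecificNodeGroup:
    """(member, node) pairs matching one condition pattern, with counts."""

    pattern: str
    focal_conditions: tuple[str, ...]
    co_active_conditions: tuple[str, ...]
    members: list[tuple[int, int]]

    @property
    def count(self) -> int:
        return len(self.members)


def _check_sets(focal, background):
    focal, background = list(focal), list(background)
    if not focal or not background:
        raise ValueError("focal and background condition sets must be non-empty")
    overlap = set(focal) & set(background)
    if overlap:
        raise ValueError(f"focal and background conditions overlap: {sorted(overlap)}")
    return focal, background


def find_specific_nodes(states: pd.DataFrame, focal, background) -> SpecificNodeGroup:
    """Nodes ON for all focal conditions and OFF for all background ones.

    AMBIGUOUS states fail both requirements, so they exclude the pair.
    """
    focal, background = _check_sets(focal, background)
    grid = _state_grid(states)
    missing = [c for c in focal + background if c not in grid.columns]
    if missing:
        raise ValueError(f"conditions absent from the state table: {missing}")
    mask = np.ones(len(grid), dtype=bool)
    for c in focal:
        mask &= (grid[c] == ON).to_numpy()
    for c in background:
        mask &= (grid[c] == OFF).to_numpy()
    pairs = [tuple(ix) for ix in grid.index[mask]]
    return SpecificNodeGroup(
        pattern="+".join(focal) + "-only",
        focal_conditions=tuple(focal),
        co_active_conditions=(),
        members=pairs,
    )


def pattern_census(states: pd.DataFrame, focal, background) -> dict[str, SpecificNodeGroup]:
    """Census of exclusive activation patterns over focal + background.

    Patterns are the focal-only group (ON for all focal, OFF for every
    background condition) and, for each background condition X, the group
    ON for all focal plus X and OFF for the remaining background. The
    patterns are mutually exclusive by construction.
    """
    focal, background = _check_sets(focal, background)
    census: dict[str, SpecificNodeGroup] = {}
    only = find_specific_nodes(states, focal, background)
    if only.members:
        census[only.pattern] = only
    for x in background:
        rest = [c for c in background if c != x]
        if not rest:
            continue
        grp = find_specific_nodes(states, focal + [x], rest)
        grp = SpecificNodeGroup(
            pattern="+".join(focal) + f"+{x}",
            focal_conditions=tuple(focal),
            co_active_conditions=(x,),
            members=grp.members,
        )
        if grp.members:
            census[grp.pattern] = grp
    return census


def census_counts(census: dict[str, SpecificNodeGroup]) -> dict[str, int]:
    return {k: v.count for k, v in census.items()}
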