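"""Between-group comparison of per-feature spatial structure scores."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)


@dataclass
class MultiSampleScores:
    """Per-sample score maps with a two-group labelling."""

    groups: Mapping[str, str]                    # sample_id -> group label
    scores: Mapping[str, Mapping[str, float]]    # sample_id -> {feature: score}

    def __post_init__(self):
        if set(self.groups) != set(self.scores):
            raise DataError("sample ids of groups and scores differ")
        if len(set(self.groups.values())) < 2:
            raise DataError("need at least two distinct group labels")


def mean_coss_difference(
    ms: MultiSampleScores,
    group_a: str,
    group_b: str,
    min_samples_per_group: int = 1,
) -> pd.DataFrame:
    """Per-feature difference of group-mean scores, descending.

    A feature's mean in a group is taken over the samples in which it was
    scored; features scored in fewer than ``min_samples_per_group`` samples
    of either group are excluded (counted in a log line, not imputed as 0).
    """
    labels = set(ms.groups.values())
    for g in (group_a, group_b):
        if g not in labels:
            raise UsageError(f"unknown group label {g!r}")
    if min_samples_per_group < 1:
        raise UsageError("min_samples_per_group must be >= 1")

    per_group = {group_a: [], group_b: []}
    for sid, g in ms.groups.items():
        if g in per_group:
            per_group[g].append(ms.scores[sid])

    features = sorted(
        {f for maps in per_group.values() for mp in maps for f in mp}
    )
    rows, n_excluded = [], 0
    for f in features:
        va = [mp[f] for mp in per_group[group_a] if f in mp and mp[f] is not None]
        vb = [mp[f] for mp in per_group[group_b] if f in mp and mp[f] is not None]
        if len(va) < min_samples_per_group or len(vb) < min_samples_per_group:
            n_excluded += 1
            continue
        ma, mb = float(np.mean(va)), float(np.mean(vb))
        rows.append((f, ma, mb, ma - mb, len(va), len(vb)))
    if n_excluded:
        logger.info(
            "%d features excluded (scored in < %d samples of a group)",
            n_excluded,
            min_samples_per_group,
        )
    df = pd.DataFrame(
        rows, columns=["feature_id", "mean_a", "mean_b", "difference", "n_a", "n_b"]
    )
    return df.sort_values(
        ["difference", "feature_id"], ascending=[False, True]
    ).reset_index(drop=True)


def label_permutation_pvalues(
    ms: MultiSampleScores,
    group_a: str,
    group_b: str,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    min_samples_per_group: int = 1,
) -> pd.DataFrame:
    """Optional two-sided label-permutation p-value per feature.

    Not part of the core ranking output; provided as an extra.
    """
    observed = mean_coss_difference(ms, group_a, group_b, min_samples_per_group)
    rng = np.random.default_rng(seed)
    sids = [s for s, g in ms.groups.items() if g in (group_a, group_b)]
    orig = [ms.groups[s] for s in sids]
    exceed = np.zeros(len(observed), dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(orig)
        shuffled = MultiSampleScores(
            groups=dict(zip(sids, perm)), scores={s: ms.scores[s] for s in sids}
        )
        d = mean_coss_difference(shuffled, group_a, group_b, min_samples_per_group)
        d = d.set_index("feature_id")["difference"]
        vals = d.reindex(observed["feature_id"]).to_numpy()
        exceed += np.abs(vals) >= np.abs(observed["difference"].to_numpy()) - 1e-15
    observed["p_value"] = (exceed + 1) / (n_permutations + 1)
    return observed
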