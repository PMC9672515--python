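"""Short time-series trend-profile assignment and permutation enrichment.

For a 3-stage series the full set of (2c+1)^(n_stages-1) step profiles is
enumerated (c = 2 by default, 25 profiles at 3 stages — small enough that
no greedy model-profile selection is needed).  Each feature's stage-mean
vector is assigned to the non-flat profile with the highest Pearson
correlation to the profile's cumulative value vector; constant vectors go
to the flat profile.  Profile enrichment permutes each feature's stage
labels and compares observed profile counts to the permutation
distribution with an add-one p-value estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "TrendProfile",
    "enumerate_profiles",
    "assign_to_profile",
    "assign_features",
    "profile_enrichment",
    "stage_mean_matrix",
]

#: correlations are rounded to this many decimals before the argmax so that
#: analytically tied profiles (scalar multiples of one another) resolve to
#: the lowest profile id regardless of floating-point noise.
CORR_DECIMALS = 12


@dataclass(frozen=True)
class TrendProfile:
    """A step profile over ordered stages; values start at 0."""

    profile_id: int
    steps: tuple[int, ...]

    @property
    def values(self) -> tuple[int, ...]:
        out = [0]
        for s in self.steps:
            out.append(out[-1] + s)
        return tuple(out)

    @property
    def is_flat(self) -> bool:
        return all(s == 0 for s in self.steps)

    @property
    def net_change(self) -> int:
        return sum(self.steps)


def enumerate_profiles(n_stages: int = 3, c: int = 2) -> list[TrendProfile]:
    """All (2c+1)^(n_stages-1) step combinations, lexicographic over steps."""
    if n_stages < 2:
        raise ValueError("n_stages must be >= 2")
    if c < 1:
        raise ValueError("c must be >= 1")
    combos = product(range(-c, c + 1), repeat=n_stages - 1)
    return [TrendProfile(i, steps) for i, steps in enumerate(combos)]


def _profile_corr_matrix(profiles: list[TrendProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Centered, norm-scaled profile value matrix and a non-flat mask."""
    V = np.array([p.values for p in profiles], dtype=float)
    Vc = V - V.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Vc, axis=1)
    nonflat = norms > 0
    Vc[nonflat] /= norms[nonflat, None]
    return Vc, nonflat


def assign_features(stage_means: np.ndarray, profiles: list[TrendProfile]) -> np.ndarray:
    """Vectorized profile assignment for a features x stages array."""
    X = np.asarray(stage_means, dtype=float)
    if X.ndim != 2:
        raise ValueError("stage_means must be 2-D (features x stages)")
    Vc, nonflat = _profile_corr_matrix(profiles)
    flat_ids = [p.profile_id for p in profiles if p.is_flat]
    if not flat_ids:
        raise ValueError("profile set must include the flat profile")
    flat_id = flat_ids[0]

    Xc = X - X.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(Xc, axis=1)
    constant = xnorm == 0
    Xc[~constant] /= xnorm[~constant, None]
    R = np.round(Xc @ Vc.T, CORR_DECIMALS)
    R[:, ~nonflat] = -np.inf  # flat profile excluded from the argmax
    assigned = R.argmax(axis=1)
    assigned[constant] = flat_id
    return assigned


def assign_to_profile(stage_means, profiles: list[TrendProfile]) -> int:
    """Profile id for one stage-mean vector (ties -> lowest profile id)."""
    x = np.asarray(stage_means, dtype=float)[None, :]
    return int(assign_features(x, profiles)[0])


def stage_mean_matrix(matrix, design: pd.DataFrame, stage_order: list[str]) -> pd.DataFrame:
    """Per-feature stage means (features x ordered stages) from an
    ExpressionMatrix and a sample design."""
    cols = {}
    for stage in stage_order:
        samples = design.loc[design["stage"] == stage, "sample_id"].tolist()
        if not samples:
            raise ValueError(f"stage {stage!r} has no samples in design")
        cols[stage] = matrix.data[samples].mean(axis=1)
    return pd.DataFrame(cols, index=matrix.data.index)


def profile_enrichment(
    stage_means: pd.DataFrame,
    profiles: list[TrendProfile],
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment of features over trend profiles.

    Each permutation round independently shuffles every feature's stage
    labels and re-assigns profiles; expected_count is the mean permuted
    count and p = (1 + #{rounds with count >= observed}) / (n_perm + 1),
    so p is never 0.  Significant at p < 0.05.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    X = stage_means.to_numpy(dtype=float)
    n_feat, n_stage = X.shape
    n_prof = len(profiles)
    rng = np.random.default_rng(seed)

    observed = np.bincount(assign_features(X, profiles), minlength=n_prof)
    ge_obs = np.zeros(n_prof, dtype=int)
    perm_sum = np.zeros(n_prof, dtype=float)
    for _ in range(n_perm):
        idx = rng.permuted(
            np.broadcast_to(np.arange(n_stage), (n_feat, n_stage)).copy(), axis=1
        )
        perm_counts = np.bincount(
            assign_features(np.take_along_axis(X, idx, axis=1), profiles),
            minlength=n_prof,
        )
        perm_sum += perm_counts
        ge_obs += perm_counts >= observed

    pvals = (1.0 + ge_obs) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "profile_id": [p.profile_id for p in profiles],
            "steps": [",".join(map(str, p.steps)) for p in profiles],
            "net_change": [p.net_change for p in profiles],
            "observed_count": observed,
            "expected_count": perm_sum / n_perm,
            "p_value": pvals,
            "significant": pvals < 0.05,
        }
    ).set_index("profile_id")
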