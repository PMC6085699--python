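"""Similarity index (SI) family with artificial-pair permutation nulls.

The SI compares two tumours of one patient on discretized aberration calls.
Per common probe the pair of calls is classified as *shared* (both aberrant
in the same direction, N_S), *unique* (exactly one aberrant, N_U), or
*opposite* (aberrant in opposite directions, N_O); probes neutral in both
tumours do not count. Then::

    SI = N_S / (N_S + N_U + N_O)

ranging from 0 (no aberration in common) to 1 (identical aberration
profiles). The methylation variant SI_met instead counts the fraction of
probes whose three-level methylation state (unmethylated / hemi-methylated
/ methylated) is identical, including matches in the hemi-methylated
middle class, because methylation has no single biologically neutral state
to measure changes from.

The permutation quantity P_SI is the percentage of a pair's similarity not
attributable to recurrent aberrations or chance. It is reconstructed here
(the published description is verbal) as::

    P_SI = max(0, 100 * (SI_obs - mean(SI_null)) / SI_obs)

where the null is the SI over all artificial cross-patient pairs of the
cohort; artificial pairs carry the population-recurrent and random
component of similarity but no patient-specific clonal component. An
add-one empirical p-value against the same null accompanies it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    CallLabel,
    DiscreteProfile,
    Platform,
    ProbeProfile,
    Scheme,
    TumourPair,
    enumerate_pairs,
)

__all__ = [
    "SimilarityCounts",
    "SiNull",
    "discretize_copy_number",
    "discretize_expression",
    "discretize_methylation",
    "count_states",
    "similarity_index",
    "pair_similarity",
    "similarity_index_met",
    "si_null_distribution",
    "score_against_null",
    "si_permutation",
    "beta_variability",
    "compute_aberration_frequency",
]

# Default discretization thresholds: copy-number log2 ratios call a
# heterozygous loss below -0.3 and a low-level gain above +0.3 (strict);
# expression log2 ratios use a 1.5-fold cut-off (|log2| > 0.58); beta
# values call methylated above 0.8 and unmethylated below 0.2.
CN_LOSS_THR = -0.3
CN_GAIN_THR = 0.3
EXPR_THR = 0.58
BETA_LOW = 0.2
BETA_HIGH = 0.8


@dataclass
class SimilarityCounts:
    """Per-probe call-pair tallies behind the similarity index."""

    n_shared: int
    n_unique: int
    n_opposite: int
    n_neutral: int

    @property
    def n_informative(self) -> int:
        return self.n_shared + self.n_unique + self.n_opposite

    @property
    def si(self) -> float | None:
        """SI = N_S / (N_S + N_U + N_O); None when no probe is aberrant."""
        if self.n_informative == 0:
            return None
        return self.n_shared / self.n_informative


@dataclass
class SiNull:
    """Artificial-pair null summary for one observed pair."""

    observed: float
    null_si: np.ndarray
    mean_null: float
    p_si: float  # percent in [0, 100]
    p_empirical: float
    call: CallLabel = CallLabel.NOT_EVALUABLE


def _discretize_signed(values: np.ndarray, low: float, high: float) -> np.ndarray:
    states = np.zeros(len(values), dtype=int)
    states[values < low] = -1
    states[values > high] = 1
    return states


def discretize_copy_number(
    profile: ProbeProfile,
    loss_thr: float = CN_LOSS_THR,
    gain_thr: float = CN_GAIN_THR,
) -> DiscreteProfile:
    """Call loss/neutral/gain from log2 ratios with strict thresholds.

    Values strictly below ``loss_thr`` become -1, strictly above
    ``gain_thr`` become +1; values equal to a threshold stay neutral.
    Accepts copy-number, methylation-intensity and SNP log-R-ratio
    platforms, which all measure the same phenomenon.
    """
    if profile.platform not in (
        Platform.COPY_NUMBER, Platform.METHYLATION_INTENSITY, Platform.SNP_LRR
    ):
        raise ValueError(
            f"cannot discretize platform {profile.platform.value} as copy number"
        )
    return DiscreteProfile(
        profile.sample_id,
        Scheme.CN3,
        profile.probes,
        _discretize_signed(profile.values, loss_thr, gain_thr),
        (loss_thr, gain_thr),
    )


def discretize_expression(
    profile: ProbeProfile, thr: float = EXPR_THR
) -> DiscreteProfile:
    """Call under-/neutral/over-expressed at a symmetric log2 cut-off."""
    if profile.platform is not Platform.EXPRESSION:
        raise ValueError("discretize_expression requires an expression profile")
    return DiscreteProfile(
        profile.sample_id,
        Scheme.EXPR3,
        profile.probes,
        _discretize_signed(profile.values, -thr, thr),
        (-thr, thr),
    )


def discretize_methylation(
    profile: ProbeProfile, low: float = BETA_LOW, high: float = BETA_HIGH
) -> DiscreteProfile:
    """Call U/H/M methylation states from beta values.

    Beta > ``high`` is methylated (M), beta < ``low`` unmethylated (U),
    and the closed middle range [low, high] hemi-methylated (H).
    """
    if profile.platform is not Platform.METHYLATION_BETA:
        raise ValueError("discretize_methylation requires beta values")
    states = np.full(len(profile), "H", dtype="<U1")
    states[profile.values > high] = "M"
    states[profile.values < low] = "U"
    return DiscreteProfile(
        profile.sample_id, Scheme.METH3, profile.probes, states, (low, high)
    )


def _common_states(a: DiscreteProfile, b: DiscreteProfile):
    """Align two discrete profiles on their shared probe ids."""
    if a.probe_ids == b.probe_ids:
        return a.states, b.states
    ids_a = {pid: i for i, pid in enumerate(a.probe_ids)}
    idx_a, idx_b = [], []
    for j, pid in enumerate(b.probe_ids):
        i = ids_a.get(pid)
        if i is not None:
            idx_a.append(i)
            idx_b.append(j)
    if not idx_a:
        raise ValueError(
            f"no common probes between {a.sample_id} and {b.sample_id}"
        )
    return a.states[idx_a], b.states[idx_b]


def count_states(a: DiscreteProfile, b: DiscreteProfile) -> SimilarityCounts:
    """Tally shared/unique/opposite aberration calls over common probes."""
    if a.scheme != b.scheme:
        raise ValueError(f"scheme mismatch: {a.scheme.value} vs {b.scheme.value}")
    if a.scheme is Scheme.METH3:
        raise ValueError(
            "count_states is defined for signed aberration calls; "
            "use similarity_index_met for methylation states"
        )
    sa, sb = _common_states(a, b)
    both = (sa != 0) & (sb != 0)
    n_shared = int(np.sum(both & (sa == sb)))
    n_opposite = int(np.sum(both & (sa != sb)))
    n_unique = int(np.sum((sa != 0) ^ (sb != 0)))
    n_neutral = int(np.sum((sa == 0) & (sb == 0)))
    return SimilarityCounts(n_shared, n_unique, n_opposite, n_neutral)


def similarity_index(counts: SimilarityCounts) -> float | None:
    """SI from pre-computed counts; None if no probe is aberrant in either."""
    return counts.si


def pair_similarity(a: DiscreteProfile, b: DiscreteProfile) -> float | None:
    """Convenience: SI directly from two signed discrete profiles."""
    return count_states(a, b).si


def similarity_index_met(a: DiscreteProfile, b: DiscreteProfile) -> float:
    """Fraction of common probes with identical U/H/M state.

    Unlike the SI, matches in the hemi-methylated middle state count.
    """
    if a.scheme is not Scheme.METH3 or b.scheme is not Scheme.METH3:
        raise ValueError("similarity_index_met requires meth3 profiles")
    sa, sb = _common_states(a, b)
    return float(np.mean(sa == sb))


def _pair_statistic(profiles, pair, statistic):
    a, b = profiles[pair.sample_a], profiles[pair.sample_b]
    if statistic == "si_met":
        return similarity_index_met(a, b)
    return pair_similarity(a, b)


def si_null_distribution(
    profiles: dict[str, DiscreteProfile],
    patient_samples: dict[str, tuple[str, str]],
    statistic: str = "si",
) -> np.ndarray:
    """Similarity statistic over every artificial cross-patient pair.

    Pairs whose SI is undefined (no aberrant probe in either tumour) are
    dropped. The null does not depend on which true pair is being scored,
    so it is computed once per cohort and platform.
    """
    if len(patient_samples) < 2:
        raise ValueError("permutation null requires at least 2 patients")
    if statistic not in ("si", "si_met"):
        raise ValueError(f"unknown statistic {statistic!r}")
    _, artificial = enumerate_pairs(patient_samples)
    null = [
        v for v in (_pair_statistic(profiles, p, statistic) for p in artificial)
        if v is not None
    ]
    return np.asarray(null, dtype=float)


def score_against_null(
    observed: float | None, null_arr: np.ndarray, alpha: float = 0.05
) -> SiNull:
    """P_SI and the empirical p for one observed similarity value.

    P_SI = max(0, 100 * (SI_obs - mean_null) / SI_obs); the empirical p
    uses the add-one rule (1 + #{null >= obs}) / (1 + N). An undefined
    observed SI yields a not_evaluable result.
    """
    null_arr = np.asarray(null_arr, dtype=float)
    if observed is None or len(null_arr) == 0:
        return SiNull(
            np.nan, null_arr,
            float(np.mean(null_arr)) if len(null_arr) else np.nan,
            np.nan, np.nan, CallLabel.NOT_EVALUABLE,
        )
    mean_null = float(np.mean(null_arr))
    p_si = max(0.0, 100.0 * (observed - mean_null) / observed) if observed > 0 else 0.0
    p_emp = (1.0 + int(np.sum(null_arr >= observed))) / (1.0 + len(null_arr))
    call = CallLabel.CLONAL if p_emp <= alpha else CallLabel.INDEPENDENT
    return SiNull(float(observed), null_arr, mean_null, p_si, p_emp, call)


def si_permutation(
    observed_pair: TumourPair,
    profiles: dict[str, DiscreteProfile],
    patient_samples: dict[str, tuple[str, str]],
    statistic: str = "si",
    alpha: float = 0.05,
) -> SiNull:
    """Score one pair's similarity against the artificial-pair null."""
    null_arr = si_null_distribution(profiles, patient_samples, statistic)
    obs = _pair_statistic(profiles, observed_pair, statistic)
    return score_against_null(obs, null_arr, alpha)


def beta_variability(profile: ProbeProfile, min_probes: int = 20) -> float:
    """Spread of a sample's beta values: 95th minus 5th percentile."""
    if profile.platform is not Platform.METHYLATION_BETA:
        raise ValueError("beta_variability requires beta values")
    if len(profile) < min_probes:
        raise ValueError(
            f"need at least {min_probes} probes, got {len(profile)}"
        )
    p5, p95 = np.percentile(profile.values, [5, 95])
    return float(p95 - p5)


def compute_aberration_frequency(
    profiles: list[DiscreteProfile],
    min_freq: float = 0.25,
    exclude_sex_chromosomes: bool = False,
):
    """Per-probe gain/loss frequencies across a cohort of cn3 calls.

    Returns a pandas DataFrame with columns probe_id, chrom, pos,
    gain_freq, loss_freq and a ``recurrent`` flag marking probes aberrant
    in at least ``min_freq`` of samples in either direction.
    """
    import pandas as pd

    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if p.probe_ids != ref.probe_ids:
            raise ValueError("aberration frequency requires a shared probe set")
        if p.scheme is not ref.scheme:
            raise ValueError("mixed discretization schemes")
    states = np.stack([p.states.astype(int) for p in profiles])
    gain = np.mean(states == 1, axis=0)
    loss = np.mean(states == -1, axis=0)
    df = pd.DataFrame(
        {
            "probe_id": ref.probe_ids,
            "chrom": [p.chrom for p in ref.probes],
            "pos": [p.pos for p in ref.probes],
            "gain_freq": gain,
            "loss_freq": loss,
        }
    )
    df["recurrent"] = (df["gain_freq"] >= min_freq) | (df["loss_freq"] >= min_freq)
    if exclude_sex_chromosomes:
        df = df[~df["chrom"].isin(["X", "Y"])].reset_index(drop=True)
    return df
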