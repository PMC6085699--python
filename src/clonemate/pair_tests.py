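"""Per-pair clonality tests beyond the similarity index.

All tests share one logic: a statistic measured on the true pair (the two
tumours of one patient) is ranked against the same statistic over the
artificial cross-patient pairs of the cohort. A true pair is called clonal
when it is more similar than almost all artificial pairs — distance in the
lower 5th percentile, or shared segments / shared mutations strictly above
the 95th percentile of the permutation distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .datatypes import (
    CallLabel,
    FusionSet,
    PairTestResult,
    ProbeProfile,
    SegmentedProfile,
    TumourPair,
    VariantSet,
    enumerate_pairs,
    normalise_chrom,
)

__all__ = [
    "PanelRegions",
    "euclidean_distance",
    "distance_test",
    "cluster_cherry_test",
    "shared_segments",
    "shared_segment_test",
    "shared_mutations",
    "shared_mutation_test",
    "fusion_overlap",
    "distance_matrix",
]

MIN_NULL_SIZE = 20  # artificial pairs needed for a meaningful tail percentile


@dataclass
class PanelRegions:
    """Genomic regions restricting mutation counting to a gene panel."""

    name: str
    regions: list[tuple[str, int, int]]  # (chrom, start, end), 1-based inclusive

    def __post_init__(self) -> None:
        self.regions = [
            (normalise_chrom(c), int(s), int(e)) for c, s, e in self.regions
        ]
        for c, s, e in self.regions:
            if s > e:
                raise ValueError(f"panel region {c}:{s}-{e} has negative span")

    def contains(self, chrom: str, pos: int) -> bool:
        chrom = normalise_chrom(chrom)
        return any(c == chrom and s <= pos <= e for c, s, e in self.regions)

    def restrict(self, vs: VariantSet) -> VariantSet:
        return VariantSet(
            vs.sample_id,
            [v for v in vs.variants if self.contains(v[0], v[1])],
        )


def _aligned_values(a: ProbeProfile, b: ProbeProfile):
    if a.platform != b.platform:
        raise ValueError(
            f"platform mismatch: {a.platform.value} vs {b.platform.value}"
        )
    if a.probe_ids == b.probe_ids:
        return a.values, b.values
    ids_a = {pid: i for i, pid in enumerate(a.probe_ids)}
    idx_a, idx_b = [], []
    for j, pid in enumerate(b.probe_ids):
        i = ids_a.get(pid)
        if i is not None:
            idx_a.append(i)
            idx_b.append(j)
    if len(idx_a) < 2:
        raise ValueError(
            f"fewer than 2 common probes between {a.sample_id} and {b.sample_id}"
        )
    return a.values[idx_a], b.values[idx_b]


def euclidean_distance(a: ProbeProfile, b: ProbeProfile) -> float:
    """Euclidean distance over the common probes of two profiles."""
    va, vb = _aligned_values(a, b)
    return float(np.sqrt(np.sum((va - vb) ** 2)))


def distance_matrix(profiles: list[ProbeProfile]) -> np.ndarray:
    """Full symmetric Euclidean distance matrix (profiles share probes)."""
    ref = profiles[0]
    for p in profiles[1:]:
        if p.probe_ids != ref.probe_ids:
            raise ValueError("distance_matrix requires a common probe set")
    x = np.stack([p.values for p in profiles])
    sq = np.sum(x**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * x @ x.T, 0.0)
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(d2)


def _percentile_test(
    pair: TumourPair,
    method: str,
    observed: float,
    null_values: np.ndarray,
    q: float,
    clonal_when: str,
) -> PairTestResult:
    null_values = np.asarray(null_values, dtype=float)
    if len(null_values) < MIN_NULL_SIZE:
        return PairTestResult(
            pair, method, float(observed), CallLabel.NOT_EVALUABLE,
            null_values=null_values,
        )
    thr = float(np.percentile(null_values, q))  # linear interpolation
    if clonal_when == "le":
        clonal = observed <= thr
    else:  # strict 'above'
        clonal = observed > thr
    return PairTestResult(
        pair,
        method,
        float(observed),
        CallLabel.CLONAL if clonal else CallLabel.INDEPENDENT,
        threshold=thr,
        null_values=null_values,
    )


def distance_test(
    pair: TumourPair, observed: float, artificial: np.ndarray
) -> PairTestResult:
    """Clonal iff the true-pair distance lies at or below the artificial
    5th percentile."""
    return _percentile_test(pair, "distance", observed, artificial, 5.0, "le")


def shared_segment_test(
    pair: TumourPair, observed: int, artificial: np.ndarray
) -> PairTestResult:
    """Clonal iff the shared-segment count is strictly above the
    artificial 95th percentile."""
    return _percentile_test(pair, "shared_segments", observed, artificial, 95.0, "gt")


def shared_mutation_test(
    pair: TumourPair, observed: int, artificial: np.ndarray, method: str = "shared_mutations"
) -> PairTestResult:
    """Clonal iff the shared-mutation count is strictly above the
    artificial 95th percentile."""
    return _percentile_test(pair, method, observed, artificial, 95.0, "gt")


def cluster_cherry_test(
    profiles: list[ProbeProfile],
    patient_samples: dict[str, tuple[str, str]],
) -> list[PairTestResult]:
    """Single-linkage dendrogram test: a true pair is clonal iff its two
    samples form a cherry (merge with each other before anything else).

    Samples are ordered lexicographically before linkage so that merge
    order — and thus the dendrogram — is reproducible under ties.
    """
    if len(profiles) < 4:
        raise ValueError("clustering needs at least 4 samples")
    profiles = sorted(profiles, key=lambda p: p.sample_id)
    ids = [p.sample_id for p in profiles]
    dm = distance_matrix(profiles)
    z = linkage(squareform(dm, checks=False), method="single")
    n = len(ids)
    cherries = set()
    for left, right, _height, _count in z:
        if left < n and right < n:  # both children are leaves
            a, b = ids[int(left)], ids[int(right)]
            cherries.add(frozenset((a, b)))
    true_pairs, _ = enumerate_pairs(patient_samples)
    results = []
    for pair in true_pairs:
        clonal = frozenset((pair.sample_a, pair.sample_b)) in cherries
        results.append(
            PairTestResult(
                pair,
                "clustering",
                1.0 if clonal else 0.0,
                CallLabel.CLONAL if clonal else CallLabel.INDEPENDENT,
            )
        )
    return results


def _segment_keys(profile: SegmentedProfile) -> set[tuple]:
    return {
        (s.chrom, s.start, s.end, s.status)
        for s in profile.segments
        if s.status != "normal"
    }


def shared_segments(
    a: SegmentedProfile, b: SegmentedProfile, tolerance_bp: int = 0
) -> int:
    """Count segments identical in both profiles: same chromosome, exact
    start and end breakpoints, and the same aberrant direction.

    Normal segments never count. ``tolerance_bp`` optionally relaxes the
    breakpoint match to +/- that many bases (default 0 keeps the exact
    rule); each segment matches at most once.
    """
    ka, kb = _segment_keys(a), _segment_keys(b)
    if tolerance_bp == 0:
        return len(ka & kb)
    count = 0
    unused = list(kb)
    for c, s, e, st in sorted(ka):
        for j, (c2, s2, e2, st2) in enumerate(unused):
            if (
                c == c2 and st == st2
                and abs(s - s2) <= tolerance_bp
                and abs(e - e2) <= tolerance_bp
            ):
                count += 1
                unused.pop(j)
                break
    return count


def shared_mutations(
    a: VariantSet, b: VariantSet, panel: PanelRegions | None = None
) -> int:
    """Count variants identical in both tumours on (chrom, pos, ref, alt).

    With a panel, both sets are first restricted to the panel regions.
    """
    if panel is not None:
        a, b = panel.restrict(a), panel.restrict(b)
    return len(a.variants & b.variants)


def fusion_overlap(a: FusionSet, b: FusionSet) -> tuple[int, set]:
    """Fusion transcripts with identical 5' and 3' partner breakpoints.

    Returns the count and the set of shared breakpoint keys
    (chrom5, pos5, chrom3, pos3). Gene symbols are reported alongside in
    the fusion records but do not participate in matching.
    """
    shared = a.breakpoint_keys() & b.breakpoint_keys()
    return len(shared), shared
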