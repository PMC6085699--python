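"""Core domain types for paired-tumour clonality analysis.

Coordinates are 1-based with inclusive start and end (SEG convention)
throughout. Chromosome names are normalised to "1".."22", "X", "Y"
(any leading "chr" is stripped).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Platform",
    "Scheme",
    "CallLabel",
    "Probe",
    "ProbeProfile",
    "DiscreteProfile",
    "Segment",
    "SegmentedProfile",
    "VariantSet",
    "FusionSet",
    "ClinicalRecord",
    "TumourPair",
    "PairTestResult",
    "CohortData",
    "normalise_chrom",
    "enumerate_pairs",
]

_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER["X"] = 23
_CHROM_ORDER["Y"] = 24


def normalise_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix and canonicalise case for X/Y."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c.lower() in ("x", "y"):
        c = c.upper()
    return c


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing autosomes 1..22 first, then X, Y, then others."""
    return (_CHROM_ORDER.get(chrom, 99), chrom)


class Platform(str, enum.Enum):
    COPY_NUMBER = "copy_number"
    EXPRESSION = "expression"
    METHYLATION_BETA = "methylation_beta"
    METHYLATION_INTENSITY = "methylation_intensity"
    SNP_LRR = "snp_lrr"
    SNP_BAF = "snp_baf"


class Scheme(str, enum.Enum):
    CN3 = "cn3"
    EXPR3 = "expr3"
    METH3 = "meth3"


class CallLabel(str, enum.Enum):
    CLONAL = "clonal"
    INDEPENDENT = "independent"
    NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class Probe:
    probe_id: str
    chrom: str
    pos: int


@dataclass
class ProbeProfile:
    """Ordered genomic probe values for one sample on one platform.

    Probes are sorted by (chromosome, position); beta-value platforms are
    constrained to [0, 1]; all values must be finite.
    """

    sample_id: str
    platform: Platform
    probes: list[Probe]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.probes) != len(self.values):
            raise ValueError(
                f"{self.sample_id}: {len(self.probes)} probes but "
                f"{len(self.values)} values"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.sample_id}: non-finite probe values")
        keys = [(chrom_sort_key(p.chrom), p.pos) for p in self.probes]
        if any(keys[i] > keys[i + 1] for i in range(len(keys) - 1)):
            idx = sorted(range(len(keys)), key=lambda i: keys[i])
            self.probes = [self.probes[i] for i in idx]
            self.values = self.values[idx]
        if self.platform is Platform.METHYLATION_BETA:
            if np.any((self.values < 0) | (self.values > 1)):
                bad = self.values[(self.values < 0) | (self.values > 1)][0]
                raise ValueError(
                    f"{self.sample_id}: beta value {bad} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]


@dataclass
class DiscreteProfile:
    """Per-probe 3-state calls derived from a :class:`ProbeProfile`.

    ``cn3``/``expr3`` use -1/0/+1 (loss/neutral/gain, under/neutral/over);
    ``meth3`` uses the strings U/H/M (un-/hemi-/fully methylated).
    """

    sample_id: str
    scheme: Scheme
    probes: list[Probe]
    states: np.ndarray
    thresholds: tuple[float, float]

    def __post_init__(self) -> None:
        self.scheme = Scheme(self.scheme)
        self.states = np.asarray(self.states)
        if len(self.states) != len(self.probes):
            raise ValueError("states/probes length mismatch")
        if self.scheme in (Scheme.CN3, Scheme.EXPR3):
            if not np.isin(self.states, [-1, 0, 1]).all():
                raise ValueError(f"{self.scheme.value} states must be -1/0/+1")
        else:
            if not np.isin(self.states, ["U", "H", "M"]).all():
                raise ValueError("meth3 states must be U/H/M")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return [p.probe_id for p in self.probes]


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    mean_value: float
    status: str  # loss | normal | gain

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.status not in ("loss", "normal", "gain"):
            raise ValueError(f"invalid segment status {self.status!r}")


@dataclass
class SegmentedProfile:
    """Non-overlapping, status-labelled copy-number segments for one sample."""

    sample_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = sorted(
            self.segments, key=lambda s: (chrom_sort_key(s.chrom), s.start)
        )
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(
                    f"overlapping segments in sample {self.sample_id} "
                    f"on chromosome {a.chrom}: "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
        self.segments = segs

    def aberrant(self) -> list[Segment]:
        return [s for s in self.segments if s.status != "normal"]

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class VariantSet:
    """Deduplicated set of small variants keyed by (chrom, pos, ref, alt)."""

    sample_id: str
    variants: frozenset

    def __init__(self, sample_id: str, variants: Iterable[tuple]) -> None:
        self.sample_id = sample_id
        vs = set()
        for chrom, pos, ref, alt in variants:
            if ref == alt:
                raise ValueError(f"variant with ref == alt at {chrom}:{pos}")
            vs.add((normalise_chrom(chrom), int(pos), str(ref), str(alt)))
        self.variants = frozenset(vs)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class FusionSet:
    """Fusion transcripts keyed by 5' and 3' partner breakpoints.

    Gene symbols travel along for reporting but are never the match key.
    """

    sample_id: str
    fusions: frozenset

    def __init__(self, sample_id: str, fusions: Iterable[tuple]) -> None:
        self.sample_id = sample_id
        seen: dict[tuple, tuple] = {}
        for chrom5, pos5, gene5, chrom3, pos3, gene3 in fusions:
            key = (normalise_chrom(chrom5), int(pos5),
                   normalise_chrom(chrom3), int(pos3))
            seen.setdefault(key, (*key[:2], str(gene5), *key[2:], str(gene3)))
        self.fusions = frozenset(seen.values())

    def breakpoint_keys(self) -> set[tuple]:
        return {(c5, p5, c3, p3) for c5, p5, _, c3, p3, _ in self.fusions}

    def __len__(self) -> int:
        return len(self.fusions)


_ND = "ND"


@dataclass
class ClinicalRecord:
    """Clinical features of one patient's two tumours.

    ``ND`` marks a feature that was not determined; such features are
    excluded from concordance denominators.
    """

    patient_id: str
    laterality: str  # bilateral | ipsilateral
    interval_days: int
    histology: tuple[str, str]
    er: tuple[str, str]
    her2: tuple[str, str]
    subtype: tuple[str, str]

    def __post_init__(self) -> None:
        if self.laterality not in ("bilateral", "ipsilateral"):
            raise ValueError(f"invalid laterality {self.laterality!r}")
        if self.interval_days < 0:
            raise ValueError("interval_days must be non-negative")
        for name in ("er", "her2"):
            for v in getattr(self, name):
                if v not in ("pos", "neg", _ND):
                    raise ValueError(f"invalid {name} value {v!r}")


@dataclass(frozen=True)
class TumourPair:
    """Two tumour samples compared for clonal relatedness.

    A *true* pair is the two tumours of one patient; an *artificial* pair
    combines tumours of different patients and feeds the permutation null.
    """

    sample_a: str
    sample_b: str
    is_true_pair: bool
    patient_id: str | None = None
    group: str = "NA"

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError("a pair needs two distinct samples")
        if self.is_true_pair and self.patient_id is None:
            raise ValueError("true pair requires a patient_id")


@dataclass
class PairTestResult:
    """One clonality method's verdict on one tumour pair."""

    pair: TumourPair
    method: str
    statistic: float | None
    call: CallLabel
    threshold: float | None = None
    p_like: float | None = None
    null_values: Sequence[float] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.call = CallLabel(self.call)
        if self.p_like is not None and not (0.0 <= self.p_like <= 1.0):
            raise ValueError(f"p_like {self.p_like} outside [0, 1]")


@dataclass
class CohortData:
    """Everything one analysis run consumes, grouped per platform.

    ``profiles`` maps a platform name (copy_number, expression,
    methylation_beta, methylation_intensity, snp_lrr) to one
    ProbeProfile per sample; ``segments`` maps a copy-number-like
    platform to SegmentedProfiles. Platforms may be missing — analyses
    simply skip them.
    """

    patient_samples: dict[str, tuple[str, str]]
    profiles: dict[str, dict[str, "ProbeProfile"]] = field(default_factory=dict)
    segments: dict[str, dict[str, "SegmentedProfile"]] = field(default_factory=dict)
    variants: dict[str, "VariantSet"] = field(default_factory=dict)
    fusions: dict[str, "FusionSet"] = field(default_factory=dict)
    clinical: list["ClinicalRecord"] = field(default_factory=list)
    ground_truth: object | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patient_samples)

    def pairs(self) -> tuple[list["TumourPair"], list["TumourPair"]]:
        return enumerate_pairs(self.patient_samples)


def enumerate_pairs(
    patient_samples: dict[str, tuple[str, str]],
) -> tuple[list[TumourPair], list[TumourPair]]:
    """Enumerate true (same-patient) and artificial (cross-patient) pairs.

    Parameters
    ----------
    patient_samples
        Mapping patient_id -> (sample_1, sample_2); every patient must
        contribute exactly two samples.

    Returns
    -------
    (true_pairs, artificial_pairs)
        One true pair per patient and every unordered cross-patient sample
        combination: for n patients, 2n(n-1) artificial pairs, so that
        together they exhaust the C(2n, 2) sample pairs.
    """
    for pid, samples in patient_samples.items():
        if len(samples) != 2 or len(set(samples)) != 2:
            raise ValueError(
                f"patient {pid} must contribute exactly 2 distinct samples"
            )
    patients = sorted(patient_samples)
    true_pairs = [
        TumourPair(*patient_samples[pid], is_true_pair=True, patient_id=pid)
        for pid in patients
    ]
    owner = {s: pid for pid, ss in patient_samples.items() for s in ss}
    all_samples = sorted(owner)
    artificial = [
        TumourPair(a, b, is_true_pair=False)
        for i, a in enumerate(all_samples)
        for b in all_samples[i + 1:]
        if owner[a] != owner[b]
    ]
    return true_pairs, artificial
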