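"""Seeded generator of paired-tumour multi-platform cohorts.

The generator emulates the statistical structure that clonality tests
assume. Each patient contributes two tumours and is either *clonal* (both
tumours inherit one founder set of copy-number events, somatic variants
and fusions, then diverge by private subclonal drift) or *independent*
(each tumour acquires its own events; any sharing arises from
population-recurrent hotspot aberrations and residual common variants).

Copy-number events live on a fixed block grid: every chromosome is split
into candidate segments of a few probes each, so that an event present in
two tumours has *identical* breakpoints — mirroring segmentation on a
shared probe grid, which is what makes exact-breakpoint shared-segment
counting meaningful at all. Hotspot blocks model the gains (1q, 8q, 16p,
17q, 20q) and losses (1p, 8p, 11q, 13q, 16q) recurrently seen in breast
cancer, each present in a given tumour with its population frequency.

Variant sets mix patient-specific somatic variants with a residual
population-polymorphism background (imperfect germline filtering of
sequencing-derived calls): each tumour carries background site *i* with
probability f_i drawn from a Beta site-frequency spectrum, independently
across tumours, so cross-tumour sharing of background variants is common
— exactly the chance component the permutation null is meant to absorb.

All randomness flows from one seed through per-patient substreams, so a
cohort is bit-identical under a fixed config and stable when patients are
reordered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    CallLabel,
    CohortData,
    Platform,
    Probe,
    ProbeProfile,
    Segment,
    SegmentedProfile,
    ClinicalRecord,
    FusionSet,
    VariantSet,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "recover_labels"]

# Recurrent copy-number hotspots: (chromosome, arm, direction, population freq)
DEFAULT_HOTSPOTS = [
    ("1", "q", "gain", 0.35),
    ("8", "q", "gain", 0.40),
    ("16", "p", "gain", 0.30),
    ("17", "q", "gain", 0.30),
    ("20", "q", "gain", 0.30),
    ("1", "p", "loss", 0.25),
    ("8", "p", "loss", 0.30),
    ("11", "q", "loss", 0.30),
    ("13", "q", "loss", 0.25),
    ("16", "q", "loss", 0.35),
]

_AUTOSOMES = [str(i) for i in range(1, 23)]
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Copy-number noise ``noise_sd`` is the per-probe Gaussian SD on the
    log2 ratio scale; segment effects sit at +/-0.6, safely beyond the
    +/-0.3 discretization thresholds. ``beta_noise_scale`` is the
    per-tumour SD on the logit-beta scale.
    """

    n_patients: int = 20
    clonal_fraction: float = 0.5
    seed: int = 0
    # copy-number platform
    n_probes: int = 500
    probes_per_block: int = 5
    n_founder_events: int = 8
    n_drift_events: int = 3
    noise_sd: float = 0.10
    gain_value: float = 0.6
    loss_value: float = -0.6
    hotspot_spec: list = field(default_factory=lambda: list(DEFAULT_HOTSPOTS))
    # methylation
    n_beta_probes: int = 300
    beta_noise_scale: float = 0.5
    beta_shared_scale: float = 1.5
    intensity_noise_sd: float = 0.15
    # expression
    n_expression_probes: int = 400
    expr_shared_scale: float = 0.7
    expr_noise_sd: float = 0.4
    # SNP genotyping
    lrr_noise_sd: float = 0.15
    # variants: somatic per tumour + residual population background
    n_variants: int = 30
    variant_share_rate_clonal: float = 0.7
    variant_pool_size: int = 5000
    # fusions
    n_fusions: int = 10
    fusion_share_count_clonal: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.clonal_fraction <= 1.0:
            raise ValueError("clonal_fraction must be in [0, 1]")
        for name in ("n_patients", "n_probes", "n_founder_events",
                     "n_drift_events", "n_variants", "n_fusions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for _, _, direction, freq in self.hotspot_spec:
            if direction not in ("gain", "loss"):
                raise ValueError(f"hotspot direction {direction!r}")
            if not 0.0 <= freq <= 1.0:
                raise ValueError("hotspot frequency must be in [0, 1]")


@dataclass
class PatientTruth:
    patient_id: str
    is_clonal: bool
    founder_blocks: list
    drift_blocks: tuple[list, list]
    shared_variants: set
    shared_fusions: set


@dataclass
class GroundTruth:
    """Per-patient generative record used to score recovered calls."""

    patients: dict[str, PatientTruth]

    def is_clonal(self, patient_id: str) -> bool:
        return self.patients[patient_id].is_clonal


class _Genome:
    """Probe grid partitioned into candidate segment blocks."""

    def __init__(self, n_probes: int, probes_per_block: int):
        per_chrom = np.full(22, n_probes // 22)
        per_chrom[: n_probes % 22] += 1
        self.probes: list[Probe] = []
        self.blocks: list[tuple[str, int, int]] = []  # chrom, probe lo, hi (excl)
        self.block_span: list[tuple[str, int, int]] = []  # chrom, start bp, end bp
        idx = 0
        for c, npc in zip(_AUTOSOMES, per_chrom):
            npc = int(npc)
            for j in range(npc):
                self.probes.append(Probe(f"p{c}_{j}", c, (j + 1) * 1_000_000))
            for lo in range(0, npc, probes_per_block):
                hi = min(lo + probes_per_block, npc)
                self.blocks.append((c, idx + lo, idx + hi))
                self.block_span.append(
                    (c, (lo + 1) * 1_000_000 - 500_000, hi * 1_000_000 + 499_999)
                )
            idx += npc
        self.n_probes = idx
        self.n_blocks = len(self.blocks)
        self.chrom_probe_count = {c: int(n) for c, n in zip(_AUTOSOMES, per_chrom)}

    def hotspot_block(self, chrom: str, arm: str) -> int:
        """Deterministic block index for a chromosome arm hotspot."""
        candidates = [i for i, (c, _, _) in enumerate(self.blocks) if c == chrom]
        if not candidates:
            raise ValueError(f"no blocks on chromosome {chrom}")
        half = len(candidates) // 2
        return candidates[0] if arm == "p" else candidates[min(half, len(candidates) - 1)]

    def block_probe_mask(self, block: int) -> slice:
        _, lo, hi = self.blocks[block]
        return slice(lo, hi)


def _draw_blocks(rng, available: list[int], k: int) -> list[int]:
    k = min(k, len(available))
    if k == 0:
        return []
    chosen = rng.choice(len(available), size=k, replace=False)
    return [available[i] for i in sorted(chosen)]


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SimulationConfig) -> CohortData:
    """Generate a full multi-platform cohort with ground-truth labels."""
    genome = _Genome(config.n_probes, config.probes_per_block)
    if config.n_founder_events + config.n_drift_events > genome.n_blocks:
        raise ValueError(
            f"founder + drift events ({config.n_founder_events} + "
            f"{config.n_drift_events}) exceed the {genome.n_blocks} "
            "available segment blocks"
        )
    ss = np.random.SeedSequence(config.seed)
    cohort_seed, *patient_seeds = ss.spawn(config.n_patients + 1)
    cohort_rng = np.random.default_rng(cohort_seed)

    hotspots = [
        (genome.hotspot_block(chrom, arm), 1 if direction == "gain" else -1, freq)
        for chrom, arm, direction, freq in config.hotspot_spec
    ]
    hotspot_blocks = {b for b, _, _ in hotspots}
    free_blocks = [b for b in range(genome.n_blocks) if b not in hotspot_blocks]

    # shared cohort-level landscapes
    pool_chrom = cohort_rng.choice(len(_AUTOSOMES), size=config.variant_pool_size)
    pool_pos = cohort_rng.integers(1, 200_000_000, size=config.variant_pool_size)
    pool_ref = cohort_rng.integers(0, 4, size=config.variant_pool_size)
    pool_alt = (pool_ref + cohort_rng.integers(1, 4, size=config.variant_pool_size)) % 4
    pool_freq = cohort_rng.beta(0.5, 2.5, size=config.variant_pool_size)
    pool_variants = [
        (_AUTOSOMES[c], int(p), str(_BASES[r]), str(_BASES[a]))
        for c, p, r, a in zip(pool_chrom, pool_pos, pool_ref, pool_alt)
    ]
    # methylation baseline: bimodal CpG landscape on the logit scale
    comp = cohort_rng.choice(3, size=config.n_beta_probes, p=[0.4, 0.4, 0.2])
    beta_baseline = np.where(
        comp == 0,
        cohort_rng.normal(-2.5, 0.5, config.n_beta_probes),
        np.where(
            comp == 1,
            cohort_rng.normal(2.5, 0.5, config.n_beta_probes),
            cohort_rng.normal(0.0, 0.7, config.n_beta_probes),
        ),
    )

    n_clonal = int(round(config.clonal_fraction * config.n_patients))
    clonal_flags = np.zeros(config.n_patients, dtype=bool)
    clonal_flags[:n_clonal] = True
    cohort_rng.shuffle(clonal_flags)

    data = CohortData(patient_samples={})
    for key in ("copy_number", "expression", "methylation_beta",
                "methylation_intensity", "snp_lrr"):
        data.profiles[key] = {}
    for key in ("copy_number", "methylation_intensity", "snp_lrr"):
        data.segments[key] = {}
    truth = {}

    beta_probes = [
        Probe(f"cg{j:06d}", _AUTOSOMES[j % 22], 10_000_000 + 1000 * j)
        for j in range(config.n_beta_probes)
    ]
    beta_probes.sort(key=lambda p: (int(p.chrom), p.pos))
    expr_probes = [
        Probe(f"g{j:05d}", _AUTOSOMES[j % 22], 5_000_000 + 2000 * j)
        for j in range(config.n_expression_probes)
    ]
    expr_probes.sort(key=lambda p: (int(p.chrom), p.pos))

    for pi in range(config.n_patients):
        pid = f"P{pi + 1:03d}"
        rng = np.random.default_rng(patient_seeds[pi])
        is_clonal = bool(clonal_flags[pi])
        sids = (f"{pid}_T1", f"{pid}_T2")
        data.patient_samples[pid] = sids

        # --- copy-number block states -----------------------------------
        founder: dict[int, int] = {}
        if is_clonal:
            for b in _draw_blocks(rng, free_blocks, config.n_founder_events):
                founder[b] = int(rng.choice([-1, 1]))
            for b, direction, freq in hotspots:
                if rng.random() < freq:
                    founder[b] = direction
        drift_record: list[list[int]] = []
        tumour_states = []
        for _t in range(2):
            states: dict[int, int] = dict(founder)
            if not is_clonal:
                for b in _draw_blocks(rng, free_blocks, config.n_founder_events):
                    states[b] = int(rng.choice([-1, 1]))
                for b, direction, freq in hotspots:
                    if rng.random() < freq:
                        states[b] = direction
            taken = set(states)
            avail = [b for b in range(genome.n_blocks) if b not in taken]
            drift = _draw_blocks(rng, avail, config.n_drift_events)
            for b in drift:
                states[b] = int(rng.choice([-1, 1]))
            drift_record.append(drift)
            tumour_states.append(states)

        for sid, states in zip(sids, tumour_states):
            signal = np.zeros(genome.n_probes)
            segs = []
            for b, s in sorted(states.items()):
                mean = config.gain_value if s > 0 else config.loss_value
                signal[genome.block_probe_mask(b)] = mean
                chrom, start, end = genome.block_span[b]
                segs.append(
                    Segment(chrom, start, end, mean, "gain" if s > 0 else "loss")
                )
            for platform, noise, key in (
                (Platform.COPY_NUMBER, config.noise_sd, "copy_number"),
                (Platform.METHYLATION_INTENSITY, config.intensity_noise_sd,
                 "methylation_intensity"),
                (Platform.SNP_LRR, config.lrr_noise_sd, "snp_lrr"),
            ):
                values = signal + rng.normal(0.0, noise, genome.n_probes) \
                    if noise > 0 else signal.copy()
                data.profiles[key][sid] = ProbeProfile(
                    sid, platform, list(genome.probes), values
                )
                data.segments[key][sid] = SegmentedProfile(sid, list(segs))

        # --- methylation beta values ------------------------------------
        shared_dev = rng.normal(0.0, config.beta_shared_scale, config.n_beta_probes)
        for t, sid in enumerate(sids):
            dev = shared_dev if is_clonal else rng.normal(
                0.0, config.beta_shared_scale, config.n_beta_probes
            )
            noise = rng.normal(0.0, config.beta_noise_scale, config.n_beta_probes) \
                if config.beta_noise_scale > 0 else 0.0
            betas = _logistic(beta_baseline + dev + noise)
            data.profiles["methylation_beta"][sid] = ProbeProfile(
                sid, Platform.METHYLATION_BETA, list(beta_probes), betas
            )

        # --- expression -------------------------------------------------
        shared_expr = rng.normal(0.0, config.expr_shared_scale,
                                 config.n_expression_probes)
        for t, sid in enumerate(sids):
            dev = shared_expr if is_clonal else rng.normal(
                0.0, config.expr_shared_scale, config.n_expression_probes
            )
            noise = rng.normal(0.0, config.expr_noise_sd,
                               config.n_expression_probes) \
                if config.expr_noise_sd > 0 else 0.0
            data.profiles["expression"][sid] = ProbeProfile(
                sid, Platform.EXPRESSION, expr_probes, dev + noise
            )

        # --- variants ---------------------------------------------------
        n_shared_somatic = (
            int(round(config.variant_share_rate_clonal * config.n_variants))
            if is_clonal else 0
        )
        founder_variants = {
            (_AUTOSOMES[int(c)], int(p), "A", "T")
            for c, p in zip(
                rng.integers(0, 22, n_shared_somatic),
                rng.integers(200_000_001, 240_000_000, n_shared_somatic),
            )
        }
        for sid in sids:
            carried = rng.random(config.variant_pool_size) < pool_freq
            background = {pool_variants[i] for i in np.flatnonzero(carried)}
            n_private = config.n_variants - n_shared_somatic
            private = {
                (_AUTOSOMES[int(c)], int(p), "C", "G")
                for c, p in zip(
                    rng.integers(0, 22, n_private),
                    rng.integers(240_000_001, 280_000_000, n_private),
                )
            }
            data.variants[sid] = VariantSet(
                sid, founder_variants | private | background
            )

        # --- fusions ----------------------------------------------------
        def _random_fusions(k, lo):
            return {
                (
                    _AUTOSOMES[int(c5)], int(p5), f"GENE{int(p5) % 10000}",
                    _AUTOSOMES[int(c3)], int(p3), f"GENE{int(p3) % 10000}",
                )
                for c5, p5, c3, p3 in zip(
                    rng.integers(0, 22, k), rng.integers(lo, lo + 40_000_000, k),
                    rng.integers(0, 22, k), rng.integers(lo, lo + 40_000_000, k),
                )
            }

        n_shared_fus = min(config.fusion_share_count_clonal, config.n_fusions) \
            if is_clonal else 0
        shared_fusions = _random_fusions(n_shared_fus, 300_000_000)
        for sid in sids:
            private = _random_fusions(config.n_fusions - n_shared_fus, 400_000_000)
            data.fusions[sid] = FusionSet(sid, shared_fusions | private)

        # --- clinical ---------------------------------------------------
        laterality = "bilateral" if rng.random() < 0.5 else "ipsilateral"
        interval = int(rng.integers(0, 31)) if rng.random() < 0.5 \
            else int(rng.integers(200, 2500))
        histologies = ["Invasive carcinoma NST", "Invasive lobular carcinoma",
                       "Invasive carcinoma NOS"]
        subtypes = ["Luminal A", "Luminal B", "Basal-like", "HER2/ER-"]

        def _feat(draw):
            v1 = draw()
            if is_clonal and rng.random() < 0.95:
                v2 = v1
            else:
                v2 = draw()
            return v1, v2

        def _maybe_nd(pair, p_nd=0.2):
            return tuple(v if rng.random() > p_nd else "ND" for v in pair)

        hist = _maybe_nd(_feat(lambda: histologies[
            int(rng.choice(3, p=[0.7, 0.2, 0.1]))]))
        er = _feat(lambda: "pos" if rng.random() < 0.7 else "neg")
        her2 = _feat(lambda: "pos" if rng.random() < 0.15 else "neg")
        subtype = _maybe_nd(_feat(lambda: subtypes[int(rng.integers(0, 4))]), 0.5)
        data.clinical.append(
            ClinicalRecord(pid, laterality, interval, hist, er, her2, subtype)
        )

        truth[pid] = PatientTruth(
            pid, is_clonal, sorted(founder), tuple(drift_record),
            set(founder_variants), {(f[0], f[1], f[3], f[4]) for f in shared_fusions},
        )

    data.ground_truth = GroundTruth(truth)
    return data


def recover_labels(data: CohortData, method: str, alpha: float = 0.05) -> dict:
    """Run one clonality test end-to-end and score it against the truth.

    ``method`` is one of ``si``, ``si_met``, ``distance``, ``clustering``,
    ``shared_segments``, ``shared_mutations``. Returns accuracy,
    sensitivity and specificity over evaluable true pairs, plus the raw
    per-patient calls.
    """
    from .model import ClonalityAnalysis

    method_map = {
        "si": "si:copy_number",
        "si_met": "si_met:methylation_beta",
        "distance": "distance:copy_number",
        "clustering": "clustering:copy_number",
        "shared_segments": "segments:copy_number",
        "shared_mutations": "mutations",
    }
    if method not in method_map:
        raise ValueError(f"unknown method {method!r}")
    if data.ground_truth is None:
        raise ValueError("dataset has no ground truth to score against")
    res = ClonalityAnalysis(data).fit(alpha=alpha, methods=[method_map[method]])
    calls = {
        r.pair.patient_id: r.call
        for r in res.results_by_method[method_map[method]]
    }
    tp = fp = tn = fn = 0
    for pid, call in calls.items():
        if call is CallLabel.NOT_EVALUABLE:
            continue
        clonal_truth = data.ground_truth.is_clonal(pid)
        clonal_call = call is CallLabel.CLONAL
        if clonal_truth and clonal_call:
            tp += 1
        elif clonal_truth:
            fn += 1
        elif clonal_call:
            fp += 1
        else:
            tn += 1
    n = tp + fp + tn + fn
    return {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "calls": calls,
        "n_evaluable": n,
    }
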