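"""Model/Results front end tying the clonality tests together.

`ClonalityAnalysis` is built from a :class:`~clonemate.datatypes.CohortData`
(or directly from input files / a simulation config); its :meth:`fit`
executes every applicable clonality test on every true tumour pair and
returns a :class:`ClonalityResults` holding the per-method statistics and
calls, the patients x methods call matrix, Cohen's kappa agreement between
methods, and per-patient consensus tallies.

Method names are ``test:platform`` (``si:copy_number``,
``distance:methylation_beta``, ...) plus the platform-free ``mutations``,
``mutations_panel`` and ``fusions``. The copy-number similarity index
(``si:copy_number``) is treated as the primary classification in the
summary, with every other method reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from . import pair_tests as pt
from . import similarity as sim
from .consensus import agreement_matrix, build_call_matrix, consensus_tally
from .datatypes import (
    CallLabel,
    CohortData,
    PairTestResult,
    Platform,
)

logger = logging.getLogger(__name__)

__all__ = ["ClonalityAnalysis", "ClonalityResults"]

PRIMARY_METHOD = "si:copy_number"

_PROBE_PLATFORMS = (
    "copy_number", "expression", "methylation_beta",
    "methylation_intensity", "snp_lrr",
)
_SIGNED_SI_PLATFORMS = ("copy_number", "methylation_intensity", "snp_lrr")


def _discretize_for(platform: str, profile, thresholds):
    if platform == "expression":
        return sim.discretize_expression(profile, thresholds.get("expr_thr", sim.EXPR_THR))
    if platform == "methylation_beta":
        return sim.discretize_methylation(
            profile, thresholds.get("beta_low", sim.BETA_LOW),
            thresholds.get("beta_high", sim.BETA_HIGH),
        )
    return sim.discretize_copy_number(
        profile, thresholds.get("loss_thr", sim.CN_LOSS_THR),
        thresholds.get("gain_thr", sim.CN_GAIN_THR),
    )


class ClonalityAnalysis:
    """Clonality testing for a cohort of paired tumours.

    Parameters
    ----------
    data
        The assembled cohort. Missing platforms are allowed; methods that
        need them are simply not offered.
    panel
        Optional :class:`~clonemate.pair_tests.PanelRegions` restricting a
        second shared-mutation test to a gene panel.
    thresholds
        Discretization overrides: loss_thr, gain_thr, expr_thr, beta_low,
        beta_high, segment_tolerance_bp.
    """

    def __init__(
        self,
        data: CohortData,
        panel: pt.PanelRegions | None = None,
        thresholds: dict | None = None,
    ):
        if not data.patient_samples:
            raise ValueError("cohort has no patients")
        self.data = data
        self.panel = panel
        self.thresholds = dict(thresholds or {})
        self.true_pairs, self.artificial_pairs = data.pairs()

    @classmethod
    def from_files(
        cls,
        manifest: str | Path,
        probe_matrices: dict[str, str | Path] | None = None,
        segments: dict[str, str | Path] | None = None,
        variants: str | Path | None = None,
        fusions: str | Path | None = None,
        clinical: str | Path | None = None,
        panel: str | Path | None = None,
        thresholds: dict | None = None,
    ) -> "ClonalityAnalysis":
        """Assemble an analysis from the plain-text input files.

        ``probe_matrices`` and ``segments`` map platform names to paths.
        """
        data = CohortData(patient_samples=cio.read_manifest(manifest))
        for platform, path in (probe_matrices or {}).items():
            profs = cio.read_probe_matrix(path, Platform(platform))
            data.profiles[platform] = {p.sample_id: p for p in profs}
        for platform, path in (segments or {}).items():
            segs = cio.read_segments(path)
            data.segments[platform] = {s.sample_id: s for s in segs}
        if variants:
            data.variants = {v.sample_id: v for v in cio.read_variants(variants)}
        if fusions:
            data.fusions = {f.sample_id: f for f in cio.read_fusions(fusions)}
        if clinical:
            data.clinical = cio.read_clinical(clinical)
        panel_obj = None
        if panel:
            df = pd.read_csv(panel, sep="\t")
            panel_obj = pt.PanelRegions(
                str(panel),
                list(zip(df["chrom"].astype(str), df["start"], df["end"])),
            )
        return cls(data, panel=panel_obj, thresholds=thresholds)

    @classmethod
    def from_simulation(cls, config=None, **kwargs) -> "ClonalityAnalysis":
        """Build from a synthetic cohort (see :mod:`clonemate.simulate`)."""
        from .simulate import SimulationConfig, simulate_cohort

        if config is None:
            config = SimulationConfig(**kwargs)
        return cls(simulate_cohort(config))

    # ------------------------------------------------------------------
    def available_methods(self) -> list[str]:
        methods = []
        for platform in _PROBE_PLATFORMS:
            if not self.data.profiles.get(platform):
                continue
            if platform in _SIGNED_SI_PLATFORMS or platform == "expression":
                methods.append(f"si:{platform}")
            if platform == "methylation_beta":
                methods.append(f"si_met:{platform}")
            methods.append(f"clustering:{platform}")
            methods.append(f"distance:{platform}")
        for platform, segs in self.data.segments.items():
            if segs:
                methods.append(f"segments:{platform}")
        if self.data.variants:
            methods.append("mutations")
            if self.panel is not None:
                methods.append("mutations_panel")
        if self.data.fusions:
            methods.append("fusions")
        return methods

    def fit(self, alpha: float = 0.05, methods: list[str] | None = None) -> "ClonalityResults":
        """Run every requested clonality test on every true pair."""
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        available = self.available_methods()
        if methods is None:
            methods = available
        else:
            missing = [m for m in methods if m not in available]
            if missing:
                raise ValueError(
                    f"methods {missing} not available for this cohort; "
                    f"have {available}"
                )
        if not methods:
            raise ValueError("no evaluable test for this cohort")
        results: dict[str, list[PairTestResult]] = {}
        for method in methods:
            test, _, platform = method.partition(":")
            runner = getattr(self, f"_run_{test}")
            results[method] = runner(platform, method, alpha)
            logger.info(
                "%s: %d true pairs scored (alpha=%g)", method,
                len(results[method]), alpha,
            )
        return ClonalityResults(self, results, alpha)

    # ---- individual test runners --------------------------------------
    def _profiles(self, platform: str) -> dict:
        return self.data.profiles[platform]

    def _run_si(self, platform: str, method: str, alpha: float):
        return self._run_si_family(platform, method, alpha, "si")

    def _run_si_met(self, platform: str, method: str, alpha: float):
        return self._run_si_family(platform, method, alpha, "si_met")

    def _run_si_family(self, platform, method, alpha, statistic):
        profs = self._profiles(platform)
        disc = {
            sid: _discretize_for(platform, p, self.thresholds)
            for sid, p in profs.items()
        }
        null = sim.si_null_distribution(
            disc, self.data.patient_samples, statistic
        )
        out = []
        for pair in self.true_pairs:
            if statistic == "si_met":
                obs = sim.similarity_index_met(
                    disc[pair.sample_a], disc[pair.sample_b]
                )
            else:
                obs = sim.pair_similarity(disc[pair.sample_a], disc[pair.sample_b])
            scored = sim.score_against_null(obs, null, alpha)
            out.append(
                PairTestResult(
                    pair, method,
                    scored.observed if np.isfinite(scored.observed) else None,
                    scored.call,
                    threshold=scored.mean_null,
                    p_like=None if np.isnan(scored.p_empirical) else scored.p_empirical,
                    null_values=null,
                    extra={"p_si": scored.p_si, "mean_null": scored.mean_null},
                )
            )
        return out

    def _run_distance(self, platform: str, method: str, alpha: float):
        profs = self._profiles(platform)
        ids = sorted(profs)
        index = {sid: i for i, sid in enumerate(ids)}
        dm = pt.distance_matrix([profs[s] for s in ids])
        null = np.array([
            dm[index[p.sample_a], index[p.sample_b]]
            for p in self.artificial_pairs
        ])
        out = []
        for pair in self.true_pairs:
            r = pt.distance_test(
                pair, dm[index[pair.sample_a], index[pair.sample_b]], null
            )
            r.method = method
            out.append(r)
        return out

    def _run_clustering(self, platform: str, method: str, alpha: float):
        profs = self._profiles(platform)
        results = pt.cluster_cherry_test(
            list(profs.values()), self.data.patient_samples
        )
        for r in results:
            r.method = method
        return results

    def _run_segments(self, platform: str, method: str, alpha: float):
        segs = self.data.segments[platform]
        tol = int(self.thresholds.get("segment_tolerance_bp", 0))
        counts = {
            pair: pt.shared_segments(segs[pair.sample_a], segs[pair.sample_b], tol)
            for pair in self.true_pairs + self.artificial_pairs
        }
        null = np.array([counts[p] for p in self.artificial_pairs], dtype=float)
        out = []
        for pair in self.true_pairs:
            r = pt.shared_segment_test(pair, counts[pair], null)
            r.method = method
            out.append(r)
        return out

    def _run_mutations(self, platform: str, method: str, alpha: float):
        panel = self.panel if method == "mutations_panel" else None
        vs = self.data.variants
        if panel is not None:
            vs = {sid: panel.restrict(v) for sid, v in vs.items()}
        counts = {
            pair: pt.shared_mutations(vs[pair.sample_a], vs[pair.sample_b])
            for pair in self.true_pairs + self.artificial_pairs
        }
        null = np.array([counts[p] for p in self.artificial_pairs], dtype=float)
        return [
            pt.shared_mutation_test(pair, counts[pair], null, method)
            for pair in self.true_pairs
        ]

    def _run_mutations_panel(self, platform: str, method: str, alpha: float):
        return self._run_mutations(platform, method, alpha)

    def _run_fusions(self, platform: str, method: str, alpha: float):
        fs = self.data.fusions
        counts = {
            pair: pt.fusion_overlap(fs[pair.sample_a], fs[pair.sample_b])[0]
            for pair in self.true_pairs + self.artificial_pairs
        }
        null = np.array([counts[p] for p in self.artificial_pairs], dtype=float)
        return [
            pt.shared_mutation_test(pair, counts[pair], null, "fusions")
            for pair in self.true_pairs
        ]


@dataclass
class ClonalityResults:
    """Fitted clonality calls, agreement and consensus for one cohort."""

    model: ClonalityAnalysis
    results_by_method: dict[str, list[PairTestResult]]
    alpha: float
    call_matrix: pd.DataFrame = field(init=False)
    kappa_table: pd.DataFrame | None = field(init=False, default=None)
    mean_kappa: pd.Series | None = field(init=False, default=None)
    consensus: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.call_matrix = build_call_matrix(self.results_by_method)
        # keep patients in manifest order
        order = [p for p in self.model.data.patient_samples if p in self.call_matrix.index]
        self.call_matrix = self.call_matrix.loc[order]
        if len(self.call_matrix.columns) >= 2:
            self.kappa_table, self.mean_kappa = agreement_matrix(self.call_matrix)
        self.consensus = consensus_tally(self.call_matrix)

    # ------------------------------------------------------------------
    @property
    def primary_calls(self) -> pd.Series | None:
        """Calls of the designated primary method (copy-number SI)."""
        if PRIMARY_METHOD in self.call_matrix.columns:
            return self.call_matrix[PRIMARY_METHOD]
        return None

    def n_clonal(self, method: str | None = None) -> int:
        col = method or (
            PRIMARY_METHOD if PRIMARY_METHOD in self.call_matrix.columns
            else self.call_matrix.columns[0]
        )
        return int((self.call_matrix[col] == CallLabel.CLONAL.value).sum())

    def method_table(self, method: str) -> pd.DataFrame:
        """Per-pair statistic, threshold, p and call for one method."""
        rows = []
        for r in self.results_by_method[method]:
            rows.append(
                {
                    "patient_id": r.pair.patient_id,
                    "sample_a": r.pair.sample_a,
                    "sample_b": r.pair.sample_b,
                    "method": r.method,
                    "statistic": r.statistic,
                    "threshold": r.threshold,
                    "p": r.p_like,
                    "p_si": r.extra.get("p_si"),
                    "call": r.call.value,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text report: calls per method, agreement, consensus."""
        lines = []
        n = len(self.call_matrix)
        lines.append("Clonality analysis summary")
        lines.append("=" * 60)
        lines.append(f"Patients (true pairs): {n}")
        lines.append(
            f"Artificial pairs in permutation null: {len(self.model.artificial_pairs)}"
        )
        lines.append(f"Alpha: {self.alpha}")
        lines.append("")
        lines.append("Clonal calls per method:")
        for method in self.call_matrix.columns:
            col = self.call_matrix[method]
            nc = int((col == CallLabel.CLONAL.value).sum())
            ne = int(col.isin(["clonal", "independent"]).sum())
            marker = "  [primary]" if method == PRIMARY_METHOD else ""
            lines.append(f"  {method:<32s} {nc}/{ne}{marker}")
        if self.mean_kappa is not None:
            lines.append("")
            lines.append("Mean Cohen's kappa vs other methods (best first):")
            for m, k in self.mean_kappa.items():
                lines.append(f"  {m:<32s} {k: .3f}")
        lines.append("")
        lines.append("Consensus (methods voting clonal / evaluable):")
        for pid, row in self.consensus.iterrows():
            lines.append(
                f"  {pid:<10s} {int(row.n_clonal)}/{int(row.n_evaluable)}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_files(self, outdir: str | Path) -> None:
        """Write call matrix, per-method tables, kappa, consensus, report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.call_matrix.to_csv(outdir / "call_matrix.tsv", sep="\t")
        (outdir / "results").mkdir(exist_ok=True)
        for method in self.results_by_method:
            safe = method.replace(":", "_")
            self.method_table(method).to_csv(
                outdir / "results" / f"{safe}.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
        if self.kappa_table is not None:
            self.kappa_table.to_csv(
                outdir / "kappa.tsv", sep="\t", float_format="%.6g"
            )
        self.consensus.to_csv(outdir / "consensus.tsv", sep="\t")
        (outdir / "report.md").write_text(self.summary() + "\n")

    def plot_call_matrix(self, ax=None):
        """Heatmap of the call matrix: red clonal, blue independent,
        grey not evaluable."""
        import matplotlib.pyplot as plt
        from matplotlib.colors import ListedColormap

        code = {"clonal": 2, "independent": 1, "not_evaluable": 0}
        coded = self.call_matrix.apply(lambda col: col.map(code)).astype(int)
        if ax is None:
            _, ax = plt.subplots(
                figsize=(0.6 * len(coded.columns) + 2, 0.3 * len(coded) + 1)
            )
        cmap = ListedColormap(["#cccccc", "#4878cf", "#d65f5f"])
        ax.imshow(coded.to_numpy(), cmap=cmap, vmin=0, vmax=2, aspect="auto")
        ax.set_xticks(range(len(coded.columns)))
        ax.set_xticklabels(coded.columns, rotation=90, fontsize=7)
        ax.set_yticks(range(len(coded)))
        ax.set_yticklabels(coded.index, fontsize=7)
        return ax
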