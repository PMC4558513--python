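"""Generative model of RT-MLPA measurements.

No patient data ship with the assay, so every pipeline stage is exercised
on synthetic cohorts that encode the biology the panel was designed
around: cluster I genes are induced by irradiation in wild-type samples
and blunted in TP53- or ATM-defective ones; clusters II+III are induced
and cluster IV repressed in TP53-defective relative to ATM-defective
samples, which in turn behave near-neutrally on those genes.

Noise is lognormal (normal on the log2 scale) for both biological and
technical variation, the standard model for amplification-based signals.
Default effect magnitudes are generator parameters chosen to give clear
but not trivial group separation; they are declared configuration, not
measured biology.

The module also provides technical-replicate simulation and clone-mixture
dilution series: mixing acts on raw probe signals (the in-silico analogue
of mixing RNA before the assay), after which the ordinary normalization
and fold-induction machinery applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .classifier import NestedClassifier
from .panel_model import (
    CallValue,
    Condition,
    GenotypeLabel,
    PanelDefinition,
    SampleMeasurement,
    SampleMetadata,
    default_panel,
)
from .probe_selection import ProbeSelectionResult, resolve_profile
from .quantification import compute_fi_table

#: Default mean log2 fold inductions per genotype and cluster. Cluster I
#: carries the irradiation response (strong in WT, residual in defective
#: samples); clusters II-IV carry the TP53-vs-ATM signature. TP53 defects
#: blunt the p53-target response slightly more than ATM defects, which
#: leave residual p53 activation through redundant kinases.
DEFAULT_MU_BY_CLUSTER: dict[GenotypeLabel, dict[str, float]] = {
    GenotypeLabel.WT: {"I": 1.5, "II": 0.0, "III": 0.0, "IV": 0.0},
    GenotypeLabel.TP53_BIALLELIC: {"I": 0.1, "II": 1.0, "III": 1.0, "IV": -1.0},
    GenotypeLabel.ATM_BIALLELIC: {"I": 0.3, "II": 0.0, "III": 0.0, "IV": 0.0},
}


def default_mu_log2fi(
    panel: PanelDefinition,
) -> dict[GenotypeLabel, dict[str, float]]:
    """Expand the per-cluster default means to per-gene means."""
    return {
        g: {
            gene.gene_id: by_cluster[gene.cluster]
            for gene in panel.classification_genes
        }
        for g, by_cluster in DEFAULT_MU_BY_CLUSTER.items()
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic measurement model.

    mu_log2fi: per genotype, per gene, the mean log2 fold induction.
    sigma_log2fi: biological SD of the log2 FI (between patients).
    sigma_baseline: biological SD of the log2 non-IR expression level.
    sigma_tech: technical SD (log2) added independently per probe and
        condition; this is the only noise in technical replicates.
    sibling_probe_attenuation: factor applied to the genotype effect on
        every probe of a gene after the first; 1.0 means all probes carry
        the full signal, 0.0 makes siblings pure noise (used to verify
        that probe selection finds the informative probe).
    """

    panel: PanelDefinition = field(default_factory=default_panel)
    mu_log2fi: Mapping[GenotypeLabel, Mapping[str, float]] | None = None
    sigma_log2fi: float = 0.4
    sigma_baseline: float = 0.3
    sigma_tech: float = 0.15
    baseline_expr: float = 1.0
    housekeeping_signal_mean: float = 500.0
    sigma_housekeeping: float = 0.1
    n_per_group: int = 30
    seed: int = 0
    sibling_probe_attenuation: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "sigma_log2fi",
            "sigma_baseline",
            "sigma_tech",
            "sigma_housekeeping",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_expr <= 0 or self.housekeeping_signal_mean <= 0:
            raise ValueError("expression means must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")

    def mu(self, genotype: GenotypeLabel, gene_id: str) -> float:
        table = self.mu_log2fi or default_mu_log2fi(self.panel)
        return table[genotype][gene_id]


# ---------------------------------------------------------------------------
# Core signal synthesis


def _normalized_expression(
    genotype: GenotypeLabel,
    config: GeneratorConfig,
    rng: np.random.Generator | None,
    biological: bool = True,
    technical: bool = True,
    sigma_tech: float | None = None,
) -> dict[str, tuple[float, float]]:
    """Per classification probe, the (non-IR, IR) normalized expression.

    ``rng=None`` (or both noise flags off) yields the genotype's exact
    prototype: FI = 2**mu on every full-signal probe.
    """
    if sigma_tech is None:
        sigma_tech = config.sigma_tech

    def draw(sigma: float) -> float:
        if rng is None or sigma == 0:
            return 0.0
        return float(rng.normal(0.0, sigma))

    out: dict[str, tuple[float, float]] = {}
    for gene in config.panel.classification_genes:
        b = draw(config.sigma_baseline) if biological else 0.0
        d = config.mu(genotype, gene.gene_id)
        if biological:
            d += draw(config.sigma_log2fi)
        for k, probe in enumerate(gene.probe_ids):
            atten = 1.0 if k == 0 else config.sibling_probe_attenuation
            t0 = draw(sigma_tech) if technical else 0.0
            t1 = draw(sigma_tech) if technical else 0.0
            e_nonir = config.baseline_expr * 2.0 ** (b + t0)
            e_ir = config.baseline_expr * 2.0 ** (b + atten * d + t1)
            out[probe] = (e_nonir, e_ir)
    return out


def _housekeeping_signals(
    config: GeneratorConfig,
    rng: np.random.Generator | None,
    technical: bool = True,
) -> dict[str, tuple[float, float]]:
    out: dict[str, tuple[float, float]] = {}
    for probe in config.panel.housekeeping_probes:
        def draw() -> float:
            if rng is None or not technical or config.sigma_housekeeping == 0:
                return 0.0
            return float(rng.normal(0.0, config.sigma_housekeeping))

        out[probe] = (
            config.housekeeping_signal_mean * 2.0 ** draw(),
            config.housekeeping_signal_mean * 2.0 ** draw(),
        )
    return out


def _geomean(values: Sequence[float]) -> float:
    return float(np.exp(np.mean(np.log(values))))


def _measurement_pair(
    sample_id: str,
    expr: Mapping[str, tuple[float, float]],
    hk: Mapping[str, tuple[float, float]],
) -> tuple[SampleMeasurement, SampleMeasurement]:
    """Reconstruct raw signals: target raw = normalized expression times
    the measurement's housekeeping geometric mean."""
    g_nonir = _geomean([v[0] for v in hk.values()])
    g_ir = _geomean([v[1] for v in hk.values()])
    sig_nonir = {p: v[0] for p, v in hk.items()}
    sig_ir = {p: v[1] for p, v in hk.items()}
    for probe, (e0, e1) in expr.items():
        sig_nonir[probe] = e0 * g_nonir
        sig_ir[probe] = e1 * g_ir
    return (
        SampleMeasurement(sample_id=sample_id, condition=Condition.NONIR, signals=sig_nonir),
        SampleMeasurement(sample_id=sample_id, condition=Condition.IR, signals=sig_ir),
    )


# ---------------------------------------------------------------------------
# Cohort, replicate and mixture simulation

_GROUP_TAG = {
    GenotypeLabel.WT: "WT",
    GenotypeLabel.TP53_BIALLELIC: "TP53",
    GenotypeLabel.ATM_BIALLELIC: "ATM",
}


def simulate_cohort(
    config: GeneratorConfig,
) -> tuple[list[SampleMeasurement], list[SampleMetadata]]:
    """Simulate n_per_group patients per training genotype.

    Fully reproducible from config.seed; returns the paired IR/non-IR raw
    measurements and matching metadata.
    """
    rng = np.random.default_rng(config.seed)
    measurements: list[SampleMeasurement] = []
    metadata: list[SampleMetadata] = []
    for genotype in (
        GenotypeLabel.WT,
        GenotypeLabel.TP53_BIALLELIC,
        GenotypeLabel.ATM_BIALLELIC,
    ):
        for i in range(config.n_per_group):
            sid = f"{_GROUP_TAG[genotype]}_{i + 1:03d}"
            expr = _normalized_expression(genotype, config, rng)
            hk = _housekeeping_signals(config, rng)
            measurements.extend(_measurement_pair(sid, expr, hk))
            metadata.append(
                SampleMetadata(
                    sample_id=sid,
                    genotype=genotype,
                    clone_fraction=0.0 if genotype is GenotypeLabel.WT else 1.0,
                    viability_fraction=0.9,
                    cohort="training",
                )
            )
    return measurements, metadata


def simulate_replicates(
    prototype: GenotypeLabel,
    n: int,
    sigma_tech: float,
    seed: int,
    config: GeneratorConfig | None = None,
) -> list[SampleMeasurement]:
    """n technical replicates of a genotype's mean profile.

    Only technical noise (sigma_tech, log2 units) is applied — the
    replicate series emulates one pooled RNA sample re-assayed repeatedly,
    so biological between-patient variation is absent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    out: list[SampleMeasurement] = []
    for i in range(n):
        sid = f"{_GROUP_TAG[prototype]}_rep_{i + 1:02d}"
        expr = _normalized_expression(
            prototype, config, rng, biological=False, technical=True,
            sigma_tech=sigma_tech,
        )
        hk = _housekeeping_signals(config, rng)
        out.extend(_measurement_pair(sid, expr, hk))
    return out


@dataclass(frozen=True)
class MixtureSpec:
    """A dilution series of a defective clone into wild-type background.

    Mixing acts on raw probe signals: mixed = f * defective + (1-f) * WT,
    the in-silico analogue of mixing RNA from two patients before the
    assay.
    """

    defective_component: GenotypeLabel
    grid: tuple[float, ...]
    replicates_per_point: int = 20

    def __post_init__(self) -> None:
        if any(not (0.0 <= f <= 1.0) for f in self.grid):
            raise ValueError("mixture fractions must lie in [0, 1]")
        if self.replicates_per_point < 1:
            raise ValueError("replicates_per_point must be >= 1")


def simulate_mixture(
    spec: MixtureSpec,
    config: GeneratorConfig | None = None,
    seed: int = 0,
) -> dict[float, list[SampleMeasurement]]:
    """Per grid fraction, replicate measurements of the signal-level
    convex combination of a defective and a WT prototype.

    Each replicate draws fresh technical noise for both components before
    mixing; biological prototypes are the genotype means.
    """
    if config is None:
        config = GeneratorConfig()
    rng = np.random.default_rng(seed)
    out: dict[float, list[SampleMeasurement]] = {}
    for f in spec.grid:
        measurements: list[SampleMeasurement] = []
        for r in range(spec.replicates_per_point):
            sid = f"mix_{_GROUP_TAG[spec.defective_component]}_f{f:.3f}_r{r + 1:02d}"
            expr_d = _normalized_expression(
                spec.defective_component, config, rng, biological=False
            )
            hk_d = _housekeeping_signals(config, rng)
            expr_w = _normalized_expression(
                GenotypeLabel.WT, config, rng, biological=False
            )
            hk_w = _housekeeping_signals(config, rng)
            nonir_d, ir_d = _measurement_pair(sid, expr_d, hk_d)
            nonir_w, ir_w = _measurement_pair(sid, expr_w, hk_w)
            mixed_nonir = {
                p: f * nonir_d.signals[p] + (1 - f) * nonir_w.signals[p]
                for p in nonir_d.signals
            }
            mixed_ir = {
                p: f * ir_d.signals[p] + (1 - f) * ir_w.signals[p]
                for p in ir_d.signals
            }
            measurements.append(
                SampleMeasurement(sample_id=sid, condition=Condition.NONIR, signals=mixed_nonir)
            )
            measurements.append(
                SampleMeasurement(sample_id=sid, condition=Condition.IR, signals=mixed_ir)
            )
        out[f] = measurements
    return out


@dataclass
class LodReport:
    """Detection curve of a dilution series and the derived limit of
    detection (smallest clone fraction whose detection proportion reaches
    the threshold)."""

    defective_component: GenotypeLabel
    grid: list[float]
    detection_proportion: list[float]
    lod: float | None
    threshold: float


def classify_measurements(
    measurements: Sequence[SampleMeasurement],
    model: NestedClassifier,
    selection: ProbeSelectionResult,
    panel: PanelDefinition,
):
    """Convenience: measurements -> FI table -> gene profiles -> calls."""
    fi = compute_fi_table(measurements, panel)
    profiles, not_evaluable = resolve_profile(fi, selection)
    if not_evaluable:
        raise ValueError(f"not evaluable: {not_evaluable}")
    return model.predict_many(profiles)


def limit_of_detection(
    model: NestedClassifier,
    selection: ProbeSelectionResult,
    spec: MixtureSpec,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> LodReport:
    """Scan the dilution grid and report, per clone fraction, the
    proportion of replicates called dysfunctional."""
    if config is None:
        config = GeneratorConfig()
    by_fraction = simulate_mixture(spec, config, seed)
    grid = sorted(by_fraction)
    proportions: list[float] = []
    for f in grid:
        calls = classify_measurements(
            by_fraction[f], model, selection, config.panel
        )
        dysf = sum(1 for c in calls if c.value is not CallValue.FUNCTIONAL)
        proportions.append(dysf / len(calls))
    lod = next(
        (f for f, p in zip(grid, proportions) if p >= threshold), None
    )
    return LodReport(
        defective_component=spec.defective_component,
        grid=list(grid),
        detection_proportion=proportions,
        lod=lod,
        threshold=threshold,
    )


def noiseless_lod(
    model: NestedClassifier,
    selection: ProbeSelectionResult,
    defective: GenotypeLabel,
    config: GeneratorConfig | None = None,
    tol: float = 1e-6,
) -> float | None:
    """Deterministic stage-1 boundary crossing along the zero-noise
    mixture path, located by bisection.

    Returns None if even the pure defective prototype is called
    functional.
    """
    if config is None:
        config = GeneratorConfig()
    quiet = replace(
        config,
        sigma_tech=0.0,
        sigma_housekeeping=0.0,
        sigma_baseline=0.0,
        sigma_log2fi=0.0,
    )

    def stage1_margin(f: float) -> float:
        spec = MixtureSpec(
            defective_component=defective, grid=(f,), replicates_per_point=1
        )
        calls = classify_measurements(
            simulate_mixture(spec, quiet, seed=0)[f],
            model,
            selection,
            quiet.panel,
        )
        return calls[0].stage1_margin

    lo, hi = 0.0, 1.0
    if stage1_margin(hi) <= 0:
        return None
    if stage1_margin(lo) > 0:
        return 0.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if stage1_margin(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
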