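"""Domain model for the ATM-p53 RT-MLPA functional assay.

The assay measures a fixed panel of probes: ten classification genes whose
fold induction after irradiation carries the diagnostic signal, organised in
four response clusters, plus four housekeeping genes used only for
within-sample normalization. This module holds the panel catalogue, the raw
measurement and metadata records, and readers/writers for the plain-text
table formats the pipeline consumes.

Signal tables are delimiter-separated text with one row per
(sample_id, condition) and one column per probe. Metadata tables carry
sample_id, genotype, clone_fraction, viability_fraction, cohort. Panel
configuration is a YAML document (see ``data/panel_default.yaml``).
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger("mlpa_ddr")

#: Strict viability cut-off: samples below this fraction of viable cells are
#: excluded because low-viability material yields spuriously dysfunctional
#: profiles.
DEFAULT_VIABILITY_THRESHOLD = 0.5

CLUSTERS = ("I", "II", "III", "IV")


class Condition(str, enum.Enum):
    """Treatment arm of one measurement: irradiated or untreated."""

    IR = "IR"
    NONIR = "NONIR"


class GenotypeLabel(str, enum.Enum):
    """Molecular TP53/ATM status of a sample.

    Biallelic means deletion plus mutation; only WT and the two biallelic
    labels map to training classes. Monoallelic labels are prediction-only.
    """

    WT = "WT"
    TP53_BIALLELIC = "TP53_BIALLELIC"
    ATM_BIALLELIC = "ATM_BIALLELIC"
    TP53_MUT_ONLY = "TP53_MUT_ONLY"
    DEL17P_ONLY = "DEL17P_ONLY"
    ATM_MUT_ONLY = "ATM_MUT_ONLY"
    DEL11Q_ONLY = "DEL11Q_ONLY"


#: Genotypes usable for classifier fitting and probe-selection contrasts.
TRAINING_GENOTYPES = frozenset(
    {GenotypeLabel.WT, GenotypeLabel.TP53_BIALLELIC, GenotypeLabel.ATM_BIALLELIC}
)

MONOALLELIC_GENOTYPES = frozenset(
    {
        GenotypeLabel.TP53_MUT_ONLY,
        GenotypeLabel.DEL17P_ONLY,
        GenotypeLabel.ATM_MUT_ONLY,
        GenotypeLabel.DEL11Q_ONLY,
    }
)


class CallValue(str, enum.Enum):
    """Three-way functional verdict of the nested classifier."""

    FUNCTIONAL = "FUNCTIONAL"
    P53_DYSFUNCTIONAL = "P53_DYSFUNCTIONAL"
    ATM_DYSFUNCTIONAL = "ATM_DYSFUNCTIONAL"


class PanelError(ValueError):
    """Panel configuration violates an invariant."""


class MeasurementError(ValueError):
    """A measurement record violates an invariant."""


@dataclass(frozen=True)
class GeneEntry:
    gene_id: str
    cluster: str | None  # None for housekeeping genes
    probe_ids: tuple[str, ...]
    is_housekeeping: bool = False

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise PanelError(f"gene {self.gene_id}: empty probe list")
        if self.is_housekeeping and self.cluster is not None:
            raise PanelError(
                f"housekeeping gene {self.gene_id} must not carry a cluster"
            )
        if not self.is_housekeeping:
            if self.cluster not in CLUSTERS:
                raise PanelError(
                    f"gene {self.gene_id}: cluster must be one of {CLUSTERS}, "
                    f"got {self.cluster!r}"
                )


@dataclass(frozen=True)
class PanelDefinition:
    """The gene/probe/cluster catalogue of one assay version."""

    genes: tuple[GeneEntry, ...]
    panel_version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g in self.genes:
            for p in g.probe_ids:
                if p in seen:
                    raise PanelError(
                        f"probe {p} listed under both {seen[p]} and {g.gene_id}"
                    )
                seen[p] = g.gene_id

    # -- convenience views -------------------------------------------------

    @property
    def classification_genes(self) -> tuple[GeneEntry, ...]:
        return tuple(g for g in self.genes if not g.is_housekeeping)

    @property
    def housekeeping_genes(self) -> tuple[GeneEntry, ...]:
        return tuple(g for g in self.genes if g.is_housekeeping)

    @property
    def housekeeping_probes(self) -> tuple[str, ...]:
        return tuple(p for g in self.housekeeping_genes for p in g.probe_ids)

    @property
    def classification_probes(self) -> tuple[str, ...]:
        return tuple(p for g in self.classification_genes for p in g.probe_ids)

    @property
    def all_probes(self) -> tuple[str, ...]:
        return tuple(p for g in self.genes for p in g.probe_ids)

    def genes_in_cluster(self, cluster: str) -> tuple[str, ...]:
        return tuple(
            g.gene_id for g in self.classification_genes if g.cluster == cluster
        )

    def gene_of_probe(self, probe_id: str) -> str:
        for g in self.genes:
            if probe_id in g.probe_ids:
                return g.gene_id
        raise KeyError(probe_id)

    def gene(self, gene_id: str) -> GeneEntry:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class SampleMeasurement:
    """Raw probe signals for one sample under one condition.

    Signals are arbitrary fluorescence units, nonnegative. All housekeeping
    probes must be present with strictly positive signal, otherwise the
    sample cannot be normalized.
    """

    sample_id: str
    condition: Condition
    signals: Mapping[str, float]

    def validate(self, panel: PanelDefinition) -> None:
        for probe, value in self.signals.items():
            if value < 0:
                raise MeasurementError(
                    f"sample {self.sample_id} ({self.condition.value}): "
                    f"negative signal {value} for probe {probe}"
                )
        for probe in panel.housekeeping_probes:
            if probe not in self.signals or self.signals[probe] <= 0:
                raise MeasurementError(
                    f"sample {self.sample_id} ({self.condition.value}): "
                    f"housekeeping probe {probe} missing or nonpositive"
                )


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    genotype: GenotypeLabel
    clone_fraction: float | None = None
    viability_fraction: float | None = None
    cohort: str = "other"

    def __post_init__(self) -> None:
        for name in ("clone_fraction", "viability_fraction"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"sample {self.sample_id}: {name}={v} outside [0, 1]"
                )


@dataclass(frozen=True)
class FunctionalCall:
    """One classifier verdict with its decision-function margins.

    ``stage2_margin`` is present iff the first stage called the sample
    dysfunctional (only then is the subtype machine consulted).
    """

    sample_id: str
    value: CallValue
    stage1_margin: float
    stage2_margin: float | None = None

    def __post_init__(self) -> None:
        dysf = self.value is not CallValue.FUNCTIONAL
        if dysf != (self.stage2_margin is not None):
            raise ValueError(
                "stage2_margin must be present exactly for dysfunctional calls"
            )


@dataclass(frozen=True)
class FoldInductionProfile:
    """Gene-keyed fold-induction feature vector for one patient."""

    sample_id: str
    fi: Mapping[str, float]

    def __post_init__(self) -> None:
        for gene, value in self.fi.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(
                    f"sample {self.sample_id}: FI for {gene} must be finite "
                    f"and positive, got {value}"
                )


@dataclass
class MeasurementLoadReport:
    """Bookkeeping for load_measurements: nothing is dropped silently."""

    measurements: list[SampleMeasurement] = field(default_factory=list)
    unpaired_samples: list[str] = field(default_factory=list)
    unknown_probes: list[str] = field(default_factory=list)
    n_rows_in: int = 0


# ---------------------------------------------------------------------------
# Panel configuration I/O


def _panel_from_dict(doc: dict) -> PanelDefinition:
    genes: list[GeneEntry] = []
    for entry in doc.get("genes", []):
        genes.append(
            GeneEntry(
                gene_id=str(entry["gene_id"]),
                cluster=str(entry["cluster"]),
                probe_ids=tuple(str(p) for p in entry["probes"]),
                is_housekeeping=False,
            )
        )
    for entry in doc.get("housekeeping", []):
        if "cluster" in entry:
            raise PanelError(
                f"housekeeping gene {entry.get('gene_id')} carries a cluster "
                "assignment"
            )
        genes.append(
            GeneEntry(
                gene_id=str(entry["gene_id"]),
                cluster=None,
                probe_ids=tuple(str(p) for p in entry["probes"]),
                is_housekeeping=True,
            )
        )
    return PanelDefinition(
        genes=tuple(genes), panel_version=str(doc.get("panel_version", "unversioned"))
    )


def load_panel(path: str | Path) -> PanelDefinition:
    """Read a panel configuration file (YAML) into a PanelDefinition.

    Raises PanelError on duplicate probes, housekeeping genes with cluster
    assignments, or malformed documents.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise PanelError(f"cannot parse panel config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise PanelError(f"panel config {path} is not a mapping")
    return _panel_from_dict(doc)


def write_panel(panel: PanelDefinition, path: str | Path) -> None:
    doc = {
        "panel_version": panel.panel_version,
        "genes": [
            {"gene_id": g.gene_id, "cluster": g.cluster, "probes": list(g.probe_ids)}
            for g in panel.classification_genes
        ],
        "housekeeping": [
            {"gene_id": g.gene_id, "probes": list(g.probe_ids)}
            for g in panel.housekeeping_genes
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_panel() -> PanelDefinition:
    """The shipped 10-gene + 4-housekeeping panel."""
    ref = resources.files("mlpa_ddr").joinpath("data/panel_default.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _panel_from_dict(doc)


def default_panel_path() -> Path:
    return Path(str(resources.files("mlpa_ddr").joinpath("data/panel_default.yaml")))


# ---------------------------------------------------------------------------
# Signal-table I/O


def load_measurements(
    path: str | Path, panel: PanelDefinition, sep: str = "\t"
) -> MeasurementLoadReport:
    """Read a signal table: one row per (sample_id, condition), one column
    per probe_id.

    Unknown probe columns are reported as warnings, never errors. Samples
    lacking either the IR or the NONIR row are flagged unpaired (they remain
    in the result; pairing is enforced when fold inductions are computed).
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise MeasurementError(f"signal table missing required column {col!r}")

    probe_cols = [c for c in df.columns if c not in ("sample_id", "condition")]
    known = set(panel.all_probes)
    unknown = [c for c in probe_cols if c not in known]
    if unknown:
        warnings.warn(
            f"signal table contains probes not in the panel: {unknown}",
            stacklevel=2,
        )

    report = MeasurementLoadReport(unknown_probes=unknown, n_rows_in=len(df))
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["sample_id"], row["condition"])
        if key in seen:
            raise MeasurementError(
                f"duplicate (sample_id, condition) = {key} in signal table"
            )
        seen.add(key)
        m = SampleMeasurement(
            sample_id=row["sample_id"],
            condition=Condition(row["condition"]),
            signals={p: float(row[p]) for p in probe_cols if p in known},
        )
        m.validate(panel)
        report.measurements.append(m)

    by_sample: dict[str, set[Condition]] = {}
    for m in report.measurements:
        by_sample.setdefault(m.sample_id, set()).add(m.condition)
    report.unpaired_samples = sorted(
        s for s, conds in by_sample.items() if len(conds) != 2
    )
    for s in report.unpaired_samples:
        logger.warning("sample %s is unpaired (only one condition present)", s)
    return report


def write_measurements(
    measurements: Iterable[SampleMeasurement], path: str | Path, sep: str = "\t"
) -> None:
    rows = []
    for m in measurements:
        row = {"sample_id": m.sample_id, "condition": m.condition.value}
        row.update(m.signals)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Metadata I/O and filters


def load_metadata(path: str | Path, sep: str = "\t") -> list[SampleMetadata]:
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = {"sample_id", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        def _frac(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        out.append(
            SampleMetadata(
                sample_id=row["sample_id"],
                genotype=GenotypeLabel(row["genotype"]),
                clone_fraction=_frac("clone_fraction"),
                viability_fraction=_frac("viability_fraction"),
                cohort=str(row["cohort"]) if "cohort" in df.columns and not pd.isna(row["cohort"]) else "other",
            )
        )
    return out


def write_metadata(
    metadata: Iterable[SampleMetadata], path: str | Path, sep: str = "\t"
) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "genotype": m.genotype.value,
                "clone_fraction": m.clone_fraction,
                "viability_fraction": m.viability_fraction,
                "cohort": m.cohort,
            }
            for m in metadata
        ]
    ).to_csv(path, sep=sep, index=False)


def filter_by_viability(
    samples: Iterable[SampleMetadata],
    threshold: float = DEFAULT_VIABILITY_THRESHOLD,
) -> tuple[list[SampleMetadata], list[SampleMetadata]]:
    """Exclude samples with viability strictly below ``threshold``.

    Unknown viability is kept with a warning: the assay is unreliable below
    50% viable cells, but absence of the measurement is not evidence of
    failure.
    """
    kept: list[SampleMetadata] = []
    excluded: list[SampleMetadata] = []
    for s in samples:
        if s.viability_fraction is None:
            warnings.warn(
                f"sample {s.sample_id}: viability unknown, keeping",
                stacklevel=2,
            )
            kept.append(s)
        elif s.viability_fraction < threshold:
            excluded.append(s)
        else:
            kept.append(s)
    return kept, excluded
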