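"""Housekeeping normalization and fold-induction computation.

Every signal is first normalized within its own sample to the geometric
mean of the housekeeping probe signals, which removes sample-level gain
(input amount, amplification efficiency). Fold induction (FI) is then the
ratio of normalized expression in the irradiated aliquot to that in the
paired non-irradiated aliquot of the same patient. FI stays probe-keyed
here; collapsing to one probe per gene happens after probe selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_model import (
    Condition,
    MeasurementError,
    PanelDefinition,
    SampleMeasurement,
    logger,
)


def geometric_mean(xs: Sequence[float]) -> float:
    """Geometric mean of strictly positive values, computed in log space."""
    if len(xs) == 0:
        raise ValueError("geometric_mean of empty sequence")
    arr = np.asarray(xs, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("geometric_mean requires finite, strictly positive values")
    return float(np.exp(np.mean(np.log(arr))))


@dataclass(frozen=True)
class NormalizedExpression:
    """Probe signals of one measurement divided by the housekeeping
    geometric mean of the same measurement (dimensionless)."""

    sample_id: str
    condition: Condition
    values: Mapping[str, float]


def normalize_sample(
    m: SampleMeasurement, panel: PanelDefinition
) -> NormalizedExpression:
    """Divide every probe signal by the geometric mean of the sample's
    housekeeping signals.

    A zero signal on a non-housekeeping probe normalizes to zero with a
    warning (probe dropout is not a sample-level failure); a nonpositive or
    missing housekeeping signal is an error because the normalizer itself
    is undefined.
    """
    m.validate(panel)
    hk = [m.signals[p] for p in panel.housekeeping_probes]
    gm = geometric_mean(hk)
    values: dict[str, float] = {}
    for probe, signal in m.signals.items():
        if signal == 0:
            warnings.warn(
                f"sample {m.sample_id} ({m.condition.value}): zero signal for "
                f"probe {probe}",
                stacklevel=2,
            )
        values[probe] = signal / gm
    return NormalizedExpression(
        sample_id=m.sample_id, condition=m.condition, values=values
    )


@dataclass
class ProbeFoldInduction:
    """Probe-keyed fold inductions for one patient.

    ``fi`` holds FI = IR / NONIR per probe; probes whose non-irradiated
    normalized value was zero are listed in ``missing_probes`` instead.
    """

    sample_id: str
    fi: dict[str, float] = field(default_factory=dict)
    missing_probes: list[str] = field(default_factory=list)


def fold_induction(
    ir: NormalizedExpression,
    nonir: NormalizedExpression,
    panel: PanelDefinition,
) -> ProbeFoldInduction:
    """FI per classification probe: irradiated over non-irradiated
    normalized expression of the same patient."""
    if ir.sample_id != nonir.sample_id:
        raise MeasurementError(
            f"fold_induction on mismatched samples {ir.sample_id!r} vs "
            f"{nonir.sample_id!r}"
        )
    if ir.condition is not Condition.IR or nonir.condition is not Condition.NONIR:
        raise MeasurementError("fold_induction expects an (IR, NONIR) pair")

    out = ProbeFoldInduction(sample_id=ir.sample_id)
    for probe in panel.classification_probes:
        if probe not in ir.values or probe not in nonir.values:
            out.missing_probes.append(probe)
            continue
        denom = nonir.values[probe]
        if denom == 0:
            logger.warning(
                "sample %s: non-IR value 0 for probe %s, FI marked missing",
                ir.sample_id,
                probe,
            )
            out.missing_probes.append(probe)
            continue
        out.fi[probe] = ir.values[probe] / denom
    return out


def compute_fi_table(
    measurements: Iterable[SampleMeasurement], panel: PanelDefinition
) -> pd.DataFrame:
    """Run normalization + fold induction over a cohort.

    Returns a probe x sample DataFrame of FIs (rows ordered as in the
    panel); probes with a missing FI hold NaN. Unpaired samples are skipped
    with a warning.
    """
    by_sample: dict[str, dict[Condition, SampleMeasurement]] = {}
    for m in measurements:
        by_sample.setdefault(m.sample_id, {})[m.condition] = m

    columns: dict[str, dict[str, float]] = {}
    for sample_id, conds in by_sample.items():
        if Condition.IR not in conds or Condition.NONIR not in conds:
            logger.warning("sample %s unpaired, skipping FI computation", sample_id)
            continue
        ir = normalize_sample(conds[Condition.IR], panel)
        nonir = normalize_sample(conds[Condition.NONIR], panel)
        pfi = fold_induction(ir, nonir, panel)
        col = {p: math.nan for p in panel.classification_probes}
        col.update(pfi.fi)
        columns[sample_id] = col

    table = pd.DataFrame(columns)
    return table.reindex(list(panel.classification_probes))


def write_fi_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    table.to_csv(path, sep=sep, index_label="probe_id")


def read_fi_table(path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col="probe_id")
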