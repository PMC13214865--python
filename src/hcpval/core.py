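"""Shared domain types for total-error validation of untargeted HCP quantification.

The unit of every validation statistic is the *replicate block*: one independent
sample preparation's reportable total-HCP result (ng), defined as the arithmetic
mean of its technical injections.  A validation design specifies the spike
levels (nominal ng of HCP standard per injection), which assays include which
levels, how many preparations and injections each assay runs, and the
predefined acceptance limits for the tolerance-interval decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "SpikeLevel",
    "AssayPlan",
    "ValidationDesign",
    "PeptideObservation",
    "ReplicateBlock",
    "ProteinGroup",
    "ResponseFactor",
    "default_design",
    "reportable_from_injections",
    "relative_error",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class SpikeLevel:
    """One nominal spike level: a label (e.g. ``"L1"``) and its amount in ng."""

    label: str
    nominal_ng: float

    def __post_init__(self) -> None:
        if self.nominal_ng <= 0:
            raise ValueError(f"nominal spike must be > 0, got {self.nominal_ng}")


@dataclass(frozen=True)
class AssayPlan:
    """Levels included in one assay and its replication structure."""

    levels: tuple[str, ...]
    n_preparations: int = 3
    n_injections: int = 3

    def __post_init__(self) -> None:
        if self.n_preparations < 1:
            raise ValueError("n_preparations must be >= 1")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")


@dataclass(frozen=True)
class ValidationDesign:
    """Hierarchical spike-recovery design and predefined acceptance limits.

    Parameters
    ----------
    levels
        Spike levels in strictly increasing nominal amount.
    assay_layout
        Mapping assay id -> :class:`AssayPlan`.  Levels absent from an assay
        simply contribute no replicate blocks there.
    beta
        Coverage probability of the beta-expectation tolerance interval.
    acceptance_limit_aggregate
        Symmetric acceptance limit (percent) for the aggregate total-HCP
        accuracy profile.
    acceptance_limit_stratified
        Wider symmetric limit (percent) for abundance-stratified profiles.
    mab_mass_per_injection_mg
        Product (mAb) mass loaded per injection, used for the ng -> ppm
        conversion (ppm = ng HCP per mg product).
    """

    levels: tuple[SpikeLevel, ...]
    assay_layout: Mapping[str, AssayPlan]
    beta: float = 0.95
    acceptance_limit_aggregate: float = 30.0
    acceptance_limit_stratified: float = 35.0
    mab_mass_per_injection_mg: float = 0.5

    def __post_init__(self) -> None:
        amounts = [lv.nominal_ng for lv in self.levels]
        if any(b <= a for a, b in zip(amounts, amounts[1:])):
            raise ValueError("spike levels must be strictly increasing")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.acceptance_limit_aggregate <= 0 or self.acceptance_limit_stratified <= 0:
            raise ValueError("acceptance limits must be > 0")
        if self.mab_mass_per_injection_mg <= 0:
            raise ValueError("mab_mass_per_injection_mg must be > 0")
        known = {lv.label for lv in self.levels}
        for assay, plan in self.assay_layout.items():
            unknown = set(plan.levels) - known
            if unknown:
                raise ValueError(f"assay {assay!r} references unknown levels {sorted(unknown)}")

    def nominal(self, label: str) -> float:
        for lv in self.levels:
            if lv.label == label:
                return lv.nominal_ng
        raise KeyError(label)

    @property
    def level_labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    def assays_with_level(self, label: str) -> list[str]:
        return [a for a, plan in self.assay_layout.items() if label in plan.levels]


def default_design(**overrides) -> ValidationDesign:
    """The reference hierarchical design: seven levels, 20-80 ng, four assays.

    Assay 1 carries the complete seven-level series; assays 2-4 carry five
    levels (L1, L2, L4, L6, L7), concentrating between-assay degrees of
    freedom where they matter.  Each included level is run as three
    independent preparations in technical triplicate.
    """
    levels = tuple(
        SpikeLevel(f"L{i + 1}", ng) for i, ng in enumerate((20, 30, 40, 50, 60, 70, 80))
    )
    full = tuple(lv.label for lv in levels)
    partial = ("L1", "L2", "L4", "L6", "L7")
    layout = {
        "A1": AssayPlan(full),
        "A2": AssayPlan(partial),
        "A3": AssayPlan(partial),
        "A4": AssayPlan(partial),
    }
    return ValidationDesign(levels=levels, assay_layout=layout, **overrides)


@dataclass(frozen=True)
class PeptideObservation:
    """One peptide-level identification/quantification row.

    ``accessions`` lists every protein the (stripped) sequence maps to;
    design coordinates (assay/level/preparation/injection) are resolved from
    a run-annotation map, not from the raw export.  ``is_heavy`` marks the
    stable-isotope-labeled channel; it is an input contract, never inferred.
    """

    sequence: str
    accessions: tuple[str, ...]
    run_id: str
    assay: str = ""
    level: str = ""
    preparation: int = 0
    injection: int = 0
    intensity: float = 0.0
    q_value: float = 0.0
    is_heavy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if not set(self.sequence) <= _AA_ALPHABET:
            bad = sorted(set(self.sequence) - _AA_ALPHABET)
            raise ValueError(f"non-amino-acid characters in sequence: {bad}")
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if not 0 <= self.q_value <= 1:
            raise ValueError("q_value must be in [0, 1]")


@dataclass(frozen=True)
class ReplicateBlock:
    """One reportable result: assay a, level j, block k, total HCP in ng."""

    assay: str
    level: str
    block: int
    reportable_ng: float
    nominal_ng: float

    def __post_init__(self) -> None:
        if self.reportable_ng < 0:
            raise ValueError("reportable must be >= 0")
        if self.nominal_ng <= 0:
            raise ValueError("nominal spike must be > 0")

    @property
    def relative_error(self) -> float:
        """Relative error in percent: 100 * (Y - mu) / mu."""
        return relative_error(self.reportable_ng, self.nominal_ng)


@dataclass
class ProteinGroup:
    """Parsimony-derived protein equivalence class with its Hi3 quantities."""

    lead_accession: str
    member_accessions: tuple[str, ...]
    peptides: tuple[str, ...] = ()
    unique_peptide_count: int = 0
    hi3_peptides: tuple[str, ...] = ()
    i_hcp: float = 0.0
    mw_da: float = 0.0
    mass_ng: float = 0.0
    abundance_ppm: float = 0.0

    def __post_init__(self) -> None:
        if self.lead_accession not in self.member_accessions:
            raise ValueError("lead accession must be a member of the group")
        if self.mass_ng < 0:
            raise ValueError("mass must be >= 0")


@dataclass(frozen=True)
class ResponseFactor:
    """Median intensity-per-fmol of the spiked digest standards."""

    standards: tuple[tuple[float, float], ...]  # (intensity, fmol)
    rf: float

    def __post_init__(self) -> None:
        if self.rf <= 0:
            raise ValueError("response factor must be > 0")


def reportable_from_injections(values: Sequence[float]) -> float:
    """Arithmetic mean of a block's technical injections (the reportable)."""
    if len(values) == 0:
        raise ValueError("at least one injection value is required")
    if any(v < 0 for v in values):
        raise ValueError("injection values must be >= 0")
    return float(sum(values)) / len(values)


def relative_error(reportable_ng: float, nominal_ng: float) -> float:
    """Percent relative error 100 * (Y - mu) / mu of one replicate block."""
    if nominal_ng <= 0:
        raise ValueError("nominal spike must be > 0")
    return 100.0 * (reportable_ng - nominal_ng) / nominal_ng
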