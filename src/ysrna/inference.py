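"""Terminal-modification calls from differential treatment libraries.

The logic mirrors how chemists read a periodate-oxidation / PNK / RppH
library panel:

* 3' terminus — if a fragment class keeps (most of) its RPM after periodate
  oxidation with beta-elimination, its 3' end must lack the reactive
  2',3'-diol, i.e. it is 2'-O-methylated (piRNA-like protection).  A class
  that collapses after oxidation has an unprotected 3'-OH.
* 5' terminus — a class that only becomes visible (or strongly gains) after
  RppH carried a 5' triphosphate, because RppH trims 5'-PPP to the ligatable
  5'-P.  A class that is abundant untreated but markedly reduced by PNK
  carried a canonical 5' monophosphate, which PNK's phosphatase/exchange
  activity removes.

Calls are categorical and purely ratio-based; no significance testing is
attached.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .reference import Side
from .simulate import Treatment

__all__ = [
    "INSUFFICIENT_DATA",
    "ThreePrimeCall",
    "FivePrimeCall",
    "CallThresholds",
    "TreatmentPanel",
    "ModificationCall",
    "protection_ratio",
    "gain_ratio",
    "call_three_prime",
    "call_five_prime",
    "run_inference",
    "panels_from_tables",
    "write_calls",
]


class _InsufficientData:
    """Sentinel for ratios/calls that cannot be computed from the data."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "INSUFFICIENT_DATA"


INSUFFICIENT_DATA = _InsufficientData()


class ThreePrimeCall(str, Enum):
    PROTECTED_2OME = "PROTECTED_2OME"
    UNPROTECTED = "UNPROTECTED"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


class FivePrimeCall(str, Enum):
    MONO_P = "MONO_P"
    TRI_P = "TRI_P"
    INSUFFICIENT_DATA = "INSUFFICIENT_DATA"


@dataclass(frozen=True)
class CallThresholds:
    """Decision thresholds for the categorical calls.

    ``floor`` (RPM) guards every ratio against near-empty classes;
    ``protected_threshold`` splits post-oxidation retention into
    protected/unprotected; ``gain_threshold`` is the minimum RppH fold-gain
    read as 5'-PPP; ``loss_threshold`` the maximum PNK retention read as a
    canonical 5'-P being stripped.
    """

    floor: float = 1.0
    protected_threshold: float = 0.5
    gain_threshold: float = 2.0
    loss_threshold: float = 0.5

    def validate(self) -> None:
        if min(self.floor, self.protected_threshold, self.gain_threshold,
               self.loss_threshold) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class TreatmentPanel:
    """Aggregate RPM of one fragment class across the treatment arms of one
    experiment.  The untreated (NONE) arm is mandatory."""

    parent_id: str
    side: Side
    rpm: Mapping[Treatment, float]

    def validate(self) -> None:
        if Treatment.NONE not in self.rpm:
            raise ValueError(
                f"panel {self.parent_id}/{self.side}: untreated (NONE) arm missing"
            )
        if any(v < 0 for v in self.rpm.values()):
            raise ValueError(f"panel {self.parent_id}/{self.side}: negative RPM")


@dataclass
class ModificationCall:
    parent_id: str
    side: Side
    three_prime_call: ThreePrimeCall
    five_prime_call: FivePrimeCall
    ox_ratio: float | _InsufficientData
    pnk_ratio: float | _InsufficientData
    rpph_ratio: float | _InsufficientData
    thresholds: CallThresholds = field(default_factory=CallThresholds)


def protection_ratio(
    rpm_treated: float, rpm_untreated: float, floor: float = 1.0
) -> float | _InsufficientData:
    """treated/untreated RPM ratio, or INSUFFICIENT_DATA when the untreated
    class is below ``floor`` RPM (a ratio over a near-empty class is noise)."""
    if rpm_treated < 0 or rpm_untreated < 0:
        raise ValueError("RPM values must be non-negative")
    if rpm_untreated < floor:
        return INSUFFICIENT_DATA
    return rpm_treated / rpm_untreated


def gain_ratio(
    rpm_treated: float, rpm_untreated: float, floor: float = 1.0
) -> float | _InsufficientData:
    """Fold-gain of a treatment over the untreated arm, usable when the
    untreated class is empty.

    A genuinely 5'-triphosphorylated population is invisible untreated, so
    its RppH gain cannot be a plain ratio; when the untreated RPM is below
    the floor but the treated RPM is not, the denominator is clamped at the
    floor, yielding a lower bound on the true gain.  INSUFFICIENT_DATA only
    when both arms are below the floor.
    """
    if rpm_treated < 0 or rpm_untreated < 0:
        raise ValueError("RPM values must be non-negative")
    if rpm_untreated >= floor:
        return rpm_treated / rpm_untreated
    if rpm_treated >= floor:
        return rpm_treated / floor
    return INSUFFICIENT_DATA


def call_three_prime(
    ox_ratio: float | _InsufficientData, protected_threshold: float = 0.5
) -> ThreePrimeCall:
    """Post-oxidation retention >= threshold means the 3' end resisted
    periodate, i.e. carries a 2'-O-methyl group."""
    if ox_ratio is INSUFFICIENT_DATA:
        return ThreePrimeCall.INSUFFICIENT_DATA
    if ox_ratio >= protected_threshold:
        return ThreePrimeCall.PROTECTED_2OME
    return ThreePrimeCall.UNPROTECTED


def call_five_prime(
    pnk_ratio: float | _InsufficientData,
    rpph_ratio: float | _InsufficientData,
    untreated_rpm: float = 0.0,
    gain_threshold: float = 2.0,
    loss_threshold: float = 0.5,
) -> FivePrimeCall:
    """5' call from the PNK and RppH arms.

    An RppH gain of at least ``gain_threshold`` is read as a 5' triphosphate
    and takes precedence (a 5'-PPP population is invisible untreated, so the
    gain is the stronger signal).  Otherwise a PNK retention of at most
    ``loss_threshold`` with no RppH gain is read as a canonical 5'
    monophosphate.  Anything else is INSUFFICIENT_DATA.
    """
    if rpph_ratio is not INSUFFICIENT_DATA and rpph_ratio >= gain_threshold:
        return FivePrimeCall.TRI_P
    if (
        pnk_ratio is not INSUFFICIENT_DATA
        and rpph_ratio is not INSUFFICIENT_DATA
        and pnk_ratio <= loss_threshold
        and rpph_ratio < gain_threshold
    ):
        return FivePrimeCall.MONO_P
    return FivePrimeCall.INSUFFICIENT_DATA


def run_inference(
    panels: Iterable[TreatmentPanel],
    thresholds: CallThresholds | None = None,
) -> list[ModificationCall]:
    """One ModificationCall per panel, with the supporting ratios and the
    thresholds used recorded in the output."""
    th = thresholds or CallThresholds()
    th.validate()
    calls = []
    for panel in panels:
        panel.validate()
        none_rpm = float(panel.rpm[Treatment.NONE])
        ox = panel.rpm.get(Treatment.OXIDATION_BETA_ELIM)
        pnk = panel.rpm.get(Treatment.PNK)
        rpph = panel.rpm.get(Treatment.RPPH)
        ox_ratio = (
            protection_ratio(float(ox), none_rpm, th.floor)
            if ox is not None else INSUFFICIENT_DATA
        )
        pnk_ratio = (
            protection_ratio(float(pnk), none_rpm, th.floor)
            if pnk is not None else INSUFFICIENT_DATA
        )
        rpph_ratio = (
            gain_ratio(float(rpph), none_rpm, th.floor)
            if rpph is not None else INSUFFICIENT_DATA
        )
        calls.append(
            ModificationCall(
                parent_id=panel.parent_id,
                side=panel.side,
                three_prime_call=call_three_prime(ox_ratio, th.protected_threshold),
                five_prime_call=call_five_prime(
                    pnk_ratio, rpph_ratio, none_rpm,
                    th.gain_threshold, th.loss_threshold,
                ),
                ox_ratio=ox_ratio,
                pnk_ratio=pnk_ratio,
                rpph_ratio=rpph_ratio,
                thresholds=th,
            )
        )
    return calls


def panels_from_tables(tables) -> list[TreatmentPanel]:
    """Build per-(homolog, half) treatment panels from CountTables labelled
    with their treatment arm.  Raises if the untreated arm is absent or a
    treatment is duplicated."""
    tables = list(tables)
    if not tables:
        raise ValueError("no count tables given")
    treatments = [t.treatment for t in tables]
    if len(set(treatments)) != len(treatments):
        raise ValueError("duplicate treatment arms in panel input")
    if Treatment.NONE not in treatments:
        raise ValueError("untreated (NONE) library missing from panel input")
    parent_ids = tables[0].parent_ids
    if any(t.parent_ids != parent_ids for t in tables):
        raise ValueError("count tables were built against different references")
    panels = []
    for parent in parent_ids:
        for side in (Side.FIVE_PRIME, Side.THREE_PRIME):
            rpm = {t.treatment: t.class_rpm(parent, side) for t in tables}
            panels.append(TreatmentPanel(parent, side, rpm))
    return panels


def write_calls(
    calls: Iterable[ModificationCall], path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Export calls as TSV (ratios formatted as 'NA' when unavailable)."""

    def fmt(x):
        return "NA" if x is INSUFFICIENT_DATA else f"{x:.6g}"

    with open(path, "w") as out:
        if header_comment:
            out.write(f"# {header_comment}\n")
        out.write(
            "parent_id\tside\tthree_prime_call\tfive_prime_call\t"
            "ox_ratio\tpnk_ratio\trpph_ratio\t"
            "floor\tprotected_threshold\tgain_threshold\tloss_threshold\n"
        )
        for c in calls:
            th = c.thresholds
            out.write(
                f"{c.parent_id}\t{c.side}\t{c.three_prime_call.value}\t"
                f"{c.five_prime_call.value}\t{fmt(c.ox_ratio)}\t{fmt(c.pnk_ratio)}\t"
                f"{fmt(c.rpph_ratio)}\t{th.floor:g}\t{th.protected_threshold:g}\t"
                f"{th.gain_threshold:g}\t{th.loss_threshold:g}\n"
            )
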