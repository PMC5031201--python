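"""Protein fate across purification steps: retained, decreased, or lost.

For every pair of consecutive process stages ("transition") the mean reporter
ratio of each quantifiable protein -- destination-stage signal over
source-stage signal, replicates averaged arithmetically before the division --
says whether the purification step carried the protein along (ratio >= 1,
*retained*) or depleted it (ratio < 1, *decreased*). Merging these ratios
with the detectability calls yields three lists per step: proteins above the
limit of detection at the destination, and the retained/decreased partition
of that list. Ties at exactly 1 are classified retained ("preferentially
retained" reads as >=); this comparator is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .design import ChannelDesign
from .noise import DetectionCall
from .quant import ProteinQuant

__all__ = [
    "FluxRecord",
    "FluxError",
    "ThreeLists",
    "transition_name",
    "transition_ratios",
    "three_lists",
    "hcp_summary",
]

RETAINED = "retained"
DECREASED = "decreased"
BELOW_DETECTION = "below_detection"


class FluxError(ValueError):
    """Raised on inconsistent flux-analysis inputs."""


def transition_name(src: str, dest: str) -> str:
    return f"{src}->{dest}"


@dataclass(frozen=True)
class FluxRecord:
    """One protein's fate across one stage transition."""

    accession: str
    transition: str
    mean_ratio: float
    fate: str


class ThreeLists(NamedTuple):
    """Per-transition protein lists: detectable at the destination stage,
    and its retained/decreased partition. All sorted by accession."""

    above_detection: tuple[str, ...]
    retained: tuple[str, ...]
    decreased: tuple[str, ...]


def _stage_means(q: ProteinQuant, design: ChannelDesign) -> dict[str, float]:
    return {
        s: float(np.mean([q.signal[l] for l in design.labels_for_stage(s)]))
        for s in design.occupied_stages
    }


def _detectable_map(detections: Sequence[DetectionCall] | None) -> dict[tuple[str, str], bool]:
    if detections is None:
        return {}
    return {(c.accession, c.stage): c.detectable for c in detections}


def transition_ratios(
    quants: Sequence[ProteinQuant],
    design: ChannelDesign,
    transitions: Sequence[tuple[str, str]] | None = None,
    detections: Sequence[DetectionCall] | None = None,
    tie_retained: bool = True,
) -> list[FluxRecord]:
    """Mean stage-to-stage ratio and fate for every quantifiable protein.

    *transitions* defaults to the consecutive pairs of the design's stage
    order; any ordered pair of stages (e.g. an HCCF-anchored comparison) may
    be passed instead. Replicate labels are averaged before the ratio. A zero
    source with nonzero destination yields an infinite ratio (fate retained);
    zero over zero is undefined and reported ``below_detection``. When
    *detections* are supplied, a protein not detectable at the destination
    stage is ``below_detection`` regardless of its ratio.
    """
    if transitions is None:
        transitions = design.default_transitions()
    for src, dest in transitions:
        if src not in design.stages or dest not in design.stages:
            raise FluxError(f"unknown stage in transition {src!r}->{dest!r}")
    detectable = _detectable_map(detections)

    records: list[FluxRecord] = []
    for q in quants:
        if not q.quantifiable:
            continue
        means = _stage_means(q, design)
        for src, dest in transitions:
            name = transition_name(src, dest)
            s_from, s_to = means[src], means[dest]
            if s_from == 0 and s_to == 0:
                ratio, fate = float("nan"), BELOW_DETECTION
            elif s_from == 0:
                ratio = float("inf")
                fate = RETAINED
            else:
                ratio = s_to / s_from
                if tie_retained:
                    fate = RETAINED if ratio >= 1 else DECREASED
                else:
                    fate = RETAINED if ratio > 1 else DECREASED
            if detections is not None and not detectable.get((q.accession, dest), False):
                fate = BELOW_DETECTION
            records.append(FluxRecord(accession=q.accession, transition=name, mean_ratio=ratio, fate=fate))
    return records


def three_lists(
    flux: Sequence[FluxRecord], detections: Sequence[DetectionCall]
) -> dict[str, ThreeLists]:
    """Merge ratios and detectability into the three lists per transition.

    ``above_detection`` holds the proteins detectable at the transition's
    destination stage; ``retained`` and ``decreased`` partition it by the
    mean ratio. Lists are sorted by accession.
    """
    detectable = _detectable_map(detections)
    out: dict[str, ThreeLists] = {}
    by_transition: dict[str, list[FluxRecord]] = {}
    for rec in flux:
        by_transition.setdefault(rec.transition, []).append(rec)
    for name, recs in by_transition.items():
        dest = name.split("->", 1)[1]
        above, retained, decreased = [], [], []
        for rec in recs:
            if not detectable.get((rec.accession, dest), False):
                continue
            above.append(rec.accession)
            if np.isnan(rec.mean_ratio):
                continue  # zero signal yet detectable cannot occur; defensive
            if rec.mean_ratio >= 1:
                retained.append(rec.accession)
            else:
                decreased.append(rec.accession)
        out[name] = ThreeLists(
            above_detection=tuple(sorted(above)),
            retained=tuple(sorted(retained)),
            decreased=tuple(sorted(decreased)),
        )
    return out


def hcp_summary(
    quants: Sequence[ProteinQuant],
    composition: Mapping[str, tuple[float, float]],
    design: ChannelDesign,
    detections: Sequence[DetectionCall] | None = None,
) -> pd.DataFrame:
    """Per-stage bookkeeping: identified, quantifiable, detectable, mAb share.

    A protein counts as identified at a stage when it has positive signal in
    any of that stage's labels; quantifiable additionally requires the
    unique-peptide gate; detectable comes from the detection calls (0 when
    none are supplied). The mAb fraction is the mean of the composition over
    the stage's labels.
    """
    detectable = _detectable_map(detections)
    rows = []
    for stage in design.occupied_stages:
        labels = design.labels_for_stage(stage)
        n_id = sum(1 for q in quants if any(q.signal[l] > 0 for l in labels))
        n_quant = sum(
            1 for q in quants if q.quantifiable and any(q.signal[l] > 0 for l in labels)
        )
        n_det = sum(1 for q in quants if detectable.get((q.accession, stage), False))
        fracs = [composition[l][0] for l in labels if l in composition]
        mab_fraction = float(np.nanmean(fracs)) if fracs else float("nan")
        rows.append(
            {
                "stage": stage,
                "n_identified": int(n_id),
                "n_quantifiable": int(n_quant),
                "n_detectable": int(n_det),
                "mab_fraction": mab_fraction,
            }
        )
    return pd.DataFrame(rows).set_index("stage")
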