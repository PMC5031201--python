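"""Normalization, peptide ratios, protein roll-up and product stoichiometry.

The quantitative backbone of the pipeline:

* **Channel-sum normalization** rescales every label (channel) so that the
  summed reporter-ion intensity is the same in each, removing unequal labeling
  or loading between channels. After normalization, a protein's share of a
  channel is directly comparable across the process stages.
* **Ratios** follow the convention of dividing each intensity by the mean of
  the intensities in the same row, so every ratio vector has mean 1 and is
  dimensionless.
* **Roll-up** aggregates PSM intensities to proteins, summing over PSMs of
  *unique* peptides only; shared peptides count as identification evidence
  but never contribute signal. A protein is flagged quantifiable when it has
  at least ``min_unique_peptides`` distinct unique peptide sequences
  (default 3), the conventional robustness gate.
* **Composition and stoichiometry**: the product (mAb) share of total signal
  per channel, and the heavy:light chain ratio series balanced to 1 at the
  reference stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import ChannelDesign
from .io import PsmCollection, PsmRecord

__all__ = [
    "ProteinQuant",
    "QuantError",
    "channel_sum_normalize",
    "normalize_collection",
    "psm_ratios",
    "rollup_proteins",
    "global_composition",
    "hc_lc_series",
    "quants_to_frame",
]


class QuantError(ValueError):
    """Raised on quantification contract violations (zero-sum channel, ...)."""


@dataclass
class ProteinQuant:
    """Per-protein aggregated reporter signal.

    ``signal`` maps every design label to the summed normalized intensity of
    the protein's unique-peptide PSMs; ``ratio`` maps each *sample* label to
    ``signal / mean(sample signals)`` (mean 1 across sample labels when the
    protein has any signal). ``n_spectra`` counts every PSM naming the
    accession (shared peptides included); ``n_quant_spectra`` counts only the
    unique-peptide PSMs with nonzero intensity that fed ``signal``.
    """

    accession: str
    n_unique_peptides: int
    n_spectra: int
    n_quant_spectra: int
    signal: dict[str, float]
    ratio: dict[str, float]
    quantifiable: bool


def channel_sum_normalize(m: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Scale columns so all column sums equal the mean of the input sums.

    Operates on *columns* (default: all). Within-column value ratios are
    preserved exactly, and the operation is idempotent.

    Raises
    ------
    QuantError
        If any targeted column has non-positive sum; the message names it.
    """
    cols = list(columns) if columns is not None else list(m.columns)
    out = m.copy()
    sums = out[cols].sum(axis=0)
    zero = [c for c in cols if not sums[c] > 0]
    if zero:
        raise QuantError(f"channel(s) with non-positive intensity sum: {', '.join(map(str, zero))}")
    target = float(sums.mean())
    factors = target / sums
    out[cols] = out[cols] * factors
    return out


def normalize_collection(coll: PsmCollection) -> tuple[PsmCollection, dict[str, float]]:
    """Channel-sum normalize a PSM collection's sample channels.

    Sample labels are scaled so their channel sums are equal; blank (noise)
    labels are scaled by the mean of the sample factors so the background
    stays on the common normalized scale rather than being inflated to a
    sample-sized channel sum. Returns the normalized collection and the
    per-label scale factors.
    """
    matrix = coll.intensity_matrix
    sample = list(coll.design.sample_labels)
    normed = channel_sum_normalize(matrix, columns=sample)
    sums = matrix[sample].sum(axis=0)
    factors = {l: float(sums.mean() / sums[l]) for l in sample}
    blank_factor = float(np.mean(list(factors.values()))) if factors else 1.0
    for label in coll.design.blank_labels:
        normed[label] = matrix[label] * blank_factor
        factors[label] = blank_factor
    out = coll.with_intensities(normed, note="channel-sum normalized")
    out.provenance["channel_factors"] = factors
    return out, factors


def psm_ratios(rec: PsmRecord) -> dict[str, float]:
    """Per-label ratios of one PSM: intensity divided by the row mean.

    The returned ratios have mean 1 over the record's labels. An all-zero
    record carries no quantitative information and yields an empty mapping.
    """
    values = np.array(list(rec.intensities.values()), dtype=float)
    mean = values.mean()
    if mean == 0:
        return {}
    return {label: float(v / mean) for label, v in zip(rec.intensities, values)}


def rollup_proteins(coll: PsmCollection, min_unique_peptides: int = 3) -> list[ProteinQuant]:
    """Aggregate PSM-level intensities to one :class:`ProteinQuant` per accession.

    Every accession appearing in any record is reported. Signal sums the
    intensities of the protein's unique-peptide PSMs (all-zero PSMs contribute
    nothing); ``n_unique_peptides`` counts distinct unique peptide sequences
    (identification evidence, so all-zero PSMs still count); shared peptides
    raise ``n_spectra`` only. Expects intensities already normalized if
    cross-channel comparison is intended.
    """
    design = coll.design
    labels = list(design.labels)
    sample = list(design.sample_labels)
    df = coll.table
    if df.empty:
        return []

    unique_mask = ~df["proteins"].str.contains(";", regex=False)
    any_pos = df[labels].gt(0).any(axis=1)

    uniq = df.loc[unique_mask]
    signal = uniq.groupby("proteins")[labels].sum()
    n_unique_peptides = uniq.groupby("proteins")["peptide"].nunique()
    n_quant_spectra = df.loc[unique_mask & any_pos].groupby("proteins").size()

    exploded = df["proteins"].str.split(";").explode()
    n_spectra = exploded.groupby(exploded).size()

    quants: list[ProteinQuant] = []
    for acc in sorted(n_spectra.index):
        sig = signal.loc[acc] if acc in signal.index else pd.Series(0.0, index=labels)
        sample_vals = sig[sample].to_numpy(dtype=float)
        mean = sample_vals.mean()
        if mean > 0:
            ratio = {l: float(sig[l] / mean) for l in sample}
        else:
            ratio = {l: float("nan") for l in sample}
        n_up = int(n_unique_peptides.get(acc, 0))
        quants.append(
            ProteinQuant(
                accession=acc,
                n_unique_peptides=n_up,
                n_spectra=int(n_spectra[acc]),
                n_quant_spectra=int(n_quant_spectra.get(acc, 0)),
                signal={l: float(sig[l]) for l in labels},
                ratio=ratio,
                quantifiable=n_up >= min_unique_peptides,
            )
        )
    return quants


def global_composition(
    quants: Sequence[ProteinQuant], design: ChannelDesign
) -> dict[str, tuple[float, float]]:
    """Product vs host-cell share of total signal, per label.

    Returns ``label -> (mab_fraction, hcp_fraction)``; the two fractions sum
    to 1. A label whose total signal is zero has no defined composition and
    maps to ``(nan, nan)``.
    """
    if not quants:
        raise QuantError("global_composition requires at least one protein")
    mab = set(design.mab_accessions)
    out: dict[str, tuple[float, float]] = {}
    for label in design.labels:
        total = sum(q.signal[label] for q in quants)
        if total <= 0:
            out[label] = (float("nan"), float("nan"))
            continue
        mab_sum = sum(q.signal[label] for q in quants if q.accession in mab)
        out[label] = (mab_sum / total, 1.0 - mab_sum / total)
    return out


def hc_lc_series(quants: Sequence[ProteinQuant], design: ChannelDesign) -> dict[str, float]:
    """Light:heavy chain ratio per stage, balanced to 1 at the reference stage.

    The balancing scalar ``b`` is the mean of ``LC/HC`` over the reference
    stage's replicate labels, so the reference stage reports exactly 1.0;
    other stages report the replicate-mean of ``LC / (b * HC)``. The series is
    invariant to any global rescaling of either chain's intensities.

    Raises
    ------
    QuantError
        If either chain is absent, not quantifiable, or has zero signal at a
        reference-stage label.
    """
    by_acc = {q.accession: q for q in quants}
    hc_accs = design.chain_accessions("HC")
    lc_accs = design.chain_accessions("LC")
    if not hc_accs or not lc_accs:
        raise QuantError("design declares no HC/LC product accessions")
    missing = [a for a in (*hc_accs, *lc_accs) if a not in by_acc]
    if missing:
        raise QuantError(f"product chain accession(s) absent from quantification: {', '.join(missing)}")
    for acc in (*hc_accs, *lc_accs):
        if not by_acc[acc].quantifiable:
            raise QuantError(f"product chain {acc} is not quantifiable (too few unique peptides)")

    def chain_signal(accs: Iterable[str], label: str) -> float:
        return sum(by_acc[a].signal[label] for a in accs)

    ref_stage = design.reference_stage
    ref_labels = design.labels_for_stage(ref_stage)
    ref_ratios = []
    for label in ref_labels:
        hc = chain_signal(hc_accs, label)
        lc = chain_signal(lc_accs, label)
        if hc <= 0 or lc <= 0:
            raise QuantError(f"zero product-chain signal at reference-stage label {label!r}")
        ref_ratios.append(lc / hc)
    b = float(np.mean(ref_ratios))

    series: dict[str, float] = {}
    for stage in design.occupied_stages:
        if stage == ref_stage:
            series[stage] = 1.0
            continue
        vals = []
        for label in design.labels_for_stage(stage):
            hc = chain_signal(hc_accs, label)
            if hc <= 0:
                raise QuantError(f"zero heavy-chain signal at label {label!r}")
            vals.append(chain_signal(lc_accs, label) / (b * hc))
        series[stage] = float(np.mean(vals))
    return series


def quants_to_frame(quants: Sequence[ProteinQuant], what: str = "signal") -> pd.DataFrame:
    """Stack protein quants into an accession-by-label DataFrame of *what*
    (``"signal"`` or ``"ratio"``)."""
    if what not in ("signal", "ratio"):
        raise ValueError("what must be 'signal' or 'ratio'")
    rows = {q.accession: getattr(q, what) for q in quants}
    return pd.DataFrame.from_dict(rows, orient="index")
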