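"""Blank-channel background modeling and per-stage detectability calls.

A multiplex design can reserve labels that carry no sample ("blanks"): the
reporter intensity observed there is pure background -- chemical noise,
co-isolation residue, detector floor. Background reporter intensities are
well described as log-normal, so the model fits the mean and standard
deviation of log blank intensities and places the limit of detection at

    threshold = exp(mu_log + k * sigma_log)

with ``k = 3`` by default (the conventional mean + 3 sigma rule, applied in
the log domain). A protein is called detectable at a stage when its mean
per-spectrum signal there exceeds the threshold; dividing by the PSM count
keeps the call independent of how many spectra the protein happened to
accumulate.

Designs without blank labels (e.g. the eight-sample layout) supply an
explicit floor via :func:`set_noise_floor`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import ChannelDesign
from .io import PsmCollection
from .quant import ProteinQuant

__all__ = ["NoiseModel", "NoiseError", "DetectionCall", "fit_noise", "set_noise_floor", "call_detection"]


class NoiseError(ValueError):
    """Raised when a noise model cannot be fitted or applied."""


@dataclass(frozen=True)
class NoiseModel:
    """Log-normal background model with a k-sigma detection threshold."""

    mu_log: float
    sigma_log: float
    n_obs: int
    k: float = 3.0
    source: str = "fitted"

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise NoiseError("sigma_log must be non-negative")
        if self.source == "fitted" and self.n_obs < 2:
            raise NoiseError("a fitted noise model needs at least 2 blank observations")

    @property
    def threshold(self) -> float:
        """Limit of detection on the intensity scale: exp(mu + k * sigma)."""
        return float(np.exp(self.mu_log + self.k * self.sigma_log))


@dataclass(frozen=True)
class DetectionCall:
    """Detectability verdict for one protein at one stage.

    ``margin`` is the mean per-spectrum stage signal divided by the
    threshold; ``detectable`` is exactly ``margin > 1``.
    """

    accession: str
    stage: str
    detectable: bool
    margin: float


def fit_noise(coll: PsmCollection, k: float = 3.0) -> NoiseModel:
    """Fit the background model from the blank labels of *coll*.

    Pools every positive blank-channel intensity over all PSMs and takes the
    mean and (n-1) standard deviation of their natural logs. With ``k = 0``
    the threshold is the geometric mean of the blanks.

    Raises
    ------
    NoiseError
        If the design has no blank labels (use :func:`set_noise_floor` for
        such designs) or fewer than two positive blank intensities exist.
    """
    blanks = coll.design.blank_labels
    if not blanks:
        raise NoiseError(
            "design has no blank labels; supply an explicit floor with set_noise_floor()"
        )
    values = coll.table[list(blanks)].to_numpy(dtype=float).ravel()
    values = values[values > 0]
    if values.size < 2:
        raise NoiseError("need at least 2 positive blank intensities to fit the noise model")
    logs = np.log(values)
    return NoiseModel(
        mu_log=float(logs.mean()),
        sigma_log=float(logs.std(ddof=1)),
        n_obs=int(values.size),
        k=float(k),
        source="fitted",
    )


def set_noise_floor(threshold: float) -> NoiseModel:
    """Degenerate model with a user-supplied detection threshold."""
    if not threshold > 0:
        raise NoiseError("noise floor must be a positive intensity")
    return NoiseModel(mu_log=float(np.log(threshold)), sigma_log=0.0, n_obs=0, k=0.0, source="user-supplied")


def call_detection(
    quants: Sequence[ProteinQuant], noise: NoiseModel, design: ChannelDesign
) -> list[DetectionCall]:
    """Detectability calls for every quantifiable protein at every stage.

    The stage signal is the mean of the protein's replicate-label signals at
    that stage divided by its quantified PSM count (per-spectrum scale, the
    same scale the blanks are modeled on). Non-quantifiable proteins receive
    no calls.
    """
    calls: list[DetectionCall] = []
    threshold = noise.threshold
    stages = design.occupied_stages
    if not stages:
        raise NoiseError("design has no stage with sample labels")
    for q in quants:
        if not q.quantifiable:
            continue
        n = max(q.n_quant_spectra, 1)
        for stage in stages:
            labels = design.labels_for_stage(stage)
            stage_signal = float(np.mean([q.signal[l] for l in labels])) / n
            margin = stage_signal / threshold
            calls.append(
                DetectionCall(accession=q.accession, stage=stage, detectable=margin > 1, margin=margin)
            )
    return calls
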