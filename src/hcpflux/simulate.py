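"""Synthetic PSM experiments with known ground truth.

The generator emulates the statistical structure of a multiplexed
reporter-ion experiment tracking host-cell proteins (HCPs) through an
antibody downstream process, so that every analysis stage can be tested
against a known answer:

* HCP abundances at harvest (HCCF) are log-normal with a wide dynamic range.
* Each stage transition multiplies each HCP's abundance by a per-protein
  clearance factor, itself log-normal; a configurable fraction of HCPs is
  *retained* (factor > 1), the rest *decreased* (factor < 1).
* Abundances are relative (composition) quantities: each channel carries the
  same total signal -- emulating equal protein loading per label -- and the
  product (mAb) makes up the channel total not taken by HCPs. Its share
  therefore rises as HCPs clear, as in a real capture step.
* The mAb heavy/light chains dominate PSM counts (undersampling HCP
  identifications); their light:heavy abundance ratio is 2:1 at HCCF and 1:1
  downstream, emulating removal of free light chain by the capture column.
* Every channel of every PSM receives additive log-normal background; blank
  labels receive background only.
* Per-peptide ionization efficiencies are drawn once per peptide and shared
  across channels, so they cancel in within-spectrum ratios.

Reporter intensity for a PSM of protein *p* in sample label *l*::

    I = abundance_p(stage(l)) * ion_factor(peptide) * noise + background

with mean-one multiplicative log-normal noise (coefficient of variation
``replicate_cv``) and log-normal background ``LN(blank_mu, blank_sigma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ChannelDesign
from .flux import DECREASED, RETAINED, transition_name
from .io import PsmCollection

__all__ = [
    "ClearanceSpec",
    "SyntheticParams",
    "GroundTruth",
    "ParameterError",
    "generate_experiment",
    "truth_summary",
]

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ParameterError(ValueError):
    """Raised when generator parameters are infeasible or inconsistent."""


@dataclass(frozen=True)
class ClearanceSpec:
    """Log-normal clearance-factor distribution for one stage transition.

    Decreased proteins draw ``log c = -|N(mu, sigma)|`` (guaranteed < 1);
    retained proteins draw ``log c = +|N(retained_mu, retained_sigma)|``
    (guaranteed > 1). ``mu`` is the log of the typical surviving fraction,
    e.g. ``log(0.3)`` for a step removing ~70% of a typical HCP.
    """

    mu: float
    sigma: float
    retained_mu: float = float(np.log(1.4))
    retained_sigma: float = 0.3


DEFAULT_CLEARANCE = ClearanceSpec(mu=float(np.log(0.3)), sigma=0.5)


@dataclass(frozen=True)
class SyntheticParams:
    """Study conditions for one synthetic experiment.

    Parameters
    ----------
    n_hcp
        Number of host-cell proteins.
    abundance_sdlog
        Standard deviation of log HCCF abundances (1.5 spans roughly four
        orders of magnitude over +-3 sigma).
    clearance
        ``"src->dest" -> ClearanceSpec`` overrides; transitions without an
        entry use :data:`DEFAULT_CLEARANCE`.
    frac_retained
        Fraction of HCPs drawn as retained (clearance factor > 1) at each
        transition.
    mab_psm_fraction
        Target fraction of all PSMs matched to product-chain peptides
        (0.834 reproduces the dominance seen in a capture-focused 8-plex).
    mab_fraction_hccf
        Product share of total channel signal at HCCF. ``None`` (default)
        matches it to ``mab_psm_fraction``, i.e. spectral sampling
        proportional to abundance.
    lc_hc_ratio_hccf
        Light:heavy chain molar ratio at HCCF (2.0 emulates excess free
        light chain); downstream stages are 1:1.
    replicate_cv
        Coefficient of variation of the multiplicative technical noise per
        PSM and channel.
    blank_mu, blank_sigma
        Location and scale of the log background intensity added to every
        channel; blank labels carry only this background.
    peptides_per_protein_mean, spectra_per_peptide_mean
        Means of the shifted-Poisson (>= 1) count distributions for HCPs.
    frac_shared_peptides
        Probability that an HCP peptide is shared with a second protein
        (non-unique), so ~95% of HCP peptides are unique by default.
    ionization_sdlog
        Spread of the per-peptide log ionization factor.
    mab_peptides_per_chain
        Peptides per product chain over which the inflated mAb PSM count is
        distributed.
    total_signal
        Total abundance per channel (arbitrary reporter units).
    abundance_override
        Optional explicit HCCF abundance per HCP (length ``n_hcp``), used
        verbatim without rescaling -- e.g. zeros for pure-background
        proteins in detection operating-characteristic studies.
    detection_k
        k used to record the theoretical detectability truth
        (``threshold = exp(blank_mu + k * blank_sigma)``).
    seed
        RNG seed; a fixed seed makes the output byte-identical.
    """

    n_hcp: int = 200
    abundance_sdlog: float = 1.5
    clearance: Mapping[str, ClearanceSpec] = field(default_factory=dict)
    frac_retained: float = 0.1
    mab_psm_fraction: float = 0.834
    mab_fraction_hccf: float | None = None
    lc_hc_ratio_hccf: float = 2.0
    replicate_cv: float = 0.1
    blank_mu: float = 0.0
    blank_sigma: float = 0.8
    peptides_per_protein_mean: float = 6.0
    spectra_per_peptide_mean: float = 4.0
    frac_shared_peptides: float = 0.05
    ionization_sdlog: float = 1.0
    mab_peptides_per_chain: int = 30
    total_signal: float = 1.0e6
    abundance_override: Sequence[float] | None = None
    detection_k: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_hcp < 1:
            raise ParameterError("n_hcp must be >= 1")
        for name in ("frac_retained", "frac_shared_peptides"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if not 0 <= self.mab_psm_fraction < 1:
            raise ParameterError("mab_psm_fraction must be in [0, 1); 1 would leave no HCP spectra")
        if self.mab_fraction_hccf is not None and not 0 <= self.mab_fraction_hccf < 1:
            raise ParameterError("mab_fraction_hccf must be in [0, 1)")
        if self.replicate_cv < 0:
            raise ParameterError("replicate_cv must be >= 0")
        if self.blank_sigma < 0:
            raise ParameterError("blank_sigma must be >= 0")
        if self.peptides_per_protein_mean < 1 or self.spectra_per_peptide_mean < 1:
            raise ParameterError("peptide and spectra count means must be >= 1")
        if self.mab_peptides_per_chain < 1:
            raise ParameterError("mab_peptides_per_chain must be >= 1")
        if not self.total_signal > 0:
            raise ParameterError("total_signal must be positive")
        if self.lc_hc_ratio_hccf <= 0:
            raise ParameterError("lc_hc_ratio_hccf must be positive")
        if self.abundance_override is not None:
            arr = np.asarray(self.abundance_override, dtype=float)
            if arr.shape != (self.n_hcp,):
                raise ParameterError("abundance_override must have length n_hcp")
            if (arr < 0).any():
                raise ParameterError("abundance_override values must be >= 0")


@dataclass
class GroundTruth:
    """Known per-protein truth of a synthetic experiment.

    ``proteins`` is indexed by accession (HCPs plus the two product chains,
    distinguished by the ``kind`` column) with columns ``abundance_<stage>``,
    ``clearance_<transition>``, ``class_<transition>``,
    ``expected_psm_signal_<stage>`` (per-spectrum scale, background included)
    and ``detectable_<stage>``. ``mab`` holds the chain abundances and
    light:heavy ratio per stage. ``noise_threshold`` is the theoretical
    blank-derived limit of detection the detectability flags refer to.
    """

    stages: tuple[str, ...]
    transitions: tuple[str, ...]
    proteins: pd.DataFrame
    mab: pd.DataFrame
    noise_threshold: float
    params: SyntheticParams

    @property
    def hcp(self) -> pd.DataFrame:
        return self.proteins.loc[self.proteins["kind"] == "hcp"]


def _shifted_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Counts >= 1 with the given mean: 1 + Poisson(mean - 1)."""
    return 1 + rng.poisson(mean - 1.0, size)


def _peptide_sequences(rng: np.random.Generator, n: int) -> list[str]:
    lengths = rng.integers(9, 17, n)
    letters = rng.integers(0, len(_AMINO_ACIDS), int(lengths.sum()))
    seqs: list[str] = []
    seen: set[str] = set()
    pos = 0
    for i, ln in enumerate(lengths):
        s = "".join(_AMINO_ACIDS[letters[pos : pos + ln]])
        pos += int(ln)
        if s in seen:  # astronomically rare; disambiguate deterministically
            s = f"{s}K{i}"
        seen.add(s)
        seqs.append(s)
    return seqs


def generate_experiment(
    params: SyntheticParams, design: ChannelDesign
) -> tuple[PsmCollection, GroundTruth]:
    """Draw one synthetic experiment for *design* under *params*.

    Deterministic for a fixed seed. Returns the PSM collection (raw, not
    normalized) and its ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    stages = design.occupied_stages
    n_stage = len(stages)
    transitions = design.default_transitions()
    t_names = tuple(transition_name(s, d) for s, d in transitions)

    use_mab = params.mab_psm_fraction > 0
    mab_frac = 0.0
    if use_mab:
        mab_frac = (
            params.mab_psm_fraction if params.mab_fraction_hccf is None else params.mab_fraction_hccf
        )
        hc_accs = sorted(design.chain_accessions("HC"))
        lc_accs = sorted(design.chain_accessions("LC"))
        if not hc_accs or not lc_accs:
            raise ParameterError(
                "mab_psm_fraction > 0 but the design declares no HC/LC product accessions"
            )
        hc_acc, lc_acc = hc_accs[0], lc_accs[0]

    # --- true abundance trajectories (composition units) ------------------
    n = params.n_hcp
    if params.abundance_override is not None:
        a0 = np.asarray(params.abundance_override, dtype=float)
    else:
        raw = rng.lognormal(0.0, params.abundance_sdlog, n)
        a0 = raw / raw.sum() * params.total_signal * (1.0 - mab_frac)

    clearance = np.empty((n, len(transitions)))
    retained = np.empty((n, len(transitions)), dtype=bool)
    for j, (src, dest) in enumerate(transitions):
        spec = params.clearance.get(transition_name(src, dest), DEFAULT_CLEARANCE)
        flags = rng.random(n) < params.frac_retained
        z_dec = rng.normal(size=n)
        z_ret = rng.normal(size=n)
        log_c = np.where(
            flags,
            np.abs(spec.retained_mu + spec.retained_sigma * z_ret),
            -np.abs(spec.mu + spec.sigma * z_dec),
        )
        clearance[:, j] = np.exp(log_c)
        retained[:, j] = flags

    abundance = np.empty((n, n_stage))
    abundance[:, 0] = a0
    for j in range(len(transitions)):
        abundance[:, j + 1] = abundance[:, j] * clearance[:, j]

    hcp_totals = abundance.sum(axis=0)
    if use_mab:
        mab_total = params.total_signal - hcp_totals
        if (mab_total <= 0).any():
            bad = stages[int(np.argmax(mab_total <= 0))]
            raise ParameterError(
                f"host-cell protein load at stage {bad!r} exceeds the channel total; "
                "lower abundances or clearance factors"
            )
        lc_hc = np.array([params.lc_hc_ratio_hccf if s == "HCCF" else 1.0 for s in stages])
        hc_abund = mab_total / (1.0 + lc_hc)
        lc_abund = mab_total * lc_hc / (1.0 + lc_hc)
    else:
        mab_total = np.zeros(n_stage)
        lc_hc = np.full(n_stage, np.nan)
        hc_abund = np.zeros(n_stage)
        lc_abund = np.zeros(n_stage)

    # full abundance matrix: HCP rows then (when present) HC, LC
    if use_mab:
        a_full = np.vstack([abundance, hc_abund[None, :], lc_abund[None, :]])
    else:
        a_full = abundance

    # --- peptides and spectra ---------------------------------------------
    hcp_accessions = [f"HCP{i + 1:05d}" for i in range(n)]
    n_pep_hcp = _shifted_poisson(rng, params.peptides_per_protein_mean, n)
    pep_owner = np.repeat(np.arange(n), n_pep_hcp)
    n_pep_total_hcp = int(pep_owner.size)

    shared = np.zeros(n_pep_total_hcp, dtype=bool)
    partner = np.zeros(n_pep_total_hcp, dtype=int)
    if n > 1 and params.frac_shared_peptides > 0:
        shared = rng.random(n_pep_total_hcp) < params.frac_shared_peptides
        partner = rng.integers(0, n - 1, n_pep_total_hcp)
        partner = np.where(partner >= pep_owner, partner + 1, partner)

    ion_hcp = rng.lognormal(0.0, params.ionization_sdlog, n_pep_total_hcp)
    n_spec_hcp = _shifted_poisson(rng, params.spectra_per_peptide_mean, n_pep_total_hcp)
    n_hcp_psm = int(n_spec_hcp.sum())

    if use_mab:
        m = params.mab_peptides_per_chain
        ion_mab = rng.lognormal(0.0, params.ionization_sdlog, 2 * m)
        f = params.mab_psm_fraction
        n_mab_psm = int(round(f / (1.0 - f) * n_hcp_psm))
        hc_pool, lc_pool = float(hc_abund.sum()), float(lc_abund.sum())
        w = np.concatenate([np.full(m, hc_pool / m), np.full(m, lc_pool / m)])
        n_spec_mab = rng.multinomial(n_mab_psm, w / w.sum())
        mab_pep_owner = np.concatenate([np.full(m, n), np.full(m, n + 1)])
    else:
        ion_mab = np.empty(0)
        n_spec_mab = np.empty(0, dtype=int)
        mab_pep_owner = np.empty(0, dtype=int)

    owner_all = np.concatenate([pep_owner, mab_pep_owner])
    ion_all = np.concatenate([ion_hcp, ion_mab])
    n_spec_all = np.concatenate([n_spec_hcp, n_spec_mab])
    sequences = _peptide_sequences(rng, owner_all.size)

    accession_of_row = hcp_accessions + ([hc_acc, lc_acc] if use_mab else [])
    pep_proteins: list[str] = []
    for i in range(owner_all.size):
        owner_acc = accession_of_row[owner_all[i]]
        if i < n_pep_total_hcp and shared[i]:
            pep_proteins.append(";".join(sorted((owner_acc, hcp_accessions[partner[i]]))))
        else:
            pep_proteins.append(owner_acc)

    # --- PSM-level intensity matrix ---------------------------------------
    psm_pep = np.repeat(np.arange(owner_all.size), n_spec_all)
    n_psm = int(psm_pep.size)
    psm_owner = owner_all[psm_pep]
    psm_ion = ion_all[psm_pep]

    labels = design.labels
    stage_index = {s: i for i, s in enumerate(stages)}
    base = np.zeros((n_psm, len(labels)))
    for col, label in enumerate(labels):
        if design.roles[label] == "sample":
            base[:, col] = a_full[psm_owner, stage_index[design.stage_of[label]]] * psm_ion

    if params.replicate_cv > 0:
        sigma_rep = float(np.sqrt(np.log1p(params.replicate_cv**2)))
        noise = rng.lognormal(-(sigma_rep**2) / 2.0, sigma_rep, base.shape)
    else:
        noise = 1.0
    background = rng.lognormal(params.blank_mu, params.blank_sigma, base.shape)
    intensity = base * noise + background

    table = pd.DataFrame(
        {
            "spectrum_id": [f"s{i:07d}" for i in range(n_psm)],
            "peptide": [sequences[j] for j in psm_pep],
            "proteins": [pep_proteins[j] for j in psm_pep],
            "score": np.nan,
        }
    )
    for col, label in enumerate(labels):
        table[label] = intensity[:, col]

    coll = PsmCollection(
        design=design,
        table=table,
        provenance={"generator": "hcpflux.simulate", "seed": params.seed, "n_psm": n_psm},
    )

    # --- ground truth ------------------------------------------------------
    bg_mean = float(np.exp(params.blank_mu + params.blank_sigma**2 / 2.0))
    threshold = float(np.exp(params.blank_mu + params.detection_k * params.blank_sigma))

    n_rows = n + (2 if use_mab else 0)
    psm_count = np.bincount(psm_owner, minlength=n_rows).astype(float)
    ion_sum = np.bincount(psm_owner, weights=psm_ion, minlength=n_rows)
    mean_ion = np.divide(
        ion_sum,
        psm_count,
        out=np.full(n_rows, float(np.exp(params.ionization_sdlog**2 / 2.0))),
        where=psm_count > 0,
    )

    truth = pd.DataFrame(index=pd.Index(accession_of_row, name="accession"))
    truth["kind"] = ["hcp"] * n + (["HC", "LC"] if use_mab else [])
    for s_i, stage in enumerate(stages):
        truth[f"abundance_{stage}"] = a_full[:, s_i]
        expected = a_full[:, s_i] * mean_ion + bg_mean
        truth[f"expected_psm_signal_{stage}"] = expected
        truth[f"detectable_{stage}"] = expected > threshold
    for j, name in enumerate(t_names):
        c_col = np.empty(n_rows)
        c_col[:n] = clearance[:, j]
        cls = np.where(retained[:, j], RETAINED, DECREASED).tolist()
        if use_mab:
            c_col[n:] = a_full[n:, j + 1] / np.where(a_full[n:, j] > 0, a_full[n:, j], np.nan)
            cls += [RETAINED if c_col[n + i] >= 1 else DECREASED for i in range(2)]
        truth[f"clearance_{name}"] = c_col
        truth[f"class_{name}"] = cls

    mab_df = pd.DataFrame(
        {"HC": hc_abund, "LC": lc_abund, "total": mab_total, "lc_hc_ratio": lc_hc},
        index=pd.Index(stages, name="stage"),
    )

    gt = GroundTruth(
        stages=stages,
        transitions=t_names,
        proteins=truth,
        mab=mab_df,
        noise_threshold=threshold,
        params=params,
    )
    return coll, gt


def truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Retained/decreased HCP counts per transition; rows sum to ``n_hcp``."""
    rows = []
    hcp = truth.hcp
    for name in truth.transitions:
        cls = hcp[f"class_{name}"]
        rows.append(
            {
                "transition": name,
                "retained": int((cls == RETAINED).sum()),
                "decreased": int((cls == DECREASED).sum()),
            }
        )
    df = pd.DataFrame(rows).set_index("transition")
    df["total"] = df["retained"] + df["decreased"]
    return df
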