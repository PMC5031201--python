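"""Channel design: how isobaric labels map to process samples and blanks.

A multiplexed reporter-ion experiment assigns each label (channel) either to a
sample -- a (purification stage, technical replicate) pair -- or reserves it as
a *blank* carrying no sample, used downstream to model the background signal
floor. The design also names one sample label as the *reference* for
ratio balancing and declares which protein accessions are the product
(antibody heavy/light chain) rather than host-cell proteins.

The on-disk representation is a small YAML document::

    labels: ["113", "114", "115", "116", "117", "118", "119", "121"]
    stages: ["HCCF", "ProteinA_FT", "ProteinA_eluate"]
    channels:
      "113": {role: sample, stage: HCCF, replicate: 1}
      "114": {role: sample, stage: HCCF, replicate: 2}
      ...
      "119": {role: blank}
      "121": {role: blank}
    reference_label: "117"
    mab_accessions: {X000002: HC, X000001: LC}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ChannelDesign",
    "DesignError",
    "load_design",
    "write_design",
    "six_sample_design",
    "eight_sample_design",
]


class DesignError(ValueError):
    """Raised when a channel design violates its structural contract."""


@dataclass(frozen=True)
class ChannelDesign:
    """Immutable mapping of isobaric labels to samples, stages and blanks.

    Parameters
    ----------
    labels
        Ordered label tags, e.g. the eight 8-plex reporter tags.
    roles
        ``label -> "sample" | "blank"``.
    stages
        Ordered purification-stage names. The order is authoritative: the
        default stage transitions are the consecutive pairs of this list.
    stage_of
        ``sample label -> stage name``.
    replicate_of
        ``sample label -> replicate index`` (positive integer).
    reference_label
        The sample label used to anchor ratio balancing (by convention the
        first Protein A eluate replicate).
    mab_accessions
        ``accession -> "HC" | "LC"`` for the product chains.
    """

    labels: tuple[str, ...]
    roles: Mapping[str, str]
    stages: tuple[str, ...]
    stage_of: Mapping[str, str]
    replicate_of: Mapping[str, int]
    reference_label: str
    mab_accessions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise DesignError(f"duplicate label(s): {', '.join(dupes)}")
        for label in self.labels:
            role = self.roles.get(label)
            if role not in ("sample", "blank"):
                raise DesignError(f"label {label!r}: role must be 'sample' or 'blank', got {role!r}")
        extra = set(self.roles) - set(self.labels)
        if extra:
            raise DesignError(f"role given for unknown label(s): {sorted(extra)}")
        if not self.sample_labels:
            raise DesignError("design has no sample labels")
        if len(set(self.stages)) != len(self.stages):
            raise DesignError("stage list contains duplicates")
        for label in self.sample_labels:
            stage = self.stage_of.get(label)
            if stage is None:
                raise DesignError(f"sample label {label!r} has no stage")
            if stage not in self.stages:
                raise DesignError(f"sample label {label!r}: unknown stage {stage!r}")
            rep = self.replicate_of.get(label)
            if not isinstance(rep, int) or rep < 1:
                raise DesignError(f"sample label {label!r}: replicate must be a positive integer")
        for label in self.blank_labels:
            if label in self.stage_of or label in self.replicate_of:
                raise DesignError(f"blank label {label!r} must not carry a stage or replicate")
        if self.reference_label not in self.labels:
            raise DesignError(f"reference label {self.reference_label!r} is not in the design")
        if self.roles[self.reference_label] != "sample":
            raise DesignError("reference label must be a sample")
        for acc, chain in self.mab_accessions.items():
            if chain not in ("HC", "LC"):
                raise DesignError(f"mab accession {acc!r}: chain tag must be 'HC' or 'LC', got {chain!r}")

    # -- convenience views ------------------------------------------------

    @property
    def sample_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.roles[l] == "sample")

    @property
    def blank_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if self.roles[l] == "blank")

    def labels_for_stage(self, stage: str) -> tuple[str, ...]:
        if stage not in self.stages:
            raise DesignError(f"unknown stage {stage!r}")
        return tuple(l for l in self.sample_labels if self.stage_of[l] == stage)

    @property
    def occupied_stages(self) -> tuple[str, ...]:
        """Stages that actually have at least one sample label, in order."""
        return tuple(s for s in self.stages if self.labels_for_stage(s))

    @property
    def reference_stage(self) -> str:
        return self.stage_of[self.reference_label]

    def default_transitions(self) -> tuple[tuple[str, str], ...]:
        """Consecutive (from, to) pairs of the occupied stage list."""
        occ = self.occupied_stages
        return tuple(zip(occ[:-1], occ[1:]))

    def chain_accessions(self, chain: str) -> tuple[str, ...]:
        return tuple(a for a, c in self.mab_accessions.items() if c == chain)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        channels = {}
        for label in self.labels:
            if self.roles[label] == "sample":
                channels[label] = {
                    "role": "sample",
                    "stage": self.stage_of[label],
                    "replicate": self.replicate_of[label],
                }
            else:
                channels[label] = {"role": "blank"}
        return {
            "labels": list(self.labels),
            "stages": list(self.stages),
            "channels": channels,
            "reference_label": self.reference_label,
            "mab_accessions": dict(self.mab_accessions),
        }


def _design_from_dict(doc: dict, source: str = "<dict>") -> ChannelDesign:
    try:
        labels = [str(l) for l in doc["labels"]]
        stages = [str(s) for s in doc["stages"]]
        channels = doc["channels"]
        reference = str(doc["reference_label"])
    except (KeyError, TypeError) as exc:
        raise DesignError(f"{source}: missing or malformed required key: {exc}") from exc

    missing = [l for l in labels if l not in {str(k) for k in channels}]
    if missing:
        raise DesignError(f"{source}: no channel entry for label(s): {', '.join(missing)}")

    roles: dict[str, str] = {}
    stage_of: dict[str, str] = {}
    replicate_of: dict[str, int] = {}
    for raw_label, entry in channels.items():
        label = str(raw_label)
        if label not in labels:
            raise DesignError(f"{source}: channel entry for unknown label {label!r}")
        if not isinstance(entry, dict):
            raise DesignError(f"{source}: channel {label!r}: expected a mapping")
        roles[label] = str(entry.get("role", ""))
        if roles[label] == "blank" and ("stage" in entry or "replicate" in entry):
            raise DesignError(f"{source}: blank label {label!r} must not carry a stage or replicate")
        if roles[label] == "sample":
            stage_of[label] = str(entry.get("stage", ""))
            rep = entry.get("replicate", 1)
            if not isinstance(rep, int):
                raise DesignError(f"{source}: channel {label!r}: replicate must be an integer")
            replicate_of[label] = rep

    mab = {str(a): str(c) for a, c in (doc.get("mab_accessions") or {}).items()}
    return ChannelDesign(
        labels=tuple(labels),
        roles=roles,
        stages=tuple(stages),
        stage_of=stage_of,
        replicate_of=replicate_of,
        reference_label=reference,
        mab_accessions=mab,
    )


def load_design(path: str | Path) -> ChannelDesign:
    """Load and validate a channel design from a YAML file.

    Raises
    ------
    DesignError
        If the file is malformed or any structural invariant is violated
        (duplicate labels, blank reference, unknown stage, ...). The message
        names the offending label or key.
    FileNotFoundError
        If *path* does not exist.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DesignError(f"{path}: design file must contain a YAML mapping")
    return _design_from_dict(doc, source=str(path))


def write_design(design: ChannelDesign, path: str | Path) -> None:
    """Write a channel design as YAML (round-trips through :func:`load_design`)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


# -- stock designs mirroring the two 8-plex layouts ------------------------

_DEFAULT_MAB = {"X000002": "HC", "X000001": "LC"}
_EIGHTPLEX_TAGS = ("113", "114", "115", "116", "117", "118", "119", "121")


def six_sample_design(mab_accessions: Mapping[str, str] | None = None) -> ChannelDesign:
    """Six samples plus two blank labels: three Protein A stages, duplicate.

    Stages HCCF -> Protein A flow-through -> Protein A eluate in technical
    duplicate occupy six labels; the last two labels carry no sample and are
    reserved for noise modeling. Reference: first Protein A eluate replicate.
    """
    stages = ("HCCF", "ProteinA_FT", "ProteinA_eluate")
    tags = _EIGHTPLEX_TAGS
    roles = {t: "sample" for t in tags[:6]}
    roles.update({tags[6]: "blank", tags[7]: "blank"})
    stage_of = {tags[i]: stages[i // 2] for i in range(6)}
    replicate_of = {tags[i]: i % 2 + 1 for i in range(6)}
    return ChannelDesign(
        labels=tags,
        roles=roles,
        stages=stages,
        stage_of=stage_of,
        replicate_of=replicate_of,
        reference_label=tags[4],
        mab_accessions=dict(mab_accessions if mab_accessions is not None else _DEFAULT_MAB),
    )


def eight_sample_design(mab_accessions: Mapping[str, str] | None = None) -> ChannelDesign:
    """Eight samples, no blanks: four downstream stages in technical duplicate.

    Stages HCCF -> Protein A eluate -> CEX eluate -> AEX flow-through.
    Reference: first Protein A eluate replicate.
    """
    stages = ("HCCF", "ProteinA_eluate", "CEX_eluate", "AEX_FT")
    tags = _EIGHTPLEX_TAGS
    roles = {t: "sample" for t in tags}
    stage_of = {tags[i]: stages[i // 2] for i in range(8)}
    replicate_of = {tags[i]: i % 2 + 1 for i in range(8)}
    return ChannelDesign(
        labels=tags,
        roles=roles,
        stages=stages,
        stage_of=stage_of,
        replicate_of=replicate_of,
        reference_label=tags[2],
        mab_accessions=dict(mab_accessions if mab_accessions is not None else _DEFAULT_MAB),
    )
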