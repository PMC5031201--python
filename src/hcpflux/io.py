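"""PSM tables and protein reports: the pipeline's file formats.

The quantification pipeline starts from a peptide-spectrum-match (PSM) table:
one row per matched fragmentation spectrum, carrying the peptide sequence, the
protein accession(s) the peptide maps to, and one reporter-ion intensity per
isobaric label. The dialect is UTF-8 TSV with a header row; intensity columns
are named exactly by the design's label tags; multiple accessions share one
cell, semicolon-delimited.

PSMs whose peptide maps to more than one protein are *shared* (``is_unique``
false); they count as identification evidence but are excluded from
quantification. PSMs with all-zero intensities are kept (they still carry an
identification) but flagged and excluded from ratio computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import ChannelDesign

if TYPE_CHECKING:  # pragma: no cover
    from .noise import DetectionCall
    from .quant import ProteinQuant

__all__ = [
    "PsmRecord",
    "PsmCollection",
    "PsmTableError",
    "load_psm_table",
    "write_psm_table",
    "write_protein_report",
]

#: fixed leading columns of the PSM TSV dialect, in order
PSM_FIXED_COLUMNS = ("spectrum_id", "peptide", "proteins", "score")


class PsmTableError(ValueError):
    """Raised on schema or value violations in a PSM table."""


@dataclass(frozen=True)
class PsmRecord:
    """One matched spectrum with its per-label reporter intensities."""

    spectrum_id: str
    peptide: str
    protein_accessions: tuple[str, ...]
    intensities: Mapping[str, float]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.protein_accessions:
            raise PsmTableError(f"PSM {self.spectrum_id!r}: empty protein accession list")
        for label, value in self.intensities.items():
            if value < 0:
                raise PsmTableError(f"PSM {self.spectrum_id!r}: negative intensity in label {label!r}")

    @property
    def is_unique(self) -> bool:
        """True iff the peptide maps to exactly one protein group."""
        return len(self.protein_accessions) == 1

    @property
    def all_zero(self) -> bool:
        return all(v == 0 for v in self.intensities.values())


@dataclass
class PsmCollection:
    """A PSM table bound to its channel design.

    The canonical store is a :class:`pandas.DataFrame` (``table``) with the
    fixed columns of :data:`PSM_FIXED_COLUMNS` plus one float column per design
    label; ``records`` offers a row-by-row dataclass view for small inputs.
    """

    design: ChannelDesign
    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("spectrum_id", "peptide", "proteins") if c not in self.table.columns]
        if missing:
            raise PsmTableError(f"PSM table missing column(s): {', '.join(missing)}")
        missing_labels = [l for l in self.design.labels if l not in self.table.columns]
        if missing_labels:
            raise PsmTableError(f"PSM table missing intensity column(s): {', '.join(missing_labels)}")
        if "score" not in self.table.columns:
            self.table = self.table.assign(score=np.nan)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> tuple[str, ...]:
        return self.design.labels

    @property
    def intensity_matrix(self) -> pd.DataFrame:
        """Spectrum-by-label intensity grid (a copy), indexed by spectrum id."""
        m = self.table.set_index("spectrum_id")[list(self.design.labels)]
        return m.astype(float)

    @property
    def is_unique(self) -> pd.Series:
        return ~self.table["proteins"].str.contains(";", regex=False)

    @property
    def all_zero(self) -> pd.Series:
        return ~self.table[list(self.design.labels)].gt(0).any(axis=1)

    @property
    def records(self) -> Iterator[PsmRecord]:
        labels = list(self.design.labels)
        for d in self.table.to_dict(orient="records"):
            score = d.get("score")
            yield PsmRecord(
                spectrum_id=str(d["spectrum_id"]),
                peptide=str(d["peptide"]),
                protein_accessions=tuple(str(d["proteins"]).split(";")),
                intensities={l: float(d[l]) for l in labels},
                score=None if score is None or (isinstance(score, float) and np.isnan(score)) else float(score),
            )

    def accessions(self) -> tuple[str, ...]:
        """All accessions appearing in any record, sorted."""
        seen = set()
        for cell in self.table["proteins"]:
            seen.update(cell.split(";"))
        return tuple(sorted(seen))

    def with_intensities(self, matrix: pd.DataFrame, note: str | None = None) -> "PsmCollection":
        """Return a copy whose label columns are replaced by *matrix*.

        *matrix* must be indexed like :attr:`intensity_matrix` (spectrum id
        order preserved) with exactly the design's label columns.
        """
        table = self.table.copy()
        for label in self.design.labels:
            table[label] = np.asarray(matrix[label], dtype=float)
        prov = dict(self.provenance)
        if note:
            prov["notes"] = [*prov.get("notes", []), note]
        return PsmCollection(design=self.design, table=table, provenance=prov)


def load_psm_table(path: str | Path, design: ChannelDesign) -> PsmCollection:
    """Read a PSM TSV and validate it against *design*.

    Rows with any negative intensity are rejected; their 1-based data-row
    numbers are recorded under ``provenance["rejected_rows"]``. All-zero rows
    are retained but flagged (see :attr:`PsmCollection.all_zero`). The input
    row count always equals accepted + rejected.

    Raises
    ------
    PsmTableError
        If the header does not carry exactly the design's label columns; the
        message lists missing and unexpected labels.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"spectrum_id": str, "peptide": str, "proteins": str},
        float_precision="round_trip",
    )
    header = list(df.columns)
    for col in ("spectrum_id", "peptide", "proteins"):
        if col not in header:
            raise PsmTableError(f"{path}: missing required column {col!r}")
    intensity_cols = [c for c in header if c not in PSM_FIXED_COLUMNS]
    missing = [l for l in design.labels if l not in intensity_cols]
    extra = [c for c in intensity_cols if c not in design.labels]
    if missing or extra:
        raise PsmTableError(
            f"{path}: intensity columns do not match design labels"
            f" (missing: {missing or 'none'}; unexpected: {extra or 'none'})"
        )
    label_cols = list(design.labels)
    df[label_cols] = df[label_cols].astype(float)
    if df[label_cols].isna().any().any():
        bad = df.index[df[label_cols].isna().any(axis=1)] + 1
        raise PsmTableError(f"{path}: non-numeric or missing intensity in data row(s) {list(bad)}")

    negative = df[label_cols].lt(0).any(axis=1)
    rejected_rows = [int(i) + 1 for i in df.index[negative]]  # 1-based data rows
    accepted = df.loc[~negative].reset_index(drop=True)
    provenance = {
        "source": str(path),
        "n_input_rows": int(len(df)),
        "n_accepted": int(len(accepted)),
        "n_rejected": len(rejected_rows),
        "rejected_rows": rejected_rows,
    }
    return PsmCollection(design=design, table=accepted, provenance=provenance)


def write_psm_table(coll: PsmCollection, path: str | Path) -> None:
    """Write a PSM collection as TSV; round-trips through :func:`load_psm_table`."""
    path = Path(path)
    cols = [c for c in PSM_FIXED_COLUMNS if c in coll.table.columns] + list(coll.design.labels)
    coll.table[cols].to_csv(path, sep="\t", index=False)


def write_protein_report(
    quants: Sequence["ProteinQuant"],
    detections: Sequence["DetectionCall"],
    path: str | Path,
    flux: Sequence | None = None,
) -> None:
    """Write the per-protein summary TSV.

    One row per protein, sorted by accession: identification counts, per-label
    normalized signal, per-stage detectability flags and, if *flux* records
    are given, the per-transition fate class. Identical inputs produce
    byte-identical files.
    """
    path = Path(path)
    det_by_protein: dict[str, dict[str, "DetectionCall"]] = {}
    for call in detections:
        det_by_protein.setdefault(call.accession, {})[call.stage] = call
    stages = sorted({c.stage for c in detections}) if detections else []
    flux_by_protein: dict[str, dict[str, str]] = {}
    transitions: list[str] = []
    if flux:
        for rec in flux:
            flux_by_protein.setdefault(rec.accession, {})[rec.transition] = rec.fate
            if rec.transition not in transitions:
                transitions.append(rec.transition)

    labels: list[str] = list(quants[0].signal.keys()) if quants else []
    header = (
        ["accession", "n_unique_peptides", "n_spectra", "quantifiable"]
        + [f"signal_{l}" for l in labels]
        + [f"detectable_{s}" for s in stages]
        + [f"fate_{t}" for t in transitions]
    )
    lines = ["\t".join(header)]
    for q in sorted(quants, key=lambda q: q.accession):
        row = [q.accession, str(q.n_unique_peptides), str(q.n_spectra), str(int(q.quantifiable))]
        row += [format(q.signal[l], ".6g") for l in labels]
        for s in stages:
            call = det_by_protein.get(q.accession, {}).get(s)
            row.append("" if call is None else str(int(call.detectable)))
        for t in transitions:
            row.append(flux_by_protein.get(q.accession, {}).get(t, ""))
        lines.append("\t".join(row))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
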