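"""Reading peptide-spectrum observation tables and class-level aggregation.

The canonical input is a flat TSV starting at identified peptides (the
upstream database search is out of scope), with header columns

    sequence  replicate  timepoint_h  [spectra]

and one row per identified peptide per sample. When the ``spectra`` column
is absent the table is read as one row per spectrum and rows are summed.
Aggregation by physicochemical class produces a class x sample contingency
table of summed spectral counts ("samples" are replicate x timepoint
pairs); per-timepoint means across replicates are computed downstream,
never at ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .properties import clean_sequence, validate_sequence, InvalidSequenceError

__all__ = [
    "PSMParseError",
    "ClassAbundanceMatrix",
    "read_psm_table",
    "aggregate_psm",
    "summarize_sample",
    "build_class_matrix",
]

PSM_COLUMNS = ("sequence", "replicate", "timepoint_h", "spectra")

#: Abundance bins for per-sample summaries (spectra per peptide).
ABUNDANCE_BINS = (">10", "5-9", "2-4", "1")


class PSMParseError(ValueError):
    """Malformed observation table; message carries the offending line."""


def read_psm_table(path) -> pd.DataFrame:
    """Read and validate a peptide-spectrum observation TSV.

    Returns a DataFrame with columns ``sequence, replicate, timepoint_h,
    spectra``, aggregated so that (sequence, replicate, timepoint_h) is
    unique. Modification annotations (e.g. ``M(ox)``) are stripped before
    validation; rows whose cleaned sequences coincide are merged.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise PSMParseError(f"{path}: cannot read TSV ({exc})") from exc

    required = {"sequence", "replicate", "timepoint_h"}
    missing = required - set(raw.columns)
    if missing:
        raise PSMParseError(f"{path}: missing column(s) {sorted(missing)}")

    if "spectra" not in raw.columns:
        raw = raw.assign(spectra=1)

    cleaned: list[str] = []
    for idx, seq in raw["sequence"].items():
        line_no = idx + 2  # header is line 1
        if not isinstance(seq, str) or not seq:
            raise PSMParseError(f"{path}:{line_no}: empty sequence")
        try:
            cleaned.append(validate_sequence(clean_sequence(seq)))
        except InvalidSequenceError as exc:
            raise PSMParseError(f"{path}:{line_no}: {exc}") from exc
    raw = raw.assign(sequence=cleaned)

    spectra = pd.to_numeric(raw["spectra"], errors="coerce")
    bad = spectra.isna() | (spectra < 0) | (spectra != spectra.round())
    if bad.any():
        line_no = bad.idxmax() + 2
        raise PSMParseError(
            f"{path}:{line_no}: spectra must be a non-negative integer, "
            f"got {raw['spectra'][bad.idxmax()]!r}"
        )
    raw = raw.assign(spectra=spectra.astype(int))
    return aggregate_psm(raw)


def aggregate_psm(records: pd.DataFrame) -> pd.DataFrame:
    """Sum spectra over duplicate (sequence, replicate, timepoint_h) rows.

    Idempotent: re-aggregating an aggregated table is a no-op.
    """
    out = (
        records.groupby(["sequence", "replicate", "timepoint_h"], as_index=False)[
            "spectra"
        ]
        .sum()
        .sort_values(["replicate", "timepoint_h", "sequence"], kind="stable")
        .reset_index(drop=True)
    )
    return out[list(PSM_COLUMNS)]


def summarize_sample(records: pd.DataFrame) -> tuple[int, int, dict[str, int]]:
    """Per-sample summary: distinct peptides, total spectra, abundance bins.

    *records* must come from a single sample (one replicate x timepoint).
    Bins count peptides by their spectral count: more than 10, 5 to 9,
    2 to 4, and exactly 1 spectrum. Peptides with zero spectra are not
    identified in the sample and are excluded.
    """
    counts = records.loc[records["spectra"] > 0, "spectra"]
    n_peptides = len(counts)
    n_spectra = int(counts.sum())
    bins = {
        ">10": int((counts > 10).sum()),
        "5-9": int(((counts >= 5) & (counts <= 9)).sum()),
        "2-4": int(((counts >= 2) & (counts <= 4)).sum()),
        "1": int((counts == 1).sum()),
    }
    return n_peptides, n_spectra, bins


@dataclass(frozen=True)
class ClassAbundanceMatrix:
    """Class x sample spectral-count contingency table.

    ``counts`` is indexed by class code with a (replicate, timepoint_h)
    column MultiIndex; ``members`` maps each class to its peptide
    sequences. Class membership partitions the distinct peptides: each
    sequence belongs to exactly one class.
    """

    counts: pd.DataFrame
    members: Mapping[str, tuple[str, ...]]

    @property
    def classes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def timepoints(self) -> list[float]:
        return sorted({t for _, t in self.counts.columns})

    @property
    def replicates(self) -> list:
        return sorted({r for r, _ in self.counts.columns})

    def timepoint_means(self) -> pd.DataFrame:
        """Per-timepoint mean count across replicates (classes x timepoints)."""
        return self.counts.T.groupby(level="timepoint_h").mean().T

    def total_spectra(self) -> int:
        return int(self.counts.to_numpy().sum())

    def subset(self, classes) -> "ClassAbundanceMatrix":
        keep = [c for c in self.counts.index if c in set(classes)]
        return ClassAbundanceMatrix(
            counts=self.counts.loc[keep],
            members={c: self.members[c] for c in keep},
        )

    def to_tsv(self, matrix_path, members_path=None) -> None:
        flat = self.counts.copy()
        flat.columns = [f"rep{r}_t{_fmt_time(t)}" for r, t in flat.columns]
        flat.index.name = "class"
        flat.to_csv(matrix_path, sep="\t")
        if members_path is not None:
            rows = [
                {"class": cls, "sequence": seq}
                for cls, seqs in self.members.items()
                for seq in seqs
            ]
            pd.DataFrame(rows, columns=["class", "sequence"]).to_csv(
                members_path, sep="\t", index=False
            )

    @classmethod
    def from_tsv(cls, matrix_path, members_path=None) -> "ClassAbundanceMatrix":
        flat = pd.read_csv(matrix_path, sep="\t", dtype={"class": str})
        flat = flat.set_index("class")
        pairs = []
        for col in flat.columns:
            rep, t = col.split("_t")
            pairs.append((int(rep.removeprefix("rep")), float(t)))
        flat.columns = pd.MultiIndex.from_tuples(
            pairs, names=["replicate", "timepoint_h"]
        )
        members: dict[str, tuple[str, ...]] = {c: () for c in flat.index}
        if members_path is not None:
            sidecar = pd.read_csv(members_path, sep="\t", dtype=str)
            for code, grp in sidecar.groupby("class"):
                members[code] = tuple(grp["sequence"])
        return cls(counts=flat, members=members)


def _fmt_time(t: float) -> str:
    return f"{t:g}"


def build_class_matrix(
    records: pd.DataFrame, barcodes: Mapping[str, str]
) -> ClassAbundanceMatrix:
    """Aggregate peptide-level spectral counts into a class-level matrix.

    *barcodes* maps every distinct sequence in *records* to its class
    code. Cells are summed member-peptide counts; absent observations are
    zeros. Classes with no counts in any sample are dropped. The grand
    total equals the total input spectra (conservation).
    """
    records = aggregate_psm(records)
    unknown = set(records["sequence"]) - set(barcodes)
    if unknown:
        example = sorted(unknown)[0]
        raise KeyError(
            f"{len(unknown)} sequence(s) without a barcode, e.g. {example!r}"
        )
    work = records.assign(cls=records["sequence"].map(barcodes))
    table = work.pivot_table(
        index="cls",
        columns=["replicate", "timepoint_h"],
        values="spectra",
        aggfunc="sum",
        fill_value=0,
    ).astype(int)
    table.columns.names = ["replicate", "timepoint_h"]
    table = table.loc[table.sum(axis=1) > 0]
    table.index.name = "class"
    members = {
        cls: tuple(sorted(grp["sequence"].unique()))
        for cls, grp in work.groupby("cls")
        if cls in table.index
    }
    return ClassAbundanceMatrix(counts=table, members=members)
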