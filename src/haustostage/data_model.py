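"""Core domain types and tabular I/O.

The pipeline's root input is a transcript x sample count matrix with
transcript lengths, a sample sheet assigning each sequencing library to a
haustorium development stage (niS, SWE, ATT, PEN) and replicate, a
transcript -> functional-bin annotation table, and long-format RT-qPCR Cq
tables with technical replicates.

All tabular formats are tab-separated UTF-8 with ``#``-prefixed comment
lines skipped; writers emit the same dialect so read/write round-trips are
the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Admissible development-stage labels, in developmental display order:
#: non-infective stem, swelling, attaching, penetrating.
STAGES: tuple[str, ...] = ("niS", "SWE", "ATT", "PEN")

#: Admissible induction systems for a sample.
SYSTEMS: tuple[str, ...] = ("host-free", "host-induced")


class DataValidationError(ValueError):
    """Raised when an input table violates the domain contracts."""


def validate_stage(label: str) -> str:
    if label not in STAGES:
        raise DataValidationError(
            f"unknown stage label {label!r}; admissible values are {', '.join(STAGES)}"
        )
    return label


def stage_order_key(label: str) -> int:
    """Developmental ordering niS < SWE < ATT < PEN (display / tie-breaking)."""
    return STAGES.index(validate_stage(label))


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: one row per sequencing library / qPCR sample.

    ``table`` has columns sample_id, stage, replicate, system; sample_ids are
    unique and stages are validated at construction.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "stage", "replicate", "system"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataValidationError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample_id(s): {dupes}")
        for s in self.table["stage"]:
            validate_stage(s)
        for sys_ in self.table["system"]:
            if sys_ not in SYSTEMS:
                raise DataValidationError(
                    f"unknown system {sys_!r}; admissible values are {', '.join(SYSTEMS)}"
                )
        reps = pd.to_numeric(self.table["replicate"], errors="coerce")
        if reps.isna().any() or (reps <= 0).any() or (reps != reps.astype(int)).any():
            raise DataValidationError("replicate must be a positive integer")
        object.__setattr__(self, "table", self.table.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def stages(self) -> pd.Series:
        return pd.Series(
            self.table["stage"].values, index=self.table["sample_id"].values, name="stage"
        )

    def samples_of_stage(self, stage: str) -> list[str]:
        validate_stage(stage)
        mask = self.table["stage"] == stage
        return self.table.loc[mask, "sample_id"].tolist()

    def stages_present(self) -> list[str]:
        present = set(self.table["stage"])
        return [s for s in STAGES if s in present]

    def require_replicated(self, min_replicates: int = 2) -> None:
        counts = self.table.groupby("stage")["sample_id"].count()
        bad = counts[counts < min_replicates]
        if len(bad):
            raise DataValidationError(
                f"stage(s) with <{min_replicates} replicates: {bad.index.tolist()}"
            )


@dataclass
class CountMatrix:
    """Raw transcript x sample integer counts plus transcript lengths.

    counts: DataFrame indexed by transcript_id, columns in sample-sheet order.
    lengths_bp: Series of positive ints aligned to the count index.
    """

    counts: pd.DataFrame
    lengths_bp: pd.Series
    samples: SampleSheet

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate transcript_id(s): {dupes}")
        if (self.counts.values < 0).any():
            raise DataValidationError("count matrix contains negative entries")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise DataValidationError("count matrix must be integer-valued")
        lengths = self.lengths_bp.reindex(self.counts.index)
        if lengths.isna().any() or (lengths <= 0).any():
            raise DataValidationError("every transcript needs a positive length_bp")
        self.lengths_bp = lengths.astype(int)
        sheet_ids = self.samples.sample_ids
        matrix_ids = list(self.counts.columns)
        if set(sheet_ids) != set(matrix_ids):
            only_matrix = sorted(set(matrix_ids) - set(sheet_ids))
            only_sheet = sorted(set(sheet_ids) - set(matrix_ids))
            raise DataValidationError(
                "sample sheet and count matrix disagree: "
                f"only in matrix {only_matrix}, only in sheet {only_sheet}"
            )
        # column order follows the sheet
        self.counts = self.counts[sheet_ids]

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_transcripts(self, ids: Iterable[str]) -> "CountMatrix":
        ids = list(ids)
        return CountMatrix(
            counts=self.counts.loc[ids].copy(),
            lengths_bp=self.lengths_bp.loc[ids].copy(),
            samples=self.samples,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountMatrix":
        sample_ids = list(sample_ids)
        sheet = SampleSheet(
            self.samples.table[self.samples.table["sample_id"].isin(sample_ids)].copy()
        )
        return CountMatrix(
            counts=self.counts[sheet.sample_ids].copy(),
            lengths_bp=self.lengths_bp.copy(),
            samples=sheet,
        )


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix tagged with its measure.

    measure is one of CPM, RPKM, log2CPM, log2RPKM, zscore. ``factors``
    optionally records the per-sample scaling factors used (provenance).
    """

    values: pd.DataFrame
    measure: str
    samples: SampleSheet
    factors: pd.Series | None = field(default=None)

    MEASURES = ("CPM", "RPKM", "log2CPM", "log2RPKM", "zscore")

    def __post_init__(self) -> None:
        if self.measure not in self.MEASURES:
            raise DataValidationError(
                f"unknown measure {self.measure!r}; admissible: {self.MEASURES}"
            )


def gene_model_of(transcript_id: str) -> str:
    """Collapse a transcript id to its gene model (strip a trailing .tN).

    Used only for "N transcripts from M gene models" style reporting.
    """
    stem, dot, suffix = transcript_id.rpartition(".")
    if dot and suffix.startswith("t") and suffix[1:].isdigit():
        return stem
    return transcript_id


def count_gene_models(transcript_ids: Iterable[str]) -> int:
    return len({gene_model_of(t) for t in transcript_ids})


@dataclass
class AnnotationTable:
    """transcript_id -> functional bin assignments (dot-separated hierarchy)."""

    table: pd.DataFrame  # columns: transcript_id, bincode, description

    def __post_init__(self) -> None:
        required = {"transcript_id", "bincode"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataValidationError(f"annotation table missing columns: {sorted(missing)}")
        if "description" not in self.table.columns:
            self.table = self.table.assign(description="")
        codes = self.table["bincode"].astype(str)
        if (codes.str.len() == 0).any():
            raise DataValidationError("empty bincode in annotation table")
        self.table = self.table.reset_index(drop=True)

    def bins_of(self, transcript_id: str) -> list[str]:
        mask = self.table["transcript_id"] == transcript_id
        return self.table.loc[mask, "bincode"].tolist()


CQ_MAX = 45.0


@dataclass
class CqTable:
    """RT-qPCR quantification cycles per gene x sample with technical replicates.

    ``cells`` maps (gene_id, sample_id) -> list of Cq values in (0, 45].
    Missing cells are simply absent and propagate as "not measured".
    """

    cells: dict[tuple[str, str], list[float]]

    def __post_init__(self) -> None:
        if not self.cells:
            raise DataValidationError("Cq table is empty")
        for (gene, sample), reps in self.cells.items():
            if not reps:
                raise DataValidationError(f"cell ({gene}, {sample}) has no replicates")
            for cq in reps:
                if not (0 < cq <= CQ_MAX):
                    raise DataValidationError(
                        f"Cq {cq} for ({gene}, {sample}) outside (0, {CQ_MAX}]"
                    )

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for gene, _ in self.cells:
            seen.setdefault(gene)
        return list(seen)

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, sample in self.cells:
            seen.setdefault(sample)
        return list(seen)

    def mean_cq(self) -> pd.DataFrame:
        """Gene x sample matrix of technical-replicate means (NaN = not measured)."""
        genes, samples = self.genes, self.sample_ids
        out = pd.DataFrame(np.nan, index=genes, columns=samples, dtype=float)
        for (gene, sample), reps in self.cells.items():
            out.loc[gene, sample] = float(np.mean(reps))
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_READ_KW = dict(sep="\t", comment="#", dtype=str)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, **_READ_KW)
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    return SampleSheet(df)


def read_counts(path: str | Path, sheet_path: str | Path) -> CountMatrix:
    """Read a counts TSV (transcript_id, length_bp, one column per sample)."""
    sheet = read_sample_sheet(sheet_path)
    df = pd.read_csv(path, **_READ_KW)
    if df.columns[0] != "transcript_id" or df.columns[1] != "length_bp":
        raise DataValidationError(
            "counts file must start with columns transcript_id, length_bp; "
            f"got {list(df.columns[:2])}"
        )
    df = df.set_index("transcript_id")
    lengths = pd.to_numeric(df["length_bp"], errors="coerce")
    if lengths.isna().any():
        bad = df.index[lengths.isna()][0]
        raise DataValidationError(f"non-numeric length_bp for transcript {bad!r}")
    raw = df.drop(columns="length_bp")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise DataValidationError(
            f"non-numeric count at transcript {numeric.index[r]!r}, sample {numeric.columns[c]!r}"
        )
    frac = numeric != np.floor(numeric)
    if frac.any().any():
        r, c = np.argwhere(frac.values)[0]
        raise DataValidationError(
            f"non-integer count {numeric.iloc[r, c]} at transcript "
            f"{numeric.index[r]!r}, sample {numeric.columns[c]!r}"
        )
    return CountMatrix(
        counts=numeric.astype(np.int64),
        lengths_bp=lengths.astype(int),
        samples=sheet,
    )


def write_counts(cm: CountMatrix, path: str | Path, sheet_path: str | Path | None = None) -> None:
    out = cm.counts.copy()
    out.insert(0, "length_bp", cm.lengths_bp)
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")
    if sheet_path is not None:
        cm.samples.table.to_csv(sheet_path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationTable:
    return AnnotationTable(pd.read_csv(path, **_READ_KW))


def read_cq(path: str | Path) -> CqTable:
    """Read a long-format Cq TSV with columns gene_id, sample_id, cq."""
    df = pd.read_csv(path, **_READ_KW)
    required = {"gene_id", "sample_id", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise DataValidationError(f"Cq table missing columns: {sorted(missing)}")
    if df.empty:
        raise DataValidationError("Cq table is empty")
    cq = pd.to_numeric(df["cq"], errors="coerce")
    if cq.isna().any():
        raise DataValidationError("non-numeric cq value in Cq table")
    cells: dict[tuple[str, str], list[float]] = {}
    for gene, sample, value in zip(df["gene_id"], df["sample_id"], cq):
        cells.setdefault((gene, sample), []).append(float(value))
    return CqTable(cells)


def write_cq(cq: CqTable, path: str | Path) -> None:
    rows = [
        {"gene_id": gene, "sample_id": sample, "cq": value}
        for (gene, sample), reps in cq.cells.items()
        for value in reps
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_expression(
    path: str | Path, sheet_path: str | Path, measure: str
) -> ExpressionMatrix:
    sheet = read_sample_sheet(sheet_path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(values=df[sheet.sample_ids].astype(float), measure=measure, samples=sheet)
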