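"""Data model, file I/O and detection QC for NPX-style multiplex protein panels.

NPX (normalized protein expression) values are relative abundances on a log2
scale: a one-unit difference is a two-fold concentration difference, and values
are comparable between samples but carry no absolute unit. Each protein has a
limit of detection (LOD) on the same scale; measurements below it are retained
as reported but flagged, never imputed or dropped.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "STAGES",
    "PanelDefinition",
    "NPXMatrix",
    "SampleMetadata",
    "QCDetectionSummary",
    "CohortParseError",
    "read_cohort",
    "write_cohort",
    "qc_detection",
    "round_half_away",
]

#: Valid disease-group labels: lung adenocarcinoma, benign (non-malignant)
#: lung disease, colorectal-cancer lung metastasis, typical carcinoid.
GROUPS: tuple[str, ...] = ("LAC", "benign", "CRC_met", "carcinoid")

#: Tumor stages recorded for LAC samples ("NA" = stage not available).
STAGES: tuple[str, ...] = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB", "IV", "NA")

#: Metadata columns in their on-disk order.
METADATA_COLUMNS = ("sample_id", "group", "stage", "inflammatory", "sex", "age_gt_70", "smoker")


class CohortParseError(ValueError):
    """Raised when an input table violates the cohort file contract."""


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round with halves away from zero (the convention of clinical tables).

    numpy's default rounds half to even, which would turn 0.625 into 0.62;
    published diagnostic tables round 0.625 to 0.63.
    """
    if np.isnan(x):
        return float("nan")
    factor = 10.0**decimals
    scaled = x * factor
    # nudge by a few ulp so that values that are exactly .5 after decimal
    # representation error (e.g. 0.445*100 = 44.499999...) still round up
    eps = np.spacing(abs(scaled)) * 4
    return float(np.sign(scaled) * np.floor(abs(scaled) + 0.5 + eps) / factor)


@dataclass(frozen=True)
class PanelDefinition:
    """A multiplex protein panel: the measured proteins and their LODs.

    Parameters
    ----------
    protein_ids:
        Unique protein symbols, in panel order.
    lod:
        Per-protein limit of detection on the NPX (log2) scale. ``-inf``
        disables below-LOD flagging for that protein.
    """

    protein_ids: tuple[str, ...]
    lod: Mapping[str, float]

    def __post_init__(self) -> None:
        ids = tuple(self.protein_ids)
        if not ids:
            raise ValueError("panel must contain at least one protein")
        if len(set(ids)) != len(ids):
            dupes = sorted({p for p in ids if list(ids).count(p) > 1})
            raise ValueError(f"duplicate protein ids in panel: {dupes}")
        object.__setattr__(self, "protein_ids", ids)
        lod = dict(self.lod)
        missing = [p for p in ids if p not in lod]
        if missing:
            raise ValueError(f"panel proteins without LOD: {missing}")
        extra = [p for p in lod if p not in set(ids)]
        if extra:
            raise ValueError(f"LOD entries for unknown proteins: {extra}")
        for p, v in lod.items():
            if np.isnan(v):
                raise ValueError(f"LOD for {p} is NaN")
        object.__setattr__(self, "lod", lod)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def lod_array(self) -> np.ndarray:
        return np.array([self.lod[p] for p in self.protein_ids], dtype=float)


@dataclass
class NPXMatrix:
    """A sample × protein grid of NPX values with below-LOD flags.

    ``values[i, j]`` is the NPX measurement of protein ``protein_ids[j]`` in
    sample ``sample_ids[i]``; ``below_lod[i, j]`` marks measurements under the
    protein's LOD (the reported value is kept).
    """

    sample_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    values: np.ndarray
    below_lod: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.protein_ids = tuple(self.protein_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dup = next(s for s in self.sample_ids if s in seen or seen.add(s))
            raise CohortParseError(f"duplicate sample id in NPX matrix: {dup!r}")
        shape = (len(self.sample_ids), len(self.protein_ids))
        if self.values.shape != shape:
            raise CohortParseError(
                f"NPX value grid has shape {self.values.shape}, expected {shape}"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise CohortParseError(
                f"non-finite NPX value for sample {self.sample_ids[bad[0]]!r}, "
                f"protein {self.protein_ids[bad[1]]!r}"
            )
        if self.below_lod is None:
            self.below_lod = np.zeros(shape, dtype=bool)
        else:
            self.below_lod = np.asarray(self.below_lod, dtype=bool)
            if self.below_lod.shape != shape:
                raise CohortParseError("below_lod grid shape mismatch")

    @classmethod
    def from_values(
        cls,
        sample_ids: Sequence[str],
        protein_ids: Sequence[str],
        values: np.ndarray,
        panel: PanelDefinition | None = None,
    ) -> "NPXMatrix":
        """Build a matrix, deriving below-LOD flags from ``panel`` if given."""
        m = cls(tuple(sample_ids), tuple(protein_ids), np.asarray(values, dtype=float))
        if panel is not None:
            if tuple(panel.protein_ids) != m.protein_ids:
                raise CohortParseError("panel protein order does not match matrix columns")
            m.below_lod = m.values < panel.lod_array()[np.newaxis, :]
        return m

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.protein_ids))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df

    def column(self, protein_id: str) -> np.ndarray:
        try:
            j = self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"protein {protein_id!r} not in matrix") from None
        return self.values[:, j]

    def subset_samples(self, mask_or_indices) -> "NPXMatrix":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return NPXMatrix(
            tuple(self.sample_ids[i] for i in idx),
            self.protein_ids,
            self.values[idx],
            self.below_lod[idx],
        )


@dataclass
class SampleMetadata:
    """Per-sample clinical annotations, aligned to an :class:`NPXMatrix`.

    Wraps a DataFrame with columns ``sample_id, group, stage, inflammatory,
    sex, age_gt_70, smoker``. ``stage`` is present only for LAC samples and
    ``inflammatory`` only for benign samples; other cells are missing (NA).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[list(METADATA_COLUMNS)].reset_index(drop=True)
        # one missing-value sentinel (pd.NA) regardless of input provenance
        df = df.astype(object).where(df.notna(), pd.NA)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CohortParseError(f"duplicate sample id in metadata: {dup!r}")
        bad_groups = set(df["group"].dropna()) - set(GROUPS)
        if bad_groups:
            raise CohortParseError(f"unknown group labels: {sorted(bad_groups)}")
        staged = df["stage"].notna()
        if (staged & (df["group"] != "LAC")).any():
            sid = df.loc[staged & (df["group"] != "LAC"), "sample_id"].iloc[0]
            raise CohortParseError(f"stage set for non-LAC sample {sid!r}")
        bad_stage = set(df.loc[staged, "stage"]) - set(STAGES)
        if bad_stage:
            raise CohortParseError(f"unknown stage labels: {sorted(bad_stage)}")
        inflam = df["inflammatory"].notna()
        if (inflam & (df["group"] != "benign")).any():
            sid = df.loc[inflam & (df["group"] != "benign"), "sample_id"].iloc[0]
            raise CohortParseError(f"inflammatory flag set for non-benign sample {sid!r}")
        self.df = df

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df["sample_id"])

    def groups(self) -> np.ndarray:
        return self.df["group"].to_numpy()

    def group_mask(self, group: str) -> np.ndarray:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
        return (self.df["group"] == group).to_numpy()

    def reordered(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        """Return a copy whose rows follow ``sample_ids`` order exactly."""
        have = set(self.df["sample_id"])
        want = list(sample_ids)
        missing = [s for s in want if s not in have]
        extra = sorted(have - set(want))
        if missing or extra:
            raise CohortParseError(
                f"metadata/matrix sample mismatch: missing {missing[:5]}, extra {extra[:5]}"
            )
        indexed = self.df.set_index("sample_id")
        return SampleMetadata(indexed.loc[want].reset_index())

    def subset(self, mask_or_indices) -> "SampleMetadata":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SampleMetadata(self.df.iloc[idx].reset_index(drop=True))


@dataclass(frozen=True)
class QCDetectionSummary:
    """Panel-level detection QC.

    A protein is *fully detected* when no sample falls below its LOD; a sample
    is *all-above-LOD* when every protein in it is above LOD. Percentages are
    rounded to the nearest integer, halves away from zero.
    """

    n_proteins_total: int
    n_proteins_fully_detected: int
    pct_proteins_fully_detected: int
    n_samples_total: int
    n_samples_all_above_lod: int
    pct_samples_all_above_lod: int


def qc_detection(matrix: NPXMatrix, panel: PanelDefinition) -> QCDetectionSummary:
    """Summarize how many proteins/samples are fully above the detection limit."""
    if matrix.n_samples == 0 or matrix.n_proteins == 0:
        raise ValueError("cannot run detection QC on an empty matrix")
    if tuple(panel.protein_ids) != matrix.protein_ids:
        raise ValueError("matrix columns do not match panel proteins")
    flagged_per_protein = matrix.below_lod.any(axis=0)
    flagged_per_sample = matrix.below_lod.any(axis=1)
    n_prot_ok = int((~flagged_per_protein).sum())
    n_samp_ok = int((~flagged_per_sample).sum())
    return QCDetectionSummary(
        n_proteins_total=matrix.n_proteins,
        n_proteins_fully_detected=n_prot_ok,
        pct_proteins_fully_detected=int(round_half_away(100.0 * n_prot_ok / matrix.n_proteins)),
        n_samples_total=matrix.n_samples,
        n_samples_all_above_lod=n_samp_ok,
        pct_samples_all_above_lod=int(round_half_away(100.0 * n_samp_ok / matrix.n_samples)),
    )


def _read_table(path) -> pd.DataFrame:
    """Read a CSV/TSV table, sniffing the delimiter from the extension/content."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    sep = "\t" if ("\t" in text.splitlines()[0] if text else False) else ","
    if path.suffix.lower() in {".tsv", ".tab"}:
        sep = "\t"
    # round_trip parsing: NPX values must survive write→read bit-exactly
    return pd.read_csv(
        io.StringIO(text), sep=sep, dtype={"sample_id": str}, float_precision="round_trip"
    )


def read_cohort(npx_table_path, metadata_table_path, panel_path):
    """Read an NPX matrix, sample metadata and panel definition from text tables.

    Returns ``(NPXMatrix, SampleMetadata, PanelDefinition)`` with the metadata
    rows reordered to the matrix's sample order and below-LOD flags derived
    from the panel LODs.
    """
    panel_df = _read_table(panel_path)
    for col in ("protein_id", "lod"):
        if col not in panel_df.columns:
            raise CohortParseError(f"panel table missing column {col!r}")
    panel = PanelDefinition(
        tuple(panel_df["protein_id"].astype(str)),
        dict(zip(panel_df["protein_id"].astype(str), panel_df["lod"].astype(float))),
    )

    npx_df = _read_table(npx_table_path)
    if "sample_id" not in npx_df.columns:
        raise CohortParseError("NPX table missing 'sample_id' column")
    missing = [p for p in panel.protein_ids if p not in npx_df.columns]
    if missing:
        raise CohortParseError(f"NPX table missing protein columns: {missing[:5]}")
    value_df = npx_df[list(panel.protein_ids)]
    numeric = value_df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise CohortParseError(
            f"non-numeric NPX cell at sample {npx_df['sample_id'].iloc[i]!r}, "
            f"protein {panel.protein_ids[j]!r}"
        )
    matrix = NPXMatrix.from_values(
        tuple(npx_df["sample_id"]), panel.protein_ids, numeric.to_numpy(), panel
    )

    meta_df = _read_table(metadata_table_path)
    if "sample_id" not in meta_df.columns:
        raise CohortParseError("metadata table missing 'sample_id' column")
    if "inflammatory" in meta_df.columns:
        meta_df["inflammatory"] = meta_df["inflammatory"].map(
            {True: True, False: False, "True": True, "False": False, 1: True, 0: False}
        )
    metadata = SampleMetadata(meta_df).reordered(matrix.sample_ids)
    return matrix, metadata, panel


def write_cohort(matrix: NPXMatrix, metadata: SampleMetadata, panel: PanelDefinition, out_dir):
    """Write the cohort triple as TSV files; returns the three paths.

    Values are written with ``repr`` round-trip precision so a read-back
    reproduces the matrix bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    npx_path = out / "npx.tsv"
    meta_path = out / "metadata.tsv"
    panel_path = out / "panel.tsv"
    matrix.to_frame().to_csv(npx_path, sep="\t", index=False, float_format="%.17g")
    metadata.df.to_csv(meta_path, sep="\t", index=False)
    pd.DataFrame(
        {"protein_id": list(panel.protein_ids), "lod": [panel.lod[p] for p in panel.protein_ids]}
    ).to_csv(panel_path, sep="\t", index=False, float_format="%.17g")
    return npx_path, meta_path, panel_path
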