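"""Domain containers and tab-separated I/O shared by all pipeline stages.

Three tabular objects travel through the pipeline:

* :class:`ProbeMatrix` — a probes x samples value matrix with a declared
  scale (``beta`` values in [0, 1], logit2 ``mvalue``, or ``expression``).
* :class:`SampleSheet` — per-sample metadata: group, age, colon location,
  batch, lifestyle flags, and lesion<->normal pairing.
* :class:`ProbeAnnotation` — probe -> chromosome / position / gene / CGI
  relation, as in Infinium array manifests (1-based coordinates).

All files are UTF-8, tab-separated, with ``NA`` for missing values,
matching GEO series-matrix conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

SCALES = ("beta", "mvalue", "expression")

GROUPS = ("HNM", "nonCIMP_CC", "CIMP_CC", "TA", "SSAP", "paired_normal")

#: Groups allowed to carry a pair_id linking them to a paired_normal sample.
LESION_GROUPS = ("nonCIMP_CC", "CIMP_CC", "TA", "SSAP")

TRISTATE = ("yes", "no", "unknown")

LOCATIONS = ("proximal", "distal")

SEX_CHROMS = frozenset({"X", "Y", "chrX", "chrY"})

SHEET_COLUMNS = (
    "sample_id",
    "group",
    "age",
    "location",
    "batch",
    "aspirin_user",
    "hrt_user",
    "pair_id",
)

ANNOTATION_COLUMNS = ("probe_id", "chrom", "position", "gene_symbols", "cgi_relation")


class MatrixFormatError(ValueError):
    """Raised for structurally malformed (e.g. ragged) tabular input."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


def _check_rectangular(path: str | Path) -> None:
    widths = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip() == "":
                continue
            widths.add(line.rstrip("\n").count("\t"))
    if len(widths) > 1:
        raise MatrixFormatError(f"{path}: ragged rows (field counts {sorted(widths)})")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    _check_rectangular(path)
    return pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False, dtype_backend="numpy_nullable"
    )


@dataclass
class ProbeMatrix:
    """Probes x samples real matrix with missing values allowed (NaN).

    Parameters
    ----------
    probe_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    values
        Float array of shape ``(len(probe_ids), len(sample_ids))``.
    scale
        One of ``beta``, ``mvalue``, ``expression``.  Beta values outside
        [0, 1] are rejected at construction.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.ndim != 2 or self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("probe ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids are not unique")
        if self.scale == "beta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
                raise ValidationError("beta matrix contains values outside [0, 1]")

    # -- indexing -------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probes: Iterable[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        try:
            return np.array([lookup[p] for p in probes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"probe {exc.args[0]!r} not in matrix") from None

    def sample_index(self, samples: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in samples], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None

    def subset(self, probes: Sequence[str] | None = None, samples: Sequence[str] | None = None) -> "ProbeMatrix":
        rows = self.probe_index(probes) if probes is not None else np.arange(self.n_probes)
        cols = self.sample_index(samples) if samples is not None else np.arange(self.n_samples)
        return ProbeMatrix(
            [self.probe_ids[i] for i in rows],
            [self.sample_ids[j] for j in cols],
            self.values[np.ix_(rows, cols)],
            self.scale,
        )

    # -- conversion -----------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, scale: str) -> "ProbeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float), scale)

    # -- I/O ------------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path, expected_scale: str) -> "ProbeMatrix":
        """Read a probes x samples TSV (first column probe ids, header sample ids)."""
        _check_rectangular(path)
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise MatrixFormatError(f"{path}: non-numeric matrix entry ({exc})") from None
        return cls([str(i) for i in df.index], [str(c) for c in df.columns], values, expected_scale)

    def write(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "probe_id"
        df.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class SampleSheet:
    """Per-sample metadata table.

    Columns: sample_id, group, age (years; may be missing for non-HNM),
    location (proximal/distal), batch, aspirin_user / hrt_user
    (yes/no/unknown), pair_id (links one lesion to one paired_normal).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df[list(SHEET_COLUMNS)]
        df["sample_id"] = df["sample_id"].astype(str)
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
        if df["sample_id"].duplicated().any():
            raise ValidationError("sample ids are not unique")
        bad_groups = set(df["group"].dropna()) - set(GROUPS)
        if bad_groups:
            raise ValidationError(f"unknown groups: {sorted(bad_groups)}")
        ages = df["age"].dropna()
        if len(ages) and (not np.isfinite(ages).all() or (ages < 0).any() or (ages >= 130).any()):
            raise ValidationError("ages must be finite, nonnegative and < 130")
        bad_loc = set(df["location"].dropna()) - set(LOCATIONS)
        if bad_loc:
            raise ValidationError(f"unknown locations: {sorted(bad_loc)}")
        for col in ("aspirin_user", "hrt_user"):
            bad = set(df[col].dropna()) - set(TRISTATE)
            if bad:
                raise ValidationError(f"{col}: values outside yes/no/unknown: {sorted(bad)}")
        self._check_pairs(df)
        self.data = df.reset_index(drop=True)

    @staticmethod
    def _check_pairs(df: pd.DataFrame) -> None:
        paired = df[df["pair_id"].notna()]
        for pid, grp in paired.groupby("pair_id"):
            groups = sorted(grp["group"])
            if len(grp) != 2 or "paired_normal" not in groups:
                raise ValidationError(
                    f"pair_id {pid!r} must link exactly one lesion sample to one "
                    f"paired_normal sample (got groups {groups})"
                )
            other = [g for g in groups if g != "paired_normal"]
            if len(other) != 1 or other[0] not in LESION_GROUPS:
                raise ValidationError(f"pair_id {pid!r}: lesion side has group {other}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def subset(self, samples: Sequence[str]) -> "SampleSheet":
        df = self.data.set_index("sample_id").loc[list(samples)].reset_index()
        return SampleSheet(df)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.data.loc[self.data["group"] == group, "sample_id"])

    def pairs(self, lesion_group: str) -> list[tuple[str, str]]:
        """(lesion_sample, normal_sample) tuples for a lesion group."""
        df = self.data[self.data["pair_id"].notna()]
        out = []
        for pid, grp in df.groupby("pair_id"):
            by_group = grp.set_index("group")["sample_id"]
            if lesion_group in by_group.index:
                out.append((by_group[lesion_group], by_group["paired_normal"]))
        return sorted(out)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = _read_tsv(path)
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        return cls(df.astype(object).where(df.notna(), np.nan))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")


@dataclass
class ProbeAnnotation:
    """Probe -> chrom / 1-based position / gene symbols / CGI relation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"probe annotation missing columns: {missing}")
        df = df[list(ANNOTATION_COLUMNS)]
        df["probe_id"] = df["probe_id"].astype(str)
        if df["probe_id"].duplicated().any():
            raise ValidationError("annotation probe ids are not unique")
        df["position"] = pd.to_numeric(df["position"], errors="raise").astype(int)
        if (df["position"] < 1).any():
            raise ValidationError("positions must be >= 1 (1-based manifest coordinates)")
        self.data = df.reset_index(drop=True)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data["probe_id"])

    def chrom_of(self) -> Mapping[str, str]:
        return dict(zip(self.data["probe_id"], self.data["chrom"]))

    @classmethod
    def read(cls, path: str | Path) -> "ProbeAnnotation":
        return cls(_read_tsv(path))

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_bed(self, path: str | Path, probes: Iterable[str] | None = None) -> None:
        """BED export (chrom, 0-based start, end, probe_id) for interoperability."""
        df = self.data
        if probes is not None:
            wanted = set(probes)
            df = df[df["probe_id"].isin(wanted)]
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in df.iterrows():
                fh.write(f"{row.chrom}\t{row.position - 1}\t{row.position}\t{row.probe_id}\n")


# ---------------------------------------------------------------------------
# Filtering / alignment


class FilterResult(NamedTuple):
    matrix: ProbeMatrix
    log: dict


def filter_probes(
    matrix: ProbeMatrix,
    annotation: ProbeAnnotation | None = None,
    drop_sex_chroms: bool = False,
    max_missing_fraction: float = 1.0,
    on_missing_annotation: str = "error",
) -> FilterResult:
    """Drop sex-chromosome probes and probes with excessive missingness.

    Missingness stands in for detection-p filtering of poor-signal probes;
    this pipeline consumes processed beta values, not raw intensities.

    ``on_missing_annotation`` controls what happens when ``drop_sex_chroms``
    is on and a probe is absent from the annotation: ``"error"`` raises,
    ``"keep"`` warns-and-keeps (recorded in the log).
    """
    if on_missing_annotation not in ("error", "keep"):
        raise ValueError("on_missing_annotation must be 'error' or 'keep'")
    keep = np.ones(matrix.n_probes, dtype=bool)
    log: dict = {"input_probes": matrix.n_probes}

    if drop_sex_chroms:
        if annotation is None:
            raise ValidationError("drop_sex_chroms requires a probe annotation")
        chrom = annotation.chrom_of()
        unannotated = [p for p in matrix.probe_ids if p not in chrom]
        if unannotated:
            if on_missing_annotation == "error":
                raise ValidationError(
                    f"{len(unannotated)} probes missing from annotation (e.g. {unannotated[0]!r})"
                )
            log["unannotated_kept"] = len(unannotated)
        sex = np.array([chrom.get(p) in SEX_CHROMS for p in matrix.probe_ids])
        log["removed_sex_chrom"] = int((keep & sex).sum())
        keep &= ~sex

    if max_missing_fraction < 1.0:
        frac_missing = np.isnan(matrix.values).mean(axis=1)
        high = frac_missing > max_missing_fraction
        log["removed_missingness"] = int((keep & high).sum())
        keep &= ~high

    out = matrix.subset(probes=[p for p, k in zip(matrix.probe_ids, keep) if k])
    log["output_probes"] = out.n_probes
    return FilterResult(out, log)


def align_samples(matrix: ProbeMatrix, sheet: SampleSheet) -> tuple[ProbeMatrix, SampleSheet, dict]:
    """Restrict matrix and sheet to their shared samples, in matrix order."""
    in_sheet = set(sheet.sample_ids)
    shared = [s for s in matrix.sample_ids if s in in_sheet]
    if not shared:
        raise ValidationError("matrix and sample sheet share no samples")
    log = {
        "dropped_from_matrix": matrix.n_samples - len(shared),
        "dropped_from_sheet": len(in_sheet) - len(shared),
        "aligned_samples": len(shared),
    }
    return matrix.subset(samples=shared), sheet.subset(shared), log


def write_probe_list(probes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in sorted(probes):
            fh.write(f"{p}\n")


def read_probe_list(path: str | Path) -> set[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}
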