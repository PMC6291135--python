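"""Data model, TSV readers/writers, validation, and the probe-filtering stage.

The central container is :class:`BetaDataset`: a sites x samples matrix of
methylation beta-values (fractions in [0, 1]) together with per-site genomic
annotations and a sample sheet describing the paired design
(subjects x extraction methods).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BetaDataset",
    "FilterSpec",
    "FilterReport",
    "DatasetValidationError",
    "read_beta_dataset",
    "write_beta_dataset",
    "filter_sites",
]

ANNOTATION_COLUMNS = ["site_id", "chrom", "pos", "context"]
SAMPLESHEET_COLUMNS = [
    "sample_id",
    "subject_id",
    "method",
    "chip_position",
    "yield_ug",
    "a260_280",
    "a260_230",
]
CONTEXTS = {"cpg", "non_cpg"}


class DatasetValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass
class BetaDataset:
    """Sites x samples beta matrix with site annotations and a sample sheet.

    Attributes
    ----------
    betas
        DataFrame indexed by ``site_id`` with one float column per
        ``sample_id``. Values must lie in [0, 1]; NaN is allowed before
        filtering.
    sites
        DataFrame indexed by ``site_id`` with columns ``chrom`` (str),
        ``pos`` (1-based int) and ``context`` ("cpg" or "non_cpg").
    samples
        DataFrame indexed by ``sample_id`` with columns ``subject_id``,
        ``method``, ``chip_position``, ``yield_ug``, ``a260_280``,
        ``a260_230``. One row per beta-matrix column, in column order.
    """

    betas: pd.DataFrame
    sites: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    @property
    def methods(self) -> list[str]:
        return list(pd.unique(self.samples["method"]))

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.samples["subject_id"]))

    def validate(self) -> None:
        if list(self.betas.index) != list(self.sites.index):
            missing = set(self.betas.index).symmetric_difference(self.sites.index)
            raise DatasetValidationError(
                f"beta-matrix rows and site annotations disagree; "
                f"offending site ids: {sorted(map(str, missing))[:10]}"
            )
        if list(self.betas.columns) != list(self.samples.index):
            missing = set(self.betas.columns).symmetric_difference(self.samples.index)
            raise DatasetValidationError(
                f"beta-matrix columns and sample sheet disagree; "
                f"offending sample ids: {sorted(map(str, missing))[:10]}"
            )
        if self.sites.index.has_duplicates:
            dups = self.sites.index[self.sites.index.duplicated()].unique()
            raise DatasetValidationError(f"duplicate site ids: {list(dups[:10])}")
        if (self.sites["pos"] < 1).any():
            bad = self.sites.index[self.sites["pos"] < 1]
            raise DatasetValidationError(f"positions must be >= 1; offending sites: {list(bad[:10])}")
        bad_ctx = set(self.sites["context"].unique()) - CONTEXTS
        if bad_ctx:
            raise DatasetValidationError(f"unknown site contexts: {sorted(bad_ctx)}")
        pairs = self.samples.reset_index()[["subject_id", "method"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise DatasetValidationError(
                f"(subject_id, method) must be unique; duplicate: ({dup.subject_id}, {dup.method})"
            )
        vals = self.betas.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            out = (vals < 0.0) | (vals > 1.0)
        if out.any():
            i, j = np.argwhere(out)[0]
            raise DatasetValidationError(
                f"beta value {vals[i, j]} outside [0, 1] at site "
                f"{self.betas.index[i]!r}, sample {self.betas.columns[j]!r}"
            )

    def has_missing(self) -> bool:
        return bool(self.betas.isna().any().any())

    def require_complete_design(self, method1: str, method2: str) -> list[str]:
        """Return subject ids ordered as in the sample sheet; raise if any
        subject lacks either method."""
        for m in (method1, method2):
            if m not in self.methods:
                raise DatasetValidationError(f"method {m!r} not present (have {self.methods})")
        by_subject = self.samples.groupby("subject_id", sort=False)["method"].apply(set)
        incomplete = [s for s, ms in by_subject.items() if not {method1, method2} <= ms]
        if incomplete:
            raise DatasetValidationError(
                f"subjects missing a method for pair ({method1}, {method2}): {incomplete}"
            )
        return list(by_subject.index)

    def method_matrix(self, method: str, subjects: list[str] | None = None) -> pd.DataFrame:
        """Sites x subjects matrix for one extraction method."""
        sel = self.samples[self.samples["method"] == method]
        if sel.empty:
            raise DatasetValidationError(f"method {method!r} not present")
        sel = sel.reset_index().set_index("subject_id")
        if subjects is None:
            subjects = list(sel.index)
        cols = sel.loc[subjects, "sample_id"]
        mat = self.betas[list(cols)]
        mat.columns = list(subjects)
        return mat

    def subset_sites(self, keep: pd.Index | np.ndarray) -> "BetaDataset":
        return BetaDataset(self.betas.loc[keep], self.sites.loc[keep], self.samples)


@dataclass
class FilterSpec:
    """Site-removal rules, applied in the fixed order
    blacklist -> detection -> non-CpG -> missing -> chromosome."""

    detection_p: pd.DataFrame | None = None
    detection_threshold: float = 0.01
    blacklist_ids: frozenset[str] = field(default_factory=frozenset)
    drop_non_cpg: bool = True
    drop_missing: bool = True
    drop_chroms: frozenset[str] = frozenset({"chrX", "chrY"})

    def __post_init__(self) -> None:
        if not (0.0 < self.detection_threshold < 1.0):
            raise ValueError("detection_threshold must lie in (0, 1)")
        self.blacklist_ids = frozenset(self.blacklist_ids)
        self.drop_chroms = frozenset(self.drop_chroms)


@dataclass
class FilterReport:
    """Per-category removal counts; each site is counted once, under the
    first rule (in application order) that removes it."""

    counts: dict[str, int]
    n_input: int
    n_retained: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"counts": self.counts, "n_input": self.n_input, "n_retained": self.n_retained},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def filter_sites(ds: BetaDataset, spec: FilterSpec) -> tuple[BetaDataset, FilterReport]:
    """Remove sites by the rules in *spec*, reporting exclusive counts.

    Order: blacklist, detection p-value (any sample above threshold),
    non-CpG context, missing beta value, excluded chromosome. A site failing
    several rules is counted once under the first.
    """
    if spec.detection_p is not None:
        if spec.detection_p.shape != ds.betas.shape:
            raise DatasetValidationError(
                f"detection_p shape {spec.detection_p.shape} != betas shape {ds.betas.shape}"
            )

    removed_by = pd.Series("", index=ds.betas.index, dtype=object)

    def _mark(mask: np.ndarray, label: str) -> None:
        new = mask & (removed_by == "").to_numpy()
        removed_by.iloc[np.flatnonzero(new)] = label

    if spec.blacklist_ids:
        _mark(ds.betas.index.isin(spec.blacklist_ids), "blacklist")
    if spec.detection_p is not None:
        bad = (spec.detection_p.to_numpy(dtype=float) > spec.detection_threshold).any(axis=1)
        _mark(bad, "detection")
    if spec.drop_non_cpg:
        _mark((ds.sites["context"] == "non_cpg").to_numpy(), "non_cpg")
    if spec.drop_missing:
        _mark(ds.betas.isna().any(axis=1).to_numpy(), "missing")
    if spec.drop_chroms:
        _mark(ds.sites["chrom"].isin(spec.drop_chroms).to_numpy(), "chromosome")

    keep = removed_by == ""
    counts = {
        cat: int((removed_by == cat).sum())
        for cat in ["blacklist", "detection", "non_cpg", "missing", "chromosome"]
    }
    if not keep.any():
        raise DatasetValidationError("no sites retained after filtering")
    out = ds.subset_sites(ds.betas.index[keep])
    report = FilterReport(counts=counts, n_input=ds.n_sites, n_retained=out.n_sites)
    return out, report


# -- TSV round trip --------------------------------------------------------

def read_beta_dataset(
    beta_path: str | Path,
    annotation_path: str | Path,
    samplesheet_path: str | Path,
) -> BetaDataset:
    """Read a dataset from three TSV files.

    The beta matrix has ``site_id`` as first column and one column per
    sample; missing values may be encoded as empty fields or ``NA``.
    Sample columns are matched to the sample sheet by ``sample_id``.
    """
    betas = pd.read_csv(beta_path, sep="\t", index_col=0, na_values=["NA", ""])
    non_num = [c for c in betas.columns if not np.issubdtype(betas[c].dtype, np.number)]
    if non_num:
        raise DatasetValidationError(f"non-numeric beta columns: {non_num}")
    sites = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    missing_cols = set(ANNOTATION_COLUMNS) - set(sites.columns)
    if missing_cols:
        raise DatasetValidationError(f"annotation lacks columns: {sorted(missing_cols)}")
    sites = sites.set_index("site_id")
    samples = pd.read_csv(samplesheet_path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing_cols = set(SAMPLESHEET_COLUMNS) - set(samples.columns)
    if missing_cols:
        raise DatasetValidationError(f"sample sheet lacks columns: {sorted(missing_cols)}")
    samples = samples.set_index("sample_id")

    unmatched = [c for c in betas.columns if c not in samples.index]
    if unmatched:
        raise DatasetValidationError(
            f"beta-matrix columns absent from sample sheet: {unmatched}"
        )
    extra = [s for s in samples.index if s not in betas.columns]
    if extra:
        raise DatasetValidationError(f"sample-sheet rows absent from beta matrix: {extra}")
    samples = samples.loc[list(betas.columns)]

    missing_sites = [s for s in betas.index if s not in sites.index]
    if missing_sites:
        raise DatasetValidationError(
            f"beta-matrix sites absent from annotation: {missing_sites[:10]}"
        )
    sites = sites.loc[list(betas.index)]
    return BetaDataset(betas=betas, sites=sites, samples=samples)


def write_beta_dataset(ds: BetaDataset, out_dir: str | Path, prefix: str = "dataset") -> dict[str, Path]:
    """Write the three TSVs; values at full (repr) precision so that
    read(write(ds)) round-trips bit-exactly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": out / f"{prefix}_betas.tsv",
        "annotation": out / f"{prefix}_annotation.tsv",
        "samplesheet": out / f"{prefix}_samples.tsv",
    }
    ds.betas.to_csv(paths["betas"], sep="\t", index_label="site_id", float_format="%.17g", na_rep="NA")
    ds.sites.to_csv(paths["annotation"], sep="\t", index_label="site_id")
    ds.samples.to_csv(paths["samplesheet"], sep="\t", index_label="sample_id")
    return paths
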