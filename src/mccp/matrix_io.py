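"""Reading, validation, transformation and filtering of quantitation matrices.

The central container is :class:`RatioMatrix`: a proteins x experiments
grid of log2 SILAC ratios with explicit missingness.  Missing cells are
stored as IEEE NaN — a value distinct from every real number — and all
downstream code branches on it explicitly via ``np.isnan``; nothing in
the pipeline imputes.

TSV dialect: tab-separated, UTF-8, '.' decimal, mandatory header row.
The first column holds protein identifiers; an optional final column
named ``abundance`` carries per-protein summed peptide intensities.
The default missing token is "NA"; empty cells are missing too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical missing-cell marker (any NaN compares missing)
MISSING = np.nan

ABUNDANCE_COLUMN = "abundance"


def is_missing(x) -> np.ndarray:
    """Elementwise missingness test for cells of a RatioMatrix."""
    return np.isnan(x)


@dataclass
class RatioMatrix:
    """Proteins x experiments matrix of log2 ratios with explicit missingness.

    Parameters
    ----------
    protein_ids
        Unique protein identifiers, one per row.
    experiment_ids
        Unique experiment labels, one per column.
    values
        float64 array of shape (n_proteins, n_experiments); NaN == missing,
        every non-missing cell must be finite.
    abundance
        Optional per-protein summed intensity (nonnegative, arbitrary units).
    """

    protein_ids: list[str]
    experiment_ids: list[str]
    values: np.ndarray
    abundance: np.ndarray | None = None

    def __post_init__(self):
        self.protein_ids = list(self.protein_ids)
        self.experiment_ids = list(self.experiment_ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            seen = set()
            dup = next(p for p in self.protein_ids if p in seen or seen.add(p))
            raise ValueError(f"duplicate protein id: {dup!r}")
        if len(set(self.experiment_ids)) != len(self.experiment_ids):
            raise ValueError("duplicate experiment ids")
        if self.values.shape != (len(self.protein_ids), len(self.experiment_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.experiment_ids)} experiments"
            )
        if np.isinf(self.values).any():
            raise ValueError("non-missing cells must be finite (found +/-inf)")
        if self.abundance is not None:
            self.abundance = np.asarray(self.abundance, dtype=np.float64)
            if self.abundance.shape != (len(self.protein_ids),):
                raise ValueError("abundance length does not match protein count")
            if np.any(self.abundance < 0):
                raise ValueError("abundance must be nonnegative")
        self._index = {p: i for i, p in enumerate(self.protein_ids)}

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_experiments(self) -> int:
        return len(self.experiment_ids)

    def observed_mask(self) -> np.ndarray:
        """Boolean mask, True where a cell holds a value."""
        return ~np.isnan(self.values)

    def observation_counts(self) -> np.ndarray:
        """Per-protein number of non-missing cells (the feature count)."""
        return self.observed_mask().sum(axis=1)

    def row_index(self, ids) -> np.ndarray:
        """Row positions of the given protein ids (KeyError if absent)."""
        return np.array([self._index[p] for p in ids], dtype=np.int64)

    def subset_rows(self, keep: np.ndarray) -> "RatioMatrix":
        """New matrix restricted to the given row positions, order preserved."""
        ab = self.abundance[keep] if self.abundance is not None else None
        return RatioMatrix(
            [self.protein_ids[i] for i in keep],
            list(self.experiment_ids),
            self.values[keep],
            abundance=ab,
        )


def read_ratio_matrix(path, missing_token: str = "NA") -> RatioMatrix:
    """Read a ratio matrix TSV.

    First column: protein id; header row: experiment labels; optional final
    column ``abundance``.  Cells equal to *missing_token* or empty become
    missing.  Duplicate ids and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus at least one experiment")
    id_col = df.columns[0]
    ids = df[id_col].tolist()
    dups = df[id_col][df[id_col].duplicated()]
    if len(dups):
        raise ValueError(f"duplicate protein id: {dups.iloc[0]!r}")

    exp_cols = list(df.columns[1:])
    abundance = None
    if exp_cols and exp_cols[-1] == ABUNDANCE_COLUMN:
        exp_cols = exp_cols[:-1]
        abundance = _parse_numeric_block(df, [ABUNDANCE_COLUMN], ids, missing_token)[:, 0]
    values = _parse_numeric_block(df, exp_cols, ids, missing_token)
    return RatioMatrix(ids, exp_cols, values, abundance=abundance)


def _parse_numeric_block(df, cols, ids, missing_token):
    raw = df[cols].to_numpy(dtype=object)
    blank = (raw == missing_token) | (raw == "")
    out = pd.DataFrame(df[cols]).replace({missing_token: np.nan, "": np.nan})
    num = out.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    bad = np.isnan(num) & ~blank
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric cell {raw[r, c]!r} at row {ids[r]!r}, column {cols[c]!r}"
        )
    return num


def write_ratio_matrix(m: RatioMatrix, path, missing_token: str = "NA") -> None:
    """Write a matrix back to the TSV dialect read_ratio_matrix accepts."""
    df = pd.DataFrame(m.values, columns=m.experiment_ids)
    df.insert(0, "protein_id", m.protein_ids)
    if m.abundance is not None:
        df[ABUNDANCE_COLUMN] = m.abundance
    df.to_csv(path, sep="\t", index=False, na_rep=missing_token)


def filter_min_observations(m: RatioMatrix, min_obs: int) -> RatioMatrix:
    """Keep exactly the proteins quantified in >= min_obs experiments.

    Row order and the experiment list are preserved.  The study's setting
    is min_obs = 10 of 45 ratio columns.
    """
    if not 0 <= min_obs <= m.n_experiments:
        raise ValueError(
            f"min_obs={min_obs} outside [0, {m.n_experiments}] experiments"
        )
    keep = np.flatnonzero(m.observation_counts() >= min_obs)
    return m.subset_rows(keep)


def log_transform(m: RatioMatrix, base: float = 2.0) -> RatioMatrix:
    """Log-transform raw (multiplicative) ratios.

    Non-missing cells x > 0 become log_base(x); cells <= 0 are demoted to
    missing and their count is logged as a warning.  Missing stays missing.
    """
    if base <= 1:
        raise ValueError("base must be > 1")
    vals = m.values.copy()
    obs = ~np.isnan(vals)
    nonpos = obs & (vals <= 0)
    n_demoted = int(nonpos.sum())
    if n_demoted:
        logger.warning(
            "log_transform: %d non-positive cell(s) demoted to missing", n_demoted
        )
        vals[nonpos] = np.nan
    ok = ~np.isnan(vals)
    vals[ok] = np.log(vals[ok]) / np.log(base)
    return RatioMatrix(m.protein_ids, m.experiment_ids, vals, abundance=m.abundance)


def median_center(m: RatioMatrix) -> RatioMatrix:
    """Optional per-experiment median centering (off by default upstream)."""
    med = np.nanmedian(m.values, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    return RatioMatrix(
        m.protein_ids, m.experiment_ids, m.values - med, abundance=m.abundance
    )


@dataclass
class CatalogEntry:
    locations: set[str]
    annotation_score: int | None = None

    def __post_init__(self):
        if self.annotation_score is not None and not 0 <= self.annotation_score <= 5:
            raise ValueError(f"annotation score {self.annotation_score} outside [0, 5]")


@dataclass
class AnnotationCatalog:
    """Per-protein subcellular localization labels with evidence scores.

    Models a localization database snapshot (Uniprot subcellular location,
    GO cellular component, MitoCarta, Human Protein Atlas, ...): a map from
    protein id to a set of location labels plus an optional 0-5 annotation
    score, tagged with the catalog's name.
    """

    entries: dict[str, CatalogEntry] = field(default_factory=dict)
    source: str = ""

    def __len__(self):
        return len(self.entries)

    def __contains__(self, pid):
        return pid in self.entries

    def has_label(self, pid: str, label: str) -> bool:
        """True if the protein carries the label (case-insensitive)."""
        e = self.entries.get(pid)
        if e is None:
            return False
        lab = label.lower()
        return any(loc.lower() == lab for loc in e.locations)

    def ids_with_label(self, label: str) -> set[str]:
        return {p for p in self.entries if self.has_label(p, label)}


def read_annotation_catalog(path, source_name: str = "") -> AnnotationCatalog:
    """Read a catalog TSV: ``protein_id<TAB>locations[<TAB>score]``.

    Locations are ';'-separated; the score column is optional and may be
    empty per row.  A malformed score is a hard error naming the row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need id and locations columns")
    entries: dict[str, CatalogEntry] = {}
    has_score = df.shape[1] >= 3
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = row[0]
        if pid in entries:
            raise ValueError(f"duplicate protein id {pid!r} in catalog {path}")
        locs = {s.strip() for s in str(row[1]).split(";") if s.strip()}
        score = None
        if has_score:
            raw = str(row[2]).strip()
            if raw:
                try:
                    score = int(raw)
                except ValueError:
                    raise ValueError(
                        f"malformed annotation score {raw!r} at row {row_no} of {path}"
                    ) from None
        entries[pid] = CatalogEntry(locations=locs, annotation_score=score)
    return AnnotationCatalog(entries=entries, source=source_name or str(path))


def write_annotation_catalog(catalog: AnnotationCatalog, path) -> None:
    rows = [
        {
            "protein_id": pid,
            "locations": ";".join(sorted(e.locations)),
            "score": "" if e.annotation_score is None else e.annotation_score,
        }
        for pid, e in catalog.entries.items()
    ]
    pd.DataFrame(rows, columns=["protein_id", "locations", "score"]).to_csv(
        path, sep="\t", index=False
    )
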