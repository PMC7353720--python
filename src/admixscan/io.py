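"""Containers and readers/writers for local-ancestry matrices, bin manifests,
genetic maps and exclusion annotations.

Conventions
-----------
* Physical coordinates are 1-based inclusive bp spans; BED input (0-based
  half-open) is converted on load.
* Local ancestry is diploid African-allele dosage in {0, 1, 2} (float columns
  are accepted as long as values lie in [0, 2]).
* Genetic positions are in centiMorgans, taken from the map marker nearest a
  bin's physical midpoint ("middle marker" convention).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

MANIFEST_COLUMNS = ["bin_id", "chrom", "start_bp", "end_bp", "mid_bp", "mid_cM"]

_FLOAT_FMT = "%.17g"


@dataclass
class BinManifest:
    """Genomic bin coordinates with representative-marker positions.

    ``table`` has columns bin_id, chrom, start_bp, end_bp, mid_bp, mid_cM;
    bins are sorted and non-overlapping within each chromosome and mid_cM is
    non-decreasing along a chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"bin manifest missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"].astype(str)))

    @property
    def n_bins(self) -> int:
        return len(self.table)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.table["bin_id"])

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        sub = self.table[self.table["chrom"].astype(str) == str(chrom)]
        return sub.reset_index(drop=True)

    def validate(self) -> None:
        """Raise DataError on any violated manifest invariant."""
        if self.table["bin_id"].duplicated().any():
            raise DataError("duplicate bin_id in manifest")
        for chrom in self.chroms:
            sub = self.for_chrom(chrom)
            start = sub["start_bp"].to_numpy()
            end = sub["end_bp"].to_numpy()
            if np.any(end < start):
                raise DataError(f"chrom {chrom}: bin with end_bp < start_bp")
            if np.any(start[1:] <= end[:-1]):
                raise DataError(f"chrom {chrom}: overlapping or unsorted bins")
            cm = sub["mid_cM"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise DataError(f"chrom {chrom}: mid_cM not non-decreasing")

    def distances_cM(self, chrom: str) -> np.ndarray:
        """Pairwise genetic distance matrix |cM_i - cM_j| for one chromosome."""
        cm = self.for_chrom(chrom)["mid_cM"].to_numpy(dtype=float)
        return np.abs(cm[:, None] - cm[None, :])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path) -> "BinManifest":
        table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(table)


@dataclass
class LocalAncestryMatrix:
    """Diploid African-ancestry dosage, individuals x bins.

    ``dosage`` is a DataFrame indexed by sample_id with one column per bin_id.
    """

    dosage: pd.DataFrame
    cohort_label: str = ""

    def __post_init__(self) -> None:
        values = self.dosage.to_numpy()
        if values.size and (np.isnan(values).any()):
            raise DataError("missing dosage entries are not allowed")
        if values.size and (values.min() < 0 or values.max() > 2):
            raise DataError("dosage values must lie in [0, 2]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosage.index)

    @property
    def bin_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def n_samples(self) -> int:
        return len(self.dosage)

    def ancestry_proportions(self) -> pd.Series:
        """Genome-wide African ancestry proportion per sample (mean dosage / 2)."""
        return self.dosage.mean(axis=1) / 2.0

    def check_manifest(self, manifest: BinManifest) -> None:
        if list(self.dosage.columns) != manifest.bin_ids:
            raise DataError("matrix bin_ids do not match manifest")

    def to_tsv(self, path) -> None:
        out = self.dosage.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)

    @classmethod
    def from_tsv(cls, path, cohort_label: str = "") -> "LocalAncestryMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, cohort_label=cohort_label)


@dataclass
class ExclusionAnnotation:
    """Telomere/centromere intervals per chromosome, 1-based inclusive bp."""

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start_bp", "end_bp"])
    )

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and (iv["start_bp"] > iv["end_bp"]).any():
            raise DataError("exclusion interval with start > end")

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"].astype(str) == str(chrom)]

    @classmethod
    def from_bed(cls, path) -> "ExclusionAnnotation":
        bed = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={0: str},
        )
        # BED 0-based half-open -> 1-based inclusive
        out = pd.DataFrame(
            {
                "chrom": bed["chrom"].astype(str),
                "start_bp": bed["start"].astype(int) + 1,
                "end_bp": bed["end"].astype(int),
            }
        )
        return cls(out)


def read_genetic_map(path) -> pd.DataFrame:
    """Read a PLINK .map-style file: chrom, marker_id, cM, bp (whitespace-separated)."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        comment="#",
        names=["chrom", "marker_id", "cM", "bp"],
        dtype={0: str},
    )
    df["chrom"] = df["chrom"].astype(str)
    df["cM"] = df["cM"].astype(float)
    df["bp"] = df["bp"].astype(int)
    return df


def make_bins(genetic_map: pd.DataFrame, bin_size_bp: int) -> BinManifest:
    """Divide each chromosome into fixed-width bp bins with a middle-marker representative.

    Consecutive ``bin_size_bp`` windows start at bp 1.  A bin's representative
    is the map marker inside the bin nearest the bin's physical midpoint (ties
    broken toward the smaller bp); bins containing no marker are dropped.  The
    representative's bp and cM become the bin's mid_bp and mid_cM.
    """
    if bin_size_bp <= 0:
        raise DataError("bin_size_bp must be positive")
    rows = []
    chrom_order = list(dict.fromkeys(genetic_map["chrom"].astype(str)))
    for chrom in chrom_order:
        sub = genetic_map[genetic_map["chrom"].astype(str) == chrom]
        bp = sub["bp"].to_numpy()
        cm = sub["cM"].to_numpy(dtype=float)
        if np.any(np.diff(bp) < 0):
            raise DataError(f"genetic map not sorted by bp on chrom {chrom}")
        max_bp = int(bp.max())
        n_windows = -(-max_bp // bin_size_bp)  # ceil
        for k in range(n_windows):
            start = k * bin_size_bp + 1
            end = (k + 1) * bin_size_bp
            inside = (bp >= start) & (bp <= end)
            if not inside.any():
                continue
            mid = (start + end) // 2
            cand_bp = bp[inside]
            cand_cm = cm[inside]
            best = int(np.argmin(np.abs(cand_bp - mid)))
            rows.append(
                {
                    "bin_id": f"{chrom}:{start}-{end}",
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": end,
                    "mid_bp": int(cand_bp[best]),
                    "mid_cM": float(cand_cm[best]),
                }
            )
    if not rows:
        raise DataError("no non-empty bins produced")
    return BinManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


def apply_exclusions(
    manifest: BinManifest,
    annot: ExclusionAnnotation,
    radius_bp: int = 2_000_000,
) -> BinManifest:
    """Drop bins whose bp span intersects any annotated interval dilated by radius_bp."""
    keep = np.ones(manifest.n_bins, dtype=bool)
    tab = manifest.table
    for chrom in manifest.chroms:
        iv = annot.for_chrom(chrom)
        if not len(iv):
            continue
        on_chrom = (tab["chrom"].astype(str) == chrom).to_numpy()
        start = tab["start_bp"].to_numpy()
        end = tab["end_bp"].to_numpy()
        for _, row in iv.iterrows():
            lo = row["start_bp"] - radius_bp
            hi = row["end_bp"] + radius_bp
            keep &= ~(on_chrom & (start <= hi) & (end >= lo))
    return BinManifest(tab[keep].reset_index(drop=True))


def filter_samples(
    matrix: LocalAncestryMatrix,
    low: float = 0.05,
    high: float = 0.98,
) -> LocalAncestryMatrix:
    """Remove samples with extreme genome-wide African ancestry proportion.

    A sample is removed when its proportion is <= ``low`` or >= ``high``
    (boundaries excluded, matching the published filter).
    """
    prop = matrix.ancestry_proportions()
    keep = (prop > low) & (prop < high)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise DataError(
            f"all {n_removed} samples removed by ancestry-proportion filter "
            f"(bounds {low}/{high})"
        )
    return LocalAncestryMatrix(
        matrix.dosage.loc[keep], cohort_label=matrix.cohort_label
    )
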