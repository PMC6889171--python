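"""Reading, writing and cleaning of genotype, phenotype, kinship and result tables.

Genotypes are held as a dense numeric matrix coded either {0, 1} (inbred
homozygotes, the convention for the selfing *Arabidopsis* panels this package
targets) or {0, 1, 2} (minor-allele dosage for heterozygote-capable data).
Downstream stages operate on the numeric matrix regardless of the coding.

Supported on-disk formats:

* delimited genotype matrix -- first row marker ids, optional ``chromosome``
  and ``position`` metadata rows, then one row per sample (``sample_id`` +
  codes); tab or comma, sniffed from the header;
* PLINK-style ``.raw`` dosage export (``FID IID PAT MAT SEX PHENOTYPE`` then
  0/1/2 SNP columns);
* VCF 4.x (biallelic sites only, read through :mod:`cyvcf2` when available).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "ImportanceTable",
    "FormatError",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "filter_maf",
    "impute_missing",
    "write_importance_table",
    "read_importance_table",
]

MISSING_TOKENS = {"NA", "N/A", "NAN", ".", ""}


class FormatError(ValueError):
    """A file does not parse under its declared format."""


@dataclass
class GenotypeMatrix:
    """An n x p coded marker matrix with per-marker metadata.

    ``values`` holds numeric codes; entries where ``missing_mask`` is True are
    placeholders (NaN after reading) and carry no information.  ``max_code``
    is the largest legal code (1 for inbred {0,1} data, 2 for dosage data) and
    fixes the denominator of allele-frequency computations.
    """

    sample_ids: list[str]
    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    max_code: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if not (len(self.marker_ids) == len(self.chromosomes) == len(self.positions) == p):
            raise ValueError("marker metadata length does not match column count")
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape mismatch")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def markers(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosomes,
                "position": self.positions,
            }
        )

    def validate(self) -> None:
        """Check the code-set, position and ordering invariants; raise on failure."""
        observed = self.values[~self.missing_mask]
        legal = set(range(self.max_code + 1))
        bad = ~np.isin(observed, sorted(legal))
        if bad.any():
            raise ValueError(
                f"{bad.sum()} non-missing genotype entries outside code set {sorted(legal)}"
            )
        if (self.positions < 0).any():
            raise ValueError("negative bp positions")
        for chrom in pd.unique(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if (np.diff(pos) < 0).any():
                raise ValueError(f"positions not non-decreasing on chromosome {chrom}")

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            marker_ids=self.marker_ids[index],
            chromosomes=self.chromosomes[index],
            positions=self.positions[index],
            values=self.values[:, index],
            missing_mask=self.missing_mask[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in index],
            values=self.values[index, :],
            missing_mask=self.missing_mask[index, :],
        )


@dataclass
class PhenotypeVector:
    """Ordered phenotype observations; missing entries are NaN."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.sample_ids) != self.values.size:
            raise ValueError("phenotype length does not match sample ids")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ImportanceTable:
    """Per-SNP %IncMSE scores and 1-based ranks (rank 1 = largest score).

    Ties are broken by original marker order so that ranking is deterministic.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    score: np.ndarray
    rank: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        self.rank = np.asarray(self.rank, dtype=np.int64)
        k = self.score.size
        if not (len(self.marker_id) == len(self.chromosome) == len(self.position) == k == self.rank.size):
            raise ValueError("importance table column length mismatch")
        if k and sorted(self.rank) != list(range(1, k + 1)):
            raise ValueError("ranks must be a permutation of 1..k")

    @classmethod
    def from_scores(
        cls,
        marker_id: Sequence,
        chromosome: Sequence,
        position: Sequence,
        score: np.ndarray,
    ) -> "ImportanceTable":
        score = np.asarray(score, dtype=np.float64)
        # stable sort on -score keeps original marker order among ties
        order = np.argsort(-score, kind="stable")
        rank = np.empty(score.size, dtype=np.int64)
        rank[order] = np.arange(1, score.size + 1)
        return cls(
            marker_id=np.asarray(marker_id, dtype=object),
            chromosome=np.asarray(chromosome, dtype=object),
            position=np.asarray(position, dtype=np.int64),
            score=score,
            rank=rank,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "score": self.score,
                "rank": self.rank,
            }
        )
        return df.sort_values("rank").reset_index(drop=True)

    def top(self, m: int) -> pd.DataFrame:
        return self.to_frame().head(m)


# ---------------------------------------------------------------------------
# genotype readers / writers


def _sniff_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _parse_code(token: str, path, row: int, col: int) -> float:
    token = token.strip()
    if token.upper() in MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: unknown genotype symbol {token!r} at row {row}, column {col}"
        ) from None


def read_genotypes(path, format: str = "delimited") -> GenotypeMatrix:
    """Read a genotype file into a :class:`GenotypeMatrix`.

    ``format`` is one of ``delimited``, ``plink_raw`` or ``vcf``.  Multi-allelic
    VCF sites are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"genotype file not found: {path}")
    if format == "delimited":
        return _read_delimited(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_delimited(path: Path) -> GenotypeMatrix:
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        marker_ids = [t.strip() for t in header[1:]]
        p = len(marker_ids)
        chroms: list | None = None
        positions: list | None = None
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for i, rec in enumerate(csv.reader(fh, delimiter=delim), start=2):
            if not rec or all(not t.strip() for t in rec):
                continue
            key = rec[0].strip().lower()
            if key in {"chromosome", "chrom", "chr"}:
                chroms = [t.strip() for t in rec[1:]]
                continue
            if key in {"position", "pos", "bp"}:
                positions = [int(float(t)) for t in rec[1:]]
                continue
            if len(rec) - 1 != p:
                raise FormatError(
                    f"{path}: row {i} has {len(rec) - 1} genotype fields, expected {p}"
                )
            sample_ids.append(rec[0].strip())
            rows.append([_parse_code(t, path, i, j + 2) for j, t in enumerate(rec[1:])])
    values = np.array(rows, dtype=np.float64)
    if chroms is None:
        chroms = ["0"] * p
    if positions is None:
        positions = list(range(1, p + 1))
    max_code = 2 if np.nanmax(values, initial=0.0) > 1 else 1
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=np.array(marker_ids, dtype=object),
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        values=values,
        max_code=max_code,
    )


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().split()
        expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if header[: len(expected)] != expected:
            raise FormatError(f"{path}: not a PLINK raw export (header {header[:6]})")
        marker_ids = header[len(expected):]
        p = len(marker_ids)
        sample_ids, rows = [], []
        for i, line in enumerate(fh, start=2):
            rec = line.split()
            if not rec:
                continue
            if len(rec) != len(expected) + p:
                raise FormatError(f"{path}: row {i} has {len(rec)} fields")
            sample_ids.append(rec[1])
            rows.append([_parse_code(t, path, i, j + 7) for j, t in enumerate(rec[6:])])
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=np.array(marker_ids, dtype=object),
        chromosomes=np.array(["0"] * p, dtype=object),
        positions=np.arange(1, p + 1, dtype=np.int64),
        values=np.array(rows, dtype=np.float64),
        max_code=2,
    )


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("VCF support requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    marker_ids, chroms, positions, cols, masks = [], [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        gt = np.asarray(var.gt_types)
        col = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        positions.append(var.POS)
        cols.append(col)
        masks.append(np.isnan(col))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} multi-allelic VCF sites")
    values = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(
        sample_ids=sample_ids,
        marker_ids=np.array(marker_ids, dtype=object),
        chromosomes=np.array(chroms, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        values=values,
        max_code=2,
    )


def write_genotypes(g: GenotypeMatrix, path, delimiter: str = "\t") -> None:
    """Write ``g`` in the delimited layout understood by :func:`read_genotypes`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["sample_id", *g.marker_ids])
        w.writerow(["chromosome", *g.chromosomes])
        w.writerow(["position", *g.positions])
        vals = g.values.astype(object)
        vals[g.missing_mask] = "NA"
        for sid, row in zip(g.sample_ids, vals):
            w.writerow([sid, *[v if isinstance(v, str) else format(v, "g") for v in row]])


def read_phenotypes(path, trait: str | None = None) -> PhenotypeVector:
    """Read a delimited phenotype table (sample_id + one or more trait columns)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: phenotype table needs sample_id and a value column")
    col = trait if trait is not None else df.columns[1]
    return PhenotypeVector(
        sample_ids=[str(s) for s in df.iloc[:, 0]],
        values=pd.to_numeric(df[col], errors="coerce").to_numpy(),
    )


def write_phenotypes(y: PhenotypeVector, path, trait: str = "trait") -> None:
    pd.DataFrame({"sample_id": y.sample_ids, trait: y.values}).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


# ---------------------------------------------------------------------------
# filtering / imputation


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF over non-missing calls (NaN for all-missing markers)."""
    obs = np.where(g.missing_mask, np.nan, g.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        freq = np.nansum(obs, axis=0) / (np.sum(~g.missing_mask, axis=0) * g.max_code)
    freq[np.sum(~g.missing_mask, axis=0) == 0] = np.nan
    return np.minimum(freq, 1.0 - freq)


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Drop markers with minor-allele frequency below ``threshold``.

    MAF is computed over non-missing calls; all-missing markers are excluded
    with a warning.  Sample set and marker order are preserved.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError(f"MAF threshold must be in [0, 0.5], got {threshold}")
    maf = minor_allele_frequencies(g)
    all_missing = np.isnan(maf)
    if all_missing.any():
        warnings.warn(f"excluding {all_missing.sum()} markers with no observed calls")
    keep = ~all_missing & (maf >= threshold)
    return g.subset_markers(np.flatnonzero(keep))


def impute_missing(g: GenotypeMatrix, strategy: str = "column_mean") -> GenotypeMatrix:
    """Replace missing calls column-wise by the mean or the major (modal) code."""
    if strategy not in {"column_mean", "column_major"}:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    if not g.missing_mask.any():
        return replace(g, missing_mask=np.zeros_like(g.missing_mask))
    counts = np.sum(~g.missing_mask, axis=0)
    if (counts == 0).any():
        raise ValueError(
            "fully missing marker column; run filter_maf before impute_missing"
        )
    obs = np.where(g.missing_mask, np.nan, g.values)
    if strategy == "column_mean":
        fill = np.nanmean(obs, axis=0)
    else:
        fill = np.empty(g.n_markers)
        for j in range(g.n_markers):
            codes, cnt = np.unique(obs[~g.missing_mask[:, j], j], return_counts=True)
            fill[j] = codes[np.argmax(cnt)]  # np.unique sorts: ties -> smallest code
    values = np.where(g.missing_mask, fill[None, :], g.values)
    return replace(g, values=values, missing_mask=np.zeros_like(g.missing_mask))


# ---------------------------------------------------------------------------
# importance table round-trip


def write_importance_table(t: ImportanceTable, path) -> None:
    t.to_frame().to_csv(path, sep="\t", index=False)


def read_importance_table(path) -> ImportanceTable:
    df = pd.read_csv(path, sep="\t")
    required = ["marker_id", "chromosome", "position", "score", "rank"]
    if list(df.columns) != required:
        raise FormatError(f"{path}: expected columns {required}, got {list(df.columns)}")
    return ImportanceTable(
        marker_id=df["marker_id"].astype(str).to_numpy(dtype=object),
        chromosome=df["chromosome"].astype(str).to_numpy(dtype=object),
        position=df["position"].to_numpy(),
        score=df["score"].to_numpy(),
        rank=df["rank"].to_numpy(),
    )
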