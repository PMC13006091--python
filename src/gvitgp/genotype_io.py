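"""Genotype, marker-map and phenotype I/O plus per-marker quality control.

Dosages are coded 0/1/2 as the count of the second allele at a biallelic
marker; missing genotypes are NaN in the float matrix. Supported on-disk
dialects are plain TSV (samples x markers, header row of marker ids, first
column the sample id), PLINK text ``.ped``/``.map`` pairs, and PLINK
``--recode A`` ``.raw`` files.

QC follows the usual chip-data pipeline: a marker survives iff
call rate > cr_min, MAF > maf_min and the Hardy-Weinberg exact-test p-value
> hwe_min (all strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyPanelError,
    FormatError,
    UndefinedMarkerError,
    ValidationError,
)

MISSING_TOKENS = {"NA", "-9", ".", "nan", "NaN", ""}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Per-marker id, chromosome label and 1-based physical position."""

    ids: np.ndarray          # str array, unique
    chromosomes: np.ndarray  # str array
    positions: np.ndarray    # int array, bp, 1-based

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if not (len(self.ids) == len(self.chromosomes) == len(self.positions)):
            raise ValidationError("marker map fields have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate marker ids in map")
        if np.any(self.positions < 0):
            raise ValidationError("negative marker position")
        for chrom in dict.fromkeys(self.chromosomes):
            pos = self.positions[self.chromosomes == chrom]
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"positions on chromosome {chrom} not non-decreasing"
                )

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.ids[idx], self.chromosomes[idx], self.positions[idx])

    @staticmethod
    def default(n_markers: int) -> "MarkerMap":
        """Single-chromosome map with unit spacing, for map-less inputs."""
        return MarkerMap(
            ids=np.array([f"m{j}" for j in range(n_markers)], dtype=object),
            chromosomes=np.array(["1"] * n_markers, dtype=object),
            positions=np.arange(1, n_markers + 1, dtype=np.int64),
        )


@dataclass
class GenotypeMatrix:
    """samples x markers dosage matrix with NaN for missing calls."""

    dosages: np.ndarray       # float array (n, m), entries in {0,1,2,NaN}
    sample_ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be 2-D")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValidationError("sample_ids length != number of rows")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if len(self.markers) != self.dosages.shape[1]:
            raise ValidationError("marker map length != number of columns")
        finite = self.dosages[np.isfinite(self.dosages)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0, 2.0))):
            raise ValidationError("non-missing dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def row_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise ValidationError(f"unknown sample id {e.args[0]!r}") from None

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx], list(self.sample_ids), self.markers.subset(idx)
        )

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        rows = self.row_index(ids)
        return GenotypeMatrix(
            self.dosages[rows], [self.sample_ids[i] for i in rows], self.markers
        )


@dataclass
class PhenotypeTable:
    """sample id -> trait -> numeric value; NaN allowed."""

    frame: pd.DataFrame  # index: sample id, columns: traits

    def __post_init__(self) -> None:
        self.frame.index = self.frame.index.astype(str)
        if self.frame.index.duplicated().any():
            raise ValidationError("duplicate sample ids in phenotype table")

    def values_for(self, ids: Iterable[str], trait: str) -> np.ndarray:
        ids = list(ids)
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise ValidationError(f"phenotype table lacks sample ids {missing[:5]}")
        return self.frame.loc[ids, trait].to_numpy(dtype=float)

    @property
    def traits(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class QCReport:
    """Per-marker QC statistics and pass flags under the thresholds used."""

    marker_ids: np.ndarray
    call_rate: np.ndarray
    maf: np.ndarray
    hwe_p: np.ndarray
    passed: np.ndarray
    cr_min: float
    maf_min: float
    hwe_min: float
    parse_log: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "call_rate": self.call_rate,
                "maf": self.maf,
                "hwe_p": self.hwe_p,
                "passed": self.passed,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_dosage_token(tok: str) -> float:
    tok = tok.strip()
    if tok in MISSING_TOKENS:
        return np.nan
    try:
        v = float(tok)
    except ValueError:
        return np.nan
    if v in (0.0, 1.0, 2.0):
        return v
    return np.nan


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix in one of the supported dialects.

    ``format`` is one of ``tsv``, ``ped_map`` (``path`` is the .ped; the .map
    sits beside it), or ``raw`` (PLINK --recode A). Unparseable genotype
    tokens become missing; their count is kept on the returned matrix as
    ``g.parse_log``.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "ped_map":
        return _read_ped_map(path)
    if format == "raw":
        return _read_raw(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tsv(path: Path) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: line 1: header needs sample-id column + markers")
    marker_ids = header[1:]
    n_m = len(marker_ids)
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    bad = 0
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != n_m + 1:
            raise FormatError(
                f"{path}: line {ln}: expected {n_m + 1} fields, got {len(parts)}"
            )
        sample_ids.append(parts[0])
        vals = []
        for tok in parts[1:]:
            v = _parse_dosage_token(tok)
            if np.isnan(v) and tok.strip() not in MISSING_TOKENS:
                bad += 1
            vals.append(v)
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    g = GenotypeMatrix(np.array(rows, dtype=float), sample_ids, MarkerMap.default(n_m))
    g.markers = MarkerMap(
        ids=np.array(marker_ids, dtype=object),
        chromosomes=g.markers.chromosomes,
        positions=g.markers.positions,
    )
    g.parse_log = {"unparseable_tokens": bad}
    return g


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a PLINK .map (chrom, id, cM, bp) or 3-column (id, chrom, bp) TSV."""
    recs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) == 4:  # PLINK: chrom id cM bp
            recs.append((parts[1], parts[0], int(parts[3])))
        elif len(parts) == 3:  # id chrom bp
            if ln == 1 and not parts[2].lstrip("-").isdigit():
                continue  # header
            recs.append((parts[0], parts[1], int(parts[2])))
        else:
            raise FormatError(f"{path}: line {ln}: expected 3 or 4 columns")
    if not recs:
        raise FormatError(f"{path}: empty map")
    ids, chroms, pos = zip(*recs)
    return MarkerMap(np.array(ids, dtype=object), np.array(chroms, dtype=object),
                     np.array(pos, dtype=np.int64))


def _read_ped_map(ped_path: Path) -> GenotypeMatrix:
    """PLINK text .ped/.map: dosage = count of the second allele per marker.

    When the file supplies no allele order, the second allele at a marker is
    the lexicographically later of the two observed alleles.
    """
    map_path = ped_path.with_suffix(".map")
    if not map_path.exists():
        raise FormatError(f"missing map file {map_path}")
    mmap = read_marker_map(map_path)
    n_m = len(mmap)

    text = ped_path.read_text().splitlines()
    if not any(line.strip() for line in text):
        raise FormatError(f"{ped_path}: empty file")
    sample_ids: list[str] = []
    allele_pairs: list[list[tuple[str, str]]] = []
    for ln, line in enumerate(text, start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_m:
            raise FormatError(
                f"{ped_path}: line {ln}: expected {6 + 2 * n_m} fields, got {len(parts)}"
            )
        sample_ids.append(parts[1])  # IID
        allele_pairs.append(
            [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(n_m)]
        )
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{ped_path}: duplicate sample ids")

    # second allele per marker: lexicographically later of observed alleles
    dosages = np.full((len(sample_ids), n_m), np.nan)
    bad = 0
    for j in range(n_m):
        observed = sorted(
            {a for pairs in allele_pairs for a in pairs[j] if a != "0"}
        )
        if len(observed) > 2:
            raise FormatError(f"{ped_path}: marker {mmap.ids[j]} has >2 alleles")
        second = observed[-1] if observed else None
        for i, pairs in enumerate(allele_pairs):
            a, b = pairs[j]
            if a == "0" or b == "0":
                if (a == "0") != (b == "0"):
                    bad += 1  # half-missing call treated as missing
                continue
            dosages[i, j] = (a == second) + (b == second)
    g = GenotypeMatrix(dosages, sample_ids, mmap)
    g.parse_log = {"unparseable_tokens": bad}
    return g


def _read_raw(path: Path) -> GenotypeMatrix:
    """PLINK --recode A: whitespace table, 6 meta columns then dosage columns."""
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty file")
    header = lines[0].split()
    if header[:6] != ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]:
        raise FormatError(f"{path}: line 1: not a PLINK .raw header")
    marker_ids = [c.rsplit("_", 1)[0] for c in header[6:]]
    n_m = len(marker_ids)
    sample_ids, rows = [], []
    bad = 0
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + n_m:
            raise FormatError(
                f"{path}: line {ln}: expected {6 + n_m} fields, got {len(parts)}"
            )
        sample_ids.append(parts[1])
        vals = []
        for tok in parts[6:]:
            v = _parse_dosage_token(tok)
            if np.isnan(v) and tok not in MISSING_TOKENS:
                bad += 1
            vals.append(v)
        rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: no sample rows")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{path}: duplicate sample ids")
    mmap = MarkerMap.default(n_m)
    mmap = MarkerMap(np.array(marker_ids, dtype=object), mmap.chromosomes, mmap.positions)
    g = GenotypeMatrix(np.array(rows, dtype=float), sample_ids, mmap)
    g.parse_log = {"unparseable_tokens": bad}
    return g


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect; NaN becomes ``NA``. Round-trips exactly."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(map(str, g.markers.ids)) + "\n")
        for i, sid in enumerate(g.sample_ids):
            toks = [
                "NA" if not np.isfinite(v) else str(int(v)) for v in g.dosages[i]
            ]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def write_marker_map(m: MarkerMap, path: str | Path) -> None:
    pd.DataFrame(
        {"marker": m.ids, "chrom": m.chromosomes, "pos_bp": m.positions}
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: phenotype table needs sample id + >=1 trait")
    frame = frame.set_index(frame.columns[0])
    return PhenotypeTable(frame.astype(float))


def write_phenotypes(p: PhenotypeTable, path: str | Path) -> None:
    p.frame.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------


def marker_call_rate(col: np.ndarray) -> float:
    """Fraction of non-missing genotypes in a dosage column."""
    col = np.asarray(col, dtype=float)
    if col.size == 0:
        raise ValueError("empty dosage column")
    return float(np.isfinite(col).sum() / col.size)


def marker_maf(col: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p) with p the second-allele frequency.

    p = sum of non-missing dosages / (2 * number of non-missing genotypes).
    """
    col = np.asarray(col, dtype=float)
    obs = col[np.isfinite(col)]
    if obs.size == 0:
        raise UndefinedMarkerError("MAF undefined: all genotypes missing")
    p = obs.sum() / (2.0 * obs.size)
    return float(min(p, 1.0 - p))


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton-style).

    Enumerates every heterozygote count consistent with the observed allele
    totals via the standard probability recurrence and sums the probabilities
    of configurations no more likely than the observed one. Monomorphic
    markers return 1.0 by convention.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # copies of the rarer allele
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # heterozygote counts share the parity of n_rare
    het_max = min(n_rare, 2 * n - n_rare)
    hets = list(range(n_rare % 2, het_max + 1, 2))
    probs = {}
    # start from the largest het count; unnormalized prob 1 there
    h = hets[-1]
    probs[h] = 1.0
    while h >= 2:
        # P(h-2) = P(h) * h*(h-1) / ((n_rare-h+2)*(2n-n_rare-h+2))
        probs[h - 2] = (
            probs[h] * h * (h - 1)
            / ((n_rare - h + 2.0) * (2 * n - n_rare - h + 2.0))
        )
        h -= 2
    total = sum(probs.values())
    p_obs = probs[n_Aa]
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return float(min(1.0, p))


def _hwe_column(col: np.ndarray) -> float:
    obs = col[np.isfinite(col)]
    if obs.size == 0:
        return 0.0  # undefined; will already fail call-rate at any cr_min>0
    n_AA = int((obs == 0).sum())
    n_Aa = int((obs == 1).sum())
    n_aa = int((obs == 2).sum())
    return hwe_exact_p(n_AA, n_Aa, n_aa)


def apply_qc(
    g: GenotypeMatrix,
    cr_min: float = 0.95,
    maf_min: float = 0.01,
    hwe_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers by strict-inequality call-rate / MAF / HWE thresholds.

    Returns the surviving column subset (original order) and the full report.
    Raises :class:`EmptyPanelError` if nothing survives.
    """
    n_m = g.n_markers
    call = np.empty(n_m)
    maf = np.empty(n_m)
    hwe = np.empty(n_m)
    for j in range(n_m):
        col = g.dosages[:, j]
        call[j] = marker_call_rate(col)
        obs = col[np.isfinite(col)]
        maf[j] = (
            min(obs.sum() / (2.0 * obs.size), 1 - obs.sum() / (2.0 * obs.size))
            if obs.size
            else 0.0
        )
        hwe[j] = _hwe_column(col)
    passed = (call > cr_min) & (maf > maf_min) & (hwe > hwe_min)
    report = QCReport(
        marker_ids=np.asarray(g.markers.ids),
        call_rate=call,
        maf=maf,
        hwe_p=hwe,
        passed=passed,
        cr_min=cr_min,
        maf_min=maf_min,
        hwe_min=hwe_min,
        parse_log=getattr(g, "parse_log", {}),
    )
    if not passed.any():
        raise EmptyPanelError(
            f"no markers survive QC (cr>{cr_min}, maf>{maf_min}, hwe>{hwe_min})"
        )
    return g.subset_markers(np.where(passed)[0]), report
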