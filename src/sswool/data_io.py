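"""Readers and writers for the standard formats the pipeline touches.

Internal conventions
--------------------
* Genomic coordinates are 1-based inclusive everywhere inside the package;
  conversion to/from 0-based half-open (BED) happens only at format
  boundaries.
* Genotype dosages count the A1 allele as listed in the marker map / .bim
  file, coded 0/1/2 with ``numpy.nan`` for missing calls.
* Pedigrees are stored topologically sorted: every parent precedes its
  offspring, unknown parents are ``None``.
"""

from __future__ import annotations


import os

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeTable",
    "MarkerMap",
    "GenotypeMatrix",
    "PhenotypeTable",
    "GeneAnnotation",
    "ExpressionMatrix",
    "SampleMetadata",
    "PedigreeError",
    "FormatError",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_gene_annotation",
    "write_gene_annotation_bed",
    "read_phenotypes",
    "write_table",
    "read_expression",
    "write_expression",
    "read_sample_metadata",
]

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "OARX", "OARY", "26X", "27"}
PLINK_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, duplicate id)."""


class FormatError(ValueError):
    """Malformed or internally inconsistent input file."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class PedigreeTable:
    """Topologically ordered (animal, sire, dam) trios.

    ``sire``/``dam`` entries are ``None`` when unknown.  ``sire_idx`` /
    ``dam_idx`` give positional indices into ``animals`` (-1 = unknown),
    which is what the relationship machinery consumes.
    """

    animals: list[str]
    sires: list[str | None]
    dams: list[str | None]

    def __post_init__(self) -> None:
        if len(set(self.animals)) != len(self.animals):
            dupes = pd.Series(self.animals)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise PedigreeError(f"duplicate animal ids: {dupes[:5]}")
        pos = {a: i for i, a in enumerate(self.animals)}
        self._pos = pos
        self.sire_idx = np.array(
            [pos[s] if s is not None else -1 for s in self.sires], dtype=np.int64
        )
        self.dam_idx = np.array(
            [pos[d] if d is not None else -1 for d in self.dams], dtype=np.int64
        )
        for i in range(len(self.animals)):
            if self.sire_idx[i] >= i or self.dam_idx[i] >= i:
                bad = self.animals[i]
                raise PedigreeError(f"pedigree not topologically sorted at {bad!r}")

    def __len__(self) -> int:
        return len(self.animals)

    def index_of(self, ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._pos[i] for i in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown animal id {exc.args[0]!r}") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animals, "sire": self.sires, "dam": self.dams}
        )


@dataclass
class MarkerMap:
    """Per-SNP id, chromosome and 1-based bp position, in genome order."""

    snp_id: np.ndarray
    chromosome: np.ndarray
    position_bp: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if np.any(self.position_bp < 1):
            raise FormatError("marker positions must be >= 1 (1-based)")

    def __len__(self) -> int:
        return len(self.snp_id)

    def is_sex_chromosome(self) -> np.ndarray:
        return np.array([str(c) in SEX_CHROMOSOMES for c in self.chromosome])

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.snp_id[keep], self.chromosome[keep], self.position_bp[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix; nan encodes a missing call."""

    dosage: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        if self.dosage.ndim != 2:
            raise FormatError("dosage must be a 2-D individuals x markers array")
        if self.dosage.shape[0] != len(self.individual_ids):
            raise FormatError(
                f"{self.dosage.shape[0]} dosage rows but "
                f"{len(self.individual_ids)} individual ids"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise FormatError("dosages must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def subset(self, individuals: np.ndarray | None = None, markers: np.ndarray | None = None) -> "GenotypeMatrix":
        d = self.dosage
        ids = self.individual_ids
        if individuals is not None:
            d = d[individuals]
            ids = [ids[i] for i in np.atleast_1d(np.arange(len(self.individual_ids))[individuals])]
        if markers is not None:
            d = d[:, markers]
        return GenotypeMatrix(d.copy(), list(ids))


@dataclass
class PhenotypeTable:
    """Per-animal trait values plus the fixed-effect factors of the model."""

    data: pd.DataFrame  # columns: animal, flock, birth_year, season, <traits...>
    trait_names: list[str]
    factor_names: list[str] = field(default_factory=lambda: ["flock", "birth_year", "season"])

    def __post_init__(self) -> None:
        missing = [c for c in ["animal", *self.factor_names, *self.trait_names] if c not in self.data.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, with strand kept but unused."""

    table: pd.DataFrame  # gene_id, chromosome, start_bp, end_bp, strand

    def __post_init__(self) -> None:
        req = ["gene_id", "chromosome", "start_bp", "end_bp", "strand"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        t = self.table
        if (t["end_bp"] < t["start_bp"]).any():
            bad = t.loc[t["end_bp"] < t["start_bp"], "gene_id"].tolist()
            raise FormatError(f"gene end < start after normalization: {bad[:5]}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression values (typically TPM)."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("expression matrix shape does not match id lists")
        if (self.values < 0).any():
            raise FormatError("expression values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleMetadata:
    """Per-sample tissue, organ system, age stage and sex labels."""

    table: pd.DataFrame  # sample_id, tissue, organ_system, age_stage, sex

    def __post_init__(self) -> None:
        req = ["sample_id", "tissue", "organ_system", "age_stage", "sex"]
        missing = [c for c in req if c not in self.table.columns]
        if missing:
            raise FormatError(f"sample metadata missing columns: {missing}")
        # each tissue must belong to exactly one organ system
        n_sys = self.table.groupby("tissue")["organ_system"].nunique()
        multi = n_sys[n_sys > 1].index.tolist()
        if multi:
            raise FormatError(f"tissues mapped to multiple organ systems: {multi[:5]}")
        self.table = self.table.reset_index(drop=True)

    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def organ_systems(self) -> list[str]:
        return sorted(self.table["organ_system"].unique())

    def organ_system_of(self, tissue: str) -> str:
        rows = self.table.loc[self.table["tissue"] == tissue, "organ_system"]
        if rows.empty:
            raise KeyError(f"unknown tissue {tissue!r}")
        return rows.iloc[0]


# ---------------------------------------------------------------------------
# pedigree I/O
# ---------------------------------------------------------------------------


def _toposort_pedigree(
    trios: list[tuple[str, str | None, str | None]]
) -> tuple[list[str], list[str | None], list[str | None]]:
    """Stable Kahn topological sort: input order is preserved whenever it is
    already consistent; parents never listed as animals become founders and
    sort just before their first child."""
    import heapq

    animals = [t[0] for t in trios]
    if len(set(animals)) != len(animals):
        s = pd.Series(animals)
        raise PedigreeError(f"duplicate animal ids: {sorted(s[s.duplicated()].unique())[:5]}")
    known = set(animals)
    parent_of: dict[str, tuple[str | None, str | None]] = {}
    appear: dict[str, float] = {}
    for i, (a, s, d) in enumerate(trios):
        parent_of[a] = (s, d)
        appear[a] = float(i)
        for p in (s, d):
            if p is not None and p not in known and p not in appear:
                appear[p] = i - 0.5
                parent_of[p] = (None, None)
    children: dict[str, list[str]] = {a: [] for a in parent_of}
    indeg: dict[str, int] = {a: 0 for a in parent_of}
    for a, (s, d) in parent_of.items():
        for p in {s, d} - {None}:
            children[p].append(a)
            indeg[a] += 1
    heap = [(appear[a], a) for a, k in indeg.items() if k == 0]
    heapq.heapify(heap)
    out: list[str] = []
    while heap:
        _, a = heapq.heappop(heap)
        out.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (appear[c], c))
    if len(out) != len(parent_of):
        cyc = sorted(a for a, k in indeg.items() if k > 0)
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc[:10]}")
    sires = [parent_of[a][0] for a in out]
    dams = [parent_of[a][1] for a in out]
    return out, sires, dams


def read_pedigree(path: str | os.PathLike, unknown_code: str = "0", header: bool = False) -> PedigreeTable:
    """Read a 3-column delimited pedigree (animal, sire, dam)."""
    try:
        df = pd.read_csv(
            path,
            sep=None,
            engine="python",
            header=0 if header else None,
            dtype=str,
            comment="#",
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return PedigreeTable([], [], [])
    except Exception as exc:
        if "delimiter" in str(exc).lower():  # csv sniffer on an empty file
            return PedigreeTable([], [], [])
        raise
    if df.empty:
        return PedigreeTable([], [], [])
    if df.shape[1] < 3:
        raise FormatError(f"pedigree file needs 3 columns, found {df.shape[1]}")
    trios = []
    for a, s, d in df.iloc[:, :3].itertuples(index=False):
        trios.append(
            (
                str(a),
                None if str(s) == unknown_code or pd.isna(s) else str(s),
                None if str(d) == unknown_code or pd.isna(d) else str(d),
            )
        )
    return PedigreeTable(*_toposort_pedigree(trios))


def write_pedigree(ped: PedigreeTable, path: str | os.PathLike, unknown_code: str = "0") -> None:
    df = ped.to_frame().fillna(unknown_code)
    df.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# PLINK genotype I/O
# ---------------------------------------------------------------------------


def _read_map(path: str | os.PathLike) -> tuple[MarkerMap, pd.DataFrame]:
    cols = ["chromosome", "snp_id", "cm", "position_bp"]
    df = pd.read_csv(path, sep=r"\s+", header=None, names=cols, dtype={0: str, 1: str})
    mm = MarkerMap(df["snp_id"].to_numpy(), df["chromosome"].to_numpy(), df["position_bp"].to_numpy())
    return mm, df


def _read_bim(path: str | os.PathLike) -> tuple[MarkerMap, pd.DataFrame]:
    cols = ["chromosome", "snp_id", "cm", "position_bp", "a1", "a2"]
    df = pd.read_csv(path, sep=r"\s+", header=None, names=cols, dtype={0: str, 1: str, 4: str, 5: str})
    mm = MarkerMap(df["snp_id"].to_numpy(), df["chromosome"].to_numpy(), df["position_bp"].to_numpy())
    return mm, df


def _read_plink_text(prefix: str) -> tuple[GenotypeMatrix, MarkerMap]:
    """.ped/.map reader.  The .map format carries no allele column, so the
    counted (A1) allele is the lexicographically smaller symbol observed at
    each marker — deterministic without an external reference."""
    mm, _ = _read_map(prefix + ".map")
    m = len(mm)
    ids: list[str] = []
    calls_a: list[np.ndarray] = []
    calls_b: list[np.ndarray] = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields "
                    f"({m} markers), found {len(parts)}"
                )
            ids.append(parts[1])
            calls = np.array(parts[6:], dtype=object)
            calls_a.append(calls[0::2])
            calls_b.append(calls[1::2])
    if not ids:
        return GenotypeMatrix(np.empty((0, m)), []), mm
    a = np.vstack(calls_a)
    b = np.vstack(calls_b)
    missing = (a == "0") | (b == "0")
    dosage = np.full(a.shape, np.nan)
    for j in range(m):
        seen = set(a[~missing[:, j], j]) | set(b[~missing[:, j], j])
        if len(seen) > 2:
            raise FormatError(
                f"{prefix}.ped marker {mm.snp_id[j]}: more than two allele "
                f"symbols {sorted(seen)}"
            )
        if not seen:
            continue
        if len(seen) == 1:
            # orientation of a monomorphic marker is unrecoverable from
            # .ped; the single observed symbol is taken as the non-counted
            # allele (dosage 0)
            dosage[:, j] = np.where(missing[:, j], np.nan, 0.0)
            continue
        a1 = sorted(seen)[0]
        col = (a[:, j] == a1).astype(float) + (b[:, j] == a1).astype(float)
        dosage[:, j] = np.where(missing[:, j], np.nan, col)
    return GenotypeMatrix(dosage, ids), mm


def _read_plink_bed(prefix: str) -> tuple[GenotypeMatrix, MarkerMap]:
    mm, bim = _read_bim(prefix + ".bim")
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None, dtype=str)
    ids = fam.iloc[:, 1].tolist()
    n, m = len(ids), len(mm)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != PLINK_BED_MAGIC:
            raise FormatError(f"{prefix}.bed: bad magic bytes {magic!r} (need SNP-major v1.0)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise FormatError(
            f"{prefix}.bed: {raw.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} individuals x {m} SNPs"
        )
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (raw[:, :, None] >> shifts[None, None, :]) & 0b11  # m x bytes x 4
    codes = codes.reshape(m, -1)[:, :n]
    # PLINK: 00=hom A1 (dosage 2), 10=het (1), 11=hom A2 (0), 01=missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosage = lut[codes].T.copy()
    return GenotypeMatrix(dosage, ids), mm


def read_genotypes(path_prefix: str | os.PathLike, dialect: str = "plink_text") -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK fileset; dosage counts the A1 allele of the map/bim."""
    prefix = str(path_prefix)
    if dialect == "plink_text":
        return _read_plink_text(prefix)
    if dialect == "plink_bed":
        return _read_plink_bed(prefix)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_genotypes(
    genotypes: GenotypeMatrix,
    marker_map: MarkerMap,
    path_prefix: str | os.PathLike,
    dialect: str = "plink_text",
    alleles: tuple[str, str] = ("A", "B"),
) -> None:
    """Write a PLINK fileset; allele symbols default to A (=A1, counted) / B."""
    prefix = str(path_prefix)
    if genotypes.n_markers != len(marker_map):
        raise FormatError("genotype matrix and marker map disagree on marker count")
    a1, a2 = alleles
    if dialect == "plink_text":
        with open(prefix + ".map", "w") as fh:
            for c, s, p in zip(marker_map.chromosome, marker_map.snp_id, marker_map.position_bp):
                fh.write(f"{c}\t{s}\t0\t{p}\n")
        pair = {2.0: f"{a1} {a1}", 1.0: f"{a1} {a2}", 0.0: f"{a2} {a2}"}
        with open(prefix + ".ped", "w") as fh:
            for i, iid in enumerate(genotypes.individual_ids):
                cells = [
                    "0 0" if np.isnan(d) else pair[d] for d in genotypes.dosage[i]
                ]
                fh.write(f"FAM {iid} 0 0 0 -9 " + " ".join(cells) + "\n")
    elif dialect == "plink_bed":
        with open(prefix + ".bim", "w") as fh:
            for c, s, p in zip(marker_map.chromosome, marker_map.snp_id, marker_map.position_bp):
                fh.write(f"{c}\t{s}\t0\t{p}\t{a1}\t{a2}\n")
        with open(prefix + ".fam", "w") as fh:
            for iid in genotypes.individual_ids:
                fh.write(f"FAM {iid} 0 0 0 -9\n")
        n, m = genotypes.n_individuals, genotypes.n_markers
        # dosage -> 2-bit code: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
        code = np.full((m, n), 0b01, dtype=np.uint8)
        d = genotypes.dosage.T
        code[d == 2.0] = 0b00
        code[d == 1.0] = 0b10
        code[d == 0.0] = 0b11
        bytes_per_snp = (n + 3) // 4
        padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
        padded[:, :n] = code
        packed = (
            padded.reshape(m, bytes_per_snp, 4)
            << (np.arange(4, dtype=np.uint8) * 2)[None, None, :]
        ).sum(axis=2, dtype=np.uint8)
        with open(prefix + ".bed", "wb") as fh:
            fh.write(PLINK_BED_MAGIC)
            fh.write(packed.tobytes())
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# gene annotation I/O
# ---------------------------------------------------------------------------


def read_gene_annotation(path: str | os.PathLike, dialect: str = "bed") -> GeneAnnotation:
    """Read gene intervals from BED4+ (0-based half-open) or GFF3 (1-based)."""
    if dialect == "bed":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#", dtype={0: str, 3: str}
        )
        if df.shape[1] < 4:
            raise FormatError("BED gene file needs at least 4 columns (chrom start end name)")
        out = pd.DataFrame(
            {
                "gene_id": df.iloc[:, 3],
                "chromosome": df.iloc[:, 0],
                "start_bp": df.iloc[:, 1].astype(np.int64) + 1,  # 0-based -> 1-based
                "end_bp": df.iloc[:, 2].astype(np.int64),
                "strand": df.iloc[:, 5] if df.shape[1] > 5 else "+",
            }
        )
        return GeneAnnotation(out)
    if dialect == "gff3":
        import gffutils

        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        rows = []
        for feat in db.features_of_type("gene", order_by=("seqid", "start")):
            gid = feat.attributes.get("ID", [feat.id])[0]
            rows.append(
                {
                    "gene_id": gid,
                    "chromosome": feat.seqid,
                    "start_bp": feat.start,
                    "end_bp": feat.end,
                    "strand": feat.strand or "+",
                }
            )
        return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "strand"]))
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def write_gene_annotation_bed(genes: GeneAnnotation, path: str | os.PathLike) -> None:
    t = genes.table
    out = pd.DataFrame(
        {
            "chrom": t["chromosome"],
            "start": t["start_bp"] - 1,  # 1-based -> 0-based half-open
            "end": t["end_bp"],
            "name": t["gene_id"],
            "score": 0,
            "strand": t["strand"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# phenotypes, tables, expression
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | os.PathLike, trait_names: Sequence[str] | None = None) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str, "flock": str, "birth_year": str, "season": str})
    if trait_names is None:
        trait_names = [c for c in df.columns if c not in ("animal", "flock", "birth_year", "season")]
    return PhenotypeTable(df, list(trait_names))


def write_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Deterministic TSV writer: header, fixed column order, '%.10g' floats."""
    if records is None:
        raise ValueError("records must not be None")
    records.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df.to_numpy(), [str(g) for g in df.index], [str(s) for s in df.columns])


def read_sample_metadata(path: str | os.PathLike) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df)
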