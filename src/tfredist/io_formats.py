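"""Genomic data model and readers/writers for the plain-text formats the pipeline touches.

Coordinates are 0-based, half-open throughout (BED convention).  Summits and
TSSs are absolute base-pair point positions; all distances are in bp between
point positions.  Chromosome names are compared by exact string match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GenomicInterval",
    "PeakSet",
    "CountMatrix",
    "GeneAnnotation",
    "MotifModel",
    "SurvivalRecord",
    "read_peaks",
    "write_peaks",
    "read_count_table",
    "write_count_table",
    "read_gene_table",
    "write_gene_table",
    "read_meme_motif",
    "write_meme_motif",
    "read_survival_table",
    "write_survival_table",
]

ALPHABET = "ACGT"


class ParseError(ValueError):
    """A line of an input file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval, optionally with a point-source summit."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.name}: start {self.start} < 0")
        if not self.start < self.end:
            raise ValidationError(
                f"{self.name}: empty or inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"{self.name}: bad strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"{self.name}: summit {self.summit} outside [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered collection of intervals, sorted by (chrom, start).

    Names must be unique within a set; an optional ``genome`` maps chromosome
    name to length.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        genome: Mapping[str, int] | None = None,
    ):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.name)
        )
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate peak names: {dupes[:5]}")
        self.genome = dict(genome) if genome is not None else None
        if self.genome is not None:
            for iv in self.intervals:
                if iv.chrom in self.genome and iv.end > self.genome[iv.chrom]:
                    raise ValidationError(
                        f"{iv.name}: end {iv.end} beyond {iv.chrom} length "
                        f"{self.genome[iv.chrom]}"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    def by_name(self) -> dict[str, GenomicInterval]:
        return {iv.name: iv for iv in self.intervals}

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def subset(self, names: Iterable[str]) -> "PeakSet":
        keep = set(names)
        return PeakSet([iv for iv in self.intervals if iv.name in keep], self.genome)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "name": [iv.name for iv in self.intervals],
                "score": [iv.score for iv in self.intervals],
                "strand": [iv.strand for iv in self.intervals],
                "summit": [iv.summit for iv in self.intervals],
            }
        )


class CountMatrix:
    """Integer read counts in features across samples, with sample metadata.

    ``counts`` is features x samples; ``sample_meta`` is indexed by sample id
    with columns ``condition``, ``timepoint`` (minutes) and ``replicate``.
    """

    REQUIRED_META = ("condition", "timepoint", "replicate")

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.copy()
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            flo = np.asarray(arr, dtype=float)
            if not np.all(flo == np.floor(flo)):
                bad = counts.columns[np.where(flo != np.floor(flo))[1][0]]
                raise ValidationError(f"non-integer count in sample {bad!r}")
            counts = counts.astype(np.int64)
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative counts present")
        if counts.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        meta = sample_meta.copy()
        missing_cols = [c for c in self.REQUIRED_META if c not in meta.columns]
        if missing_cols:
            raise ValidationError(f"sample metadata missing columns {missing_cols}")
        table_samples = list(counts.columns)
        meta_samples = list(meta.index)
        only_table = sorted(set(table_samples) - set(meta_samples))
        only_meta = sorted(set(meta_samples) - set(table_samples))
        if only_table or only_meta:
            raise ValidationError(
                f"sample mismatch: in table only {only_table}, in metadata only {only_meta}"
            )
        self.counts = counts
        self.sample_meta = meta.loc[table_samples]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def samples_for(self, condition=None, timepoint=None) -> list[str]:
        m = self.sample_meta
        mask = pd.Series(True, index=m.index)
        if condition is not None:
            mask &= m["condition"] == condition
        if timepoint is not None:
            mask &= m["timepoint"] == timepoint
        return list(m.index[mask])

    def subset_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(feature_ids)], self.sample_meta)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.sample_meta.loc[list(sample_ids)])


class GeneAnnotation:
    """Per-gene TSS table: gene_id, chrom, tss, strand (+ optional class column)."""

    def __init__(self, table: pd.DataFrame):
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"gene table missing columns {sorted(missing)}")
        if table["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id")
        bad = ~table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValidationError(
                f"bad strand for genes {list(table.loc[bad, 'gene_id'])[:5]}"
            )
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def with_classes(self, classes: Mapping[str, str]) -> "GeneAnnotation":
        t = self.table.copy()
        t["class"] = t["gene_id"].map(classes)
        return GeneAnnotation(t)


@dataclass(frozen=True)
class MotifModel:
    """A position probability matrix over ACGT with a 0-order background."""

    name: str
    probs: np.ndarray  # (length, 4)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )  # (4,)
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValidationError(f"{self.name}: probs must be (length, 4)")
        if (probs < 0).any() or (bg < 0).any():
            raise ValidationError(f"{self.name}: negative probabilities")
        rs = probs.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-3):
            raise ValidationError(
                f"{self.name}: probability rows do not sum to 1 (max dev "
                f"{np.abs(rs - 1).max():.3g})"
            )
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-3):
            raise ValidationError(f"{self.name}: background does not sum to 1")
        if self.pseudocount <= 0:
            raise ValidationError(f"{self.name}: pseudocount must be positive")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    def smoothed_probs(self) -> np.ndarray:
        """Pseudocount-smoothed, renormalized position probabilities."""
        p = self.probs + self.pseudocount * self.background[None, :]
        return p / p.sum(axis=1, keepdims=True)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(
            name=self.name + "_rc",
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in months, event 1=death / 0=censored."""

    patient_id: str
    time: float
    event: int
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"{self.patient_id}: negative follow-up time")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.patient_id}: event must be 0 or 1")


# ---------------------------------------------------------------------------
# Peak files


def read_peaks(path: str | Path, format: str = "narrowPeak") -> PeakSet:
    """Read a narrowPeak (10-column) or BED6 file into a PeakSet.

    narrowPeak summits are ``start + column-10 offset``; BED6 records, which
    carry no point source, default to the interval midpoint.
    """
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format {format!r}")
    ncol = 10 if format == "narrowPeak" else 6
    intervals = []
    autonames = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {ncol} columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                score = float(fields[4]) if fields[4] != "." else 0.0
                strand = fields[5]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if name == ".":
                autonames += 1
                name = f"peak_{autonames}"
            if format == "narrowPeak":
                try:
                    offset = int(fields[9])
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
                if offset < 0 or offset >= end - start:
                    raise ValidationError(
                        f"{path}: line {lineno}: summit offset {offset} outside "
                        f"interval of length {end - start}"
                    )
                summit = start + offset
            else:
                summit = (start + end) // 2
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name, score, strand, summit)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
    return PeakSet(intervals)


def write_peaks(peaks: PeakSet, path: str | Path, format: str = "narrowPeak") -> None:
    if format not in ("narrowPeak", "bed6"):
        raise ValueError(f"unknown peak format {format!r}")
    with open(path, "w") as fh:
        for iv in peaks:
            base = [iv.chrom, str(iv.start), str(iv.end), iv.name, f"{iv.score:g}", iv.strand]
            if format == "narrowPeak":
                summit = iv.summit if iv.summit is not None else iv.midpoint
                base += ["0", "-1", "-1", str(summit - iv.start)]
            fh.write("\t".join(base) + "\n")


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a features x samples TSV plus a sample metadata TSV."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


def write_count_table(cm: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")
    cm.sample_meta.to_csv(meta_path, sep="\t")


def read_gene_table(path: str | Path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t"))


def write_gene_table(genes: GeneAnnotation, path: str | Path) -> None:
    genes.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MEME minimal motif format
#
# Parsed directly (rather than through a motif library) because the contract
# here validates the letter-probability rows as printed; round-tripping the
# matrix through integer counts would erase exactly what is being checked.


def read_meme_motif(path: str | Path) -> list[MotifModel]:
    """Parse a minimal MEME text file into MotifModels.

    Background letter frequencies default to uniform 0.25 when the file has
    no background block.  Rows of the letter-probability matrix must sum to 1
    within 1e-3.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not any(ln.strip().startswith("MEME version") for ln in lines):
        raise ParseError(f"{path}: missing 'MEME version' header")
    background = np.full(4, 0.25)
    motifs: list[MotifModel] = []
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("ALPHABET"):
            alpha = ln.split("=", 1)[-1].strip()
            if alpha != "ACGT":
                raise ParseError(f"{path}: unsupported alphabet {alpha!r}")
        elif ln.startswith("Background letter frequencies"):
            i += 1
            toks: list[str] = []
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                toks += lines[i].split()
                i += 1
            freq = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            if set(freq) != set(ALPHABET):
                raise ParseError(f"{path}: background letters {sorted(freq)} != ACGT")
            background = np.array([freq[b] for b in ALPHABET])
            continue
        elif ln.startswith("MOTIF"):
            name = ln.split()[1] if len(ln.split()) > 1 else f"motif_{len(motifs) + 1}"
            i += 1
            width = None
            while i < len(lines):
                s = lines[i].strip()
                if s.startswith("letter-probability matrix"):
                    toks = s.replace("=", " = ").split()
                    if "w" in toks:
                        width = int(toks[toks.index("w") + 2])
                    i += 1
                    break
                if s.startswith("MOTIF"):
                    raise ParseError(f"{path}: motif {name} has no probability matrix")
                i += 1
            rows = []
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                try:
                    row = [float(x) for x in s.split()]
                except ValueError:
                    break
                if len(row) != 4:
                    raise ParseError(
                        f"{path}: motif {name}: expected 4 probabilities, got {len(row)}"
                    )
                rows.append(row)
                i += 1
            if not rows:
                raise ParseError(f"{path}: motif {name}: empty probability matrix")
            if width is not None and len(rows) != width:
                raise ParseError(
                    f"{path}: motif {name}: declared w={width} but {len(rows)} rows"
                )
            motifs.append(MotifModel(name=name, probs=np.array(rows), background=background))
            continue
        i += 1
    if not motifs:
        raise ParseError(f"{path}: no MOTIF blocks found")
    return motifs


def write_meme_motif(motifs: Sequence[MotifModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifs[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.6f}" for b, p in zip(ALPHABET, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m)} nsites= 20 E= 0\n")
            for row in m.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Survival tables


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a survival TSV: patient_id, time, event, then covariate columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"patient_id", "time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"survival table missing columns {sorted(missing)}")
    covar_cols = [c for c in df.columns if c not in required]
    return [
        SurvivalRecord(
            patient_id=str(row["patient_id"]),
            time=float(row["time"]),
            event=int(row["event"]),
            covariates={c: row[c] for c in covar_cols},
        )
        for _, row in df.iterrows()
    ]


def write_survival_table(records: Sequence[SurvivalRecord], path: str | Path) -> None:
    covar_cols = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "time": r.time, "event": r.event}
        row.update({c: r.covariates.get(c) for c in covar_cols})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
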